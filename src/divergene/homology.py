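"""Gene-family construction from similarity hits, plus ORF utilities.

Paralogs are each sequence's best within-genotype homolog and orthologs
its best cross-genotype homolog, both under an e-value cutoff (default
1e-10).  Families are connected components of the best-hit graph
(single linkage); a reciprocal-best-hit-only mode restricts ortholog
edges to mutual best hits.

The similarity search itself is external: the module consumes 12-column
tabular hits (the common outfmt-6 dialect).  Helpers are provided to run
a local nucleotide BLAST when the binaries are on PATH, and an exact
Smith-Waterman aligner (match 1, mismatch -1, gap -2) for desk-scale
inputs.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from Bio.Seq import Seq

__all__ = [
    "SimilarityHit",
    "HomologyFamily",
    "ORF",
    "best_hits",
    "build_families",
    "longest_orf",
    "smith_waterman",
    "sw_hits",
    "blastn_hits",
    "read_hits",
    "write_hits",
]

HIT_COLUMNS = [
    "query_id",
    "subject_id",
    "identity_pct",
    "aln_length",
    "mismatches",
    "gap_opens",
    "q_start",
    "q_end",
    "s_start",
    "s_end",
    "e_value",
    "bitscore",
]


@dataclass(frozen=True)
class SimilarityHit:
    query_id: str
    subject_id: str
    e_value: float
    bitscore: float
    identity_pct: float = 100.0
    aln_length: int = 0


@dataclass
class HomologyFamily:
    family_id: str
    members: dict[str, list[str]]  # genotype -> sorted member ids
    ortholog_pairs: list[tuple[str, str]] = field(default_factory=list)
    paralog_links: list[tuple[str, str]] = field(default_factory=list)

    @property
    def genotypes(self) -> list[str]:
        return sorted(g for g, ids in self.members.items() if ids)

    @property
    def is_shared(self) -> bool:
        return len(self.genotypes) > 1


def best_hits(hits: Iterable[SimilarityHit], cutoff: float = 1e-10) -> dict[str, SimilarityHit]:
    """Best surviving hit per query under the e-value cutoff.

    Self-hits are ignored.  Ties on e-value break by higher bitscore, then
    lexicographically smallest subject id.  Queries with no surviving hit
    are absent from the output.
    """
    best: dict[str, SimilarityHit] = {}
    for h in hits:
        if h.query_id == h.subject_id:
            continue
        if not (h.e_value < cutoff):
            continue
        cur = best.get(h.query_id)
        if cur is None:
            best[h.query_id] = h
            continue
        key = (h.e_value, -h.bitscore, h.subject_id)
        cur_key = (cur.e_value, -cur.bitscore, cur.subject_id)
        if key < cur_key:
            best[h.query_id] = h
    return best


def _genotype_of(seq_id: str, genotype_ids: Mapping[str, Iterable[str]]) -> str:
    for g, ids in genotype_ids.items():
        if seq_id in ids:
            return g
    raise KeyError(f"sequence id {seq_id!r} not assigned to any genotype")


def build_families(
    best_within: Mapping[str, Mapping[str, SimilarityHit]],
    best_between: Mapping[str, SimilarityHit],
    genotype_ids: Mapping[str, Iterable[str]],
    *,
    reciprocal_only: bool = False,
) -> tuple[list[HomologyFamily], dict[str, int]]:
    """Cluster best-hit edges into gene families and count the Venn layout.

    ``best_within`` maps genotype -> per-query best within-genotype hit;
    ``best_between`` is the pooled per-query best cross-genotype hit map.
    ``genotype_ids`` assigns every emitted sequence id to its genotype and
    defines the universe for the unique-unigene counts.  Ids must be
    disjoint across genotypes.

    With ``reciprocal_only`` cross-genotype edges require mutual best hits.
    Returns the families (only components containing at least one edge)
    and a summary dict with family/member/unique counts per genotype.
    """
    sets = {g: set(ids) for g, ids in genotype_ids.items()}
    names = sorted(sets)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            clash = sets[a] & sets[b]
            if clash:
                raise ValueError(
                    f"sequence ids present in both {a} and {b} (e.g. {sorted(clash)[0]!r}); "
                    "namespace ids per genotype"
                )
    id2geno = {sid: g for g, ids in sets.items() for sid in ids}

    graph = nx.Graph()
    paralog_edges: set[tuple[str, str]] = set()
    ortholog_edges: set[tuple[str, str]] = set()
    for g, bh in best_within.items():
        for q, hit in bh.items():
            e = tuple(sorted((q, hit.subject_id)))
            paralog_edges.add(e)
            graph.add_edge(*e)
    for q, hit in best_between.items():
        if reciprocal_only:
            back = best_between.get(hit.subject_id)
            if back is None or back.subject_id != q:
                continue
        e = tuple(sorted((q, hit.subject_id)))
        ortholog_edges.add(e)
        graph.add_edge(*e)

    for node in graph.nodes:
        if node not in id2geno:
            raise KeyError(f"hit references unknown sequence id {node!r}")

    families: list[HomologyFamily] = []
    components = sorted(nx.connected_components(graph), key=lambda c: min(c))
    for k, comp in enumerate(components):
        members: dict[str, list[str]] = {g: [] for g in names}
        for sid in sorted(comp):
            members[id2geno[sid]].append(sid)
        fam = HomologyFamily(family_id=f"FAM{k + 1:05d}", members=members)
        fam.ortholog_pairs = sorted(e for e in ortholog_edges if e[0] in comp)
        fam.paralog_links = sorted(e for e in paralog_edges if e[0] in comp)
        families.append(fam)

    shared = [f for f in families if f.is_shared]
    clustered_shared = {sid for f in shared for ids in f.members.values() for sid in ids}
    summary: dict[str, int] = {"families_total": len(families), "families_shared": len(shared)}
    for g in names:
        in_shared = sum(len(f.members[g]) for f in shared)
        summary[f"members_{g}"] = in_shared
        summary[f"unique_{g}"] = len(sets[g] - clustered_shared)
    return families, summary


@dataclass(frozen=True)
class ORF:
    """An open reading frame; coordinates 1-based inclusive on the forward strand."""

    start: int
    end: int
    strand: str  # "+" or "-"
    frame: int  # 0,1,2 offset within the strand
    translation: str

    @property
    def length_nt(self) -> int:
        return self.end - self.start + 1


_STOPS = {"TAA", "TAG", "TGA"}


def longest_orf(sequence: str, min_length: int = 30) -> ORF | None:
    """Longest ATG-to-stop ORF over all six frames (standard code).

    The ORF length includes the stop codon; the translation does not.
    ORFs running off the sequence end without a stop are not counted.
    Ties break toward the forward strand, then the smallest forward-strand
    start.  Returns None when no ORF reaches ``min_length`` nucleotides.
    """
    seq = sequence.upper()
    if set(seq) - set("ACGTN"):
        raise ValueError("sequence must be over the ACGTN alphabet")
    L = len(seq)
    candidates: list[tuple[int, int, int, str, int, str]] = []
    for strand, s in (("+", seq), ("-", str(Seq(seq).reverse_complement()))):
        for frame in range(3):
            start_idx = None
            for i in range(frame, L - 2, 3):
                codon = s[i : i + 3]
                if start_idx is None:
                    if codon == "ATG":
                        start_idx = i
                elif codon in _STOPS:
                    orf_len = i + 3 - start_idx
                    if orf_len >= min_length:
                        if strand == "+":
                            fwd_start, fwd_end = start_idx + 1, i + 3
                        else:
                            fwd_start, fwd_end = L - (i + 3) + 1, L - start_idx
                        prot = str(Seq(s[start_idx:i]).translate())
                        # sort key: longest first, forward strand first, smallest start
                        candidates.append(
                            (-orf_len, 0 if strand == "+" else 1, fwd_start, strand, frame, prot)
                        )
                    start_idx = None
    if not candidates:
        return None
    neg_len, _, start, strand, frame, prot = min(candidates)
    return ORF(start=start, end=start - neg_len - 1, strand=strand, frame=frame, translation=prot)


def smith_waterman(a: str, b: str, match: int = 1, mismatch: int = -1, gap: int = -2):
    """Exact local alignment score and identity; desk-scale inputs only.

    Returns (score, identity_fraction, alignment_length).
    """
    a, b = a.upper(), b.upper()
    n, m = len(a), len(b)
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    av = np.frombuffer(a.encode(), dtype=np.uint8)
    bv = np.frombuffer(b.encode(), dtype=np.uint8)
    for i in range(1, n + 1):
        sub = np.where(bv == av[i - 1], match, mismatch)
        row_prev = H[i - 1]
        row = H[i]
        diag = row_prev[:-1] + sub
        up = row_prev[1:] + gap
        best = np.maximum(np.maximum(diag, up), 0)
        # left-gap dependency is sequential within the row
        run = 0
        for j in range(m):
            run = max(best[j], run + gap, 0)
            row[j + 1] = run
    score = int(H.max())
    if score == 0:
        return 0, 0.0, 0
    i, j = np.unravel_index(int(H.argmax()), H.shape)
    matches = 0
    length = 0
    while i > 0 and j > 0 and H[i, j] > 0:
        sub = match if a[i - 1] == b[j - 1] else mismatch
        if H[i, j] == H[i - 1, j - 1] + sub:
            matches += a[i - 1] == b[j - 1]
            i, j = i - 1, j - 1
        elif H[i, j] == H[i - 1, j] + gap:
            i -= 1
        else:
            j -= 1
        length += 1
    return score, matches / length, length


def sw_hits(
    queries: Mapping[str, str],
    subjects: Mapping[str, str],
    *,
    min_score: int = 20,
) -> list[SimilarityHit]:
    """All-vs-all Smith-Waterman hits with a crude bit-score style e-value.

    The surrogate e-value m*n*2^-score is only meant to rank hits and pass
    a cutoff on toy data; real pipelines should use :func:`blastn_hits`.
    """
    hits = []
    total = sum(map(len, queries.values())) * sum(map(len, subjects.values()))
    for q, qs in queries.items():
        for s, ss in subjects.items():
            if q == s:
                continue
            score, ident, length = smith_waterman(qs, ss)
            if score >= min_score:
                hits.append(
                    SimilarityHit(
                        query_id=q,
                        subject_id=s,
                        e_value=float(total) * 2.0 ** (-score),
                        bitscore=float(score),
                        identity_pct=100.0 * ident,
                        aln_length=length,
                    )
                )
    return hits


def blastn_hits(
    queries: Mapping[str, str],
    subjects: Mapping[str, str],
    *,
    evalue: float = 1e-10,
) -> list[SimilarityHit]:
    """Run a local nucleotide BLAST (makeblastdb + blastn, outfmt 6)."""
    for exe in ("makeblastdb", "blastn"):
        if shutil.which(exe) is None:
            raise RuntimeError(f"{exe} not found on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        qf, sf = tmp / "q.fa", tmp / "s.fa"
        for path, seqs in ((qf, queries), (sf, subjects)):
            with open(path, "w") as fh:
                for sid, seq in seqs.items():
                    fh.write(f">{sid}\n{seq}\n")
        subprocess.run(
            ["makeblastdb", "-in", str(sf), "-dbtype", "nucl"],
            check=True,
            capture_output=True,
        )
        out = tmp / "hits.tsv"
        subprocess.run(
            [
                "blastn",
                "-query",
                str(qf),
                "-db",
                str(sf),
                "-evalue",
                str(evalue),
                "-outfmt",
                "6",
                "-out",
                str(out),
            ],
            check=True,
            capture_output=True,
        )
        return read_hits(out)


def read_hits(path) -> list[SimilarityHit]:
    """Read 12-column tabular similarity hits (outfmt-6 dialect)."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=HIT_COLUMNS)
    except pd.errors.EmptyDataError:
        return []
    return [
        SimilarityHit(
            query_id=str(r.query_id),
            subject_id=str(r.subject_id),
            e_value=float(r.e_value),
            bitscore=float(r.bitscore),
            identity_pct=float(r.identity_pct),
            aln_length=int(r.aln_length),
        )
        for r in df.itertuples()
    ]


def write_hits(hits: Sequence[SimilarityHit], path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.identity_pct:.2f}\t{h.aln_length}"
                f"\t0\t0\t0\t0\t0\t0\t{h.e_value:.3g}\t{h.bitscore:.1f}\n"
            )
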