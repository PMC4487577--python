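"""Microsatellite (SSR) detection and cross-genotype polymorphism calling.

Detection finds all maximal perfect tandem repeats of primitive 1-6 nt
motifs in sequences above a length cutoff (default 1 kb), resolves
overlaps longest-first, and attaches up to 300 nt of flanking sequence on
each side for primer design.  Matched SSR loci between ortholog pairs that
differ in tract length are emitted as polymorphic; a locus pair passes the
primer-design rule when the length divergence exceeds two nucleotides.

Coordinates are 1-based inclusive throughout.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import edlib
import pandas as pd

__all__ = [
    "SSRLocus",
    "PolymorphicSSR",
    "DEFAULT_THRESHOLDS",
    "canonical_motif",
    "detect_ssrs",
    "classify_ssrs",
    "match_polymorphic",
    "export_primer_regions",
]

# Minimum repeat counts per unit length 1..6.  The source study's marker
# panel contains loci as short as (T)8 and (TGT)4, looser than the common
# MISA defaults (mono>=10, di>=6, tri>=5); these defaults keep such loci.
DEFAULT_THRESHOLDS: dict[int, int] = {1: 8, 2: 6, 3: 4, 4: 4, 5: 4, 6: 4}

DEFAULT_MIN_SEQ_LEN = 1000
FLANK_LEN = 300

_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def _is_primitive(motif: str) -> bool:
    """True when the motif is not itself a repeat of a shorter unit."""
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return False
    return True


def canonical_motif(motif: str) -> str:
    """Orientation- and phase-independent motif label.

    The lexicographically smallest string among all rotations of the motif
    and of its reverse complement, so that e.g. TGT, GTT, TTG and their
    complements ACA, CAA, AAC all map to AAC.
    """
    variants = []
    for m in (motif, _revcomp(motif)):
        variants.extend(m[i:] + m[:i] for i in range(len(m)))
    return min(variants)


@dataclass(frozen=True)
class SSRLocus:
    unigene_id: str
    motif: str
    canonical: str
    unit: int
    repeats: int
    start: int  # 1-based inclusive
    end: int
    upstream_flank: str
    downstream_flank: str

    @property
    def tract_length(self) -> int:
        return self.unit * self.repeats


@dataclass(frozen=True)
class PolymorphicSSR:
    id_a: str
    id_b: str
    locus_a: SSRLocus
    locus_b: SSRLocus
    divergence_nt: int
    passes_primer_rule: bool


def _maximal_tracts(seq: str, thresholds: Mapping[int, int]):
    """All maximal perfect repeat tracts of primitive motifs, phase-leftmost.

    A tract of unit u starts at i when seq[j] == seq[j+u] holds along it;
    it is reported from its leftmost base with floor(len/u) full copies.
    Motifs containing N are skipped.
    """
    L = len(seq)
    tracts = []
    for u, min_reps in sorted(thresholds.items()):
        if u < 1:
            raise ValueError("unit lengths must be >= 1")
        i = 0
        while i + u < L:
            if seq[i] != seq[i + u]:
                i += 1
                continue
            # maximal periodic region: seq[k] == seq[k+u] for k in [i, j]
            j = i
            while j + 1 + u < L and seq[j + 1] == seq[j + 1 + u]:
                j += 1
            span = j + u - i + 1
            reps = span // u
            motif = seq[i : i + u]
            if reps >= min_reps and _is_primitive(motif) and "N" not in motif:
                tracts.append((i, u, reps, motif))
            # periodicity fails at j+1, so the next region starts at j+2 earliest
            i = j + 2
    return tracts


def detect_ssrs(
    sequences: Mapping[str, str],
    thresholds: Mapping[int, int] | None = None,
    min_seq_len: int = DEFAULT_MIN_SEQ_LEN,
    flank_len: int = FLANK_LEN,
) -> list[SSRLocus]:
    """Detect SSR loci in every sequence at least ``min_seq_len`` long.

    Overlapping tracts (e.g. a mononucleotide run inside a longer
    dinucleotide region) are resolved longest-first; ties by smaller
    start, then smaller unit.  Flanks of up to ``flank_len`` nt are
    attached, truncated at sequence ends.
    """
    thresholds = dict(DEFAULT_THRESHOLDS if thresholds is None else thresholds)
    out: list[SSRLocus] = []
    for sid in sorted(sequences):
        seq = sequences[sid].upper()
        bad = set(seq) - set("ACGTN")
        if bad:
            raise ValueError(f"sequence {sid!r} contains non-ACGTN characters: {sorted(bad)}")
        if len(seq) < min_seq_len:
            continue
        tracts = _maximal_tracts(seq, thresholds)
        tracts.sort(key=lambda t: (-t[1] * t[2], t[0], t[1]))
        taken: list[tuple[int, int]] = []
        kept = []
        for i, u, reps, motif in tracts:
            lo, hi = i, i + u * reps - 1
            if any(not (hi < a or lo > b) for a, b in taken):
                continue
            taken.append((lo, hi))
            kept.append((i, u, reps, motif))
        for i, u, reps, motif in sorted(kept):
            lo, hi = i, i + u * reps - 1
            out.append(
                SSRLocus(
                    unigene_id=sid,
                    motif=motif,
                    canonical=canonical_motif(motif),
                    unit=u,
                    repeats=reps,
                    start=lo + 1,
                    end=hi + 1,
                    upstream_flank=seq[max(0, lo - flank_len) : lo],
                    downstream_flank=seq[hi + 1 : hi + 1 + flank_len],
                )
            )
    return out


_CLASS_NAMES = {1: "mono", 2: "di", 3: "tri", 4: "tetra", 5: "penta", 6: "hexa"}


def classify_ssrs(loci: Iterable[SSRLocus | int]) -> pd.DataFrame:
    """Counts and percentages per motif-length class (mono .. hexa).

    Accepts SSRLocus objects or bare unit lengths.  Percentages are of the
    total, rounded to two decimals.
    """
    units = [l.unit if isinstance(l, SSRLocus) else int(l) for l in loci]
    counts = Counter(units)
    total = sum(counts.values())
    rows = []
    for u in range(1, 7):
        c = counts.get(u, 0)
        rows.append(
            {
                "ssr_class": _CLASS_NAMES[u],
                "unit": u,
                "count": c,
                "percentage": round(100.0 * c / total, 2) if total else 0.0,
            }
        )
    return pd.DataFrame(rows)


def _flank_anchor_ok(a: SSRLocus, b: SSRLocus, anchor_len: int, min_identity: float) -> bool:
    """Check the inner ``anchor_len`` nt of both flanks agree between loci.

    Flanks are compared over their common length (inner-anchored), so a
    flank truncated at a sequence end is not penalized for being short.
    """
    sides = (
        (a.upstream_flank, b.upstream_flank, True),
        (a.downstream_flank, b.downstream_flank, False),
    )
    for fa, fb, inner_is_suffix in sides:
        k = min(len(fa), len(fb), anchor_len)
        if k == 0:
            continue  # fully truncated flank: no evidence against the match
        fa, fb = (fa[-k:], fb[-k:]) if inner_is_suffix else (fa[:k], fb[:k])
        dist = edlib.align(fa, fb, task="distance")["editDistance"]
        if 1.0 - dist / k < min_identity:
            return False
    return True


def match_polymorphic(
    ssrs_a: Sequence[SSRLocus],
    ssrs_b: Sequence[SSRLocus],
    ortholog_pairs: Iterable[tuple[str, str]],
    min_divergence: int = 1,
    *,
    primer_rule_nt: int = 2,
    anchor_len: int = 50,
    anchor_identity: float = 0.8,
) -> list[PolymorphicSSR]:
    """Call SSR length polymorphisms between ortholog pairs.

    Within each ortholog pair, loci are grouped by canonical motif and
    matched in rank order along each sequence; matches must agree over the
    inner ``anchor_len`` nt of both flanks at >= ``anchor_identity``.
    Matched loci whose repeat tracts differ by at least ``min_divergence``
    nt are returned; ``passes_primer_rule`` marks divergence strictly
    greater than ``primer_rule_nt``.
    """
    by_seq_a: dict[str, list[SSRLocus]] = {}
    by_seq_b: dict[str, list[SSRLocus]] = {}
    for loci, acc in ((ssrs_a, by_seq_a), (ssrs_b, by_seq_b)):
        for l in loci:
            acc.setdefault(l.unigene_id, []).append(l)
    out: list[PolymorphicSSR] = []
    for id_a, id_b in ortholog_pairs:
        la = sorted(by_seq_a.get(id_a, []), key=lambda l: l.start)
        lb = sorted(by_seq_b.get(id_b, []), key=lambda l: l.start)
        if not la or not lb:
            continue
        groups_a: dict[str, list[SSRLocus]] = {}
        groups_b: dict[str, list[SSRLocus]] = {}
        for l in la:
            groups_a.setdefault(l.canonical, []).append(l)
        for l in lb:
            groups_b.setdefault(l.canonical, []).append(l)
        for motif in sorted(set(groups_a) & set(groups_b)):
            for a, b in zip(groups_a[motif], groups_b[motif]):
                if not _flank_anchor_ok(a, b, anchor_len, anchor_identity):
                    continue
                div = abs(a.tract_length - b.tract_length)
                if div >= max(1, min_divergence):
                    out.append(
                        PolymorphicSSR(
                            id_a=id_a,
                            id_b=id_b,
                            locus_a=a,
                            locus_b=b,
                            divergence_nt=div,
                            passes_primer_rule=div > primer_rule_nt,
                        )
                    )
    return out


def export_primer_regions(
    polymorphic: Iterable[PolymorphicSSR],
    min_flank: int = 50,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Primer-design-ready records for polymorphic loci.

    Returns (records, flagged): loci whose shorter flank is below
    ``min_flank`` nt are flagged instead of emitted.  Each record carries
    the template (upstream + tract + downstream of the first genotype's
    locus) and the 1-based inclusive target span within that template.
    """
    records, flagged = [], []
    for p in polymorphic:
        a = p.locus_a
        row = {
            "id_a": p.id_a,
            "id_b": p.id_b,
            "motif": a.motif,
            "repeats_a": a.repeats,
            "repeats_b": p.locus_b.repeats,
            "divergence_nt": p.divergence_nt,
            "passes_primer_rule": p.passes_primer_rule,
        }
        if min(len(a.upstream_flank), len(a.downstream_flank)) < min_flank:
            flagged.append({**row, "reason": f"flank shorter than {min_flank} nt"})
            continue
        template = a.upstream_flank + a.motif * a.repeats + a.downstream_flank
        row.update(
            template=template,
            target_start=len(a.upstream_flank) + 1,
            target_end=len(a.upstream_flank) + a.tract_length,
        )
        records.append(row)
    return pd.DataFrame(records), pd.DataFrame(flagged)
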