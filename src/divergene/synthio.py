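"""Synthetic two-genotype transcriptome generator with planted ground truth.

Every input the pipeline consumes can be generated here: paired unigene
sets for a susceptible (P) and a resistant (G) genotype with planted
ortholog pairs, within-genotype paralogs, SSR length polymorphisms and
SNPs at a chosen transition/transversion mix; two-condition read-count
tables with planted differentially expressed genes; gene-to-term
annotation maps with planted enriched terms; SNP call-record tables;
diploid SSR genotype matrices drawn under Hardy-Weinberg from known
allele frequencies; and qPCR Ct tables with known fold changes.

The planted features are returned as a :class:`GroundTruth` object so
each downstream stage supports parameter-recovery testing: the planted
polymorphic-SSR count is recoverable exactly, ortholog pairs as shared
families, the transition fraction and allele frequencies within sampling
error.

Each generator stage draws from its own RNG stream derived from the
master seed, so adding a stage never perturbs earlier outputs, and a
fixed seed reproduces byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .expression import CountRow, CtRecord
from .popdiv import GenotypeMatrix
from .snpmine import SNPRecord
from .ssrmine import DEFAULT_THRESHOLDS, _maximal_tracts

__all__ = [
    "SynthSpec",
    "GroundTruth",
    "UnigeneSet",
    "PlantedSSR",
    "PlantedSNP",
    "generate_transcriptomes",
    "generate_counts",
    "generate_annotations",
    "generate_snp_calls",
    "generate_genotype_matrix",
    "generate_ct_records",
    "write_all",
]

# motif classes mirroring common plant EST-SSR marker panels
SSR_MOTIFS = [
    "T", "A", "G",
    "TC", "CT", "GA", "AG",
    "TGT", "TCC", "TTC", "GAA", "TGA", "TTG", "GGC", "GCG", "CTC", "CCA", "GGT",
    "TCTT",
]

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}

# stage tags for per-stage RNG streams
_STAGES = {
    "sequences": 1,
    "counts": 2,
    "annotation": 3,
    "snp_calls": 4,
    "genotypes": 5,
    "ct": 6,
}


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of the synthetic study.

    Scales are deliberately modest (hundreds of gene families, 1e6-read
    libraries) so full pipeline runs stay fast while every filter and
    threshold downstream is still exercised.
    """

    seed: int = 0
    n_families: int = 200
    paralog_rate: float = 0.25
    orf_fraction: float = 0.9
    snp_rate: float = 0.01
    tstv_ratio: float = 1.5
    ssr_plant_rate: float = 0.15
    ssr_poly_rate: float = 0.32
    n_de_genes: int = 20
    de_fold: float = 4.0
    library_size: int = 1_000_000
    n_accessions: int = 32
    n_markers: int = 30
    allele_freqs: tuple[tuple[float, ...], ...] | None = None
    missing_rate: float = 0.0031
    # fraction of families whose sequence exceeds 1 kb (SSR length filter)
    long_fraction: float = 0.6
    # planted SNPs keep at least this spacing, so the 5-bp interval filter
    # retains every planted SNP and expected survivor counts are exact
    snp_min_spacing: int = 6
    n_terms: int = 30
    n_enriched_terms: int = 3
    decoy_snp_rate: float = 0.1
    ambiguity_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "paralog_rate", "orf_fraction", "snp_rate", "ssr_plant_rate",
            "ssr_poly_rate", "missing_rate", "long_fraction", "decoy_snp_rate",
            "ambiguity_rate",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.tstv_ratio <= 0:
            raise ValueError(f"tstv_ratio must be > 0, got {self.tstv_ratio}")
        if self.de_fold <= 1:
            raise ValueError(f"de_fold must be > 1, got {self.de_fold}")
        for name in ("n_families", "n_de_genes", "n_accessions", "n_markers",
                     "n_terms", "n_enriched_terms"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.library_size <= 0:
            raise ValueError(f"library_size must be positive, got {self.library_size}")
        if self.snp_min_spacing < 1:
            raise ValueError(f"snp_min_spacing must be >= 1, got {self.snp_min_spacing}")
        if self.allele_freqs is not None:
            for i, fv in enumerate(self.allele_freqs):
                if abs(sum(fv) - 1.0) > 1e-9:
                    raise ValueError(f"allele_freqs[{i}] must sum to 1 (+-1e-9)")

    def rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng([_STAGES[stage], self.seed])


@dataclass(frozen=True)
class PlantedSSR:
    family: int
    motif: str
    unit: int
    repeats_p: int
    repeats_g: int
    position: int  # 1-based start in base (pre-insertion) coordinates

    @property
    def divergence_nt(self) -> int:
        return abs(self.repeats_p - self.repeats_g) * self.unit

    @property
    def is_polymorphic(self) -> bool:
        return self.repeats_p != self.repeats_g


@dataclass(frozen=True)
class PlantedSNP:
    family: int
    position: int  # 1-based in base coordinates
    allele_p: str
    allele_g: str
    is_transition: bool


@dataclass
class UnigeneSet:
    genotype: str
    sequences: dict[str, str]

    def __len__(self) -> int:
        return len(self.sequences)

    def lengths(self) -> list[int]:
        return [len(s) for s in self.sequences.values()]

    def write_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in sorted(self.sequences.items())
        ]
        SeqIO.write(records, str(path), "fasta")

    @classmethod
    def read_fasta(cls, path, genotype: str) -> "UnigeneSet":
        seqs = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}
        return cls(genotype=genotype, sequences=seqs)


@dataclass
class GroundTruth:
    ortholog_pairs: list[tuple[str, str]] = field(default_factory=list)
    paralog_sets: dict[str, list[list[str]]] = field(default_factory=dict)
    planted_ssrs: list[PlantedSSR] = field(default_factory=list)
    planted_snps: list[PlantedSNP] = field(default_factory=list)
    de_genes: list[tuple[str, str, float]] = field(default_factory=list)
    enriched_terms: list[str] = field(default_factory=list)
    marker_allele_freqs: list[dict[str, tuple[float, ...]]] = field(default_factory=list)
    group_assignments: list[str] = field(default_factory=list)
    # P-genotype coordinate of each planted SNP (after SSR insertion shifts)
    snp_positions_p: list[tuple[str, int]] = field(default_factory=list)

    @property
    def n_polymorphic_ssrs(self) -> int:
        return sum(s.is_polymorphic for s in self.planted_ssrs)

    @property
    def n_primer_rule_ssrs(self) -> int:
        return sum(s.is_polymorphic and s.divergence_nt > 2 for s in self.planted_ssrs)

    def transition_fraction(self) -> float:
        if not self.planted_snps:
            return float("nan")
        return sum(s.is_transition for s in self.planted_snps) / len(self.planted_snps)


_SCRUB_THRESHOLDS = {u: max(2, t - 2) for u, t in DEFAULT_THRESHOLDS.items()}
_BASES = "ACGT"


def _scrub_repeats(seq: list[str], protected: range | None = None) -> None:
    """Destroy incidental tandem repeats in-place.

    Any maximal tract reaching two repeats below the detection thresholds
    is broken by rewriting its middle base, so chance repeats (including
    ones created by planted substitutions) never reach the detector's
    thresholds and planted SSR loci stay the only detectable ones.
    """
    for _ in range(50):
        tracts = _maximal_tracts("".join(seq), _SCRUB_THRESHOLDS)
        dirty = False
        for i, u, reps, motif in tracts:
            lo, hi = i, i + u * reps - 1
            if protected is not None and not (hi < protected.start or lo > protected[-1]):
                continue
            mid = (lo + hi) // 2
            cur = seq[mid]
            left = seq[mid - 1] if mid > 0 else ""
            right = seq[mid + 1] if mid + 1 < len(seq) else ""
            repl = next(b for b in _BASES if b != cur and b != left and b != right)
            seq[mid] = repl
            dirty = True
        if not dirty:
            return


def _plant_orf(seq: list[str], rng: np.random.Generator) -> None:
    """Embed a clean ATG..stop ORF covering most of the sequence middle."""
    L = len(seq)
    span = min(L - 60, max(90, int(0.5 * L)))
    span -= span % 3
    start = int(rng.integers(30, L - span - 3))
    start -= start % 3
    seq[start : start + 3] = list("ATG")
    stops = {"TAA", "TAG", "TGA"}
    for i in range(start + 3, start + span - 3, 3):
        if "".join(seq[i : i + 3]) in stops:
            seq[i] = "C"
    seq[start + span - 3 : start + span] = list("TAA")


def generate_transcriptomes(spec: SynthSpec) -> tuple[UnigeneSet, UnigeneSet, GroundTruth]:
    """Generate the paired P/G unigene sets and the planted ground truth.

    Each family derives from one random base sequence; the two genotype
    copies differ by planted SNPs (transition with probability
    tstv_ratio / (tstv_ratio + 1)) and, where planted, by SSR repeat-count
    differences.  Paralogs are within-genotype copies mutated at 5% per
    base.  SSRs are only planted in families whose sequence exceeds 1 kb,
    so the detector's length filter passes exactly the planted loci.
    """
    rng = spec.rng("sequences")
    truth = GroundTruth(paralog_sets={"P": [], "G": []})
    p_seqs: dict[str, str] = {}
    g_seqs: dict[str, str] = {}

    for fam in range(spec.n_families):
        long_seq = rng.random() < spec.long_fraction
        L = int(rng.integers(1100, 2001)) if long_seq else int(rng.integers(300, 901))
        base = list(rng.choice(list(_BASES), size=L))
        _scrub_repeats(base)
        if rng.random() < spec.orf_fraction:
            _plant_orf(base, rng)
            _scrub_repeats(base)

        # --- SSR planting (long sequences only) ---
        planted: PlantedSSR | None = None
        if long_seq and rng.random() < spec.ssr_plant_rate:
            motif = str(rng.choice(SSR_MOTIFS))
            u = len(motif)
            base_reps = {1: (9, 14), 2: (6, 9), 3: (4, 7), 4: (5, 7)}[u]
            reps_p = int(rng.integers(*base_reps))
            reps_g = reps_p
            if rng.random() < spec.ssr_poly_rate:
                delta = int(rng.integers(1, 4)) * (1 if rng.random() < 0.5 else -1)
                reps_g = max(DEFAULT_THRESHOLDS[u], reps_p + delta)
                if reps_g == reps_p:
                    reps_g = reps_p + abs(delta)
            pos = int(rng.integers(400, L - 400 - u * max(reps_p, reps_g)))
            # boundary guards: no full-copy extension, left edge fixed at pos
            base[pos - 1] = next(b for b in _BASES if b != motif[-1] and b != base[pos - 2])
            planted = PlantedSSR(
                family=fam, motif=motif, unit=u, repeats_p=reps_p, repeats_g=reps_g,
                position=pos + 1,
            )
            truth.planted_ssrs.append(planted)

        # --- SNP planting on base coordinates ---
        p_ts = spec.tstv_ratio / (spec.tstv_ratio + 1.0)
        snps: list[PlantedSNP] = []
        if planted is not None:
            guard_lo = planted.position - 2
            guard_hi = planted.position + planted.unit * max(planted.repeats_p, planted.repeats_g) + 1
        else:
            guard_lo, guard_hi = -1, -1
        last = -(10**9)
        hits = np.flatnonzero(rng.random(L) < spec.snp_rate)
        for pos0 in hits:
            pos0 = int(pos0)
            if pos0 < 2 or pos0 > L - 3:
                continue
            if guard_lo - 2 <= pos0 + 1 <= guard_hi + 1:
                continue
            if pos0 - last < spec.snp_min_spacing:
                continue
            last = pos0
            ref = base[pos0]
            if rng.random() < p_ts:
                alt, is_ts = _TRANSITION[ref], True
            else:
                alt, is_ts = _TRANSVERSIONS[ref][int(rng.integers(2))], False
            snps.append(
                PlantedSNP(family=fam, position=pos0 + 1, allele_p=ref, allele_g=alt,
                           is_transition=is_ts)
            )
        truth.planted_snps.extend(snps)

        # --- assemble the two genotype copies ---
        def build(reps: int, alleles: dict[int, str]) -> tuple[str, int]:
            seq = list(base)
            for pos0, alt in alleles.items():
                seq[pos0] = alt
            if planted is None:
                _scrub_repeats(seq)
                return "".join(seq), 0
            ins = planted.position - 1
            tract = list(planted.motif * reps)
            out = seq[:ins] + tract + seq[ins:]
            # right boundary guard after insertion
            k = ins + len(tract)
            out[k] = next(b for b in _BASES
                          if b != planted.motif[0] and b != (out[k + 1] if k + 1 < len(out) else ""))
            _scrub_repeats(out, protected=range(ins - 1, k + 1))
            return "".join(out), len(tract)

        pid, gid = f"P_fam{fam:04d}", f"G_fam{fam:04d}"
        p_seq, _ = build(planted.repeats_p if planted else 0, {})
        g_seq, _ = build(planted.repeats_g if planted else 0,
                         {s.position - 1: s.allele_g for s in snps})
        p_seqs[pid], g_seqs[gid] = p_seq, g_seq
        truth.ortholog_pairs.append((pid, gid))

        tract_p = 0 if planted is None else planted.unit * planted.repeats_p
        ins0 = -1 if planted is None else planted.position - 1
        for s in snps:
            p_pos = s.position if (ins0 < 0 or s.position - 1 < ins0) else s.position + tract_p
            truth.snp_positions_p.append((pid, p_pos))

        # --- paralogs: mutated within-genotype copies ---
        for geno, seqs, main_id in (("P", p_seqs, pid), ("G", g_seqs, gid)):
            if rng.random() < spec.paralog_rate:
                src = list(seqs[main_id])
                n_mut = max(1, int(round(0.05 * len(src))))
                sites = rng.choice(len(src), size=n_mut, replace=False)
                for site in sites:
                    choices = [b for b in _BASES if b != src[site]]
                    src[site] = choices[int(rng.integers(3))]
                par_id = f"{geno}_fam{fam:04d}_par"
                seqs[par_id] = "".join(src)
                truth.paralog_sets[geno].append([main_id, par_id])

        if spec.ambiguity_rate > 0:
            for seqs, sid in ((p_seqs, pid), (g_seqs, gid)):
                seq = list(seqs[sid])
                for k in np.flatnonzero(rng.random(len(seq)) < spec.ambiguity_rate):
                    k = int(k)
                    if not (guard_lo - 2 <= k + 1 <= guard_hi + 1):
                        seq[k] = "N"
                seqs[sid] = "".join(seq)

    return UnigeneSet("P", p_seqs), UnigeneSet("G", g_seqs), truth


def generate_counts(
    truth: GroundTruth, spec: SynthSpec, sequences: UnigeneSet
) -> list[CountRow]:
    """Two-condition read counts over one genotype's unigenes.

    Baseline expression weights are log-normal; the planted DE genes'
    treated-condition weights are scaled by de_fold (up) or 1/de_fold
    (down).  Counts are multinomial over genes with ``library_size``
    draws per condition, the simplest exchangeable-read model for a
    single library pair.
    """
    rng = spec.rng("counts")
    genes = sorted(sequences.sequences)
    if not genes:
        return []
    weights = rng.lognormal(mean=0.0, sigma=1.0, size=len(genes))
    mains = [g for g in genes if not g.endswith("_par")]
    n_de = min(spec.n_de_genes, len(mains))
    de_idx = rng.choice(len(mains), size=n_de, replace=False)
    truth.de_genes = []
    treated = weights.copy()
    for k, i in enumerate(sorted(int(x) for x in de_idx)):
        gene = mains[i]
        j = genes.index(gene)
        if k % 2 == 0:
            treated[j] *= spec.de_fold
            truth.de_genes.append((gene, "up", spec.de_fold))
        else:
            treated[j] /= spec.de_fold
            truth.de_genes.append((gene, "down", spec.de_fold))
    p_ctrl = weights / weights.sum()
    p_trt = treated / treated.sum()
    c_ctrl = rng.multinomial(spec.library_size, p_ctrl)
    c_trt = rng.multinomial(spec.library_size, p_trt)
    return [
        CountRow(
            gene_id=g,
            length_nt=len(sequences.sequences[g]),
            count_treated=int(c_trt[j]),
            count_control=int(c_ctrl[j]),
            lib_treated=spec.library_size,
            lib_control=spec.library_size,
        )
        for j, g in enumerate(genes)
    ]


def generate_annotations(
    truth: GroundTruth, spec: SynthSpec, genes: Sequence[str]
) -> dict[str, list[str]]:
    """Gene -> term map with planted enriched terms.

    Every gene gets one background term; planted DE genes additionally
    join one of the enriched terms with probability 0.6, making those
    terms genuinely over-represented among DEGs.
    """
    rng = spec.rng("annotation")
    if spec.n_terms < 1:
        return {}
    terms = [f"T{k:03d}" for k in range(spec.n_terms)]
    enriched = terms[: spec.n_enriched_terms]
    truth.enriched_terms = list(enriched)
    de_set = {g for g, _, _ in truth.de_genes}
    out: dict[str, list[str]] = {}
    for g in sorted(genes):
        assigned = {str(rng.choice(terms))}
        if g in de_set and enriched and rng.random() < 0.6:
            assigned.add(str(rng.choice(enriched)))
        out[g] = sorted(assigned)
    return out


def generate_snp_calls(truth: GroundTruth, spec: SynthSpec) -> list[SNPRecord]:
    """SNP call records for every planted SNP, plus low-quality decoys.

    Planted records carry depth > 10 and score > 30 so they all pass the
    quality filters; decoys (a ``decoy_snp_rate`` fraction extra) fail
    depth or score and must be removed by filtering.
    """
    rng = spec.rng("snp_calls")
    records: list[SNPRecord] = []
    used: set[tuple[str, int]] = set()
    for snp, (sid, pos) in zip(truth.planted_snps, truth.snp_positions_p):
        records.append(
            SNPRecord(
                seq_id=sid,
                position=pos,
                ref_allele=snp.allele_p,
                alt_allele=snp.allele_g,
                depth=11 + int(rng.poisson(20)),
                score=31.0 + float(rng.exponential(10.0)),
            )
        )
        used.add((sid, pos))
    n_decoys = int(round(spec.decoy_snp_rate * len(records)))
    seq_ids = sorted({sid for sid, _ in used}) or ["P_fam0000"]
    made = 0
    while made < n_decoys:
        sid = str(rng.choice(seq_ids))
        pos = int(rng.integers(1, 5000))
        if (sid, pos) in used:
            continue
        used.add((sid, pos))
        ref = str(rng.choice(list(_BASES)))
        alt = str(rng.choice([b for b in _BASES if b != ref]))
        if rng.random() < 0.5:
            depth, score = int(rng.integers(0, 11)), 31.0 + float(rng.exponential(10.0))
        else:
            depth, score = 11 + int(rng.poisson(20)), float(rng.uniform(0, 30))
        records.append(SNPRecord(seq_id=sid, position=pos, ref_allele=ref,
                                 alt_allele=alt, depth=depth, score=score))
        made += 1
    return records


@dataclass
class GenotypeTruth:
    allele_freqs: list[dict[str, tuple[float, ...]]]
    group_assignments: list[str]


def generate_genotype_matrix(
    spec: SynthSpec, *, n_groups: int = 1
) -> tuple[GenotypeMatrix, GenotypeTruth]:
    """Diploid SSR genotype matrix under Hardy-Weinberg equilibrium.

    With ``n_groups > 1`` accessions are split evenly into groups with
    independently drawn allele frequencies per marker, planting strong
    population structure for clustering tests.  ``spec.allele_freqs``,
    when given, fixes group-0 frequencies.  Missing calls appear at
    ``missing_rate``.
    """
    rng = spec.rng("genotypes")
    accessions = [f"ACC{i + 1:03d}" for i in range(spec.n_accessions)]
    markers = [f"M{j + 1:03d}" for j in range(spec.n_markers)]
    groups = [f"grp{(i * n_groups) // max(1, spec.n_accessions)}" for i in range(spec.n_accessions)]

    freq_table: list[dict[str, tuple[float, ...]]] = []
    for j in range(spec.n_markers):
        per_group: dict[str, tuple[float, ...]] = {}
        for g in range(n_groups):
            if g == 0 and spec.allele_freqs is not None:
                fv = tuple(spec.allele_freqs[j % len(spec.allele_freqs)])
            else:
                k = int(rng.integers(2, 5))
                alpha = 0.8 if n_groups > 1 else 2.0
                fv = tuple(sorted(rng.dirichlet([alpha] * k), reverse=True))
            per_group[f"grp{g}"] = fv
        freq_table.append(per_group)

    calls: list[list[tuple[str, str] | None]] = []
    for i in range(spec.n_accessions):
        row: list[tuple[str, str] | None] = []
        for j in range(spec.n_markers):
            if rng.random() < spec.missing_rate:
                row.append(None)
                continue
            grp_idx = int(groups[i][3:])
            fv = freq_table[j][groups[i]]
            k = len(fv)
            a, b = rng.choice(k, size=2, p=fv)
            # each group draws from its own allele-size range, so groups
            # carry private alleles and are strongly differentiated
            base_sz = 150 + 20 * grp_idx
            labels = tuple(sorted((f"{base_sz + 2 * int(a)}", f"{base_sz + 2 * int(b)}")))
            row.append(labels)
        calls.append(row)
    matrix = GenotypeMatrix(accessions=accessions, markers=markers, calls=calls)
    return matrix, GenotypeTruth(allele_freqs=freq_table, group_assignments=groups)


def generate_ct_records(
    spec: SynthSpec,
    true_folds: dict[str, float] | None = None,
    n_replicates: int = 3,
    noise_sd: float = 0.05,
) -> tuple[list[CtRecord], dict[str, float]]:
    """qPCR Ct tables for a treated sample vs a control calibrator.

    ``true_folds`` maps gene -> fold change of "treated" relative to
    "control"; dCt(treated) = dCt(control) - log2(fold) plus Gaussian
    replicate noise.
    """
    rng = spec.rng("ct")
    if true_folds is None:
        true_folds = {"OSC": 4.0, "UGT73C11": 8.0, "HMGS": 1.0}
    records: list[CtRecord] = []
    for gene, fold in sorted(true_folds.items()):
        base_dct = float(rng.uniform(2.0, 6.0))
        for sample, dct in (("control", base_dct), ("treated", base_dct - np.log2(fold))):
            for rep in range(1, n_replicates + 1):
                ct_ref = float(rng.uniform(15.0, 18.0))
                records.append(
                    CtRecord(
                        sample=sample,
                        gene=gene,
                        replicate=rep,
                        ct_target=ct_ref + dct + float(rng.normal(0.0, noise_sd)),
                        ct_reference=ct_ref,
                    )
                )
    return records, dict(true_folds)


def write_all(spec: SynthSpec, outdir) -> dict:
    """Generate every synthetic input and write it under ``outdir``.

    Emits FASTA unigene sets, a counts TSV, an annotation TSV, a SNP-call
    TSV, a genotype CSV, a Ct CSV, a ground-truth JSON and a manifest.
    Returns the manifest dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    p_set, g_set, truth = generate_transcriptomes(spec)
    p_set.write_fasta(outdir / "unigenes_P.fasta")
    g_set.write_fasta(outdir / "unigenes_G.fasta")

    counts = generate_counts(truth, spec, p_set)
    pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in counts],
            "length": [c.length_nt for c in counts],
            "count_treated": [c.count_treated for c in counts],
            "count_control": [c.count_control for c in counts],
            "lib_treated": [c.lib_treated for c in counts],
            "lib_control": [c.lib_control for c in counts],
        }
    ).to_csv(outdir / "counts.tsv", sep="\t", index=False)

    annotation = generate_annotations(truth, spec, sorted(p_set.sequences))
    with open(outdir / "annotation.tsv", "w") as fh:
        for gene, terms in sorted(annotation.items()):
            for t in terms:
                fh.write(f"{gene}\t{t}\n")

    snp_calls = generate_snp_calls(truth, spec)
    pd.DataFrame([r.__dict__ for r in snp_calls]).to_csv(
        outdir / "snp_calls.tsv", sep="\t", index=False
    )

    matrix, gtruth = generate_genotype_matrix(spec, n_groups=2)
    matrix.to_csv(outdir / "genotypes.csv")

    ct_records, folds = generate_ct_records(spec)
    pd.DataFrame([r.__dict__ for r in ct_records]).to_csv(outdir / "qpcr_ct.csv", index=False)

    truth_doc = {
        "ortholog_pairs": truth.ortholog_pairs,
        "paralog_sets": truth.paralog_sets,
        "planted_ssrs": [asdict(s) for s in truth.planted_ssrs],
        "planted_snps": [asdict(s) for s in truth.planted_snps],
        "de_genes": truth.de_genes,
        "enriched_terms": truth.enriched_terms,
        "qpcr_true_folds": folds,
        "genotype_groups": gtruth.group_assignments,
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth_doc, fh, indent=1)

    manifest = {
        "spec": asdict(spec),
        "files": sorted(p.name for p in outdir.iterdir() if p.name != "manifest.json"),
        "n_sequences": {"P": len(p_set), "G": len(g_set)},
        "n_planted_snps": len(truth.planted_snps),
        "n_planted_ssrs": len(truth.planted_ssrs),
        "n_polymorphic_ssrs": truth.n_polymorphic_ssrs,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
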