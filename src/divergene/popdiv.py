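"""Population-diversity statistics from SSR genotype matrices and
bootstrapped UPGMA clustering.

Per-locus statistics follow the classic marker-panel summary: major
allele frequency (MAF), allele number (ANo), genotype number (GNo),
gene diversity GD = 1 - sum p_i^2, observed heterozygosity H, and
polymorphism information content

    PIC = 1 - sum p_i^2 - sum_{i<j} 2 p_i^2 p_j^2,

all computed with plug-in allele frequencies from the non-missing diploid
calls (homozygotes contribute two copies of one allele).

Accession distances default to the shared-allele distance
D(a,b) = 1 - mean_l (shared alleles at locus l) / 2 over loci typed in
both accessions.  Trees are built by UPGMA (arithmetic-mean linkage,
lexicographic tie-breaks) and branch support estimated by bootstrapping
marker columns.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "LocusStats",
    "ClusterNode",
    "BootTree",
    "diversity_from_freqs",
    "locus_stats",
    "all_locus_stats",
    "shared_allele_similarity",
    "distance_matrix",
    "upgma",
    "bootstrap",
]

MISSING = "."


@dataclass
class GenotypeMatrix:
    """Accessions x markers diploid SSR calls.

    ``calls[i][j]`` is an unordered allele pair (tuple of two strings) or
    None for missing.  The CSV representation uses ``a/b`` cells and ``.``
    for missing.
    """

    accessions: list[str]
    markers: list[str]
    calls: list[list[tuple[str, str] | None]]

    def __post_init__(self) -> None:
        if len(self.calls) != len(self.accessions):
            raise ValueError("one call row per accession required")
        for row in self.calls:
            if len(row) != len(self.markers):
                raise ValueError("one call per marker required in every row")

    def column(self, marker: str) -> list[tuple[str, str] | None]:
        j = self.markers.index(marker)
        return [row[j] for row in self.calls]

    def subset_markers(self, indices: Sequence[int]) -> "GenotypeMatrix":
        return GenotypeMatrix(
            accessions=list(self.accessions),
            markers=[self.markers[j] for j in indices],
            calls=[[row[j] for j in indices] for row in self.calls],
        )

    @classmethod
    def read_csv(cls, path) -> "GenotypeMatrix":
        df = pd.read_csv(path, index_col=0, dtype=str)
        calls = []
        for _, row in df.iterrows():
            parsed = []
            for cell in row:
                if pd.isna(cell) or cell == MISSING:
                    parsed.append(None)
                else:
                    alleles = tuple(sorted(str(cell).split("/")))
                    if len(alleles) != 2:
                        raise ValueError(f"malformed diploid call {cell!r}")
                    parsed.append(alleles)
            calls.append(parsed)
        return cls(accessions=[str(i) for i in df.index], markers=list(df.columns), calls=calls)

    def to_csv(self, path) -> None:
        data = [
            [MISSING if c is None else f"{c[0]}/{c[1]}" for c in row] for row in self.calls
        ]
        pd.DataFrame(data, index=self.accessions, columns=self.markers).to_csv(path)


@dataclass(frozen=True)
class LocusStats:
    marker: str
    maf: float
    allele_count: int  # ANo
    genotype_count: int  # GNo
    gene_diversity: float  # GD
    heterozygosity: float  # H (observed)
    pic: float
    n_typed: int
    allele_freqs: tuple[float, ...] = ()


def diversity_from_freqs(freqs: Sequence[float]) -> tuple[float, float]:
    """(GD, PIC) from an allele-frequency vector (plug-in, no correction)."""
    p = np.asarray(freqs, dtype=float)
    if p.size == 0 or p.min() < -1e-12 or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("allele frequencies must be non-negative and sum to 1")
    gd = 1.0 - float((p**2).sum())
    pairwise = sum(2.0 * p[i] ** 2 * p[j] ** 2 for i, j in itertools.combinations(range(p.size), 2))
    return gd, gd - float(pairwise)


def locus_stats(matrix: GenotypeMatrix, marker: str) -> LocusStats:
    calls = [c for c in matrix.column(marker) if c is not None]
    if not calls:
        raise ValueError(f"marker {marker!r} has no non-missing calls")
    alleles: dict[str, int] = {}
    het = 0
    genotypes = set()
    for call in calls:
        a, b = sorted(call)
        alleles[a] = alleles.get(a, 0) + 1
        alleles[b] = alleles.get(b, 0) + 1
        het += a != b
        genotypes.add((a, b))
    total = 2 * len(calls)
    names = sorted(alleles)
    freqs = tuple(alleles[a] / total for a in names)
    gd, pic = diversity_from_freqs(freqs)
    return LocusStats(
        marker=marker,
        maf=max(freqs),
        allele_count=len(names),
        genotype_count=len(genotypes),
        gene_diversity=gd,
        heterozygosity=het / len(calls),
        pic=pic,
        n_typed=len(calls),
        allele_freqs=freqs,
    )


def all_locus_stats(matrix: GenotypeMatrix) -> pd.DataFrame:
    rows = []
    for m in matrix.markers:
        s = locus_stats(matrix, m)
        rows.append(
            {
                "marker": s.marker,
                "MAF": s.maf,
                "GNo": s.genotype_count,
                "ANo": s.allele_count,
                "GD": s.gene_diversity,
                "H": s.heterozygosity,
                "PIC": s.pic,
                "n_typed": s.n_typed,
            }
        )
    return pd.DataFrame(rows)


def shared_allele_similarity(a: tuple[str, str], b: tuple[str, str]) -> float:
    """Shared alleles between two diploid calls, halved (0, 0.5 or 1)."""
    ca, cb = list(a), list(b)
    shared = 0
    for x in ca:
        if x in cb:
            cb.remove(x)
            shared += 1
    return shared / 2.0


def distance_matrix(matrix: GenotypeMatrix, method: str = "shared_allele") -> pd.DataFrame:
    """Symmetric accession-by-accession distances.

    ``shared_allele``: D(a,b) = 1 - mean over co-typed loci of the halved
    shared-allele count.  A pair with zero co-typed loci raises.
    """
    if method != "shared_allele":
        raise ValueError(f"unknown distance method {method!r}")
    n = len(matrix.accessions)
    if n < 2:
        raise ValueError("need at least two accessions")
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            sims = [
                shared_allele_similarity(ci, cj)
                for ci, cj in zip(matrix.calls[i], matrix.calls[j])
                if ci is not None and cj is not None
            ]
            if not sims:
                raise ValueError(
                    f"accessions {matrix.accessions[i]!r} and {matrix.accessions[j]!r} "
                    "share no co-typed loci"
                )
            D[i, j] = D[j, i] = 1.0 - float(np.mean(sims))
    return pd.DataFrame(D, index=matrix.accessions, columns=matrix.accessions)


@dataclass
class ClusterNode:
    """Node of an ultrametric UPGMA tree; height is distance/2 units."""

    label: str | None = None
    height: float = 0.0
    children: list["ClusterNode"] = field(default_factory=list)
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> frozenset[str]:
        if self.is_leaf:
            return frozenset([self.label])
        return frozenset().union(*(c.leaves() for c in self.children))

    def clades(self) -> dict[frozenset[str], "ClusterNode"]:
        """Internal (non-leaf, non-trivial) clades by leaf set."""
        out: dict[frozenset[str], ClusterNode] = {}
        if not self.is_leaf:
            out[self.leaves()] = self
            for c in self.children:
                out.update(c.clades())
        return out

    def newick(self, *, with_support: bool = False) -> str:
        def fmt(node: ClusterNode, parent_height: float) -> str:
            bl = parent_height - node.height
            if node.is_leaf:
                return f"{node.label}:{bl:.6g}"
            inner = ",".join(fmt(c, node.height) for c in node.children)
            label = ""
            if with_support and node.support is not None:
                label = f"{node.support:.0f}"
            return f"({inner}){label}:{bl:.6g}"

        inner = ",".join(fmt(c, self.height) for c in self.children)
        label = f"{self.support:.0f}" if (with_support and self.support is not None) else ""
        return f"({inner}){label};"

    def to_dendropy(self, *, with_support: bool = False) -> dendropy.Tree:
        return dendropy.Tree.get(data=self.newick(with_support=with_support), schema="newick")


@dataclass
class BootTree:
    tree: ClusterNode
    n_replicates: int = 0

    @property
    def newick(self) -> str:
        return self.tree.newick(with_support=self.n_replicates > 0)

    def supports(self) -> dict[frozenset[str], float]:
        return {k: v.support for k, v in self.tree.clades().items() if v.support is not None}


def upgma(distances: pd.DataFrame) -> ClusterNode:
    """UPGMA with arithmetic-mean cluster distances.

    Tie-breaks join the pair whose (sorted) smallest member labels come
    first lexicographically.  Node heights are half the join distance, so
    the tree is ultrametric with leaves at height 0.
    """
    D = distances.to_numpy(dtype=float)
    labels = [str(x) for x in distances.index]
    if list(distances.columns.map(str)) != labels:
        raise ValueError("distance matrix index and columns must match")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if (D < -1e-12).any():
        raise ValueError("distances must be non-negative")
    clusters: dict[str, tuple[ClusterNode, int]] = {
        lab: (ClusterNode(label=lab), 1) for lab in labels
    }
    dist: dict[frozenset[str], float] = {}
    for i, a in enumerate(labels):
        for j in range(i + 1, len(labels)):
            dist[frozenset((a, labels[j]))] = D[i, j]

    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for i, a in enumerate(keys):
            for b in keys[i + 1 :]:
                d = dist[frozenset((a, b))]
                cand = (d, a, b)
                if best is None or cand < best:
                    best = cand
        d, a, b = best
        (na, sa), (nb, sb) = clusters.pop(a), clusters.pop(b)
        merged = ClusterNode(height=d / 2.0, children=[na, nb])
        new_key = min(a, b)
        for other in clusters:
            dm = (
                sa * dist.pop(frozenset((a, other))) + sb * dist.pop(frozenset((b, other)))
            ) / (sa + sb)
            dist[frozenset((new_key, other))] = dm
        dist.pop(frozenset((a, b)))
        clusters[new_key] = (merged, sa + sb)
    (root, _), = clusters.values()
    return root


def bootstrap(
    matrix: GenotypeMatrix,
    B: int = 1000,
    seed: int | None = None,
    *,
    distance: Callable[[GenotypeMatrix], pd.DataFrame] = distance_matrix,
) -> BootTree:
    """Bootstrap marker columns and annotate the UPGMA tree with supports.

    Supports are the percentage of ``B`` replicates whose UPGMA tree
    contains each internal clade of the tree built from the full matrix.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if len(matrix.accessions) < 3:
        raise ValueError("need at least three accessions to bootstrap")
    rng = np.random.default_rng(seed)
    base = upgma(distance(matrix))
    clades = base.clades()
    counts = {k: 0 for k in clades}
    L = len(matrix.markers)
    for _ in range(B):
        idx = rng.integers(0, L, size=L)
        rep = upgma(distance(matrix.subset_markers(idx)))
        rep_clades = set(rep.clades())
        for k in counts:
            counts[k] += k in rep_clades
    all_leaves = base.leaves()
    for k, node in clades.items():
        if k == all_leaves:
            continue  # the root clade is trivially present
        node.support = 100.0 * counts[k] / B
    return BootTree(tree=base, n_replicates=B)
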