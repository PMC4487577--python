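"""Hypergeometric over-representation analysis of flat gene-set annotations.

Given an annotated gene universe of size N, a DEG subset of size n, a term
annotated to M genes of which m are DEGs, the enrichment p-value is the
upper tail

    P = 1 - sum_{i=0}^{m-1} C(M,i) C(N-M, n-i) / C(N,n)
      = P(X >= m),  X ~ Hypergeometric(N, M, n),

evaluated through the survival function so that small tails do not
underflow.  Raw p-values are Bonferroni-corrected by the number of terms
actually tested (terms with at least one annotated gene).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom

__all__ = ["EnrichmentCounts", "hypergeom_p", "bonferroni", "enrich_table", "read_annotation"]


@dataclass(frozen=True)
class EnrichmentCounts:
    """Counts feeding one term's hypergeometric test.

    N: annotated universe size; n: DEGs among N; M: genes annotated to the
    term; m: DEGs annotated to the term.
    """

    term_id: str
    N: int
    n: int
    M: int
    m: int

    def __post_init__(self) -> None:
        if not (0 <= self.M <= self.N):
            raise ValueError(f"{self.term_id}: require 0 <= M <= N")
        if not (0 <= self.n <= self.N):
            raise ValueError(f"{self.term_id}: require 0 <= n <= N")
        if not (0 <= self.m <= min(self.n, self.M)):
            raise ValueError(f"{self.term_id}: require 0 <= m <= min(n, M)")


def hypergeom_p(c: EnrichmentCounts) -> float:
    """Upper-tail enrichment p-value, P(X >= m)."""
    if c.m == 0:
        return 1.0
    return float(hypergeom.sf(c.m - 1, c.N, c.M, c.n))


def bonferroni(p: float, n_terms: int) -> float:
    """Bonferroni-corrected p-value, min(1, p * n_terms)."""
    if n_terms < 1:
        raise ValueError("number of tested terms must be >= 1")
    return min(1.0, p * n_terms)


def enrich_table(
    annotation: Mapping[str, Iterable[str]],
    degs: Iterable[str],
    *,
    drop_unannotated_degs: bool = True,
) -> pd.DataFrame:
    """Rank all annotated terms by DEG over-representation.

    ``annotation`` maps gene id -> term ids; the universe N is every gene
    in the map.  DEGs absent from the universe are dropped (their number is
    recorded in ``frame.attrs['n_degs_dropped']``) unless
    ``drop_unannotated_degs=False``, which raises instead.

    Returns one row per term with M > 0, sorted ascending by raw p-value,
    with frequencies m/n and M/N as percentages (two decimals) mirroring
    the usual pathway-report layout.
    """
    universe = set(annotation)
    deg_set = set(degs)
    dropped = deg_set - universe
    if dropped and not drop_unannotated_degs:
        raise ValueError(f"{len(dropped)} DEGs missing from the annotated universe")
    deg_set &= universe

    term_genes: dict[str, set[str]] = {}
    for gene, terms in annotation.items():
        for t in terms:
            term_genes.setdefault(t, set()).add(gene)

    N, n = len(universe), len(deg_set)
    rows = []
    n_terms = len(term_genes)
    for term, genes in sorted(term_genes.items()):
        M = len(genes)
        m = len(genes & deg_set)
        c = EnrichmentCounts(term_id=term, N=N, n=n, M=M, m=m)
        p = hypergeom_p(c)
        rows.append(
            {
                "term_id": term,
                "m": m,
                "deg_freq_pct": round(100.0 * m / n, 2) if n else 0.0,
                "M": M,
                "universe_freq_pct": round(100.0 * M / N, 2) if N else 0.0,
                "p_value": p,
                "corrected_p": bonferroni(p, n_terms) if n_terms else 1.0,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["term_id", "m", "deg_freq_pct", "M", "universe_freq_pct", "p_value", "corrected_p"],
    )
    if len(out):
        out = out.sort_values(["p_value", "term_id"], kind="mergesort").reset_index(drop=True)
    out.attrs["N"] = N
    out.attrs["n"] = n
    out.attrs["n_terms_tested"] = n_terms
    out.attrs["n_degs_dropped"] = len(dropped)
    return out


def read_annotation(path) -> dict[str, list[str]]:
    """Read a two-column TSV of gene_id<TAB>term_id pairs (no header)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "term_id"], dtype=str)
    out: dict[str, list[str]] = {}
    for r in df.itertuples():
        out.setdefault(r.gene_id, []).append(r.term_id)
    return out
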