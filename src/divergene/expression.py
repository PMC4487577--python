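"""Expression quantification and two-library differential-expression calling.

Quantification uses RPKM (reads per kilobase of transcript per million
uniquely aligned reads).  Differential expression between a single treated
and a single control library is assessed per gene with a Pearson chi-square
test on the 2x2 table {gene reads, library remainder} x {treated, control},
followed by Benjamini-Hochberg control of the false discovery rate.  A gene
is called differentially expressed (DEG) when its RPKM fold change exceeds
2 in either direction and its FDR is below 1e-2.

The module also provides the 2^-ddCt helper for relative qPCR
quantification against a reference gene and a calibrator sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CountRow",
    "DEResult",
    "CtRecord",
    "rpkm",
    "de_test",
    "call_degs",
    "call_degs_frame",
    "ddct",
    "read_counts",
    "write_de_table",
]

DEFAULT_FDR = 1e-2
DEFAULT_FC = 2.0


@dataclass(frozen=True)
class CountRow:
    """Read counts for one gene in a treated and a control library."""

    gene_id: str
    length_nt: int
    count_treated: int
    count_control: int
    lib_treated: int
    lib_control: int

    def __post_init__(self) -> None:
        if self.length_nt <= 0:
            raise ValueError(f"{self.gene_id}: gene length must be positive")
        if self.count_treated < 0 or self.count_control < 0:
            raise ValueError(f"{self.gene_id}: counts must be non-negative")
        if self.lib_treated <= 0 or self.lib_control <= 0:
            raise ValueError(f"{self.gene_id}: library sizes must be positive")


@dataclass(frozen=True)
class DEResult:
    gene_id: str
    rpkm_treated: float
    rpkm_control: float
    fold_change: float
    p_value: float
    fdr: float
    is_deg: bool
    direction: str  # "up", "down" or "ns"


@dataclass(frozen=True)
class CtRecord:
    """One qPCR well: threshold cycles for a target and the reference gene."""

    sample: str
    gene: str
    replicate: int
    ct_target: float
    ct_reference: float

    def __post_init__(self) -> None:
        for v in (self.ct_target, self.ct_reference):
            if not math.isfinite(v) or v <= 0:
                raise ValueError("Ct values must be finite and positive")


def rpkm(count: float, lib_size: float, length_nt: float, *, literal: bool = False) -> float:
    """Expression of a gene as reads per kilobase per million aligned reads.

    Default is the standard definition 1e9 * C / (N * L) with C aligned
    reads, N the library total and L the gene length in bases.  With
    ``literal=True`` the value is 1e6 * C / (N * L * 1000), a form that
    differs only by a constant factor (which cancels in any fold change).
    """
    if lib_size <= 0:
        raise ValueError("library size must be positive")
    if length_nt <= 0:
        raise ValueError("gene length must be positive")
    scale = 1e6 / 1000.0 if literal else 1e9
    return scale * count / (lib_size * length_nt)


def de_test(row: CountRow) -> float:
    """Pearson chi-square p-value for equal expression proportions.

    The 2x2 table is {gene count, library remainder} x {treated, control};
    the statistic is the plain Pearson sum (1 df, no continuity correction)
    and the p-value its chi-square survival function.  A gene absent from
    both libraries carries no information and gets p = 1 by convention.
    """
    a, b = row.count_treated, row.count_control
    n1, n2 = row.lib_treated, row.lib_control
    if a + b == 0:
        return 1.0
    table = np.array([[a, n1 - a], [b, n2 - b]], dtype=float)
    colsum = table.sum(axis=0)
    rowsum = table.sum(axis=1)
    expected = np.outer(rowsum, colsum) / table.sum()
    stat = float(((table - expected) ** 2 / expected).sum())
    return float(chi2.sf(stat, df=1))


def _fold_change(row: CountRow) -> float:
    # pseudo-count 1 on zero counts keeps folds finite without reordering
    ct = row.count_treated if row.count_treated > 0 else 1
    cc = row.count_control if row.count_control > 0 else 1
    rt = rpkm(ct, row.lib_treated, row.length_nt)
    rc = rpkm(cc, row.lib_control, row.length_nt)
    return rt / rc


def call_degs(
    rows: Sequence[CountRow],
    *,
    fdr_threshold: float = DEFAULT_FDR,
    fc_threshold: float = DEFAULT_FC,
    method: str = "fdr_bh",
) -> list[DEResult]:
    """Test every gene, correct for multiplicity, and flag DEGs.

    FDR control defaults to Benjamini-Hochberg step-up over all tested
    genes (``method`` accepts any statsmodels multipletests method name).
    A gene is a DEG when fold change > fc_threshold or < 1/fc_threshold
    and its FDR is below fdr_threshold.
    """
    if not rows:
        return []
    pvals = np.array([de_test(r) for r in rows])
    fdrs = multipletests(pvals, method=method)[1]
    out = []
    for row, p, q in zip(rows, pvals, fdrs):
        fc = _fold_change(row)
        is_deg = bool((fc > fc_threshold or fc < 1.0 / fc_threshold) and q < fdr_threshold)
        direction = "ns"
        if is_deg:
            direction = "up" if fc > 1 else "down"
        out.append(
            DEResult(
                gene_id=row.gene_id,
                rpkm_treated=rpkm(row.count_treated, row.lib_treated, row.length_nt),
                rpkm_control=rpkm(row.count_control, row.lib_control, row.length_nt),
                fold_change=fc,
                p_value=float(p),
                fdr=float(q),
                is_deg=is_deg,
                direction=direction,
            )
        )
    return out


def call_degs_frame(results: Iterable[DEResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def ddct(records: Sequence[CtRecord], calibrator: str) -> pd.DataFrame:
    """Relative expression by the 2^-ddCt method.

    dCt = Ct_target - Ct_reference per replicate; ddCt = mean dCt(sample)
    - mean dCt(calibrator); fold = 2^-ddCt.  The reported SD is the fold
    change recomputed at ddCt +/- SD(dCt) of the sample's replicates,
    i.e. the usual asymmetric range collapsed to 2^-ddCt * (2^sd - 2^-sd)/2
    is avoided; instead sd_fold = fold * ln(2) * sd(dCt) (delta method).

    Returns a frame indexed by (sample, gene) with columns
    ``fold`` and ``sd``.
    """
    if not records:
        raise ValueError("no Ct records supplied")
    df = pd.DataFrame([r.__dict__ for r in records])
    if calibrator not in set(df["sample"]):
        raise ValueError(f"calibrator sample {calibrator!r} not present")
    df["dct"] = df["ct_target"] - df["ct_reference"]
    rows = []
    for gene, sub in df.groupby("gene", sort=True):
        cal = sub[sub["sample"] == calibrator]["dct"]
        if cal.empty:
            raise ValueError(f"calibrator sample {calibrator!r} missing for gene {gene!r}")
        cal_mean = cal.mean()
        for sample, grp in sub.groupby("sample", sort=True):
            ddct_val = grp["dct"].mean() - cal_mean
            fold = 2.0 ** (-ddct_val)
            sd_dct = float(grp["dct"].std(ddof=1)) if len(grp) > 1 else 0.0
            rows.append(
                {
                    "sample": sample,
                    "gene": gene,
                    "ddct": float(ddct_val),
                    "fold": float(fold),
                    "sd": float(fold * math.log(2.0) * sd_dct),
                    "n_replicates": len(grp),
                }
            )
    return pd.DataFrame(rows).set_index(["sample", "gene"])


def read_counts(path) -> list[CountRow]:
    """Read a counts TSV: gene_id, length, count_treated, count_control.

    Library sizes are the column sums unless ``lib_treated``/``lib_control``
    columns are present (they must then be constant).
    """
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "length", "count_treated", "count_control"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"counts table missing columns: {sorted(missing)}")
    if "lib_treated" in df.columns:
        nt = int(df["lib_treated"].iloc[0])
        nc = int(df["lib_control"].iloc[0])
    else:
        nt = int(df["count_treated"].sum())
        nc = int(df["count_control"].sum())
    return [
        CountRow(
            gene_id=str(r.gene_id),
            length_nt=int(r.length),
            count_treated=int(r.count_treated),
            count_control=int(r.count_control),
            lib_treated=nt,
            lib_control=nc,
        )
        for r in df.itertuples()
    ]


def write_de_table(results: Iterable[DEResult], path) -> None:
    call_degs_frame(results).to_csv(path, sep="\t", index=False)
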