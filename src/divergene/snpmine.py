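"""Quality and spacing filters for SNP call records, and substitution-class
summaries.

Call records (sequence id, 1-based position, two alleles, read depth,
call score) are filtered by strict depth and score thresholds
(depth > 10, score > 30 by default), then by spacing: any record closer
than 5 bp to another depth/score-passing record on the same reference is
dropped — both members of a too-close pair — because dense SNP clusters
in assembled transcripts usually flag misassembly or paralog collapse.

Substitutions are summarized in the six unordered classes A/G, C/T, A/C,
A/T, G/C, G/T; transitions are A/G and C/T.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "SNPRecord",
    "is_transition",
    "filter_snps",
    "classify_substitutions",
    "read_snp_table",
]

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}
SUBSTITUTION_CLASSES = ["A/G", "C/T", "A/C", "A/T", "G/C", "G/T"]
_CLASS_BY_PAIR = {frozenset(c.split("/")): c for c in SUBSTITUTION_CLASSES}


def is_transition(a: str, b: str) -> bool:
    pair = {a.upper(), b.upper()}
    return pair == _PURINES or pair == _PYRIMIDINES


@dataclass(frozen=True)
class SNPRecord:
    seq_id: str
    position: int  # 1-based
    ref_allele: str
    alt_allele: str
    depth: int
    score: float

    def __post_init__(self) -> None:
        ref, alt = self.ref_allele.upper(), self.alt_allele.upper()
        if ref not in "ACGT" or alt not in "ACGT" or len(ref) != 1 or len(alt) != 1:
            raise ValueError(f"{self.seq_id}:{self.position}: alleles must be single A/C/G/T")
        if ref == alt:
            raise ValueError(f"{self.seq_id}:{self.position}: alleles must differ")
        if self.depth < 0:
            raise ValueError(f"{self.seq_id}:{self.position}: depth must be >= 0")

    @property
    def substitution_class(self) -> str:
        pair = frozenset((self.ref_allele.upper(), self.alt_allele.upper()))
        return _CLASS_BY_PAIR[pair]

    @property
    def is_transition(self) -> bool:
        return is_transition(self.ref_allele, self.alt_allele)


def filter_snps(
    records: Iterable[SNPRecord],
    min_depth: int = 10,
    min_score: float = 30.0,
    min_spacing: int = 5,
) -> list[SNPRecord]:
    """Apply depth, score and adjacent-SNP spacing filters.

    Depth and score are strict (> min_depth, > min_score).  The spacing
    rule removes every candidate whose distance to its nearest
    depth/score-passing neighbour on the same sequence is below
    ``min_spacing``; an interval of exactly ``min_spacing`` is kept.
    Records are sorted internally; duplicate (seq, position) entries
    raise.
    """
    by_seq: dict[str, list[SNPRecord]] = {}
    seen: set[tuple[str, int]] = set()
    for r in records:
        key = (r.seq_id, r.position)
        if key in seen:
            raise ValueError(f"duplicate SNP position {r.seq_id}:{r.position}")
        seen.add(key)
        if r.depth > min_depth and r.score > min_score:
            by_seq.setdefault(r.seq_id, []).append(r)
    out: list[SNPRecord] = []
    for sid in sorted(by_seq):
        cand = sorted(by_seq[sid], key=lambda r: r.position)
        for i, r in enumerate(cand):
            too_close = False
            if i > 0 and r.position - cand[i - 1].position < min_spacing:
                too_close = True
            if i + 1 < len(cand) and cand[i + 1].position - r.position < min_spacing:
                too_close = True
            if not too_close:
                out.append(r)
    return out


def classify_substitutions(records: Iterable[SNPRecord | str]) -> pd.DataFrame:
    """Count the six substitution classes with percentages (one decimal).

    Accepts SNPRecord objects or bare class strings like ``"A/G"``.
    The returned frame also exposes ``attrs['transition_fraction']``.
    """
    classes = []
    for r in records:
        c = r if isinstance(r, str) else r.substitution_class
        if c not in SUBSTITUTION_CLASSES:
            raise ValueError(f"unknown substitution class {c!r}")
        classes.append(c)
    counts = Counter(classes)
    total = sum(counts.values())
    rows = [
        {
            "substitution": c,
            "count": counts.get(c, 0),
            "percentage": round(100.0 * counts.get(c, 0) / total, 1) if total else 0.0,
            "kind": "transition" if c in ("A/G", "C/T") else "transversion",
        }
        for c in SUBSTITUTION_CLASSES
    ]
    df = pd.DataFrame(rows)
    ts = counts.get("A/G", 0) + counts.get("C/T", 0)
    df.attrs["total"] = total
    df.attrs["transition_count"] = ts
    df.attrs["transition_fraction"] = ts / total if total else float("nan")
    return df


def read_snp_table(path) -> list[SNPRecord]:
    """Read a SNP-call TSV: seq_id, position, ref_allele, alt_allele, depth, score."""
    df = pd.read_csv(path, sep="\t")
    required = {"seq_id", "position", "ref_allele", "alt_allele", "depth", "score"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"SNP table missing columns: {sorted(missing)}")
    return [
        SNPRecord(
            seq_id=str(r.seq_id),
            position=int(r.position),
            ref_allele=str(r.ref_allele),
            alt_allele=str(r.alt_allele),
            depth=int(r.depth),
            score=float(r.score),
        )
        for r in df.itertuples()
    ]


def write_snp_table(records: Sequence[SNPRecord], path) -> None:
    pd.DataFrame([r.__dict__ for r in records]).to_csv(path, sep="\t", index=False)
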