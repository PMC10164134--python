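"""Gene and chromosome-arm annotations shared across the pipeline.

All internal coordinates are 0-based, half-open. Conversion to and from
1-based external dialects happens only at file boundaries (see
:mod:`wntgct.cohort_io`).
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = [
    "GeneAnnotation",
    "ArmDefinition",
    "promoter_window",
    "load_arm_definitions",
    "default_arms",
]


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene locus with its promoter interval.

    ``start``/``end`` span the gene body; ``promoter_start``/``promoter_end``
    span the strand-aware promoter window around the TSS. All coordinates are
    0-based half-open on ``chrom``.
    """

    gene: str
    chrom: str
    start: int
    end: int
    strand: str
    promoter_start: int
    promoter_end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.gene}: gene interval empty ({self.start}..{self.end})")
        if self.promoter_start >= self.promoter_end:
            raise ValueError(f"{self.gene}: promoter interval empty")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene}: strand must be + or -, got {self.strand!r}")


@dataclass(frozen=True)
class ArmDefinition:
    """A chromosome arm (p or q), 0-based half-open."""

    chrom: str
    arm: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.arm not in ("p", "q"):
            raise ValueError(f"arm must be p or q, got {self.arm!r}")
        if self.start >= self.end:
            raise ValueError(f"{self.chrom}{self.arm}: empty arm interval")

    @property
    def name(self) -> str:
        return f"{self.chrom}{self.arm}"

    @property
    def length(self) -> int:
        return self.end - self.start


def promoter_window(start: int, end: int, strand: str, upstream: int = 1500,
                    downstream: int = 500) -> tuple[int, int]:
    """Strand-aware promoter interval TSS-upstream .. TSS+downstream.

    For a ``+`` gene the TSS is ``start``; for a ``-`` gene it is ``end``.
    The returned interval is clamped at zero and 0-based half-open.
    """
    if strand == "+":
        lo, hi = start - upstream, start + downstream
    elif strand == "-":
        lo, hi = end - downstream, end + upstream
    else:
        raise ValueError(f"strand must be + or -, got {strand!r}")
    return max(lo, 0), max(hi, 1)


def load_arm_definitions(path) -> list[ArmDefinition]:
    """Read an arm table TSV with columns chrom, arm, start, end (0-based half-open)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "arm": str})
    arms = [ArmDefinition(r.chrom, r.arm, int(r.start), int(r.end)) for r in df.itertuples()]
    _check_arms(arms)
    return arms


def default_arms(autosomes_only: bool = False) -> list[ArmDefinition]:
    """The packaged hg19 arm table (cytoband-derived, approximate centromere midpoints)."""
    with resources.as_file(resources.files("wntgct.data") / "hg19_arms.tsv") as p:
        arms = load_arm_definitions(p)
    if autosomes_only:
        arms = [a for a in arms if a.chrom not in ("chrX", "chrY")]
    return arms


def _check_arms(arms: list[ArmDefinition]) -> None:
    by_chrom: dict[str, list[ArmDefinition]] = {}
    for a in arms:
        by_chrom.setdefault(a.chrom, []).append(a)
    for chrom, group in by_chrom.items():
        group = sorted(group, key=lambda a: a.start)
        for prev, nxt in zip(group, group[1:]):
            if nxt.start < prev.end:
                raise ValueError(f"overlapping arms on {chrom}")


def arm_of(arms: list[ArmDefinition], chrom: str, pos: int) -> ArmDefinition | None:
    """The arm containing ``pos`` on ``chrom``, or None."""
    for a in arms:
        if a.chrom == chrom and a.start <= pos < a.end:
            return a
    return None
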