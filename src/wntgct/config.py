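"""Pipeline configuration: every tunable threshold in one serializable object.

Defaults follow common practice for tumor-normal exome filtering and
array-based copy-number calling; each is documented in docs/methods.md and can
be overridden from a YAML file.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "FilterThresholds",
    "CopyNumberOptions",
    "PromoterWindowOptions",
    "VcfFieldNames",
    "OutcomeOptions",
    "PipelineConfig",
]


@dataclass
class FilterThresholds:
    """Somatic post-calling filter cascade thresholds.

    A variant passes only if all of the following hold:

    * tumor VAF >= ``tumor_vaf_min`` and normal alt reads <= ``normal_alt_max``
      (default 0: any alt evidence in the matched normal fails the variant);
    * >= ``min_alt_per_strand`` alt reads on each strand and total alt reads
      strictly greater than ``min_alt_total``;
    * mapping quality >= ``mapq_min`` and base quality >= ``baseq_min``;
    * tumor and normal depth each >= ``min_depth``;
    * population allele frequency <= ``popaf_max`` (absent = not catalogued
      in population databases = pass).
    """

    tumor_vaf_min: float = 0.10
    normal_alt_max: int = 0
    min_alt_per_strand: int = 1
    min_alt_total: int = 6  # strict: total alt reads must exceed this
    mapq_min: float = 30.0
    baseq_min: float = 15.0
    min_depth: int = 10
    popaf_max: float = 0.01


@dataclass
class CopyNumberOptions:
    """Gene-level CN calling and arm-level LOH calling options.

    log2 ratio thresholds of +/-0.3 approximate a single-copy change on the
    array log2 scale. A call is *focal* when its supporting run of altered
    segments spans less than ``focal_max_arm_fraction`` of the chromosome arm
    (broad/focal convention by arm fraction). An arm is called LOH when
    LOH-flagged segments cover at least ``loh_min_arm_fraction`` of it.
    """

    gain_log2: float = 0.3
    loss_log2: float = -0.3
    focal_max_arm_fraction: float = 0.5
    aggregation: str = "length_weighted"  # or "max_magnitude"
    loh_min_arm_fraction: float = 0.7


@dataclass
class PromoterWindowOptions:
    """Strand-aware promoter window around the TSS (bp)."""

    upstream: int = 1500
    downstream: int = 500


@dataclass
class VcfFieldNames:
    """Names of VCF annotation fields, configurable to absorb caller dialects."""

    ad: str = "AD"          # FORMAT: ref,alt depths
    adf: str = "ADF"        # FORMAT: forward-strand ref,alt depths
    adr: str = "ADR"        # FORMAT: reverse-strand ref,alt depths
    dp: str = "DP"          # FORMAT: total depth
    mapq: str = "MQ"        # INFO: site mapping quality
    baseq: str = "BQ"       # INFO: alt base quality
    popaf: str = "PAF"      # INFO: population allele frequency (optional)
    gene: str = "GENE"      # INFO: gene symbol
    consequence: str = "CSQ"  # INFO: consequence term
    tumor_sample: str = "TUMOR"
    normal_sample: str = "NORMAL"


@dataclass
class OutcomeOptions:
    """Burden stratification and survival-analysis options.

    ``burden_threshold`` t splits burden scores into none (0), cn_poor (1..t)
    and cn_rich (>t). ``median_tie_under`` sends expression values equal to
    the cohort median to the under-expressed group.
    """

    burden_threshold: int = 5
    sensitivity_thresholds: tuple[int, ...] = (3, 5, 7, 9)
    focal_only: bool = True
    age_cut_years: float = 6.0
    welch: bool = True
    median_tie_under: bool = True


@dataclass
class PipelineConfig:
    filter: FilterThresholds = field(default_factory=FilterThresholds)
    cn: CopyNumberOptions = field(default_factory=CopyNumberOptions)
    promoter: PromoterWindowOptions = field(default_factory=PromoterWindowOptions)
    vcf_fields: VcfFieldNames = field(default_factory=VcfFieldNames)
    outcome: OutcomeOptions = field(default_factory=OutcomeOptions)
    seg_dialect: str = "1based_closed"  # or "0based_halfopen"
    target_mb: float = 38.0  # exome target size used as the mutation-rate denominator

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in raw:
                continue
            val = raw[f.name]
            if dataclasses.is_dataclass(f.type) or f.name in (
                "filter", "cn", "promoter", "vcf_fields", "outcome"
            ):
                sub_cls = {
                    "filter": FilterThresholds,
                    "cn": CopyNumberOptions,
                    "promoter": PromoterWindowOptions,
                    "vcf_fields": VcfFieldNames,
                    "outcome": OutcomeOptions,
                }[f.name]
                if f.name == "outcome" and "sensitivity_thresholds" in val:
                    val = dict(val)
                    val["sensitivity_thresholds"] = tuple(val["sensitivity_thresholds"])
                kwargs[f.name] = sub_cls(**val)
            else:
                kwargs[f.name] = val
        return cls(**kwargs)
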