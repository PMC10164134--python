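"""Readers and writers for every external format, and cohort assembly.

Formats: clinical TSV, VCF 4.x (via pysam), SEG, BED6 gene/promoter
annotations, gene-set TSV and beta/expression matrices (TSV). Internal
coordinates are 0-based half-open; the VCF keeps its native 1-based positions
at the boundary and the SEG dialect (default 1-based closed) is converted at
ingest.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pysam
from importlib import resources

from .annotations import ArmDefinition, GeneAnnotation, load_arm_definitions
from .cn_burden import Segment, SegmentProfile, WntGeneSet
from .config import VcfFieldNames
from .somatic_filter import CONSEQUENCES, VariantCall

logger = logging.getLogger(__name__)

HISTOLOGIES = ("EC", "SE", "TER", "MMGCT", "YST")
GCT_TYPES = ("I", "II")
SEXES = ("male", "female")
SITES = ("testis", "ovary", "extragonadal")

CLINICAL_COLUMNS = ("sample_id", "age_years", "sex", "site", "histology",
                    "gct_type", "relapse", "survival_time", "event")


@dataclass
class Sample:
    """One patient: clinical descriptors plus outcome fields (possibly missing)."""

    sample_id: str
    age_years: float
    sex: str
    site: str
    histology: str
    gct_type: str
    relapse: Optional[bool] = None
    survival_time: Optional[float] = None
    event: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.age_years < 0:
            raise ValueError(f"{self.sample_id}: negative age")
        if self.sex not in SEXES:
            raise ValueError(f"{self.sample_id}: unknown sex {self.sex!r}")
        if self.site not in SITES:
            raise ValueError(f"{self.sample_id}: unknown site {self.site!r}")
        if self.histology not in HISTOLOGIES:
            raise ValueError(f"{self.sample_id}: unknown histology {self.histology!r}")
        if self.gct_type not in GCT_TYPES:
            raise ValueError(f"{self.sample_id}: unknown GCT type {self.gct_type!r}")
        if self.event is not None and self.event and self.survival_time is None:
            raise ValueError(f"{self.sample_id}: event recorded without survival time")
        if self.survival_time is not None and self.survival_time < 0:
            raise ValueError(f"{self.sample_id}: negative survival time")

    @property
    def has_outcome(self) -> bool:
        return self.survival_time is not None and self.event is not None


@dataclass
class Cohort:
    """Multi-layer cohort: samples plus optional per-sample data layers."""

    samples: list[Sample]
    variant_layer: Optional[dict[str, list[VariantCall]]] = None
    cn_layer: Optional[dict[str, SegmentProfile]] = None
    methylation_layer: Optional[object] = None  # MethylationMatrix
    expression_layer: Optional[pd.DataFrame] = None
    expression_groups: Optional[dict[str, str]] = None
    genes: Optional[list[GeneAnnotation]] = None
    geneset: Optional[WntGeneSet] = None
    arms: Optional[list[ArmDefinition]] = None

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate sample ids in cohort")
        known = set(ids)
        for name in ("variant_layer", "cn_layer"):
            layer = getattr(self, name)
            if layer is not None:
                extra = set(layer) - known
                if extra:
                    raise ValueError(f"{name} keys not in samples: {sorted(extra)[:5]}")

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def clinical_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "sample_id": s.sample_id, "age_years": s.age_years, "sex": s.sex,
            "site": s.site, "histology": s.histology, "gct_type": s.gct_type,
            "relapse": s.relapse, "survival_time": s.survival_time, "event": s.event,
        } for s in self.samples])


# ---------------------------------------------------------------- clinical TSV

def _parse_bool(raw: str, where: str) -> Optional[bool]:
    if raw == "":
        return None
    if raw in ("1", "True", "true", "TRUE"):
        return True
    if raw in ("0", "False", "false", "FALSE"):
        return False
    raise ValueError(f"{where}: cannot parse boolean {raw!r}")


def read_clinical(path) -> list[Sample]:
    """Parse a clinical TSV into validated Samples (missing outcomes preserved)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = set(CLINICAL_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"clinical table missing columns: {sorted(missing_cols)}")
    seen: set[str] = set()
    samples = []
    for i, row in df.iterrows():
        sid = row["sample_id"]
        if sid in seen:
            raise ValueError(f"duplicate sample_id {sid!r} (row {i + 2})")
        seen.add(sid)
        st = row["survival_time"]
        try:
            samples.append(Sample(
                sample_id=sid,
                age_years=float(row["age_years"]),
                sex=row["sex"], site=row["site"],
                histology=row["histology"], gct_type=row["gct_type"],
                relapse=_parse_bool(row["relapse"], sid),
                survival_time=float(st) if st != "" else None,
                event=_parse_bool(row["event"], sid),
            ))
        except ValueError as err:
            raise ValueError(f"clinical row {i + 2} ({sid!r}): {err}") from err
    return samples


def write_clinical(samples: Sequence[Sample], path) -> None:
    def fmt_bool(b: Optional[bool]) -> str:
        return "" if b is None else str(int(b))

    with open(path, "w") as fh:
        fh.write("\t".join(CLINICAL_COLUMNS) + "\n")
        for s in samples:
            fh.write("\t".join([
                s.sample_id, f"{s.age_years:.2f}", s.sex, s.site, s.histology,
                s.gct_type, fmt_bool(s.relapse),
                "" if s.survival_time is None else f"{s.survival_time:.2f}",
                fmt_bool(s.event),
            ]) + "\n")


# ----------------------------------------------------------------------- VCF

@dataclass
class VariantReadResult:
    calls: list[VariantCall]
    n_unscorable: int
    unscorable_keys: list[str] = field(default_factory=list)


def read_variant_calls(path, sample_id: str,
                       fields: VcfFieldNames | None = None) -> VariantReadResult:
    """Read tumor-normal candidate calls for one sample pair from a VCF.

    Records lacking a required annotation (allele depths, strand counts,
    depth, qualities or consequence) are flagged unscorable, counted and
    excluded; a missing population-AF field is legitimate (variant not
    catalogued). VAFs are computed as alt depth / total allele depth.
    """
    f = fields or VcfFieldNames()
    calls: list[VariantCall] = []
    unscorable: list[str] = []
    with pysam.VariantFile(str(path)) as vcf:
        if f.tumor_sample not in vcf.header.samples or \
                f.normal_sample not in vcf.header.samples:
            raise ValueError(f"VCF must contain samples {f.tumor_sample!r} and "
                             f"{f.normal_sample!r}")
        for rec in vcf:
            key = f"{rec.chrom}:{rec.pos}"
            try:
                tum, nor = rec.samples[f.tumor_sample], rec.samples[f.normal_sample]
                ad_t = tum[f.ad]
                ad_n = nor[f.ad]
                adf = tum[f.adf]
                adr = tum[f.adr]
                mq = rec.info[f.mapq]
                bq = rec.info[f.baseq]
                gene = rec.info[f.gene]
                csq = rec.info[f.consequence]
                if any(v is None for v in (ad_t, ad_n, adf, adr, mq, bq, gene, csq)) \
                        or any(x is None for x in ad_t) or any(x is None for x in ad_n) \
                        or any(x is None for x in adf) or any(x is None for x in adr):
                    raise KeyError("missing annotation")
            except KeyError:
                unscorable.append(key)
                continue
            pop_af = rec.info.get(f.popaf)
            if isinstance(pop_af, tuple):
                pop_af = pop_af[0]
            if isinstance(gene, tuple):
                gene = gene[0]
            if isinstance(csq, tuple):
                csq = csq[0]
            if csq not in CONSEQUENCES:
                unscorable.append(key)
                continue
            t_depth, n_depth = sum(ad_t), sum(ad_n)
            calls.append(VariantCall(
                sample_id=sample_id, chrom=rec.chrom, pos=rec.pos,
                ref=rec.ref, alt=rec.alts[0] if rec.alts else ".",
                tumor_vaf=ad_t[1] / t_depth if t_depth else 0.0,
                normal_vaf=ad_n[1] / n_depth if n_depth else 0.0,
                tumor_depth=int(t_depth), normal_depth=int(n_depth),
                alt_fwd=int(adf[1]), alt_rev=int(adr[1]),
                mapping_quality=float(mq), base_quality=float(bq),
                pop_af=float(pop_af) if pop_af is not None else None,
                consequence=str(csq), gene=str(gene),
                normal_alt=int(ad_n[1]),
            ))
    if unscorable:
        logger.warning("%s: %d unscorable VCF records excluded", sample_id,
                       len(unscorable))
    return VariantReadResult(calls, len(unscorable), unscorable)


def vcf_header(contigs: dict[str, int], fields: VcfFieldNames | None = None) -> pysam.VariantHeader:
    """A VCF header carrying the annotation fields the filter cascade reads."""
    f = fields or VcfFieldNames()
    h = pysam.VariantHeader()
    for name, length in contigs.items():
        h.contigs.add(name, length=length)
    h.info.add(f.mapq, 1, "Float", "Site mapping quality")
    h.info.add(f.baseq, 1, "Float", "Alt base quality")
    h.info.add(f.popaf, 1, "Float", "Population alternate allele frequency")
    h.info.add(f.gene, 1, "String", "Gene symbol")
    h.info.add(f.consequence, 1, "String", "Consequence class")
    h.formats.add(f.ad, "R", "Integer", "Allele depths (ref,alt)")
    h.formats.add(f.adf, "R", "Integer", "Forward-strand allele depths")
    h.formats.add(f.adr, "R", "Integer", "Reverse-strand allele depths")
    h.formats.add(f.dp, 1, "Integer", "Total depth")
    for rule in ("R1_vaf", "R2_strand_reads", "R3_quality", "R4_depth", "R5_popaf"):
        h.filters.add(rule, None, None, f"Failed somatic filter rule {rule}")
    h.add_sample(f.tumor_sample)
    h.add_sample(f.normal_sample)
    return h


def write_filtered_vcf(in_path, report, out_path,
                       fields: VcfFieldNames | None = None) -> None:
    """Copy a VCF, populating FILTER with PASS or the violated rule ids."""
    status = {(c.chrom, c.pos): f for c, f in zip(report.calls, report.failed_rules)}
    with pysam.VariantFile(str(in_path)) as vin:
        with pysam.VariantFile(str(out_path), "w", header=vin.header) as vout:
            for rec in vin:
                failed = status.get((rec.chrom, rec.pos))
                rec.filter.clear()
                if failed is None:
                    pass  # unscorable record: leave FILTER unset
                elif failed:
                    for rule in failed:
                        rec.filter.add(rule)
                else:
                    rec.filter.add("PASS")
                vout.write(rec)


# ----------------------------------------------------------------------- SEG

SEG_COLUMNS = ("ID", "chrom", "loc.start", "loc.end", "num.mark", "seg.mean")


def read_segments(path, dialect: str = "1based_closed") -> dict[str, SegmentProfile]:
    """Read a SEG file into per-sample profiles (0-based half-open internally).

    ``dialect`` selects the input coordinate convention: "1based_closed"
    (default, converted by start-1) or "0based_halfopen" (taken as is). An
    optional ``loh`` column (0/1) is preserved.
    """
    if dialect not in ("1based_closed", "0based_halfopen"):
        raise ValueError(f"unknown SEG dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", dtype={"ID": str, "chrom": str})
    missing = set(SEG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"SEG file missing columns: {sorted(missing)}")
    shift = 1 if dialect == "1based_closed" else 0
    has_loh = "loh" in df.columns
    profiles: dict[str, SegmentProfile] = {}
    for sid, sub in df.groupby("ID", sort=True):
        segs = [Segment(chrom=r["chrom"], start=int(r["loc.start"]) - shift,
                        end=int(r["loc.end"]),
                        log2_ratio=float(r["seg.mean"]),
                        loh=bool(int(r["loh"])) if has_loh else None,
                        n_markers=int(r["num.mark"]))
                for _, r in sub.iterrows()]
        profiles[str(sid)] = SegmentProfile(str(sid), segs)  # validates overlap
    return profiles


def write_segments(profiles: dict[str, SegmentProfile], path,
                   dialect: str = "1based_closed") -> None:
    shift = 1 if dialect == "1based_closed" else 0
    any_loh = any(s.loh is not None for p in profiles.values() for s in p.segments)
    with open(path, "w") as fh:
        cols = list(SEG_COLUMNS) + (["loh"] if any_loh else [])
        fh.write("\t".join(cols) + "\n")
        for sid in sorted(profiles):
            for s in profiles[sid].segments:
                row = [sid, s.chrom, str(s.start + shift), str(s.end),
                       str(s.n_markers), f"{s.log2_ratio:.4f}"]
                if any_loh:
                    row.append(str(int(bool(s.loh))))
                fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------- gene BED6

def write_gene_beds(genes: Sequence[GeneAnnotation], genes_bed, promoters_bed) -> None:
    """Write gene bodies and promoter windows as paired BED6 files."""
    with open(genes_bed, "w") as g, open(promoters_bed, "w") as p:
        for a in genes:
            g.write(f"{a.chrom}\t{a.start}\t{a.end}\t{a.gene}\t0\t{a.strand}\n")
            p.write(f"{a.chrom}\t{a.promoter_start}\t{a.promoter_end}\t{a.gene}\t0\t{a.strand}\n")


def read_gene_annotations(genes_bed, promoters_bed) -> list[GeneAnnotation]:
    """Assemble GeneAnnotations from paired gene-body and promoter BED6 files."""
    cols = ["chrom", "start", "end", "name", "score", "strand"]
    g = pd.read_csv(genes_bed, sep="\t", names=cols, dtype={"chrom": str})
    p = pd.read_csv(promoters_bed, sep="\t", names=cols, dtype={"chrom": str})
    if g["name"].duplicated().any():
        dup = g.loc[g["name"].duplicated(), "name"].iloc[0]
        raise ValueError(f"duplicate gene record {dup!r} in gene BED")
    pm = p.set_index("name")
    out = []
    for r in g.itertuples():
        if r.name not in pm.index:
            raise ValueError(f"gene {r.name!r} missing from promoter BED")
        pr = pm.loc[r.name]
        out.append(GeneAnnotation(r.name, r.chrom, int(r.start), int(r.end),
                                  r.strand, int(pr["start"]), int(pr["end"])))
    return out


# -------------------------------------------------------------- gene set TSV

def read_geneset(path) -> WntGeneSet:
    """Read a two-column gene/role TSV; conflicting duplicate roles are an error."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene", "role"} <= set(df.columns):
        raise ValueError("gene set TSV needs columns gene, role")
    role: dict[str, str] = {}
    for r in df.itertuples():
        if r.role not in ("activator", "repressor"):
            raise ValueError(f"gene {r.gene!r}: unknown role {r.role!r}")
        if r.gene in role:
            if role[r.gene] != r.role:
                raise ValueError(f"gene {r.gene!r} listed with conflicting roles")
            logger.info("gene %s duplicated with same role; deduplicated", r.gene)
            continue
        role[r.gene] = r.role
    return WntGeneSet(role)


def write_geneset(geneset: WntGeneSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\trole\n")
        for gene in sorted(geneset.role):
            fh.write(f"{gene}\t{geneset.role[gene]}\n")


def default_wnt_geneset() -> WntGeneSet:
    """The packaged WNT activator/repressor list.

    This is a reconstruction assembled from genes recurrently implicated as
    canonical-WNT activators (CTNNB1, FZD1, FZD7, LRP5, LRP6, WNT5B, CCND2,
    TCF7L2) and repressors (APC, BTRC, CHD8, FAT1-4) in germ cell tumors, not
    an exhaustive pathway annotation.
    """
    with resources.as_file(resources.files("wntgct.data") / "wnt_geneset.tsv") as p:
        return read_geneset(p)


# -------------------------------------------------------------- matrices TSV

def read_matrix(path) -> pd.DataFrame:
    """Read a TSV matrix with row labels in the first column."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(df: pd.DataFrame, path, float_format: str = "%.4f") -> None:
    df.to_csv(path, sep="\t", float_format=float_format)


def read_probe_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0,
                     dtype={"chrom": str, "gene": str})
    for flag in ("cross_hybridizing", "in_repeat"):
        df[flag] = df[flag].astype(bool)
    return df


# --------------------------------------------------------------- assembly

def load_cohort(directory) -> Cohort:
    """Assemble a Cohort from the on-disk layout the simulator emits."""
    from .methylation_expression import MethylationMatrix

    d = Path(directory)
    samples = read_clinical(d / "clinical.tsv")
    genes = read_gene_annotations(d / "genes.bed", d / "promoters.bed")
    geneset = read_geneset(d / "geneset.tsv")
    arms = load_arm_definitions(d / "arms.tsv")
    cn = read_segments(d / "segments.seg")
    variant_layer: dict[str, list[VariantCall]] = {}
    vcf_dir = d / "vcf"
    if vcf_dir.is_dir():
        for s in samples:
            path = vcf_dir / f"{s.sample_id}.vcf"
            if path.exists():
                variant_layer[s.sample_id] = read_variant_calls(path, s.sample_id).calls
    meth = None
    if (d / "methylation_betas.tsv").exists():
        meth = MethylationMatrix(read_matrix(d / "methylation_betas.tsv"),
                                 read_probe_annotation(d / "probe_annotation.tsv"))
    expr = groups = None
    if (d / "expression.tsv").exists():
        expr = read_matrix(d / "expression.tsv")
        gdf = pd.read_csv(d / "expression_groups.tsv", sep="\t", dtype=str)
        groups = dict(zip(gdf["sample_id"], gdf["group"]))
    return Cohort(samples=samples, variant_layer=variant_layer or None,
                  cn_layer=cn, methylation_layer=meth, expression_layer=expr,
                  expression_groups=groups, genes=genes, geneset=geneset, arms=arms)
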