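"""File-format boundary: variant TSV/VCF, coverage bins, matrices, clinical CSV, YAML configs.

The pipeline's native interchange is plain TSV/CSV written and read by
pandas; a minimal VCF 4.2 path (AD/DP in FORMAT, annotations in INFO) is
provided for interoperability, parsed with cyvcf2.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from .clinical_assoc import ClinicalRecord
from .copy_number import CoverageBin
from .synthetic_cohort import CNEvent, CohortBundle, CohortConfig
from .variant_filters import PurityEstimate, VariantRecord

_OPTIONAL_FLOAT = ("pop_af_gnomad", "pop_af_swefreq")
_OPTIONAL_INT = ("alt_support_normal", "depth_normal")
_OPTIONAL_STR = ("context5", "context3", "gene", "impact", "consequence")


def _none_if_nan(value):
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    if pd.isna(value):
        return None
    return value


def variants_from_frame(df: pd.DataFrame) -> list[VariantRecord]:
    """Materialize VariantRecord objects from the variant-table dialect."""
    records = []
    for row in df.to_dict("records"):
        kwargs = {
            "chrom": str(row["chrom"]),
            "pos": int(row["pos"]),
            "ref": str(row["ref"]),
            "alt": str(row["alt"]),
            "alt_support_tumor": int(row["alt_support_tumor"]),
            "depth_tumor": int(row["depth_tumor"]),
        }
        for col in _OPTIONAL_INT:
            v = _none_if_nan(row.get(col))
            kwargs[col] = None if v is None else int(v)
        for col in _OPTIONAL_FLOAT:
            v = _none_if_nan(row.get(col))
            kwargs[col] = None if v is None else float(v)
        for col in _OPTIONAL_STR:
            v = _none_if_nan(row.get(col))
            kwargs[col] = None if v is None else str(v)
        records.append(VariantRecord(**kwargs))
    return records


def read_variants_tsv(path) -> list[VariantRecord]:
    return variants_from_frame(pd.read_csv(path, sep="\t"))


def write_variants_tsv(records: Sequence[VariantRecord], path) -> None:
    rows = [
        {
            "chrom": r.chrom,
            "pos": r.pos,
            "ref": r.ref,
            "alt": r.alt,
            "alt_support_tumor": r.alt_support_tumor,
            "depth_tumor": r.depth_tumor,
            "alt_support_normal": r.alt_support_normal,
            "depth_normal": r.depth_normal,
            "pop_af_gnomad": r.pop_af_gnomad,
            "pop_af_swefreq": r.pop_af_swefreq,
            "context5": r.context5,
            "context3": r.context3,
            "gene": r.gene,
            "impact": r.impact,
            "consequence": r.consequence,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


VCF_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=GNOMAD_AF,Number=1,Type=Float,Description="gnomAD population allele frequency">
##INFO=<ID=SWEFREQ_AF,Number=1,Type=Float,Description="SweFreq population allele frequency">
##INFO=<ID=CTX5,Number=1,Type=String,Description="5' flanking base">
##INFO=<ID=CTX3,Number=1,Type=String,Description="3' flanking base">
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=IMPACT,Number=1,Type=String,Description="Annotated impact">
##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence term">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref, alt)">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
"""


def write_variants_vcf(records: Sequence[VariantRecord], path, sample_id: str = "TUMOR") -> None:
    """Write a minimal uncompressed VCF 4.2 with AD/DP in FORMAT."""
    lines = [VCF_HEADER.rstrip("\n")]
    contigs = sorted({r.chrom for r in records})
    for c in contigs:
        lines.append(f"##contig=<ID={c}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample_id)
    for r in sorted(records, key=lambda v: (v.chrom, v.pos)):
        info = []
        if r.pop_af_gnomad is not None:
            info.append(f"GNOMAD_AF={r.pop_af_gnomad:g}")
        if r.pop_af_swefreq is not None:
            info.append(f"SWEFREQ_AF={r.pop_af_swefreq:g}")
        for key, val in (
            ("CTX5", r.context5), ("CTX3", r.context3), ("GENE", r.gene),
            ("IMPACT", r.impact), ("CSQ", r.consequence),
        ):
            if val is not None:
                info.append(f"{key}={val}")
        ad = f"{r.depth_tumor - r.alt_support_tumor},{r.alt_support_tumor}"
        lines.append(
            f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t"
            + (";".join(info) or ".")
            + f"\tAD:DP\t{ad}:{r.depth_tumor}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_variants_vcf(path) -> list[VariantRecord]:
    """Read the minimal VCF dialect back (first sample's AD/DP)."""
    from cyvcf2 import VCF

    records = []
    vcf = VCF(str(path))
    for v in vcf:
        ad = v.format("AD")
        dp = v.format("DP")
        records.append(
            VariantRecord(
                chrom=v.CHROM,
                pos=v.POS,
                ref=v.REF,
                alt=v.ALT[0],
                alt_support_tumor=int(ad[0][1]),
                depth_tumor=int(dp[0][0]),
                pop_af_gnomad=_info_float(v, "GNOMAD_AF"),
                pop_af_swefreq=_info_float(v, "SWEFREQ_AF"),
                context5=v.INFO.get("CTX5"),
                context3=v.INFO.get("CTX3"),
                gene=v.INFO.get("GENE"),
                impact=v.INFO.get("IMPACT"),
                consequence=v.INFO.get("CSQ"),
            )
        )
    vcf.close()
    return records


def _info_float(v, key: str) -> Optional[float]:
    value = v.INFO.get(key)
    return None if value is None else float(value)


def read_purity_table(path) -> dict[str, PurityEstimate]:
    df = pd.read_csv(path, sep="\t")
    out = {}
    for row in df.to_dict("records"):
        p = _none_if_nan(row.get("purity"))
        out[str(row["sample_id"])] = PurityEstimate(str(row["sample_id"]), None if p is None else float(p))
    return out


def write_bins_tsv(bins: Sequence[CoverageBin], path) -> None:
    pd.DataFrame(
        [{"chrom": b.chrom, "start": b.start, "end": b.end, "gc": b.gc, "coverage": b.coverage} for b in bins]
    ).to_csv(path, sep="\t", index=False)


def read_bins_tsv(path) -> list[CoverageBin]:
    df = pd.read_csv(path, sep="\t")
    return [
        CoverageBin(str(r["chrom"]), int(r["start"]), int(r["end"]), float(r["gc"]), float(r["coverage"]))
        for r in df.to_dict("records")
    ]


def read_clinical_csv(path) -> list[ClinicalRecord]:
    df = pd.read_csv(path)
    records = []
    for row in df.to_dict("records"):
        records.append(
            ClinicalRecord(
                patient_id=str(row["patient_id"]),
                role=str(row["role"]),
                er=_none_if_nan(row.get("ER")),
                pgr=_none_if_nan(row.get("PgR")),
                ki67=_none_if_nan(row.get("Ki67")),
                erbb2=_none_if_nan(row.get("ERBB2")),
                grade=_none_if_nan(row.get("grade")),
                age_group=_none_if_nan(row.get("age_group")),
                ibtrfs_time=_none_if_nan(row.get("ibtrfs_time_months")),
                event=bool(row["event"]) if _none_if_nan(row.get("event")) is not None else None,
            )
        )
    return records


def load_config_yaml(path) -> CohortConfig:
    """Read a cohort configuration from YAML (see docs for the schema)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if "cn_events" in raw:
        raw["cn_events"] = [CNEvent(**ev) for ev in raw["cn_events"]]
    if "purity_range" in raw:
        raw["purity_range"] = tuple(raw["purity_range"])
    return CohortConfig(**raw)


def save_config_yaml(config: CohortConfig, path) -> None:
    data = {
        "n_patients": config.n_patients,
        "purity_range": list(config.purity_range),
        "depth_mean": config.depth_mean,
        "n_shared_variants": config.n_shared_variants,
        "n_private_pt": config.n_private_pt,
        "n_private_ibtr": config.n_private_ibtr,
        "signature_mix_pt": list(map(float, config.signature_mix_pt)),
        "signature_mix_ibtr": list(map(float, config.signature_mix_ibtr)),
        "cn_events": [
            {"chrom": e.chrom, "start": e.start, "end": e.end, "log2_shift": e.log2_shift, "target": e.target}
            for e in config.cn_events
        ],
        "drift_sigma": config.drift_sigma,
        "germline_af_fraction": config.germline_af_fraction,
        "pon_artifact_fraction": config.pon_artifact_fraction,
        "seed": config.seed,
        "chrom_lengths": dict(config.chrom_lengths),
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def write_bundle(bundle: CohortBundle, outdir) -> None:
    """Write every bundle component in the formats the pipeline reads."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for sample, table in bundle.variant_tables.items():
        table.to_csv(out / f"variants_{sample}.tsv", sep="\t", index=False)
    bundle.purity.to_csv(out / "purity.tsv", sep="\t", index=False)
    for sample, bins in bundle.coverage_bins.items():
        write_bins_tsv(bins, out / f"bins_{sample}.tsv")
    bundle.expression.to_csv(out / "expression.tsv", sep="\t", index_label="feature")
    bundle.protein.to_csv(out / "protein.tsv", sep="\t", index_label="feature")
    bundle.clinical.to_csv(out / "clinical.csv", index=False)
    pd.DataFrame(
        [{"normal": i, "key": f"{c}:{p}:{r}:{a}"} for i, s in enumerate(bundle.normal_variant_sets) for (c, p, r, a) in sorted(s)]
    ).to_csv(out / "normal_variants.tsv", sep="\t", index=False)
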