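"""Readers and writers for the tabular pipeline formats.

All interchange formats are plain TSV; VCF ingestion is optional and uses
cyvcf2 when available, falling back to pysam.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import pandas as pd

from .caller import AllelicStatusCall, PhasingObservation, SampleGenomics, SomaticMutation

MUTATION_COLUMNS = [
    "sample_id", "mutation_id", "gene", "chrom", "pos", "ref", "alt",
    "vaf", "alt_reads", "ref_reads", "effect", "subclonal_probability",
]


def _opt_int(value):
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return int(value)


def read_mutations_tsv(path) -> dict:
    """Read a mutations TSV into ``{sample_id: [SomaticMutation, ...]}``."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = {"sample_id", "mutation_id", "gene", "vaf"} - set(df.columns)
    if missing:
        raise ValueError(f"mutations TSV lacks required columns: {sorted(missing)}")
    out: dict = {}
    for row in df.itertuples(index=False):
        mut = SomaticMutation(
            mutation_id=str(row.mutation_id),
            gene=str(row.gene),
            chrom=str(getattr(row, "chrom", ".")),
            pos=int(getattr(row, "pos", 1)),
            ref=str(getattr(row, "ref", "N")),
            alt=str(getattr(row, "alt", "N")),
            vaf=float(row.vaf),
            alt_reads=_opt_int(getattr(row, "alt_reads", None)),
            ref_reads=_opt_int(getattr(row, "ref_reads", None)),
            effect=str(getattr(row, "effect", "non_synonymous")),
            subclonal_probability=float(getattr(row, "subclonal_probability", 0.0) or 0.0),
        )
        out.setdefault(str(row.sample_id), []).append(mut)
    return out


def read_genomics_tsv(path) -> dict:
    df = pd.read_csv(path, sep="\t")
    out = {}
    for row in df.itertuples(index=False):
        sid = str(row.sample_id)
        out[sid] = SampleGenomics(
            sample_id=sid,
            purity=float(row.purity),
            ploidy=float(getattr(row, "ploidy", 2.0)),
            gene_total_cn=int(row.gene_total_cn),
            gene_minor_cn=_opt_int(getattr(row, "gene_minor_cn", None)),
            megabases_sequenced=float(getattr(row, "megabases_sequenced", 3000.0)),
        )
    return out


def read_phasing_tsv(path) -> dict:
    df = pd.read_csv(path, sep="\t")
    out: dict = {}
    for row in df.itertuples(index=False):
        obs = PhasingObservation(
            mutation_id_a=str(row.mutation_id_a),
            mutation_id_b=str(row.mutation_id_b),
            spanning_reads_both_alt=int(row.spanning_reads_both_alt),
            spanning_reads_a_only=int(row.spanning_reads_a_only),
            spanning_reads_b_only=int(row.spanning_reads_b_only),
            spanning_reads_neither=int(getattr(row, "spanning_reads_neither", 0)),
        )
        out.setdefault(str(row.sample_id), []).append(obs)
    return out


def read_expression_tsv(path, library_sizes_path=None):
    """Read a genes x samples count matrix and optional library sizes."""
    expr = pd.read_csv(path, sep="\t", index_col=0)
    lib = None
    if library_sizes_path is not None:
        lib_df = pd.read_csv(library_sizes_path, sep="\t", index_col=0)
        lib = lib_df.iloc[:, 0].astype(float)
    return expr, lib


def read_clinical_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise ValueError("clinical TSV lacks a sample_id column")
    df["sample_id"] = df["sample_id"].astype(str)
    return df


def calls_to_frame(calls) -> pd.DataFrame:
    rows = []
    for call in calls:
        rows.append(
            {
                "sample_id": call.sample_id,
                "b2m_status": call.b2m_status,
                "biallelic_class": call.biallelic_class,
                "clonal_nonsynonymous_count": call.clonal_nonsynonymous_count,
                "n_mutations": len(call.mut_cn_per_mutation),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id", "b2m_status", "biallelic_class",
            "clonal_nonsynonymous_count", "n_mutations",
        ],
    )


def write_calls(calls, tsv_path, json_path=None) -> None:
    """Write calls as a TSV plus an optional JSON evidence dump."""
    calls = list(calls)
    calls_to_frame(calls).to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        payload = {
            call.sample_id: {
                "b2m_status": call.b2m_status,
                "biallelic_class": call.biallelic_class,
                "mut_cn_per_mutation": call.mut_cn_per_mutation,
                "loh_per_mutation": call.loh_per_mutation,
                "phasing_relations": {
                    "|".join(k): v for k, v in call.phasing_relations.items()
                },
                "clonal_nonsynonymous_count": call.clonal_nonsynonymous_count,
                "evidence": call.evidence,
            }
            for call in calls
        }
        Path(json_path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_calls_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["sample_id"] = df["sample_id"].astype(str)
    return df


def read_mutations_vcf(path, sample_field=None) -> dict:
    """Read somatic mutations from a VCF, deriving VAF from AD or AF.

    Requires cyvcf2 or pysam.  Gene symbols are taken from an INFO ``GENE``
    annotation when present, the effect from INFO ``EFFECT``.
    """
    try:
        from cyvcf2 import VCF
    except ImportError:  # pragma: no cover - depends on environment extras
        return _read_mutations_vcf_pysam(path)
    out: dict = {}
    vcf = VCF(str(path))
    samples = vcf.samples
    for idx, variant in enumerate(vcf):
        gene = variant.INFO.get("GENE", ".")
        effect = variant.INFO.get("EFFECT", "non_synonymous")
        depths = variant.format("AD")
        afs = variant.format("AF") if depths is None else None
        for s_i, sid in enumerate(samples):
            if depths is not None:
                ref_reads, alt_reads = int(depths[s_i][0]), int(depths[s_i][1])
                total = ref_reads + alt_reads
                if total == 0:
                    continue
                vaf = alt_reads / total
            elif afs is not None:
                vaf = float(afs[s_i][0])
                alt_reads = ref_reads = None
            else:
                continue
            mut = SomaticMutation(
                mutation_id=variant.ID or f"var{idx}",
                gene=str(gene),
                chrom=str(variant.CHROM),
                pos=int(variant.POS),
                ref=str(variant.REF),
                alt=str(variant.ALT[0]) if variant.ALT else "N",
                vaf=float(vaf),
                alt_reads=alt_reads,
                ref_reads=ref_reads,
                effect=str(effect),
            )
            out.setdefault(sid, []).append(mut)
    return out


def _read_mutations_vcf_pysam(path) -> dict:
    import pysam

    out: dict = {}
    with pysam.VariantFile(str(path)) as vcf:
        for idx, rec in enumerate(vcf):
            gene = rec.info.get("GENE", ".")
            effect = rec.info.get("EFFECT", "non_synonymous")
            for sid, sample in rec.samples.items():
                ad = sample.get("AD")
                if ad is not None and len(ad) >= 2 and ad[0] is not None:
                    ref_reads, alt_reads = int(ad[0]), int(ad[1])
                    total = ref_reads + alt_reads
                    if total == 0:
                        continue
                    vaf = alt_reads / total
                else:
                    af = sample.get("AF")
                    if af is None:
                        continue
                    vaf = float(af[0] if isinstance(af, tuple) else af)
                    alt_reads = ref_reads = None
                out.setdefault(sid, []).append(
                    SomaticMutation(
                        mutation_id=rec.id or f"var{idx}",
                        gene=str(gene),
                        chrom=str(rec.chrom),
                        pos=int(rec.pos),
                        ref=str(rec.ref),
                        alt=str(rec.alts[0]) if rec.alts else "N",
                        vaf=float(vaf),
                        alt_reads=alt_reads,
                        ref_reads=ref_reads,
                        effect=str(effect),
                    )
                )
    return out
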