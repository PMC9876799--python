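"""Synthetic cohort generation with known ground truth.

Produces per-sample somatic mutations with binomially sampled read support,
cis/trans spanning-read phasing evidence, a raw-count expression matrix with
a status-dependent shift on TRDV1/TRDV3 and KIR genes, and logistic
clinical-benefit outcomes — everything the downstream stages consume, with
truth labels for recovery testing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .caller import PhasingObservation, SampleGenomics, SomaticMutation

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "expected_vaf",
    "simulate_phasing_reads",
    "simulate_cohort",
]

KIR_GENES = ["KIR2DL1", "KIR2DL3", "KIR2DL4", "KIR2DS4", "KIR3DL1", "KIR3DL2"]
MARKER_GENES = {
    "TRDV1": 20.0,
    "TRDV3": 12.0,
    "CD4": 80.0,
    "NCR1": 15.0,
    "KLRF1": 15.0,
    "GZMA": 60.0,
    "GZMB": 50.0,
    "GZMH": 30.0,
    "PRF1": 40.0,
    "GNLY": 45.0,
    "CTSW": 35.0,
    "IL21R": 10.0,
    "XCL1": 8.0,
    "XCL2": 6.0,
    "B2M": 500.0,
}
KIR_BASE_RPM = 10.0
N_BACKGROUND_GENES = 40

TUMOUR_TYPES = ["CRC", "gastric", "endometrial", "other"]
TUMOUR_TYPE_WEIGHTS = [0.5, 0.2, 0.2, 0.1]
BIOPSY_SITES = ["primary", "liver", "lymph_node", "peritoneum"]
BIOPSY_SITE_WEIGHTS = [0.4, 0.3, 0.2, 0.1]

B2M_LOCUS = ("15", 44_711_000)  # chrom, approximate first exon position


@dataclass
class SimulationConfig:
    """Knobs of the generative model; every field has a tested default."""

    n_samples: int = 100
    frac_b2m_mut: float = 0.3
    frac_biallelic_given_mut: float = 0.6
    purity_range: tuple = (0.3, 0.9)
    depth: float = 80.0
    gene_cn_distribution: dict = field(
        default_factory=lambda: {1: 0.1, 2: 0.7, 3: 0.15, 4: 0.05}
    )
    effect_trdv: float = 1.0
    effect_kir: float = 0.8
    cb_intercept: float = 0.2
    cb_beta_b2m: float = 2.0
    cb_beta_tmb: float = 0.02
    tmb_lognormal_params: tuple = (3.3, 0.5)  # (mu, sigma) of log TMB/Mb
    frac_decoy_mutations: float = 0.15
    library_size_lognormal_params: tuple = (13.8, 0.2)  # ~1e6 reads
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_b2m_mut", "frac_biallelic_given_mut", "frac_decoy_mutations"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.purity_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError(f"invalid purity_range {self.purity_range}")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if not self.gene_cn_distribution:
            raise ValueError("gene_cn_distribution must be non-empty")
        if any(cn < 1 or cn > 4 for cn in self.gene_cn_distribution):
            raise ValueError("gene copy numbers must lie in 1..4")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        if "purity_range" in raw:
            raw["purity_range"] = tuple(raw["purity_range"])
        if "tmb_lognormal_params" in raw:
            raw["tmb_lognormal_params"] = tuple(raw["tmb_lognormal_params"])
        if "library_size_lognormal_params" in raw:
            raw["library_size_lognormal_params"] = tuple(
                raw["library_size_lognormal_params"]
            )
        if "gene_cn_distribution" in raw:
            raw["gene_cn_distribution"] = {
                int(k): float(v) for k, v in raw["gene_cn_distribution"].items()
            }
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = {
            **self.__dict__,
            "purity_range": list(self.purity_range),
            "tmb_lognormal_params": list(self.tmb_lognormal_params),
            "library_size_lognormal_params": list(self.library_size_lognormal_params),
        }
        with open(path, "w") as handle:
            yaml.safe_dump(data, handle, sort_keys=True)


@dataclass
class SyntheticCohort:
    """Simulated inputs plus the truth labels used to generate them."""

    mutations: dict  # sample_id -> list[SomaticMutation]
    genomics: dict  # sample_id -> SampleGenomics
    phasing: dict  # sample_id -> list[PhasingObservation]
    expression: pd.DataFrame  # genes x samples, raw counts
    library_sizes: pd.Series
    clinical: pd.DataFrame  # sample_id, tumour_type, biopsy_site, cb, tmb
    truth: pd.DataFrame  # sample_id, b2m_status, biallelic_class

    def __post_init__(self) -> None:
        samples = set(self.truth["sample_id"])
        if set(self.genomics) != samples:
            raise ValueError("truth labels must cover every sample")
        for sid in self.mutations:
            if sid not in self.genomics:
                raise ValueError(f"mutations for unknown sample {sid}")
        if (self.expression.values < 0).any():
            raise ValueError("expression counts must be non-negative")

    @property
    def sample_ids(self) -> list:
        return list(self.truth["sample_id"])

    def write(self, out_dir) -> None:
        """Write the standard pipeline input TSVs to a directory."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        mut_rows = []
        for sid, muts in self.mutations.items():
            for m in muts:
                mut_rows.append(
                    {
                        "sample_id": sid,
                        "mutation_id": m.mutation_id,
                        "gene": m.gene,
                        "chrom": m.chrom,
                        "pos": m.pos,
                        "ref": m.ref,
                        "alt": m.alt,
                        "vaf": m.vaf,
                        "alt_reads": m.alt_reads,
                        "ref_reads": m.ref_reads,
                        "effect": m.effect,
                        "subclonal_probability": m.subclonal_probability,
                    }
                )
        pd.DataFrame(
            mut_rows,
            columns=[
                "sample_id", "mutation_id", "gene", "chrom", "pos", "ref",
                "alt", "vaf", "alt_reads", "ref_reads", "effect",
                "subclonal_probability",
            ],
        ).to_csv(out / "mutations.tsv", sep="\t", index=False)

        pd.DataFrame(
            [
                {
                    "sample_id": g.sample_id,
                    "purity": g.purity,
                    "ploidy": g.ploidy,
                    "gene_total_cn": g.gene_total_cn,
                    "gene_minor_cn": g.gene_minor_cn,
                    "megabases_sequenced": g.megabases_sequenced,
                }
                for g in self.genomics.values()
            ]
        ).to_csv(out / "genomics.tsv", sep="\t", index=False)

        phase_rows = []
        for sid, obs_list in self.phasing.items():
            for o in obs_list:
                phase_rows.append(
                    {
                        "sample_id": sid,
                        "mutation_id_a": o.mutation_id_a,
                        "mutation_id_b": o.mutation_id_b,
                        "spanning_reads_both_alt": o.spanning_reads_both_alt,
                        "spanning_reads_a_only": o.spanning_reads_a_only,
                        "spanning_reads_b_only": o.spanning_reads_b_only,
                        "spanning_reads_neither": o.spanning_reads_neither,
                    }
                )
        pd.DataFrame(
            phase_rows,
            columns=[
                "sample_id", "mutation_id_a", "mutation_id_b",
                "spanning_reads_both_alt", "spanning_reads_a_only",
                "spanning_reads_b_only", "spanning_reads_neither",
            ],
        ).to_csv(out / "phasing.tsv", sep="\t", index=False)

        expr = self.expression.copy()
        expr.index.name = "gene"
        expr.to_csv(out / "expression.tsv", sep="\t")
        lib = self.library_sizes.rename("library_size")
        lib.index.name = "sample_id"
        lib.to_csv(out / "library_sizes.tsv", sep="\t")
        self.clinical.to_csv(out / "clinical.tsv", sep="\t", index=False)
        self.truth.to_csv(out / "truth.tsv", sep="\t", index=False)


def expected_vaf(mut_cn: int, total_cn: int, purity: float) -> float:
    """Expected allele fraction of a mutation on ``mut_cn`` of ``total_cn``
    tumour copies in a sample of the given purity (normal cells diploid)."""
    if not 1 <= mut_cn:
        raise ValueError("mut_cn must be >= 1")
    if mut_cn > total_cn:
        raise ValueError(f"mut_cn {mut_cn} exceeds total_cn {total_cn}")
    if not 0.0 < purity <= 1.0:
        raise ValueError(f"purity must be in (0, 1], got {purity}")
    return (mut_cn * purity) / (total_cn * purity + 2.0 * (1.0 - purity))


def simulate_phasing_reads(
    relation: str, depth: int, seed_or_rng
) -> PhasingObservation:
    """Draw a spanning-read observation consistent with the given relation.

    ``seed_or_rng`` may be an integer seed or a ``numpy`` Generator.
    Phased relations degrade to unphaseable when no spanning read is drawn.
    """
    if relation not in ("cis", "trans", "unphaseable"):
        raise ValueError(f"unknown phasing relation {relation!r}")
    if depth < 0:
        raise ValueError("depth must be >= 0")
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    obs = dict(
        spanning_reads_both_alt=0,
        spanning_reads_a_only=0,
        spanning_reads_b_only=0,
        spanning_reads_neither=0,
    )
    if depth > 0:
        if relation == "cis":
            both = int(rng.binomial(depth, 0.5))
            obs["spanning_reads_both_alt"] = max(both, 1)
            obs["spanning_reads_neither"] = depth - max(both, 1)
        elif relation == "trans":
            a = int(rng.binomial(depth, 0.4))
            b = int(rng.binomial(depth - a, 0.5)) if depth - a > 0 else 0
            obs["spanning_reads_a_only"] = max(a, 1)
            obs["spanning_reads_b_only"] = max(b, 1)
            leftover = depth - obs["spanning_reads_a_only"] - obs["spanning_reads_b_only"]
            obs["spanning_reads_neither"] = max(leftover, 0)
    return PhasingObservation(mutation_id_a="", mutation_id_b="", **obs)


def _draw_vaf(rng, mut_cn, total_cn, purity, depth, ccf=1.0):
    """Binomial read sampling at the expected allele fraction."""
    evaf = expected_vaf(mut_cn, total_cn, purity) * ccf
    site_depth = max(int(rng.poisson(depth)), 1)
    alt = int(rng.binomial(site_depth, evaf))
    ref = site_depth - alt
    return alt / site_depth, alt, ref


def _mutation(rng, sid, idx, vaf, alt, ref, effect="non_synonymous", subclonal_p=0.0):
    chrom, base_pos = B2M_LOCUS
    pos = base_pos + int(rng.integers(0, 8000))
    ref_base, alt_base = rng.choice(["A", "C", "G", "T"], size=2, replace=False)
    return SomaticMutation(
        mutation_id=f"{sid}_m{idx}",
        gene="B2M",
        chrom=chrom,
        pos=pos,
        ref=str(ref_base),
        alt=str(alt_base),
        vaf=vaf,
        alt_reads=alt,
        ref_reads=ref,
        effect=effect,
        subclonal_probability=subclonal_p,
    )


def _plan_mutant(rng, biallelic: bool, total_cn: int):
    """Choose a ground-truth mutation architecture for a mutant sample.

    Returns (class label, list of mut_cn, pair relation or None, minor CN).
    Multi-mutation architectures are only generated at gene CN 2, where the
    diploid VAF-to-copy-number inversion used by the caller is exact; at
    other copy numbers LOH is conveyed through the minor allele CN, as a
    segmentation caller would report it.
    """
    if total_cn == 1:
        # any clonal mutation on a single remaining copy implies LOH
        return "biallelic", [1], None, 0
    if biallelic:
        if total_cn == 2 and rng.random() < 0.5:
            return "biallelic", [1, 1], "trans", 1
        return "biallelic", [total_cn], None, 0  # all copies mutated
    if total_cn == 2:
        r = rng.random()
        if r < 1.0 / 3.0:
            return "potentially_biallelic", [1, 1], "unphaseable", 1
        if r < 2.0 / 3.0:
            return "not_biallelic", [1, 1], "cis", 1
        return "not_biallelic", [1], None, 1
    return "not_biallelic", [1], None, 1


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a fully labelled cohort under the configured model."""
    rng = np.random.default_rng(config.seed)
    if 0 < config.frac_b2m_mut and config.n_samples * config.frac_b2m_mut < 1:
        warnings.warn(
            "expected number of mutant samples is below 1; "
            "the cohort may contain none",
            stacklevel=2,
        )

    cn_values = sorted(config.gene_cn_distribution)
    cn_weights = np.array([config.gene_cn_distribution[v] for v in cn_values], float)
    cn_weights /= cn_weights.sum()

    mutations: dict = {}
    genomics: dict = {}
    phasing: dict = {}
    truth_rows = []
    clinical_rows = []
    is_mutant = np.zeros(config.n_samples, dtype=bool)
    tmb = np.exp(
        rng.normal(*config.tmb_lognormal_params, size=config.n_samples)
    ) / 100.0  # per-Mb scale

    for i in range(config.n_samples):
        sid = f"S{i:04d}"
        purity = float(rng.uniform(*config.purity_range))
        total_cn = int(rng.choice(cn_values, p=cn_weights))
        mutations[sid] = []
        phasing[sid] = []

        mutant = bool(rng.random() < config.frac_b2m_mut)
        is_mutant[i] = mutant
        minor_cn = 0 if total_cn == 1 else 1
        if mutant:
            biallelic = bool(rng.random() < config.frac_biallelic_given_mut)
            label, mut_cns, relation, minor_cn = _plan_mutant(
                rng, biallelic, total_cn
            )
            for j, cn in enumerate(mut_cns):
                vaf, alt, ref = _draw_vaf(rng, cn, total_cn, purity, config.depth)
                mutations[sid].append(_mutation(rng, sid, j, vaf, alt, ref))
            if relation is not None:
                obs = simulate_phasing_reads(relation, int(config.depth), rng)
                phasing[sid].append(
                    PhasingObservation(
                        mutation_id_a=mutations[sid][0].mutation_id,
                        mutation_id_b=mutations[sid][1].mutation_id,
                        spanning_reads_both_alt=obs.spanning_reads_both_alt,
                        spanning_reads_a_only=obs.spanning_reads_a_only,
                        spanning_reads_b_only=obs.spanning_reads_b_only,
                        spanning_reads_neither=obs.spanning_reads_neither,
                    )
                )
        else:
            label = "not_applicable"

        genomics[sid] = SampleGenomics(
            sample_id=sid,
            purity=purity,
            ploidy=2.0,
            gene_total_cn=total_cn,
            gene_minor_cn=minor_cn,
            megabases_sequenced=3000.0,
        )

        # decoy mutations never change the call: synonymous or subclonal
        if rng.random() < config.frac_decoy_mutations:
            decoy_cn = 1
            if rng.random() < 0.5:
                vaf, alt, ref = _draw_vaf(rng, decoy_cn, max(total_cn, 1), purity, config.depth)
                mutations[sid].append(
                    _mutation(rng, sid, 90, vaf, alt, ref, effect="synonymous")
                )
            else:
                ccf = float(rng.uniform(0.1, 0.5))
                vaf, alt, ref = _draw_vaf(
                    rng, decoy_cn, max(total_cn, 1), purity, config.depth, ccf=ccf
                )
                mutations[sid].append(
                    _mutation(
                        rng, sid, 91, vaf, alt, ref,
                        subclonal_p=float(rng.uniform(0.6, 1.0)),
                    )
                )

        truth_rows.append(
            {
                "sample_id": sid,
                "b2m_status": "mutant" if mutant else "wildtype",
                "biallelic_class": label,
            }
        )
        clinical_rows.append(
            {
                "sample_id": sid,
                "tumour_type": str(rng.choice(TUMOUR_TYPES, p=TUMOUR_TYPE_WEIGHTS)),
                "biopsy_site": str(rng.choice(BIOPSY_SITES, p=BIOPSY_SITE_WEIGHTS)),
                "tmb": float(tmb[i]),
            }
        )

    # logistic clinical-benefit outcomes
    eta = (
        config.cb_intercept
        + config.cb_beta_b2m * is_mutant.astype(float)
        + config.cb_beta_tmb * tmb
    )
    p_cb = 1.0 / (1.0 + np.exp(-eta))
    cb = rng.random(config.n_samples) < p_cb
    for row, benefit in zip(clinical_rows, cb):
        row["clinical_benefit"] = "CB" if benefit else "NCB"

    expression, library_sizes = _simulate_expression(rng, config, is_mutant)

    return SyntheticCohort(
        mutations=mutations,
        genomics=genomics,
        phasing=phasing,
        expression=expression,
        library_sizes=library_sizes,
        clinical=pd.DataFrame(clinical_rows)[
            ["sample_id", "tumour_type", "biopsy_site", "clinical_benefit", "tmb"]
        ],
        truth=pd.DataFrame(truth_rows),
    )


def _simulate_expression(rng, config, is_mutant):
    """Poisson counts around per-gene baseline RPM, with the configured
    log2-scale shift applied to TRDV and KIR genes in mutant samples."""
    genes = list(MARKER_GENES) + KIR_GENES + [
        f"BG{i:03d}" for i in range(N_BACKGROUND_GENES)
    ]
    base_rpm = dict(MARKER_GENES)
    for g in KIR_GENES:
        base_rpm[g] = KIR_BASE_RPM
    bg_levels = np.exp(rng.normal(3.0, 1.0, size=N_BACKGROUND_GENES))
    for i in range(N_BACKGROUND_GENES):
        base_rpm[f"BG{i:03d}"] = float(bg_levels[i])

    n = len(is_mutant)
    sample_ids = [f"S{i:04d}" for i in range(n)]
    lib = np.exp(rng.normal(*config.library_size_lognormal_params, size=n))
    lib = np.maximum(lib, 1e4).round()

    rpm = np.empty((len(genes), n))
    for gi, g in enumerate(genes):
        level = np.full(n, base_rpm[g])
        shift = 0.0
        if g in ("TRDV1", "TRDV3"):
            shift = config.effect_trdv
        elif g in KIR_GENES:
            shift = config.effect_kir
        if shift:
            # exact shift on the log2(RPM + 1) scale used by the scorer
            level = np.where(
                is_mutant, (base_rpm[g] + 1.0) * 2.0 ** shift - 1.0, level
            )
        rpm[gi] = level

    lam = rpm * lib[None, :] / 1e6
    counts = rng.poisson(lam)
    expression = pd.DataFrame(counts, index=genes, columns=sample_ids)
    library_sizes = pd.Series(lib, index=sample_ids, name="library_size")
    return expression, library_sizes
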