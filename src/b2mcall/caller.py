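"""Somatic allelic-status calling for a single target gene.

Implements mutation copy number from VAF and tumour purity, LOH calling,
read-backed cis/trans phasing, the three-class biallelic decision tree and
tumour mutational burden.  The target gene defaults to *B2M* but the logic
is gene-generic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "SomaticMutation",
    "SampleGenomics",
    "PhasingObservation",
    "AllelicStatusCall",
    "mutation_copy_number",
    "call_loh",
    "phase_pair",
    "is_subclonal",
    "classify_allelic_status",
    "compute_tmb",
]

CIS = "cis"
TRANS = "trans"
UNPHASEABLE = "unphaseable"

SUBCLONAL_PROBABILITY_THRESHOLD = 0.5
IMPLAUSIBLE_MUT_CN = 10


@dataclass(frozen=True)
class SomaticMutation:
    """One somatic variant with allele-fraction support and annotation."""

    mutation_id: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    vaf: float
    alt_reads: Optional[int] = None
    ref_reads: Optional[int] = None
    effect: str = "non_synonymous"
    subclonal_probability: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"vaf must be in [0, 1], got {self.vaf}")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.effect not in ("synonymous", "non_synonymous"):
            raise ValueError(f"unknown effect {self.effect!r}")
        if not 0.0 <= self.subclonal_probability <= 1.0:
            raise ValueError("subclonal_probability must be in [0, 1]")
        if self.alt_reads is not None and self.ref_reads is not None:
            total = self.alt_reads + self.ref_reads
            if total > 0 and abs(self.vaf - self.alt_reads / total) >= 1e-6:
                raise ValueError(
                    f"vaf {self.vaf} inconsistent with read counts "
                    f"{self.alt_reads}/{total} for {self.mutation_id}"
                )


@dataclass(frozen=True)
class SampleGenomics:
    """Per-sample purity, ploidy and target-gene copy number."""

    sample_id: str
    purity: float
    ploidy: float = 2.0
    gene_total_cn: int = 2
    gene_minor_cn: Optional[int] = None
    megabases_sequenced: float = 3000.0

    def __post_init__(self) -> None:
        if not 0.0 < self.purity <= 1.0:
            raise ValueError(f"purity must be in (0, 1], got {self.purity}")
        if self.gene_total_cn < 0:
            raise ValueError("gene_total_cn must be >= 0")
        if self.gene_minor_cn is not None and self.gene_minor_cn > self.gene_total_cn:
            raise ValueError("gene_minor_cn cannot exceed gene_total_cn")


@dataclass(frozen=True)
class PhasingObservation:
    """Spanning-read counts for a pair of mutations on the same fragment."""

    mutation_id_a: str
    mutation_id_b: str
    spanning_reads_both_alt: int = 0
    spanning_reads_a_only: int = 0
    spanning_reads_b_only: int = 0
    spanning_reads_neither: int = 0

    def __post_init__(self) -> None:
        for name in (
            "spanning_reads_both_alt",
            "spanning_reads_a_only",
            "spanning_reads_b_only",
            "spanning_reads_neither",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class AllelicStatusCall:
    """Per-sample verdict for the target gene with its evidence trail."""

    sample_id: str
    b2m_status: str  # "wildtype" | "mutant"
    biallelic_class: str  # "biallelic" | "potentially_biallelic" | "not_biallelic" | "not_applicable"
    mut_cn_per_mutation: dict = field(default_factory=dict)
    loh_per_mutation: dict = field(default_factory=dict)
    phasing_relations: dict = field(default_factory=dict)
    clonal_nonsynonymous_count: int = 0
    evidence: list = field(default_factory=list)


def mutation_copy_number(vaf: float, purity: float) -> int:
    """Estimate the integer number of tumour genome copies carrying a mutation.

    Computed as round(2 * vaf / purity), with exact halves rounded away
    from zero so the result does not depend on the platform's default
    (banker's) rounding.

    Parameters
    ----------
    vaf : variant allele frequency in [0, 1].
    purity : tumour cell fraction in (0, 1].
    """
    if not 0.0 <= vaf <= 1.0:
        raise ValueError(f"vaf must be in [0, 1], got {vaf}")
    if not 0.0 < purity <= 1.0:
        raise ValueError(f"purity must be in (0, 1], got {purity}")
    raw = 2.0 * vaf / purity
    mut_cn = int(math.floor(raw + 0.5))  # half away from zero (raw >= 0)
    if mut_cn > IMPLAUSIBLE_MUT_CN:
        warnings.warn(
            f"mutation copy number {mut_cn} is implausibly high; "
            "purity may be underestimated",
            stacklevel=2,
        )
    return mut_cn


def call_loh(
    mut_cn: int, gene_total_cn: int, gene_minor_cn: Optional[int] = None
) -> bool:
    """True when no wild-type copy of the locus remains in tumour cells.

    A mutation copy number equal to (or exceeding) the gene's total copy
    number means every tumour copy carries the mutation; alternatively a
    minor allele copy number of zero from segmentation shows the second
    allele was lost.
    """
    if mut_cn < 0:
        raise ValueError("mut_cn must be >= 0")
    if gene_total_cn < 1:
        raise ValueError("gene_total_cn must be >= 1")
    if mut_cn >= gene_total_cn:
        return True
    return gene_minor_cn == 0


def phase_pair(obs: PhasingObservation) -> str:
    """Classify a mutation pair as cis, trans or unphaseable.

    A single spanning read carrying both alternate alleles is sufficient
    for cis.  Trans requires spanning reads carrying exactly one alternate
    allele each, for both mutations, and none carrying both.  Without any
    alt-bearing spanning read the pair is unphaseable.
    """
    if obs.spanning_reads_both_alt >= 1:
        if obs.spanning_reads_a_only >= 1 and obs.spanning_reads_b_only >= 1:
            warnings.warn(
                f"conflicting phasing evidence for "
                f"({obs.mutation_id_a}, {obs.mutation_id_b}); resolving to cis",
                stacklevel=2,
            )
        return CIS
    if obs.spanning_reads_a_only >= 1 and obs.spanning_reads_b_only >= 1:
        return TRANS
    return UNPHASEABLE


def is_subclonal(subclonal_probability: float) -> bool:
    """True when a mutation is more likely subclonal than clonal (p > 0.5)."""
    if not 0.0 <= subclonal_probability <= 1.0:
        raise ValueError("subclonal_probability must be in [0, 1]")
    return subclonal_probability > SUBCLONAL_PROBABILITY_THRESHOLD


def _pair_key(id_a: str, id_b: str) -> tuple:
    return tuple(sorted((id_a, id_b)))


def _cis_components(ids: Sequence[str], relations: Mapping[tuple, str]) -> list:
    """Group mutation ids into components connected by cis edges."""
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for (a, b), rel in relations.items():
        if rel == CIS and a in parent and b in parent:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[rb] = ra
    comps: dict = {}
    for i in ids:
        comps.setdefault(find(i), []).append(i)
    return [sorted(v) for v in comps.values()]


def classify_allelic_status(
    mutations: Iterable[SomaticMutation],
    genomics: SampleGenomics,
    phasing: Iterable[PhasingObservation] = (),
    gene: str = "B2M",
) -> AllelicStatusCall:
    """Run the full allelic-status decision tree for one sample.

    A sample is mutant when it carries at least one clonal, non-synonymous
    mutation in the target gene (or a homozygous deletion of the gene).
    Mutant samples are assigned one of three biallelic classes:

    * ``biallelic`` — mutations in trans whose integer mutation copy
      numbers sum to at least the gene copy number (cis groups contribute
      a single representative), or any mutation showing LOH;
    * ``potentially_biallelic`` — the copy-number sum reaches the gene
      copy number but at least one pair could not be phased, and no
      mutation shows LOH;
    * ``not_biallelic`` — the sum falls short of the gene copy number and
      no mutation shows LOH.

    Synonymous and subclonal mutations are excluded from classification
    but recorded in the evidence trail.
    """
    mutations = list(mutations)
    evidence: list = []

    for mut in mutations:
        if mut.gene != gene:
            raise ValueError(
                f"mutation {mut.mutation_id} is in gene {mut.gene!r}, "
                f"not target gene {gene!r}"
            )

    mut_cn = {
        m.mutation_id: mutation_copy_number(m.vaf, genomics.purity)
        for m in mutations
    }
    loh = {
        mid: call_loh(cn, genomics.gene_total_cn, genomics.gene_minor_cn)
        if genomics.gene_total_cn >= 1
        else False
        for mid, cn in mut_cn.items()
    }

    excluded = []
    clonal_nonsyn = []
    for m in mutations:
        if m.effect == "synonymous":
            excluded.append((m.mutation_id, "synonymous"))
        elif is_subclonal(m.subclonal_probability):
            excluded.append((m.mutation_id, "subclonal"))
        else:
            clonal_nonsyn.append(m)
    for mid, why in excluded:
        evidence.append(f"excluded {mid} from classification: {why}")

    call = AllelicStatusCall(
        sample_id=genomics.sample_id,
        b2m_status="wildtype",
        biallelic_class="not_applicable",
        mut_cn_per_mutation=mut_cn,
        loh_per_mutation=loh,
        clonal_nonsynonymous_count=len(clonal_nonsyn),
    )
    call.evidence = evidence

    if genomics.gene_total_cn == 0:
        # total loss of the gene without any point mutation still abolishes it
        evidence.append("homozygous deletion of target gene: mutant, biallelic")
        call.b2m_status = "mutant"
        call.biallelic_class = "biallelic"
        return call

    if not clonal_nonsyn:
        evidence.append("no clonal non-synonymous mutation: wildtype")
        return call

    call.b2m_status = "mutant"
    ids = [m.mutation_id for m in clonal_nonsyn]

    if len(clonal_nonsyn) == 1:
        mid = ids[0]
        evidence.append(f"single-mutation path for {mid}")
        if loh[mid]:
            evidence.append(f"{mid} shows LOH (Mut_CN {mut_cn[mid]} vs gene CN "
                            f"{genomics.gene_total_cn}): biallelic")
            call.biallelic_class = "biallelic"
        else:
            evidence.append(f"{mid} without LOH: not_biallelic")
            call.biallelic_class = "not_biallelic"
        return call

    # multiple clonal non-synonymous mutations: resolve pairwise phasing
    observed = {}
    for obs in phasing:
        key = _pair_key(obs.mutation_id_a, obs.mutation_id_b)
        observed[key] = phase_pair(obs)
    relations = {}
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            key = _pair_key(a, b)
            if key in observed:
                relations[key] = observed[key]
            else:
                warnings.warn(
                    f"no phasing observation for pair {key}; "
                    "treating as unphaseable",
                    stacklevel=2,
                )
                relations[key] = UNPHASEABLE
    call.phasing_relations = relations

    components = _cis_components(ids, relations)
    representatives = []
    for comp in components:
        rep = max(comp, key=lambda mid: (mut_cn[mid], mid))
        representatives.append(rep)
        if len(comp) > 1:
            evidence.append(
                f"cis group {comp} collapsed to representative {rep}"
            )

    cn_sum = sum(mut_cn[r] for r in representatives)
    any_loh = any(loh[i] for i in ids)
    evidence.append(
        f"representative Mut_CN sum {cn_sum} vs gene CN {genomics.gene_total_cn}"
    )

    if any_loh:
        evidence.append("at least one mutation shows LOH: biallelic")
        call.biallelic_class = "biallelic"
        return call

    # relation between two cis components: trans beats absence of evidence
    comp_of = {mid: idx for idx, comp in enumerate(components) for mid in comp}
    all_trans = True
    any_unphaseable = False
    for i, a in enumerate(representatives):
        for b in representatives[i + 1:]:
            cross = [
                rel
                for (x, y), rel in relations.items()
                if {comp_of[x], comp_of[y]} == {comp_of[a], comp_of[b]}
            ]
            if any(rel == TRANS for rel in cross):
                continue
            all_trans = False
            any_unphaseable = True

    if len(representatives) >= 2 and all_trans and cn_sum >= genomics.gene_total_cn:
        evidence.append("mutations in trans and Mut_CN sum covers gene CN: biallelic")
        call.biallelic_class = "biallelic"
    elif any_unphaseable and cn_sum >= genomics.gene_total_cn:
        evidence.append(
            "unphaseable pair with Mut_CN sum covering gene CN: potentially_biallelic"
        )
        call.biallelic_class = "potentially_biallelic"
    else:
        evidence.append("Mut_CN sum below gene CN without LOH: not_biallelic")
        call.biallelic_class = "not_biallelic"
    return call


def compute_tmb(n_mutations: int, megabases_sequenced: float) -> float:
    """Tumour mutational burden: mutation count per megabase sequenced."""
    if megabases_sequenced <= 0:
        raise ValueError("megabases_sequenced must be > 0")
    if n_mutations < 0:
        raise ValueError("n_mutations must be >= 0")
    return n_mutations / megabases_sequenced
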