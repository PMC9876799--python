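"""Immune marker gene-set scoring and infiltration clustering.

Scores are per-sample means of log2(RPM + 1) over marker genes.  Sample
clustering uses Ward linkage on Euclidean distances over Z-scored set
scores, split into high- and low-infiltration groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

__all__ = [
    "GeneSet",
    "rpm",
    "log2_rpm",
    "build_kir_set",
    "assemble_default_sets",
    "score_sets",
    "zscore_rows",
    "ward_cluster",
    "read_gmt",
    "write_gmt",
]

GD13_SET_NAME = "gd1/3 T cells"
KIR_SET_NAME = "KIR"
NK_SET_NAME = "NK cells"
CYTOTOXIC_SET_NAME = "Cytotoxic cells"
CD4_SET_NAME = "CD4+ T cells"

EXCLUDED_SET_NAMES = ("NK CD56dim cells",)
NK_GENES = ("NCR1", "KLRF1")
CYTOTOXIC_GENES = ("GZMA", "GZMB", "GZMH", "PRF1", "GNLY", "CTSW")
# both spellings accepted when pruning the NK base set
GD_CHEMOKINE_ALIASES = ("XCL1", "XCL2", "XLC1", "XLC2")


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: tuple

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene set needs a name")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"duplicate symbols in gene set {self.name!r}")

    @classmethod
    def of(cls, name: str, genes: Iterable[str]) -> "GeneSet":
        return cls(name=name, genes=tuple(genes))


def rpm(
    counts: pd.DataFrame, library_sizes: Optional[pd.Series] = None
) -> pd.DataFrame:
    """Normalize raw counts to reads per million.

    Library sizes default to column totals when not supplied.
    """
    if counts.index.duplicated().any():
        dups = counts.index[counts.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene symbols in expression matrix: {dups}")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    library_sizes = library_sizes.reindex(counts.columns)
    if library_sizes.isna().any():
        missing = library_sizes.index[library_sizes.isna()].tolist()
        raise ValueError(f"missing library sizes for samples: {missing}")
    if (library_sizes <= 0).any():
        bad = library_sizes.index[library_sizes <= 0].tolist()
        raise ValueError(f"non-positive library sizes for samples: {bad}")
    return counts * 1e6 / library_sizes


def log2_rpm(rpm_matrix: pd.DataFrame) -> pd.DataFrame:
    """log2(RPM + 1) transform."""
    return np.log2(rpm_matrix + 1.0)


def build_kir_set(gene_universe: Sequence[str]) -> GeneSet:
    """All symbols starting with ``KIR`` and containing ``DL`` or ``DS``.

    Matching is case-sensitive on official symbols, so e.g. KIR3DX1 and
    KIRREL1 are excluded.
    """
    seen = set()
    genes = []
    for g in gene_universe:
        if g in seen:
            continue
        seen.add(g)
        if g.startswith("KIR") and ("DL" in g[3:] or "DS" in g[3:]):
            genes.append(g)
    if not genes:
        warnings.warn("no KIR genes found in the gene universe", stacklevel=2)
    return GeneSet.of(KIR_SET_NAME, genes)


def assemble_default_sets(
    gene_universe: Sequence[str], base_sets: Iterable[GeneSet] = ()
) -> list:
    """Apply the marker-set edits on top of user-supplied base sets.

    Adds CD4, TRDV1/TRDV3 (gamma-delta 1/3) and KIR sets; drops the
    'NK CD56dim cells' set; prunes XCL1/XCL2 (either spelling) from a base
    NK set and adds KLRF1, falling back to {NCR1, KLRF1}; and fixes the
    cytotoxic set to the genes encoding cytotoxic molecules.
    """
    out = []
    for s in base_sets:
        if s.name in EXCLUDED_SET_NAMES:
            continue
        if s.name == NK_SET_NAME:
            pruned = [g for g in s.genes if g not in GD_CHEMOKINE_ALIASES]
            if "KLRF1" not in pruned:
                pruned.append("KLRF1")
            out.append(GeneSet.of(NK_SET_NAME, pruned))
            continue
        if s.name == CYTOTOXIC_SET_NAME:
            out.append(GeneSet.of(CYTOTOXIC_SET_NAME, CYTOTOXIC_GENES))
            continue
        out.append(s)
    names = {s.name for s in out}
    if NK_SET_NAME not in names:
        out.append(GeneSet.of(NK_SET_NAME, NK_GENES))
    if CYTOTOXIC_SET_NAME not in names:
        out.append(GeneSet.of(CYTOTOXIC_SET_NAME, CYTOTOXIC_GENES))
    out.append(GeneSet.of(CD4_SET_NAME, ("CD4",)))
    out.append(GeneSet.of(GD13_SET_NAME, ("TRDV1", "TRDV3")))
    out.append(build_kir_set(gene_universe))
    counts: dict = {}
    for s in out:
        counts[s.name] = counts.get(s.name, 0) + 1
    dupes = [n for n, c in counts.items() if c > 1]
    if dupes:
        raise ValueError(f"duplicate set names after assembly: {dupes}")
    return out


def score_sets(
    rpm_matrix: pd.DataFrame, sets: Iterable[GeneSet]
) -> pd.DataFrame:
    """Mean log2(RPM + 1) over each set's genes, per sample.

    Genes absent from the matrix are dropped with a warning; a set with no
    present genes scores NaN for every sample.
    """
    log_expr = log2_rpm(rpm_matrix)
    rows = {}
    for s in sets:
        present = [g for g in s.genes if g in log_expr.index]
        missing = [g for g in s.genes if g not in log_expr.index]
        if missing:
            warnings.warn(
                f"set {s.name!r}: genes absent from matrix dropped: {missing}",
                stacklevel=2,
            )
        if present:
            rows[s.name] = log_expr.loc[present].mean(axis=0)
        else:
            rows[s.name] = pd.Series(np.nan, index=log_expr.columns)
    return pd.DataFrame(rows).T


def zscore_rows(table: pd.DataFrame) -> pd.DataFrame:
    """Row-wise Z-scoring with population (n) standard deviation.

    Constant rows are mapped to zeros with a warning.
    """
    if table.shape[1] < 2:
        raise ValueError("need at least 2 samples to Z-score")
    mean = table.mean(axis=1)
    sd = table.std(axis=1, ddof=0)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"constant rows Z-scored to zeros: {table.index[constant].tolist()}",
            stacklevel=2,
        )
    safe_sd = sd.replace(0, 1.0)
    z = table.sub(mean, axis=0).div(safe_sd, axis=0)
    z.loc[constant] = 0.0
    return z


def ward_cluster(table: pd.DataFrame, k: int):
    """Ward/Euclidean hierarchical clustering of samples (columns).

    Returns ``(labels, linkage_matrix)``.  With ``k`` = 2 labels are
    ``high``/``low`` by mean column score; otherwise integer cluster ids
    as strings.
    """
    n = table.shape[1]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of samples ({n})")
    data = table.to_numpy(dtype=float).T  # samples x features
    if n == 1:
        return pd.Series(["1"], index=table.columns), np.empty((0, 4))
    link = linkage(data, method="ward", metric="euclidean")
    assignments = fcluster(link, t=k, criterion="maxclust")
    labels = pd.Series(assignments.astype(str), index=table.columns)
    if k == 2 and len(set(assignments)) == 2:
        col_means = table.mean(axis=0)
        cluster_means = {
            c: col_means[labels == str(c)].mean() for c in sorted(set(assignments))
        }
        high = max(cluster_means, key=cluster_means.get)
        labels = labels.map(lambda c: "high" if int(c) == high else "low")
    return labels, link


def read_gmt(path) -> list:
    """Read gene sets from GMT (name, description, genes...)."""
    sets = []
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line!r}")
            name, _desc, *genes = fields
            genes = [g for g in genes if g]
            sets.append(GeneSet.of(name, dict.fromkeys(genes)))
    return sets


def write_gmt(sets: Iterable[GeneSet], path) -> None:
    with open(path, "w") as handle:
        for s in sets:
            handle.write("\t".join([s.name, "na", *s.genes]) + "\n")
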