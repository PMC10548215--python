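"""Ground-reference trait derivation and multivariate structure.

Secondary leaf traits (SLA, C:N, SLA_C, SLN) are derived from leaf area,
dry weight and elemental composition; skewed traits are log-transformed
and bounded traits min-max normalized; the multivariate analyses are
pairwise Pearson correlations (mean-imputed), a correlation-matrix PCA on
accession means, and average-linkage (UPGMA) hierarchical clustering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = [
    "RAW_TRAITS",
    "ANALYSIS_TRAITS",
    "derive_traits",
    "transform_traits",
    "correlation_analysis",
    "trait_pca",
    "cluster_accessions",
    "accession_mean_traits",
    "PCAResult",
    "ClusterResult",
]

RAW_TRAITS = ["A", "C", "N", "C:N", "E", "gsw", "FB", "Jmax", "Vcmax",
              "pQY", "mQY", "SLA", "SLA_C", "SLN"]
# Trait set entering correlations/PCA/clustering: transformed columns
# replace their raw, skewed or unbounded counterparts.
ANALYSIS_TRAITS = ["A", "C", "N", "C:N", "log_E", "log_gsw", "FB", "Jmax",
                   "Vcmax", "pQY", "mQY", "SLA", "SLA_C", "SLN"]


def derive_traits(leaf_area, dry_weight, C, N):
    """Secondary traits from primary leaf measurements.

    SLA = area/dry weight (cm^2 g^-1); C:N = C/N; SLA_C = area per mg of
    leaf carbon; SLN = mg of leaf N per cm^2.  Percentages are mass
    fractions of the dry weight (g -> mg conversion by x1000).  Nonpositive
    denominators yield NaN (an undefined-trait flag), never a silent zero.
    """
    leaf_area = np.asarray(leaf_area, dtype=float)
    dry_weight = np.asarray(dry_weight, dtype=float)
    C = np.asarray(C, dtype=float)
    N = np.asarray(N, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        sla = np.where(dry_weight > 0, leaf_area / dry_weight, np.nan)
        cn = np.where(N > 0, C / N, np.nan)
        carbon_mg = dry_weight * 1000.0 * C / 100.0
        sla_c = np.where(carbon_mg > 0, leaf_area / carbon_mg, np.nan)
        sln = np.where(leaf_area > 0, dry_weight * 1000.0 * N / 100.0 / leaf_area, np.nan)
    return {"SLA": sla, "C:N": cn, "SLA_C": sla_c, "SLN": sln}


def add_derived_traits(table: pd.DataFrame) -> pd.DataFrame:
    """Append SLA, C:N, SLA_C, SLN columns derived per plant."""
    out = table.copy()
    derived = derive_traits(out["leaf_area"], out["dry_weight"], out["C"], out["N"])
    for k, v in derived.items():
        out[k] = v
    return out


def _minmax(col: pd.Series) -> pd.Series:
    lo, hi = col.min(), col.max()
    if not np.isfinite(hi - lo) or hi == lo:
        raise ValueError(f"cannot min-max scale a constant column ({col.name})")
    return (col - lo) / (hi - lo)


def transform_traits(table: pd.DataFrame, norm: str = "minmax") -> pd.DataFrame:
    """Add transformed columns: natural logs of the right-skewed traits
    (E, gsw, SLN) and normalized FB/pQY/mQY.

    ``norm`` is "minmax" (default, keeps yields in [0, 1]) or "zscore".
    Nonpositive values under a log become NaN (flagged missing).
    """
    out = table.copy()
    for raw, name in (("E", "log_E"), ("gsw", "log_gsw"), ("SLN", "log_SLN")):
        vals = out[raw].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            logged = np.where(vals > 0, np.log(vals), np.nan)
        out[name] = logged
    for raw, name in (("FB", "normFB"), ("pQY", "normpQY"), ("mQY", "normmQY")):
        if norm == "minmax":
            out[name] = _minmax(out[raw])
        elif norm == "zscore":
            out[name] = (out[raw] - out[raw].mean()) / out[raw].std(ddof=1)
        else:
            raise ValueError(f"unknown normalization {norm!r}")
    return out


def correlation_analysis(table: pd.DataFrame, traits: list[str] | None = None,
                         alpha: float = 0.01):
    """Pairwise Pearson correlations with mean imputation.

    Missing entries are replaced by the column mean over observed values
    before the correlation is computed; significance is a two-sided t-test
    per pair at ``alpha`` (no multiplicity correction).  Returns
    (correlation matrix, boolean significance mask) as DataFrames.
    """
    traits = traits or [t for t in ANALYSIS_TRAITS if t in table.columns]
    X = table[traits].astype(float)
    if len(X.dropna(how="all")) < 3:
        raise ValueError("need at least 3 rows for a correlation analysis")
    X = X.fillna(X.mean())
    sd = X.std(ddof=0)
    if (sd == 0).any():
        bad = sd.index[sd == 0].tolist()
        raise ValueError(f"constant column(s), correlation undefined: {bad}")
    corr = X.corr(method="pearson")
    n = len(X)
    r = corr.to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.clip(1.0 - r ** 2, 1e-300, None))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    np.fill_diagonal(p, 0.0)
    mask = pd.DataFrame(p < alpha, index=corr.index, columns=corr.columns)
    return corr, mask


def accession_mean_traits(table: pd.DataFrame, traits: list[str] | None = None) -> pd.DataFrame:
    """Accession x treatment means; a missing replicate is represented by
    its surviving replicate(s) (mean over observed values)."""
    traits = traits or [t for t in ANALYSIS_TRAITS if t in table.columns]
    grouped = table.groupby(["accession", "treatment"], sort=True)[traits].mean()
    if grouped.isna().any().any():
        bad = grouped.index[grouped.isna().any(axis=1)][0]
        raise ValueError(f"no replicate with data for accession cell {bad}")
    return grouped.reset_index()


@dataclass
class PCAResult:
    scores: np.ndarray
    loadings: np.ndarray          # columns = components, orthonormal
    explained_variance_ratio: np.ndarray
    columns: list
    row_meta: pd.DataFrame | None = None
    mean: np.ndarray | None = None
    scale: np.ndarray | None = None


def trait_pca(accession_means: pd.DataFrame, traits: list[str] | None = None) -> PCAResult:
    """Correlation-matrix PCA of accession-mean traits.

    Columns are standardized to zero mean / unit variance before the
    decomposition, making the result invariant to affine rescaling of any
    input trait.  Requires complete data (replicate fallback upstream).
    """
    traits = traits or [t for t in ANALYSIS_TRAITS if t in accession_means.columns]
    X = accession_means[traits].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("trait PCA requires complete data")
    sd = X.std(axis=0, ddof=1)
    zero = sd == 0
    if zero.any():
        raise ValueError(f"zero-variance trait(s): {[t for t, z in zip(traits, zero) if z]}")
    mean = X.mean(axis=0)
    Z = (X - mean) / sd
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    var = S ** 2 / (len(X) - 1)
    meta_cols = [c for c in ("accession", "treatment") if c in accession_means.columns]
    return PCAResult(
        scores=U * S,
        loadings=Vt.T,
        explained_variance_ratio=var / var.sum(),
        columns=traits,
        row_meta=accession_means[meta_cols].copy() if meta_cols else None,
        mean=mean,
        scale=sd,
    )


@dataclass
class ClusterResult:
    linkage: np.ndarray
    labels: pd.DataFrame          # row metadata + cluster assignment at k
    k: int
    newick: str


def _to_newick(node, leaf_names) -> str:
    if node.is_leaf():
        return leaf_names[node.id]
    left = _to_newick(node.get_left(), leaf_names)
    right = _to_newick(node.get_right(), leaf_names)
    dl = node.dist - node.get_left().dist
    dr = node.dist - node.get_right().dist
    return f"({left}:{dl:.6g},{right}:{dr:.6g})"


def cluster_accessions(accession_means: pd.DataFrame, traits: list[str] | None = None,
                       k: int = 2) -> ClusterResult:
    """UPGMA (average-linkage) clustering of accession-mean traits.

    Traits are standardized before the Euclidean distance (mixed units make
    raw distances meaningless).  Scipy's linkage is deterministic given the
    input order; distance ties are broken by cluster index order.
    """
    traits = traits or [t for t in ANALYSIS_TRAITS if t in accession_means.columns]
    X = accession_means[traits].to_numpy(dtype=float)
    if len(X) < 2:
        raise ValueError("need at least two rows to cluster")
    if np.isnan(X).any():
        raise ValueError("clustering requires complete data")
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValueError("zero-variance trait in clustering input")
    Z = hierarchy.linkage(pdist((X - X.mean(axis=0)) / sd, metric="euclidean"),
                          method="average")
    flat = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    meta_cols = [c for c in ("accession", "treatment") if c in accession_means.columns]
    labels = accession_means[meta_cols].copy() if meta_cols else pd.DataFrame(index=range(len(X)))
    labels["cluster"] = flat
    if meta_cols:
        names = (accession_means[meta_cols].astype(str).agg("_".join, axis=1)).tolist()
    else:
        names = [str(i) for i in range(len(X))]
    tree = hierarchy.to_tree(Z)
    newick = _to_newick(tree, names) + ";"
    return ClusterResult(linkage=Z, labels=labels, k=k, newick=newick)
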