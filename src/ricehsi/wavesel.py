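"""Wavelength selection: PCA loadings (classification) and RReliefF (regression).

Two selection routes feed the downstream models.  For treatment
classification, a covariance-matrix PCA of weekly accession-mean spectra
is computed and, from the principal components that cumulatively explain
more than 90% of the variance, the wavelengths with the largest absolute
loadings are pooled (the ``W_SVM`` set).  For trait regression, the
RReliefF estimator with exponential rank-based neighbor weighting
("expRank") scores every wavelength by how well its local differences
track response differences, and the top-scoring wavelengths form the
``W_PLSR`` set.

RReliefF here follows Robnik-Sikonja & Kononenko's regression estimator:
for m randomly drawn instances, accumulate over the k nearest neighbors

    N_dC        += diff(y) * w
    N_dA[a]     += diff(a) * w
    N_dC&dA[a]  += diff(y) * diff(a) * w

with neighbor weights w = exp(-(rank/sigma)^2) normalized to sum to one
per draw, and finally

    W[a] = N_dC&dA[a]/N_dC - (N_dA[a] - N_dC&dA[a]) / (m - N_dC).

Because neighbors and diffs are deterministic given the data, each
instance's accumulated contribution is computed once and the m draws (with
replacement) only weight them -- numerically identical to the literal
iteration loop, at a fraction of the cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "SelectionResult",
    "SpectraPCAResult",
    "spectra_pca",
    "select_wsvm",
    "rrelieff_rank",
    "select_wplsr",
]


@dataclass
class SelectionResult:
    """Ranked/selected wavelength subset.

    ``scores`` aligns with ``wavelengths`` (RReliefF weight or max
    |loading|); ``selected`` is the chosen subset in ascending wavelength
    order; ``provenance`` records how the selection was made.
    """

    method: str
    wavelengths: np.ndarray
    scores: np.ndarray
    selected: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.scores = np.asarray(self.scores, dtype=float)
        self.selected = np.asarray(self.selected, dtype=float)
        if len(self.scores) != len(self.wavelengths):
            raise ValueError("scores must align with wavelengths")
        if len(np.unique(self.selected)) != len(self.selected):
            raise ValueError("selected wavelengths contain duplicates")
        if not np.isin(self.selected, self.wavelengths).all():
            raise ValueError("selected wavelengths must lie on the scored grid")


@dataclass
class SpectraPCAResult:
    wavelengths: np.ndarray
    scores: np.ndarray
    loadings: np.ndarray           # (n_wavelengths, n_components), orthonormal
    explained_variance_ratio: np.ndarray
    mean: np.ndarray
    row_meta: object = None


def spectra_pca(spectra) -> SpectraPCAResult:
    """Covariance-matrix PCA of a SpectraSet (centered, unscaled)."""
    X = np.asarray(spectra.values, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least two spectra for a PCA")
    mean = X.mean(axis=0)
    U, S, Vt = np.linalg.svd(X - mean, full_matrices=False)
    var = S ** 2
    total = var.sum()
    if total == 0:
        raise ValueError("spectra have zero variance")
    return SpectraPCAResult(
        wavelengths=spectra.wavelengths,
        scores=U * S,
        loadings=Vt.T,
        explained_variance_ratio=var / total,
        mean=mean,
        row_meta=getattr(spectra, "meta", None),
    )


def select_wsvm(pca: SpectraPCAResult, var_threshold: float = 0.90,
                top_k: int = 10) -> SelectionResult:
    """Classification wavelengths from PCA loadings.

    Retains the minimal leading set of components whose cumulative
    explained-variance fraction strictly exceeds ``var_threshold`` and, for
    each, pools the ``top_k`` wavelengths by absolute loading (sign flips
    of a component change nothing).  The union is returned sorted by
    wavelength; per-wavelength scores are the max |loading| over retained
    components.
    """
    cum = np.cumsum(pca.explained_variance_ratio)
    n_pc = int(np.searchsorted(cum, var_threshold, side="right")) + 1
    n_pc = min(n_pc, pca.loadings.shape[1])
    absload = np.abs(pca.loadings[:, :n_pc])
    chosen: set[float] = set()
    for j in range(n_pc):
        # stable ordering: descending |loading|, ties by ascending wavelength
        order = np.lexsort((pca.wavelengths, -absload[:, j]))
        chosen.update(pca.wavelengths[order[:top_k]].tolist())
    selected = np.array(sorted(chosen))
    return SelectionResult(
        method="pca_loadings",
        wavelengths=pca.wavelengths,
        scores=absload.max(axis=1),
        selected=selected,
        provenance={"n_components": n_pc, "var_threshold": var_threshold, "top_k": top_k},
    )


def _scale01(M: np.ndarray) -> np.ndarray:
    lo = M.min(axis=0)
    span = M.max(axis=0) - lo
    out = np.zeros_like(M, dtype=float)
    nz = span > 0
    out[:, nz] = (M[:, nz] - lo[nz]) / span[nz]
    return out  # constant columns stay 0 -> diff identically 0


def rrelieff_rank(X: np.ndarray, y: np.ndarray, k_neighbors: int = 70,
                  sigma: float = 20.0, m_iterations: int | None = None,
                  seed: int | np.random.Generator = 0,
                  wavelengths: np.ndarray | None = None) -> SelectionResult:
    """RReliefF expRank attribute weights for a regression response.

    Attributes and the response are min-max scaled internally so the diff
    function is |a_i - a_j| in [0, 1]; neighborhoods use the Manhattan
    distance on the scaled attributes.  ``m_iterations`` defaults to the
    standard rule of 100 x n.  Weights lie in [-1, 1]; a constant
    attribute scores exactly 0.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if len(y) != n:
        raise ValueError("X and y disagree on the number of instances")
    y_span = y.max() - y.min()
    if y_span == 0:
        raise ValueError("response is constant; RReliefF weights are undefined")
    k = min(k_neighbors, n - 1)
    if k < 1:
        raise ValueError("need at least two instances")
    m = m_iterations if m_iterations is not None else 100 * n
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    Xs = _scale01(X)
    ys = (y - y.min()) / y_span
    D = cdist(Xs, Xs, metric="cityblock")

    w_rank = np.exp(-((np.arange(1, k + 1) / sigma) ** 2))
    w_rank /= w_rank.sum()

    # Per-instance accumulated contributions (deterministic given data).
    dC = np.empty(n)
    dA = np.empty((n, p))
    dCdA = np.empty((n, p))
    for i in range(n):
        order = np.argsort(D[i], kind="stable")
        nb = order[order != i][:k]
        diff_a = np.abs(Xs[nb] - Xs[i])             # (k, p)
        diff_y = np.abs(ys[nb] - ys[i])             # (k,)
        wk = w_rank[: len(nb)]
        dC[i] = wk @ diff_y
        dA[i] = wk @ diff_a
        dCdA[i] = (wk * diff_y) @ diff_a

    counts = np.bincount(rng.integers(0, n, size=m), minlength=n).astype(float)
    NdC = counts @ dC
    NdA = counts @ dA
    NdCdA = counts @ dCdA
    W = NdCdA / NdC - (NdA - NdCdA) / (m - NdC)

    wl = np.asarray(wavelengths, float) if wavelengths is not None else np.arange(p, dtype=float)
    return SelectionResult(
        method="rrelieff",
        wavelengths=wl,
        scores=W,
        selected=np.array([]),
        provenance={"k_neighbors": k, "sigma": sigma, "m_iterations": m},
    )


def select_wplsr(scores: SelectionResult, n_wavelengths: int) -> SelectionResult:
    """Top-n wavelengths by score, ties broken by ascending wavelength;
    returned in wavelength order."""
    if n_wavelengths <= 0:
        raise ValueError("n_wavelengths must be positive")
    if n_wavelengths > len(scores.wavelengths):
        raise ValueError("requested more wavelengths than were scored")
    order = np.lexsort((scores.wavelengths, -scores.scores))
    selected = np.sort(scores.wavelengths[order[:n_wavelengths]])
    return SelectionResult(
        method=scores.method,
        wavelengths=scores.wavelengths,
        scores=scores.scores,
        selected=selected,
        provenance={**scores.provenance, "n_wavelengths": n_wavelengths},
    )
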