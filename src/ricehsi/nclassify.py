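"""SVM nitrogen-treatment classification with rough/fine grid search.

Treatment labels are predicted from plant-level reflectance at the
``W_SVM`` wavelengths.  Hyperparameters follow an exponential lattice:
the rough search spans cost = 2^-5..2^15 and (RBF only) gamma =
2^-15..2^23, both at steps of 2^2, scored by pooled 23-fold
cross-validation accuracy; the rough optimum seeds a fine lattice of
+/- 0.5 in the exponent at steps of 0.1 (widened to +/- 2 and clipped
when the rough optimum sits on a range boundary), and the fine point is
adopted only on a strict CV-accuracy improvement.  Cross-week evaluation
trains on one week's selected wavelengths and predicts every week by
extracting those same wavelengths from the evaluation week's spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import GroupKFold, StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .reflectance import SpectraSet, accession_mean
from .wavesel import select_wsvm, spectra_pca

__all__ = ["GridSpec", "ClassifierRun", "grid_search", "cross_week_evaluate"]


@dataclass(frozen=True)
class GridSpec:
    """Exponential grid-search specification (exponents of 2)."""

    kernel: str = "rbf"
    cost_exponent_range: tuple[float, float, float] = (-5.0, 15.0, 2.0)
    gamma_exponent_range: tuple[float, float, float] = (-15.0, 23.0, 2.0)
    fine_halfwidth_exponent: float = 0.5
    fine_step_exponent: float = 0.1
    boundary_halfwidth_exponent: float = 2.0
    folds: int = 23
    folding: str = "stratified"   # or "accession" (one fold per accession)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kernel not in ("rbf", "linear"):
            raise ValueError("kernel must be 'rbf' or 'linear'")
        for lo, hi, step in (self.cost_exponent_range, self.gamma_exponent_range):
            if hi < lo or step <= 0:
                raise ValueError("exponent ranges must be nonempty with positive step")
        if self.fine_step_exponent <= 0 or self.folds < 2:
            raise ValueError("invalid fine step or fold count")


@dataclass
class ClassifierRun:
    """Outcome of one rough+fine grid search."""

    kernel: str
    best_cost_exponent: float
    best_gamma_exponent: float | None
    rough_accuracy: float
    fine_accuracy: float
    adopted: str                  # "rough" or "fine"
    model: object                 # fitted sklearn pipeline pieces (scaler, svc)
    scaler: StandardScaler
    fold_assignment: np.ndarray

    @property
    def best_cost(self) -> float:
        return 2.0 ** self.best_cost_exponent

    @property
    def best_gamma(self) -> float | None:
        return None if self.best_gamma_exponent is None else 2.0 ** self.best_gamma_exponent

    @property
    def cv_accuracy(self) -> float:
        return self.fine_accuracy if self.adopted == "fine" else self.rough_accuracy


def _lattice(lo: float, hi: float, step: float) -> np.ndarray:
    n = int(round((hi - lo) / step))
    return lo + step * np.arange(n + 1)


def _make_folds(y: np.ndarray, spec: GridSpec, groups: np.ndarray | None):
    if spec.folding == "accession":
        if groups is None:
            raise ValueError("accession folding requires group labels")
        splitter = GroupKFold(n_splits=spec.folds)
        return list(splitter.split(np.zeros_like(y), y, groups))
    splitter = StratifiedKFold(n_splits=spec.folds, shuffle=True, random_state=spec.seed)
    return list(splitter.split(np.zeros_like(y), y))


def _cv_accuracy(Xs: np.ndarray, y: np.ndarray, folds, kernel: str,
                 cost: float, gamma: float | None) -> float:
    correct = 0
    for train, test in folds:
        svc = SVC(C=cost, kernel=kernel,
                  gamma=gamma if gamma is not None else "scale")
        svc.fit(Xs[train], y[train])
        correct += int((svc.predict(Xs[test]) == y[test]).sum())
    return correct / len(y)


def _search(Xs, y, folds, kernel, cost_exps, gamma_exps):
    best = (-1.0, None, None)
    for ce in cost_exps:
        for ge in (gamma_exps if gamma_exps is not None else [None]):
            acc = _cv_accuracy(Xs, y, folds, kernel, 2.0 ** ce,
                               None if ge is None else 2.0 ** ge)
            # ties resolve to the earliest (smallest) exponents
            if acc > best[0]:
                best = (acc, ce, ge)
    return best


def _fine_window(best_exp: float, rough: tuple[float, float, float],
                 spec: GridSpec) -> np.ndarray:
    lo, hi, _ = rough
    on_boundary = best_exp in (lo, hi)
    half = spec.boundary_halfwidth_exponent if on_boundary else spec.fine_halfwidth_exponent
    w_lo = max(lo, best_exp - half)
    w_hi = min(hi, best_exp + half)
    return _lattice(w_lo, w_hi, spec.fine_step_exponent)


def grid_search(X: np.ndarray, labels, spec: GridSpec | None = None,
                groups: np.ndarray | None = None) -> ClassifierRun:
    """Rough + fine exponential grid search with cross-validated accuracy.

    Accuracy is the pooled proportion correct over held-out folds.  The
    final model is refit on all rows at the adopted parameters.
    """
    spec = spec or GridSpec()
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("both treatment classes must be present")
    if len(y) < spec.folds:
        raise ValueError("fewer samples than folds")
    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)
    folds = _make_folds(y, spec, groups)

    cost_exps = _lattice(*spec.cost_exponent_range)
    gamma_exps = _lattice(*spec.gamma_exponent_range) if spec.kernel == "rbf" else None
    rough_acc, rough_ce, rough_ge = _search(Xs, y, folds, spec.kernel,
                                            cost_exps, gamma_exps)

    fine_cost = _fine_window(rough_ce, spec.cost_exponent_range, spec)
    fine_gamma = (_fine_window(rough_ge, spec.gamma_exponent_range, spec)
                  if gamma_exps is not None else None)
    fine_acc, fine_ce, fine_ge = _search(Xs, y, folds, spec.kernel,
                                         fine_cost, fine_gamma)

    if fine_acc > rough_acc:
        adopted, ce, ge, acc = "fine", fine_ce, fine_ge, fine_acc
    else:
        adopted, ce, ge = "rough", rough_ce, rough_ge
    svc = SVC(C=2.0 ** ce, kernel=spec.kernel,
              gamma=(2.0 ** ge) if ge is not None else "scale")
    svc.fit(Xs, y)

    assignment = np.empty(len(y), dtype=int)
    for f, (_, test) in enumerate(folds):
        assignment[test] = f
    return ClassifierRun(
        kernel=spec.kernel,
        best_cost_exponent=float(ce),
        best_gamma_exponent=None if ge is None else float(ge),
        rough_accuracy=rough_acc,
        fine_accuracy=fine_acc,
        adopted=adopted,
        model=svc,
        scaler=scaler,
        fold_assignment=assignment,
    )


def cross_week_evaluate(spectra: SpectraSet, design: pd.DataFrame,
                        spec: GridSpec | None = None,
                        var_threshold: float = 0.90, top_k: int = 10):
    """Train-week x evaluation-week treatment-classification accuracy matrix.

    For each training week, wavelengths are selected from that week's
    accession-mean PCA, a classifier is tuned on the training week's
    plant-level spectra, and every week is scored by extracting the
    training week's wavelengths from the evaluation week's spectra (the
    training-week scaler applied).  Diagonal entries reuse the training
    data and are optimistic by construction.  Returns (accuracy DataFrame,
    dict of ClassifierRun per training week, dict of selections).
    """
    spec = spec or GridSpec()
    weeks = sorted(spectra.meta["week"].unique())
    if not weeks:
        raise ValueError("no weeks present in the spectra")
    trt = design.set_index("plant_id")["treatment"]
    acc = design.set_index("plant_id")["accession"]
    matrix = pd.DataFrame(index=weeks, columns=weeks, dtype=float)
    runs: dict = {}
    selections: dict = {}
    means = accession_mean(spectra, design)
    for train_week in weeks:
        sel = select_wsvm(spectra_pca(means.select_week(train_week)),
                          var_threshold=var_threshold, top_k=top_k)
        selections[train_week] = sel
        train = spectra.select_week(train_week).subset_wavelengths(sel.selected)
        y_train = trt.loc[train.meta["plant_id"]].to_numpy()
        run = grid_search(train.values, y_train, spec,
                          groups=acc.loc[train.meta["plant_id"]].to_numpy())
        runs[train_week] = run
        for eval_week in weeks:
            ev = spectra.select_week(eval_week).subset_wavelengths(sel.selected)
            y_ev = trt.loc[ev.meta["plant_id"]].to_numpy()
            pred = run.model.predict(run.scaler.transform(ev.values))
            matrix.loc[train_week, eval_week] = float((pred == y_ev).mean())
    matrix.index.name = "training_week"
    matrix.columns.name = "evaluation_week"
    return matrix, runs, selections
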