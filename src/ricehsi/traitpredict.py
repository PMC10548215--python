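"""RReliefF-PLSR trait prediction: splits, runs, transfer and grid studies.

The prediction protocol: complete-case rows are split 80/20 stratified by
treatment (floor per stratum), RReliefF scores wavelengths on the
calibration rows only (iterations = 100 x calibration size; no leakage of
validation responses), the top-n wavelengths feed an orthogonal-scores
PLSR whose component count minimizes leave-one-out RMSEP, and performance
is reported as LOO-calibration and validation R^2 / RMSEP / %RMSEP with
jackknife 95% prediction intervals.  Transfer experiments calibrate
entirely inside one treatment or subpopulation and validate on the whole
other group; the hyperparameter grid crosses wavelength counts with total
sample sizes over repeated stratified subsamples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import pls
from .pls import Metrics
from .reflectance import SpectraSet
from .wavesel import rrelieff_rank, select_wplsr

__all__ = [
    "SplitSpec",
    "RReliefFParams",
    "PLSRRun",
    "GridResult",
    "stratified_split",
    "run_trait_model",
    "transfer_experiment",
    "hyperparameter_grid",
]

DEFAULT_WAVELENGTH_COUNTS = (10, 50, 100, 150, 200, 300, 400, 500, 600, 700)
DEFAULT_TOTALS = (48, 60, 70, 78, 88)


@dataclass(frozen=True)
class SplitSpec:
    """Calibration/validation split: fraction and stratification variable."""

    calibration_fraction: float = 0.8
    strata: str = "treatment"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.calibration_fraction < 1.0:
            raise ValueError("calibration_fraction must be in (0, 1)")


@dataclass(frozen=True)
class RReliefFParams:
    k_neighbors: int = 70
    sigma: float = 20.0
    iterations_per_sample: int = 100   # m = this x n_cal


@dataclass
class PLSRRun:
    """One full selection + fit + evaluation."""

    trait: str
    fittable: bool
    n_components: int
    selected_wavelengths: np.ndarray
    calibration_ids: list
    validation_ids: list
    calibration_metrics: Metrics | None = None
    validation_metrics: Metrics | None = None
    model: pls.PLSRModel | None = None
    predictions: pd.DataFrame | None = None
    diagnosis: str = ""


@dataclass
class GridResult:
    """Mean and SE of metrics per (n_wavelengths, total sample size) cell."""

    table: pd.DataFrame
    iterations: int


def stratified_split(sample_ids, strata, spec: SplitSpec):
    """Split ids into (calibration, validation), stratified.

    Per stratum, floor(fraction x stratum size) ids go to calibration
    (sampled without replacement, seeded); the remainder validate.  The
    two sets are disjoint and exhaustive.
    """
    ids = np.asarray(sample_ids)
    strata = np.asarray(strata)
    if len(ids) != len(strata):
        raise ValueError("sample_ids and strata must align")
    rng = np.random.default_rng(spec.seed)
    cal, val = [], []
    for level in sorted(pd.unique(strata)):
        members = ids[strata == level]
        if len(members) < 2:
            raise ValueError(f"stratum {level!r} has fewer than 2 samples")
        n_cal = int(np.floor(spec.calibration_fraction * len(members)))
        chosen = rng.choice(members, size=n_cal, replace=False)
        cal.extend(chosen.tolist())
        val.extend(sorted(set(members) - set(chosen)))
    return cal, val


def _complete_cases(spectra: SpectraSet, traits: pd.DataFrame, trait_name: str):
    """Plant-level design matrix and response for rows where both the
    trait and a spectrum are available."""
    if trait_name not in traits.columns:
        raise KeyError(f"trait {trait_name!r} not in the trait table")
    tr = traits.loc[traits[trait_name].notna(), ["plant_id", "treatment", trait_name]]
    meta = spectra.meta.reset_index(drop=True)
    pos = {pid: i for i, pid in enumerate(meta["plant_id"])}
    tr = tr[tr["plant_id"].isin(pos)]
    rows = [pos[p] for p in tr["plant_id"]]
    X = spectra.values[rows]
    return tr.reset_index(drop=True), X


def _fit_and_evaluate(X_cal, y_cal, X_val, y_val, wavelengths, n_wavelengths,
                      relieff: RReliefFParams, seed, trait_name,
                      cal_ids, val_ids, compute_intervals, max_components=20):
    m_iter = relieff.iterations_per_sample * len(y_cal)
    scores = rrelieff_rank(X_cal, y_cal, k_neighbors=relieff.k_neighbors,
                           sigma=relieff.sigma, m_iterations=m_iter,
                           seed=seed, wavelengths=wavelengths)
    sel = select_wplsr(scores, min(n_wavelengths, len(wavelengths)))
    cols = np.searchsorted(wavelengths, sel.selected)
    Xc, Xv = X_cal[:, cols], X_val[:, cols]

    a = pls.select_components_loo(Xc, y_cal, max_components=max_components)
    if a == 0:
        return PLSRRun(
            trait=trait_name, fittable=False, n_components=0,
            selected_wavelengths=sel.selected, calibration_ids=cal_ids,
            validation_ids=val_ids,
            diagnosis="0-component model optimal in LOO: the calibration mean "
                      "predicts no worse than any latent-variable model",
        )
    loo = pls.loo_predictions(Xc, y_cal, a)[:, a]
    cal_metrics = pls.evaluate(y_cal, loo, context="calibration_loo")
    model = pls.fit_plsr(Xc, y_cal, a, selected_wavelengths=sel.selected)
    val_metrics = pls.evaluate(y_val, model.predict(Xv), context="validation")

    predictions = None
    if compute_intervals and len(y_val):
        point, lo, hi = pls.jackknife_predict(Xc, y_cal, a, Xv)
        predictions = pd.DataFrame(
            {"plant_id": val_ids, "measured": y_val, "predicted": point,
             "lower95": lo, "upper95": hi}
        )
    return PLSRRun(
        trait=trait_name, fittable=True, n_components=a,
        selected_wavelengths=sel.selected, calibration_ids=cal_ids,
        validation_ids=val_ids, calibration_metrics=cal_metrics,
        validation_metrics=val_metrics, model=model, predictions=predictions,
    )


def run_trait_model(spectra: SpectraSet, traits: pd.DataFrame, trait_name: str,
                    n_wavelengths: int = 400, split: SplitSpec | None = None,
                    relieff: RReliefFParams | None = None,
                    compute_intervals: bool = True,
                    max_components: int = 20) -> PLSRRun:
    """Full-dataset RReliefF-PLSR run for one trait.

    Wavelength scoring uses calibration rows exclusively; metrics are
    reported for LOO calibration and for the held-out validation set.  A
    0-component LOO optimum yields a non-fittable run with a diagnosis,
    never an exception.
    """
    split = split or SplitSpec()
    relieff = relieff or RReliefFParams()
    tr, X = _complete_cases(spectra, traits, trait_name)
    cal_ids, val_ids = stratified_split(tr["plant_id"], tr[split.strata], split)
    pos = {p: i for i, p in enumerate(tr["plant_id"])}
    ci = [pos[p] for p in cal_ids]
    vi = [pos[p] for p in val_ids]
    y = tr[trait_name].to_numpy(dtype=float)
    return _fit_and_evaluate(
        X[ci], y[ci], X[vi], y[vi], spectra.wavelengths, n_wavelengths,
        relieff, split.seed, trait_name, cal_ids, val_ids, compute_intervals,
        max_components,
    )


def transfer_experiment(spectra: SpectraSet, traits: pd.DataFrame, trait_name: str,
                        group_var: str, train_level, n_wavelengths: int = 300,
                        relieff: RReliefFParams | None = None, seed: int = 0,
                        compute_intervals: bool = False,
                        max_components: int = 20) -> PLSRRun:
    """Calibrate within one group level, validate on the entire other level.

    ``group_var`` is "treatment" or "subpopulation".  Selection and
    calibration (including LOO component choice) never see the held-out
    group; calibration metrics are LOO within the training level.
    """
    relieff = relieff or RReliefFParams()
    if group_var not in traits.columns:
        raise KeyError(f"{group_var!r} not in the trait table")
    tr_all = traits.loc[traits[trait_name].notna()]
    levels = sorted(tr_all[group_var].unique())
    if train_level not in levels or len(levels) != 2:
        raise ValueError(f"need exactly two populated levels of {group_var!r}, "
                         f"with train_level among them")
    tr, X = _complete_cases(spectra, traits, trait_name)
    in_train = (tr[group_var] if group_var in tr.columns else
                tr["plant_id"].map(traits.set_index("plant_id")[group_var])) == train_level
    in_train = np.asarray(in_train)
    y = tr[trait_name].to_numpy(dtype=float)
    if np.ptp(y[in_train]) == 0:
        raise ValueError(f"trait {trait_name!r} is constant in {train_level!r}")
    return _fit_and_evaluate(
        X[in_train], y[in_train], X[~in_train], y[~in_train],
        spectra.wavelengths, n_wavelengths, relieff, seed, trait_name,
        tr.loc[in_train, "plant_id"].tolist(), tr.loc[~in_train, "plant_id"].tolist(),
        compute_intervals, max_components,
    )


def hyperparameter_grid(spectra: SpectraSet, traits: pd.DataFrame, trait_name: str,
                        wavelength_counts=DEFAULT_WAVELENGTH_COUNTS,
                        totals=DEFAULT_TOTALS, iterations: int = 100,
                        seed: int = 0, relieff: RReliefFParams | None = None,
                        max_components: int = 20) -> GridResult:
    """Wavelength-count x sample-size grid with repeated stratified subsamples.

    Each cell subsamples ``total`` complete-case rows (balanced across
    treatments), runs the full protocol, and aggregates mean and standard
    error of R^2/RMSEP/%RMSEP for calibration and validation over the
    iterations; non-fittable iterations are counted, not failed.
    """
    if iterations < 2:
        raise ValueError("need at least 2 iterations for a standard error")
    relieff = relieff or RReliefFParams()
    tr, X = _complete_cases(spectra, traits, trait_name)
    n_avail = len(tr)
    if max(totals) > n_avail:
        raise ValueError(f"largest total {max(totals)} exceeds the "
                         f"{n_avail} available complete cases")
    rng = np.random.default_rng(seed)
    trt = tr["treatment"].to_numpy()
    levels = sorted(pd.unique(trt))
    rows = []
    for total in totals:
        per = total // len(levels)
        for n_wl in wavelength_counts:
            recs = {m: {"r2": [], "rmsep": [], "pct_rmsep": []} for m in ("cal", "val")}
            n_unfit = 0
            for it in range(iterations):
                take = np.concatenate([
                    rng.choice(np.flatnonzero(trt == lv),
                               size=min(per, (trt == lv).sum()), replace=False)
                    for lv in levels
                ])
                sub = tr.iloc[take].reset_index(drop=True)
                sub_spectra = SpectraSet(spectra.wavelengths, X[take],
                                         sub[["plant_id"]].assign(week=0), level="plant")
                run = run_trait_model(
                    sub_spectra, sub, trait_name, n_wavelengths=n_wl,
                    split=SplitSpec(seed=int(rng.integers(2 ** 31))),
                    relieff=relieff, compute_intervals=False,
                    max_components=max_components,
                )
                if not run.fittable:
                    n_unfit += 1
                    continue
                for m, met in (("cal", run.calibration_metrics),
                               ("val", run.validation_metrics)):
                    recs[m]["r2"].append(met.r2)
                    recs[m]["rmsep"].append(met.rmsep)
                    recs[m]["pct_rmsep"].append(met.pct_rmsep)
            row = {"n_wavelengths": n_wl, "n_total": total,
                   "n_not_fittable": n_unfit,
                   "n_fitted": iterations - n_unfit}
            for m in ("cal", "val"):
                for k, vals in recs[m].items():
                    arr = np.asarray(vals, dtype=float)
                    row[f"{m}_{k}_mean"] = arr.mean() if len(arr) else np.nan
                    row[f"{m}_{k}_se"] = (arr.std(ddof=1) / np.sqrt(len(arr))
                                          if len(arr) > 1 else np.nan)
            rows.append(row)
    return GridResult(table=pd.DataFrame(rows), iterations=iterations)
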