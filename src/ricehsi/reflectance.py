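"""White/dark reflectance calibration and spectral aggregation.

Raw digital numbers from the imaging booth are converted to relative
reflectance (%) by the normalized difference against white and dark
reference scans,

    reflectance = 100 * (plant - dark) / (white - dark),

then aggregated: imaging events within a week are averaged per plant, and
replicate plants are averaged to accession x treatment means for the
multivariate analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synth import RawScan

__all__ = [
    "Spectrum",
    "SpectraSet",
    "CalibrationError",
    "calibrate_reflectance",
    "scans_to_spectraset",
    "weekly_average",
    "accession_mean",
    "qc_report",
]


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class Spectrum:
    """A single calibrated reflectance spectrum."""

    wavelengths: np.ndarray
    reflectance: np.ndarray
    plant_id: str
    week: int

    def __post_init__(self) -> None:
        if len(self.wavelengths) != len(self.reflectance):
            raise ValueError("wavelengths and reflectance differ in length")
        if not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")


@dataclass
class SpectraSet:
    """Spectra on a shared wavelength grid plus row metadata.

    ``values`` has one row per observation; ``meta`` is an aligned
    DataFrame carrying join keys (plant_id/event/week at plant level,
    accession/treatment/week at accession-mean level).  ``level`` records
    the aggregation state.
    """

    wavelengths: np.ndarray
    values: np.ndarray
    meta: pd.DataFrame
    level: str = "plant"

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.wavelengths):
            raise ValueError("values must be (rows, len(wavelengths))")
        if len(self.meta) != self.values.shape[0]:
            raise ValueError("metadata rows must align with the spectra matrix")
        if not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if self.values.shape[0] and np.isnan(self.values).all(axis=1).any():
            raise ValueError("a row with all-missing values is not allowed")
        self.meta = self.meta.reset_index(drop=True)

    def subset_wavelengths(self, wavelengths: np.ndarray) -> "SpectraSet":
        """Restrict to the given wavelengths (error if any is absent)."""
        idx = np.searchsorted(self.wavelengths, wavelengths)
        bad = (idx >= len(self.wavelengths)) | ~np.isclose(
            self.wavelengths[np.clip(idx, 0, len(self.wavelengths) - 1)], wavelengths
        )
        if np.any(bad):
            missing = np.asarray(wavelengths)[bad][:5]
            raise KeyError(f"wavelengths not on the grid: {missing}")
        return SpectraSet(np.asarray(wavelengths, float), self.values[:, idx],
                          self.meta.copy(), level=self.level)

    def select_week(self, week) -> "SpectraSet":
        mask = (self.meta["week"] == week).to_numpy()
        return SpectraSet(self.wavelengths, self.values[mask],
                          self.meta.loc[mask].reset_index(drop=True), level=self.level)


def calibrate_reflectance(scan: RawScan) -> Spectrum:
    """Apply the white/dark normalized-difference calibration to one scan."""
    denom = scan.white_dn - scan.dark_dn
    bad = denom <= 0
    if np.any(bad):
        wl = scan.wavelengths[bad][0]
        raise CalibrationError(
            f"white reference does not exceed dark reference at {wl:g} nm"
        )
    refl = 100.0 * (scan.plant_dn - scan.dark_dn) / denom
    return Spectrum(scan.wavelengths, refl, plant_id=scan.plant_id, week=scan.week)


def scans_to_spectraset(scans: list[RawScan]) -> SpectraSet:
    """Calibrate a collection of scans sharing one grid into a SpectraSet."""
    if not scans:
        raise ValueError("no scans provided")
    grid = scans[0].wavelengths
    rows, meta = [], []
    for scan in scans:
        if not np.array_equal(scan.wavelengths, grid):
            raise ValueError("scans do not share a wavelength grid")
        rows.append(calibrate_reflectance(scan).reflectance)
        meta.append({"plant_id": scan.plant_id, "week": scan.week, "event": scan.event})
    return SpectraSet(grid, np.vstack(rows), pd.DataFrame(meta), level="plant")


def weekly_average(spectra: SpectraSet, event_to_week: dict | None = None) -> SpectraSet:
    """Average imaging events within a week, per plant.

    ``event_to_week`` maps each event label to a week; if omitted, the
    ``week`` column already present in the metadata is used.  Plants with
    no event in a week are simply absent from the result.
    """
    meta = spectra.meta.copy()
    if event_to_week is not None:
        unmapped = set(meta["event"]) - set(event_to_week)
        if unmapped:
            raise KeyError(f"imaging events with no week assignment: {sorted(unmapped)[:5]}")
        meta["week"] = meta["event"].map(event_to_week)
    df = pd.DataFrame(spectra.values)
    df[["plant_id", "week"]] = meta[["plant_id", "week"]]
    grouped = df.groupby(["plant_id", "week"], sort=True).mean()
    out_meta = grouped.index.to_frame(index=False)
    return SpectraSet(spectra.wavelengths, grouped.to_numpy(), out_meta, level="plant")


def accession_mean(spectra: SpectraSet, design: pd.DataFrame) -> SpectraSet:
    """Average replicate plants to accession x treatment x week means.

    Missing replicates are simply dropped from the mean, so a surviving
    replicate represents its accession; an accession x treatment cell with
    no replicate at all raises.
    """
    known = set(design["plant_id"])
    unknown = set(spectra.meta["plant_id"]) - known
    if unknown:
        raise KeyError(f"plants absent from the design table: {sorted(unknown)[:5]}")
    meta = spectra.meta.merge(design[["plant_id", "accession", "treatment"]], on="plant_id")
    df = pd.DataFrame(spectra.values)
    df[["accession", "treatment", "week"]] = meta[["accession", "treatment", "week"]]
    grouped = df.groupby(["accession", "treatment", "week"], sort=True).mean()
    expected = (
        design[["accession", "treatment"]].drop_duplicates().merge(
            spectra.meta[["week"]].drop_duplicates(), how="cross")
    )
    present = grouped.index.to_frame(index=False)
    missing = expected.merge(present, how="left", indicator=True)
    missing = missing[missing["_merge"] == "left_only"]
    if len(missing):
        first = missing.iloc[0]
        raise ValueError(
            f"no replicate available for accession {first['accession']} "
            f"({first['treatment']}, week {first['week']})"
        )
    return SpectraSet(spectra.wavelengths, grouped.to_numpy(),
                      present, level="accession_mean")


def qc_report(spectra: SpectraSet, lo: float = -5.0, hi: float = 105.0,
              max_frac: float = 0.01) -> pd.DataFrame:
    """Flag rows with more than ``max_frac`` of bands outside [lo, hi].

    Out-of-range reflectance can occur under noise and is retained rather
    than clipped (clipping would bias the means); this report is the QC
    surface for it.
    """
    frac = ((spectra.values < lo) | (spectra.values > hi)).mean(axis=1)
    out = spectra.meta.copy()
    out["frac_out_of_range"] = frac
    out["flagged"] = frac > max_frac
    return out
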