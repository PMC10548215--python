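"""Synthetic rice canopy experiments with known spectrum-trait couplings.

This module emulates the statistical design of a greenhouse phenotyping
experiment: 23 rice accessions from two subpopulations (*indica*, IND, and
*tropical japonica*, TRJ), grown under high (N1) and low (N2) nitrogen
fertigation, imaged weekly with VNIR (400-1000 nm) and SWIR (1000-2500 nm)
hyperspectral cameras, and phenotyped for leaf- and canopy-level traits.

Each plant is driven by three latent physiological levels: chlorophyll
(controls visible absorption, the Red Edge position and leaf nitrogen),
water (controls the 1450/1940 nm short-wave-infrared troughs), and canopy
structure (controls the near-infrared plateau).  Traits are generated as
noisy functions of the same latents, so the mapping the downstream models
must recover is known by construction and the attainable prediction skill
has a closed-form ceiling (:func:`analytic_r2_ceiling`).

The generative spectrum is a smooth baseline with Gaussian absorption
features and a logistic Red-Edge ramp -- plant-like, not a radiative
transfer model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticConfig",
    "PlantState",
    "RawScan",
    "make_design",
    "make_wavelength_grid",
    "true_reflectance",
    "simulate_scan",
    "simulate_traits",
    "generate_experiment",
    "analytic_r2_ceiling",
    "make_planted_band_data",
]

TREATMENTS = ("N1", "N2")

# Trait-coupling coefficients: leaf N (%) is affine in the chlorophyll
# latent; leaf C (%) is near-constant so C:N = C/N tracks 1/N.
N_INTERCEPT = 1.0
N_SLOPE = 1.2
C_MEAN = 40.0
C_SD = 0.5
E_PER_GSW = 1.6  # nighttime transpiration exactly proportional to gsw


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of a synthetic experiment.

    Defaults emulate the reference design: 15 IND + 8 TRJ accessions,
    two replicates per accession x treatment cell with one TRJ accession
    (the "Cybonnet" slot) carrying three replicates, two nitrogen levels,
    and four weekly imaging timepoints -> 94 occupied pots.
    """

    n_accessions_ind: int = 15
    n_accessions_trj: int = 8
    reps_per_cell: int = 2
    triple_rep_accession: str | None = "TRJ08"  # one accession x 3 reps x 2 treatments
    treatments: tuple[str, str] = TREATMENTS
    weeks: tuple[int, ...] = (6, 9, 10, 13)
    scans_per_week: int = 3
    vnir_range_nm: tuple[float, float] = (400.0, 1000.0)
    swir_range_nm: tuple[float, float] = (1000.0, 2500.0)
    vnir_step_nm: float = 2.0
    swir_step_nm: float = 5.0
    # Effect sizes and noise scales
    treatment_chl_gap: float = 0.5        # N1 - N2 difference in the chlorophyll latent
    treatment_structure_gap: float = 0.3  # N1 - N2 difference in the structure latent
    treatment_n_extra: float = 0.3        # luxury N (%) under N1 beyond the chlorophyll track
    treatment_redge_shift_nm: float = 10.0  # mean Red-Edge shift implied by the chl gap
    accession_sd: float = 0.08            # accession random effect on each latent
    residual_sd: float = 0.07             # per-plant residual on each latent
    trait_noise_sd: float = 0.13          # sd of the noise on leaf N (%)
    spectral_noise_sd: float = 1.0        # sd of per-scan reflectance noise (%)
    week13_attenuation: float = 0.45      # fraction of the chl gap remaining at week 13
    week13_water_stress: bool = True      # N1 water deficit at the final timepoint
    n_missing_traits: int = 6             # plants with unavailable SLA/C/N
    trait_week: int = 9                   # week whose state drives destructive traits
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_accessions_ind + self.n_accessions_trj < 1:
            raise ValueError("need at least one accession")
        if self.reps_per_cell < 1:
            raise ValueError("need at least one replicate per cell")
        if len(self.treatments) != 2:
            raise ValueError("exactly two treatment levels are required")
        if self.scans_per_week < 1 or self.n_missing_traits < 0:
            raise ValueError("counts must be positive")
        for lo, hi in (self.vnir_range_nm, self.swir_range_nm):
            if not lo < hi:
                raise ValueError("wavelength ranges must be increasing")
        if self.vnir_step_nm <= 0 or self.swir_step_nm <= 0:
            raise ValueError("sampling steps must be positive")

    def accession_names(self) -> list[str]:
        ind = [f"IND{i + 1:02d}" for i in range(self.n_accessions_ind)]
        trj = [f"TRJ{i + 1:02d}" for i in range(self.n_accessions_trj)]
        return ind + trj


@dataclass(frozen=True)
class PlantState:
    """Latent physiological state of one plant at one timepoint."""

    chlorophyll_level: float
    water_level: float
    structure_level: float
    accession_effect: float = 0.0
    residual: float = 0.0

    def __post_init__(self) -> None:
        for v in (self.chlorophyll_level, self.water_level, self.structure_level):
            if not np.isfinite(v):
                raise ValueError("latent levels must be finite")


@dataclass(frozen=True)
class RawScan:
    """One imaging event: raw digital numbers plus white/dark references."""

    wavelengths: np.ndarray
    plant_dn: np.ndarray
    white_dn: np.ndarray
    dark_dn: np.ndarray
    plant_id: str
    week: int
    event: str

    def __post_init__(self) -> None:
        n = len(self.wavelengths)
        if not (len(self.plant_dn) == len(self.white_dn) == len(self.dark_dn) == n):
            raise ValueError("all scan vectors must share one wavelength grid")
        if not np.all(self.white_dn > self.dark_dn):
            raise ValueError("white reference must exceed dark reference everywhere")


def make_wavelength_grid(config: SyntheticConfig | None = None) -> np.ndarray:
    """Merged VNIR+SWIR grid.

    Both cameras cover 1000 nm; the merged grid keeps the VNIR sample at
    1000 nm and starts SWIR one step later (half-open junction), avoiding a
    duplicate wavelength.  Defaults give 301 + 300 = 601 bands.
    """
    cfg = config or SyntheticConfig()
    v_lo, v_hi = cfg.vnir_range_nm
    s_lo, s_hi = cfg.swir_range_nm
    vnir = np.arange(v_lo, v_hi + 1e-9, cfg.vnir_step_nm)
    swir = np.arange(s_lo + cfg.swir_step_nm, s_hi + 1e-9, cfg.swir_step_nm)
    grid = np.concatenate([vnir, swir])
    if not np.all(np.diff(grid) > 0):
        raise ValueError("wavelength grid must be strictly increasing")
    return grid


def make_design(config: SyntheticConfig) -> pd.DataFrame:
    """Design table: one row per occupied pot.

    Columns: plant_id, accession, subpopulation, treatment, replicate.
    With defaults, 22 accessions x 2 reps x 2 treatments plus one
    accession x 3 reps x 2 treatments = 94 rows (purge pots excluded).
    """
    rows = []
    for acc in config.accession_names():
        subpop = "IND" if acc.startswith("IND") else "TRJ"
        reps = config.reps_per_cell + (1 if acc == config.triple_rep_accession else 0)
        for trt in config.treatments:
            for rep in range(1, reps + 1):
                rows.append(
                    {
                        "plant_id": f"{acc}_{trt}_r{rep}",
                        "accession": acc,
                        "subpopulation": subpop,
                        "treatment": trt,
                        "replicate": rep,
                    }
                )
    return pd.DataFrame(rows)


def _gauss(x: np.ndarray, mu: float, sd: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - mu) / sd) ** 2)


def true_reflectance(state: PlantState, grid: np.ndarray,
                     redge_slope_nm: float = 20.0) -> np.ndarray:
    """Noise-free reflectance (%) of a plant in a given latent state.

    Visible reflectance is a small baseline with a green bump, attenuated
    multiplicatively by chlorophyll absorption bands (480-510, 640-670 nm);
    a logistic Red-Edge ramp whose inflection shifts with chlorophyll joins
    it to a NIR plateau set by canopy structure; beyond 1000 nm the plateau
    decays and is carved by water troughs (1450, 1940 nm) whose depth grows
    with the water latent, plus a fixed dry-matter feature near 2300 nm.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.min() < 400.0 or grid.max() > 2500.0:
        raise ValueError("wavelength grid outside supported 400-2500 nm range")
    c = max(state.chlorophyll_level, 0.05)
    w = max(state.water_level, 0.0)
    s = state.structure_level

    plateau_level = 40.0 + 8.0 * (s - 1.0)
    absorb = 1.1 * _gauss(grid, 495.0, 18.0) + 1.3 * _gauss(grid, 655.0, 14.0)
    vis = (4.0 + 9.0 * _gauss(grid, 550.0, 35.0)) * np.exp(-0.6 * c * absorb) + 2.5

    redge_center = 702.0 + redge_slope_nm * (c - 1.0)
    ramp = 1.0 / (1.0 + np.exp(-(grid - redge_center) / 13.0))

    decay = np.where(grid <= 1000.0, 1.0, 0.9 * np.exp(-(grid - 1000.0) / 1200.0) + 0.1)
    troughs = (
        np.clip(0.32 * w, 0.0, 0.85) * _gauss(grid, 1450.0, 60.0)
        + np.clip(0.45 * w, 0.0, 0.92) * _gauss(grid, 1940.0, 85.0)
        + 0.12 * _gauss(grid, 2300.0, 80.0)
    )
    plateau = plateau_level * decay * (1.0 - np.clip(troughs, 0.0, 0.98))

    return np.clip(vis * (1.0 - ramp) + plateau * ramp, 0.0, 100.0)


def _correlated_noise(rng: np.random.Generator, n: int, noise_sd: float,
                      smooth_sigma: float = 10.0, smooth_frac: float = 0.7
                      ) -> np.ndarray:
    """Stationary spectral noise with per-band sd exactly ``noise_sd``.

    Real canopy scans do not have independent noise per band: illumination
    geometry and plant pose perturb whole spectral regions together.  The
    draw mixes a circularly-smoothed component (Gaussian kernel,
    ``smooth_sigma`` samples) with a white component; circular smoothing
    keeps the variance stationary and the normalization exact.
    """
    from scipy.ndimage import gaussian_filter1d

    white = rng.normal(0.0, 1.0, size=n)
    smooth = gaussian_filter1d(rng.normal(0.0, 1.0, size=n), smooth_sigma,
                               mode="wrap")
    impulse = np.zeros(n)
    impulse[0] = 1.0
    kernel = gaussian_filter1d(impulse, smooth_sigma, mode="wrap")
    smooth /= np.sqrt((kernel ** 2).sum())
    return noise_sd * (np.sqrt(smooth_frac) * smooth
                       + np.sqrt(1.0 - smooth_frac) * white)


def simulate_scan(state: PlantState, grid: np.ndarray, noise_sd: float,
                  seed: int | np.random.Generator, plant_id: str = "plant",
                  week: int = 0, event: str = "e0",
                  redge_slope_nm: float = 20.0) -> RawScan:
    """Raw digital numbers for one imaging event.

    The scan is constructed so that white/dark calibration recovers
    ``true_reflectance(state)`` plus additive spectrally-correlated noise
    of per-band standard deviation ``noise_sd`` (reflectance-% units): the
    plant signal is dark + gain x (R + eps)/100 with a wavelength-dependent
    lamp gain.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    grid = np.asarray(grid, dtype=float)
    refl = true_reflectance(state, grid, redge_slope_nm=redge_slope_nm)
    dark = 100.0 + 0.01 * (grid - 400.0)
    gain = 3000.0 * (0.7 + 0.3 * _gauss(grid, 1100.0, 700.0))
    noisy = refl + _correlated_noise(rng, len(grid), noise_sd) if noise_sd > 0 else refl
    plant = dark + gain * noisy / 100.0
    return RawScan(
        wavelengths=grid,
        plant_dn=plant,
        white_dn=dark + gain,
        dark_dn=dark,
        plant_id=plant_id,
        week=week,
        event=event,
    )


def simulate_traits(state: PlantState, design_row: pd.Series | dict,
                    seed: int | np.random.Generator,
                    trait_noise_sd: float = 0.13,
                    treatment_n_extra: float = 0.0,
                    high_n_label: str = "N1") -> dict:
    """Ground-reference trait record for one plant.

    Leaf N (%) is affine in the chlorophyll latent, with a luxury-uptake
    offset under the high-nitrogen treatment (``treatment_n_extra``):
    heavily fertigated plants store N beyond what pigment levels track, so
    the N-chlorophyll mapping is treatment-dependent.  C (%) is
    near-constant, making the derived C:N ratio strongly anti-correlated
    with N.  Stomatal conductance gsw is right-skewed (log-normal) and
    nighttime transpiration E is exactly proportional to it.  Quantum
    yields rise with chlorophyll; final biomass couples weakly to water
    and structure; leaf area and dry weight imply higher SLA under high
    nitrogen.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    c = state.chlorophyll_level
    extra = treatment_n_extra if dict(design_row).get("treatment") == high_n_label else 0.0
    n_pct = max(N_INTERCEPT + N_SLOPE * c + extra + rng.normal(0.0, trait_noise_sd), 0.2)
    c_pct = C_MEAN + rng.normal(0.0, C_SD)
    gsw = float(np.exp(rng.normal(-1.6, 0.35) + 0.15 * (c - 1.0)))
    pqy = float(np.clip(0.70 + 0.10 * (c - 1.0) + rng.normal(0.0, 0.04), 0.0, 1.0))
    mqy = float(np.clip(0.52 + 0.08 * (c - 1.0) + rng.normal(0.0, 0.05), 0.0, 1.0))
    fb = max(28.0 + 6.0 * (state.water_level - 1.0)
             + 4.0 * (state.structure_level - 1.0) + rng.normal(0.0, 2.0), 1.0)
    leaf_area = max(20.0 + 5.0 * (c - 1.0) + rng.normal(0.0, 2.5), 5.0)
    dry_weight = max(0.10 - 0.015 * (c - 1.0) + rng.normal(0.0, 0.012), 0.02)
    vcmax = max(55.0 + 12.0 * (c - 1.0) + rng.normal(0.0, 6.0), 5.0)
    jmax = max(1.9 * vcmax + rng.normal(0.0, 8.0), 5.0)
    row = dict(design_row)
    row.update(
        {
            "A": rng.normal(-0.9, 0.25),
            "C": c_pct,
            "N": n_pct,
            "E": E_PER_GSW * gsw,
            "gsw": gsw,
            "FB": fb,
            "Jmax": jmax,
            "Vcmax": vcmax,
            "pQY": pqy,
            "mQY": mqy,
            "leaf_area": leaf_area,
            "dry_weight": dry_weight,
        }
    )
    return row


def _gap_factor(week: int, config: SyntheticConfig) -> float:
    return config.week13_attenuation if week == max(config.weeks) and len(config.weeks) > 1 else 1.0


def _plant_states(config: SyntheticConfig, design: pd.DataFrame,
                  rng: np.random.Generator) -> dict[tuple[str, int], PlantState]:
    """Latent states per (plant, week): treatment effect + accession and
    plant random effects + a linear week drift; at the final week the
    treatment gap is attenuated and high-N plants may be water-stressed."""
    accs = design["accession"].unique()
    acc_fx = {a: rng.normal(0.0, config.accession_sd, size=3) for a in accs}
    states: dict[tuple[str, int], PlantState] = {}
    for _, row in design.iterrows():
        res = rng.normal(0.0, config.residual_sd, size=3)
        sign = 0.5 if row["treatment"] == config.treatments[0] else -0.5
        a = acc_fx[row["accession"]]
        for week in config.weeks:
            g = _gap_factor(week, config)
            chl = 1.0 + sign * config.treatment_chl_gap * g + a[0] + res[0] - 0.005 * (week - config.trait_week)
            water = 1.0 + a[1] + res[1]
            if (config.week13_water_stress and week == max(config.weeks)
                    and len(config.weeks) > 1 and sign > 0):
                water -= 0.35
            struct = 1.0 + sign * config.treatment_structure_gap + a[2] + res[2] + 0.02 * (week - min(config.weeks))
            states[(row["plant_id"], week)] = PlantState(
                chlorophyll_level=chl, water_level=water, structure_level=struct,
                accession_effect=a[0], residual=res[0],
            )
    return states


def generate_experiment(config: SyntheticConfig, seed: int | None = None
                        ) -> tuple[list[RawScan], pd.DataFrame, pd.DataFrame]:
    """Full synthetic experiment: raw scans over weeks, traits, design.

    Every plant gets ``scans_per_week`` imaging events per week (so weekly
    averaging is exercised); destructive traits are driven by the
    ``trait_week`` state; SLA/C/N-related fields are blanked for exactly
    ``n_missing_traits`` plants (seeded draw), emulating lab losses.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    design = make_design(config)
    grid = make_wavelength_grid(config)
    states = _plant_states(config, design, rng)
    redge_slope = config.treatment_redge_shift_nm / config.treatment_chl_gap

    scans: list[RawScan] = []
    for _, row in design.iterrows():
        for week in config.weeks:
            st = states[(row["plant_id"], week)]
            for j in range(config.scans_per_week):
                scans.append(
                    simulate_scan(
                        st, grid, config.spectral_noise_sd, rng,
                        plant_id=row["plant_id"], week=week, event=f"w{week}e{j}",
                        redge_slope_nm=redge_slope,
                    )
                )

    trait_week = config.trait_week if config.trait_week in config.weeks else config.weeks[0]
    records = [
        simulate_traits(states[(row["plant_id"], trait_week)], row, rng,
                        trait_noise_sd=config.trait_noise_sd,
                        treatment_n_extra=config.treatment_n_extra,
                        high_n_label=config.treatments[0])
        for _, row in design.iterrows()
    ]
    traits = pd.DataFrame(records)

    if config.n_missing_traits > 0:
        # Seeded draw constrained so every accession x treatment cell keeps at
        # least one replicate with data (the replicate-fallback rule presumes
        # a survivor, as in the emulated study).
        order = rng.permutation(len(traits))
        cell_left = design.groupby(["accession", "treatment"]).size().to_dict()
        missing_idx = []
        for i in order:
            cell = (design.iloc[i]["accession"], design.iloc[i]["treatment"])
            if cell_left[cell] > 1:
                cell_left[cell] -= 1
                missing_idx.append(i)
            if len(missing_idx) == config.n_missing_traits:
                break
        traits.loc[traits.index[missing_idx], ["C", "N", "leaf_area", "dry_weight"]] = np.nan
    return scans, traits, design


def analytic_r2_ceiling(config: SyntheticConfig) -> float:
    """Best attainable R^2 for predicting leaf N from noise-free spectra.

    Spectra identify the chlorophyll latent and the treatment (via the
    structure baseline and Red-Edge position), so the predictable part of
    N comprises the slope-scaled latent variance and the luxury-uptake
    offset; the irreducible part is the additive trait noise.  With
    balanced treatments the treatment indicator has variance 1/4.
    """
    between = (N_SLOPE * config.treatment_chl_gap + config.treatment_n_extra) ** 2 / 4.0
    within = N_SLOPE ** 2 * (config.accession_sd ** 2 + config.residual_sd ** 2)
    signal = between + within
    return signal / (signal + config.trait_noise_sd ** 2)


def make_planted_band_data(n: int = 70, n_bands: int = 600, n_informative: int = 10,
                           latent_weight: float = 0.6, noise_sd: float = 0.05,
                           seed: int = 0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Feature-selection benchmark: y depends on a known subset of bands.

    The planted bands share a common latent signal (as spectral features
    driven by one biochemical constituent do): each planted band is
    latent_weight x latent + (1 - latent_weight) x independent noise, all
    other bands are independent uniforms, and the response is the mean of
    the planted bands plus Gaussian noise.  Returns (X, y, planted_indices).
    """
    rng = np.random.default_rng(seed)
    X = rng.uniform(0.0, 1.0, size=(n, n_bands))
    latent = rng.uniform(0.0, 1.0, size=n)
    planted = np.linspace(0, n_bands - 1, n_informative).round().astype(int)
    X[:, planted] = latent_weight * latent[:, None] + (1.0 - latent_weight) * X[:, planted]
    y = X[:, planted].mean(axis=1) + rng.normal(0.0, noise_sd, size=n)
    return X, y, planted


def with_overrides(config: SyntheticConfig, **kwargs) -> SyntheticConfig:
    """Convenience: a copy of ``config`` with fields replaced."""
    return replace(config, **kwargs)
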