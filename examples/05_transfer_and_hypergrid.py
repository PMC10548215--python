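"""Transfer experiments and the wavelength-count x sample-size grid.

Calibrating within one nitrogen treatment and validating on the other
fails (the N-chlorophyll mapping is treatment-dependent), while
calibrating within one rice subpopulation transfers to the other (no
genetic-background signature in the spectra).  The hyperparameter grid
shows that small calibration sets with every wavelength underperform
larger sets with a selected subset.
"""

import ricehsi as rh
from ricehsi import groundtruth as gt

cfg = rh.SyntheticConfig()
scans, traits, design = rh.generate_experiment(cfg, seed=42)
week9 = rh.weekly_average(rh.scans_to_spectraset(scans)).select_week(9)
traits = gt.transform_traits(gt.add_derived_traits(traits))
traits = traits.merge(design[["plant_id", "subpopulation"]], on="plant_id",
                      suffixes=("", "_design"))

for var, level in (("treatment", "N1"), ("subpopulation", "IND")):
    t = rh.transfer_experiment(week9, traits, "N", var, level,
                               n_wavelengths=300, seed=0)
    print(f"train on {var}={level}: calibration R2={t.calibration_metrics.r2:.2f}, "
          f"cross-{var} validation R2={t.validation_metrics.r2:.2f}")
print("(cross-treatment prediction collapses; cross-subpopulation holds)\n")

grid = rh.hyperparameter_grid(week9, traits, "N",
                              wavelength_counts=(300, 700), totals=(48, 88),
                              iterations=10, seed=0)
cols = ["n_total", "n_wavelengths", "val_r2_mean", "val_r2_se"]
print("validation R2 by sample size and wavelength count (10 iterations):")
print(grid.table[cols].round(3).to_string(index=False))
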