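#!/usr/bin/env python
"""Calibrate the 48-model PLS panel on the low-HDL cohort.

Reads the simulated cohort from results/cohorts/, splits 122 samples
80/42 by Kennard-Stone on the TG window, selects components by 10-fold
cross-validation, and tests each model with 199 response permutations
(a scaled-down permutation count; the published protocol uses 1000).
Writes a two-set validation report shaped like the study's model
tables and one JSON per model under results/calibration/.
"""

from pathlib import Path

from lipopls.chemometrics import PanelConfig, calibrate_panel
from lipopls.concentrations import ConcentrationTable
from lipopls.pipeline import derive_seeds
from lipopls.spectra import read_spectra

COHORTS = Path("results/cohorts")
OUT = Path("results/calibration")
MASTER_SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    panel_seed = derive_seeds(MASTER_SEED, 3)[2]
    for preset, B in (("low_hdl_cm", 199), ("hyperchol", 1)):
        spectra = read_spectra(COHORTS / f"{preset}_spectra.csv")
        truth = ConcentrationTable.read_csv(COHORTS / f"{preset}_truth.csv")
        panel = calibrate_panel(
            spectra, truth,
            PanelConfig(m_train=80, n_permutations=B, alpha=0.01, seed=panel_seed),
        )
        panel.report.to_csv(OUT / f"{preset}_report.csv", index=False)
        panel.save_models(OUT / f"{preset}_models")
        test = panel.report.query("set == 'test'")
        print(f"\n{preset}: {panel.n_attempted} models attempted "
              f"(train {len(panel.train_idx)} / test {len(panel.test_idx)})")
        print(f"  held-out Q2 median {test['Q2'].median():.2f}; "
              f"{int((test['Q2'] >= 0.6).sum())} models with Q2 >= 0.6")
        strong = test.nlargest(5, "Q2")[["class", "lipid", "n_lv", "Q2", "RMSE_mgdl", "CV_pct"]]
        print(strong.round(3).to_string(index=False))


if __name__ == "__main__":
    main()
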