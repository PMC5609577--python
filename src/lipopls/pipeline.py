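"""End-to-end replica pipeline: simulate -> calibrate -> cross-cohort
bias -> crossover treatment effects.

All randomness flows from one master seed through
``numpy.random.SeedSequence`` spawning, so a run is reproducible from
its manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .chemometrics import PanelConfig, calibrate_panel
from .cross_cohort import bias_report, cross_predict, plot_bias
from .crossover import simulate_crossover_study
from .simulate import DEFAULT_NOISE_SD, simulate_cohort
from .spectra import write_spectra
from .treatment_effect import analyze_study

log = logging.getLogger("lipopls")

__all__ = ["RunConfig", "run_study_replica", "derive_seeds"]

DEFAULT_EFFECT_MAP = {
    ("LDL_tot", "CH"): 0.95,
    ("LDL08", "CH"): 0.96,
    ("LDL09", "CH"): 0.945,
    ("LDL10", "CH"): 0.93,
    ("LDL11", "CH"): 0.94,
}


@dataclass
class RunConfig:
    """Settings of a full replica run."""

    master_seed: int = 1
    cohort_n: int = 122
    m_train: int = 80
    noise_sd: float = DEFAULT_NOISE_SD
    cv_folds: int = 10
    n_permutations: int = 1000
    alpha: float = 0.001
    lv_range: tuple[int, int] = (1, 15)
    n_subjects: int = 40
    sigma_subject: float = 0.15
    sigma_visit: float = 0.05
    effect_map: dict = field(default_factory=lambda: dict(DEFAULT_EFFECT_MAP))
    out_dir: str = "results/replica"
    make_plots: bool = True

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["effect_map"] = {f"{c}:{l}": v for (c, l), v in self.effect_map.items()}
        d["lv_range"] = list(self.lv_range)
        return d


def derive_seeds(master_seed: int, n: int) -> list[int]:
    """Deterministic child seeds (< 2**31) from the master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(c.generate_state(1)[0] % (2**31 - 1)) for c in ss.spawn(n)]


def run_study_replica(config: RunConfig | None = None) -> dict:
    """Execute the full synthetic replica; returns the artifact paths.

    Stages: (1) simulate a low-HDL+chylomicron cohort and a
    hypercholesterolemic cohort; (2) calibrate the 48-model panel on
    each; (3) predict the low-HDL test samples with the foreign
    (hyperchol-trained) panel and summarize bias against the same-
    cohort baseline; (4) simulate the crossover study and estimate
    treatment effects. A manifest records config, seeds and versions.
    """
    cfg = config or RunConfig()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = derive_seeds(cfg.master_seed, 4)
    manifest: dict = {
        "config": cfg.to_jsonable(),
        "seeds": {"low_hdl_cm": seeds[0], "hyperchol": seeds[1],
                  "panel": seeds[2], "crossover": seeds[3]},
        "lipopls_version": __version__,
        "numpy_version": np.__version__,
        "stages": {},
    }
    artifacts: dict[str, str] = {}

    def stage(name):
        t0 = time.time()
        log.info("stage %s started", name)
        return t0

    t0 = stage("simulate")
    low = simulate_cohort("low_hdl_cm", cfg.cohort_n, seed=seeds[0], noise_sd=cfg.noise_sd)
    hyper = simulate_cohort("hyperchol", cfg.cohort_n, seed=seeds[1], noise_sd=cfg.noise_sd)
    write_spectra(low.spectra, out / "low_hdl_cm_spectra.csv")
    low.truth.to_csv(out / "low_hdl_cm_truth.csv")
    low.subjects.to_csv(out / "low_hdl_cm_subjects.csv", index=False)
    artifacts["spectra"] = str(out / "low_hdl_cm_spectra.csv")
    artifacts["truth"] = str(out / "low_hdl_cm_truth.csv")
    manifest["stages"]["simulate"] = {"seconds": round(time.time() - t0, 2)}

    t0 = stage("calibrate")
    pcfg = PanelConfig(m_train=cfg.m_train, cv_folds=cfg.cv_folds,
                       n_permutations=cfg.n_permutations, alpha=cfg.alpha,
                       lv_range=cfg.lv_range, seed=seeds[2])
    panel_low = calibrate_panel(low.spectra, low.truth, pcfg)
    panel_hyper = calibrate_panel(hyper.spectra, hyper.truth, pcfg)
    panel_low.report.to_csv(out / "calibration_report.csv", index=False)
    panel_hyper.report.to_csv(out / "calibration_report_hyperchol.csv", index=False)
    panel_low.save_models(out / "models_low_hdl_cm")
    artifacts["calibration_report"] = str(out / "calibration_report.csv")
    manifest["stages"]["calibrate"] = {
        "seconds": round(time.time() - t0, 2),
        "n_attempted": panel_low.n_attempted,
        "n_significant": int(panel_low.report.query("set == 'test'")["significant"].sum()),
    }

    t0 = stage("cross_cohort")
    test_spectra = [low.spectra[i] for i in panel_low.test_idx]
    test_truth_df = low.truth.data.iloc[panel_low.test_idx]
    from .concentrations import ConcentrationTable
    test_truth = ConcentrationTable(test_truth_df, units="mg/dL")
    pred_foreign = cross_predict(panel_hyper.models, test_spectra)
    pred_own = cross_predict(panel_low.models, test_spectra)
    bias_foreign = bias_report(pred_foreign, test_truth)
    bias_own = bias_report(pred_own, test_truth)
    bias_foreign["cohort"] = "crossed"
    bias_own["cohort"] = "matched"
    bias = pd.concat([bias_own, bias_foreign], ignore_index=True)
    bias.to_csv(out / "bias_report.csv", index=False)
    artifacts["bias_report"] = str(out / "bias_report.csv")
    if cfg.make_plots:
        plot_bias(pred_foreign, test_truth, out / "bias_pred_vs_obs.png")
    manifest["stages"]["cross_cohort"] = {"seconds": round(time.time() - t0, 2)}

    t0 = stage("treatment_effect")
    study = simulate_crossover_study("low_hdl_cm", cfg.n_subjects, cfg.effect_map,
                                     cfg.sigma_subject, cfg.sigma_visit, seed=seeds[3])
    study.records_mmol().to_csv(out / "study.csv", index=False)
    effects = analyze_study(study.records_mmol())
    effects.to_csv(out / "effects_report.csv", index=False)
    artifacts["effects_report"] = str(out / "effects_report.csv")
    manifest["stages"]["treatment_effect"] = {"seconds": round(time.time() - t0, 2)}

    manifest["config_hash"] = hashlib.sha256(
        json.dumps(cfg.to_jsonable(), sort_keys=True).encode()
    ).hexdigest()[:16]
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    artifacts["manifest"] = str(out / "manifest.json")
    return artifacts
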