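"""Two-period crossover study simulator.

Emulates a randomized, double-blind, placebo-controlled crossover
design: each subject receives both treatments (active "TB" vs placebo)
across two periods with balanced sequence allocation, sampled at the
period starts (D1, D57; pre-treatment baselines) and twice in the
fourth treatment week (D25/D28 and D81/D84; post-treatment visits 1
and 2).

Outcomes are multiplicative: for subject i, outcome o, visit v,

    y = b_io * m_o(trt) * exp(u_i) * exp(e_iv)

where b_io is the subject's phenotype-drawn baseline level, m_o the
treatment multiplier (1 under placebo and on baseline days), u_i a
subject random effect and e a visit-level noise term, both on the log
scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .registry import SPECIES
from .simulate import PhenotypePreset, _draw_concentrations, load_preset

__all__ = ["CrossoverDataset", "simulate_crossover_study", "BASELINE_DAYS", "POST_DAYS"]

BASELINE_DAYS = {1: "D1", 2: "D57"}
POST_DAYS = {1: {1: "D25", 2: "D28"}, 2: {1: "D81", 2: "D84"}}


@dataclass
class CrossoverDataset:
    """Long-format study records plus the generating ground truth."""

    records: pd.DataFrame          # subject, day, period, treatment, visit, covariates, class, lipid, value_mgdl
    subjects: pd.DataFrame         # subject, gender, age, bmi, sequence
    effect_map: dict[tuple[str, str], float]
    subject_effects: pd.Series     # log-scale random intercepts
    seed: int

    def records_mmol(self) -> pd.DataFrame:
        """Records with outcomes converted to mmol/L (reporting scale)."""
        out = self.records.copy()
        mm = out["lipid"].map(lambda s: SPECIES[s].molar_mass)
        out["value_mmol_per_L"] = out["value_mgdl"] * 10.0 / mm
        return out.drop(columns=["value_mgdl"])


def simulate_crossover_study(preset: PhenotypePreset | str, n_subjects: int,
                             effect_map: dict[tuple[str, str], float] | None,
                             sigma_subject: float = 0.15, sigma_visit: float = 0.05,
                             seed: int = 0,
                             drop_records: list[tuple[str, str]] | None = None) -> CrossoverDataset:
    """Simulate a balanced two-period crossover study.

    ``effect_map`` maps (class, lipid) to a multiplicative treatment
    effect (e.g. 0.95 for a 5% reduction under active treatment);
    unlisted outcomes get 1.0. ``drop_records`` optionally removes
    specific (subject, day) samples to emulate missing data.
    """
    if n_subjects % 2 != 0:
        raise ValueError("n_subjects must be even for balanced sequence allocation")
    if isinstance(preset, str):
        preset = load_preset(preset)
    effect_map = dict(effect_map or {})
    rng = np.random.default_rng(seed)

    subjects = [f"S{i + 1:02d}" for i in range(n_subjects)]
    # Balanced randomization: half the subjects get TB in period 1.
    order = rng.permutation(n_subjects)
    tb_first = np.zeros(n_subjects, bool)
    tb_first[order[: n_subjects // 2]] = True

    meta = pd.DataFrame(
        {
            "subject": subjects,
            "gender": np.where(rng.random(n_subjects) < 0.6, "M", "F"),
            "age": np.clip(rng.normal(60.0, 6.0, n_subjects), 40, 80).round(1),
            "bmi": np.clip(rng.normal(29.0, 3.0, n_subjects), 20, 40).round(1),
            "sequence": np.where(tb_first, "TB-placebo", "placebo-TB"),
        }
    )

    base = _draw_concentrations(preset, n_subjects, rng)  # subject-level trait values
    # category totals are outcomes too (sum of member subclasses at baseline)
    from .registry import LpCategory
    for cat in LpCategory:
        for lipid in ("TG", "CH"):
            cols = [c for c in base.columns
                    if c[1] == lipid and c[0].startswith(cat.value) and "_tot" not in c[0]]
            base[(f"{cat.value}_tot", lipid)] = base[cols].sum(axis=1)
    outcomes = list(base.columns)
    mult = np.array([effect_map.get(o, 1.0) for o in outcomes])
    u = rng.normal(0.0, sigma_subject, n_subjects)

    drop = set(drop_records or [])
    rows = []
    for i, subj in enumerate(subjects):
        for period in (1, 2):
            trt = ("TB" if tb_first[i] else "placebo") if period == 1 else (
                "placebo" if tb_first[i] else "TB")
            day_plan = [(BASELINE_DAYS[period], None, 1.0)] + [
                (POST_DAYS[period][v], v, np.where(trt == "TB", mult, 1.0)) for v in (1, 2)
            ]
            for day, visit, m in day_plan:
                if (subj, day) in drop:
                    continue
                eps = rng.normal(0.0, sigma_visit, len(outcomes))
                vals = base.iloc[i].to_numpy() * m * np.exp(u[i]) * np.exp(eps)
                for (cls, lipid), v in zip(outcomes, vals):
                    rows.append((subj, day, period, trt if visit else "baseline",
                                 visit, cls, lipid, v))

    rec = pd.DataFrame(
        rows, columns=["subject", "day", "period", "treatment", "visit",
                       "class", "lipid", "value_mgdl"],
    ).merge(meta.drop(columns=["sequence"]), on="subject")
    return CrossoverDataset(rec, meta, effect_map,
                            pd.Series(u, index=subjects, name="u"), seed)
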