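"""Crossover treatment-effect analysis.

For each (lipoprotein class, lipid) outcome, post-treatment
observations are analyzed with a linear mixed model

    y ~ treatment + baseline + gender + age + BMI + visit,
    random intercept per subject (REML)

where "baseline" is the subject's same-period pre-treatment value
entered as a continuous covariate (ANCOVA reading of baseline
correction). Least-squares means per arm are model predictions at the
mean of the continuous covariates and balanced margins of the
categorical factors; the treatment effect is reported as the percent
difference of LSMeans, active vs placebo, with a Wald p-value. With
only two arms the Dunnett-Hsu multiplicity adjustment is the identity;
the adjust step is kept as an explicit labeled pass-through.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "EffectEstimate",
    "build_design",
    "fit_mixed_model",
    "percent_difference",
    "adjust_posthoc",
    "analyze_study",
]


@dataclass
class EffectEstimate:
    """Treatment contrast for one lipid-in-class outcome."""

    lp_class: str
    lipid: str
    lsmean_placebo: float
    lsmean_tb: float
    se_placebo: float
    se_tb: float
    pct_diff: float
    p_value: float
    adjusted: bool = False
    method: str = "mixed"  # "mixed" or "subject-fixed" fallback


def build_design(records: pd.DataFrame,
                 excluded_subjects: set | None = None) -> pd.DataFrame:
    """One analysis row per post-treatment observation of one outcome.

    ``records`` is the long table of a single (class, lipid) outcome
    with columns subject, day, period, treatment, visit, gender, age,
    bmi and a value column. Baseline days (visit is NA) supply the
    same-period baseline covariate; subject-periods with no baseline
    are dropped with a warning, as are excluded subjects.
    """
    value_col = next(c for c in records.columns if c.startswith("value"))
    df = records.copy()
    excluded = set(excluded_subjects or ())
    if excluded:
        df = df[~df["subject"].isin(excluded)]

    base = df[df["visit"].isna()].set_index(["subject", "period"])[value_col]
    post = df[df["visit"].notna()].copy()
    key = pd.MultiIndex.from_frame(post[["subject", "period"]])
    post["baseline"] = base.reindex(key).to_numpy()
    missing = post["baseline"].isna()
    if missing.any():
        lost = post.loc[missing, ["subject", "period"]].drop_duplicates()
        warnings.warn(
            "dropping subject-periods without a baseline: "
            + ", ".join(f"{s}/P{p}" for s, p in lost.itertuples(index=False))
        )
        post = post[~missing]

    out = pd.DataFrame({
        "subject": post["subject"].to_numpy(),
        "period": post["period"].to_numpy(int),
        "value": post[value_col].to_numpy(float),
        "tb": (post["treatment"] == "TB").astype(float).to_numpy(),
        "baseline": post["baseline"].to_numpy(float),
        "male": (post["gender"] == "M").astype(float).to_numpy(),
        "age": post["age"].to_numpy(float),
        "bmi": post["bmi"].to_numpy(float),
        "visit2": (post["visit"] == 2).astype(float).to_numpy(),
    })
    return out.reset_index(drop=True)


_FIXED = ["tb", "baseline", "male", "age", "bmi", "visit2"]


def _lsmean_vectors(rows: pd.DataFrame, names: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Design rows for arm-wise LSMeans: continuous covariates at their
    observed means, categorical factors at balanced (0.5) margins."""
    base = {"const": 1.0, "baseline": rows["baseline"].mean(),
            "male": 0.5, "age": rows["age"].mean(),
            "bmi": rows["bmi"].mean(), "visit2": 0.5}
    v_placebo = np.array([base.get(n, 0.0) if n != "tb" else 0.0 for n in names])
    v_tb = np.array([base.get(n, 0.0) if n != "tb" else 1.0 for n in names])
    return v_placebo, v_tb


def fit_mixed_model(rows: pd.DataFrame, lp_class: str = "", lipid: str = "") -> EffectEstimate:
    """Random-intercept mixed model for one outcome; LSMeans contrast.

    Falls back to a subject-fixed-effects least-squares fit (with a
    warning) when the REML fit fails or does not converge.
    """
    if rows.groupby("tb")["subject"].nunique().min() < 2:
        raise ValueError("need at least 2 subjects per treatment arm")
    # Drop constant covariates (e.g. single-gender designs) to keep X full rank.
    fixed = [c for c in _FIXED if rows[c].nunique() > 1 or c == "tb"]
    names = ["const"] + fixed
    y = rows["value"].to_numpy(float)

    method = "mixed"
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            # subject random intercept plus a subject-period variance
            # component: the two visits of a period share their baseline
            # measurement, so period-level correlation must be absorbed
            # for calibrated treatment SEs
            vc = {"period": "0 + C(period)"} if "period" in rows.columns else None
            mod = sm.MixedLM.from_formula(
                "value ~ " + " + ".join(fixed), groups="subject",
                re_formula="1", vc_formula=vc, data=rows,
            )
            res = mod.fit(reml=True)
        if not np.all(np.isfinite(np.asarray(res.bse_fe))):
            raise ValueError("singular mixed fit")
        order = [list(res.fe_params.index).index(n if n != "const" else "Intercept")
                 for n in names]
        params = np.asarray(res.fe_params)[order]
        cov = np.asarray(res.cov_params())[np.ix_(order, order)]
        p_tb = float(np.asarray(res.pvalues)[order[names.index("tb")]])
    except Exception:
        warnings.warn("mixed model failed; falling back to subject fixed effects")
        method = "subject-fixed"
        dummies = pd.get_dummies(rows["subject"], drop_first=True, dtype=float)
        # Between-subject covariates are collinear with subject dummies.
        within = [c for c in fixed if c in ("tb", "baseline", "visit2")]
        Xf = sm.add_constant(pd.concat([rows[within], dummies], axis=1), has_constant="add")
        ols = sm.OLS(y, Xf.to_numpy(float)).fit()
        names = list(Xf.columns)
        params = np.asarray(ols.params)
        cov = np.asarray(ols.cov_params())
        p_tb = float(np.asarray(ols.pvalues)[names.index("tb")])

    v0, v1 = _lsmean_vectors(rows, names)
    ls0, ls1 = float(v0 @ params[: len(names)]), float(v1 @ params[: len(names)])
    se0 = float(np.sqrt(v0 @ cov @ v0))
    se1 = float(np.sqrt(v1 @ cov @ v1))
    return EffectEstimate(
        lp_class=lp_class, lipid=lipid,
        lsmean_placebo=ls0, lsmean_tb=ls1, se_placebo=se0, se_tb=se1,
        pct_diff=percent_difference(ls0, ls1), p_value=p_tb, method=method,
    )


def percent_difference(lsmean_placebo: float, lsmean_tb: float) -> float:
    """100 * (TB - placebo) / placebo, reported to two decimals."""
    if lsmean_placebo <= 0:
        raise ValueError("placebo LSMean must be positive")
    return round(100.0 * (lsmean_tb - lsmean_placebo) / lsmean_placebo, 2)


def adjust_posthoc(estimates: list[EffectEstimate], n_arms: int = 2) -> list[EffectEstimate]:
    """Dunnett-Hsu-style multiplicity adjustment vs control.

    With exactly two treatment levels the adjustment is the identity
    (the degenerate Dunnett case); for more arms a conservative
    Sidak-type bound over the k = n_arms - 1 comparisons is applied.
    """
    k = n_arms - 1
    out = []
    for e in estimates:
        p = e.p_value if k <= 1 else float(1.0 - (1.0 - e.p_value) ** k)
        out.append(EffectEstimate(
            e.lp_class, e.lipid, e.lsmean_placebo, e.lsmean_tb,
            e.se_placebo, e.se_tb, e.pct_diff, min(p, 1.0),
            adjusted=True, method=e.method,
        ))
    return out


def analyze_study(records: pd.DataFrame, excluded_subjects: set | None = None,
                  outcomes: list[tuple[str, str]] | None = None) -> pd.DataFrame:
    """Fit the mixed model for every (class, lipid) outcome in a study
    table and return a report shaped like the trial's effect tables."""
    pairs = outcomes or [tuple(p) for p in
                         records[["class", "lipid"]].drop_duplicates().itertuples(index=False)]
    rows = []
    for cls, lipid in pairs:
        sub = records[(records["class"] == cls) & (records["lipid"] == lipid)]
        design = build_design(sub, excluded_subjects)
        est = adjust_posthoc([fit_mixed_model(design, cls, lipid)])[0]
        rows.append({
            "class": cls, "lipid": lipid,
            "lsmean_placebo": est.lsmean_placebo, "lsmean_tb": est.lsmean_tb,
            "se_placebo": est.se_placebo, "se_tb": est.se_tb,
            "pct_diff": est.pct_diff, "p_value": est.p_value, "method": est.method,
        })
    return pd.DataFrame(rows)
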