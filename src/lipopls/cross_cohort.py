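"""Cross-cohort application of a calibration model set and bias
diagnosis.

A PLS calibration trained on one cohort encodes that cohort's
lipoprotein phenotype; applying it to spectra from a cohort with a
different phenotype (e.g. chylomicron-containing spectra fed to a
chylomicron-naive model) produces systematic over- or under-estimation
even when correlations stay high. This module quantifies that bias per
(class, lipid): mean signed error, the slope/intercept of the
predicted-vs-observed line, and the fraction of predictions outside
the foreign model's training concentration range.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .chemometrics import PlsModel, predict_panel
from .concentrations import ConcentrationTable
from .spectra import Spectrum

__all__ = ["cross_predict", "bias_report", "plot_bias"]


def cross_predict(models: dict[tuple[str, str], PlsModel],
                  spectra: list[Spectrum]) -> pd.DataFrame:
    """Predict concentrations of foreign spectra with a model set.

    Thin wrapper over :func:`predict_panel`; kept separate to make the
    cross-cohort intent explicit and to host axis validation.
    """
    if not spectra:
        raise ValueError("no spectra supplied")
    return predict_panel(models, spectra)


def bias_report(pred: pd.DataFrame, obs: ConcentrationTable) -> pd.DataFrame:
    """Per-(class, lipid) systematic-error summary on the mg/dL scale.

    ``pred`` is tidy output of :func:`cross_predict`; ``obs`` the
    matched reference table. Columns: mean signed error (pred - obs),
    its SE, slope and intercept of the least-squares pred-vs-obs line,
    Pearson r, and the out-of-range fraction.
    """
    if obs.units != "mg/dL":
        raise ValueError("observations must be in mg/dL")
    rows = []
    for (cls, lipid), grp in pred.groupby(["class", "lipid"], sort=False):
        if (cls, lipid) not in obs.data.columns:
            continue
        grp = grp.set_index("sample_id").loc[obs.sample_ids]
        y_obs = obs.column(cls, lipid)
        y_pred = grp["value"].to_numpy(float)
        n = len(y_obs)
        if n < 3:
            raise ValueError("need at least 3 matched samples")
        err = y_pred - y_obs
        if np.std(y_obs) > 0:
            slope, intercept = np.polyfit(y_obs, y_pred, 1)
            r = float(np.corrcoef(y_obs, y_pred)[0, 1]) if np.std(y_pred) > 0 else np.nan
        else:
            slope, intercept, r = np.nan, np.nan, np.nan
        rows.append({
            "class": cls, "lipid": lipid, "n": n,
            "mean_signed_error_mgdl": float(err.mean()),
            "se_signed_error": float(err.std(ddof=1) / np.sqrt(n)),
            "slope": float(slope), "intercept": float(intercept), "pearson_r": r,
            "frac_out_of_range": float(grp["out_of_range"].mean()),
        })
    return pd.DataFrame(rows)


def plot_bias(pred: pd.DataFrame, obs: ConcentrationTable, path: str | Path,
              classes: list[tuple[str, str]] | None = None) -> None:
    """Predicted-vs-observed panels with the identity line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pairs = classes or [tuple(p) for p in
                        pred[["class", "lipid"]].drop_duplicates().itertuples(index=False)]
    pairs = [p for p in pairs if p in obs.data.columns][:12]
    ncol = 4
    nrow = int(np.ceil(len(pairs) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(3.2 * ncol, 3.0 * nrow), squeeze=False)
    for ax, (cls, lipid) in zip(axes.ravel(), pairs):
        grp = pred[(pred["class"] == cls) & (pred["lipid"] == lipid)]
        grp = grp.set_index("sample_id").loc[obs.sample_ids]
        y_obs = obs.column(cls, lipid)
        ax.scatter(y_obs, grp["value"], s=8, alpha=0.7)
        lim = [0, max(float(y_obs.max()), float(grp["value"].max())) * 1.05]
        ax.plot(lim, lim, color="green", lw=1)
        ax.set_title(f"{cls}-{lipid}", fontsize=9)
        ax.set_xlabel("observed (mg/dL)", fontsize=8)
        ax.set_ylabel("predicted (mg/dL)", fontsize=8)
    for ax in axes.ravel()[len(pairs):]:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
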