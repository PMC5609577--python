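"""Forward model: diffusion-edited-like serum lipid spectra.

Each lipoprotein subclass contributes two Lorentzian resonances inside
the 0.6-1.4 ppm lipid region — a terminal-methyl line and a chain-
methylene line — whose chemical shifts increase with particle diameter
(larger, more fluid particles resonate downfield). Peak areas are linear
in the TG and CH concentrations of the subclass. Cholesterol signal is
concentrated in the methyl line (85/15 split) while TG splits 40/60
toward methylene; this is what makes the methyl-only window informative
for CH and the full window necessary for TG.

Concentrations are drawn per phenotype preset from log-normal marginals
(mean/CV parameterisation) coupled by a Gaussian copula with positive
within-category correlation. A synthetic alanine doublet at 1.49 ppm is
added outside the lipid windows so peak alignment can be exercised.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .concentrations import ConcentrationTable, sum_category
from .registry import LpCategory, subclass_registry
from .spectra import PpmAxis, Spectrum, default_axis

__all__ = [
    "SubclassSignalModel",
    "PhenotypePreset",
    "SyntheticCohort",
    "load_preset",
    "default_signal_model",
    "render_spectrum",
    "simulate_cohort",
]

# Free constants of the forward model (config, not claims).
METHYL_BASE, METHYL_SLOPE = 0.70, 0.055      # ppm; center = base + slope*ln(d/9.8)
METHYLENE_BASE, METHYLENE_SLOPE = 1.18, 0.040
LINEWIDTH_HWHM = 0.012                       # ppm, Lorentzian half width at half max
SPECIES_SPLIT = {"CH": (0.85, 0.15), "TG": (0.40, 0.60)}  # (methyl, methylene) area fractions
RESPONSE = {"CH": 1.0, "TG": 1.0}            # integrated area per mg/dL
ALANINE_PPM = (1.49, 1.478)                  # doublet, left line is the alignment reference
ALANINE_HWHM = 0.004
DEFAULT_NOISE_SD = 2.0


@dataclass(frozen=True)
class SubclassSignalModel:
    """Per-subclass resonance positions and responses."""

    methyl_center: dict[str, float]
    methylene_center: dict[str, float]
    linewidth: float = LINEWIDTH_HWHM
    split: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(SPECIES_SPLIT))
    response: dict[str, float] = field(default_factory=lambda: dict(RESPONSE))
    alanine_area: float = 5.0


def default_signal_model() -> SubclassSignalModel:
    methyl, methylene = {}, {}
    for c in subclass_registry():
        if c.is_total:
            continue
        r = math.log(c.diameter_nm / 9.8)
        methyl[c.name] = METHYL_BASE + METHYL_SLOPE * r
        methylene[c.name] = METHYLENE_BASE + METHYLENE_SLOPE * r
    return SubclassSignalModel(methyl, methylene)


def _lorentzian(x: np.ndarray, center: float, hwhm: float) -> np.ndarray:
    """Unit-area Lorentzian line."""
    return (hwhm / math.pi) / ((x - center) ** 2 + hwhm**2)


def lorentzian_area(center: float, hwhm: float, lo: float, hi: float) -> float:
    """Closed-form area of the unit Lorentzian on [lo, hi]."""
    return (math.atan((hi - center) / hwhm) - math.atan((lo - center) / hwhm)) / math.pi


def continuous_intensity(model: SubclassSignalModel, ppm: np.ndarray,
                         conc_row: pd.Series, alanine: bool = True) -> np.ndarray:
    """Noise-free signal evaluated at arbitrary ppm positions.

    ``conc_row`` is indexed by (class, lipid) in mg/dL; totals are
    ignored (they are sums, not independent emitters).
    """
    ppm = np.asarray(ppm, float)
    out = np.zeros_like(ppm)
    for (cls, lipid), conc in conc_row.items():
        if cls not in model.methyl_center:
            continue
        if conc < 0:
            raise ValueError(f"negative concentration for {cls}-{lipid}")
        f_me, f_ch2 = model.split[lipid]
        area = model.response[lipid] * float(conc)
        out += area * f_me * _lorentzian(ppm, model.methyl_center[cls], model.linewidth)
        out += area * f_ch2 * _lorentzian(ppm, model.methylene_center[cls], model.linewidth)
    if alanine and model.alanine_area > 0:
        for c in ALANINE_PPM:
            out += model.alanine_area * 0.5 * _lorentzian(ppm, c, ALANINE_HWHM)
    return out


def render_spectrum(conc_row: pd.Series, signal_model: SubclassSignalModel | None = None,
                    noise_sd: float = DEFAULT_NOISE_SD, baseline: float = 0.0,
                    seed: int | np.random.Generator = 0,
                    axis: PpmAxis | None = None, sample_id: str = "synthetic") -> Spectrum:
    """Render one spectrum: superposed Lorentzians + baseline + iid noise."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    model = signal_model or default_signal_model()
    axis = axis or default_axis()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    signal = continuous_intensity(model, axis.values, conc_row)
    noise = rng.normal(0.0, noise_sd, size=len(axis)) if noise_sd > 0 else 0.0
    return Spectrum(sample_id, axis, signal + baseline + noise)


@dataclass(frozen=True)
class PhenotypePreset:
    """Per-(subclass, lipid) log-normal concentration targets."""

    name: str
    means: pd.Series          # (class, lipid) -> mean mg/dL
    cvs: pd.Series            # (class, lipid) -> coefficient of variation
    within_category_corr: float = 0.5


def load_preset(name: str) -> PhenotypePreset:
    """Load a phenotype preset from the packaged config file."""
    raw = yaml.safe_load(
        importlib.resources.files("lipopls").joinpath("presets.yaml").read_text()
    )
    if name not in raw:
        raise ValueError(f"unknown preset {name!r}; available: {sorted(raw)}")
    spec = raw[name]
    idx, means, cvs = [], [], []
    for cls, lipids in spec["classes"].items():
        for lipid, p in lipids.items():
            idx.append((cls, lipid))
            means.append(float(p["mean"]))
            cvs.append(float(p["cv"]))
    mi = pd.MultiIndex.from_tuples(idx, names=["class", "lipid"])
    return PhenotypePreset(name, pd.Series(means, index=mi), pd.Series(cvs, index=mi),
                           float(spec.get("correlation_within_category", 0.5)))


@dataclass
class SyntheticCohort:
    """Paired spectra + ground-truth concentrations + subject metadata."""

    spectra: list[Spectrum]
    truth: ConcentrationTable  # mg/dL, subclasses + category totals
    subjects: pd.DataFrame     # sample_id, gender, age, bmi
    seed: int
    preset_name: str


def _draw_concentrations(preset: PhenotypePreset, n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Log-normal marginals with a within-category Gaussian copula."""
    cols = preset.means.index
    z = np.empty((n, len(cols)))
    by_cat: dict[str, list[int]] = {}
    for j, (cls, _) in enumerate(cols):
        cat = next(c.category.value for c in subclass_registry() if c.name == cls)
        by_cat.setdefault(cat, []).append(j)
    rho = preset.within_category_corr
    for cat, js in by_cat.items():
        k = len(js)
        cov = np.full((k, k), rho) + (1 - rho) * np.eye(k)
        z[:, js] = rng.multivariate_normal(np.zeros(k), cov, size=n, method="cholesky")
    sigma = np.sqrt(np.log1p(preset.cvs.to_numpy() ** 2))
    mu = np.log(preset.means.to_numpy()) - sigma**2 / 2
    vals = np.exp(mu + sigma * z)
    return pd.DataFrame(vals, columns=cols)


def simulate_cohort(preset: PhenotypePreset | str, n: int, seed: int,
                    noise_sd: float = DEFAULT_NOISE_SD,
                    signal_model: SubclassSignalModel | None = None,
                    axis: PpmAxis | None = None) -> SyntheticCohort:
    """Generate ``n`` paired (spectrum, reference-concentration) samples.

    Same seed -> bit-identical output. Category totals in the truth
    table are exact sums of their member subclasses.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if isinstance(preset, str):
        preset = load_preset(preset)
    rng = np.random.default_rng(seed)
    axis = axis or default_axis()
    model = signal_model or default_signal_model()

    conc = _draw_concentrations(preset, n, rng)
    ids = [f"{preset.name}-{i:04d}" for i in range(n)]
    conc.index = pd.Index(ids, name="sample_id")
    truth = ConcentrationTable(conc, units="mg/dL")

    totals = {}
    for cat in LpCategory:
        tot = sum_category(truth, cat)
        for lipid in tot.columns:
            totals[(f"{cat.value}_tot", lipid)] = tot[lipid]
    full = pd.concat([conc, pd.DataFrame(totals, index=conc.index)], axis=1)
    full.columns = pd.MultiIndex.from_tuples(full.columns, names=["class", "lipid"])
    truth = ConcentrationTable(full, units="mg/dL")

    spectra = [
        render_spectrum(conc.iloc[i], model, noise_sd=noise_sd, baseline=0.0,
                        seed=rng, axis=axis, sample_id=ids[i])
        for i in range(n)
    ]

    subjects = pd.DataFrame(
        {
            "sample_id": ids,
            "gender": np.where(rng.random(n) < 0.6, "M", "F"),
            "age": np.clip(rng.normal(60.0, 6.0, n), 40, 80).round(1),
            "bmi": np.clip(rng.normal(29.0, 3.0, n), 20, 40).round(1),
        }
    )
    return SyntheticCohort(spectra, truth, subjects, seed=seed, preset_name=preset.name)
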