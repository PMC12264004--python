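"""Guanylyl-cyclase enzymology computations.

Covers the downstream quantification math of the cyclase activity assay:
nucleotide concentrations from HPLC peak areas (standard curve or
area-ratio mode), turnover slopes from short time courses, Hill-equation
fits of substrate-saturation data, fluorescence-based normalization of
activities across constructs, and a seeded synthetic-data generator.

The Hill model is ``v(S) = Vmax * S**h / (K_M**h + S**h)`` with ``h`` the
cooperativity and ``K_M`` the half-saturation substrate concentration;
``fix_h=1`` reduces it to Michaelis-Menten.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

#: cGMP standard-curve concentrations in mM
STANDARD_CONCENTRATIONS_MM = (0.05, 0.1, 0.2, 0.5, 1.0, 2.0, 5.0)


def hill(S, vmax: float, km: float, h: float = 1.0):
    """Hill equation v(S)."""
    S = np.asarray(S, dtype=float)
    return vmax * S**h / (km**h + S**h)


@dataclass
class StandardCurve:
    """Linear detector calibration: peak area vs known concentration."""

    concentrations: np.ndarray
    areas: np.ndarray
    slope: float = field(init=False)
    intercept: float = field(init=False)
    r_squared: float = field(init=False)

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        a = np.asarray(self.areas, dtype=float)
        if len(c) < 2 or np.any(np.diff(c) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        res = stats.linregress(c, a)
        self.slope = float(res.slope)
        self.intercept = float(res.intercept)
        self.r_squared = float(res.rvalue**2)
        self.concentrations = c
        self.areas = a


def quantify_nucleotide(peak_area: float,
                        curve: StandardCurve | None = None,
                        mode: str = "standard_curve",
                        total_area: float | None = None,
                        total_nucleotide_mm: float | None = None
                        ) -> tuple[float, bool]:
    """Nucleotide concentration (mM) from a chromatogram peak area.

    ``standard_curve`` mode inverts the fitted linear calibration;
    ``area_ratio`` mode multiplies the fraction of total nucleotide area
    by the known total nucleotide concentration.  Returns (concentration,
    flagged); concentrations that invert to below zero are clipped to 0
    and flagged.
    """
    if mode == "standard_curve":
        if curve is None:
            raise ValueError("standard_curve mode requires a fitted curve")
        conc = (peak_area - curve.intercept) / curve.slope
    elif mode == "area_ratio":
        if total_area is None or total_area <= 0:
            raise ValueError("area_ratio mode requires total_area > 0")
        if total_nucleotide_mm is None:
            raise ValueError("area_ratio mode requires total_nucleotide_mm")
        conc = peak_area / total_area * total_nucleotide_mm
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if conc < 0:
        return 0.0, True
    return float(conc), False


def linear_turnover(timepoints, concentrations) -> tuple[float, float]:
    """Turnover per minute: OLS slope of mean product vs time.

    ``concentrations`` may be a 1D array (one value per timepoint) or 2D
    (timepoints x replicates); replicate means are fit.  Returns
    (slope mM/min, standard error).  Short time courses inside the
    enzyme's linear range (2-3 points) are the intended use.
    """
    t = np.asarray(timepoints, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    if c.ndim == 2:
        c = c.mean(axis=1)
    if len(t) < 2:
        raise ValueError("need at least two timepoints (or a t=0 anchor)")
    res = stats.linregress(t, c)
    stderr = float(res.stderr) if len(t) > 2 else float("nan")
    return float(res.slope), stderr


@dataclass
class KineticsDataset:
    """Substrate-saturation observations: S (mM) vs measured rate v."""

    data: pd.DataFrame  # columns: condition, S_mM, replicate, v

    def __post_init__(self) -> None:
        if np.any(self.data["S_mM"].to_numpy() < 0):
            raise ValueError("substrate concentrations must be non-negative")
        if self.data["S_mM"].nunique() < 3:
            raise ValueError("need at least 3 substrate levels for fitting")


@dataclass
class HillFit:
    """Fitted Hill parameters with asymptotic standard errors."""

    vmax: float
    km: float
    h: float
    vmax_se: float
    km_se: float
    h_se: float
    fixed_h: bool = False

    def predict(self, S):
        return hill(S, self.vmax, self.km, self.h)


def fit_hill(dataset: KineticsDataset | pd.DataFrame,
             fix_h: float | None = None,
             weighting: str | None = None) -> HillFit:
    """Nonlinear least-squares Hill fit of substrate-saturation data.

    Initialization: Vmax0 = max(v), K_M0 = S at half-max, h0 = 1.
    Unweighted least squares by default (matching the usual
    plotting-software default); ``weighting="relative"`` scales
    residuals by the measured rates, the efficient choice when the
    measurement error is a constant coefficient of variation.
    ``fix_h=1`` gives a Michaelis-Menten fit.
    """
    df = dataset.data if isinstance(dataset, KineticsDataset) else dataset
    S = df["S_mM"].to_numpy(dtype=float)
    v = df["v"].to_numpy(dtype=float)
    if np.all(v == 0):
        raise ValueError("all rates are zero; nothing to fit")
    if weighting is None:
        sigma = None
    elif weighting == "relative":
        sigma = np.maximum(np.abs(v), 1e-12 * np.max(np.abs(v)))
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    vmax0 = float(np.max(v))
    km0 = float(S[np.argmin(np.abs(v - vmax0 / 2.0))])
    km0 = max(km0, 1e-6)
    if fix_h is None:
        p0 = [vmax0, km0, 1.0]
        popt, pcov = optimize.curve_fit(
            hill, S, v, p0=p0, sigma=sigma, maxfev=20_000,
            bounds=([0, 1e-9, 1e-3], [np.inf, np.inf, 20.0]))
        se = np.sqrt(np.diag(pcov))
        return HillFit(vmax=popt[0], km=popt[1], h=popt[2],
                       vmax_se=se[0], km_se=se[1], h_se=se[2])
    h = float(fix_h)
    popt, pcov = optimize.curve_fit(
        lambda s, vmax, km: hill(s, vmax, km, h), S, v,
        p0=[vmax0, km0], sigma=sigma, maxfev=20_000,
        bounds=([0, 1e-9], [np.inf, np.inf]))
    se = np.sqrt(np.diag(pcov))
    return HillFit(vmax=popt[0], km=popt[1], h=h,
                   vmax_se=se[0], km_se=se[1], h_se=0.0, fixed_h=True)


def normalize_by_fluorescence(activities, fluorescence,
                              reference: float | None = None) -> np.ndarray:
    """Scale activities by intrinsic NeoR fluorescence.

    Each activity is multiplied by ``reference / fluorescence_i`` so that
    samples expressing more photoreceptor are not over-counted; the
    reference defaults to the first sample's fluorescence.
    """
    act = np.asarray(activities, dtype=float)
    fl = np.asarray(fluorescence, dtype=float)
    if np.any(fl <= 0):
        raise ValueError("fluorescence readouts must be positive")
    ref = fl[0] if reference is None else float(reference)
    return act * (ref / fl)


def generate_kinetics(truth: HillFit, S_grid=None, noise_cv: float = 0.05,
                      n_reps: int = 3,
                      seed: int | np.random.Generator | None = 0,
                      condition: str = "synthetic") -> KineticsDataset:
    """Synthetic saturation data: truth model with multiplicative noise.

    ``v = v_model * (1 + N(0, noise_cv))`` per replicate.  The default
    substrate grid is the printed cGMP standard-curve concentration set
    (0.05-5 mM).
    """
    rng = np.random.default_rng(seed)
    if S_grid is None:
        S_grid = np.asarray(STANDARD_CONCENTRATIONS_MM)
    S_grid = np.asarray(S_grid, dtype=float)
    rows = []
    for S in S_grid:
        v_true = float(hill(S, truth.vmax, truth.km, truth.h))
        for rep in range(n_reps):
            noise = rng.normal(0.0, noise_cv) if noise_cv > 0 else 0.0
            rows.append((condition, S, rep, v_true * (1.0 + noise)))
    return KineticsDataset(pd.DataFrame(
        rows, columns=["condition", "S_mM", "replicate", "v"]))


def make_truth(vmax: float, km: float, h: float = 1.0) -> HillFit:
    """Convenience constructor for a ground-truth parameter set."""
    if vmax <= 0 or km <= 0 or h <= 0:
        raise ValueError("Vmax, K_M and h must be positive")
    return HillFit(vmax=vmax, km=km, h=h, vmax_se=0.0, km_se=0.0, h_se=0.0)


def saturation_grid(km: float, n: int = 7, lo: float = 0.1,
                    hi: float = 4.0) -> np.ndarray:
    """Log-spaced substrate grid spanning ``lo``–``hi`` times K_M."""
    return np.geomspace(lo * km, hi * km, n)


#: Hill parameters of the guanylyl-cyclase constructs used as synthetic
#: ground truth.  Vmax in umol/min/mg for the purified soluble domains
#: (RGC1-cat and its mixtures); for crude-membrane assays only K_M is
#: meaningful and Vmax is in arbitrary units.
CONSTRUCT_PARAMETERS = {
    "NeoR/RGC1": make_truth(vmax=1.0, km=0.55),
    "CaRGC": make_truth(vmax=1.0, km=0.47),
    "RGC1-cat": make_truth(vmax=0.96, km=5.53),
    "RGC1-cat+NeoR-cat": make_truth(vmax=0.49, km=1.54),
    "RGC2-cat+NeoR-cat": make_truth(vmax=0.49, km=0.98),
}
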