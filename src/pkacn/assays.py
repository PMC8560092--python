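"""Quantitative analysis of the non-ODE assays.

Covers the ³²P phosphatase release assay arithmetic and Michaelis–Menten
fitting, quantitative immunoblot reference curves (Hill fits) with molar
conversion of extract percentages, the AKAR4-rate → free-C calibration,
and simple fold-change reporting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import pearsonr

from .synth import ReleaseRecord

__all__ = [
    "ReleaseRecord",
    "MMFit",
    "ReferenceCurve",
    "CCalibration",
    "FoldChange",
    "fraction_released",
    "cn_activity",
    "fit_michaelis_menten",
    "fit_linear_activity",
    "fit_reference_curve",
    "quantify_extract",
    "percent_to_molar",
    "molar_ratio",
    "build_c_calibration",
    "estimate_free_c",
    "fold_change",
]

# initial-rate regime: < 10% of substrate dephosphorylated per assay
RELEASE_REGIME_LIMIT = 0.10
# CN activity below this (s⁻¹) at ≤ 5 µM substrate indicates low-affinity kinetics
LOW_ACTIVITY_CUTOFF = 0.03

# molar-conversion defaults; masses are sequence molar masses of the human
# PKA subunits used for the reference standards
TISSUE_DENSITY_G_PER_L = 1040.0
PROTEIN_CONTENT_FRACTION = 0.08
MOLAR_MASS_DA = {"RIIalpha": 45518.0, "RIIbeta": 46303.0, "C": 40623.0,
                 "RIalpha": 42982.0}


def fraction_released(record: ReleaseRecord) -> float:
    """Fraction of ³²P in the supernatant: cpm_sup / (cpm_sup + cpm_pellet)."""
    total = record.cpm_supernatant + record.cpm_pellet
    if total <= 0:
        raise ValueError("zero total counts")
    return record.cpm_supernatant / total


@dataclass
class Activity:
    turnover_per_s: float
    regime_ok: bool  # False when > 10% of substrate was consumed

    def __float__(self) -> float:
        return self.turnover_per_s


def cn_activity(record: ReleaseRecord) -> Activity:
    """Per-enzyme turnover from one release record.

    activity = fraction × [S] / ([E] × t).  The result is flagged when the
    released fraction exceeds the 10% initial-rate regime.
    """
    frac = fraction_released(record)
    ok = frac < RELEASE_REGIME_LIMIT
    if not ok:
        warnings.warn(
            f"released fraction {frac:.3f} outside the initial-rate regime",
            RuntimeWarning,
        )
    act = frac * record.substrate_conc / (record.enzyme_conc * record.reaction_time)
    return Activity(act, ok)


@dataclass
class MMFit:
    K_m: float           # µM
    k_cat: float         # s⁻¹
    K_m_se: float
    k_cat_se: float
    residual_norm: float

    def velocity(self, S) -> np.ndarray:
        S = np.asarray(S, dtype=float)
        return self.k_cat * S / (self.K_m + S)


def fit_michaelis_menten(S, v) -> MMFit:
    """Nonlinear least-squares fit of v = k_cat·S/(K_m + S).

    ``v`` is per-enzyme turnover (s⁻¹).  Points are weighted equally;
    standard errors come from the fit covariance.
    """
    S = np.asarray(S, dtype=float)
    v = np.asarray(v, dtype=float)
    if np.unique(S).size < 4:
        raise ValueError("need at least 4 distinct substrate concentrations")

    def mm(s, km, kcat):
        return kcat * s / (km + s)

    p0 = (np.median(S), float(np.max(v)))
    popt, pcov = curve_fit(mm, S, v, p0=p0, maxfev=20000)
    km, kcat = popt
    if km <= 0 or kcat <= 0:
        raise ValueError(f"non-physical estimates: K_m={km:.3g}, k_cat={kcat:.3g}")
    se = np.sqrt(np.diag(pcov))
    resid = v - mm(S, *popt)
    return MMFit(float(km), float(kcat), float(se[0]), float(se[1]),
                 float(np.linalg.norm(resid)))


@dataclass
class LinearActivityFit:
    slope: float                 # k_cat/K_m composite, µM⁻¹ s⁻¹
    low_activity: bool           # all activities < 0.03 s⁻¹ at S ≤ 5 µM
    km_lower_bound: float | None # µM, reported when the relation stays linear
    residual_norm: float


def fit_linear_activity(S, v) -> LinearActivityFit:
    """Through-origin linear fit for low-affinity (K_m ≫ range) kinetics.

    The slope estimates the composite k_cat/K_m.  When the fit is good over
    the sampled range the data only bound K_m from below by the largest
    concentration tested.
    """
    S = np.asarray(S, dtype=float)
    v = np.asarray(v, dtype=float)
    if np.unique(S).size < 3:
        raise ValueError("need at least 3 substrate concentrations")
    denom = float(S @ S)
    slope = float(S @ v) / denom if denom > 0 else 0.0
    resid = v - slope * S
    low = bool(np.all(v[S <= 5.0] < LOW_ACTIVITY_CUTOFF)) if np.any(S <= 5.0) else False
    rel_resid = (np.linalg.norm(resid) / np.linalg.norm(v)
                 if np.linalg.norm(v) > 0 else 0.0)
    km_bound = float(S.max()) if rel_resid < 0.2 else None
    return LinearActivityFit(slope, low, km_bound, float(np.linalg.norm(resid)))


@dataclass
class ReferenceCurve:
    """Hill fit of band intensity vs loaded amount for one immunoblot."""

    Imax: float
    K: float
    h: float
    r_squared: float
    valid_range: tuple[float, float]  # loaded-amount range of the references

    def intensity(self, amount) -> np.ndarray:
        c = np.asarray(amount, dtype=float)
        return self.Imax * c ** self.h / (self.K ** self.h + c ** self.h)

    def invert(self, intensity: float) -> float:
        """Loaded amount giving ``intensity``; only within the fitted range."""
        if intensity == 0:
            return 0.0
        if intensity < 0 or intensity >= self.Imax:
            raise ValueError(f"intensity {intensity} outside invertible range")
        amount = self.K * (intensity / (self.Imax - intensity)) ** (1.0 / self.h)
        lo, hi = self.valid_range
        if amount > hi * (1 + 1e-9):
            raise ValueError(
                f"inverted amount {amount:.3g} above reference range {hi:.3g}; "
                "extrapolation refused"
            )
        if amount < lo:
            warnings.warn(
                f"inverted amount {amount:.3g} below lowest reference {lo:.3g}",
                RuntimeWarning,
            )
        return float(amount)


def fit_reference_curve(amounts, intensities) -> ReferenceCurve:
    """Iterative least-squares Hill fit I = Imax·c^h/(K^h + c^h)."""
    c = np.asarray(amounts, dtype=float)
    I = np.asarray(intensities, dtype=float)
    if c.size < 5:
        raise ValueError("need at least 5 reference points")
    order = np.argsort(c)
    if np.any(np.diff(I[order]) < -0.2 * np.max(np.abs(I))):
        warnings.warn("reference intensities are not monotone", RuntimeWarning)

    def hill(x, imax, K, h):
        return imax * x ** h / (K ** h + x ** h)

    p0 = (float(I.max()) * 1.2, float(np.median(c)), 1.0)
    popt, _ = curve_fit(
        hill, c, I, p0=p0,
        bounds=([1e-12, 1e-12, 0.1], [np.inf, np.inf, 10.0]),
        maxfev=40000,
    )
    pred = hill(c, *popt)
    ss_res = float(np.sum((I - pred) ** 2))
    ss_tot = float(np.sum((I - I.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return ReferenceCurve(float(popt[0]), float(popt[1]), float(popt[2]),
                          r2, (float(c.min()), float(c.max())))


def quantify_extract(
    curve: ReferenceCurve, band_intensity: float, loaded_protein_ug: float
) -> float:
    """Percent of total protein from an extract-lane intensity.

    Inverts the Hill reference curve (amounts in ng) and divides by the
    loaded total protein.
    """
    if loaded_protein_ug <= 0:
        raise ValueError("loaded protein must be positive")
    amount_ng = curve.invert(band_intensity)
    return 100.0 * amount_ng / (loaded_protein_ug * 1000.0)


def percent_to_molar(
    percent_total_protein: float,
    protein_content_fraction: float = PROTEIN_CONTENT_FRACTION,
    tissue_density_g_per_L: float = TISSUE_DENSITY_G_PER_L,
    molar_mass_Da: float = MOLAR_MASS_DA["RIIalpha"],
) -> float:
    """Tissue concentration (µM) of a protein measured as % of total protein.

    Assumes protein is 8% of tissue wet weight by default:
    c = (percent/100) × protein_fraction × density / molar mass.
    """
    if min(protein_content_fraction, tissue_density_g_per_L, molar_mass_Da) <= 0:
        raise ValueError("conversion factors must be positive")
    grams_per_L = (percent_total_protein / 100.0) * protein_content_fraction \
        * tissue_density_g_per_L
    return grams_per_L / molar_mass_Da * 1e6


def molar_ratio(
    percentA: float, massA: float, percentB: float, massB: float
) -> float:
    """Molar abundance ratio A:B from protein-mass percentages."""
    if min(percentA, massA, percentB, massB) <= 0:
        raise ValueError("inputs must be positive")
    return (percentA / massA) / (percentB / massB)


@dataclass
class CCalibration:
    """Linear-through-origin map between AKAR4 rate and free C concentration."""

    slope: float            # (%/min) per µM C
    r: float                # Pearson correlation over the linear range
    linear_bound: float     # µM; rates above slope×bound need the saturating fit
    max_rate: float         # largest calibrated rate (%/min)

    def rate(self, C) -> np.ndarray:
        return self.slope * np.asarray(C, dtype=float)

    def concentration(self, rate: float) -> float:
        if rate < 0:
            raise ValueError("negative rate")
        if rate > self.max_rate * 1.05:
            raise ValueError(
                f"rate {rate:.3g} above calibrated range ({self.max_rate:.3g})"
            )
        return rate / self.slope


def build_c_calibration(
    C_concs, rates, linear_bound: float = 0.4
) -> CCalibration:
    """Calibrate AKAR4 phosphorylation rate against C-subunit concentration.

    The relation is close to linear up to ~0.4 µM C; the through-origin
    slope is fitted on that range and the Pearson r reported for it.
    """
    C = np.asarray(C_concs, dtype=float)
    v = np.asarray(rates, dtype=float)
    if C.size < 3 or not np.any(C <= 0.1):
        raise ValueError("need >= 3 concentrations including one <= 0.1 µM")
    order = np.argsort(C)
    if np.any(np.diff(v[order]) < -0.05 * np.max(np.abs(v))):
        raise ValueError("rates are not monotone in C concentration")
    m = C <= linear_bound
    denom = float(C[m] @ C[m])
    if denom <= 0:
        raise ValueError("no points inside the linear range")
    slope = float(C[m] @ v[m]) / denom
    nz = m & (C > 0)
    r = float(pearsonr(C[nz], v[nz])[0]) if nz.sum() >= 3 else 1.0
    return CCalibration(slope, r, linear_bound, float(v.max()))


def estimate_free_c(
    cal: CCalibration, observed_rate: float, C_total: float
) -> tuple[float, float]:
    """Free C concentration and fraction from an observed AKAR4 rate."""
    if C_total <= 0:
        raise ValueError("C_total must be positive")
    free = cal.concentration(observed_rate)
    frac = free / C_total
    if frac > 1.05:
        warnings.warn(
            f"inverted free C exceeds C_total by {100 * (frac - 1):.1f}%",
            RuntimeWarning,
        )
    return free, float(np.clip(frac, 0.0, 1.0))


@dataclass(frozen=True)
class FoldChange:
    value: float   # full precision
    sig2: float    # rounded to 2 significant figures

    def __float__(self) -> float:
        return self.value


def fold_change(rate_ref: float, rate_test: float) -> FoldChange:
    """rate_ref / rate_test, reported at 2 significant figures."""
    if rate_test == 0:
        raise ZeroDivisionError("zero test rate")
    value = rate_ref / rate_test
    if value == 0:
        return FoldChange(0.0, 0.0)
    ndigits = 1 - int(np.floor(np.log10(abs(value))))
    return FoldChange(value, round(value, ndigits))
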