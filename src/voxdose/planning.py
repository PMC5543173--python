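"""Treatment-planning application of the voxel-based analysis.

Converts the significant subregion into a patient-specific avoidance
structure (back-warped through the inverse of the patient-to-CCS
registration) and into a mean-dose constraint: the first percentile of the
toxicity group's mean doses, estimated parametrically as
``mean + sd * probit(percentile)`` once a Kolmogorov-Smirnov test supports
Gaussianity. Plans are evaluated against the constraint via the region's
mean dose and cumulative DVH.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .fields import VelocityField, exp_velocity, warp_mask
from .grids import BinaryMask, ScalarVolume
from .vbstats import mean_dose

__all__ = [
    "ConstraintSpec",
    "DVHCurve",
    "ks_normality",
    "dose_constraint",
    "derive_constraint",
    "warp_region_to_patient",
    "cumulative_dvh",
    "evaluate_constraint",
]


@dataclass
class ConstraintSpec:
    """A mean-dose planning constraint on a region (in the CCS)."""

    region: BinaryMask
    bound: float  # Gy
    percentile: float = 0.01
    gaussianity_p: float | None = None  # KS p-value backing the parametric bound

    def __post_init__(self) -> None:
        if self.bound <= 0:
            raise ValueError("bound must be positive")
        if not 0 < self.percentile < 0.5:
            raise ValueError("percentile must lie in (0, 0.5)")


@dataclass
class DVHCurve:
    """Cumulative dose-volume histogram V(d) = volume fraction receiving >= d."""

    edges: np.ndarray  # Gy
    volume_fraction: np.ndarray
    structure: str = ""

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.volume_fraction = np.asarray(self.volume_fraction, dtype=float)
        if self.edges.shape != self.volume_fraction.shape:
            raise ValueError("edges and volume_fraction must align")

    def integral(self) -> float:
        """Riemann integral of V(d) over dose; equals the mean dose up to one
        bin width."""
        if self.edges.size < 2:
            return 0.0
        w = np.diff(self.edges)
        return float((self.volume_fraction[:-1] * w).sum())


def ks_normality(values) -> float:
    """One-sample KS p-value against a normal fitted to the sample.

    Parameters are estimated from the data (mean, sample sd) and the p-value
    comes from the asymptotic KS distribution, matching the plain test the
    constraint derivation gates on; with estimated parameters this is
    anti-conservative (a Lilliefors correction would reject more often).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        raise ValueError("KS normality test needs at least 4 values")
    sd = values.std(ddof=1)
    if sd == 0:
        raise ValueError("KS normality test undefined for zero variance")
    res = stats.kstest(values, "norm", args=(values.mean(), sd))
    return float(res.pvalue)


def dose_constraint(values, percentile: float = 0.01) -> float:
    """Parametric low-percentile bound on a sample of mean doses (Gy).

    Returns ``mean + sd * probit(percentile)`` with the sample (n-1) standard
    deviation. The caller supplies the toxicity-group values only; with the
    default percentile 0.01 this is the first percentile of the fitted
    normal, the dose below which the planner should push the region mean.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values")
    if not 0 < percentile < 1:
        raise ValueError("percentile must lie in (0, 1)")
    return float(values.mean() + values.std(ddof=1) * stats.norm.ppf(percentile))


def derive_constraint(
    region: BinaryMask,
    case_mean_doses,
    percentile: float = 0.01,
    gate_alpha: float = 0.05,
) -> ConstraintSpec:
    """Full constraint derivation with the Gaussianity gate.

    If the KS test against the fitted normal yields p > ``gate_alpha`` the
    parametric percentile is used; otherwise the empirical percentile is
    taken instead, with a warning.
    """
    case_mean_doses = np.asarray(case_mean_doses, dtype=float)
    p_ks = ks_normality(case_mean_doses)
    if p_ks > gate_alpha:
        bound = dose_constraint(case_mean_doses, percentile)
    else:
        warnings.warn(
            f"Gaussianity rejected (KS p = {p_ks:.3g}); "
            "falling back to the empirical percentile",
            RuntimeWarning,
        )
        bound = float(np.quantile(case_mean_doses, percentile))
    return ConstraintSpec(region=region, bound=bound, percentile=percentile,
                          gaussianity_p=p_ks)


def warp_region_to_patient(
    region: BinaryMask, field_patient_to_ccs: VelocityField
) -> BinaryMask:
    """Back-warp a CCS region into a patient's planning space.

    ``field_patient_to_ccs`` is the stationary velocity obtained by
    registering the patient to the CCS; the region is warped with its
    inverse exponential ``exp(-v)``, the deformation that maps the CCS into
    the patient scan.
    """
    warped = warp_mask(region, exp_velocity(-field_patient_to_ccs))
    if region.n_voxels > 0 and warped.n_voxels == 0:
        warnings.warn(
            "warped region is empty (outside the patient field of view?)",
            RuntimeWarning,
        )
    return warped


def cumulative_dvh(
    dose: ScalarVolume, region: BinaryMask, bin_width: float = 0.1
) -> DVHCurve:
    """Cumulative DVH of a structure at fixed dose-bin edges 0, w, 2w, ...

    The last edge is the first multiple of the bin width at or above the
    region's maximum dose, so V drops to 0 by construction only beyond it.
    """
    if region.n_voxels == 0:
        raise ValueError("DVH of an empty region is undefined")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    vals = dose.data[region.data]
    top = float(vals.max())
    n_edges = int(np.ceil(top / bin_width)) + 1
    edges = np.arange(n_edges + 1) * bin_width
    vf = (vals[None, :] >= edges[:, None]).mean(axis=1)
    return DVHCurve(edges, vf, structure=region.name)


def evaluate_constraint(
    dose: ScalarVolume, region: BinaryMask, spec: ConstraintSpec,
    dvh_bin_width: float = 0.1,
) -> dict:
    """Evaluate a plan's dose against a mean-dose constraint on a region."""
    dm = mean_dose(dose, region)
    dvh = cumulative_dvh(dose, region, dvh_bin_width)
    return {
        "mean_dose_gy": dm,
        "bound_gy": spec.bound,
        "passed": bool(dm <= spec.bound),
        "dvh": dvh,
    }
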