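"""Registration-quality scores and the paired test used to report improvement.

Dice, modified Hausdorff distance (Dubuisson-Jain, in mm) and dose-organ
overlap (DOO, a dose-weighted Dice) quantify how well two structure masks
agree before and after deformable registration; the Wilcoxon signed-rank test
gives the significance of the paired pre/post change across the cohort.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from scipy.stats import norm

from .grids import BinaryMask, ScalarVolume

__all__ = ["dice", "mhd", "doo", "wilcoxon_signed_rank", "score_table", "summarize_scores"]


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|)."""
    if not a.grid.same_as(b.grid):
        raise ValueError("masks must share a grid")
    na, nb = a.n_voxels, b.n_voxels
    if na + nb == 0:
        raise ValueError("Dice is undefined for two empty masks")
    inter = int((a.data & b.data).sum())
    return 2.0 * inter / (na + nb)


def _boundary_voxels(mask: BinaryMask) -> np.ndarray:
    """Physical coordinates (mm) of the 6-connectivity surface voxels."""
    struct = ndimage.generate_binary_structure(3, 1)
    interior = ndimage.binary_erosion(mask.data, structure=struct, border_value=0)
    surf = mask.data & ~interior
    idx = np.argwhere(surf)
    return idx * np.asarray(mask.grid.spacing) + np.asarray(mask.grid.origin)


def mhd(a: BinaryMask, b: BinaryMask) -> float:
    """Modified Hausdorff distance between mask boundaries, in mm.

    max of the two mean directed distances between boundary voxel sets.
    """
    if not a.grid.same_as(b.grid):
        raise ValueError("masks must share a grid")
    if a.n_voxels == 0 or b.n_voxels == 0:
        raise ValueError("MHD is undefined for an empty mask")
    pa = _boundary_voxels(a)
    pb = _boundary_voxels(b)
    d_ab = cKDTree(pb).query(pa, k=1)[0].mean()
    d_ba = cKDTree(pa).query(pb, k=1)[0].mean()
    return float(max(d_ab, d_ba))


def doo(a: BinaryMask, b: BinaryMask, dose: ScalarVolume) -> float:
    """Dose-organ overlap: Dice with voxels weighted by the local dose."""
    if not a.grid.same_as(b.grid) or not a.grid.same_as(dose.grid):
        raise ValueError("masks and dose must share a grid")
    if np.any(dose.data < 0):
        raise ValueError("dose must be non-negative")
    sa = float(dose.data[a.data].sum())
    sb = float(dose.data[b.data].sum())
    if sa + sb == 0:
        raise ValueError("DOO is undefined when no dose falls on either mask")
    inter = float(dose.data[a.data & b.data].sum())
    return 2.0 * inter / (sa + sb)


def wilcoxon_signed_rank(
    pre: np.ndarray, post: np.ndarray, alternative: str = "two-sided"
) -> float:
    """Wilcoxon signed-rank p-value for paired samples.

    Zero differences are dropped; tied |differences| get mid-ranks. For up to
    15 non-zero differences the null distribution of W+ is enumerated exactly
    over all sign patterns; beyond that a normal approximation with continuity
    and tie correction is used. If every difference is zero the test is
    degenerate and p = 1 is returned with a warning.

    ``alternative``: "two-sided", or "greater"/"less" for post vs pre.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ValueError("pre and post must be 1D arrays of equal length")
    d = post - pre
    d = d[d != 0]
    n = d.size
    if n == 0:
        warnings.warn("all paired differences are zero; Wilcoxon test degenerate", RuntimeWarning)
        return 1.0

    from scipy.stats import rankdata

    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    if n <= 15:
        # exact: enumerate all 2^n sign assignments of the ranked magnitudes
        signs = np.array(
            np.meshgrid(*([[0.0, 1.0]] * n), indexing="ij")
        ).reshape(n, -1)
        w_null = ranks @ signs  # (2^n,) distribution of W+
        total = w_null.size
        p_greater = float((w_null >= w_plus - 1e-9).sum()) / total
        p_less = float((w_null <= w_plus + 1e-9).sum()) / total
    else:
        mean = n * (n + 1) / 4.0
        # tie correction on the variance
        _, counts = np.unique(ranks, return_counts=True)
        tie_term = (counts**3 - counts).sum() / 48.0
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        if var <= 0:
            warnings.warn("Wilcoxon variance degenerate under ties", RuntimeWarning)
            return 1.0
        sd = np.sqrt(var)
        p_greater = float(norm.sf((w_plus - 0.5 - mean) / sd))
        p_less = float(norm.cdf((w_plus + 0.5 - mean) / sd))

    if alternative == "greater":
        return min(p_greater, 1.0)
    if alternative == "less":
        return min(p_less, 1.0)
    if alternative == "two-sided":
        return min(2.0 * min(p_greater, p_less), 1.0)
    raise ValueError(f"unknown alternative {alternative!r}")


# ---------------------------------------------------------------------------
# cohort score tables
# ---------------------------------------------------------------------------

def score_table(rows: list[dict]) -> pd.DataFrame:
    """Assemble per-patient, per-structure score rows into a DataFrame.

    Each row dict must carry: patient_id, structure, dice_pre, dice_post,
    mhd_pre, mhd_post, doo_pre, doo_post.
    """
    df = pd.DataFrame(rows)
    required = {
        "patient_id", "structure",
        "dice_pre", "dice_post", "mhd_pre", "mhd_post", "doo_pre", "doo_post",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"score rows missing columns: {sorted(missing)}")
    return df


def summarize_scores(df: pd.DataFrame) -> dict:
    """Cohort medians/ranges per score plus paired Wilcoxon p-values.

    Improvement directions: Dice and DOO should increase, MHD decrease.
    """
    out: dict = {}
    for score, better in (("dice", "greater"), ("mhd", "less"), ("doo", "greater")):
        pre = df[f"{score}_pre"].to_numpy(dtype=float)
        post = df[f"{score}_post"].to_numpy(dtype=float)
        out[score] = {
            "median_pre": float(np.median(pre)),
            "median_post": float(np.median(post)),
            "range_pre": [float(pre.min()), float(pre.max())],
            "range_post": [float(post.min()), float(post.max())],
            "wilcoxon_p": wilcoxon_signed_rank(pre, post, alternative=better),
        }
    return out
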