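"""Voxel-based statistical inference on warped dose maps.

Given N dose volumes aligned in the common coordinate system and a binary
toxicity outcome per patient, this module computes the per-voxel normalized
group dose-difference statistic, the single-maximum (T_max) permutation
gatekeeping test, familywise-corrected TFCE significance maps, the nested
sublevel-set subregion family {S_p}, per-patient mean doses, ROC/AUC and the
p_U(p) discrimination curve.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb

import numpy as np
from scipy.stats import mannwhitneyu, norm, rankdata

from ._tfce import roi_adjacency, tfce_exact, tfce_steps
from .grids import BinaryMask, Grid, ScalarVolume

__all__ = [
    "DoseStack",
    "TfceParams",
    "PermutationResult",
    "SignificanceMap",
    "SubregionFamily",
    "voxel_statistic_map",
    "tmax_test",
    "tfce_transform",
    "tfce_significance",
    "subregions",
    "mean_dose",
    "roc_auc",
    "mann_whitney",
    "pu_curve",
    "significance_levels",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class DoseStack:
    """N aligned dose maps restricted to a region of interest.

    ``data`` holds one row per patient with the dose (Gy) at each ROI voxel,
    in the voxel order produced by ``np.argwhere``-style C iteration of the
    ROI mask.
    """

    data: np.ndarray  # (N, V) Gy
    labels: np.ndarray  # (N,) binary outcome
    roi: BinaryMask

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.data.ndim != 2 or self.data.shape[0] != self.labels.size:
            raise ValueError("data must be (n_patients, n_roi_voxels)")
        if self.data.shape[1] != self.roi.n_voxels:
            raise ValueError("data columns must match ROI voxel count")
        if not self.roi.data.any():
            raise ValueError("ROI is empty")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be binary")
        if (self.labels == 1).sum() < 2 or (self.labels == 0).sum() < 2:
            raise ValueError("need at least 2 patients per outcome group")

    @classmethod
    def from_volumes(
        cls, volumes: list[ScalarVolume], labels, roi: BinaryMask
    ) -> "DoseStack":
        grid = roi.grid
        for vol in volumes:
            if not vol.grid.same_as(grid):
                raise ValueError("all dose volumes must share the ROI grid")
        data = np.stack([vol.data[roi.data] for vol in volumes])
        return cls(data, np.asarray(labels), roi)

    @property
    def n_patients(self) -> int:
        return self.data.shape[0]

    @property
    def grid(self) -> Grid:
        return self.roi.grid

    def embed(self, values: np.ndarray, fill: float = 0.0) -> ScalarVolume:
        """Scatter a flat ROI-voxel vector back into a full volume."""
        out = np.full(self.grid.shape, float(fill))
        out[self.roi.data] = values
        return ScalarVolume(out, self.grid)


@dataclass
class TfceParams:
    """TFCE settings: extent exponent E, height exponent H, integration step.

    ``n_steps=None`` integrates exactly over the sublevel structure of the
    statistic map; an integer requests the stepped integrator with
    dh = max(statistic)/n_steps. Extent is measured in mm^3 by default.
    """

    E: float = 0.5
    H: float = 2.0
    n_steps: int | None = None
    connectivity: int = 26
    extent_measure: str = "mm3"  # or "voxels"

    def __post_init__(self) -> None:
        if self.E < 0 or self.H < 0:
            raise ValueError("E and H must be non-negative")
        if self.n_steps is not None and self.n_steps < 1:
            raise ValueError("n_steps must be positive")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")
        if self.extent_measure not in ("mm3", "voxels"):
            raise ValueError("extent_measure must be 'mm3' or 'voxels'")

    def extent_multiplier(self, grid: Grid) -> float:
        return grid.voxel_volume if self.extent_measure == "mm3" else 1.0


@dataclass
class PermutationResult:
    observed: float
    null: np.ndarray
    p_value: float
    n_permutations: int
    seed: int
    exact: bool


@dataclass
class SignificanceMap:
    """Voxelwise familywise-corrected p-values (1 outside the ROI)."""

    p: ScalarVolume
    roi: BinaryMask
    n_permutations: int
    seed: int
    exact: bool

    @property
    def neglog10(self) -> ScalarVolume:
        """Companion -log10 p display map (0 outside the ROI)."""
        data = np.zeros(self.p.grid.shape)
        data[self.roi.data] = -np.log10(self.p.data[self.roi.data])
        return ScalarVolume(data, self.p.grid)


@dataclass
class SubregionFamily:
    """Nested sublevel-set masks S_p of a significance map."""

    levels: np.ndarray
    masks: list[BinaryMask]
    volumes_cm3: np.ndarray

    def mask_at(self, level: float) -> BinaryMask:
        idx = int(np.argmin(np.abs(self.levels - level)))
        if not np.isclose(self.levels[idx], level):
            raise KeyError(f"level {level} not in family")
        return self.masks[idx]


# ---------------------------------------------------------------------------
# per-voxel statistic and permutation machinery
# ---------------------------------------------------------------------------

def _t_rows(X: np.ndarray, case_rows: np.ndarray) -> np.ndarray:
    """Pooled-t group-difference maps for a batch of relabelings.

    ``case_rows``: (P, N) boolean matrix of case assignments, each row with
    the same number of cases. Returns (P, V) statistic maps; zero-pooled-
    variance voxels get statistic 0.
    """
    N, V = X.shape
    C = case_rows.astype(np.float64)
    n1 = case_rows[0].sum()
    n0 = N - n1
    X2 = X**2
    S, Q = X.sum(axis=0), X2.sum(axis=0)
    S1 = C @ X
    Q1 = C @ X2
    S0, Q0 = S - S1, Q - Q1
    ss1 = Q1 - S1**2 / n1
    ss0 = Q0 - S0**2 / n0
    sp2 = (ss1 + ss0) / (N - 2)
    denom = np.sqrt(np.maximum(sp2, 0.0) * (1.0 / n1 + 1.0 / n0))
    num = S1 / n1 - S0 / n0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    return t


def voxel_statistic_map(stack: DoseStack) -> ScalarVolume:
    """Normalized group dose difference: two-sample pooled-t per ROI voxel.

    t(v) = (mean_case - mean_control) / sqrt(s2_pooled (1/n1 + 1/n0)).
    Zero-variance voxels are assigned 0 (they carry no group evidence).
    """
    case_rows = (stack.labels == 1)[None, :]
    t = _t_rows(stack.data, case_rows)[0]
    return stack.embed(t)


def _relabelings(labels: np.ndarray, n_perm: int, seed: int):
    """Case-assignment matrix for the permutation null.

    Exhaustive enumeration when the number of distinct relabelings is at most
    ``n_perm`` (exact test); otherwise ``n_perm`` uniform random relabelings.
    """
    N = labels.size
    n1 = int((labels == 1).sum())
    total = comb(N, n1)
    if total <= n_perm:
        rows = np.zeros((total, N), dtype=bool)
        for i, idx in enumerate(itertools.combinations(range(N), n1)):
            rows[i, list(idx)] = True
        return rows, True
    rng = np.random.default_rng(seed)
    rows = np.zeros((n_perm, N), dtype=bool)
    for i in range(n_perm):
        rows[i, rng.permutation(N)[:n1]] = True
    return rows, False


def _null_p(observed, null: np.ndarray, exact: bool) -> np.ndarray:
    """Permutation p-values for observed value(s) against a null sample.

    Exhaustive null: p = #{null >= obs}/total (the identity relabeling is one
    of them). Monte Carlo null: add-one estimator (1 + #)/(1 + n_perm).
    """
    observed = np.atleast_1d(observed).astype(float)
    null_sorted = np.sort(null)
    n = null.size
    # count of null >= obs, with a tiny tolerance so ties count as exceedances
    counts = n - np.searchsorted(null_sorted, observed - 1e-12, side="left")
    if exact:
        return counts / n
    return (1.0 + counts) / (1.0 + n)


def tmax_test(
    stack: DoseStack,
    n_perm: int = 10_000,
    seed: int = 0,
    alternative: str = "greater",
) -> PermutationResult:
    """Single-maximum permutation test of any regional dose difference.

    T_max is the maximum of the voxel statistic over the ROI; its null
    distribution comes from random relabelings preserving the group sizes
    (exhaustive when feasible). ``alternative="greater"`` tests for higher
    dose in cases.
    """
    if alternative != "greater":
        raise ValueError("only alternative='greater' is supported")
    rows, exact = _relabelings(stack.labels, n_perm, seed)
    obs = float(_t_rows(stack.data, (stack.labels == 1)[None, :])[0].max())
    null = np.empty(rows.shape[0])
    chunk = max(1, int(2e7 // max(stack.data.shape[1], 1)))
    for lo in range(0, rows.shape[0], chunk):
        null[lo : lo + chunk] = _t_rows(stack.data, rows[lo : lo + chunk]).max(axis=1)
    p = float(_null_p(obs, null, exact)[0])
    return PermutationResult(obs, null, p, rows.shape[0], seed, exact)


# ---------------------------------------------------------------------------
# TFCE
# ---------------------------------------------------------------------------

def tfce_transform(
    stat: ScalarVolume, roi: BinaryMask, params: TfceParams | None = None
) -> ScalarVolume:
    """Threshold-free cluster enhancement of a statistic map inside a ROI.

    Negative statistic values contribute nothing (one-sided enhancement).
    """
    if params is None:
        params = TfceParams()
    if not stat.grid.same_as(roi.grid):
        raise ValueError("statistic map and ROI must share a grid")
    vals3 = stat.data
    if not np.all(np.isfinite(vals3[roi.data])):
        raise ValueError("statistic map must be finite inside the ROI")
    ext_mul = params.extent_multiplier(stat.grid)
    if params.n_steps is not None:
        out = tfce_steps(
            vals3, roi.data, params.E, params.H, params.n_steps,
            params.connectivity, ext_mul,
        )
        return ScalarVolume(out, stat.grid)
    index_map, nbr_idx, nbr_ptr = roi_adjacency(roi.data, params.connectivity)
    flat = vals3[roi.data]
    tf = tfce_exact(flat, nbr_idx, nbr_ptr, params.E, params.H, ext_mul)
    out = np.zeros(stat.grid.shape)
    out[roi.data] = tf
    return ScalarVolume(out, stat.grid)


def tfce_significance(
    stack: DoseStack,
    params: TfceParams | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
) -> SignificanceMap:
    """Familywise-corrected voxelwise p-values via the max-TFCE null.

    For every ROI voxel, p(v) compares the observed TFCE value against the
    permutation distribution of the ROI-wide maximum TFCE, giving strong
    familywise control at any threshold.
    """
    if params is None:
        params = TfceParams()
    roi = stack.roi
    index_map, nbr_idx, nbr_ptr = roi_adjacency(roi.data, params.connectivity)
    ext_mul = params.extent_multiplier(stack.grid)

    def _tfce_flat(tvals: np.ndarray) -> np.ndarray:
        return tfce_exact(tvals, nbr_idx, nbr_ptr, params.E, params.H, ext_mul)

    obs_t = _t_rows(stack.data, (stack.labels == 1)[None, :])[0]
    obs_tfce = _tfce_flat(obs_t)

    rows, exact = _relabelings(stack.labels, n_perm, seed)
    null = np.empty(rows.shape[0])
    chunk = max(1, int(2e7 // max(stack.data.shape[1], 1)))
    for lo in range(0, rows.shape[0], chunk):
        t_batch = _t_rows(stack.data, rows[lo : lo + chunk])
        for j in range(t_batch.shape[0]):
            null[lo + j] = _tfce_flat(t_batch[j]).max()

    p_flat = _null_p(obs_tfce, null, exact)
    p_vol = np.ones(stack.grid.shape)
    p_vol[roi.data] = p_flat
    return SignificanceMap(
        p=ScalarVolume(p_vol, stack.grid),
        roi=roi,
        n_permutations=rows.shape[0],
        seed=seed,
        exact=exact,
    )


# ---------------------------------------------------------------------------
# subregions, ROC, Mann-Whitney, p_U curve
# ---------------------------------------------------------------------------

def significance_levels(n: int = 30) -> np.ndarray:
    """Default logarithmic significance grid on [0.001, 1], always incl. 0.05."""
    levels = np.geomspace(0.001, 1.0, n)
    return np.unique(np.append(levels, 0.05))


def subregions(sig: SignificanceMap, levels=None) -> SubregionFamily:
    """Sublevel sets S_p = {v in ROI : p(v) <= p} for each requested level."""
    if levels is None:
        levels = significance_levels()
    levels = np.sort(np.asarray(levels, dtype=float))
    if np.any(levels <= 0) or np.any(levels > 1):
        raise ValueError("levels must lie in (0, 1]")
    grid = sig.p.grid
    masks = []
    vols = []
    for lev in levels:
        data = sig.roi.data & (sig.p.data <= lev)
        m = BinaryMask(data, grid, f"S_{lev:g}")
        masks.append(m)
        vols.append(m.volume_cm3)
    return SubregionFamily(levels, masks, np.asarray(vols))


def mean_dose(dose: ScalarVolume, region: BinaryMask) -> float:
    """Arithmetic mean of the dose over the region's voxels (Gy)."""
    if not dose.grid.same_as(region.grid):
        raise ValueError("dose and region must share a grid")
    if region.n_voxels == 0:
        raise ValueError("mean dose over an empty region is undefined")
    return float(dose.data[region.data].mean())


def roc_auc(values, labels, ci: tuple[int, int] | None = None):
    """AUC of ``values`` for predicting ``labels`` (Mann-Whitney identity).

    Ties count 1/2. With ``ci=(n_boot, seed)`` a stratified percentile
    bootstrap 95% CI over patients is returned as (auc, (lo, hi)).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = values[labels == 1]
    neg = values[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both outcome classes must be present")

    def _auc(p: np.ndarray, n: np.ndarray) -> float:
        ranks = rankdata(np.concatenate([p, n]))
        u = ranks[: p.size].sum() - p.size * (p.size + 1) / 2.0
        return float(u / (p.size * n.size))

    auc = _auc(pos, neg)
    if ci is None:
        return auc
    n_boot, seed = ci
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bp = pos[rng.integers(0, pos.size, pos.size)]
        bn = neg[rng.integers(0, neg.size, neg.size)]
        boots[b] = _auc(bp, bn)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return auc, (float(lo), float(hi))


def mann_whitney(x, y, alternative: str = "two-sided") -> tuple[float, float]:
    """Mann-Whitney U (of x over y) and its p-value.

    Exact by enumeration for n1+n2 <= 12 without ties; otherwise a normal
    approximation with continuity and tie correction. Fully tied degenerate
    samples return p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    n1, n2 = x.size, y.size
    ranks = rankdata(pooled)
    U = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    if n1 + n2 <= 12 and not has_ties:
        res = mannwhitneyu(x, y, alternative=alternative, method="exact")
        return U, float(res.pvalue)
    mean = n1 * n2 / 2.0
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return U, 1.0
    sd = np.sqrt(var)
    p_greater = float(norm.sf((U - 0.5 - mean) / sd))
    p_less = float(norm.cdf((U + 0.5 - mean) / sd))
    if alternative == "greater":
        p = p_greater
    elif alternative == "less":
        p = p_less
    else:
        p = min(2.0 * min(p_greater, p_less), 1.0)
    return U, min(p, 1.0)


def pu_curve(
    family: SubregionFamily, stack: DoseStack, alternative: str = "two-sided"
) -> dict:
    """Mann-Whitney significance of mean-dose group differences on each S_p.

    Returns levels, p_U values (NaN where S_p is empty), the per-level mean
    doses, and the level minimising p_U. Raises if every member is empty.
    """
    roi_flat_idx = np.flatnonzero(stack.roi.data.ravel())
    col_of_voxel = {int(v): i for i, v in enumerate(roi_flat_idx)}
    levels, pus, mean_doses = [], [], []
    for lev, mask in zip(family.levels, family.masks):
        idx = np.flatnonzero(mask.data.ravel())
        levels.append(float(lev))
        if idx.size == 0:
            pus.append(np.nan)
            mean_doses.append(None)
            continue
        cols = np.array([col_of_voxel[int(v)] for v in idx])
        dm = stack.data[:, cols].mean(axis=1)
        _, p = mann_whitney(dm[stack.labels == 1], dm[stack.labels == 0], alternative)
        pus.append(p)
        mean_doses.append(dm)
    pus_arr = np.asarray(pus)
    if np.all(np.isnan(pus_arr)):
        raise ValueError("every subregion is empty; p_U curve undefined")
    best = int(np.nanargmin(pus_arr))
    return {
        "levels": np.asarray(levels),
        "p_u": pus_arr,
        "mean_doses": mean_doses,
        "argmin_level": float(levels[best]),
        "min_p_u": float(pus_arr[best]),
    }
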