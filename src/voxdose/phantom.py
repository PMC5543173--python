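"""Synthetic head-and-neck cohort generator.

Builds a template anatomy (body, oral cavity, larynx, esophagus and the five
swallowing-related structures), deforms it per patient with random invertible
deformations, paints plan-like dose distributions with an optional planted
extra dose inside a ground-truth sensitive subregion of the cricopharyngeus /
cervical esophagus, and assigns binary toxicity outcomes. Every record keeps
its ground-truth deformation so downstream registration and inference can be
tested against a known answer.

The geometry is defined in coordinates normalised by the grid's physical
extent, so the same anatomy scales from quick 32^3 test grids to the default
96 x 96 x 120 @ 2 mm grid. Axis convention: x left-right, y anterior-posterior
(posterior = large y), z inferior-superior.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .fields import (
    DeformationField,
    VelocityField,
    exp_velocity,
    jacobian_determinant,
    warp_mask,
    warp_scalar,
)
from .grids import BinaryMask, Grid, ScalarVolume

__all__ = [
    "ORGAN_NAMES",
    "SWALLOWING_STRUCTURES",
    "CohortConfig",
    "TemplatePhantom",
    "PatientRecord",
    "CohortDataset",
    "make_template",
    "sample_patient",
    "simulate_dose",
    "generate_cohort",
    "generate_warped_cohort",
]

# Structures contoured on every patient. "body" is the external contour.
ORGAN_NAMES = (
    "oral_cavity",
    "larynx",
    "esophagus",
    "constrictor_superior",
    "constrictor_middle",
    "constrictor_inferior",
    "cricopharyngeus",
    "cervical_esophagus",
)
# Region of interest of the voxel-based analysis.
SWALLOWING_STRUCTURES = (
    "constrictor_superior",
    "constrictor_middle",
    "constrictor_inferior",
    "cricopharyngeus",
    "cervical_esophagus",
)

_HU_AIR = -1000.0
_HU_SOFT = 40.0
_HU_BONE = 700.0


@dataclass
class CohortConfig:
    """Study conditions for one simulated cohort.

    Defaults mirror the scale of the emulated clinical study: 42 patients of
    whom 9 develop the severe toxicity, ~70 Gy peak dose, anatomical
    variability of up to 15 mm displacement and 3 Gy smooth dose noise.
    """

    n_patients: int = 42
    n_cases: int = 9
    shape: tuple[int, int, int] = (96, 96, 120)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    deform_amplitude: float = 15.0  # mm, max displacement of the true deformation
    deform_smoothness: float = 12.0  # mm, kernel width of the velocity smoother
    dose_peak: float = 70.0  # Gy
    effect_size: float = 6.0  # Gy added inside the sensitive region of cases
    noise_sd: float = 3.0  # Gy, sd of the smooth dose noise
    outcome_model: str = "deterministic"  # or "logistic"
    logistic_slope: float = 0.25  # 1/Gy, only for outcome_model="logistic"
    logistic_intercept: float = -12.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases >= self.n_patients:
            raise ValueError("n_cases must be smaller than n_patients")
        if min(self.shape) < 32:
            raise ValueError("grid must be at least 32 voxels along every axis")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if self.dose_peak <= 0:
            raise ValueError("dose_peak must be positive")
        if self.effect_size < 0 or self.noise_sd < 0:
            raise ValueError("effect_size and noise_sd must be non-negative")
        if self.outcome_model not in ("deterministic", "logistic"):
            raise ValueError(f"unknown outcome model {self.outcome_model!r}")

    @property
    def grid(self) -> Grid:
        return Grid(tuple(self.shape), tuple(self.spacing))


@dataclass
class TemplatePhantom:
    """Template anatomy defining the common coordinate system's geometry."""

    image: ScalarVolume
    structures: dict[str, BinaryMask]
    sensitive_region: BinaryMask

    @property
    def grid(self) -> Grid:
        return self.image.grid

    def roi_mask(self) -> BinaryMask:
        """Union of the swallowing-related structures."""
        data = np.zeros(self.grid.shape, dtype=bool)
        for name in SWALLOWING_STRUCTURES:
            data |= self.structures[name].data
        return BinaryMask(data, self.grid, "swallowing_roi")


@dataclass
class PatientRecord:
    """One simulated subject: image, dose, contours, outcome and ground truth."""

    id: str
    image: ScalarVolume
    dose: ScalarVolume | None
    structures: dict[str, BinaryMask]
    outcome: int
    true_deformation: DeformationField  # template -> this patient (pull-back map)
    true_velocity: VelocityField
    sensitive_region: BinaryMask  # planted region in this patient's space

    @property
    def grid(self) -> Grid:
        return self.image.grid


@dataclass
class CohortDataset:
    """Ordered patient records plus the common-coordinate-system reference.

    The first record is the reference patient; its anatomy is the common
    coordinate system into which all doses are warped.
    """

    config: CohortConfig
    template: TemplatePhantom
    records: list[PatientRecord]

    @property
    def reference(self) -> PatientRecord:
        return self.records[0]

    @property
    def outcomes(self) -> np.ndarray:
        return np.array([r.outcome for r in self.records], dtype=int)

    def roi_in_ccs(self) -> BinaryMask:
        data = np.zeros(self.reference.grid.shape, dtype=bool)
        for name in SWALLOWING_STRUCTURES:
            data |= self.reference.structures[name].data
        return BinaryMask(data, self.reference.grid, "swallowing_roi")

    def sensitive_in_ccs(self) -> BinaryMask:
        return self.reference.sensitive_region

    def true_field_to_ccs(self, index: int) -> DeformationField:
        """Ground-truth displacement mapping CCS (reference) points into
        patient ``index`` space, built from the retained true velocities."""
        from .fields import compose

        ref_v = self.reference.true_velocity
        pat_v = self.records[index].true_velocity
        return compose(exp_velocity(-pat_v), exp_velocity(ref_v))

    def warp_dose_to_ccs(self, index: int) -> ScalarVolume:
        """Map a patient's dose into the CCS with the ground-truth deformation."""
        rec = self.records[index]
        if rec.dose is None:
            raise ValueError(f"patient {rec.id} has no dose volume")
        return warp_scalar(rec.dose, self.true_field_to_ccs(index), fill=0.0)


# ---------------------------------------------------------------------------
# Template construction
# ---------------------------------------------------------------------------

def _frac_coords(grid: Grid) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Voxel-centre coordinates normalised by the grid's physical extent."""
    ext = grid.extent
    axes = [np.arange(grid.shape[a]) * grid.spacing[a] / ext[a] for a in range(3)]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid(fx, fy, fz, centre, radii) -> np.ndarray:
    return (
        ((fx - centre[0]) / radii[0]) ** 2
        + ((fy - centre[1]) / radii[1]) ** 2
        + ((fz - centre[2]) / radii[2]) ** 2
    ) <= 1.0


def _tube(fx, fy, fz, centre_xy, radii_xy, z_lo, z_hi) -> np.ndarray:
    radial = (
        ((fx - centre_xy[0]) / radii_xy[0]) ** 2
        + ((fy - centre_xy[1]) / radii_xy[1]) ** 2
    ) <= 1.0
    return radial & (fz >= z_lo) & (fz < z_hi)


def make_template(config: CohortConfig) -> TemplatePhantom:
    """Build the deterministic template anatomy for a grid configuration.

    The esophagus is a tube spanning the inferior ~0.42 of the grid; the
    pharyngeal constrictors, cricopharyngeus and cervical esophagus stack
    along the posterior pharyngeal wall; the planted sensitive region is the
    part of a sphere centred at the cricopharyngeus / cervical-esophagus
    junction that lies inside those two structures.
    """
    grid = config.grid
    fx, fy, fz = _frac_coords(grid)

    body = _ellipsoid(fx, fy, fz, (0.5, 0.5, 0.5), (0.42, 0.38, 10.0))
    # vertebral column: periodic bodies with soft discs, so the image carries
    # inferior-superior contrast everywhere (no aperture problem along z)
    spine = _tube(fx, fy, fz, (0.5, 0.72), (0.07, 0.07), 0.0, 1.0)
    z_mm = fz * grid.extent[2]
    vertebra = spine & ((z_mm % 22.0) < 16.0)

    structures: dict[str, np.ndarray] = {}
    structures["oral_cavity"] = _ellipsoid(fx, fy, fz, (0.5, 0.40, 0.80), (0.17, 0.13, 0.11))
    structures["larynx"] = _tube(fx, fy, fz, (0.5, 0.46), (0.09, 0.055), 0.46, 0.64)
    structures["esophagus"] = _tube(fx, fy, fz, (0.5, 0.57), (0.045, 0.045), 0.0, 0.42)
    structures["cervical_esophagus"] = _tube(fx, fy, fz, (0.5, 0.57), (0.045, 0.045), 0.28, 0.42)
    structures["cricopharyngeus"] = _tube(fx, fy, fz, (0.5, 0.565), (0.055, 0.05), 0.42, 0.47)
    structures["constrictor_inferior"] = _tube(fx, fy, fz, (0.5, 0.56), (0.055, 0.05), 0.47, 0.55)
    structures["constrictor_middle"] = _tube(fx, fy, fz, (0.5, 0.555), (0.05, 0.045), 0.55, 0.63)
    structures["constrictor_superior"] = _tube(fx, fy, fz, (0.5, 0.55), (0.045, 0.04), 0.63, 0.71)

    # Air lumina give the registration realistic intensity gradients.
    lumina = (
        _ellipsoid(fx, fy, fz, (0.5, 0.40, 0.80), (0.10, 0.07, 0.06))
        | _tube(fx, fy, fz, (0.5, 0.46), (0.045, 0.028), 0.40, 0.66)
        | _tube(fx, fy, fz, (0.5, 0.57), (0.015, 0.015), 0.0, 0.44)
    )

    masks: dict[str, BinaryMask] = {"body": BinaryMask(body, grid, "body")}
    for name, arr in structures.items():
        arr &= body
        if not arr.any():
            raise ValueError(
                f"grid {grid.shape} too small to host structure {name!r}"
            )
        masks[name] = BinaryMask(arr, grid, name)

    sens_ball = _ellipsoid(fx, fy, fz, (0.5, 0.57, 0.42), (0.07, 0.07, 0.075))
    sensitive = sens_ball & (
        masks["cricopharyngeus"].data | masks["cervical_esophagus"].data
    )
    if not sensitive.any():
        raise ValueError(f"grid {grid.shape} too small to host the sensitive region")

    hu = np.where(body, _HU_SOFT, _HU_AIR)
    hu = np.where(vertebra & body, _HU_BONE, hu)
    hu = np.where(lumina & body, _HU_AIR, hu)
    sigma_vox = [1.5 / s for s in grid.spacing]  # ~1.5 mm partial-volume blur
    image = ScalarVolume(ndimage.gaussian_filter(hu, sigma_vox), grid)

    return TemplatePhantom(
        image=image,
        structures=masks,
        sensitive_region=BinaryMask(sensitive, grid, "sensitive_region"),
    )


# ---------------------------------------------------------------------------
# Patient sampling
# ---------------------------------------------------------------------------

def _random_velocity(grid: Grid, amplitude: float, smoothness: float, rng) -> VelocityField:
    """Smoothed white Gaussian vector noise scaled to a maximum displacement."""
    data = rng.standard_normal(grid.shape + (3,))
    sigma_vox = [smoothness / s for s in grid.spacing]
    for a in range(3):
        data[..., a] = ndimage.gaussian_filter(data[..., a], sigma_vox)
    norm = np.sqrt((data**2).sum(axis=-1)).max()
    if norm > 0 and amplitude > 0:
        data *= amplitude / norm
    else:
        data[:] = 0.0
    return VelocityField(data, grid)


def sample_patient(
    template: TemplatePhantom, config: CohortConfig, patient_seed: int
) -> PatientRecord:
    """Draw one patient: the template warped by a random diffeomorphism.

    Velocity fields whose exponential folds (min Jacobian determinant <= 0.05)
    are rejected and resampled up to 5 times before failing — the ground truth
    must stay diffeomorphic for registration tests to be meaningful.
    """
    grid = template.grid
    rng = np.random.default_rng([int(patient_seed), 0])
    if config.deform_amplitude == 0:
        # exact identity: the patient IS the template
        zero = VelocityField(np.zeros(grid.shape + (3,)), grid)
        return PatientRecord(
            id=f"P{patient_seed:04d}",
            image=template.image.copy(),
            dose=None,
            structures={n: m.copy() for n, m in template.structures.items()},
            outcome=0,
            true_deformation=exp_velocity(zero),
            true_velocity=zero,
            sensitive_region=template.sensitive_region.copy(),
        )
    for _attempt in range(5):
        v = _random_velocity(grid, config.deform_amplitude, config.deform_smoothness, rng)
        phi = exp_velocity(v)
        if config.deform_amplitude == 0 or jacobian_determinant(phi).min() > 0.05:
            break
    else:
        raise RuntimeError(
            "could not sample a non-folding deformation after 5 attempts; "
            "reduce deform_amplitude or increase deform_smoothness"
        )

    image = warp_scalar(template.image, phi, fill=_HU_AIR)
    structures = {
        name: warp_mask(mask, phi) for name, mask in template.structures.items()
    }
    sensitive = warp_mask(template.sensitive_region, phi)
    return PatientRecord(
        id=f"P{patient_seed:04d}",
        image=image,
        dose=None,
        structures=structures,
        outcome=0,
        true_deformation=phi,
        true_velocity=v,
        sensitive_region=sensitive,
    )


def simulate_dose(
    patient: PatientRecord,
    template: TemplatePhantom,
    config: CohortConfig,
    is_case: bool,
    patient_seed: int,
) -> ScalarVolume:
    """Paint a plan-like dose on the patient grid.

    The base dose is a broad Gaussian bell centred near the pharynx (peak
    ~``dose_peak``), with per-patient jitter of centre, widths and output
    level emulating inter-patient planning variability. Cases additionally
    receive ``effect_size`` Gy uniformly inside the patient-space image of the
    planted sensitive region; smooth zero-mean noise of sd ``noise_sd`` is
    added and the result is clipped at 0 Gy.
    """
    grid = patient.grid
    rng = np.random.default_rng([int(patient_seed), 1])
    ext = np.asarray(grid.extent)

    centre = np.array([0.5, 0.52, 0.52]) * ext + rng.normal(0.0, 6.0, size=3)
    widths = np.array([60.0, 55.0, 80.0]) * np.exp(rng.normal(0.0, 0.10, size=3))
    level = config.dose_peak * np.exp(rng.normal(0.0, 0.03))

    coords = grid.world_coordinates()
    q = ((coords - centre) / widths) ** 2
    dose = level * np.exp(-0.5 * q.sum(axis=-1))

    if is_case and config.effect_size > 0:
        dose = dose + config.effect_size * patient.sensitive_region.data

    if config.noise_sd > 0:
        noise = rng.standard_normal(grid.shape)
        sigma_vox = [8.0 / s for s in grid.spacing]  # 8 mm correlation length
        noise = ndimage.gaussian_filter(noise, sigma_vox)
        sd = noise.std()
        if sd > 0:
            dose = dose + noise * (config.noise_sd / sd)

    return ScalarVolume(np.clip(dose, 0.0, None), grid)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_cohort(config: CohortConfig) -> CohortDataset:
    """Generate a full cohort; deterministic given the config (incl. its seed).

    Under the ``deterministic`` outcome model a random subset of ``n_cases``
    patients receives the planted dose effect and outcome 1. Under the
    ``logistic`` model no effect is planted: outcomes are Bernoulli draws with
    probability ``sigmoid(intercept + slope * mean sensitive-region dose)``.
    Patient ``i`` uses seed ``config.seed + i``; the first patient is the
    common-coordinate-system reference.
    """
    template = make_template(config)
    assign_rng = np.random.default_rng([int(config.seed), 101])
    case_idx = set(
        assign_rng.choice(config.n_patients, size=config.n_cases, replace=False).tolist()
    )

    records: list[PatientRecord] = []
    for i in range(config.n_patients):
        seed_i = config.seed + i
        rec = sample_patient(template, config, seed_i)
        is_case = i in case_idx and config.outcome_model == "deterministic"
        rec.dose = simulate_dose(rec, template, config, is_case, seed_i)
        rec.outcome = int(is_case)
        records.append(rec)

    if config.outcome_model == "logistic":  # outcomes need all doses first
        outcome_rng = np.random.default_rng([int(config.seed), 202])
        for rec in records:
            if rec.sensitive_region.n_voxels > 0:
                dm = float(rec.dose.data[rec.sensitive_region.data].mean())
            else:  # pragma: no cover - degenerate grids only
                dm = 0.0
            p = _sigmoid(config.logistic_intercept + config.logistic_slope * dm)
            rec.outcome = int(outcome_rng.random() < p)

    return CohortDataset(config=config, template=template, records=records)


def generate_warped_cohort(config: CohortConfig):
    """Stream a cohort and map every dose into the CCS with the true fields.

    Memory-lean alternative to :func:`generate_cohort` for large grids: each
    patient is generated, dose-warped into the reference (first patient's)
    anatomy with the ground-truth deformations, and then discarded. Supports
    the deterministic outcome model only. Returns
    ``(doses_in_ccs, outcomes, reference_record)`` where the reference record
    carries the CCS structures and planted region.
    """
    if config.outcome_model != "deterministic":
        raise ValueError("streaming generation supports the deterministic model only")
    from .fields import compose

    template = make_template(config)
    assign_rng = np.random.default_rng([int(config.seed), 101])
    case_idx = set(
        assign_rng.choice(config.n_patients, size=config.n_cases, replace=False).tolist()
    )
    doses_ccs: list[ScalarVolume] = []
    outcomes = np.zeros(config.n_patients, dtype=int)
    reference: PatientRecord | None = None
    exp_ref = None
    for i in range(config.n_patients):
        seed_i = config.seed + i
        rec = sample_patient(template, config, seed_i)
        is_case = i in case_idx
        rec.dose = simulate_dose(rec, template, config, is_case, seed_i)
        rec.outcome = int(is_case)
        outcomes[i] = rec.outcome
        if i == 0:
            reference = rec
            exp_ref = exp_velocity(rec.true_velocity)
        field = compose(exp_velocity(-rec.true_velocity), exp_ref)
        doses_ccs.append(warp_scalar(rec.dose, field, fill=0.0))
        if i > 0:
            del rec
    return doses_ccs, outcomes, reference
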