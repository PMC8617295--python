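"""Synthetic phantoms with planted connectivity gradients and pain cohorts.

The phantom emulates the structure the analysis is designed to detect: an ROI
whose voxel time series blend smoothly between two latent network signals
along one spatial axis, and two disjoint "target network" boxes carrying the
pure signals.  A voxel at gradient position g has time series

    x_i(t) = (1 − g_i)·s_A(t) + g_i·s_B(t) + σ·ε_i(t),

so its connectivity fingerprint shifts monotonically from network A to
network B — the ground truth a connectopy should recover.  The latent
signals are band-limited Gaussian noise (temporally smoothed white noise)
with unit population variance, so a 0.01 Hz high-pass leaves them intact.

Cohorts add subject variability as a random monotone reparameterization
g → g^a (a log-normal around 1): anterior- vs posterior-dominant gradient
layouts with one interpretable knob.  Each subject's continuous pain
sensitivity is a linear function of the true trend-surface coefficients of
their deformed gradient plus nuisance (age, sex, menstrual-cycle day) and
Gaussian residual; modal thresholds are then *back-generated* so that the
QST scoring pipeline reproduces the planted composite exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.ndimage

from gradpain.errors import ConfigError, DataError
from gradpain.trend_surface import tsm_basis
from gradpain.volume import BoldVolume, Mask, save_mask, save_volume, voxel_coordinates

log = logging.getLogger(__name__)

# Fixed population parameters of the threshold back-generation, matching the
# published cohort statistics of the quantitative sensory testing battery
# this package targets (cold/heat in °C, mechanical in mN, log-normal).
CPT_MEAN, CPT_SD = 15.87, 8.15
HPT_MEAN, HPT_SD = 43.44, 3.36
MPT_MEAN, MPT_ARITH_SD = 46.92, 47.92
MPT_LOG_SD = float(np.sqrt(np.log1p((MPT_ARITH_SD / MPT_MEAN) ** 2)))
MPT_LOG_MEAN = float(np.log(MPT_MEAN) - 0.5 * MPT_LOG_SD**2)

Box = tuple[tuple[int, int], tuple[int, int], tuple[int, int]]


def _box_slices(box: Box) -> tuple[slice, slice, slice]:
    return tuple(slice(lo, hi) for lo, hi in box)


def _boxes_overlap(a: Box, b: Box) -> bool:
    return all(a[d][0] < b[d][1] and b[d][0] < a[d][1] for d in range(3))


@dataclass
class PhantomSpec:
    """Geometry and noise of a single phantom acquisition.

    Boxes are half-open voxel ranges ((x0,x1),(y0,y1),(z0,z1)).  The default
    geometry gives a 500-voxel ROI on a 24×12×7 grid with the gradient along
    the first axis, T = 150 volumes at TR = 2.5 s.
    """

    grid_shape: tuple[int, int, int] = (24, 12, 7)
    tr: float = 2.5
    n_timepoints: int = 150
    roi_box: Box = ((8, 18), (1, 11), (1, 6))
    target_box_a: Box = ((0, 6), (1, 11), (1, 6))
    target_box_b: Box = ((20, 24), (1, 11), (1, 6))
    gradient_axis: int = 0
    noise_sd: float = 0.5
    signal_band_hz: tuple[float, float] = (0.015, 0.08)
    signal_coupling: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_timepoints < 50:
            raise ConfigError(f"n_timepoints must be >= 50, got {self.n_timepoints}")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.gradient_axis not in (0, 1, 2):
            raise ConfigError("gradient_axis must be 0, 1 or 2")
        names = {"roi": self.roi_box, "target_a": self.target_box_a, "target_b": self.target_box_b}
        for name, box in names.items():
            for d in range(3):
                if not (0 <= box[d][0] < box[d][1] <= self.grid_shape[d]):
                    raise ConfigError(f"box '{name}' range {box[d]} outside grid axis {d}")
        pairs = [("roi", "target_a"), ("roi", "target_b"), ("target_a", "target_b")]
        for na, nb in pairs:
            if _boxes_overlap(names[na], names[nb]):
                raise ConfigError(f"boxes '{na}' and '{nb}' overlap")

    @property
    def affine(self) -> np.ndarray:
        return np.eye(4)


def _box_mask(shape: tuple[int, int, int], box: Box) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    m[_box_slices(box)] = True
    return m


def _band_limited_signal(
    rng: np.random.Generator, T: int, tr: float, f_lo: float = 0.015, f_hi: float = 0.08
) -> np.ndarray:
    """Unit-variance Gaussian signal with power confined to [f_lo, f_hi] Hz,
    built from discrete-cosine modes (mode k has frequency k/(2·T·TR))."""
    k_lo = max(1, int(np.ceil(f_lo * 2 * T * tr)))
    k_hi = min(T - 1, int(np.floor(f_hi * 2 * T * tr)))
    t = np.arange(T)
    ks = np.arange(k_lo, k_hi + 1)
    basis = np.cos(np.pi * np.outer(ks, t + 0.5) / T)
    s = rng.standard_normal(ks.size) @ basis
    return (s - s.mean()) / s.std()


def planted_gradient(spec: PhantomSpec) -> np.ndarray:
    """The deterministic g field: ROI voxel position along the gradient axis,
    scaled to [0, 1], in the package voxel scan order."""
    roi = Mask(_box_mask(spec.grid_shape, spec.roi_box), label="roi")
    pos = roi.indices()[:, spec.gradient_axis].astype(float)
    return (pos - pos.min()) / (pos.max() - pos.min())


def make_phantom(
    spec: PhantomSpec,
    exponent: float = 1.0,
    rng: np.random.Generator | None = None,
) -> tuple[BoldVolume, Mask, Mask, np.ndarray]:
    """Generate one phantom BOLD volume.

    Returns (volume, roi mask, brain mask, planted gradient g).  ``exponent``
    applies the monotone deformation g → g^exponent used for subject
    variability; the returned g is the deformed field.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    T = spec.n_timepoints
    shape = spec.grid_shape
    s_a = _band_limited_signal(rng, T, spec.tr, *spec.signal_band_hz)
    s_b = _band_limited_signal(rng, T, spec.tr, *spec.signal_band_hz)
    # the two network signals share a positive common component, as
    # large-scale network time series do through global fluctuations; the
    # coupling is imposed exactly in-sample, which also keeps the rank-2
    # noise-free fingerprint geometry away from its reflection-degenerate
    # configuration
    rho = spec.signal_coupling
    if rho:
        orth = s_b - (float(s_a @ s_b) / float(s_a @ s_a)) * s_a
        orth = (orth - orth.mean()) / orth.std()
        s_b = rho * s_a + np.sqrt(1.0 - rho**2) * orth

    g = planted_gradient(spec) ** float(exponent)
    roi = Mask(_box_mask(shape, spec.roi_box), label="roi", affine=spec.affine)
    box_a = _box_mask(shape, spec.target_box_a)
    box_b = _box_mask(shape, spec.target_box_b)
    brain = Mask(np.ones(shape, dtype=bool), label="brain", affine=spec.affine)

    data = rng.standard_normal((*shape, T)) * spec.noise_sd
    data[box_a] += s_a
    data[box_b] += s_b
    mix = np.outer(1.0 - g, s_a) + np.outer(g, s_b)  # N_roi × T
    data[roi.data] += mix
    return BoldVolume(data, spec.affine, spec.tr), roi, brain, g


def make_confounds(spec: PhantomSpec, rng: np.random.Generator | None = None) -> np.ndarray:
    """Plausible nuisance series: six motion parameters plus white-matter and
    CSF signals, as slowly varying standardized noise (T × 8)."""
    if rng is None:
        rng = np.random.default_rng(spec.seed + 104729)
    return np.column_stack(
        [_band_limited_signal(rng, spec.n_timepoints, spec.tr, 0.005, 0.05) for _ in range(8)]
    )


# --- cohorts -----------------------------------------------------------------

# Default effect direction: weight on the gradient-axis polynomial block
# (linear, quadratic, cubic of the first axis for the default geometry), the
# coefficients through which the g -> g^a deformation expresses itself.
_DEFAULT_BETA_DIRECTION = np.array([1.0, 0.0, 0.0, -0.6, 0.0, 0.0, 0.3, 0.0, 0.0])
# Magnitude chosen once so the planted signal sd is ~0.7 score units under
# the default geometry and deformation spread, i.e. a moderate effect of
# about a third of the score variance at unit residual sd (docs/methods.md).
_DEFAULT_BETA_SCALE = 30.0
DEFAULT_BETA = _DEFAULT_BETA_DIRECTION * _DEFAULT_BETA_SCALE


@dataclass
class CohortSpec:
    """Study-cohort generator settings.

    ``beta`` maps the 9 true trend-surface coefficients of a subject's
    deformed gradient to the continuous sensitivity score (score units per
    coefficient unit).  ``deformation_sd`` is the log-sd of the monotone
    reparameterization exponent a (log-normal around 1).
    """

    n_subjects: int = 60
    beta: np.ndarray = field(default_factory=lambda: DEFAULT_BETA.copy())
    age_effect: float = 0.02
    sex_effect: float = 0.3
    cycle_effect: float = 0.01
    residual_sd: float = 1.0
    modal_noise_sd: float = 0.5
    deformation_sd: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=np.float64)
        if self.n_subjects < 8:
            raise ConfigError(
                f"n_subjects must be >= 8 (permutation inference is meaningless below), got {self.n_subjects}"
            )
        if not self.residual_sd > 0:
            raise ConfigError("residual_sd must be > 0")
        if self.beta.shape != (9,):
            raise ConfigError(f"beta must have 9 entries, got shape {self.beta.shape}")


@dataclass
class SubjectRecord:
    """Covariates, raw modal thresholds and derived sensitivity scores."""

    subject_id: str
    age: float
    sex: str
    cycle_day: int | None
    cpt_C: float
    hpt_C: float
    mpt_mN: float
    z_cold: float
    z_heat: float
    z_mech: float
    composite: float
    latent_score: float
    true_tsm: np.ndarray

    def __post_init__(self) -> None:
        if self.mpt_mN <= 0:
            raise DataError(f"subject {self.subject_id}: MPT must be positive")
        if self.cpt_C >= self.hpt_C:
            raise DataError(f"subject {self.subject_id}: CPT {self.cpt_C} not below HPT {self.hpt_C}")


@dataclass
class CohortMember:
    """One synthetic subject: record plus a lazily materializable phantom."""

    record: SubjectRecord
    pspec: PhantomSpec
    exponent: float
    data_seed: int

    def make_phantom(self) -> tuple[BoldVolume, Mask, Mask, np.ndarray]:
        return make_phantom(self.pspec, exponent=self.exponent, rng=np.random.default_rng(self.data_seed))

    def make_confounds(self) -> np.ndarray:
        return make_confounds(self.pspec, rng=np.random.default_rng(self.data_seed + 104729))


_TSM_GEOMETRY_CACHE: dict = {}


def _tsm_geometry(pspec: PhantomSpec):
    key = (pspec.grid_shape, pspec.roi_box, pspec.gradient_axis)
    if key not in _TSM_GEOMETRY_CACHE:
        roi = Mask(_box_mask(pspec.grid_shape, pspec.roi_box), label="roi")
        coords = voxel_coordinates(roi, pspec.affine)
        Phi = tsm_basis(coords, order=3)
        X = np.column_stack([np.ones(Phi.shape[0]), Phi])
        pinv = np.linalg.pinv(X)
        _TSM_GEOMETRY_CACHE[key] = (planted_gradient(pspec), pinv)
    return _TSM_GEOMETRY_CACHE[key]


def true_tsm_parameters(pspec: PhantomSpec, exponent: float = 1.0) -> np.ndarray:
    """Ground-truth order-3 trend-surface coefficients of the (deformed)
    planted gradient, by ordinary least squares on the ROI coordinates."""
    g0, pinv = _tsm_geometry(pspec)
    return (pinv @ (g0 ** float(exponent)))[1:]


def _back_generate_thresholds(
    scores: np.ndarray, modal_sd: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Split latent scores into three modal z-score vectors and invert the
    scoring transforms with the fixed population parameters.

    The per-subject modal noise is centered across modalities so the subject's
    mean raw modal score equals the latent score.  Each modality is then
    standardized across the cohort, smoothly winsorized at 1.6 sd (a tanh
    squash — QST thresholds occupy a bounded physiological range, and an
    unbounded Gaussian tail would let a very sensitive subject's cold
    threshold cross their heat threshold), and re-standardized; thresholds
    are affine (cold/heat) or log-affine (mechanical) in the final z-scores,
    which makes the scoring pipeline's round trip exact.
    """
    n = scores.shape[0]
    e = rng.standard_normal((n, 3)) * modal_sd
    e -= e.mean(axis=1, keepdims=True)
    z0 = scores[:, None] + e
    z0 = (z0 - z0.mean(axis=0)) / z0.std(axis=0)
    z1 = 1.6 * np.tanh(z0 / 1.6)
    z = (z1 - z1.mean(axis=0)) / z1.std(axis=0)
    cpt = CPT_MEAN + CPT_SD * z[:, 0]
    hpt = HPT_MEAN - HPT_SD * z[:, 1]
    mpt = np.exp(MPT_LOG_MEAN - MPT_LOG_SD * z[:, 2])
    if not np.all(cpt < hpt):
        raise DataError("degenerate score distribution: back-generated CPT >= HPT")
    return cpt, hpt, mpt, z


def make_cohort(pspec: PhantomSpec, cspec: CohortSpec) -> list[CohortMember]:
    """Generate a cohort of phantom subjects with linked pain scores.

    Each subject's gradient is g^a with a ~ lognormal(0, deformation_sd); the
    latent sensitivity score is beta·theta(a) + nuisance + residual, and the
    modal thresholds are back-generated so scoring reproduces the stored
    composite exactly.
    """
    rng = np.random.default_rng(cspec.seed)
    n = cspec.n_subjects
    exponents = np.exp(rng.normal(0.0, cspec.deformation_sd, size=n))
    ages = np.clip(rng.normal(25.2, 3.5, size=n), 18.0, 45.0)
    sexes = np.array(["M", "F"] * ((n + 1) // 2))[:n]
    rng.shuffle(sexes)
    cycle = np.where(sexes == "F", rng.integers(1, 29, size=n), 0)

    thetas = np.array([true_tsm_parameters(pspec, a) for a in exponents])
    signal = thetas @ cspec.beta
    scores = (
        signal
        + cspec.age_effect * (ages - ages.mean())
        + cspec.sex_effect * (sexes == "F").astype(float)
        + cspec.cycle_effect * cycle
        + rng.normal(0.0, cspec.residual_sd, size=n)
    )
    cpt, hpt, mpt, z = _back_generate_thresholds(scores, cspec.modal_noise_sd, rng)
    composite = z.mean(axis=1)

    members = []
    data_seeds = rng.integers(0, 2**31 - 1, size=n)
    for i in range(n):
        rec = SubjectRecord(
            subject_id=f"sub-{i + 1:03d}",
            age=float(ages[i]),
            sex=str(sexes[i]),
            cycle_day=int(cycle[i]) if sexes[i] == "F" else None,
            cpt_C=float(cpt[i]),
            hpt_C=float(hpt[i]),
            mpt_mN=float(mpt[i]),
            z_cold=float(z[i, 0]),
            z_heat=float(z[i, 1]),
            z_mech=float(z[i, 2]),
            composite=float(composite[i]),
            latent_score=float(scores[i]),
            true_tsm=thetas[i],
        )
        members.append(CohortMember(record=rec, pspec=pspec, exponent=float(exponents[i]), data_seed=int(data_seeds[i])))
    return members


def cohort_table(members: list[CohortMember]) -> pd.DataFrame:
    """The cohort covariate/QST table written as CSV by :func:`write_cohort`."""
    rows = []
    for m in members:
        r = m.record
        rows.append(
            {
                "subject_id": r.subject_id,
                "age": r.age,
                "sex": r.sex,
                "cycle_day": r.cycle_day if r.cycle_day is not None else pd.NA,
                "cpt_C": r.cpt_C,
                "hpt_C": r.hpt_C,
                "mpt_mN": r.mpt_mN,
            }
        )
    return pd.DataFrame(rows)


def nuisance_design(table: pd.DataFrame) -> np.ndarray:
    """Nuisance matrix (age, sex 0/1, cycle day with males at 0) from a
    cohort table; the sex indicator absorbs the male offset."""
    sex01 = (table["sex"].astype(str) == "F").astype(float).to_numpy()
    cycle = pd.to_numeric(table["cycle_day"], errors="coerce").fillna(0).to_numpy(dtype=float)
    return np.column_stack([table["age"].to_numpy(dtype=float), sex01, cycle])


def write_cohort(members: list[CohortMember], outdir: str | Path, write_bold: bool = True) -> Path:
    """Write the cohort to disk: QST/covariate CSV plus, optionally, each
    subject's phantom NIfTI volumes, masks and confound text files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = cohort_table(members)
    csv_path = outdir / "cohort.csv"
    table.to_csv(csv_path, index=False)
    if write_bold:
        for m in members:
            sdir = outdir / m.record.subject_id
            sdir.mkdir(exist_ok=True)
            vol, roi, brain, g = m.make_phantom()
            save_volume(vol, sdir / "bold.nii.gz")
            save_mask(roi, sdir / "roi.nii.gz")
            save_mask(brain, sdir / "brain.nii.gz")
            np.savetxt(sdir / "confounds.txt", m.make_confounds(), fmt="%.6f")
            np.savetxt(sdir / "true_gradient.txt", g, fmt="%.8f")
    return csv_path
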