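"""Digital tumor phantom: ground truth, acquisition simulators, treatment effect.

The phantom emulates a subcutaneous hind-limb tumor: an axis-aligned
ellipsoidal tumor (core plus a 2-voxel rim shell) embedded in muscle under a
thin skin layer, surrounded by background air, with a smooth low-order B1
deviation field (the flip-angle scale ``zeta``). Every acquisition the
analysis pipeline consumes — variable-flip-angle, multi-echo, multi-b-value
diffusion, and dynamic contrast-enhanced series — is simulated from the same
steady-state signal equations the fits invert, so noiseless simulate->fit
round trips are exact up to solver tolerance.

A parametric treatment effect encodes the response pattern of vascular-
targeted photodynamic therapy: a contiguous non-enhanced tumor core
(K^trans = 0), reduced K^trans elsewhere in the tumor, and late diffusion
and relaxation-rate changes.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .containers import ContrastAxis, ImageStack
from .dce import AIFModel, tk_forward
from .errors import ConfigError
from .protocol import AcquisitionProtocol, VoxelGrid, compute_fluence
from .spgr import spgr_signal

__all__ = [
    "CompartmentParams",
    "DEFAULT_COMPARTMENTS",
    "PhantomGroundTruth",
    "TreatmentEffectSpec",
    "DEFAULT_EFFECTS",
    "NoiseSpec",
    "LABELS",
    "build_phantom",
    "apply_treatment_effect",
    "simulate_b1_series",
    "simulate_vfa_series",
    "simulate_echo_series",
    "simulate_dwi_series",
    "simulate_dce_series",
    "add_noise",
    "compute_fluence",
]

LABELS = {
    "background": 0,
    "muscle": 1,
    "skin": 2,
    "tumor-rim": 3,
    "tumor-core": 4,
}


@dataclass(frozen=True)
class CompartmentParams:
    """True tissue parameters of one phantom compartment."""

    t1_ms: float
    t2_ms: float
    adc_mm2_s: float
    ktrans_per_min: float
    ve_fraction: float
    m0: float = 1000.0


DEFAULT_COMPARTMENTS: dict[str, CompartmentParams] = {
    "tumor-core": CompartmentParams(2000.0, 40.0, 0.7e-3, 0.2, 0.3),
    "tumor-rim": CompartmentParams(2000.0, 40.0, 0.7e-3, 0.2, 0.3),
    "muscle": CompartmentParams(1800.0, 25.0, 1.4e-3, 0.08, 0.12),
    "skin": CompartmentParams(1600.0, 30.0, 1.2e-3, 0.10, 0.20),
    "background": CompartmentParams(1.0, 1.0, 0.0, 0.0, 0.0, m0=0.0),
}


@dataclass
class PhantomGroundTruth:
    """Per-voxel true parameters plus compartment labels.

    ``adc_mm2_s`` carries one value per diffusion direction (trailing axis);
    ``tumor_r2`` is the squared normalized ellipsoid radius of each tumor
    voxel (infinity outside the tumor), used to carve contiguous core regions.
    """

    grid: VoxelGrid
    t1_ms: np.ndarray
    t2_ms: np.ndarray
    adc_mm2_s: np.ndarray
    ktrans_per_min: np.ndarray
    ve_fraction: np.ndarray
    zeta: np.ndarray
    m0: np.ndarray
    labels: np.ndarray
    tumor_r2: np.ndarray

    def __post_init__(self) -> None:
        if np.any((self.ve_fraction < 0) | (self.ve_fraction > 1)):
            raise ConfigError("ve must lie in [0, 1]")
        if np.any(self.ktrans_per_min < 0):
            raise ConfigError("ktrans must be non-negative")
        if np.any(self.zeta <= 0):
            raise ConfigError("zeta must be strictly positive")
        if np.any(self.m0[self.labels == LABELS["background"]] != 0):
            raise ConfigError("background voxels must have m0 = 0")

    @property
    def tumor_mask(self) -> np.ndarray:
        return (self.labels == LABELS["tumor-core"]) | (
            self.labels == LABELS["tumor-rim"]
        )

    @property
    def tissue_mask(self) -> np.ndarray:
        return self.labels != LABELS["background"]

    @property
    def n_directions(self) -> int:
        return self.adc_mm2_s.shape[-1]

    def copy(self) -> "PhantomGroundTruth":
        return copy.deepcopy(self)


@dataclass(frozen=True)
class TreatmentEffectSpec:
    """Parametric change applied to tumor voxels at one post-treatment timepoint.

    A contiguous core covering ``nonenhanced_core_fraction`` of the tumor
    gets K^trans = 0 (vascular shutdown); the remaining tumor voxels are
    rescaled. Relaxation changes are expressed as multipliers on the rates
    R1 = 1/T1 and R2 = 1/T2.
    """

    timepoint: str = "post"
    nonenhanced_core_fraction: float = 0.0
    ktrans_scale: float = 1.0
    ve_shift: float = 0.0
    adc_scale: float = 1.0
    r1_scale: float = 1.0
    r2_scale: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.nonenhanced_core_fraction <= 1.0:
            raise ConfigError("nonenhanced_core_fraction must lie in [0, 1]")
        for name in ("ktrans_scale", "adc_scale", "r1_scale", "r2_scale"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be strictly positive")


# Qualitative response pattern of vascular-targeted PDT, encoded per timepoint:
# immediate partial shutdown with reduced Ktrans and expanded EES; near-total
# shutdown with raised ADC at 24 h; additional R1/R2 increases only at 72 h.
DEFAULT_EFFECTS: dict[str, TreatmentEffectSpec] = {
    "baseline": TreatmentEffectSpec(timepoint="baseline"),
    "post": TreatmentEffectSpec(
        timepoint="post", nonenhanced_core_fraction=0.45, ktrans_scale=0.5, ve_shift=0.15
    ),
    "24h": TreatmentEffectSpec(
        timepoint="24h", nonenhanced_core_fraction=0.77, ktrans_scale=0.4, adc_scale=1.3
    ),
    "72h": TreatmentEffectSpec(
        timepoint="72h",
        nonenhanced_core_fraction=0.77,
        ktrans_scale=0.4,
        adc_scale=1.6,
        r1_scale=1.25,
        r2_scale=1.25,
    ),
}


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise model for simulated stacks.

    ``gaussian`` adds zero-mean noise of standard deviation ``sigma`` (signal
    units) to each sample; ``rician`` replaces each sample by the magnitude
    of the complex signal with independent Gaussian noise on both channels —
    the distribution of magnitude MR data, approximately Gaussian at high SNR.
    """

    model: str = "gaussian"
    sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("gaussian", "rician"):
            raise ConfigError(f"unknown noise model {self.model!r}")
        if self.sigma < 0:
            raise ConfigError("sigma must be non-negative")


def _zeta_field(grid: VoxelGrid, seed: int, zeta_range: tuple[float, float]) -> np.ndarray:
    """Smooth second-order polynomial field rescaled into ``zeta_range``."""
    lo, hi = zeta_range
    if not 0 < lo <= hi:
        raise ConfigError("zeta range must be positive and ordered")
    rng = np.random.default_rng(seed)
    x, y, z = np.meshgrid(
        np.linspace(-1, 1, grid.nx),
        np.linspace(-1, 1, grid.ny),
        np.linspace(-1, 1, grid.nz) if grid.nz > 1 else np.zeros(1),
        indexing="ij",
    )
    c = rng.standard_normal(10)
    p = (
        c[0]
        + c[1] * x + c[2] * y + c[3] * z
        + c[4] * x * x + c[5] * y * y + c[6] * z * z
        + c[7] * x * y + c[8] * x * z + c[9] * y * z
    )
    span = p.max() - p.min()
    if span < 1e-12 or lo == hi:
        return np.full(grid.shape, 0.5 * (lo + hi))
    return lo + (p - p.min()) * (hi - lo) / span


def build_phantom(
    grid: VoxelGrid,
    compartment_params: dict[str, CompartmentParams] | None = None,
    seed: int = 0,
    tumor_semiaxes_vox: tuple[float, float, float] | None = None,
    rim_thickness_vox: float = 2.0,
    zeta_range: tuple[float, float] = (0.9, 1.1),
    n_directions: int = 3,
) -> PhantomGroundTruth:
    """Assemble the ground-truth phantom on the given grid.

    Geometry: a 2-voxel in-plane background margin, a 1-voxel skin ring
    inside it, muscle filling the interior, and a centred axis-aligned
    ellipsoidal tumor whose outer ``rim_thickness_vox`` shell is labelled
    rim and whose interior is core. The ADC is isotropic (identical per
    direction). Deterministic given ``seed``.
    """
    params = dict(DEFAULT_COMPARTMENTS if compartment_params is None else compartment_params)
    unknown = set(params) - set(LABELS)
    if unknown:
        raise ConfigError(f"unknown compartment(s) in table: {sorted(unknown)}")
    missing = set(LABELS) - set(params)
    if missing:
        raise ConfigError(f"compartment table missing: {sorted(missing)}")

    if tumor_semiaxes_vox is None:
        tumor_semiaxes_vox = (0.30 * grid.nx, 0.30 * grid.ny, max(0.40 * grid.nz, 1.0))
    ax, ay, az = tumor_semiaxes_vox

    labels = np.full(grid.shape, LABELS["muscle"], dtype=np.int8)
    ii, jj, kk = np.meshgrid(
        np.arange(grid.nx), np.arange(grid.ny), np.arange(grid.nz), indexing="ij"
    )
    margin = 2
    background = (
        (ii < margin) | (ii >= grid.nx - margin) | (jj < margin) | (jj >= grid.ny - margin)
    )
    skin = (
        (ii == margin) | (ii == grid.nx - margin - 1)
        | (jj == margin) | (jj == grid.ny - margin - 1)
    ) & ~background
    labels[background] = LABELS["background"]
    labels[skin] = LABELS["skin"]

    cx, cy, cz = (grid.nx - 1) / 2, (grid.ny - 1) / 2, (grid.nz - 1) / 2
    r2 = ((ii - cx) / ax) ** 2 + ((jj - cy) / ay) ** 2 + ((kk - cz) / az) ** 2
    tumor = (r2 <= 1.0) & (labels == LABELS["muscle"])
    # core: shrink every semi-axis by the rim thickness (floored at a sliver)
    core_axes = (
        max(ax - rim_thickness_vox, 0.25 * ax),
        max(ay - rim_thickness_vox, 0.25 * ay),
        max(az - rim_thickness_vox, 0.25 * az),
    )
    r2_core = (
        ((ii - cx) / core_axes[0]) ** 2
        + ((jj - cy) / core_axes[1]) ** 2
        + ((kk - cz) / core_axes[2]) ** 2
    )
    labels[tumor] = LABELS["tumor-rim"]
    labels[tumor & (r2_core <= 1.0)] = LABELS["tumor-core"]

    shape = grid.shape
    arrays = {
        "t1_ms": np.empty(shape),
        "t2_ms": np.empty(shape),
        "ktrans_per_min": np.empty(shape),
        "ve_fraction": np.empty(shape),
        "m0": np.empty(shape),
    }
    adc = np.empty(shape)
    for name, code in LABELS.items():
        p = params[name]
        sel = labels == code
        arrays["t1_ms"][sel] = p.t1_ms
        arrays["t2_ms"][sel] = p.t2_ms
        arrays["ktrans_per_min"][sel] = p.ktrans_per_min
        arrays["ve_fraction"][sel] = p.ve_fraction
        arrays["m0"][sel] = p.m0
        adc[sel] = p.adc_mm2_s

    return PhantomGroundTruth(
        grid=grid,
        adc_mm2_s=np.repeat(adc[..., None], n_directions, axis=-1),
        zeta=_zeta_field(grid, seed, zeta_range),
        labels=labels,
        tumor_r2=np.where(tumor, r2, np.inf),
        **arrays,
    )


def apply_treatment_effect(
    gt: PhantomGroundTruth, effect: TreatmentEffectSpec, seed: int = 0
) -> PhantomGroundTruth:
    """Return a new ground truth with the treatment effect applied to the tumor.

    The non-enhanced core is the contiguous, innermost
    ``nonenhanced_core_fraction`` of tumor voxels ranked by ellipsoid radius.
    Non-tumor voxels are untouched; the input is never mutated. ``seed`` is
    accepted for interface symmetry — the core carving is deterministic.
    """
    out = gt.copy()
    tumor = gt.tumor_mask
    n_tumor = int(tumor.sum())
    if n_tumor == 0:
        return out

    flat_order = np.argsort(gt.tumor_r2, axis=None, kind="stable")
    n_core = int(round(effect.nonenhanced_core_fraction * n_tumor))
    core = np.zeros(gt.grid.shape, dtype=bool)
    core.ravel()[flat_order[:n_core]] = True
    periphery = tumor & ~core

    out.ktrans_per_min[core] = 0.0
    out.ktrans_per_min[periphery] *= effect.ktrans_scale
    out.ve_fraction[tumor] = np.clip(out.ve_fraction[tumor] + effect.ve_shift, 0.0, 1.0)
    out.adc_mm2_s[tumor, :] *= effect.adc_scale
    out.t1_ms[tumor] /= effect.r1_scale
    out.t2_ms[tumor] /= effect.r2_scale
    return out


def simulate_vfa_series(
    gt: PhantomGroundTruth, protocol: AcquisitionProtocol
) -> ImageStack:
    """Variable-flip-angle SPGR series; the actual angle per voxel is zeta x nominal."""
    flips = np.asarray(protocol.flip_deg_list, dtype=float)
    if flips.size < 2:
        raise ConfigError("VFA simulation needs >= 2 flip angles")
    alpha = np.deg2rad(flips) * gt.zeta[..., None]
    r1 = 1000.0 / gt.t1_ms
    frames = spgr_signal(gt.m0[..., None], alpha, protocol.tr_ms, r1[..., None])
    return ImageStack(gt.grid, frames, ContrastAxis("flip", flips))


def simulate_b1_series(
    gt: PhantomGroundTruth, protocol: AcquisitionProtocol
) -> ImageStack:
    """Flip-angle-correction series around the 180 degree signal null.

    Signal follows the absolute-valued linear null model
    S = m0 * (pi/180) * |zeta * FA_n - 180|: magnitude data vanish where the
    actual flip angle crosses 180 degrees and grow linearly on either side
    (the small-angle expansion of |sin| about the null). The long-TR
    acquisition makes T1 weighting negligible, so only m0 scales the signal.
    """
    flips = np.asarray(protocol.b1_flip_deg_list, dtype=float)
    frames = (
        gt.m0[..., None]
        * (np.pi / 180.0)
        * np.abs(gt.zeta[..., None] * flips - 180.0)
    )
    return ImageStack(gt.grid, frames, ContrastAxis("flip", flips))


def simulate_echo_series(
    gt: PhantomGroundTruth, protocol: AcquisitionProtocol
) -> ImageStack:
    """Multi-echo series: S = m0 * exp(-TE/T2), one frame per echo time."""
    tes = np.asarray(protocol.te_list_ms, dtype=float)
    if tes.size < 2:
        raise ConfigError("echo simulation needs >= 2 echo times")
    frames = gt.m0[..., None] * np.exp(-tes / gt.t2_ms[..., None])
    return ImageStack(gt.grid, frames, ContrastAxis("echo", tes))


def simulate_dwi_series(
    gt: PhantomGroundTruth, protocol: AcquisitionProtocol
) -> ImageStack:
    """Diffusion series, direction-major frame order: S = m0 * exp(-b * ADC_dir)."""
    bvals = np.asarray(protocol.b_values, dtype=float)
    if 0.0 not in bvals:
        raise ConfigError("b-values must include 0")
    ndir = protocol.n_directions
    if gt.n_directions < ndir:
        raise ConfigError("ground truth carries fewer diffusion directions than protocol")
    frames = []
    coords = []
    for d in range(ndir):
        adc_d = gt.adc_mm2_s[..., d]
        for b in bvals:
            frames.append(gt.m0 * np.exp(-b * adc_d))
            coords.append((d, b))
    return ImageStack(
        gt.grid,
        np.stack(frames, axis=-1),
        ContrastAxis("bvalue-direction", np.asarray(coords, dtype=float)),
    )


def simulate_dce_series(
    gt: PhantomGroundTruth, protocol: AcquisitionProtocol, aif: AIFModel
) -> ImageStack:
    """Dynamic contrast-enhanced SPGR series.

    Tissue concentration follows the Tofts-Kermode forward model driven by
    the AIF; concentration raises R1 through the relaxivity, and signal
    follows the SPGR equation at the dynamic flip angle (zeta-corrected) and
    TR. Frames before the injection time carry pure pre-contrast signal, and
    voxels with K^trans = 0 stay flat at their pre-contrast level.
    """
    times = protocol.dce_times_s
    shape = gt.grid.shape
    kt = gt.ktrans_per_min.ravel()
    ve = gt.ve_fraction.ravel()
    # closed-form concentration for every voxel, vectorized over (voxel, time)
    ct = tk_forward(kt, np.where(kt > 0, ve, 1.0), aif, times).reshape(shape + times.shape)
    r1_t = (1000.0 / gt.t1_ms)[..., None] + protocol.r1_relaxivity * ct
    alpha = np.deg2rad(protocol.dce_flip_deg) * gt.zeta
    frames = spgr_signal(gt.m0[..., None], alpha[..., None], protocol.dce_tr_ms, r1_t)
    return ImageStack(gt.grid, frames, ContrastAxis("time", times))


def add_noise(stack: ImageStack, noise: NoiseSpec) -> ImageStack:
    """Seeded measurement noise; sigma = 0 returns an identical copy."""
    rng = np.random.default_rng(noise.seed)
    frames = stack.frames
    if noise.sigma == 0:
        noisy = frames.copy()
    elif noise.model == "gaussian":
        noisy = frames + rng.normal(0.0, noise.sigma, size=frames.shape)
    else:  # rician: magnitude of complex signal with noise on both channels
        real = frames + rng.normal(0.0, noise.sigma, size=frames.shape)
        imag = rng.normal(0.0, noise.sigma, size=frames.shape)
        noisy = np.hypot(real, imag)
    return ImageStack(stack.grid, noisy, stack.contrast_axis)
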