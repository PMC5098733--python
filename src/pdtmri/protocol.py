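"""Acquisition protocol and voxel-grid geometry.

The protocol bundles every sequence parameter the voxelwise fits consume:
repetition time and flip angles of the variable-flip-angle (VFA) spoiled
gradient-echo T1 series, the echo-time ladder of the T2 series, the b-values
and gradient directions of the diffusion series, and the timing, flip angle,
dose and contrast relaxivity of the dynamic contrast-enhanced (DCE) series.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigError

__all__ = [
    "AcquisitionProtocol",
    "VoxelGrid",
    "default_protocol",
    "default_grid",
    "compute_fluence",
]


@dataclass(frozen=True)
class VoxelGrid:
    """Matrix size and voxel geometry of a multi-slice acquisition.

    Slices tile space at a pitch of ``slice_thickness_mm + slice_gap_mm``;
    the voxel volume used for ROI volume integration includes the gap.
    """

    nx: int
    ny: int
    nz: int
    dx_mm: float
    dy_mm: float
    slice_thickness_mm: float = 1.0
    slice_gap_mm: float = 0.1

    def __post_init__(self) -> None:
        if min(self.nx, self.ny, self.nz) < 1:
            raise ConfigError("grid dimensions must be >= 1")
        if min(self.dx_mm, self.dy_mm, self.slice_thickness_mm) <= 0:
            raise ConfigError("voxel sizes must be positive")
        if self.slice_gap_mm < 0:
            raise ConfigError("slice gap must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.nx, self.ny, self.nz)

    @property
    def slice_pitch_mm(self) -> float:
        return self.slice_thickness_mm + self.slice_gap_mm

    @property
    def voxel_volume_mm3(self) -> float:
        """dx * dy * (thickness + gap) — the volume one voxel represents."""
        return self.dx_mm * self.dy_mm * self.slice_pitch_mm

    def with_nz(self, nz: int, thickness_mm: float, gap_mm: float = 0.0) -> "VoxelGrid":
        return replace(
            self, nz=nz, slice_thickness_mm=thickness_mm, slice_gap_mm=gap_mm
        )


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Sequence parameters for all four quantitative series.

    Defaults reproduce a 7 T small-animal tumor protocol: VFA T1 mapping with
    TR = 20 ms and 7 flip angles (2-20 deg), 7 echo times (0.9-82.6 ms),
    diffusion weighting b = 0/100/200/400 s/mm^2 in 3 orthogonal directions,
    and a dynamic series with TR = 3 ms, flip 7 deg, 3.5 s temporal
    resolution for 15 min with contrast injected 2 min after scan start
    (0.3 mmol Gd/kg, r1 = 3.53 mM^-1 s^-1 at 7 T).
    """

    tr_ms: float = 20.0
    te_list_ms: tuple[float, ...] = (0.9, 14.5, 28.1, 41.7, 55.3, 68.9, 82.6)
    flip_deg_list: tuple[float, ...] = (2.0, 3.0, 5.0, 7.0, 10.0, 13.0, 20.0)
    b1_flip_deg_list: tuple[float, ...] = (145.0, 180.0, 215.0)
    b_values: tuple[float, ...] = (0.0, 100.0, 200.0, 400.0)
    n_directions: int = 3
    dce_tr_ms: float = 3.0
    dce_flip_deg: float = 7.0
    dt_s: float = 3.5
    total_duration_s: float = 900.0
    injection_time_s: float = 120.0
    dose_mmol_per_kg: float = 0.3
    r1_relaxivity: float = 3.53

    def __post_init__(self) -> None:
        positives = {
            "tr_ms": self.tr_ms,
            "dce_tr_ms": self.dce_tr_ms,
            "dce_flip_deg": self.dce_flip_deg,
            "dt_s": self.dt_s,
            "total_duration_s": self.total_duration_s,
            "injection_time_s": self.injection_time_s,
            "dose_mmol_per_kg": self.dose_mmol_per_kg,
            "r1_relaxivity": self.r1_relaxivity,
        }
        for name, value in positives.items():
            if value <= 0:
                raise ConfigError(f"{name} must be strictly positive, got {value}")
        if any(te <= 0 for te in self.te_list_ms):
            raise ConfigError("echo times must be strictly positive")
        if any(fa <= 0 for fa in self.flip_deg_list):
            raise ConfigError("flip angles must be strictly positive")
        if any(b < 0 for b in self.b_values):
            raise ConfigError("b-values must be non-negative")
        if self.n_directions < 1:
            raise ConfigError("n_directions must be >= 1")
        if self.injection_time_s >= self.total_duration_s:
            raise ConfigError("injection_time_s must precede total_duration_s")

    @property
    def dce_times_s(self) -> np.ndarray:
        """Frame acquisition times of the dynamic series (s from scan start)."""
        return np.arange(0.0, self.total_duration_s, self.dt_s)

    @property
    def n_pre_injection_frames(self) -> int:
        return int(np.sum(self.dce_times_s < self.injection_time_s))


def default_protocol() -> AcquisitionProtocol:
    return AcquisitionProtocol()


def default_grid(nx: int = 128, ny: int = 128, nz: int = 16) -> VoxelGrid:
    """In-plane 4x4 cm^2 FOV at the given matrix, 1.0 mm slices with 0.1 mm gap."""
    return VoxelGrid(
        nx=nx,
        ny=ny,
        nz=nz,
        dx_mm=40.0 / nx,
        dy_mm=40.0 / ny,
        slice_thickness_mm=1.0,
        slice_gap_mm=0.1,
    )


def compute_fluence(irradiance_mw_per_cm2: float, duration_s: float) -> float:
    """Light dose at the tissue surface, in J/cm^2.

    Fluence = irradiance (W/cm^2) x exposure duration (s); e.g. 200 mW/cm^2
    delivered for 600 s gives 120 J/cm^2.
    """
    if irradiance_mw_per_cm2 < 0 or duration_s < 0:
        raise ValueError("irradiance and duration must be non-negative")
    return irradiance_mw_per_cm2 * 1e-3 * duration_s
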