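"""Dynamic contrast-enhanced (DCE) MRI analysis.

Covers the full tracer-kinetic chain: evaluation of a bi-exponential
arterial input function (AIF), the standard one-compartment Tofts-Kermode
forward model and its voxelwise nonlinear fit, conversion of dynamic signal
to contrast-agent concentration through the SPGR equation, area under the
concentration curve (AUC), enhancement classification, and the quality
filters that decide which tumor voxels enter K^trans / v_e averages.

Units: K^trans is carried in min^-1 at every public surface and converted
to s^-1 exactly once, inside the forward model; concentrations are mM,
times are seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .containers import ImageStack, ParameterMap
from .errors import ProtocolError
from .protocol import AcquisitionProtocol, VoxelGrid
from .spgr import spgr_amplitude_from_signal, spgr_invert_to_r1

__all__ = [
    "AIFModel",
    "ConcentrationSeries",
    "TKFitResultMaps",
    "ToftsModel",
    "ToftsResults",
    "default_aif",
    "evaluate_aif",
    "tk_forward",
    "signal_to_concentration",
    "classify_enhancement",
    "compute_auc",
    "fit_tk_map",
    "apply_qc_filters",
]


@dataclass(frozen=True)
class AIFModel:
    """Bi-exponential plasma concentration model.

    Cp(t) = A1*exp(-(t-onset)/tau1) + A2*exp(-(t-onset)/tau2) for t >= onset,
    zero before bolus arrival. Defaults are a mouse population AIF for a
    0.3 mmol/kg Gd dose: A1 = 5.36 mM, A2 = 1.27 mM, tau1 = 5.36 s,
    tau2 = 915 s.
    """

    a1_mM: float = 5.36
    a2_mM: float = 1.27
    tau1_s: float = 5.36
    tau2_s: float = 915.0
    onset_s: float = 120.0

    def __post_init__(self) -> None:
        if self.a1_mM < 0 or self.a2_mM < 0:
            raise ValueError("AIF amplitudes must be non-negative")
        if self.tau1_s <= 0 or self.tau2_s <= 0:
            raise ValueError("AIF time constants must be strictly positive")


def default_aif(onset_s: float = 120.0) -> AIFModel:
    return AIFModel(onset_s=onset_s)


def evaluate_aif(aif: AIFModel, times_s) -> np.ndarray:
    """Plasma concentration Cp(t) in mM; zero before bolus onset."""
    t = np.asarray(times_s, dtype=float) - aif.onset_s
    cp = aif.a1_mM * np.exp(-np.clip(t, 0, None) / aif.tau1_s) + aif.a2_mM * np.exp(
        -np.clip(t, 0, None) / aif.tau2_s
    )
    return np.where(t >= 0, cp, 0.0)


def tk_forward(ktrans_per_min, ve_fraction, aif: AIFModel, times_s) -> np.ndarray:
    """Tofts-Kermode tissue concentration, closed form (mM).

    Ct(t) = K^trans * int_0^t Cp(tau) exp(-K^trans (t - tau)/v_e) dtau.
    With the bi-exponential AIF the convolution evaluates to a sum of
    exponentials per AIF term:

        Ct = K^trans * sum_i A_i (exp(-t'/tau_i) - exp(-kep t')) / (kep - 1/tau_i)

    with t' = t - onset and kep = K^trans/v_e (the min^-1 -> s^-1 conversion
    happens here and only here). ``ktrans_per_min`` and ``ve_fraction`` may be
    arrays of matching shape; the output gains a trailing time axis.

    A zero K^trans yields an identically zero curve; a positive K^trans with
    v_e = 0 has an undefined kernel and raises ``ValueError``.
    """
    kt = np.asarray(ktrans_per_min, dtype=float)
    ve = np.asarray(ve_fraction, dtype=float)
    if np.any(kt < 0):
        raise ValueError("ktrans must be non-negative")
    if np.any((kt > 0) & (ve <= 0)):
        raise ValueError("ve must be positive wherever ktrans > 0")

    scalar_in = kt.ndim == 0 and ve.ndim == 0
    kt, ve = np.broadcast_arrays(np.atleast_1d(kt), np.atleast_1d(ve))
    t = np.asarray(times_s, dtype=float) - aif.onset_s
    tp = np.clip(t, 0.0, None)

    kt_s = kt[..., None] / 60.0
    with np.errstate(divide="ignore", invalid="ignore"):
        kep = np.where(kt > 0, kt_s[..., 0] / ve, 0.0)[..., None]

    ct = np.zeros(kt.shape + t.shape)
    for amp, tau in ((aif.a1_mM, aif.tau1_s), (aif.a2_mM, aif.tau2_s)):
        denom = kep - 1.0 / tau
        with np.errstate(divide="ignore", invalid="ignore"):
            generic = (np.exp(-tp / tau) - np.exp(-kep * tp)) / denom
        # kep == 1/tau limit: A * t' * exp(-kep t')
        degenerate = tp * np.exp(-kep * tp)
        term = np.where(np.abs(denom) > 1e-12, generic, degenerate)
        ct = ct + amp * kt_s * term
    ct = np.where((t >= 0) & (kt[..., None] > 0), ct, 0.0)
    return ct[0] if scalar_in else ct


def _tk_value_and_grad(kt_per_min: float, ve: float, aif: AIFModel, times_s: np.ndarray):
    """Closed-form Ct(t) with analytic gradients wrt (K^trans [min^-1], v_e).

    Used by the voxelwise fit; shares the forward model's algebra. The
    degenerate kep == 1/tau direction is handled by clamping the denominator,
    which only perturbs the gradient on a measure-zero parameter set.
    """
    tp = np.clip(times_s - aif.onset_s, 0.0, None)
    kt_s = kt_per_min / 60.0
    kep = kt_s / ve
    g = np.zeros_like(tp)
    gp = np.zeros_like(tp)
    e_kep = np.exp(-kep * tp)
    for amp, tau in ((aif.a1_mM, aif.tau1_s), (aif.a2_mM, aif.tau2_s)):
        denom = kep - 1.0 / tau
        denom = np.sign(denom) * max(abs(denom), 1e-12) if denom != 0 else 1e-12
        gi = (np.exp(-tp / tau) - e_kep) / denom
        g += amp * gi
        gp += amp * (tp * e_kep - gi) / denom
    ct = kt_s * g
    d_kt = (g + kt_s * gp / ve) / 60.0
    d_ve = -(kt_s**2) / ve**2 * gp
    mask = times_s >= aif.onset_s
    return ct * mask, d_kt * mask, d_ve * mask


@dataclass
class ConcentrationSeries:
    """Per-voxel contrast-agent concentration over the dynamic frames.

    Pre-injection frames are passed through the same signal-to-concentration
    conversion as the rest, so their scatter is an apparent-concentration
    noise level usable as a per-voxel enhancement threshold. Frames where the
    SPGR inversion was undefined carry NaN.
    """

    grid: VoxelGrid
    times_s: np.ndarray
    conc_mM: np.ndarray  # (nx, ny, nz, n_frames)
    r1_pre_per_s: np.ndarray
    injection_time_s: float
    valid_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.conc_mM = np.asarray(self.conc_mM, dtype=float)
        if self.conc_mM.shape != self.grid.shape + self.times_s.shape:
            raise ProtocolError("concentration array does not match grid x times")
        if self.valid_mask is None:
            self.valid_mask = np.isfinite(self.conc_mM).any(axis=-1)

    @property
    def pre_frames(self) -> np.ndarray:
        return np.flatnonzero(self.times_s < self.injection_time_s)

    @property
    def post_frames(self) -> np.ndarray:
        return np.flatnonzero(self.times_s >= self.injection_time_s)


def signal_to_concentration(
    dyn: ImageStack,
    r1_pre_map: ParameterMap,
    protocol: AcquisitionProtocol,
    zeta_map: ParameterMap | None = None,
) -> ConcentrationSeries:
    """Convert a dynamic SPGR series to contrast concentration, voxel by voxel.

    Per voxel: (i) estimate the effective amplitude A = M0 sin(alpha) from
    the mean pre-injection signal and the mapped pre-contrast R1 by inverting
    the SPGR equation at the (B1-corrected) dynamic flip angle; (ii) invert
    every frame to R1(t); (iii) [CA](t) = (R1(t) - R1_pre) / r1 with r1 the
    contrast relaxivity.
    """
    if dyn.contrast_axis.kind != "time":
        raise ProtocolError("dynamic stack must carry a time contrast axis")
    times = dyn.contrast_axis.values
    pre = times < protocol.injection_time_s
    if not pre.any():
        raise ProtocolError("dynamic series has no pre-injection frames")

    zeta = np.ones(dyn.grid.shape) if zeta_map is None else np.where(
        zeta_map.valid_mask, zeta_map.values, 1.0
    )
    alpha = np.deg2rad(protocol.dce_flip_deg) * zeta
    r1_pre = r1_pre_map.values

    s_pre = dyn.frames[..., pre].mean(axis=-1)
    amp = spgr_amplitude_from_signal(s_pre, alpha, protocol.dce_tr_ms, r1_pre)
    with np.errstate(invalid="ignore"):
        r1_t = spgr_invert_to_r1(
            dyn.frames, amp[..., None], alpha[..., None], protocol.dce_tr_ms
        )
        conc = (r1_t - r1_pre[..., None]) / protocol.r1_relaxivity
    valid = r1_pre_map.valid_mask & np.isfinite(conc).any(axis=-1)
    conc = np.where(valid[..., None], conc, np.nan)
    return ConcentrationSeries(
        grid=dyn.grid,
        times_s=times,
        conc_mM=conc,
        r1_pre_per_s=r1_pre,
        injection_time_s=protocol.injection_time_s,
        valid_mask=valid,
    )


def classify_enhancement(
    conc: ConcentrationSeries, sd_multiplier: float = 2.0
) -> np.ndarray:
    """Boolean map of contrast-enhancing voxels.

    A voxel is non-enhanced when the median concentration over all
    post-injection frames is smaller than ``sd_multiplier`` times the
    standard deviation of its pre-injection (apparent-concentration) frames;
    otherwise it is enhanced. Voxels with an invalid conversion are
    non-enhanced.
    """
    pre, post = conc.pre_frames, conc.post_frames
    if pre.size < 3:
        raise ProtocolError("need >= 3 pre-injection frames for a meaningful SD")
    import warnings

    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        median_post = np.nanmedian(conc.conc_mM[..., post], axis=-1)
        sd_pre = np.nanstd(conc.conc_mM[..., pre], axis=-1, ddof=1)
    # median > 0 excludes the degenerate noiseless flat curve (no uptake at all)
    enhanced = (median_post >= sd_multiplier * sd_pre) & (median_post > 0)
    return enhanced & conc.valid_mask & np.isfinite(median_post) & np.isfinite(sd_pre)


def compute_auc(conc: ConcentrationSeries) -> ParameterMap:
    """Area under the concentration curve from injection to the last frame (mM*s)."""
    post = conc.post_frames
    t = conc.times_s[post]
    c = conc.conc_mM[..., post]
    finite = np.isfinite(c)
    # trapezoid over the finite frames only; < 2 finite frames -> invalid
    c_filled = np.where(finite, c, 0.0)
    auc = np.full(conc.grid.shape, np.nan)
    ok = finite.sum(axis=-1) >= 2
    if np.any(ok):
        all_finite = finite.all(axis=-1)
        auc_full = np.trapezoid(c_filled, t, axis=-1)
        auc = np.where(all_finite, auc_full, auc)
        ragged = ok & ~all_finite
        for idx in np.argwhere(ragged):
            i, j, k = idx
            m = finite[i, j, k]
            auc[i, j, k] = np.trapezoid(c[i, j, k][m], t[m])
    return ParameterMap(conc.grid, auc, unit="mM*s", valid_mask=ok & conc.valid_mask)


@dataclass
class TKFitResultMaps:
    """Voxelwise Tofts-Kermode estimates with quality and inclusion flags."""

    grid: VoxelGrid
    ktrans_per_min: ParameterMap
    ve_fraction: ParameterMap
    r_squared: np.ndarray
    time_to_peak_s: np.ndarray
    converged: np.ndarray
    enhanced: np.ndarray | None = None
    included: np.ndarray | None = None


class ToftsModel:
    """Voxelwise standard Tofts-Kermode model bound to a concentration series.

    ``fit()`` runs bounded nonlinear least squares of the closed-form forward
    model against each voxel's measured curve over (K^trans, v_e), with a
    small multi-start grid (log-spaced K^trans x {0.1, 0.4} v_e) and the
    best-SSE start winning. K^trans is bounded to [0, 10] min^-1 and v_e to
    [1e-3, 1]; convergence pinned at a bound is reported, not hidden.
    """

    def __init__(
        self,
        conc: ConcentrationSeries,
        aif: AIFModel,
        mask: np.ndarray | None = None,
        ktrans_bounds: tuple[float, float] = (0.0, 10.0),
        ve_bounds: tuple[float, float] = (1e-3, 1.0),
        ktrans_starts: Sequence[float] = (0.05, 0.5),
        ve_starts: Sequence[float] = (0.1, 0.4),
    ) -> None:
        self.conc = conc
        self.aif = aif
        self.mask = conc.valid_mask if mask is None else (mask & conc.valid_mask)
        self.ktrans_bounds = ktrans_bounds
        self.ve_bounds = ve_bounds
        self.starts = [(kt, ve) for kt in ktrans_starts for ve in ve_starts]

    def fit(self) -> "ToftsResults":
        grid = self.conc.grid
        times = self.conc.times_s
        shape = grid.shape
        kt = np.full(shape, np.nan)
        ve = np.full(shape, np.nan)
        r2 = np.full(shape, np.nan)
        ttp = np.full(shape, np.nan)
        conv = np.zeros(shape, dtype=bool)

        lo = np.array([self.ktrans_bounds[0], self.ve_bounds[0]])
        hi = np.array([self.ktrans_bounds[1], self.ve_bounds[1]])
        aif = self.aif

        for i, j, k in np.argwhere(self.mask):
            y = self.conc.conc_mM[i, j, k]
            finite = np.isfinite(y)
            if finite.sum() < 4:
                continue
            t_fit, y_fit = times[finite], y[finite]
            tss = float(np.sum((y_fit - y_fit.mean()) ** 2))

            def residuals(p):
                return _tk_value_and_grad(p[0], p[1], aif, t_fit)[0] - y_fit

            def jacobian(p):
                _, d_kt, d_ve = _tk_value_and_grad(p[0], p[1], aif, t_fit)
                return np.column_stack([d_kt, d_ve])

            best = None
            for x0 in self.starts:
                try:
                    sol = least_squares(
                        residuals, jac=jacobian, x0=np.clip(x0, lo, hi),
                        bounds=(lo, hi), method="trf",
                        xtol=1e-12, ftol=1e-12, gtol=1e-12,
                    )
                except Exception:
                    continue
                if best is None or sol.cost < best.cost:
                    best = sol
                # an essentially perfect fit cannot be beaten by another start
                if best.cost <= 1e-16 * max(tss, 1e-30):
                    break
            if best is None or not best.success:
                continue
            kt[i, j, k], ve[i, j, k] = best.x
            conv[i, j, k] = True
            sse = 2.0 * best.cost
            r2[i, j, k] = 1.0 - sse / tss if tss > 0 else np.nan
            ttp[i, j, k] = t_fit[np.argmax(y_fit)] - self.conc.injection_time_s

        return ToftsResults(
            model=self,
            maps=TKFitResultMaps(
                grid=grid,
                ktrans_per_min=ParameterMap(grid, kt, "min^-1", conv.copy()),
                ve_fraction=ParameterMap(grid, ve, "dimensionless", conv.copy()),
                r_squared=r2,
                time_to_peak_s=ttp,
                converged=conv,
            ),
        )


@dataclass
class ToftsResults:
    """Fitted Tofts-Kermode maps plus QC composition and a text summary."""

    model: ToftsModel
    maps: TKFitResultMaps

    def apply_qc(
        self,
        enhanced: np.ndarray,
        r2_threshold: float = 0.80,
        ttp_max_s: float = 800.0,
    ) -> tuple[np.ndarray, dict[str, int]]:
        included, counts = apply_qc_filters(
            self.maps, enhanced, r2_threshold=r2_threshold, ttp_max_s=ttp_max_s
        )
        self.maps.enhanced = enhanced
        self.maps.included = included
        return included, counts

    def summary(self) -> str:
        m = self.maps
        lines = [
            "Tofts-Kermode voxelwise fit",
            f"  voxels fitted/converged: {int(self.model.mask.sum())}/{int(m.converged.sum())}",
        ]
        if m.converged.any():
            lines += [
                f"  Ktrans (min^-1): median {np.nanmedian(m.ktrans_per_min.values):.4f}",
                f"  ve (fraction):   median {np.nanmedian(m.ve_fraction.values):.4f}",
                f"  fit R^2:         median {np.nanmedian(m.r_squared):.4f}",
            ]
        if m.included is not None:
            lines.append(f"  included after QC: {int(m.included.sum())}")
        return "\n".join(lines)


def fit_tk_map(
    conc: ConcentrationSeries, aif: AIFModel, mask: np.ndarray | None = None
) -> ToftsResults:
    """Functional wrapper: fit the Tofts-Kermode model over the masked voxels."""
    return ToftsModel(conc, aif, mask=mask).fit()


def apply_qc_filters(
    fits: TKFitResultMaps,
    enhanced: np.ndarray,
    r2_threshold: float = 0.80,
    ttp_max_s: float = 800.0,
) -> tuple[np.ndarray, dict[str, int]]:
    """Compose the four inclusion criteria and count failures per criterion.

    A voxel enters K^trans / v_e averages only if it (1) is enhanced,
    (2) has fit R^2 strictly above ``r2_threshold``, (3) reached its peak
    concentration strictly before ``ttp_max_s`` after injection, and
    (4) has physiologically realistic estimates (K^trans >= 0, 0 <= v_e <= 1).
    The returned counts tally, over converged voxels, how many fail each
    criterion (a voxel can fail several).
    """
    enhanced = np.asarray(enhanced, dtype=bool)
    with np.errstate(invalid="ignore"):
        c1 = enhanced
        c2 = fits.r_squared > r2_threshold
        c3 = fits.time_to_peak_s < ttp_max_s
        kt, ve = fits.ktrans_per_min.values, fits.ve_fraction.values
        c4 = (kt >= 0) & (ve >= 0) & (ve <= 1)
    c2 &= np.isfinite(fits.r_squared)
    c3 &= np.isfinite(fits.time_to_peak_s)
    c4 &= np.isfinite(kt) & np.isfinite(ve)
    included = fits.converged & c1 & c2 & c3 & c4
    conv = fits.converged
    counts = {
        "non_enhanced": int((conv & ~c1).sum()),
        "low_r_squared": int((conv & ~c2).sum()),
        "late_peak": int((conv & ~c3).sum()),
        "nonphysiological": int((conv & ~c4).sum()),
        "included": int(included.sum()),
    }
    return included, counts
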