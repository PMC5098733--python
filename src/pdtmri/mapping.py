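"""Voxelwise relaxometry and diffusion mapping.

Each estimator is a Model class bound to an :class:`ImageStack`; ``fit()``
returns a Results object carrying the parameter maps, a per-voxel fit
quality record, and a ``summary()`` table. Thin functional wrappers
(``fit_flip_angle_map`` etc.) expose the same operations for pipeline code.

Estimator policy: final T1 and T2 estimates come from bounded nonlinear
least squares (correct error weighting at low signal), with the classical
linearized forms used only for initialization. The ADC fit is the log-linear
least-squares slope per diffusion direction, averaged over directions. The
flip-angle correction fits the absolute-valued linear null model by trying
each admissible residual sign pattern and keeping the least-squares best.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .containers import ContrastAxis, ImageStack, ParameterMap
from .errors import ProtocolError
from .protocol import AcquisitionProtocol, VoxelGrid
from .spgr import spgr_signal

__all__ = [
    "FitQuality",
    "FlipAngleModel",
    "FlipAngleResults",
    "VFAT1Model",
    "T1Results",
    "MultiEchoT2Model",
    "T2Results",
    "DiffusionModel",
    "ADCResults",
    "correct_flip_angle",
    "fit_flip_angle_map",
    "fit_t1_vfa",
    "fit_t2_map",
    "fit_adc_map",
]


@dataclass
class FitQuality:
    """Per-voxel goodness of fit: R^2, RMS residual, convergence flag."""

    r_squared: np.ndarray
    residual_norm: np.ndarray
    converged: np.ndarray


def _r_squared(y: np.ndarray, resid: np.ndarray) -> float:
    tss = float(np.sum((y - y.mean()) ** 2))
    sse = float(np.sum(resid**2))
    return 1.0 - sse / tss if tss > 0 else (1.0 if sse == 0 else np.nan)


def correct_flip_angle(nominal_deg, zeta):
    """Actual flip angle FA_a = zeta * FA_n (degrees)."""
    zeta = np.asarray(zeta, dtype=float)
    if np.any(zeta <= 0):
        raise ValueError("zeta must be strictly positive")
    return zeta * np.asarray(nominal_deg, dtype=float)


class FlipAngleModel:
    """B1 (transmit) correction from a 180-degree signal-null series.

    Magnitude signal around the null is |a*FA_n + b|; the correction factor
    is zeta = -(a/b)*180, mapping nominal to actual flip angle. Because the
    magnitude hides the residual signs, the fit tries each sign split
    consistent with a single null crossing and keeps the least-squares best;
    if two splits tie, the one whose zeta is closer to 1 wins. Voxels with
    b = 0 or zeta outside the plausibility window are marked invalid and
    fall back to zeta = 1.
    """

    def __init__(
        self,
        stack: ImageStack,
        nominal_deg=None,
        zeta_window: tuple[float, float] = (0.5, 1.5),
    ) -> None:
        if nominal_deg is None:
            nominal_deg = stack.contrast_axis.values
        self.nominal_deg = np.asarray(nominal_deg, dtype=float)
        n = self.nominal_deg.size
        if n < 3:
            raise ProtocolError("flip-angle correction needs >= 3 nominal angles")
        if not (self.nominal_deg.min() < 180.0 < self.nominal_deg.max()):
            raise ProtocolError("nominal angles must bracket 180 degrees")
        if stack.n_frames != n:
            raise ProtocolError("stack frame count does not match angle list")
        self.stack = stack
        self.zeta_window = zeta_window

    def fit(self) -> "FlipAngleResults":
        fa = self.nominal_deg
        n = fa.size
        grid = self.stack.grid
        signals = self.stack.frames.reshape(-1, n)  # (V, n)
        nvox = signals.shape[0]

        sum_f, sum_f2 = fa.sum(), (fa**2).sum()
        det = n * sum_f2 - sum_f**2

        best_sse = np.full(nvox, np.inf)
        best_a = np.zeros(nvox)
        best_b = np.zeros(nvox)
        order = np.argsort(fa)
        for split in range(1, n + 1):
            # residual signs: + for the `split` smallest angles, - beyond the null
            sign = np.ones(n)
            sign[order[split:]] = -1.0
            y = signals * sign
            sum_y = y.sum(axis=1)
            sum_fy = y @ fa
            a = (n * sum_fy - sum_f * sum_y) / det
            b = (sum_y - a * sum_f) / n
            model = np.abs(a[:, None] * fa + b[:, None])
            sse = ((model - signals) ** 2).sum(axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                zeta_new = -(a / b) * 180.0
                zeta_old = -(best_a / best_b) * 180.0
            better = sse * (1.0 + 1e-12) < best_sse
            tied = np.isclose(sse, best_sse, rtol=1e-9, atol=0.0) & (
                np.abs(zeta_new - 1.0) < np.abs(zeta_old - 1.0)
            )
            take = better | tied
            best_sse[take] = sse[take]
            best_a[take] = a[take]
            best_b[take] = b[take]

        with np.errstate(divide="ignore", invalid="ignore"):
            zeta = -(best_a / best_b) * 180.0
        lo, hi = self.zeta_window
        valid = (best_b != 0) & np.isfinite(zeta) & (zeta >= lo) & (zeta <= hi)
        valid &= np.isfinite(signals).all(axis=1) & (signals.sum(axis=1) > 0)
        zeta = np.where(valid, zeta, 1.0)  # invalid fallback: uncorrected

        tss = ((signals - signals.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = np.where(tss > 0, 1.0 - best_sse / tss, np.where(best_sse == 0, 1.0, np.nan))
        shape = grid.shape
        quality = FitQuality(
            r_squared=r2.reshape(shape),
            residual_norm=np.sqrt(best_sse / n).reshape(shape),
            converged=valid.reshape(shape),
        )
        zeta_map = ParameterMap(
            grid, zeta.reshape(shape), "dimensionless", valid.reshape(shape)
        )
        return FlipAngleResults(
            model=self,
            zeta_map=zeta_map,
            slope=best_a.reshape(shape),
            intercept=best_b.reshape(shape),
            quality=quality,
        )


@dataclass
class FlipAngleResults:
    model: FlipAngleModel
    zeta_map: ParameterMap
    slope: np.ndarray
    intercept: np.ndarray
    quality: FitQuality

    def summary(self) -> str:
        z = self.zeta_map
        return "\n".join(
            [
                "Flip-angle correction (180-degree null) fit",
                f"  valid voxels: {z.n_valid}/{z.values.size}",
                f"  zeta: median {np.nanmedian(z.values):.4f}, "
                f"range [{np.nanmin(z.values):.4f}, {np.nanmax(z.values):.4f}]",
            ]
        )


class _VoxelwiseNLLS:
    """Shared scaffolding for per-voxel two-parameter nonlinear fits."""

    @staticmethod
    def run(signals, fit_one, shape, n_params=2):
        """``fit_one(y) -> (params, resid) or None``; returns stacked maps + quality."""
        nvox = signals.shape[0]
        params = np.full((nvox, n_params), np.nan)
        r2 = np.full(nvox, np.nan)
        rnorm = np.full(nvox, np.nan)
        conv = np.zeros(nvox, dtype=bool)
        for v in range(nvox):
            y = signals[v]
            if not np.isfinite(y).all() or np.all(y <= 0):
                continue
            out = fit_one(y)
            if out is None:
                continue
            params[v], resid = out
            conv[v] = True
            r2[v] = _r_squared(y, resid)
            rnorm[v] = np.sqrt(np.mean(resid**2))
        return (
            [params[:, i].reshape(shape) for i in range(n_params)],
            FitQuality(r2.reshape(shape), rnorm.reshape(shape), conv.reshape(shape)),
        )


class VFAT1Model:
    """T1 from a variable-flip-angle SPGR series with B1 correction.

    Nominal angles are corrected per voxel through the zeta map before a
    bounded nonlinear least-squares fit of (amplitude, T1) to the SPGR
    signal equation, initialized from the classical linearization
    (S/sin(a) regressed on S/tan(a), whose slope is exp(-TR/T1)). Voxels
    converging onto a T1 bound are marked invalid.
    """

    def __init__(
        self,
        stack: ImageStack,
        protocol: AcquisitionProtocol,
        zeta_map: ParameterMap | None = None,
        t1_bounds_ms: tuple[float, float] = (50.0, 10000.0),
        mask: np.ndarray | None = None,
    ) -> None:
        if stack.n_frames < 2:
            raise ProtocolError("T1 VFA fit needs >= 2 flip angles")
        if zeta_map is not None and zeta_map.grid.shape != stack.grid.shape:
            raise ProtocolError("zeta map grid does not match stack grid")
        self.stack = stack
        self.protocol = protocol
        self.zeta_map = zeta_map
        self.t1_bounds_ms = t1_bounds_ms
        self.mask = mask
        self.nominal_deg = stack.contrast_axis.values

    def fit(self) -> "T1Results":
        grid = self.stack.grid
        tr = self.protocol.tr_ms
        lo_t1, hi_t1 = self.t1_bounds_ms
        signals = self.stack.frames.reshape(-1, self.stack.n_frames)
        if self.zeta_map is None:
            zeta = np.ones(signals.shape[0])
        else:
            zeta = np.where(self.zeta_map.valid_mask, self.zeta_map.values, 1.0).ravel()
        nominal = self.nominal_deg
        e_lo, e_hi = np.exp(-tr / lo_t1), np.exp(-tr / hi_t1)

        def make_fit_one(alpha_rad):
            sa, ta = np.sin(alpha_rad), np.tan(alpha_rad)

            def fit_one(y):
                pos = y > 0
                if pos.sum() < 2:
                    return None
                ylin, xlin = y[pos] / sa[pos], y[pos] / ta[pos]
                xc = xlin - xlin.mean()
                denom = float(xc @ xc)
                slope = float(xc @ ylin) / denom if denom > 0 else np.nan
                slope = np.clip(slope, e_hi, e_lo) if np.isfinite(slope) else 0.5 * (e_lo + e_hi)
                t1_0 = -tr / np.log(slope)
                amp_0 = max(float(np.max(y / sa)), 1e-12)

                def resid(p):
                    return spgr_signal(p[0], alpha_rad, tr, 1000.0 / p[1]) - y

                def jac(p):
                    amp, t1 = p
                    e1 = np.exp(-tr / t1)
                    ca = np.cos(alpha_rad)
                    denom = 1.0 - e1 * ca
                    d_amp = sa * (1.0 - e1) / denom
                    de_dt1 = e1 * tr / t1**2
                    d_t1 = amp * sa * (ca - 1.0) / denom**2 * de_dt1
                    return np.column_stack([d_amp, d_t1])

                sol = least_squares(
                    resid, jac=jac,
                    x0=[amp_0, float(np.clip(t1_0, lo_t1, hi_t1))],
                    bounds=([0.0, lo_t1], [np.inf, hi_t1]),
                    method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12,
                )
                if not sol.success:
                    return None
                # bound-pinned T1 is not a trustworthy estimate
                if sol.x[1] <= lo_t1 * (1 + 1e-6) or sol.x[1] >= hi_t1 * (1 - 1e-6):
                    return None
                return sol.x, sol.fun

            return fit_one

        nvox = signals.shape[0]
        params = np.full((nvox, 2), np.nan)
        r2 = np.full(nvox, np.nan)
        rnorm = np.full(nvox, np.nan)
        conv = np.zeros(nvox, dtype=bool)
        fit_sel = (
            np.ones(nvox, dtype=bool) if self.mask is None else self.mask.ravel()
        )
        for v in range(nvox):
            if not fit_sel[v]:
                continue
            y = signals[v]
            if not np.isfinite(y).all() or np.all(y <= 0):
                continue
            out = make_fit_one(np.deg2rad(correct_flip_angle(nominal, zeta[v])))(y)
            if out is None:
                continue
            params[v], resid_v = out
            conv[v] = True
            r2[v] = _r_squared(y, resid_v)
            rnorm[v] = np.sqrt(np.mean(resid_v**2))

        shape = grid.shape
        t1 = params[:, 1].reshape(shape)
        valid = conv.reshape(shape)
        t1_map = ParameterMap(grid, t1, "ms", valid)
        return T1Results(
            model=self,
            t1_map=t1_map,
            r1_map=t1_map.reciprocal("s^-1"),
            m0_map=ParameterMap(grid, params[:, 0].reshape(shape), "dimensionless", valid),
            quality=FitQuality(r2.reshape(shape), rnorm.reshape(shape), valid),
        )


@dataclass
class T1Results:
    model: VFAT1Model
    t1_map: ParameterMap
    r1_map: ParameterMap
    m0_map: ParameterMap
    quality: FitQuality

    def summary(self) -> str:
        return _map_summary("T1 (VFA SPGR) fit", self.t1_map, self.quality)


class MultiEchoT2Model:
    """T2 from a multi-echo series: bounded NLLS of S = A*exp(-TE/T2).

    Initialized from the log-linear regression on the positive signals;
    voxels whose fit converges onto a T2 bound (e.g. a constant series
    driving T2 toward infinity) are marked invalid.
    """

    def __init__(
        self,
        stack: ImageStack,
        te_list_ms=None,
        t2_bounds_ms: tuple[float, float] = (1.0, 2000.0),
    ) -> None:
        if te_list_ms is None:
            te_list_ms = stack.contrast_axis.values
        self.te = np.asarray(te_list_ms, dtype=float)
        if self.te.size < 2:
            raise ProtocolError("T2 fit needs >= 2 echoes")
        if stack.n_frames != self.te.size:
            raise ProtocolError("stack frame count does not match echo list")
        self.stack = stack
        self.t2_bounds_ms = t2_bounds_ms

    def fit(self) -> "T2Results":
        grid = self.stack.grid
        te = self.te
        lo_t2, hi_t2 = self.t2_bounds_ms
        signals = self.stack.frames.reshape(-1, te.size)

        def fit_one(y):
            pos = y > 0
            if pos.sum() < 2:
                return None
            tec = te[pos] - te[pos].mean()
            slope = float(tec @ np.log(y[pos])) / float(tec @ tec)
            t2_0 = np.clip(-1.0 / slope if slope < 0 else hi_t2, lo_t2, hi_t2)
            amp_0 = max(float(y.max()), 1e-12)

            def resid(p):
                return p[0] * np.exp(-te / p[1]) - y

            def jac(p):
                decay = np.exp(-te / p[1])
                return np.column_stack([decay, p[0] * decay * te / p[1] ** 2])

            sol = least_squares(
                resid, jac=jac,
                x0=[amp_0, float(t2_0)], bounds=([0.0, lo_t2], [np.inf, hi_t2]),
                method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
            if not sol.success:
                return None
            if sol.x[1] <= lo_t2 * (1 + 1e-6) or sol.x[1] >= hi_t2 * (1 - 1e-6):
                return None
            return sol.x, sol.fun

        maps, quality = _VoxelwiseNLLS.run(signals, fit_one, grid.shape)
        t2_map = ParameterMap(grid, maps[1], "ms", quality.converged)
        return T2Results(
            model=self,
            t2_map=t2_map,
            r2_map=t2_map.reciprocal("s^-1"),
            quality=quality,
        )


@dataclass
class T2Results:
    model: MultiEchoT2Model
    t2_map: ParameterMap
    r2_map: ParameterMap
    quality: FitQuality

    def summary(self) -> str:
        return _map_summary("T2 (multi-echo) fit", self.t2_map, self.quality)


class DiffusionModel:
    """Orientation-averaged ADC from a multi-b-value, multi-direction series.

    The per-direction ADC is the negative log-linear least-squares slope of
    signal over b; the orientation-invariant ADC is the arithmetic mean of
    the direction estimates. A stack may carry either the full
    direction-major b x direction layout or a single shared b = 0 frame
    first, which is mirrored into each direction's fit.
    """

    def __init__(
        self,
        stack: ImageStack,
        b_values=None,
        n_directions: int | None = None,
    ) -> None:
        axis = stack.contrast_axis
        if b_values is None or n_directions is None:
            if axis.kind != "bvalue-direction":
                raise ProtocolError("b-values and direction count required")
            coords = axis.values
            n_directions = int(coords[:, 0].max()) + 1
            b_values = np.unique(coords[:, 1])
        self.b = np.asarray(b_values, dtype=float)
        if self.b.size < 2:
            raise ProtocolError("ADC fit needs >= 2 b-values per direction")
        self.ndir = int(n_directions)
        nb = self.b.size
        expected_full = nb * self.ndir
        expected_shared_b0 = (nb - 1) * self.ndir + 1 if 0.0 in self.b else None
        if stack.n_frames == expected_full:
            self.shared_b0 = False
        elif expected_shared_b0 is not None and stack.n_frames == expected_shared_b0:
            self.shared_b0 = True
        else:
            raise ProtocolError(
                f"stack has {stack.n_frames} frames; expected {expected_full} "
                f"(direction-major) or {expected_shared_b0} (shared b=0)"
            )
        self.stack = stack

    def _per_direction_signals(self) -> np.ndarray:
        """(V, ndir, nb) signal array, mirroring a shared b=0 frame if needed."""
        frames = self.stack.frames.reshape(-1, self.stack.n_frames)
        nb = self.b.size
        if not self.shared_b0:
            return frames.reshape(-1, self.ndir, nb)
        if self.b[0] != 0.0:
            raise ProtocolError("shared-b0 layout requires b_values to start at 0")
        b0 = frames[:, :1]
        rest = frames[:, 1:].reshape(-1, self.ndir, nb - 1)
        out = np.empty((frames.shape[0], self.ndir, nb))
        out[:, :, 0] = b0
        out[:, :, 1:] = rest
        return out

    def fit(self) -> "ADCResults":
        grid = self.stack.grid
        b = self.b
        sig = self._per_direction_signals()  # (V, ndir, nb)
        nvox = sig.shape[0]
        ok = np.isfinite(sig).all(axis=(1, 2)) & (sig > 0).all(axis=(1, 2))

        bc = b - b.mean()
        denom = float(bc @ bc)
        adc_dir = np.full((nvox, self.ndir), np.nan)
        with np.errstate(divide="ignore", invalid="ignore"):
            logs = np.where(sig > 0, np.log(np.where(sig > 0, sig, 1.0)), np.nan)
        slopes = np.einsum("vdb,b->vd", logs, bc) / denom
        adc_dir[ok] = -slopes[ok]
        adc_mean = adc_dir.mean(axis=1)
        valid = ok & np.isfinite(adc_mean) & (adc_mean >= 0)

        # quality from pooled log-domain residuals
        pred = -adc_dir[..., None] * b + (
            logs.mean(axis=2, keepdims=True) + adc_dir[..., None] * b.mean()
        )
        resid = logs - pred
        import warnings

        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            tss = np.nansum((logs - np.nanmean(logs, axis=2, keepdims=True)) ** 2, axis=(1, 2))
            sse = np.nansum(resid**2, axis=(1, 2))
            r2 = np.where(tss > 0, 1.0 - sse / tss, np.nan)

        shape = grid.shape
        direction_maps = [
            ParameterMap(grid, adc_dir[:, d].reshape(shape), "mm^2/s", ok.reshape(shape))
            for d in range(self.ndir)
        ]
        mean_map = ParameterMap(grid, adc_mean.reshape(shape), "mm^2/s", valid.reshape(shape))
        quality = FitQuality(
            r_squared=r2.reshape(shape),
            residual_norm=np.sqrt(sse / logs.size * nvox).reshape(shape),
            converged=valid.reshape(shape),
        )
        return ADCResults(
            model=self,
            adc_map=mean_map,
            direction_maps=direction_maps,
            quality=quality,
        )


@dataclass
class ADCResults:
    model: DiffusionModel
    adc_map: ParameterMap
    direction_maps: list[ParameterMap]
    quality: FitQuality

    def summary(self) -> str:
        return _map_summary(
            f"ADC fit ({len(self.direction_maps)} directions, orientation-averaged)",
            self.adc_map,
            self.quality,
        )


def _map_summary(title: str, pmap: ParameterMap, quality: FitQuality) -> str:
    lines = [title, f"  valid voxels: {pmap.n_valid}/{pmap.values.size}"]
    if pmap.n_valid:
        lines.append(
            f"  {pmap.unit}: median {np.nanmedian(pmap.values):.4g}, "
            f"IQR [{np.nanpercentile(pmap.values, 25):.4g}, "
            f"{np.nanpercentile(pmap.values, 75):.4g}]"
        )
        lines.append(f"  median R^2: {np.nanmedian(quality.r_squared):.4f}")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# functional wrappers

def fit_flip_angle_map(stack, nominal_deg=None, zeta_window=(0.5, 1.5)):
    res = FlipAngleModel(stack, nominal_deg, zeta_window).fit()
    return res.zeta_map, res.quality


def fit_t1_vfa(stack, protocol, zeta_map=None):
    res = VFAT1Model(stack, protocol, zeta_map).fit()
    return res.t1_map, res.r1_map, res.quality


def fit_t2_map(stack, te_list_ms=None):
    res = MultiEchoT2Model(stack, te_list_ms).fit()
    return res.t2_map, res.r2_map, res.quality


def fit_adc_map(stack, b_values=None, n_directions=None):
    res = DiffusionModel(stack, b_values, n_directions).fit()
    return res.direction_maps, res.adc_map, res.quality
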