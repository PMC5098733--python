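"""Spoiled gradient-echo (SPGR/FLASH) steady-state signal model.

All series that matter for T1 — the variable-flip-angle series and the
dynamic contrast-enhanced series — share the same steady-state signal
equation

    S = M0 * sin(alpha) * (1 - E1) / (1 - E1 * cos(alpha)),   E1 = exp(-TR/T1)

with alpha the actual (B1-corrected) flip angle. This module provides the
forward evaluation and its analytic inversion to R1 = 1/T1 used by the
dynamic concentration calculation.
"""

from __future__ import annotations

import numpy as np

__all__ = ["spgr_signal", "spgr_amplitude_from_signal", "spgr_invert_to_r1"]


def spgr_signal(m0, alpha_rad, tr_ms, r1_per_s):
    """Steady-state SPGR signal; broadcasts over all arguments.

    ``r1_per_s`` is the longitudinal rate in s^-1; TR is in ms.
    """
    e1 = np.exp(-np.asarray(tr_ms) * np.asarray(r1_per_s) / 1000.0)
    sa, ca = np.sin(alpha_rad), np.cos(alpha_rad)
    return m0 * sa * (1.0 - e1) / (1.0 - e1 * ca)


def spgr_amplitude_from_signal(signal, alpha_rad, tr_ms, r1_per_s):
    """Effective amplitude A = M0*sin(alpha) from a signal of known R1.

    Used on the pre-contrast frames of a dynamic series, where R1 is the
    independently mapped pre-contrast rate.
    """
    e1 = np.exp(-np.asarray(tr_ms) * np.asarray(r1_per_s) / 1000.0)
    ca = np.cos(alpha_rad)
    return signal * (1.0 - e1 * ca) / (1.0 - e1)


def spgr_invert_to_r1(signal, amplitude, alpha_rad, tr_ms):
    """Invert the SPGR equation to R1 (s^-1) given the amplitude A = M0*sin(alpha).

    E1 = (A - S) / (A - S*cos(alpha)); frames where E1 falls outside (0, 1)
    have no physical inversion and come back NaN.
    """
    ca = np.cos(alpha_rad)
    with np.errstate(divide="ignore", invalid="ignore"):
        e1 = (amplitude - signal) / (amplitude - signal * ca)
        e1 = np.where((e1 > 0.0) & (e1 < 1.0), e1, np.nan)
        return -np.log(e1) / (np.asarray(tr_ms) / 1000.0)
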