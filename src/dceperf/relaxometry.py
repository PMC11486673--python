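"""SPGR relaxometry: VFA T1 mapping and signal <-> gadolinium concentration.

The spoiled gradient-echo steady state links signal to T1 through

    S = M0 * sin(a) * (1 - E1) / (1 - E1 * cos(a)),   E1 = exp(-TR / T1).

Contrast agent shortens T1 according to 1/T1(t) = 1/T10 + r1 * C(t), so a
dynamic SPGR series can be inverted frame by frame into concentration once
the pre-contrast T1 (from a variable-flip-angle fit or a supplied map) and
the agent relaxivity are known.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from ._errors import EstimationError, InputError

__all__ = [
    "RelaxationState",
    "spgr_signal",
    "spgr_invert",
    "fit_t1_vfa",
    "signal_to_concentration",
    "concentration_to_signal",
    "R1_GDDTPA_3T",
]

#: Longitudinal relaxivity of gadopentetate dimeglumine at 3 T, s^-1 mM^-1.
#: Standard literature value; configurable everywhere it is used.
R1_GDDTPA_3T = 3.7


@dataclasses.dataclass
class RelaxationState:
    """Pre-contrast relaxation parameters of one voxel or region.

    t10 : pre-contrast T1 in ms; m0 : equilibrium signal scale (a.u.);
    r1 : agent relaxivity in s^-1 mM^-1.
    """

    t10: float
    m0: float
    r1: float = R1_GDDTPA_3T

    def __post_init__(self):
        if not self.t10 > 0:
            raise InputError(f"t10 must be positive, got {self.t10}")
        if not self.m0 > 0:
            raise InputError(f"m0 must be positive, got {self.m0}")
        if not self.r1 > 0:
            raise InputError(f"r1 must be positive, got {self.r1}")


def spgr_signal(m0, t1, tr: float, flip: float):
    """Steady-state SPGR signal. ``t1`` and ``tr`` in ms, ``flip`` in degrees."""
    t1 = np.asarray(t1, dtype=np.float64)
    a = np.deg2rad(flip)
    e1 = np.exp(-tr / t1)
    return m0 * np.sin(a) * (1.0 - e1) / (1.0 - e1 * np.cos(a))


def spgr_invert(s, m0, tr: float, flip: float):
    """Invert SPGR signal to T1 (ms). Returns NaN where the signal is outside
    the model's attainable range for the given ``m0``."""
    s = np.asarray(s, dtype=np.float64)
    a = np.deg2rad(flip)
    y = s / (m0 * np.sin(a))
    with np.errstate(divide="ignore", invalid="ignore"):
        e1 = (1.0 - y) / (1.0 - y * np.cos(a))
        e1 = np.where((e1 > 0) & (e1 < 1), e1, np.nan)
        return -tr / np.log(e1)


def fit_t1_vfa(signals, flips, tr: float) -> tuple[float, float]:
    """DESPOT1 linearised variable-flip-angle fit -> (t10 ms, m0).

    Regresses S/sin(a) on S/tan(a); the slope is E1 and the intercept
    M0 (1 - E1). Degenerate or nonphysical data (collinear points, slope
    outside (0, 1)) yields (nan, nan) so callers can flag the voxel.
    """
    signals = np.asarray(signals, dtype=np.float64)
    flips = np.asarray(flips, dtype=np.float64)
    if signals.shape != flips.shape or signals.size < 2:
        raise EstimationError("VFA fit needs >= 2 (signal, flip) pairs")
    if len(np.unique(flips)) < 2:
        raise EstimationError("VFA fit needs >= 2 distinct flip angles")
    if np.ptp(signals) == 0:
        # identical signal at every angle carries no T1 information: the
        # regression line is fixed by geometry alone, not by the data
        return float("nan"), float("nan")
    a = np.deg2rad(flips)
    x = signals / np.tan(a)
    y = signals / np.sin(a)
    xm, ym = x.mean(), y.mean()
    denom = np.sum((x - xm) ** 2)
    if denom <= 0 or not np.all(np.isfinite([xm, ym, denom])):
        return float("nan"), float("nan")
    slope = np.sum((x - xm) * (y - ym)) / denom
    if not (0.0 < slope < 1.0):
        return float("nan"), float("nan")
    intercept = ym - slope * xm
    t10 = -tr / np.log(slope)
    m0 = intercept / (1.0 - slope)
    if not (t10 > 0 and m0 > 0):
        return float("nan"), float("nan")
    return float(t10), float(m0)


def signal_to_concentration(
    s_t,
    baseline_frames: int,
    state: RelaxationState,
    tr: float,
    flip: float,
):
    """Convert a dynamic SPGR signal curve to agent concentration (mM).

    The baseline signal S0 (mean of the first ``baseline_frames`` frames)
    anchors M0 through the known pre-contrast T1, so scanner scaling drops
    out. Frames whose signal lies outside the invertible range come back as
    NaN; negative concentrations at noisy pre-bolus frames are retained, not
    clamped, because zero-mean noise should stay zero-mean.

    Returns ``(conc, m0_effective)``.
    """
    s_t = np.asarray(s_t, dtype=np.float64)
    if baseline_frames < 1:
        raise InputError("baseline_frames must be >= 1")
    if baseline_frames > s_t.size:
        raise InputError(
            f"baseline_frames={baseline_frames} exceeds {s_t.size} frames"
        )
    s0 = float(np.nanmean(s_t[:baseline_frames]))
    if not s0 > 0:
        raise EstimationError("non-positive baseline signal; voxel excluded")
    # Effective M0 from S0 and the known T10 (this is the baseline-T1 correction)
    ref = spgr_signal(1.0, state.t10, tr, flip)
    m0 = s0 / ref
    t1_t = spgr_invert(s_t, m0, tr, flip)  # ms
    with np.errstate(invalid="ignore"):
        conc = (1.0 / (t1_t / 1000.0) - 1.0 / (state.t10 / 1000.0)) / state.r1
    return conc, m0


def concentration_to_signal(
    conc,
    state: RelaxationState,
    tr: float,
    flip: float,
):
    """Render a concentration curve (mM) into SPGR signal — the forward map
    inverted by :func:`signal_to_concentration`."""
    conc = np.asarray(conc, dtype=np.float64)
    r1_t = 1.0 / (state.t10 / 1000.0) + state.r1 * conc  # s^-1
    t1_t = 1000.0 / r1_t  # ms
    return spgr_signal(state.m0, t1_t, tr, flip)
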