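"""Voxel-wise pharmacokinetic model fitting and parametric map assembly.

Two models are fitted to gadolinium concentration-time curves against a
measured or analytic arterial input function:

* the extended Tofts model — Ktrans (min^-1), ve, vp, with kep = Ktrans/ve —
  describing leakage into the extravascular-extracellular space, and
* the two-compartment uptake (2CU) model — plasma flow Fp (min^-1), plasma
  volume vp and permeability-surface product PS — whose Fp serves as the
  model-based cerebral blood flow (rBF) estimate.

A semi-quantitative flow estimate is also computed from curve areas: CBV is
approximated by AUC(tissue)/AUC(artery) and divided by the mean-transit-time
difference of the two curves (central volume theorem).

Voxels whose dynamic signal is identically zero, or whose fit is degenerate
or fails to converge, are recorded in an exclusion mask and set to NaN in
every parameter map; VOI statistics average only the remaining voxels.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from ._conv import cum_trapz
from ._errors import EstimationError, InputError
from .aif import AIFCurve
from .io import DynamicSeries, MaskVOI, VolumeMap
from .relaxometry import R1_GDDTPA_3T, RelaxationState, signal_to_concentration
from .synthetic import TissueKineticParams, UptakeKineticParams, forward_2cu, forward_tofts

__all__ = [
    "FitResult",
    "SemiQuantFlow",
    "FitConfig",
    "KineticMaps",
    "fit_extended_tofts",
    "fit_2cu",
    "semiquant_flow",
    "compute_parameter_maps",
]

TOFTS_BOUNDS = ((0.0, 1e-4, 0.0), (5.0, 1.0, 1.0))  # ktrans, ve, vp
TCU_BOUNDS = ((1e-4, 1e-6, 0.0), (20.0, 1.0, 5.0))  # fp, vp, ps


@dataclasses.dataclass
class FitResult:
    params: TissueKineticParams | UptakeKineticParams | None
    rsq: float
    fitted: np.ndarray
    degenerate: bool = False


@dataclasses.dataclass
class SemiQuantFlow:
    cbv: float
    mtt: float  # minutes
    rbf_auc: float  # min^-1
    flagged: bool = False


def _prepare(ct, aif: AIFCurve, t):
    ct = np.asarray(ct, dtype=np.float64)
    t = aif.t if t is None else np.asarray(t, dtype=np.float64)
    if ct.shape != t.shape or aif.cp.shape != t.shape:
        raise InputError("ct, aif and t must share one frame grid")
    if ct.size < 5:
        raise InputError("need >= 5 frames to fit a kinetic model")
    finite = np.isfinite(ct)
    return ct, t, finite


def _rsq(ct, fitted, finite):
    resid = ct[finite] - fitted[finite]
    sst = float(np.sum((ct[finite] - ct[finite].mean()) ** 2))
    if sst <= 0:
        return float("nan")
    return float(min(1.0, max(0.0, 1.0 - np.sum(resid**2) / sst)))


def _multistart(residual, x0, bounds, n_starts, seed):
    """Bounded least squares from several deterministic starting points."""
    rng = np.random.default_rng(seed)
    lo, hi = np.asarray(bounds[0]), np.asarray(bounds[1])
    starts = [np.asarray(x0, dtype=np.float64)]
    for _ in range(max(0, n_starts - 1)):
        jitter = np.exp(rng.normal(0.0, 0.7, size=len(x0)))
        starts.append(np.clip(np.asarray(x0) * jitter, lo * 1.0 + 1e-12, hi))
    best = None
    for s in starts:
        s = np.minimum(np.maximum(s, lo), hi)
        try:
            res = least_squares(residual, s, bounds=(lo, hi), method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12)
        except Exception:
            continue
        sse = float(2.0 * res.cost)
        if best is None or sse < best[1]:
            best = (res.x, sse)
            if sse <= 1e-14:
                break
    return best


def fit_extended_tofts(
    ct,
    aif: AIFCurve,
    t=None,
    bounds=TOFTS_BOUNDS,
    n_starts: int = 5,
    seed: int | Sequence[int] = 0,
) -> FitResult:
    """Fit the extended Tofts model to one concentration curve.

    ``t`` defaults to the AIF frame grid (minutes). NaN frames are ignored in
    the objective. Returns a degenerate result (ktrans = vp = 0) for null
    curves and a NaN result if no start converges.
    """
    ct, t, finite = _prepare(ct, aif, t)
    if finite.sum() < 5 or np.nanmax(np.abs(ct)) <= 0:
        zero = np.zeros_like(t)
        return FitResult(TissueKineticParams(0.0, 0.0, 0.0), float("nan"), zero, degenerate=True)
    cp = aif.cp

    def residual(x):
        model = forward_tofts(TissueKineticParams(x[0], x[1], x[2]), cp, t)
        return model[finite] - ct[finite]

    best = _multistart(residual, [0.1, 0.2, 0.02], bounds, n_starts, seed)
    if best is None:
        return FitResult(None, float("nan"), np.full_like(t, np.nan), degenerate=True)
    params = TissueKineticParams(*best[0])
    fitted = forward_tofts(params, cp, t)
    return FitResult(params, _rsq(ct, fitted, finite), fitted)


def fit_2cu(
    ct,
    aif: AIFCurve,
    t=None,
    bounds=TCU_BOUNDS,
    n_starts: int = 5,
    seed: int | Sequence[int] = 0,
) -> FitResult:
    """Fit the two-compartment uptake model; Fp is the model-based rBF."""
    ct, t, finite = _prepare(ct, aif, t)
    if finite.sum() < 5 or np.nanmax(np.abs(ct)) <= 0:
        zero = np.zeros_like(t)
        return FitResult(UptakeKineticParams(1e-4, 1e-6, 0.0), float("nan"), zero, degenerate=True)
    cp = aif.cp

    def residual(x):
        model = forward_2cu(UptakeKineticParams(x[0], x[1], x[2]), cp, t)
        return model[finite] - ct[finite]

    best = _multistart(residual, [0.5, 0.05, 0.05], bounds, n_starts, seed)
    if best is None:
        return FitResult(None, float("nan"), np.full_like(t, np.nan), degenerate=True)
    params = UptakeKineticParams(*best[0])
    fitted = forward_2cu(params, cp, t)
    return FitResult(params, _rsq(ct, fitted, finite), fitted)


def semiquant_flow(ct, aif: AIFCurve, t=None, mtt_floor_min: float = 1.0 / 60.0) -> SemiQuantFlow:
    """Area-based flow estimate: CBV = AUC(ct)/AUC(aif), MTT = difference of
    the curves' first temporal moments (minutes, floored), rBF = CBV/MTT."""
    ct = np.asarray(ct, dtype=np.float64)
    t = aif.t if t is None else np.asarray(t, dtype=np.float64)
    if ct.size == 0 or ct.shape != t.shape:
        raise InputError("ct and t must be nonempty and matched")
    ct = np.nan_to_num(ct, nan=0.0)
    auc_aif = float(cum_trapz(t, aif.cp)[-1])
    if auc_aif <= 0:
        raise EstimationError("AIF has non-positive area under the curve")
    auc_ct = float(cum_trapz(t, ct)[-1])
    if auc_ct <= 0:
        return SemiQuantFlow(cbv=0.0, mtt=float("nan"), rbf_auc=0.0, flagged=True)
    cbv = auc_ct / auc_aif
    tbar_ct = float(cum_trapz(t, t * ct)[-1]) / auc_ct
    tbar_aif = float(cum_trapz(t, t * aif.cp)[-1]) / auc_aif
    mtt = tbar_ct - tbar_aif
    flagged = False
    if mtt < mtt_floor_min:
        mtt, flagged = mtt_floor_min, True
    return SemiQuantFlow(cbv=cbv, mtt=mtt, rbf_auc=cbv / mtt, flagged=flagged)


# ---------------------------------------------------------------------------
# Map assembly


@dataclasses.dataclass
class FitConfig:
    """Options for voxel-wise map computation.

    ``models`` selects which fits run per voxel; ``rbf_estimator`` chooses
    which flow estimate ('fp' model-based or 'auc' area-based) downstream VOI
    statistics consume. The zero-signal rule marks a voxel excluded when its
    maximum dynamic signal is at most ``zero_rel_threshold`` times the series
    maximum.
    """

    models: tuple[str, ...] = ("tofts", "2cu")
    n_starts: int = 5
    seed: int = 0
    r1: float = R1_GDDTPA_3T
    bolus_frame: int = 3
    baseline_frames: int | None = None  # default: all frames before bolus
    rbf_estimator: str = "fp"
    mtt_floor_s: float = 1.0
    zero_rel_threshold: float = 1e-9


@dataclasses.dataclass
class KineticMaps:
    """Per-voxel parameter maps on the reference grid (NaN = excluded)."""

    ktrans: VolumeMap
    kep: VolumeMap
    ve: VolumeMap
    vp: VolumeMap
    fp_rbf: VolumeMap
    rbf_auc: VolumeMap
    cbv: VolumeMap
    mtt: VolumeMap
    rsq: VolumeMap
    excluded: MaskVOI

    def rbf(self, estimator: str = "fp") -> VolumeMap:
        if estimator not in ("fp", "auc"):
            raise InputError(f"rbf estimator must be 'fp' or 'auc', got {estimator!r}")
        return self.fp_rbf if estimator == "fp" else self.rbf_auc

    def as_dict(self) -> dict[str, VolumeMap]:
        return {f.name: getattr(self, f.name) for f in dataclasses.fields(self) if f.name != "excluded"}


def compute_parameter_maps(
    series: DynamicSeries,
    t10_map: VolumeMap,
    aif: AIFCurve,
    masks: dict[str, MaskVOI],
    config: FitConfig | None = None,
) -> KineticMaps:
    """Convert every brain voxel to concentration and fit the configured
    models, assembling parametric maps with the zero-signal exclusion rule.

    Requires a 'brain' mask; grids of series, T1 map and masks must agree.
    Deterministic for a fixed config: each voxel's multi-start jitter is
    seeded by (config.seed, flat voxel index).
    """
    cfg = config or FitConfig()
    if "brain" not in masks or masks["brain"].n_voxels == 0:
        raise InputError("a nonempty 'brain' mask is required")
    brain = masks["brain"].data.astype(bool)
    if series.data.shape[:3] != brain.shape or t10_map.data.shape != brain.shape:
        raise InputError("series, T1 map and masks must share a grid")
    if aif.t.shape[0] != series.n_frames:
        raise InputError("AIF must be sampled on the series frame grid")

    shape = brain.shape
    names = ("ktrans", "kep", "ve", "vp", "fp_rbf", "rbf_auc", "cbv", "mtt", "rsq")
    out = {n: np.full(shape, np.nan) for n in names}
    excluded = np.zeros(shape, dtype=np.uint8)

    t_min = series.frame_times / 60.0
    n_base = cfg.baseline_frames if cfg.baseline_frames is not None else max(1, cfg.bolus_frame)
    zero_thr = cfg.zero_rel_threshold * float(np.nanmax(series.data))
    mtt_floor = cfg.mtt_floor_s / 60.0

    idx = np.argwhere(brain)
    flat = np.ravel_multi_index(idx.T, shape)
    for (i, j, k), fx in zip(idx, flat):
        sig = series.data[i, j, k, :]
        if np.nanmax(sig) <= zero_thr:
            excluded[i, j, k] = 1
            continue
        t10v = t10_map.data[i, j, k]
        if not t10v > 0:
            excluded[i, j, k] = 1
            continue
        try:
            conc, _ = signal_to_concentration(
                sig, n_base, RelaxationState(t10v, 1.0, cfg.r1), series.tr, series.flip_angle
            )
        except EstimationError:
            excluded[i, j, k] = 1
            continue
        if not np.any(np.isfinite(conc)):
            excluded[i, j, k] = 1
            continue

        ok = False
        if "tofts" in cfg.models:
            res = fit_extended_tofts(conc, aif, t_min, n_starts=cfg.n_starts, seed=[cfg.seed, int(fx)])
            if res.params is not None and not res.degenerate:
                out["ktrans"][i, j, k] = res.params.ktrans
                out["kep"][i, j, k] = res.params.kep
                out["ve"][i, j, k] = res.params.ve
                out["vp"][i, j, k] = res.params.vp
                out["rsq"][i, j, k] = res.rsq
                ok = True
        if "2cu" in cfg.models:
            res2 = fit_2cu(conc, aif, t_min, n_starts=cfg.n_starts, seed=[cfg.seed, int(fx), 1])
            if res2.params is not None and not res2.degenerate:
                out["fp_rbf"][i, j, k] = res2.params.fp
                if "tofts" not in cfg.models:
                    out["vp"][i, j, k] = res2.params.vp
                    out["rsq"][i, j, k] = res2.rsq
                ok = True
        try:
            sq = semiquant_flow(conc, aif, t_min, mtt_floor_min=mtt_floor)
            out["cbv"][i, j, k] = sq.cbv
            out["mtt"][i, j, k] = sq.mtt
            out["rbf_auc"][i, j, k] = sq.rbf_auc
        except EstimationError:
            pass
        if not ok:
            excluded[i, j, k] = 1
            for n in names:
                out[n][i, j, k] = np.nan

    aff = series.affine
    units = {
        "ktrans": "1/min", "kep": "1/min", "ve": "fraction", "vp": "fraction",
        "fp_rbf": "1/min", "rbf_auc": "1/min", "cbv": "fraction", "mtt": "min", "rsq": "",
    }
    vols = {n: VolumeMap(data=out[n], affine=aff, name=n, units=units[n]) for n in names}
    return KineticMaps(excluded=MaskVOI(excluded, aff, "brain"), **vols)
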