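"""Digital reference phantoms with known tracer-kinetic ground truth.

A phantom is a small 3D "head": an ellipsoidal brain of normal tissue with
near-zero contrast leakage, a spherical tumour whose voxels follow the
extended Tofts or two-compartment uptake (2CU) forward model, and an arterial
column carrying whole-blood signal derived from an analytic arterial input
function. Concentration curves are rendered into spoiled gradient-echo (SPGR)
signal through the relaxometry forward map, optionally with Gaussian noise,
so the entire analysis chain — T1 correction, AIF extraction, model fitting,
VOI statistics — can be validated against exact ground truth without any
clinical data.

Time convention: frame times are stored in seconds (as in files and configs);
all kinetic arithmetic runs in minutes, with Ktrans, kep, Fp and PS per
minute. This module owns the conversion.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from ._conv import cum_trapz, exp_conv
from ._errors import ConfigError, InputError
from .io import DynamicSeries, MaskVOI, VolumeMap
from .relaxometry import R1_GDDTPA_3T, RelaxationState, concentration_to_signal, spgr_signal

__all__ = [
    "TissueKineticParams",
    "UptakeKineticParams",
    "PhantomConfig",
    "analytic_aif",
    "forward_tofts",
    "forward_2cu",
    "generate_phantom",
    "generate_vfa_stack",
]


@dataclasses.dataclass(frozen=True)
class TissueKineticParams:
    """Extended Tofts parameters: ktrans and kep per minute, ve/vp fractions."""

    ktrans: float
    ve: float
    vp: float

    def __post_init__(self):
        if self.ktrans < 0:
            raise InputError(f"ktrans must be >= 0, got {self.ktrans}")
        if not 0 <= self.ve <= 1:
            raise InputError(f"ve must be in [0, 1], got {self.ve}")
        if not 0 <= self.vp <= 1:
            raise InputError(f"vp must be in [0, 1], got {self.vp}")
        if self.ktrans > 0 and self.ve <= 0:
            raise InputError("ve must be > 0 whenever ktrans > 0")

    @property
    def kep(self) -> float:
        """Efflux rate constant ktrans/ve, per minute (0 when ktrans = 0)."""
        return self.ktrans / self.ve if self.ktrans > 0 else 0.0


@dataclasses.dataclass(frozen=True)
class UptakeKineticParams:
    """Two-compartment uptake parameters: plasma flow fp and permeability-
    surface product ps per minute, plasma volume fraction vp."""

    fp: float
    vp: float
    ps: float

    def __post_init__(self):
        if not self.fp > 0:
            raise InputError(f"fp must be > 0, got {self.fp}")
        if self.ps < 0:
            raise InputError(f"ps must be >= 0, got {self.ps}")
        if not 0 < self.vp <= 1:
            raise InputError(f"vp must be in (0, 1], got {self.vp}")

    @property
    def e(self) -> float:
        """Extraction fraction ps / (fp + ps)."""
        return self.ps / (self.fp + self.ps)

    @property
    def tp(self) -> float:
        """Plasma mean transit time vp / (fp + ps), minutes."""
        return self.vp / (self.fp + self.ps)


# ---------------------------------------------------------------------------
# Analytic arterial input functions

# Population-average AIF of Parker et al.: two Gaussians plus a
# sigmoid-modulated exponential washout. Amplitudes in mM (A_n in mM.min),
# times/widths in minutes.
_PARKER = dict(
    a1=0.809, a2=0.330, t1=0.17046, t2=0.365, s1=0.0563, s2=0.132,
    alpha=1.050, beta=0.1685, s=38.078, tau=0.483,
)

# Biexponential plasma clearance (Weinmann-type), amplitudes in mM for a
# standard 0.1 mmol/kg dose, rates per minute.
_BIEXP = dict(a1=3.99, a2=4.78, m1=0.144, m2=0.0111)


def analytic_aif(
    t: np.ndarray,
    model: str = "parker",
    dose_scale: float = 1.0,
    t0: float = 0.0,
) -> np.ndarray:
    """Analytic plasma AIF Cp(t) in mM on a time grid in minutes.

    ``t0`` is the bolus-arrival time (minutes); the curve is identically zero
    at and before arrival. ``dose_scale`` linearly scales the whole curve
    (1.0 = standard dose).
    """
    t = np.asarray(t, dtype=np.float64)
    if t.size and (np.any(t < 0) or np.any(np.diff(t) <= 0)):
        raise InputError("time grid must be nonnegative and increasing")
    tt = t - t0
    if model == "parker":
        p = _PARKER
        cp = np.zeros_like(tt)
        pos = tt > 0
        u = tt[pos]
        for a, tc, sg in ((p["a1"], p["t1"], p["s1"]), (p["a2"], p["t2"], p["s2"])):
            cp[pos] += a / (sg * np.sqrt(2 * np.pi)) * np.exp(-((u - tc) ** 2) / (2 * sg**2))
        cp[pos] += p["alpha"] * np.exp(-p["beta"] * u) / (1 + np.exp(-p["s"] * (u - p["tau"])))
    elif model == "biexponential":
        p = _BIEXP
        cp = np.zeros_like(tt)
        pos = tt > 0
        u = tt[pos]
        cp[pos] = p["a1"] * np.exp(-p["m1"] * u) + p["a2"] * np.exp(-p["m2"] * u)
    else:
        raise InputError(f"unknown AIF model {model!r}; use 'parker' or 'biexponential'")
    return dose_scale * cp


# ---------------------------------------------------------------------------
# Forward models

def forward_tofts(params: TissueKineticParams, cp: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Extended Tofts tissue concentration (mM), ``t`` in minutes.

    Ct(t) = vp Cp(t) + ktrans int_0^t Cp(tau) exp(-kep (t - tau)) dtau,
    with the convolution exact for piecewise-linear Cp.
    """
    cp = np.asarray(cp, dtype=np.float64)
    t = np.asarray(t, dtype=np.float64)
    if cp.shape != t.shape:
        raise InputError(f"cp and t lengths differ: {cp.shape} vs {t.shape}")
    ct = params.vp * cp
    if params.ktrans > 0:
        ct = ct + params.ktrans * exp_conv(t, cp, params.kep)
    return ct


def forward_2cu(params: UptakeKineticParams, cp: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Two-compartment uptake tissue concentration (mM), ``t`` in minutes.

    Ct = Fp (R * Cp) with residue R(t) = E + (1 - E) exp(-t / Tp); the
    exponential part is exact for piecewise-linear Cp and the constant part
    is the running trapezoidal integral.
    """
    cp = np.asarray(cp, dtype=np.float64)
    t = np.asarray(t, dtype=np.float64)
    if cp.shape != t.shape:
        raise InputError(f"cp and t lengths differ: {cp.shape} vs {t.shape}")
    e, tp = params.e, params.tp
    if tp < 1e-12:
        return params.fp * e * cum_trapz(t, cp)
    return params.fp * (e * cum_trapz(t, cp) + (1.0 - e) * exp_conv(t, cp, 1.0 / tp))


# ---------------------------------------------------------------------------
# Phantom generation

_DEFAULT_T10 = {"tissue": 1100.0, "tumour": 1400.0, "blood": 1650.0}


@dataclasses.dataclass
class PhantomConfig:
    """Geometry, kinetics and acquisition settings of a digital phantom.

    Defaults emulate a 3 T TWIST-like brain protocol: TR 4.83 ms, 12 degree
    flip, 70 frames at 5 s spacing with the bolus arriving at frame 3, and a
    2% baseline-signal Gaussian noise floor.
    """

    shape: tuple[int, int, int] = (32, 32, 8)
    voxel_size: tuple[float, float, float] = (1.4, 1.4, 3.0)
    tr: float = 4.83
    te: float = 1.87
    flip_angle: float = 12.0
    frame_times: Sequence[float] | None = None  # seconds; default 70 x 5 s
    bolus_frame: int = 3
    aif_model: str = "parker"
    dose_scale: float = 1.0
    hct: float = 0.45
    noise_sigma: float = 0.02  # fraction of per-voxel baseline signal
    seed: int | None = 1234
    tumour_model: str = "tofts"  # 'tofts' | '2cu'
    tumour_params: TissueKineticParams | UptakeKineticParams = TissueKineticParams(0.25, 0.4, 0.05)
    tissue_model: str = "tofts"
    tissue_params: TissueKineticParams | UptakeKineticParams = TissueKineticParams(0.002, 0.1, 0.02)
    t10_ms: dict = dataclasses.field(default_factory=lambda: dict(_DEFAULT_T10))
    m0: float = 1000.0
    r1: float = R1_GDDTPA_3T
    tumour_center: tuple[int, int, int] | None = None
    tumour_radius: float | None = None

    def resolved_frame_times(self) -> np.ndarray:
        if self.frame_times is None:
            return np.arange(70, dtype=np.float64) * 5.0
        return np.asarray(self.frame_times, dtype=np.float64)

    def validate(self):
        ft = self.resolved_frame_times()
        if ft.size < 3 or np.any(np.diff(ft) <= 0):
            raise ConfigError("frame_times must be >= 3 strictly increasing values")
        if not 0 <= self.bolus_frame < ft.size:
            raise ConfigError("bolus_frame out of range")
        if self.noise_sigma > 0 and self.seed is None:
            raise ConfigError("seed is mandatory when noise_sigma > 0")
        if not 0 <= self.hct < 1:
            raise ConfigError(f"hct must be in [0, 1), got {self.hct}")
        for mdl, prm in ((self.tumour_model, self.tumour_params), (self.tissue_model, self.tissue_params)):
            want = TissueKineticParams if mdl == "tofts" else UptakeKineticParams
            if mdl not in ("tofts", "2cu"):
                raise ConfigError(f"unknown region model {mdl!r}")
            if not isinstance(prm, want):
                raise ConfigError(f"region model {mdl!r} needs {want.__name__}")


def _region_masks(cfg: PhantomConfig):
    nx, ny, nz = cfg.shape
    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    cx, cy, cz = (nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0
    ax, ay, az = 0.46 * nx, 0.46 * ny, 0.48 * nz
    brain = ((ii - cx) / ax) ** 2 + ((jj - cy) / ay) ** 2 + ((kk - cz) / az) ** 2 <= 1.0

    tc = cfg.tumour_center or (int(round(0.72 * (nx - 1))), ny // 2, nz // 2)
    tr_ = cfg.tumour_radius if cfg.tumour_radius is not None else max(2.0, round(0.1 * nx))
    tumour = ((ii - tc[0]) ** 2 + (jj - tc[1]) ** 2 + (kk - tc[2]) ** 2) <= tr_**2
    tumour &= brain
    # contralateral mirror across the sagittal midplane x = (nx-1)/2
    control = tumour[::-1, :, :] & brain

    # arterial column through the centre, clear of tumour and its mirror
    ax0 = int(round(cx)) - 1
    ay0 = int(round(0.25 * ny))
    artery = np.zeros(cfg.shape, dtype=bool)
    artery[ax0 : ax0 + 2, ay0 : ay0 + 2, :] = True
    artery &= brain

    if (tumour & control).any() or (tumour & artery).any() or (control & artery).any():
        raise ConfigError("phantom regions overlap; adjust geometry")
    if not (tumour.any() and control.any() and artery.sum() >= 10):
        raise ConfigError("phantom regions degenerate; enlarge the grid")
    return brain, tumour, control, artery


def _forward(model: str, params, cp: np.ndarray, t_min: np.ndarray) -> np.ndarray:
    return forward_tofts(params, cp, t_min) if model == "tofts" else forward_2cu(params, cp, t_min)


def generate_phantom(cfg: PhantomConfig):
    """Render a phantom acquisition.

    Returns ``(series, t10_map, truth, masks)`` where ``truth`` maps
    parameter names (ktrans/ve/vp/kep and/or fp/ps) to ground-truth
    :class:`~dceperf.io.VolumeMap` volumes (NaN outside modelled regions) and
    ``masks`` holds 'brain', 'tumour', 'control' and 'artery' VOIs. The
    series is bit-reproducible given the same config and seed; noise is
    applied only where there is signal, so background stays exactly zero.
    """
    cfg.validate()
    brain, tumour, control, artery = _region_masks(cfg)
    ft = cfg.resolved_frame_times()
    t_min = ft / 60.0
    t0_min = ft[cfg.bolus_frame] / 60.0
    cp = analytic_aif(t_min, cfg.aif_model, cfg.dose_scale, t0=t0_min)
    cb = cp * (1.0 - cfg.hct)  # whole-blood concentration seen by artery voxels

    curves = {
        "tumour": _forward(cfg.tumour_model, cfg.tumour_params, cp, t_min),
        "tissue": _forward(cfg.tissue_model, cfg.tissue_params, cp, t_min),
        "blood": cb,
    }
    t10 = cfg.t10_ms
    signals = {
        name: concentration_to_signal(
            curve, RelaxationState(t10["blood" if name == "blood" else ("tumour" if name == "tumour" else "tissue")], cfg.m0, cfg.r1),
            cfg.tr, cfg.flip_angle,
        )
        for name, curve in curves.items()
    }

    data = np.zeros(cfg.shape + (ft.size,), dtype=np.float64)
    tissue_only = brain & ~tumour & ~artery
    data[tissue_only] = signals["tissue"]
    data[tumour] = signals["tumour"]
    data[artery] = signals["blood"]

    t10_map = np.zeros(cfg.shape)
    t10_map[tissue_only] = t10["tissue"]
    t10_map[tumour] = t10["tumour"]
    t10_map[artery] = t10["blood"]

    if cfg.noise_sigma > 0:
        rng = np.random.default_rng(cfg.seed)
        nb = int(max(1, cfg.bolus_frame))
        baseline = data[..., :nb].mean(axis=-1)
        noise = rng.normal(size=data.shape) * (cfg.noise_sigma * baseline)[..., None]
        data = np.where(baseline[..., None] > 0, data + noise, data)

    affine = np.diag(list(cfg.voxel_size) + [1.0])
    series = DynamicSeries(
        data=data, frame_times=ft, tr=cfg.tr, te=cfg.te,
        flip_angle=cfg.flip_angle, voxel_size=cfg.voxel_size, affine=affine,
    )
    t10_vol = VolumeMap(data=t10_map, affine=affine, name="T10", units="ms")

    truth: dict[str, VolumeMap] = {}

    def _fill(name, tum_val, tis_val):
        arr = np.full(cfg.shape, np.nan)
        arr[tissue_only] = tis_val
        arr[tumour] = tum_val
        truth[name] = VolumeMap(data=arr, affine=affine, name=f"truth_{name}")

    for field in ("ktrans", "ve", "vp", "kep", "fp", "ps", "e", "tp"):
        tv = getattr(cfg.tumour_params, field, None)
        sv = getattr(cfg.tissue_params, field, None)
        _fill(field, np.nan if tv is None else tv, np.nan if sv is None else sv)

    masks = {
        "brain": MaskVOI(brain.astype(np.uint8), affine, "brain"),
        "tumour": MaskVOI(tumour.astype(np.uint8), affine, "tumour_CE"),
        "control": MaskVOI(control.astype(np.uint8), affine, "control"),
        "artery": MaskVOI(artery.astype(np.uint8), affine, "artery"),
    }
    return series, t10_vol, truth, masks


def generate_vfa_stack(
    t10_map: VolumeMap,
    m0: float,
    flips: Sequence[float],
    tr: float,
    noise_sigma: float = 0.0,
    seed: int | None = None,
):
    """Variable-flip-angle SPGR volumes from a T1 map, for T1-fit validation."""
    if noise_sigma > 0 and seed is None:
        raise ConfigError("seed is mandatory when noise_sigma > 0")
    rng = np.random.default_rng(seed) if noise_sigma > 0 else None
    out = []
    t1 = np.where(t10_map.data > 0, t10_map.data, np.nan)
    for a in flips:
        s = np.where(np.isfinite(t1), spgr_signal(m0, np.where(np.isfinite(t1), t1, 1.0), tr, a), 0.0)
        if rng is not None:
            s = s + rng.normal(size=s.shape) * noise_sigma * m0 * (s > 0)
        out.append(VolumeMap(data=s, affine=t10_map.affine, name=f"vfa_{a:g}"))
    return out
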