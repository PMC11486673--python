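"""End-to-end orchestration: simulate -> convert -> AIF -> fit -> VOI -> stats.

A single YAML config drives every stage; any stage failure raises a
:class:`~dceperf._errors.StageError` naming the stage. Every run logs the
config hash, the seed, per-mask voxel counts and exclusion counts, so a
result can always be traced back to its exact inputs.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from pathlib import Path

import numpy as np

from . import aif as aifmod
from . import io, kinetics, voistats
from ._errors import ConfigError, DCEError, StageError
from .synthetic import PhantomConfig, TissueKineticParams, UptakeKineticParams, analytic_aif, generate_phantom

__all__ = ["run", "phantom_config_from_dict", "DEFAULT_CONFIG"]

log = logging.getLogger("dceperf")

DEFAULT_CONFIG: dict = {
    "mode": "all",
    "seed": 1234,
    "subject": "phantom01",
    "group": "meningioma",
    "phantom": {},
    "aif": {"k": 10, "hct": 0.45, "pv_factor": 1.0, "template": "parker"},
    "kinetics": {"models": ["tofts", "2cu"], "n_starts": 5, "rbf_estimator": "fp"},
    "stats": {"sidedness": "two"},
}


def _merged(cfg: dict) -> dict:
    out = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    for k, v in (cfg or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k].update(v)
        else:
            out[k] = v
    return out


def _params_from_dict(d: dict):
    model = d.get("model", "tofts")
    if model == "tofts":
        return model, TissueKineticParams(d.get("ktrans", 0.25), d.get("ve", 0.4), d.get("vp", 0.05))
    if model == "2cu":
        return model, UptakeKineticParams(d.get("fp", 0.6), d.get("vp", 0.05), d.get("ps", 0.05))
    raise ConfigError(f"unknown region model {model!r}")


def phantom_config_from_dict(d: dict, seed: int | None = None) -> PhantomConfig:
    d = d or {}
    kw: dict = {}
    for key in ("shape", "voxel_size", "tr", "te", "flip_angle", "bolus_frame",
                "aif_model", "dose_scale", "hct", "noise_sigma", "m0", "r1",
                "tumour_center", "tumour_radius", "t10_ms"):
        if key in d:
            kw[key] = tuple(d[key]) if key in ("shape", "voxel_size", "tumour_center") else d[key]
    if "frame_times_s" in d:
        kw["frame_times"] = d["frame_times_s"]
    elif "n_frames" in d or "dt_s" in d:
        kw["frame_times"] = np.arange(int(d.get("n_frames", 70))) * float(d.get("dt_s", 5.0))
    if "tumour" in d:
        kw["tumour_model"], kw["tumour_params"] = _params_from_dict(d["tumour"])
    if "tissue" in d:
        kw["tissue_model"], kw["tissue_params"] = _params_from_dict(d["tissue"])
    if seed is not None:
        kw["seed"] = seed
    elif "seed" in d:
        kw["seed"] = d["seed"]
    return PhantomConfig(**kw)


def _stage(name):
    def wrap(fn):
        def inner(*a, **kw):
            t0 = time.perf_counter()
            try:
                out = fn(*a, **kw)
            except DCEError as e:
                raise StageError(name, str(e)) from e
            log.info("stage %s finished in %.1f s", name, time.perf_counter() - t0)
            return out

        inner.__name__ = fn.__name__
        return inner

    return wrap


@_stage("simulate")
def _simulate(cfg: dict, out: Path):
    pcfg = phantom_config_from_dict(cfg.get("phantom"), seed=cfg.get("seed"))
    series, t10, truth, masks = generate_phantom(pcfg)
    io.write_series(series, out / "series.nii")
    io.write_map(t10, out / "t10.nii")
    for name, m in masks.items():
        io.write_mask(m, out / f"mask_{name}.nii")
        log.info("mask %s: %d voxels", name, m.n_voxels)
    for name, v in truth.items():
        io.write_map(v, out / f"truth_{name}.nii")
    return series, t10, truth, masks


@_stage("load")
def _load(cfg: dict):
    paths = cfg.get("paths") or {}
    acq = cfg.get("acquisition") or {}
    if "series" not in paths:
        raise ConfigError("analyse mode needs paths.series")
    if "t1_map" not in paths:
        raise ConfigError(
            "analyse mode needs paths.t1_map: baseline T1 correction is mandatory"
        )
    if "frame_times_s" in acq:
        timing = acq["frame_times_s"]
    elif "n_frames" in acq and "dt_s" in acq:
        timing = (np.arange(int(acq["n_frames"])) * float(acq["dt_s"])).tolist()
    else:
        raise ConfigError("acquisition.frame_times_s (or n_frames + dt_s) is required")
    series = io.read_series(
        paths["series"], timing,
        tr=float(acq.get("tr", 4.83)), te=float(acq.get("te", 1.87)),
        flip_angle=float(acq.get("flip_angle", 12.0)),
    )
    t10 = io.read_map(paths["t1_map"], name="T10", units="ms")
    masks = {}
    for label, p in (paths.get("masks") or {}).items():
        masks[label] = io.read_mask(p, label=label)
    return series, t10, masks


@_stage("aif")
def _aif_stage(cfg: dict, series, t10, masks, out: Path):
    acfg = cfg["aif"]
    kcfg = cfg["kinetics"]
    t_min = series.frame_times / 60.0
    bolus = int((cfg.get("phantom") or {}).get("bolus_frame", (cfg.get("acquisition") or {}).get("bolus_frame", 3)))
    if "artery" not in masks:
        if acfg.get("fallback_analytic"):
            cp = analytic_aif(t_min, acfg.get("template", "parker"), t0=float(series.frame_times[bolus]) / 60.0)
            curve = aifmod.AIFCurve(t=t_min, cp=cp, source="analytic", n_voxels_used=0)
            aifmod.write_aif_csv(curve, out / "aif.csv")
            return curve
        raise ConfigError("no artery mask and aif.fallback_analytic not set")
    artery = masks["artery"]
    vox = np.argwhere(artery.data.astype(bool))
    conc = []
    from .relaxometry import RelaxationState, signal_to_concentration

    for i, j, k in vox:
        c, _ = signal_to_concentration(
            series.data[i, j, k, :], max(1, bolus),
            RelaxationState(float(t10.data[i, j, k]), 1.0, float(kcfg.get("r1", 3.7))),
            series.tr, series.flip_angle,
        )
        conc.append(c)
    conc = np.asarray(conc)
    template = analytic_aif(t_min, acfg.get("template", "parker"), t0=float(series.frame_times[bolus]) / 60.0)
    k = int(acfg.get("k", 10))
    blood = aifmod.extract_aif(conc, t_min, k=min(k, conc.shape[0]), template=template)
    plasma = aifmod.blood_to_plasma(blood, hct=float(acfg.get("hct", 0.45)), pv_factor=float(acfg.get("pv_factor", 1.0)))
    log.info("AIF from %d/%d artery voxels, quality %.3f", plasma.n_voxels_used, conc.shape[0], plasma.quality)
    aifmod.write_aif_csv(plasma, out / "aif.csv")
    return plasma


@_stage("fit")
def _fit_stage(cfg: dict, series, t10, aif_curve, masks, out: Path):
    kcfg = cfg["kinetics"]
    bolus = int((cfg.get("phantom") or {}).get("bolus_frame", (cfg.get("acquisition") or {}).get("bolus_frame", 3)))
    fit_cfg = kinetics.FitConfig(
        models=tuple(kcfg.get("models", ("tofts", "2cu"))),
        n_starts=int(kcfg.get("n_starts", 5)),
        seed=int(cfg.get("seed", 0)),
        r1=float(kcfg.get("r1", 3.7)),
        bolus_frame=bolus,
        rbf_estimator=kcfg.get("rbf_estimator", "fp"),
    )
    maps = kinetics.compute_parameter_maps(series, t10, aif_curve, masks, fit_cfg)
    for name, v in maps.as_dict().items():
        io.write_map(v, out / f"map_{name}.nii")
    io.write_mask(maps.excluded, out / "map_excluded.nii")
    log.info("excluded voxels: %d", maps.excluded.n_voxels)
    return maps


@_stage("voi")
def _voi_stage(cfg: dict, series, maps, masks, out: Path):
    est = cfg["kinetics"].get("rbf_estimator", "fp")
    if est == "fp" and "2cu" not in cfg["kinetics"].get("models", ("tofts", "2cu")):
        log.info("rbf_estimator 'fp' but 2CU not fitted; using area-based estimate")
        est = "auc"
    tum = masks.get("tumour_CE") or masks.get("tumour")
    if tum is None:
        raise ConfigError("analyse mode needs a tumour (or tumour_CE) mask")
    ctl = masks.get("control")
    if ctl is None:
        ctl = voistats.mirror_control_voi(tum, masks["brain"])
        io.write_mask(ctl, out / "mask_control_mirrored.nii")
    vox_mm3 = float(abs(np.linalg.det(series.affine[:3, :3])))
    models = tuple(cfg["kinetics"].get("models", ("tofts", "2cu")))
    rows = []
    for label, m in (("tumour_CE", tum), ("control", ctl)):
        sel = m.data.astype(bool)
        exc = maps.excluded.data.astype(bool)
        n_excluded = int((sel & exc).sum())
        n_usable = int((sel & ~exc).sum())
        mk = voistats.voi_mean(maps.ktrans, m, maps.excluded)[0] if "tofts" in models else float("nan")
        mr, _, _ = voistats.voi_mean(maps.rbf(est), m, maps.excluded)
        rows.append(voistats.VOISummary(
            subject=str(cfg.get("subject", "subject01")),
            group=str(cfg.get("group", "meningioma")),
            voi_label=label,
            n_voxels=n_usable,
            n_excluded=n_excluded,
            mean_ktrans=mk,
            mean_rbf=mr,
            voi_volume=m.n_voxels * vox_mm3,
        ))
        log.info("VOI %s: n=%d excluded=%d mean_ktrans=%g mean_rbf=%g", label, n_usable, n_excluded, mk, mr)
    io.write_table(rows, out / "voi_summary.csv")
    return rows


@_stage("stats")
def _stats_stage(cfg: dict, summaries, out: Path):
    if summaries is None:
        paths = cfg.get("paths") or {}
        if "voi_table" not in paths:
            raise ConfigError("stats mode needs paths.voi_table or upstream VOI summaries")
        summaries = io.read_table(paths["voi_table"])
    comparisons, text = voistats.group_comparison_report(summaries, sidedness=cfg["stats"].get("sidedness", "two"))
    (out / "stats_report.txt").write_text(text)
    import pandas as pd

    pd.DataFrame([dataclasses.asdict(c) for c in comparisons]).to_csv(out / "stats_report.csv", index=False)
    return comparisons, text


def run(config: dict, out_dir: str | Path | None = None, seed: int | None = None):
    """Execute the configured pipeline mode; returns a result dict.

    ``seed`` overrides the config seed everywhere (phantom noise and fit
    multi-starts), making the whole artefact set reproducible.
    """
    cfg = _merged(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    mode = cfg.get("mode", "all")
    if mode not in ("simulate", "analyse", "stats", "all"):
        raise ConfigError(f"unknown mode {mode!r}")
    out = Path(out_dir or cfg.get("out_dir") or "dceperf_out")
    out.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    result: dict = {"out_dir": out, "config_hash": io.config_hash(cfg), "seed": cfg.get("seed")}
    try:
        log.info("run start: mode=%s seed=%s config_hash=%s", mode, cfg.get("seed"), result["config_hash"])
        series = t10 = maps = None
        masks: dict = {}
        summaries = None
        if mode in ("simulate", "all"):
            series, t10, truth, masks = _simulate(cfg, out)
            result["truth"] = truth
        if mode == "analyse":
            series, t10, masks = _load(cfg)
        if mode in ("analyse", "all"):
            aif_curve = _aif_stage(cfg, series, t10, masks, out)
            maps = _fit_stage(cfg, series, t10, aif_curve, masks, out)
            summaries = _voi_stage(cfg, series, maps, masks, out)
            result.update(aif=aif_curve, maps=maps, summaries=summaries)
        if mode in ("stats", "all"):
            comparisons, text = _stats_stage(cfg, summaries, out)
            result.update(comparisons=comparisons, report=text)
        log.info("run complete")
    finally:
        log.removeHandler(handler)
        handler.close()
    return result
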