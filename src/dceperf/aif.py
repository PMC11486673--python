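"""Measured arterial input function: candidate scoring, extraction, and
whole-blood to plasma conversion.

A subject-specific AIF is taken from an artery mask by ranking voxel
concentration curves against a canonical arterial shape (by default the
Parker population curve evaluated on the subject's frame grid) and averaging
the best k voxels. Because the contrast agent distributes only in plasma,
the averaged whole-blood curve is divided by (1 - Hct) — and by a
partial-volume factor when the vessel under-fills its voxels — to obtain
plasma concentration.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

from ._errors import InputError

__all__ = ["AIFCurve", "score_aif_candidates", "extract_aif", "blood_to_plasma", "write_aif_csv", "read_aif_csv"]

#: default scoring weights: shape (correlation) vs normalised peak amplitude
SCORE_W_CORR = 0.7
SCORE_W_PEAK = 0.3


@dataclasses.dataclass
class AIFCurve:
    """A concentration-time curve used to drive kinetic fits.

    t in minutes, cp in mM. ``source`` records provenance ('measured' from an
    artery mask, 'analytic' from a population model); ``quality`` is the mean
    shape score of the selected voxels.
    """

    t: np.ndarray
    cp: np.ndarray
    source: str = "measured"
    n_voxels_used: int = 0
    quality: float = float("nan")

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=np.float64)
        self.cp = np.asarray(self.cp, dtype=np.float64)
        if self.t.shape != self.cp.shape:
            raise InputError("AIF time and concentration lengths differ")
        if not np.all(np.isfinite(self.cp)):
            raise InputError("AIF concentrations must be finite")
        if self.source == "measured" and self.n_voxels_used < 1:
            raise InputError("measured AIF must use >= 1 voxel")


def score_aif_candidates(
    conc_series: np.ndarray,
    template: np.ndarray,
    w_corr: float = SCORE_W_CORR,
    w_peak: float = SCORE_W_PEAK,
):
    """Score candidate artery voxels against a canonical AIF shape.

    ``conc_series`` is (n_voxels, n_frames). The score of a voxel is
    w_corr * Pearson correlation with the template (clipped at 0, and 0 for
    flat curves) plus w_peak * its peak amplitude normalised by the largest
    candidate peak. Returns ``(order, scores)``: candidate indices in
    descending score order (ties broken by ascending voxel index) and the
    per-candidate scores in input order.
    """
    conc = np.asarray(conc_series, dtype=np.float64)
    if conc.ndim != 2 or conc.shape[0] < 1:
        raise InputError("need a (n_voxels, n_frames) array with >= 1 voxel")
    tem = np.asarray(template, dtype=np.float64)
    if tem.shape != (conc.shape[1],):
        raise InputError("template length must match the frame count")

    tem_c = tem - tem.mean()
    tem_n = np.linalg.norm(tem_c)
    scores = np.zeros(conc.shape[0])
    peaks = np.nanmax(conc, axis=1)
    peaks = np.where(np.isfinite(peaks), peaks, 0.0)
    peak_ref = peaks.max()
    for i, curve in enumerate(conc):
        c = np.nan_to_num(curve, nan=0.0)
        cc = c - c.mean()
        nc = np.linalg.norm(cc)
        corr = float(cc @ tem_c / (nc * tem_n)) if nc > 0 and tem_n > 0 else 0.0
        peak = peaks[i] / peak_ref if peak_ref > 0 else 0.0
        scores[i] = w_corr * max(corr, 0.0) + w_peak * max(peak, 0.0)
    order = np.lexsort((np.arange(len(scores)), -scores))
    return order, scores


def extract_aif(
    conc_series: np.ndarray,
    t_minutes: np.ndarray,
    k: int,
    template: np.ndarray,
) -> AIFCurve:
    """Mean whole-blood curve of the k best-scoring artery voxels."""
    conc = np.asarray(conc_series, dtype=np.float64)
    if conc.ndim != 2 or conc.shape[0] < 1:
        raise InputError("need a (n_voxels, n_frames) array with >= 1 voxel")
    if k < 1 or k > conc.shape[0]:
        raise InputError(f"k={k} voxels requested but mask holds {conc.shape[0]}")
    order, scores = score_aif_candidates(conc, template)
    pick = order[:k]
    curve = np.nanmean(conc[pick], axis=0)
    curve = np.nan_to_num(curve, nan=0.0)
    return AIFCurve(
        t=np.asarray(t_minutes, dtype=np.float64),
        cp=curve,
        source="measured",
        n_voxels_used=int(k),
        quality=float(scores[pick].mean()),
    )


def blood_to_plasma(cb: AIFCurve, hct: float = 0.45, pv_factor: float = 1.0) -> AIFCurve:
    """Whole-blood -> plasma concentration: cp = cb / ((1 - hct) * pv_factor)."""
    if not 0 <= hct < 1:
        raise InputError(f"haematocrit must be in [0, 1), got {hct}")
    if not pv_factor > 0:
        raise InputError(f"pv_factor must be > 0, got {pv_factor}")
    return AIFCurve(
        t=cb.t.copy(),
        cp=cb.cp / ((1.0 - hct) * pv_factor),
        source=cb.source,
        n_voxels_used=max(cb.n_voxels_used, 1),
        quality=cb.quality,
    )


def write_aif_csv(aif: AIFCurve, path: str | Path) -> Path:
    """Two-column CSV (time_s, cp_mM) with '#'-prefixed metadata lines."""
    path = Path(path)
    lines = [
        f"# source: {aif.source}",
        f"# n_voxels_used: {aif.n_voxels_used}",
        f"# quality: {float(aif.quality)!r}",
        "time_s,cp_mM",
    ]
    lines += [f"{float(60.0 * t)!r},{float(c)!r}" for t, c in zip(aif.t, aif.cp)]
    path.write_text("\n".join(lines) + "\n")
    return path


def read_aif_csv(path: str | Path) -> AIFCurve:
    meta = {}
    t, cp = [], []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            key, _, val = line[1:].partition(":")
            meta[key.strip()] = val.strip()
        elif line and not line.startswith("time_s"):
            a, b = line.split(",")
            t.append(float(a) / 60.0)
            cp.append(float(b))
    return AIFCurve(
        t=np.asarray(t),
        cp=np.asarray(cp),
        source=meta.get("source", "measured"),
        n_voxels_used=int(meta.get("n_voxels_used", 1) or 1),
        quality=float(meta.get("quality", "nan")),
    )
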