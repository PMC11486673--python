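"""VOI summaries and exact small-sample group statistics.

Parametric maps are summarised as the mean over each volume of interest
(contrast-enhancing tumour and a mirrored contralateral control), skipping
voxels removed by the zero-signal/failed-fit rule. Group comparisons use
nonparametric tests with nulls computed by complete enumeration — the right
choice at cohort sizes of a handful of subjects, where asymptotic p-values
are unreliable:

* Wilcoxon matched-pairs signed-rank (tumour vs contralateral control within
  a group), null over all 2^n sign assignments, mid-ranks for tied |d|,
  zero differences dropped;
* Mann-Whitney U (one group vs another), null over all C(n+m, n) group
  assignments of the pooled values, with the conventional half-count for
  ties;
* Pearson product-moment correlation with the usual t reference
  distribution (for parameter-vs-volume associations).

Exact p-values are ratios of integer counts; two-sided p is twice the
smaller tail, capped at 1.
"""

from __future__ import annotations

import dataclasses
import warnings
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import ndimage, stats

from ._errors import EstimationError, InputError
from .io import DynamicSeries, MaskVOI, VolumeMap

__all__ = [
    "VOISummary",
    "GroupComparison",
    "voi_mean",
    "mirror_control_voi",
    "wilcoxon_signed_rank_exact",
    "mann_whitney_exact",
    "pearson_correlation",
    "enhancement_curve",
    "group_comparison_report",
    "render_value",
]

_ALTERNATIVES = ("two-sided", "greater", "less")


@dataclasses.dataclass
class VOISummary:
    """Per-subject, per-VOI mean parameter values."""

    subject: str
    group: str  # 'meningioma' | 'other'
    voi_label: str
    n_voxels: int
    n_excluded: int
    mean_ktrans: float
    mean_rbf: float
    voi_volume: float = float("nan")  # mm^3


@dataclasses.dataclass
class GroupComparison:
    """Outcome of one statistical comparison."""

    test: str
    label: str
    statistic: float
    p_value: float
    sidedness: str  # 'one' | 'two'
    n: tuple[int, ...]
    median_of_differences: float = float("nan")
    group_medians: tuple[float, float] | None = None
    p_count: int | None = None  # exact p = p_count / p_total
    p_total: int | None = None


def render_value(x: float, decimals: int) -> str:
    """Half-up decimal rendering (0.03125 -> '0.0313' at 4 decimals)."""
    if not np.isfinite(x):
        return "nan"
    q = Decimal(1).scaleb(-decimals)
    return str(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# VOI summarisation


def voi_mean(vmap: VolumeMap, mask: MaskVOI, excluded: MaskVOI | None = None):
    """Mean of ``vmap`` over ``mask``, skipping excluded and non-finite voxels.

    Returns ``(mean, n_used, n_excluded)``; an all-excluded VOI yields NaN
    with a warning rather than an error.
    """
    if vmap.data.shape != mask.data.shape:
        raise InputError("map and mask must share a grid")
    sel = mask.data.astype(bool)
    if excluded is not None:
        if excluded.data.shape != sel.shape:
            raise InputError("excluded mask grid mismatch")
        usable = sel & ~excluded.data.astype(bool)
    else:
        usable = sel
    vals = vmap.data[usable]
    finite = np.isfinite(vals)
    n_used = int(finite.sum())
    n_excluded = int(sel.sum()) - n_used
    if n_used == 0:
        warnings.warn(f"VOI '{mask.label}' has no usable voxels for map '{vmap.name}'")
        return float("nan"), 0, n_excluded
    return float(vals[finite].mean()), n_used, n_excluded


def mirror_control_voi(
    tumour_mask: MaskVOI,
    brain_mask: MaskVOI,
    midline_axis: int = 0,
    midline_position: float | None = None,
) -> MaskVOI:
    """Contralateral control VOI: the tumour mask reflected across the
    midline plane and clipped to brain.

    If the reflection lands partly outside the brain (or overlaps a tumour
    crossing the midline, which is warned about and removed), the control is
    topped up by deterministic dilation within brain-minus-tumour until it
    matches the tumour voxel count.
    """
    if tumour_mask.data.shape != brain_mask.data.shape:
        raise InputError("tumour and brain masks must share a grid")
    tum = tumour_mask.data.astype(bool)
    brain = brain_mask.data.astype(bool)
    n = tum.shape[midline_axis]
    pos = (n - 1) / 2.0 if midline_position is None else midline_position

    src = np.argwhere(tum)
    dst = src.copy()
    dst[:, midline_axis] = np.round(2.0 * pos - src[:, midline_axis]).astype(int)
    inside = (dst[:, midline_axis] >= 0) & (dst[:, midline_axis] < n)
    refl = np.zeros_like(tum)
    refl[tuple(dst[inside].T)] = True

    if (refl & tum).any():
        warnings.warn("tumour crosses the midline; control taken from the non-overlapping reflected part")
        refl &= ~tum
    control = refl & brain
    target = int(tum.sum())
    if control.sum() == 0:
        raise InputError(
            "reflected tumour VOI lies entirely outside the brain; supply a manual control mask"
        )
    if control.sum() < 0.9 * target:
        allowed = brain & ~tum
        while control.sum() < target:
            grown = ndimage.binary_dilation(control) & allowed
            new = np.argwhere(grown & ~control)
            if new.size == 0:
                break
            room = target - int(control.sum())
            flat = np.ravel_multi_index(new.T, control.shape)
            keep = new[np.argsort(flat)][:room]
            control[tuple(keep.T)] = True
    return MaskVOI(control.astype(np.uint8), brain_mask.affine, "control")


# ---------------------------------------------------------------------------
# Exact tests

_MAX_EXACT_N = 20


def _check_alternative(alternative: str):
    if alternative not in _ALTERNATIVES:
        raise InputError(f"alternative must be one of {_ALTERNATIVES}, got {alternative!r}")


def _half_ranks(values: np.ndarray) -> np.ndarray:
    """Mid-ranks scaled by 2 so tied ranks become exact integers."""
    r2 = np.rint(2.0 * stats.rankdata(values)).astype(np.int64)
    return r2


def wilcoxon_signed_rank_exact(x, y, alternative: str = "two-sided") -> GroupComparison:
    """Exact Wilcoxon matched-pairs signed-rank test on differences x - y.

    W is the sum of positive-signed mid-ranks; the null enumerates all 2^n
    sign assignments of the nonzero differences. ``alternative='greater'``
    means x tends to exceed y. The reported median_of_differences is the
    sample median of x - y.
    """
    _check_alternative(alternative)
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.size < 2:
        raise InputError("paired samples must have equal length >= 2")
    d = x - y
    med = float(np.median(d))
    dnz = d[d != 0]
    n = dnz.size
    if n == 0:
        raise EstimationError("all paired differences are zero")
    if n > _MAX_EXACT_N:
        raise InputError(f"exact enumeration limited to {_MAX_EXACT_N} nonzero pairs, got {n}")

    r2 = _half_ranks(np.abs(dnz))
    w2_obs = int(r2[dnz > 0].sum())
    # distribution of 2W over all sign assignments, by iterated convolution
    total = int(r2.sum())
    dist = np.zeros(total + 1, dtype=np.int64)
    dist[0] = 1
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = dist + shifted
    n_total = int(dist.sum())  # 2^n
    count_le = int(dist[: w2_obs + 1].sum())
    count_ge = int(dist[w2_obs:].sum())
    if alternative == "greater":
        cnt = count_ge
    elif alternative == "less":
        cnt = count_le
    else:
        cnt = min(n_total, 2 * min(count_le, count_ge))
    return GroupComparison(
        test="wilcoxon_signed_rank_exact",
        label="",
        statistic=w2_obs / 2.0,
        p_value=cnt / n_total,
        sidedness="two" if alternative == "two-sided" else "one",
        n=(x.size,),
        median_of_differences=med,
        p_count=cnt,
        p_total=n_total,
    )


def mann_whitney_exact(a, b, alternative: str = "two-sided") -> GroupComparison:
    """Exact Mann-Whitney U test.

    U = #{(i, j): a_i > b_j} + half the ties; the null enumerates all
    C(n_a + n_b, n_a) assignments of the pooled values to groups (a
    subset-sum dynamic programme over mid-ranks — identical counts, no
    explicit combination listing). ``alternative='greater'`` means a tends
    to exceed b.
    """
    _check_alternative(alternative)
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    na, nb = a.size, b.size
    if na < 1 or nb < 1:
        raise InputError("both groups need at least one value")
    if na + nb > _MAX_EXACT_N:
        raise InputError(f"exact enumeration limited to {_MAX_EXACT_N} pooled values")

    pooled = np.concatenate([a, b])
    r2 = _half_ranks(pooled)  # 2 * mid-ranks
    # 2U = 2 * (rank-sum of a) - na*(na+1)
    u2_obs = int(r2[:na].sum()) - na * (na + 1)
    # DP over (number chosen, 2*rank-sum)
    total = int(r2.sum())
    dp = np.zeros((na + 1, total + 1), dtype=np.int64)
    dp[0, 0] = 1
    for r in r2:
        # counts iterate downwards so each pooled value is used at most once
        for c in range(na, 0, -1):
            dp[c, r:] += dp[c - 1, : total + 1 - r]
    dist = dp[na]  # counts of each possible 2*rank-sum for group a
    n_total = int(dist.sum())  # C(na+nb, na)
    offset = na * (na + 1)
    u2 = np.arange(total + 1) - offset  # possible 2U values
    count_le = int(dist[u2 <= u2_obs].sum())
    count_ge = int(dist[u2 >= u2_obs].sum())
    if alternative == "greater":
        cnt = count_ge
    elif alternative == "less":
        cnt = count_le
    else:
        cnt = min(n_total, 2 * min(count_le, count_ge))
    return GroupComparison(
        test="mann_whitney_exact",
        label="",
        statistic=u2_obs / 2.0,
        p_value=cnt / n_total,
        sidedness="two" if alternative == "two-sided" else "one",
        n=(na, nb),
        group_medians=(float(np.median(a)), float(np.median(b))),
        p_count=cnt,
        p_total=n_total,
    )


def pearson_correlation(x, y, alternative: str = "two-sided") -> GroupComparison:
    """Pearson product-moment correlation with the t-distribution p-value."""
    _check_alternative(alternative)
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.size < 3:
        raise InputError("correlation needs equal-length samples with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise EstimationError("zero variance in a correlation input")
    res = stats.pearsonr(x, y, alternative=alternative)
    return GroupComparison(
        test="pearson",
        label="",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        sidedness="two" if alternative == "two-sided" else "one",
        n=(x.size,),
    )


# ---------------------------------------------------------------------------
# Curves and reporting


def enhancement_curve(series: DynamicSeries, mask: MaskVOI, baseline_frames: int = 3) -> np.ndarray:
    """Mean percent signal enhancement over a VOI: 100 (S(t) - S0) / S0."""
    if mask.n_voxels == 0:
        raise InputError("enhancement curve needs a nonempty mask")
    if series.data.shape[:3] != mask.data.shape:
        raise InputError("series and mask must share a grid")
    curve = series.data[mask.data.astype(bool)].mean(axis=0)
    s0 = float(curve[: max(1, baseline_frames)].mean())
    if s0 <= 0:
        raise EstimationError("non-positive baseline signal in VOI")
    return 100.0 * (curve - s0) / s0


def _summaries_frame(summaries):
    import pandas as pd

    if hasattr(summaries, "columns"):
        return summaries.copy()
    return pd.DataFrame([dataclasses.asdict(s) for s in summaries])


def group_comparison_report(summaries, sidedness: str = "two"):
    """Run the study's comparisons over per-subject VOI summaries.

    (i) paired Wilcoxon tumour-vs-control within the meningioma group for
    Ktrans and rBF (median_of_differences is control - tumour), (ii) exact
    Mann-Whitney meningioma-vs-other on tumour values of both parameters,
    (iii) Pearson correlation of each parameter against tumour VOI volume
    within the meningioma group when volumes are available. With
    ``sidedness='one'`` the directional hypotheses are tumour > control and
    meningioma > other.

    Returns ``(comparisons, report_text)``; undersized groups skip their
    test with a warning instead of failing the report. p-values render
    half-up to 4 decimals and medians to 3.
    """
    if sidedness not in ("one", "two"):
        raise InputError("sidedness must be 'one' or 'two'")
    df = _summaries_frame(summaries)
    df = df.sort_values(["subject", "voi_label"], kind="stable")
    tum_lbl = df["voi_label"].isin(("tumour", "tumour_CE"))
    men = df["group"] == "meningioma"
    results: list[GroupComparison] = []
    lines = ["Group comparison report", "======================="]

    paired = df[men & tum_lbl].merge(
        df[men & (df["voi_label"] == "control")], on="subject", suffixes=("_tum", "_ctl")
    )
    for param in ("ktrans", "rbf"):
        col = f"mean_{param}"
        if len(paired) >= 2:
            alt = "two-sided" if sidedness == "two" else "less"  # control < tumour
            try:
                r = wilcoxon_signed_rank_exact(
                    paired[f"{col}_ctl"].to_numpy(), paired[f"{col}_tum"].to_numpy(), alternative=alt
                )
                r.label = param
                results.append(r)
                lines.append(
                    f"Wilcoxon {param} (control vs tumour, n={r.n[0]}): "
                    f"median diff {render_value(r.median_of_differences, 3)}, "
                    f"W={r.statistic:g}, p={render_value(r.p_value, 4)} "
                    f"({r.p_count}/{r.p_total}, {r.sidedness}-sided)"
                )
            except EstimationError as e:
                warnings.warn(f"paired Wilcoxon on {param} skipped: {e}")
        else:
            warnings.warn(f"paired Wilcoxon on {param} skipped: fewer than 2 complete pairs")

    men_t = df[men & tum_lbl]
    oth_t = df[(df["group"] == "other") & tum_lbl]
    for param in ("ktrans", "rbf"):
        col = f"mean_{param}"
        if len(men_t) >= 1 and len(oth_t) >= 1:
            alt = "two-sided" if sidedness == "two" else "greater"  # meningioma > other
            r = mann_whitney_exact(men_t[col].to_numpy(), oth_t[col].to_numpy(), alternative=alt)
            r.label = param
            results.append(r)
            gm = r.group_medians
            lines.append(
                f"Mann-Whitney {param} (meningioma n={r.n[0]} vs other n={r.n[1]}): "
                f"medians {render_value(gm[0], 3)} vs {render_value(gm[1], 3)}, "
                f"U={r.statistic:g}, p={render_value(r.p_value, 4)} "
                f"({r.p_count}/{r.p_total}, {r.sidedness}-sided)"
            )
        else:
            warnings.warn(f"Mann-Whitney on {param} skipped: a group is empty")

    vols = men_t["voi_volume"].to_numpy(dtype=float) if "voi_volume" in men_t else np.array([])
    if vols.size >= 3 and np.all(np.isfinite(vols)) and np.std(vols) > 0:
        for param in ("ktrans", "rbf"):
            try:
                r = pearson_correlation(
                    vols, men_t[f"mean_{param}"].to_numpy(),
                    alternative="two-sided" if sidedness == "two" else "greater",
                )
                r.label = f"{param}_vs_volume"
                results.append(r)
                lines.append(
                    f"Pearson {param} vs tumour volume (n={r.n[0]}): "
                    f"r={render_value(r.statistic, 3)}, p={render_value(r.p_value, 4)}"
                )
            except EstimationError as e:
                warnings.warn(f"Pearson on {param} skipped: {e}")
    else:
        warnings.warn("Pearson vs volume skipped: needs >= 3 finite, non-constant volumes")

    return results, "\n".join(lines) + "\n"
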