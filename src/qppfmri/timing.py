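"""Peak-timing lead/lag analysis within long QPPs.

During a long (e.g. 9 s) quasi-periodic pattern, different regions reach their
peak BOLD activity at different frames; in healthy animals the basal forebrain
peaks before the default-mode-like network.  This module phase-aligns
representative QPPs across groups, estimates per-voxel mean peak times (argmax
within each occurrence window of the NON-z-scored signal, averaged over
occurrences), compares ROI timing distributions pairwise, and runs a two-way
genotype x age ANOVA on voxel-wise peak timings.

Caveat carried over from the analysis design: voxels are treated as
independent observations in the ROI-pair tests and the ANOVA, ignoring
spatial dependence; p-values are anti-conservative in that respect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .compare import bh_fdr
from .detect import _flat_corr
from .preprocess import ImageSeries
from .simulate import Atlas

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Phase alignment
# ---------------------------------------------------------------------------

def phase_align(rqpp_ref: np.ndarray, rqpp_other: np.ndarray, max_shift: int
                ) -> tuple[np.ndarray, int]:
    """Circularly shift ``rqpp_other`` to maximise its flattened space-time
    correlation with ``rqpp_ref``; returns (aligned pattern, applied shift).

    Shifts are searched over [-max_shift, max_shift]; ties prefer the smaller
    |shift|, then the smaller shift.
    """
    ref = np.asarray(rqpp_ref, dtype=float)
    other = np.asarray(rqpp_other, dtype=float)
    if ref.shape != other.shape:
        raise ValueError("patterns must have identical shape")
    best_corr, best_shift = -np.inf, None
    for s in sorted(range(-max_shift, max_shift + 1), key=lambda x: (abs(x), x)):
        r = _flat_corr(ref, np.roll(other, s, axis=1))
        if np.isfinite(r) and r > best_corr + 1e-15:
            best_corr, best_shift = r, s
    if best_shift is None:
        raise ValueError("no shift gave a finite correlation (degenerate pattern)")
    return np.roll(other, best_shift, axis=1), best_shift


# ---------------------------------------------------------------------------
# Voxel-wise peak timings
# ---------------------------------------------------------------------------

@dataclass
class PeakTimingResult:
    roi_labels: list[int]
    voxel_timings: dict[int, np.ndarray]   # label -> per-voxel mean peak frame
    roi_means: dict[int, float]            # label -> mean over voxels
    diff_matrix: np.ndarray                # (R, R), diff[x, y] = mean_y - mean_x
    window_w: int
    tr_seconds: float
    excluded_voxels: dict[int, int]        # label -> count of constant voxels


def voxel_peak_timings(series_raw: ImageSeries, occurrences: np.ndarray,
                       atlas: Atlas, window_w: int) -> PeakTimingResult:
    """Mean peak frame per voxel across QPP occurrences, grouped by ROI.

    Uses the non-z-scored (but otherwise preprocessed) series.  Within each
    occurrence window the peak is the argmax frame (maximum, not extremum
    magnitude; ties resolve to the earliest frame).  Voxels that are constant
    within every window are excluded from ROI statistics and counted.
    Peak frames are invariant to positive rescaling of the series.
    """
    if series_raw.zscored:
        raise ValueError("peak timing must use the non-z-scored series")
    occ = np.asarray(occurrences, dtype=int)
    if occ.size == 0:
        raise ValueError("need at least one occurrence")
    W = window_w
    data = series_raw.data
    peaks = np.empty((occ.size, data.shape[0]))
    flat = np.ones(data.shape[0], dtype=bool)
    for k, f in enumerate(occ):
        seg = data[:, f:f + W]
        if seg.shape[1] != W:
            raise ValueError(f"occurrence {f} window exceeds series length")
        peaks[k] = np.argmax(seg, axis=1)
        flat &= np.ptp(seg, axis=1) < 1e-12
    mean_peak = peaks.mean(axis=0)

    voxel_timings, roi_means, excluded = {}, {}, {}
    labels = atlas.roi_labels
    for lbl in labels:
        rows = atlas.roi_rows(lbl)
        good = rows[~flat[rows]]
        excluded[lbl] = int(flat[rows].sum())
        if excluded[lbl]:
            logger.warning("ROI %d: excluded %d constant voxel(s) from "
                           "timing stats", lbl, excluded[lbl])
        voxel_timings[lbl] = mean_peak[good]
        roi_means[lbl] = (float(mean_peak[good].mean()) if good.size
                          else np.nan)
    means = np.array([roi_means[l] for l in labels])
    diff = means[None, :] - means[:, None]   # diff[x, y] = mean_y - mean_x
    return PeakTimingResult(roi_labels=labels, voxel_timings=voxel_timings,
                            roi_means=roi_means, diff_matrix=diff,
                            window_w=W, tr_seconds=series_raw.tr_seconds,
                            excluded_voxels=excluded)


def roi_pairwise_timing_tests(result: PeakTimingResult, q: float = 0.05
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Unpaired two-tailed t-tests on voxel-wise mean peak timings for every
    ROI pair, BH-FDR across pairs.

    Returns (p_matrix, reject_matrix), both symmetric (R x R, NaN/False on
    the diagonal and for ROIs with < 2 usable voxels, which are logged).
    """
    labels = result.roi_labels
    R = len(labels)
    p_mat = np.full((R, R), np.nan)
    pairs, pvals = [], []
    for i in range(R):
        for j in range(i + 1, R):
            x = result.voxel_timings[labels[i]]
            y = result.voxel_timings[labels[j]]
            if x.size < 2 or y.size < 2:
                logger.warning("ROI pair (%d, %d): <2 voxels, excluded",
                               labels[i], labels[j])
                continue
            if np.array_equal(x, y) or (x.std() < 1e-15 and y.std() < 1e-15
                                        and np.isclose(x.mean(), y.mean())):
                t, p = 0.0, 1.0
            else:
                t, p = stats.ttest_ind(x, y, equal_var=True)
            pairs.append((i, j))
            pvals.append(float(p))
    reject_mat = np.zeros((R, R), dtype=bool)
    if pvals:
        rej = bh_fdr(np.asarray(pvals), q)
        for (i, j), p, r in zip(pairs, pvals, rej):
            p_mat[i, j] = p_mat[j, i] = p
            reject_mat[i, j] = reject_mat[j, i] = bool(r)
    return p_mat, reject_mat


# ---------------------------------------------------------------------------
# Two-way ANOVA on voxel peak timings
# ---------------------------------------------------------------------------

@dataclass
class AnovaResult:
    f: dict[str, float]            # genotype, age, interaction
    p: dict[str, float]
    table: pd.DataFrame            # full ANOVA table (Type II SS)
    posthoc: pd.DataFrame          # pairwise Student t with BH-FDR
    note: str = ""


def two_way_anova_timings(values: np.ndarray, genotype: np.ndarray,
                          age: np.ndarray, q: float = 0.05) -> AnovaResult:
    """Two-way ANOVA (genotype, age, genotype x age) on voxel peak timings.

    Type II sums of squares, robust to unbalanced voxel counts (identical to
    the textbook decomposition under balance).  Post-hoc: Student t-tests for
    genotype within each age and age within each genotype, BH-FDR corrected.
    Requires a full 2 x 2 design with >= 2 observations per cell.
    """
    df = pd.DataFrame({"value": np.asarray(values, dtype=float),
                       "genotype": np.asarray(genotype).astype(str),
                       "age": np.asarray(age).astype(str)})
    cells = df.groupby(["genotype", "age"]).size()
    g_levels = sorted(df["genotype"].unique())
    a_levels = sorted(df["age"].unique())
    if len(g_levels) != 2 or len(a_levels) != 2:
        raise ValueError("need exactly 2 genotype and 2 age levels")
    for g in g_levels:
        for a in a_levels:
            if cells.get((g, a), 0) < 2:
                raise ValueError(f"cell ({g}, {a}) has < 2 observations")

    note = ""
    if df["value"].std() < 1e-15:
        note = "all observations identical; all sums of squares are zero"
        zero = {"genotype": 0.0, "age": 0.0, "interaction": 0.0}
        ones = {k: 1.0 for k in zero}
        return AnovaResult(f=zero, p=ones, table=pd.DataFrame(),
                           posthoc=_posthoc(df, g_levels, a_levels, q),
                           note=note)

    model = smf.ols("value ~ C(genotype) * C(age)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    key = {"C(genotype)": "genotype", "C(age)": "age",
           "C(genotype):C(age)": "interaction"}
    f = {key[k]: float(table.loc[k, "F"]) for k in key}
    p = {key[k]: float(table.loc[k, "PR(>F)"]) for k in key}
    return AnovaResult(f=f, p=p, table=table,
                       posthoc=_posthoc(df, g_levels, a_levels, q), note=note)


def _posthoc(df: pd.DataFrame, g_levels, a_levels, q: float) -> pd.DataFrame:
    rows = []
    for a in a_levels:  # genotype effect within each age
        x = df.loc[(df.genotype == g_levels[0]) & (df.age == a), "value"]
        y = df.loc[(df.genotype == g_levels[1]) & (df.age == a), "value"]
        rows.append(("genotype", f"age={a}", *_safe_t(x, y)))
    for g in g_levels:  # age effect within each genotype
        x = df.loc[(df.genotype == g) & (df.age == a_levels[0]), "value"]
        y = df.loc[(df.genotype == g) & (df.age == a_levels[1]), "value"]
        rows.append(("age", f"genotype={g}", *_safe_t(x, y)))
    out = pd.DataFrame(rows, columns=["effect", "within", "t", "p"])
    out["significant"] = bh_fdr(out["p"].to_numpy(), q)
    return out


def _safe_t(x, y) -> tuple[float, float]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.std(ddof=1) < 1e-15 and y.std(ddof=1) < 1e-15:
        return (0.0, 1.0) if np.isclose(x.mean(), y.mean()) else (np.inf, 0.0)
    t, p = stats.ttest_ind(x, y, equal_var=True)
    return float(t), float(p)
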