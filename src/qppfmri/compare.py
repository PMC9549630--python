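"""Voxel-wise and region-wise group statistics for matched QPPs.

Covers the statistical back half of the pipeline: activation t-maps of one
group's rQPP (one-sample t across occurrences), voxel-wise group-difference
maps (pooled two-sample t), Cohen's d profiles on ROI time courses,
subject-level occurrence-rate comparisons, and the reference static
functional-connectivity (FC) analysis.  All voxel maps use Benjamini-Hochberg
FDR at q = 0.05 over every in-mask voxel-frame test of the map, followed by a
per-frame 3D connected-component extent filter (6-connectivity, minimum 10
voxels).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from .detect import QPP, find_stc_peaks, sliding_template_correlation
from .preprocess import ImageSeries
from .simulate import Atlas

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------

def bh_fdr(pvalues: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at level q."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p.ravel(), alpha=q, method="fdr_bh")
    return reject.reshape(p.shape)


# ---------------------------------------------------------------------------
# Occurrence segments and voxel-wise maps
# ---------------------------------------------------------------------------

@dataclass
class StatMap:
    """Voxel-frame statistic map with FDR + cluster-extent thresholding."""

    stat: np.ndarray         # (V, W)
    p: np.ndarray            # (V, W)
    significant: np.ndarray  # (V, W) bool, after FDR + extent filtering
    q_threshold: float = 0.05
    cluster_extent_min: int = 10


def occurrence_segments(series: ImageSeries, qpp: QPP) -> np.ndarray:
    """Stack the series segments at each QPP occurrence: (n_occ, V, W)."""
    W = qpp.window_w
    occ = np.asarray(qpp.occurrences, dtype=int)
    if occ.size == 0:
        raise ValueError("QPP has zero occurrences; nothing to stack")
    return np.stack([series.data[:, f:f + W] for f in occ])


def _extent_filter(rejected: np.ndarray, mask_index: np.ndarray,
                   grid_shape: tuple[int, int, int], min_voxels: int
                   ) -> np.ndarray:
    """Keep only voxels in >= min_voxels 6-connected 3D components, per frame."""
    V, W = rejected.shape
    out = np.zeros_like(rejected)
    ii, jj, kk = mask_index.T
    for w in range(W):
        vol = np.zeros(grid_shape, dtype=bool)
        vol[ii, jj, kk] = rejected[:, w]
        labeled, n = ndimage.label(vol)  # default structure = 6-connectivity
        if n == 0:
            continue
        counts = np.bincount(labeled.ravel())
        keep = counts >= min_voxels
        keep[0] = False
        out[:, w] = keep[labeled[ii, jj, kk]]
    return out


def _finalise_map(t: np.ndarray, p: np.ndarray, mask_index, grid_shape,
                  q: float, min_cluster_voxels: int) -> StatMap:
    reject = bh_fdr(p, q)
    significant = _extent_filter(reject, mask_index, grid_shape,
                                 min_cluster_voxels)
    return StatMap(stat=t, p=p, significant=significant, q_threshold=q,
                   cluster_extent_min=min_cluster_voxels)


def activation_tmap(segments: np.ndarray, mask_index: np.ndarray,
                    grid_shape: tuple[int, int, int], q: float = 0.05,
                    min_cluster_voxels: int = 10) -> StatMap:
    """One-sample t vs 0 across occurrences, per voxel-frame, two-sided,
    BH-FDR jointly over the whole map, then the 10-voxel extent filter."""
    n = segments.shape[0]
    if n < 3:
        raise ValueError(f"need >= 3 occurrences for a t-map, got {n}")
    mean = segments.mean(axis=0)
    sd = segments.std(axis=0, ddof=1)
    degenerate = sd < 1e-12
    if degenerate.any():
        logger.warning("activation_tmap: %d zero-variance voxel-frame(s); "
                       "p set to 1", int(degenerate.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[degenerate] = 0.0
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    p[degenerate] = 1.0
    return _finalise_map(t, p, mask_index, grid_shape, q, min_cluster_voxels)


def group_difference_tmap(segments_a: np.ndarray, segments_b: np.ndarray,
                          mask_index: np.ndarray,
                          grid_shape: tuple[int, int, int], q: float = 0.05,
                          min_cluster_voxels: int = 10) -> StatMap:
    """Pooled-variance (Student) two-sample t per voxel-frame, group A minus
    group B, with the same FDR + extent thresholding as activation maps."""
    na, nb = segments_a.shape[0], segments_b.shape[0]
    if na < 3 or nb < 3:
        raise ValueError("need >= 3 occurrences per group")
    ma, mb = segments_a.mean(axis=0), segments_b.mean(axis=0)
    va = segments_a.var(axis=0, ddof=1)
    vb = segments_b.var(axis=0, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    degenerate = sp2 < 1e-24
    if degenerate.any():
        logger.warning("group_difference_tmap: %d zero-variance "
                       "voxel-frame(s); p set to 1", int(degenerate.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    t[degenerate] = 0.0
    p = 2.0 * stats.t.sf(np.abs(t), df=na + nb - 2)
    p[degenerate] = 1.0
    return _finalise_map(t, p, mask_index, grid_shape, q, min_cluster_voxels)


# ---------------------------------------------------------------------------
# Effect sizes on ROI time courses
# ---------------------------------------------------------------------------

def roi_timecourses(segments: np.ndarray, atlas: Atlas) -> dict[int, np.ndarray]:
    """Occurrence-wise ROI-mean time courses: label -> (n_occ, W)."""
    return {lbl: segments[:, atlas.roi_rows(lbl), :].mean(axis=1)
            for lbl in atlas.roi_labels}


def cohens_d_profile(roi_tc_a: dict[int, np.ndarray],
                     roi_tc_b: dict[int, np.ndarray]) -> dict[int, np.ndarray]:
    """Per-frame Cohen's d (pooled SD, n_a + n_b - 2 denominator) per ROI.

    Frames with zero pooled SD yield NaN and are logged.
    """
    out = {}
    for lbl, a in roi_tc_a.items():
        b = roi_tc_b[lbl]
        na, nb = a.shape[0], b.shape[0]
        sp2 = ((na - 1) * a.var(axis=0, ddof=1)
               + (nb - 1) * b.var(axis=0, ddof=1)) / (na + nb - 2)
        with np.errstate(divide="ignore", invalid="ignore"):
            d = (a.mean(axis=0) - b.mean(axis=0)) / np.sqrt(sp2)
        if np.any(sp2 < 1e-24):
            logger.warning("ROI %d: zero pooled SD at %d frame(s); d is NaN",
                           lbl, int((sp2 < 1e-24).sum()))
            d[sp2 < 1e-24] = np.nan
        out[lbl] = d
    return out


# ---------------------------------------------------------------------------
# Occurrence rates
# ---------------------------------------------------------------------------

def occurrence_rates(series: ImageSeries, rqpp_pattern: np.ndarray,
                     group: str, cluster_id: int = 0,
                     stc_threshold: float = 0.2) -> pd.DataFrame:
    """Per-subject occurrence counts/rates of one rQPP on a group series.

    The rQPP's STC is computed once on the concatenated series; peaks are then
    found within each subject's own frame range, and rates are expressed in
    occurrences per minute (count / (frames * TR / 60)).
    """
    W = rqpp_pattern.shape[1]
    stc = sliding_template_correlation(series, rqpp_pattern)
    rows = []
    for sid, start, end in series.segments():
        sub_stc = np.full_like(stc, np.nan)
        last = end - W
        if last >= start:
            sub_stc[start:last + 1] = stc[start:last + 1]
        peaks = find_stc_peaks(sub_stc, stc_threshold, W)
        frames = end - start
        minutes = frames * series.tr_seconds / 60.0
        rows.append({"subject_id": sid, "group": group,
                     "cluster_id": cluster_id, "count": int(peaks.size),
                     "rate": peaks.size / minutes})
    return pd.DataFrame(rows)


def compare_occurrence_rates(table: pd.DataFrame, q: float = 0.05
                             ) -> pd.DataFrame:
    """Unpaired two-tailed Student t per cluster on per-subject rates, with
    BH-FDR across clusters.  ``t`` is first-group-minus-second (groups in
    sorted order), so its sign gives the direction of the difference."""
    groups = sorted(table["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, got {groups}")
    rows = []
    for cid, sub in table.groupby("cluster_id"):
        a = sub.loc[sub["group"] == groups[0], "rate"].to_numpy()
        b = sub.loc[sub["group"] == groups[1], "rate"].to_numpy()
        if a.size < 2 or b.size < 2:
            raise ValueError(f"cluster {cid}: each group needs >= 2 subjects")
        if np.allclose(a, a[0]) and np.allclose(b, b[0]) and np.isclose(
                a[0], b[0]):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(a, b, equal_var=True)
        rows.append({"cluster_id": cid, "group_a": groups[0],
                     "group_b": groups[1], "mean_a": a.mean(),
                     "mean_b": b.mean(), "t": float(t), "p": float(p)})
    out = pd.DataFrame(rows)
    out["significant"] = bh_fdr(out["p"].to_numpy(), q)
    return out


# ---------------------------------------------------------------------------
# Static functional connectivity (reference analysis)
# ---------------------------------------------------------------------------

_Z_CLIP = 1.0 - 1e-12


def static_fc(series: ImageSeries, atlas: Atlas) -> dict[str, np.ndarray]:
    """Per-subject ROI x ROI Fisher-z FC matrices (diagonal NaN).

    Pearson r between ROI-mean time courses, z = atanh(r); |r| is clipped at
    1 - 1e-12 (and logged) so z stays finite.
    """
    labels = atlas.roi_labels
    out = {}
    for sid, start, end in series.segments():
        tc = np.stack([series.data[atlas.roi_rows(l), start:end].mean(axis=0)
                       for l in labels])
        r = np.corrcoef(tc)
        np.fill_diagonal(r, np.nan)
        if np.any(np.abs(r) >= 1.0):
            logger.warning("subject %s: |r|=1 clipped before Fisher z", sid)
        z = np.arctanh(np.clip(r, -_Z_CLIP, _Z_CLIP))
        out[sid] = z
    return out


def compare_fc(fc_a: dict[str, np.ndarray], fc_b: dict[str, np.ndarray],
               labels: list[int], q: float = 0.05) -> pd.DataFrame:
    """Pairwise two-sample t on Fisher-z FC, BH-FDR over ROI pairs."""
    za = np.stack(list(fc_a.values()))
    zb = np.stack(list(fc_b.values()))
    rows = []
    n = len(labels)
    for i in range(n):
        for j in range(i + 1, n):
            t, p = stats.ttest_ind(za[:, i, j], zb[:, i, j], equal_var=True)
            rows.append({"roi_x": labels[i], "roi_y": labels[j],
                         "mean_z_a": za[:, i, j].mean(),
                         "mean_z_b": zb[:, i, j].mean(),
                         "t": float(t), "p": float(p)})
    out = pd.DataFrame(rows)
    out["significant"] = bh_fdr(out["p"].to_numpy(), q)
    return out
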