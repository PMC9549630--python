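"""Iterative sliding-template detection of quasi-periodic patterns (QPPs).

A QPP is a short window (W frames) of whole-brain activity that recurs
throughout an image series.  Starting from a randomly seeded W-frame template,
the algorithm correlates the template with every W-frame segment of the series
(the sliding template correlation, STC), finds STC peaks above a threshold,
voxel-wise averages the corresponding segments into an updated template, and
repeats until the template stabilises (spatial correlation between successive
templates >= 0.99).  Running this from many random seeds yields an ensemble
of QPPs that is subsequently clustered.

Offsets whose W-frame window would straddle a subject boundary are flagged
invalid (NaN in the STC) and are never seeded, never counted as occurrences.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .preprocess import ImageSeries

logger = logging.getLogger(__name__)

_EPS = 1e-12


@dataclass
class QPPParams:
    window_w: int = 6
    stc_threshold: float = 0.2
    convergence_corr: float = 0.99
    n_seeds: int = 200
    max_iter: int = 20
    rng_seed: int = 0

    def __post_init__(self):
        if self.window_w < 2:
            raise ValueError("window_w must be >= 2")
        if not (0.0 < self.stc_threshold < 1.0):
            raise ValueError("stc_threshold must be in (0, 1)")
        if not (0.0 < self.convergence_corr <= 1.0):
            raise ValueError("convergence_corr must be in (0, 1]")
        if self.n_seeds <= 0 or self.max_iter <= 0:
            raise ValueError("n_seeds and max_iter must be positive")


@dataclass
class QPP:
    pattern: np.ndarray          # (V, W)
    seed_frame: int
    stc: np.ndarray              # (T - W + 1,), NaN at invalid offsets
    occurrences: np.ndarray      # sorted frames of retained STC peaks
    n_iterations: int
    converged: bool
    mean_peak_stc: float = field(default=np.nan)

    @property
    def n_occurrences(self) -> int:
        return int(self.occurrences.size)

    @property
    def window_w(self) -> int:
        return int(self.pattern.shape[1])


# ---------------------------------------------------------------------------
# Sliding template correlation
# ---------------------------------------------------------------------------

def valid_offsets(series: ImageSeries, window_w: int) -> np.ndarray:
    """Boolean mask over offsets whose window fits inside one subject segment."""
    n_off = series.n_frames - window_w + 1
    if n_off <= 0:
        raise ValueError("window_w exceeds series length")
    valid = np.zeros(n_off, dtype=bool)
    for _, start, end in series.segments():
        last = end - window_w  # inclusive
        if last >= start:
            valid[start:last + 1] = True
    return valid


def sliding_template_correlation(series: ImageSeries, template: np.ndarray,
                                 ) -> np.ndarray:
    """Pearson correlation of the flattened (voxels x W) template with every
    valid W-frame segment of the series.

    Returns a length T-W+1 vector; offsets whose window straddles a subject
    boundary, and offsets with a zero-variance segment (or a zero-variance
    template, in which case everywhere), are NaN.  Correlations use
    population (1/N) normalisation throughout.
    """
    template = np.asarray(template, dtype=float)
    V, W = template.shape
    if V != series.n_voxels:
        raise ValueError("template voxel count does not match series")
    data = series.data
    T = series.n_frames
    n_off = T - W + 1
    N = V * W

    stc = np.full(n_off, np.nan)
    mt = template.mean()
    vt = (template**2).mean() - mt**2
    if vt < _EPS:
        return stc  # zero-variance template: everything invalid

    # numerator via W short diagonals of the (W x T) cross-product matrix
    cross = template.T @ data                          # (W, T)
    dot = np.zeros(n_off)
    for w in range(W):
        dot += cross[w, w:w + n_off]

    colsum = data.sum(axis=0)
    colsq = np.einsum("vt,vt->t", data, data)
    kernel = np.ones(W)
    segsum = np.convolve(colsum, kernel, mode="valid")
    segsq = np.convolve(colsq, kernel, mode="valid")
    ms = segsum / N
    vs = segsq / N - ms**2

    ok = valid_offsets(series, W) & (vs > _EPS)
    stc[ok] = (dot[ok] / N - mt * ms[ok]) / np.sqrt(vt * vs[ok])
    return stc


def find_stc_peaks(stc: np.ndarray, threshold: float, window_w: int
                   ) -> np.ndarray:
    """Strict local STC maxima >= threshold, greedily thinned to >= W apart.

    A peak needs both neighbours valid and strictly lower, so boundary
    offsets (and offsets adjacent to invalid ones) are never peaks.
    Suppression proceeds from the highest peak downwards; among retained
    peaks all pairwise gaps are >= W.
    """
    s = np.asarray(stc, dtype=float)
    if s.size < 3:
        return np.empty(0, dtype=int)
    mid = s[1:-1]
    cand = (np.isfinite(mid) & np.isfinite(s[:-2]) & np.isfinite(s[2:])
            & (mid > s[:-2]) & (mid > s[2:]) & (mid >= threshold))
    frames = np.flatnonzero(cand) + 1
    if frames.size == 0:
        return frames
    order = np.lexsort((frames, -s[frames]))  # highest first, earlier on ties
    kept: list[int] = []
    for f in frames[order]:
        if all(abs(int(f) - k) >= window_w for k in kept):
            kept.append(int(f))
    return np.asarray(sorted(kept), dtype=int)


# ---------------------------------------------------------------------------
# Iterative template refinement
# ---------------------------------------------------------------------------

def _flat_corr(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel() - a.mean()
    b = b.ravel() - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    return float(a @ b / denom) if denom > _EPS else np.nan


def refine_template(series: ImageSeries, template: np.ndarray,
                    params: QPPParams, seed_frame: int = -1) -> QPP:
    """Iterate STC -> peak averaging -> template update until convergence.

    Returns an unconverged QPP if an iteration yields fewer than 2 peaks or
    ``max_iter`` updates pass without the template stabilising.
    """
    W = params.window_w
    data = series.data
    template = np.asarray(template, dtype=float).copy()
    prev_mean_peak = -np.inf
    stc = sliding_template_correlation(series, template)
    peaks = find_stc_peaks(stc, params.stc_threshold, W)

    for it in range(1, params.max_iter + 1):
        if peaks.size < 2:
            return QPP(template, seed_frame, stc, peaks, it - 1, False,
                       float(stc[peaks].mean()) if peaks.size else np.nan)
        new = np.zeros_like(template)
        for f in peaks:
            new += data[:, f:f + W]
        new /= peaks.size
        corr = _flat_corr(new, template)
        template = new
        stc = sliding_template_correlation(series, template)
        peaks = find_stc_peaks(stc, params.stc_threshold, W)
        mean_peak = float(stc[peaks].mean()) if peaks.size else np.nan
        if np.isfinite(mean_peak):
            if mean_peak < prev_mean_peak - 1e-9:
                logger.debug("iteration %d: mean peak STC decreased "
                             "(%.4f -> %.4f)", it, prev_mean_peak, mean_peak)
            prev_mean_peak = mean_peak
        if corr >= params.convergence_corr:
            return QPP(template, seed_frame, stc, peaks, it, True, mean_peak)
    return QPP(template, seed_frame, stc, peaks, params.max_iter, False,
               prev_mean_peak if np.isfinite(prev_mean_peak) else np.nan)


def detect_qpp(series: ImageSeries, seed_frame: int, params: QPPParams) -> QPP:
    """One detection run seeded at ``seed_frame`` (must be a valid offset)."""
    W = params.window_w
    valid = valid_offsets(series, W)
    if not (0 <= seed_frame < valid.size) or not valid[seed_frame]:
        raise ValueError(f"seed frame {seed_frame} is not a valid window start")
    template = series.data[:, seed_frame:seed_frame + W]
    return refine_template(series, template, params, seed_frame=seed_frame)


def extract_qpp_ensemble(series: ImageSeries, params: QPPParams) -> list[QPP]:
    """Detection from ``n_seeds`` random seed frames, sampled without
    replacement from the valid offsets; deterministic given rng_seed."""
    valid = np.flatnonzero(valid_offsets(series, params.window_w))
    if valid.size < params.n_seeds:
        raise ValueError(
            f"only {valid.size} valid seed positions but n_seeds="
            f"{params.n_seeds}; reduce n_seeds")
    rng = np.random.default_rng(params.rng_seed)
    seeds = rng.choice(valid, size=params.n_seeds, replace=False)
    return [detect_qpp(series, int(f), params) for f in seeds]


# ---------------------------------------------------------------------------
# Space-time pattern similarity (shared by clustering, matching, alignment)
# ---------------------------------------------------------------------------

def pattern_similarity(a: np.ndarray, b: np.ndarray, max_shift: int
                       ) -> tuple[float, int]:
    """Signed space-time Pearson correlation at the best integer shift.

    For shift s, ``a[:, i]`` is compared with ``b[:, i - s]`` on the
    overlapping frames; a positive best shift therefore means ``a`` contains
    ``b`` delayed by s frames.  The shift is chosen by maximum correlation
    MAGNITUDE (ties prefer the smaller |shift|, then the smaller shift) and
    the signed correlation at that shift is returned: two anti-correlated
    patterns score near -1 rather than being folded together (no sign-flip
    equivalence — a network-activation pattern and its mirror image are
    distinct states).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("patterns must have identical shape")
    W = a.shape[1]
    if max_shift >= W:
        raise ValueError("max_shift must be smaller than window length")
    best = (np.nan, 0)
    for s in sorted(range(-max_shift, max_shift + 1), key=lambda x: (abs(x), x)):
        if s >= 0:
            r = _flat_corr(a[:, s:], b[:, :W - s])
        else:
            r = _flat_corr(a[:, :W + s], b[:, -s:])
        if np.isfinite(r) and (not np.isfinite(best[0])
                               or abs(r) > abs(best[0]) + 1e-15):
            best = (r, s)
    if not np.isfinite(best[0]):
        raise ValueError("no shift gave a finite correlation")
    return best


# ---------------------------------------------------------------------------
# Ensemble serialisation (.npz + JSON metadata sidecar)
# ---------------------------------------------------------------------------

def save_ensemble(path: str | Path, qpps: list[QPP], params: QPPParams) -> None:
    path = Path(path)
    arrays = {}
    for i, q in enumerate(qpps):
        arrays[f"pattern_{i}"] = q.pattern
        arrays[f"stc_{i}"] = q.stc
        arrays[f"occurrences_{i}"] = q.occurrences
    np.savez_compressed(path, n_qpps=len(qpps), **arrays)
    meta = {
        "params": {k: getattr(params, k) for k in
                   ("window_w", "stc_threshold", "convergence_corr",
                    "n_seeds", "max_iter", "rng_seed")},
        "qpps": [{"seed_frame": q.seed_frame, "n_iterations": q.n_iterations,
                  "converged": bool(q.converged),
                  "n_occurrences": q.n_occurrences,
                  "mean_peak_stc": (None if not np.isfinite(q.mean_peak_stc)
                                    else round(float(q.mean_peak_stc), 6))}
                 for q in qpps],
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_ensemble(path: str | Path) -> tuple[list[QPP], QPPParams]:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    params = QPPParams(**meta["params"])
    with np.load(path) as npz:
        n = int(npz["n_qpps"])
        qpps = []
        for i in range(n):
            m = meta["qpps"][i]
            qpps.append(QPP(
                pattern=npz[f"pattern_{i}"], seed_frame=m["seed_frame"],
                stc=npz[f"stc_{i}"],
                occurrences=npz[f"occurrences_{i}"].astype(int),
                n_iterations=m["n_iterations"], converged=m["converged"],
                mean_peak_stc=(np.nan if m["mean_peak_stc"] is None
                               else m["mean_peak_stc"])))
    return qpps, params
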