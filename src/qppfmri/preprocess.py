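"""Signal-level preprocessing of masked BOLD series.

Fixed pipeline order: global-signal regression -> quadratic detrend (demeaning
is its intercept term) -> voxel-wise z-scoring -> Butterworth band-pass ->
group concatenation.  Every step operates strictly per subject segment; no
regression or filter ever crosses a subject boundary.  Two variants of each
group series are kept: the z-scored one drives pattern detection, while a
parallel non-z-scored series (all other steps applied) is retained because
peak-timing analysis reads amplitudes off the un-normalised signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy.signal import butter, filtfilt

logger = logging.getLogger(__name__)

Bounds = tuple[str, int, int]  # subject_id, start frame, end frame (half-open)


@dataclass
class FilterSpec:
    """Band-pass specification: 0.01-0.17 Hz, order-5 Butterworth applied
    forward-backward (zero phase)."""

    low_hz: float = 0.01
    high_hz: float = 0.17
    order: int = 5

    def validate(self, tr_seconds: float) -> None:
        nyq = 1.0 / (2.0 * tr_seconds)
        if not (0.0 < self.low_hz < self.high_hz):
            raise ValueError(f"need 0 < low_hz < high_hz, got {self.low_hz}, {self.high_hz}")
        if self.high_hz >= nyq:
            raise ValueError(f"high_hz {self.high_hz} >= Nyquist {nyq:.4f} Hz")
        if self.order <= 0:
            raise ValueError("filter order must be positive")


@dataclass
class ImageSeries:
    """Masked, flattened 4D series: voxels x frames plus segment bookkeeping.

    ``mask_index`` maps matrix row -> 3D voxel coordinate (C order over the
    mask, matching :class:`qppfmri.simulate.Atlas`).
    """

    data: np.ndarray                     # (V, T) float
    mask_index: np.ndarray               # (V, 3) int
    tr_seconds: float
    subject_bounds: list[Bounds] = field(default_factory=list)
    zscored: bool = False

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        V, T = self.data.shape
        if self.mask_index.shape != (V, 3):
            raise ValueError("mask_index must be (n_voxels, 3)")
        if not self.subject_bounds:
            self.subject_bounds = [("sub", 0, T)]
        self._check_bounds()

    def _check_bounds(self) -> None:
        T = self.n_frames
        pos = 0
        for sid, start, end in self.subject_bounds:
            if start != pos or end <= start:
                raise ValueError(f"subject_bounds do not partition frames at {sid}")
            pos = end
        if pos != T:
            raise ValueError("subject_bounds do not cover all frames")

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    def segments(self):
        for sid, start, end in self.subject_bounds:
            yield sid, start, end

    def copy_with(self, data: np.ndarray, **kw) -> "ImageSeries":
        return replace(self, data=data, **kw)

    def subject_view(self, subject_id: str) -> "ImageSeries":
        """Single-subject series sharing this series' mask and TR."""
        for sid, start, end in self.subject_bounds:
            if sid == subject_id:
                return ImageSeries(self.data[:, start:end].copy(),
                                   self.mask_index, self.tr_seconds,
                                   [(sid, 0, end - start)], self.zscored)
        raise KeyError(subject_id)


def from_dense(volume4d: np.ndarray, mask: np.ndarray, tr_seconds: float,
               subject_id: str = "sub") -> ImageSeries:
    """Mask and flatten an (X,Y,Z,T) array into an ImageSeries."""
    data = volume4d[mask.astype(bool)]
    return ImageSeries(data=np.asarray(data, dtype=float),
                       mask_index=np.argwhere(mask.astype(bool)),
                       tr_seconds=float(tr_seconds),
                       subject_bounds=[(subject_id, 0, volume4d.shape[3])])


def load_subject(bold_path: str | Path, mask_path: str | Path,
                 subject_id: str, tr_seconds: float | None = None) -> ImageSeries:
    """Read one subject's 4D NIfTI restricted to a brain mask."""
    img = nib.load(str(bold_path))
    mask = np.asarray(nib.load(str(mask_path)).dataobj) > 0
    tr = float(tr_seconds if tr_seconds is not None else img.header.get_zooms()[3])
    return from_dense(np.asarray(img.dataobj, dtype=np.float64), mask, tr,
                      subject_id=subject_id)


# ---------------------------------------------------------------------------
# Per-segment operations
# ---------------------------------------------------------------------------

def _residualise(seg: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Least-squares residual of each row of seg against design columns."""
    coef, *_ = np.linalg.lstsq(design, seg.T, rcond=None)
    return seg - (design @ coef).T


def regress_global_signal(series: ImageSeries) -> ImageSeries:
    """Regress the in-mask mean time course out of every voxel, per subject.

    Residuals are exactly orthogonal to [intercept, global signal] within each
    segment.  Must run before z-scoring.
    """
    if series.zscored:
        raise ValueError("global signal regression must precede z-scoring")
    out = series.data.copy()
    for sid, start, end in series.segments():
        seg = out[:, start:end]
        g = seg.mean(axis=0)
        if g.std() < 1e-12:
            raise ValueError(f"global signal of segment {sid!r} has zero variance")
        design = np.column_stack([np.ones(g.size), g])
        out[:, start:end] = _residualise(seg, design)
    return series.copy_with(out)


def detrend_quadratic(series: ImageSeries) -> ImageSeries:
    """Residual of each voxel against [1, t, t^2] per segment (so the output
    segment mean is exactly zero — demeaning is the intercept term)."""
    out = series.data.copy()
    for sid, start, end in series.segments():
        n = end - start
        if n < 4:
            raise ValueError(f"segment {sid!r} too short to detrend ({n} frames)")
        t = np.linspace(-1.0, 1.0, n)  # scaled for conditioning
        design = np.column_stack([np.ones(n), t, t**2])
        out[:, start:end] = _residualise(out[:, start:end], design)
    return series.copy_with(out)


def zscore_voxelwise(series: ImageSeries) -> ImageSeries:
    """Per-segment zero mean / unit SD per voxel; near-constant rows are set
    to zero (and logged) rather than dropped, keeping voxel indexing stable."""
    out = series.data.copy()
    for sid, start, end in series.segments():
        seg = out[:, start:end]
        mu = seg.mean(axis=1, keepdims=True)
        sd = seg.std(axis=1, keepdims=True)
        degenerate = sd[:, 0] < 1e-12
        sd[degenerate] = 1.0
        seg = (seg - mu) / sd
        if degenerate.any():
            logger.warning("segment %s: zeroed %d zero-variance voxel(s)",
                           sid, int(degenerate.sum()))
            seg[degenerate] = 0.0
        out[:, start:end] = seg
    return series.copy_with(out, zscored=True)


def bandpass_filter(series: ImageSeries, spec: FilterSpec | None = None
                    ) -> ImageSeries:
    """Zero-phase Butterworth band-pass, applied per subject segment."""
    spec = spec or FilterSpec()
    spec.validate(series.tr_seconds)
    fs = 1.0 / series.tr_seconds
    b, a = butter(spec.order, [spec.low_hz, spec.high_hz], btype="band", fs=fs)
    out = series.data.copy()
    for _, start, end in series.segments():
        out[:, start:end] = filtfilt(b, a, out[:, start:end], axis=1)
    return series.copy_with(out)


def concatenate_group(series_list: list[ImageSeries]) -> ImageSeries:
    """Concatenate per-subject series frame-wise, recording subject bounds."""
    if not series_list:
        raise ValueError("no series to concatenate")
    first = series_list[0]
    for s in series_list[1:]:
        if not np.array_equal(s.mask_index, first.mask_index):
            raise ValueError(
                f"mask mismatch between {first.subject_bounds[0][0]!r} and "
                f"{s.subject_bounds[0][0]!r}")
        if s.tr_seconds != first.tr_seconds:
            raise ValueError(
                f"TR mismatch between {first.subject_bounds[0][0]!r} and "
                f"{s.subject_bounds[0][0]!r}")
        if s.zscored != first.zscored:
            raise ValueError("cannot concatenate z-scored with non-z-scored series")
    bounds: list[Bounds] = []
    pos = 0
    for s in series_list:
        for sid, start, end in s.subject_bounds:
            bounds.append((sid, pos, pos + (end - start)))
            pos += end - start
    data = np.concatenate([s.data for s in series_list], axis=1)
    return ImageSeries(data, first.mask_index, first.tr_seconds, bounds,
                       first.zscored)


def preprocess_group(subject_series: list[ImageSeries],
                     filter_spec: FilterSpec | None = None,
                     ) -> tuple[ImageSeries, ImageSeries]:
    """Full per-subject pipeline, returning (z-scored, non-z-scored) group
    series.  The non-z-scored variant gets every step except normalisation."""
    zs, raw = [], []
    for s in subject_series:
        base = detrend_quadratic(regress_global_signal(s))
        zs.append(bandpass_filter(zscore_voxelwise(base), filter_spec))
        raw.append(bandpass_filter(base, filter_spec))
    return concatenate_group(zs), concatenate_group(raw)
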