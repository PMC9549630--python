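"""Synthetic multi-subject BOLD cohorts with planted quasi-periodic events.

Generates two-group resting-state-like 4D series in which a "default-mode-like"
network (DMLN) co-activates while a "lateral cortical" network (LCN)
co-deactivates, plus a small basal-forebrain-like (BFB) region whose peak can
lead the rest by a configurable number of frames.  Every planted event is
recorded in a ground-truth structure so that detection, clustering, group
statistics and lead/lag estimation can all be scored against known truth.

The generator is deliberately simple: block ROIs on a regular grid, a
one-cycle raised-cosine event waveform, iid Gaussian voxel noise, an optional
shared low-frequency random-walk "global signal" and an optional quadratic
scanner drift.  No hemodynamic convolution, physiological noise or motion is
simulated.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import nibabel as nib

logger = logging.getLogger(__name__)

# Default acquisition emulated throughout: 600 ms TR, 10 min scans.
DEFAULT_TR = 0.6

Block = tuple[tuple[int, int], tuple[int, int], tuple[int, int]]


# ---------------------------------------------------------------------------
# Atlas
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ROIDef:
    """One labelled region built from axis-aligned half-open voxel blocks."""

    label: int
    name: str
    blocks: tuple[Block, ...]

    def __post_init__(self):
        if self.label <= 0:
            raise ValueError(f"ROI label must be positive, got {self.label}")


@dataclass
class AtlasSpec:
    grid_shape: tuple[int, int, int]
    roi_defs: tuple[ROIDef, ...]
    brain_mask: np.ndarray | None = None  # bool (X,Y,Z); None means all-brain

    def __post_init__(self):
        if len(self.grid_shape) != 3 or any(s <= 0 for s in self.grid_shape):
            raise ValueError(f"grid_shape must be 3 positive ints, got {self.grid_shape}")
        labels = [r.label for r in self.roi_defs]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate ROI labels: {sorted(labels)}")
        if len(self.roi_defs) < 3:
            raise ValueError("atlas needs at least 3 ROIs (two networks plus a small lead region)")


class Atlas:
    """Label volume + brain mask with voxel<->ROI lookups.

    Masked-row ordering is C order over in-mask voxels; this same ordering is
    used by :class:`qppfmri.preprocess.ImageSeries`, so ``roi_rows`` indexes
    directly into masked data matrices.
    """

    def __init__(self, labels: np.ndarray, mask: np.ndarray,
                 names: dict[int, str]):
        self.labels = labels
        self.mask = mask.astype(bool)
        self.names = dict(names)
        self.mask_index = np.argwhere(self.mask)  # (V, 3)
        # flat voxel -> masked-row lookup
        self._row_of = -np.ones(self.mask.size, dtype=np.int64)
        flat = np.flatnonzero(self.mask.ravel())
        self._row_of[flat] = np.arange(flat.size)
        self._label_rows = {
            int(lbl): np.flatnonzero(self.labels[self.mask] == lbl)
            for lbl in names
        }

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def roi_labels(self) -> list[int]:
        return sorted(self.names)

    def roi_rows(self, label: int) -> np.ndarray:
        """Masked-data row indices of one ROI."""
        return self._label_rows[int(label)]

    def roi_size(self, label: int) -> int:
        return int(self._label_rows[int(label)].size)

    def label_of_row(self, row: int) -> int:
        """ROI label of a masked row (0 if unlabelled brain)."""
        i, j, k = self.mask_index[row]
        return int(self.labels[i, j, k])


def build_atlas(spec: AtlasSpec) -> Atlas:
    """Rasterise block ROI definitions into a label volume.

    Raises ``ValueError`` naming the offending labels if two ROIs overlap or
    an ROI voxel falls outside the brain mask.
    """
    shape = tuple(spec.grid_shape)
    mask = (np.ones(shape, dtype=bool) if spec.brain_mask is None
            else spec.brain_mask.astype(bool))
    if mask.shape != shape:
        raise ValueError(f"brain_mask shape {mask.shape} != grid_shape {shape}")
    labels = np.zeros(shape, dtype=np.int32)
    for roi in spec.roi_defs:
        for (x0, x1), (y0, y1), (z0, z1) in roi.blocks:
            if not (0 <= x0 < x1 <= shape[0] and 0 <= y0 < y1 <= shape[1]
                    and 0 <= z0 < z1 <= shape[2]):
                raise ValueError(f"ROI {roi.label} block out of grid bounds")
            region = labels[x0:x1, y0:y1, z0:z1]
            clash = region[(region != 0) & (region != roi.label)]
            if clash.size:
                raise ValueError(
                    f"ROI blocks overlap: labels {int(clash[0])} and {roi.label}")
            if not mask[x0:x1, y0:y1, z0:z1].all():
                raise ValueError(f"ROI {roi.label} extends outside the brain mask")
            region[...] = roi.label
    return Atlas(labels, mask, {r.label: r.name for r in spec.roi_defs})


# ---------------------------------------------------------------------------
# Event template
# ---------------------------------------------------------------------------

def raised_cosine(window_w: int) -> np.ndarray:
    """One-cycle raised cosine over W frames, normalised to unit peak.

    Smooth and unimodal, so the planted peak time is unambiguous (interior
    ties are possible only for even W, where argmax resolves to the earlier
    frame).
    """
    if window_w < 2:
        raise ValueError("window_w must be >= 2")
    if window_w == 2:  # degenerate: no interior sample, use a flat pulse
        return np.ones(2)
    t = np.arange(window_w)
    w = 0.5 * (1.0 - np.cos(2.0 * np.pi * t / (window_w - 1)))
    return w / w.max()


@dataclass
class EventTemplate:
    """Spatiotemporal signature of one planted event type.

    ``roi_amplitudes`` are signed (a.u.): the anti-correlated network pair is
    expressed as one positive and one negative amplitude.  ``roi_lags`` shift
    that ROI's waveform by whole frames relative to the event onset (negative
    = the region peaks early, i.e. leads).
    """

    window_w: int
    roi_amplitudes: dict[int, float]
    roi_lags: dict[int, int] = field(default_factory=dict)
    waveform: np.ndarray | None = None

    def __post_init__(self):
        if self.waveform is None:
            self.waveform = raised_cosine(self.window_w)
        self.waveform = np.asarray(self.waveform, dtype=float)
        if self.waveform.shape != (self.window_w,):
            raise ValueError("waveform length must equal window_w")
        if not np.isclose(np.abs(self.waveform).max(), 1.0):
            raise ValueError("waveform must have unit peak amplitude")
        amps = list(self.roi_amplitudes.values())
        if not (any(a > 0 for a in amps) and any(a < 0 for a in amps)):
            raise ValueError("need at least one positive and one negative ROI "
                             "amplitude (anti-correlated networks)")
        for lbl, lag in self.roi_lags.items():
            if abs(lag) > self.window_w / 2:
                raise ValueError(f"ROI {lbl} lag {lag} exceeds W/2")

    @property
    def min_lag(self) -> int:
        return min([0, *self.roi_lags.values()])

    @property
    def max_lag(self) -> int:
        return max([0, *self.roi_lags.values()])

    def render(self, atlas: Atlas) -> np.ndarray:
        """Dense voxels x W pattern of one event (lags applied, window-cropped).

        Lagged contributions falling outside [0, W) are dropped, mirroring how
        a W-frame detection window sees the event.
        """
        W = self.window_w
        out = np.zeros((atlas.n_voxels, W))
        for lbl, amp in self.roi_amplitudes.items():
            lag = int(self.roi_lags.get(lbl, 0))
            lo, hi = max(0, lag), min(W, W + lag)
            out[np.ix_(atlas.roi_rows(lbl), np.arange(lo, hi))] = \
                amp * self.waveform[lo - lag:hi - lag]
        return out


# ---------------------------------------------------------------------------
# Cohort specification and ground truth
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    n_subjects_per_group: int = 6
    frames_per_subject: int = 500
    tr_seconds: float = DEFAULT_TR
    events_per_scan: dict[str, float] = field(
        default_factory=lambda: {"wt": 30.0, "tg": 15.0})
    noise_sd: float = 1.0
    global_amp: float = 0.5
    drift_coeffs: tuple[float, float, float] | None = None
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_subjects_per_group <= 0:
            raise ValueError("n_subjects_per_group must be positive")
        if self.noise_sd < 0 or self.global_amp < 0:
            raise ValueError("noise_sd and global_amp must be non-negative")

    def validate_window(self, window_w: int) -> None:
        if self.frames_per_subject <= 2 * window_w:
            raise ValueError("frames_per_subject must exceed 2*window_w")


@dataclass
class SubjectTruth:
    subject_id: str
    group: str
    onsets: list[int]
    amplitudes: list[float]


@dataclass
class GroundTruth:
    """Everything needed to reconstruct the noiseless planted signal."""

    subjects: list[SubjectTruth]
    templates: dict[str, EventTemplate]
    frames_per_subject: int
    tr_seconds: float

    def onsets_of(self, subject_id: str) -> np.ndarray:
        for s in self.subjects:
            if s.subject_id == subject_id:
                return np.asarray(s.onsets, dtype=int)
        raise KeyError(subject_id)

    def group_onsets_concatenated(self, group: str) -> np.ndarray:
        """Event onsets in the frame numbering of the concatenated group series."""
        out = []
        i = 0
        for s in self.subjects:
            if s.group == group:
                out.extend(np.asarray(s.onsets) + i * self.frames_per_subject)
                i += 1
        return np.asarray(sorted(out), dtype=int)

    def to_json(self) -> str:
        obj = {
            "frames_per_subject": self.frames_per_subject,
            "tr_seconds": self.tr_seconds,
            "templates": {
                g: {
                    "window_w": t.window_w,
                    "waveform": [float(x) for x in t.waveform],
                    "roi_amplitudes": {str(k): float(v)
                                       for k, v in sorted(t.roi_amplitudes.items())},
                    "roi_lags": {str(k): int(v)
                                 for k, v in sorted(t.roi_lags.items())},
                }
                for g, t in sorted(self.templates.items())
            },
            "subjects": [
                {"subject_id": s.subject_id, "group": s.group,
                 "onsets": [int(o) for o in s.onsets],
                 "amplitudes": [float(a) for a in s.amplitudes]}
                for s in self.subjects
            ],
        }
        return json.dumps(obj, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        obj = json.loads(text)
        templates = {
            g: EventTemplate(
                window_w=t["window_w"],
                waveform=np.asarray(t["waveform"]),
                roi_amplitudes={int(k): v for k, v in t["roi_amplitudes"].items()},
                roi_lags={int(k): v for k, v in t["roi_lags"].items()},
            )
            for g, t in obj["templates"].items()
        }
        subjects = [SubjectTruth(s["subject_id"], s["group"], s["onsets"],
                                 s["amplitudes"]) for s in obj["subjects"]]
        return cls(subjects, templates, obj["frames_per_subject"],
                   obj["tr_seconds"])


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def sample_onsets(n_events: int, frames: int, window_w: int,
                  rng: np.random.Generator,
                  lo: int = 0, hi: int | None = None,
                  separation: int | None = None,
                  max_tries: int = 2000) -> np.ndarray:
    """Uniform event onsets with greedy rejection enforcing a minimum
    separation (default W + 2 frames: quasi-periodic events do not run
    back-to-back, and one extra frame of slack on each side keeps adjacent
    detection windows disjoint even at +-1-frame phase offsets)."""
    if separation is None:
        separation = window_w + 2
    if separation < window_w:
        raise ValueError("separation must be at least window_w")
    if hi is None:
        hi = frames - window_w
    if hi < lo:
        raise ValueError("no feasible onset positions")
    onsets: list[int] = []
    tries = 0
    while len(onsets) < n_events:
        cand = int(rng.integers(lo, hi + 1))
        if all(abs(cand - o) >= separation for o in onsets):
            onsets.append(cand)
        tries += 1
        if tries > max_tries * max(n_events, 1):
            raise ValueError(
                f"cannot place {n_events} events with >= {separation}-frame "
                f"separation in {frames} frames")
    return np.asarray(sorted(onsets), dtype=int)


def max_feasible_events(frames: int, window_w: int,
                        separation: int | None = None) -> int:
    """Conservative cap on how many events random placement can fit.

    Random sequential placement with a minimum gap saturates well below the
    dense-packing limit; 60% of span/separation places reliably.
    """
    if separation is None:
        separation = window_w + 2
    span = frames - window_w
    return max(1, int(0.6 * span / separation))


def draw_event_count(mean_events: float, frames: int, window_w: int,
                     rng: np.random.Generator,
                     separation: int | None = None) -> int:
    """Poisson-distributed realised event count, clipped to feasibility."""
    cap = max_feasible_events(frames, window_w, separation)
    n = int(rng.poisson(mean_events))
    if n > cap:
        logger.warning("clipping realised event count %d to feasible %d",
                       n, cap)
    return min(max(1, n), cap)


def _global_walk(frames: int, rng: np.random.Generator) -> np.ndarray:
    """Low-frequency random walk, standardised to zero mean / unit SD."""
    walk = np.cumsum(rng.standard_normal(frames))
    walk -= walk.mean()
    sd = walk.std()
    return walk / sd if sd > 0 else walk


def generate_subject(atlas: Atlas, template: EventTemplate, n_events: int,
                     noise_sd: float, global_amp: float,
                     drift: tuple[float, float, float] | None,
                     frames: int, rng: np.random.Generator,
                     subject_id: str = "sub", group: str = "wt",
                     ) -> tuple[np.ndarray, SubjectTruth]:
    """One subject's masked voxels x frames series plus its ground truth.

    series = sum over events of the lagged ROI waveforms
             + global_amp * shared random walk + drift + N(0, noise_sd^2).
    """
    W = template.window_w
    if n_events * W > frames:
        raise ValueError("n_events * window_w exceeds frames")
    V = atlas.n_voxels
    data = np.zeros((V, frames))

    lo = max(0, -template.min_lag)
    hi = frames - W - max(0, template.max_lag)
    onsets = sample_onsets(n_events, frames, W, rng, lo=lo, hi=hi)
    for onset in onsets:
        for lbl, amp in template.roi_amplitudes.items():
            lag = int(template.roi_lags.get(lbl, 0))
            start = onset + lag
            data[atlas.roi_rows(lbl), start:start + W] += amp * template.waveform

    if global_amp > 0:
        data += global_amp * _global_walk(frames, rng)
    if drift is not None:
        u = np.linspace(-1.0, 1.0, frames)
        data += drift[0] + drift[1] * u + drift[2] * u**2
    if noise_sd > 0:
        data += noise_sd * rng.standard_normal((V, frames))

    truth = SubjectTruth(subject_id=subject_id, group=group,
                         onsets=[int(o) for o in onsets],
                         amplitudes=[1.0] * len(onsets))
    return data, truth


def reconstruct_noiseless(atlas: Atlas, truth: SubjectTruth,
                          template: EventTemplate, frames: int) -> np.ndarray:
    """Planted-signal-only series implied by a subject's ground truth."""
    W = template.window_w
    data = np.zeros((atlas.n_voxels, frames))
    for onset, amp_ev in zip(truth.onsets, truth.amplitudes):
        for lbl, amp in template.roi_amplitudes.items():
            lag = int(template.roi_lags.get(lbl, 0))
            data[atlas.roi_rows(lbl), onset + lag:onset + lag + W] += \
                amp_ev * amp * template.waveform
    return data


def dense_volume(atlas: Atlas, masked: np.ndarray) -> np.ndarray:
    """Embed masked (V,) or (V,T) data back into the full grid."""
    shape = atlas.mask.shape + (() if masked.ndim == 1 else (masked.shape[1],))
    out = np.zeros(shape, dtype=masked.dtype)
    out[atlas.mask] = masked
    return out


def generate_cohort(cohort: CohortSpec, atlas: Atlas,
                    templates: dict[str, EventTemplate],
                    out_dir: str | Path,
                    ) -> tuple[pd.DataFrame, GroundTruth]:
    """Write a full two-group cohort to disk: NIfTI per subject, mask, atlas,
    subject TSV and ground-truth JSON.  Fully reproducible from rng_seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cohort.rng_seed)

    affine = np.eye(4)
    try:
        nib.save(nib.Nifti1Image(atlas.mask.astype(np.uint8), affine),
                 str(out / "mask.nii.gz"))
        nib.save(nib.Nifti1Image(atlas.labels.astype(np.int16), affine),
                 str(out / "atlas.nii.gz"))
    except OSError as exc:
        raise OSError(f"failed writing atlas files under {out}: {exc}") from exc

    rows = []
    subjects: list[SubjectTruth] = []
    for group in sorted(templates):
        template = templates[group]
        cohort.validate_window(template.window_w)
        mean_events = cohort.events_per_scan[group]
        for i in range(cohort.n_subjects_per_group):
            sid = f"sub-{group}{i + 1:02d}"
            n_events = draw_event_count(mean_events,
                                        cohort.frames_per_subject,
                                        template.window_w, rng)
            data, truth = generate_subject(
                atlas, template, n_events, cohort.noise_sd, cohort.global_amp,
                cohort.drift_coeffs, cohort.frames_per_subject, rng,
                subject_id=sid, group=group)
            fname = f"{sid}_bold.nii.gz"
            img = nib.Nifti1Image(
                dense_volume(atlas, data.astype(np.float32)), affine)
            img.header.set_zooms((1.0, 1.0, 1.0, cohort.tr_seconds))
            try:
                nib.save(img, str(out / fname))
            except OSError as exc:
                raise OSError(f"failed writing {out / fname}: {exc}") from exc
            rows.append({"subject_id": sid, "group": group, "file": fname,
                         "frames": cohort.frames_per_subject})
            subjects.append(truth)

    table = pd.DataFrame(rows)
    table.to_csv(out / "subjects.tsv", sep="\t", index=False)
    truth = GroundTruth(subjects=subjects, templates=templates,
                        frames_per_subject=cohort.frames_per_subject,
                        tr_seconds=cohort.tr_seconds)
    (out / "ground_truth.json").write_text(truth.to_json())
    return table, truth


# ---------------------------------------------------------------------------
# Study defaults
# ---------------------------------------------------------------------------

DMLN, LCN, BFB = 1, 2, 3


def default_atlas_spec() -> AtlasSpec:
    """24 x 24 x 8 grid with a 22 x 22 x 6 brain box.

    The two anti-correlated networks cover ~91% of the brain between them
    (1320 voxels each) — mirroring real data, where the default-mode-like and
    lateral cortical networks together span most of cortex and whole-brain
    template correlations are therefore dominated by pattern voxels — plus a
    small 36-voxel basal-forebrain-like region in the band separating them.
    """
    mask = np.zeros((24, 24, 8), dtype=bool)
    mask[1:23, 1:23, 1:7] = True
    rois = (
        ROIDef(DMLN, "DMLN", (((1, 23), (1, 11), (1, 7)),)),
        ROIDef(LCN, "LCN", (((1, 23), (13, 23), (1, 7)),)),
        ROIDef(BFB, "BFB", (((10, 13), (11, 13), (1, 7)),)),
    )
    return AtlasSpec(grid_shape=(24, 24, 8), roi_defs=rois, brain_mask=mask)


def default_templates(window_w: int = 6, bfb_lead_frames: int = 1,
                      tg_bfb_amplitude: float = 0.0,
                      ) -> dict[str, EventTemplate]:
    """Two-group event templates emulating the studied phenotype.

    "wt": DMLN +1 / LCN -1 / BFB +1 peaking ``bfb_lead_frames`` early.
    "tg": same networks but BFB amplitude reduced (default absent) and no
    lead — the group difference the comparison stages are meant to find.
    The unit ROI amplitude against unit noise SD gives per-voxel CNR ~= 1.
    """
    wt = EventTemplate(window_w=window_w,
                       roi_amplitudes={DMLN: 1.0, LCN: -1.0, BFB: 1.0},
                       roi_lags={BFB: -int(bfb_lead_frames)})
    tg_amps = {DMLN: 1.0, LCN: -1.0}
    if tg_bfb_amplitude != 0.0:
        tg_amps[BFB] = tg_bfb_amplitude
    tg = EventTemplate(window_w=window_w, roi_amplitudes=tg_amps, roi_lags={})
    return {"wt": wt, "tg": tg}


# ---------------------------------------------------------------------------
# Recovery scoring against ground truth
# ---------------------------------------------------------------------------

def planted_pattern_filtered(atlas: Atlas, template: EventTemplate,
                             tr_seconds: float = DEFAULT_TR,
                             filter_spec=None) -> np.ndarray:
    """The planted event pattern as it exists in the analysed series.

    Detection never sees the raw planted window: every series is band-pass
    filtered first, which reshapes a short event (attenuation at the band
    edge plus zero-phase ringing).  This renders one noiseless event in a
    long series, applies the pipeline's own band-pass, and returns the
    W-frame window at the onset — the correct reference when scoring what
    the detector can possibly recover.  (Global-signal regression and
    detrending barely touch an isolated event in noisy data and are omitted;
    correlation-based scores are insensitive to the z-score rescaling.)
    """
    from .preprocess import ImageSeries, bandpass_filter

    W = template.window_w
    frames = max(20 * W, 120)
    onset = frames // 2
    truth = SubjectTruth("ref", "ref", [onset], [1.0])
    noiseless = reconstruct_noiseless(atlas, truth, template, frames)
    series = ImageSeries(noiseless, atlas.mask_index, tr_seconds,
                         [("ref", 0, frames)])
    filtered = bandpass_filter(series, filter_spec)
    return filtered.data[:, onset:onset + W]


def score_recovery(pattern: np.ndarray, occurrences: np.ndarray,
                   planted_pattern: np.ndarray, planted_onsets: np.ndarray,
                   max_shift: int | None = None,
                   frame_tolerance: int = 1) -> dict:
    """Score a detected QPP against planted truth.

    The detector is free to converge onto a time-shifted copy of the planted
    pattern, so the spatial correlation is maximised over integer shifts.
    Occurrence recall/precision likewise allow one global alignment shift:
    each candidate shift in [-max_shift, max_shift] is applied to all
    detected occurrence frames and the shift with the best F1 at
    ``frame_tolerance`` is scored (a pattern detected at a consistent phase
    offset has its events systematically offset by the same amount).
    """
    from .detect import pattern_similarity

    W = pattern.shape[1]
    if max_shift is None:
        max_shift = W // 2
    sim, corr_shift = pattern_similarity(pattern, planted_pattern, max_shift)
    occ = np.asarray(occurrences, dtype=int)
    planted = np.asarray(planted_onsets, dtype=int)

    def _hits(a, b):
        if a.size == 0 or b.size == 0:
            return 0
        d = np.abs(a[:, None] - b[None, :])
        return int((d.min(axis=1) <= frame_tolerance).sum())

    best = {"recall": 0.0, "precision": 0.0, "shift": 0, "f1": -1.0}
    for s in sorted(range(-max_shift, max_shift + 1), key=lambda x: (abs(x), x)):
        est = occ + s
        recall = _hits(planted, est) / planted.size if planted.size else np.nan
        precision = _hits(est, planted) / est.size if est.size else np.nan
        f1 = (0.0 if (recall + precision) == 0
              else 2 * recall * precision / (recall + precision))
        if f1 > best["f1"] + 1e-12:
            best = {"recall": recall, "precision": precision, "shift": s,
                    "f1": f1}
    return {"template_corr": float(sim), "corr_shift": int(corr_shift),
            "shift": int(best["shift"]), "recall": float(best["recall"]),
            "precision": float(best["precision"]),
            "n_detected": int(occ.size), "n_planted": int(planted.size)}
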