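"""Shared fixtures: default atlas/templates and seeded synthetic studies.

The expensive end-to-end studies (cohort generation -> preprocessing ->
ensemble detection -> clustering) are session-scoped so the detection,
clustering and acceptance tests reuse one computation.
"""

import numpy as np
import pytest

import qppfmri as q


@pytest.fixture(scope="session")
def atlas():
    return q.build_atlas(q.default_atlas_spec())


@pytest.fixture(scope="session")
def templates6():
    return q.default_templates(window_w=6, bfb_lead_frames=1)


def make_group(atlas, template, n_subjects, frames, n_events, rng, group="wt",
               noise_sd=1.0, global_amp=0.5, tr=0.6):
    """Per-subject series list plus concatenated-frame onsets."""
    subs, onsets = [], []
    for i in range(n_subjects):
        data, truth = q.generate_subject(
            atlas, template, n_events, noise_sd, global_amp, None, frames,
            rng, subject_id=f"{group}{i}", group=group)
        subs.append(q.ImageSeries(data, atlas.mask_index, tr,
                                  [(f"{group}{i}", 0, frames)]))
        onsets.extend(np.asarray(truth.onsets) + i * frames)
    return subs, np.asarray(sorted(onsets), dtype=int)


@pytest.fixture(scope="session")
def wt_study(atlas, templates6):
    """Default-condition detection study: 6 subjects x 500 frames, 30
    planted events/scan, per-voxel CNR ~1, W=6, 50-seed ensemble."""
    rng = np.random.default_rng(1000)
    subs, onsets = make_group(atlas, templates6["wt"], 6, 500, 30, rng)
    zscored, raw = q.preprocess_group(subs)
    params = q.QPPParams(window_w=6, n_seeds=50, rng_seed=2000)
    ensemble = q.extract_qpp_ensemble(zscored, params)
    clusters = q.cluster_qpps(ensemble, zscored.subject_bounds,
                              min_size=max(2, params.n_seeds // 10))
    return {
        "zscored": zscored, "raw": raw, "onsets": onsets,
        "ensemble": ensemble, "clusters": clusters, "params": params,
        "planted_raw": templates6["wt"].render(atlas),
        "planted_filtered": q.planted_pattern_filtered(atlas, templates6["wt"]),
    }


def best_robust_recovery(study, atlas=None):
    """Best-matching robust cluster's recovery scores vs planted truth."""
    best = None
    for c in study["clusters"]:
        if not c.robust:
            continue
        rq = study["ensemble"][c.representative_id]
        sc = q.score_recovery(rq.pattern, rq.occurrences,
                              study["planted_filtered"], study["onsets"])
        if best is None or sc["template_corr"] > best[1]["template_corr"]:
            best = (c, sc)
    return best


@pytest.fixture(scope="session")
def timing_studies(atlas):
    """W=15 lead/lag studies: wild-type-like cohort with a 1-frame basal
    forebrain lead, and a transgenic-like cohort with the lead removed."""
    templates = q.default_templates(window_w=15, bfb_lead_frames=1,
                                    tg_bfb_amplitude=1.0)
    out = {}
    for group, gseed, eseed in (("wt", 11, 5), ("tg", 22, 6)):
        rng = np.random.default_rng(gseed)
        subs, onsets = make_group(atlas, templates[group], 6, 500, 12, rng,
                                  group=group)
        zscored, raw = q.preprocess_group(subs)
        ensemble = q.extract_qpp_ensemble(
            zscored, q.QPPParams(window_w=15, n_seeds=30, rng_seed=eseed))
        clusters = q.cluster_qpps(ensemble, zscored.subject_bounds, min_size=3)
        planted_f = q.planted_pattern_filtered(atlas, templates[group])
        best = None
        for c in clusters:
            if not c.robust:
                continue
            rq = ensemble[c.representative_id]
            sc = q.score_recovery(rq.pattern, rq.occurrences, planted_f,
                                  onsets, max_shift=7)
            if best is None or sc["template_corr"] > best[1]["template_corr"]:
                best = (c, sc)
        rqpp = ensemble[best[0].representative_id]
        out[group] = {"raw": raw, "rqpp": rqpp, "onsets": onsets,
                      "recovery": best[1]}
    return out
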