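"""Group statistics: t-maps with FDR + extent filtering, effect sizes,
occurrence rates and static functional connectivity."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import qppfmri as q


def box_mask_index(shape):
    mask = np.ones(shape, dtype=bool)
    return np.argwhere(mask), mask


class TestBhFdr:
    def test_hand_computed_stepup(self):
        # thresholds i/m*q = .0125, .025, .0375, .05 -> reject first two
        rejected = q.bh_fdr(np.array([0.01, 0.02, 0.04, 0.2]), q=0.05)
        assert rejected.tolist() == [True, True, False, False]

    def test_degenerate_inputs(self):
        assert q.bh_fdr(np.array([]), 0.05).size == 0
        assert not q.bh_fdr(np.ones(5), 0.05).any()
        assert q.bh_fdr(np.zeros(5), 0.05).all()

    def test_matches_naive_stepup_on_random_p(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=200)
        mine = q.bh_fdr(p, 0.05)
        # independent step-up oracle
        order = np.argsort(p)
        m = p.size
        below = np.flatnonzero(p[order] <= (np.arange(1, m + 1) / m) * 0.05)
        oracle = np.zeros(m, dtype=bool)
        if below.size:
            oracle[order[:below[-1] + 1]] = True
        assert np.array_equal(mine, oracle)


class TestOccurrenceSegments:
    def test_noiseless_segments_equal_planted_pattern(self, atlas, templates6):
        rng = np.random.default_rng(1)
        data, truth = q.generate_subject(atlas, templates6["tg"], 25, 0.0,
                                         0.0, None, 400, rng)
        series = q.ImageSeries(data, atlas.mask_index, 0.6, [("s", 0, 400)])
        qpp = q.QPP(pattern=templates6["tg"].render(atlas), seed_frame=0,
                    stc=np.zeros(395), occurrences=np.asarray(truth.onsets),
                    n_iterations=1, converged=True)
        segments = q.occurrence_segments(series, qpp)
        assert segments.shape == (25, atlas.n_voxels, 6)
        planted = templates6["tg"].render(atlas)
        assert np.max(np.abs(segments - planted[None])) == 0.0

    def test_last_valid_offset_included_and_empty_errors(self):
        rng = np.random.default_rng(2)
        data = rng.standard_normal((5, 50))
        idx = np.column_stack([np.arange(5), np.zeros(5, int), np.zeros(5, int)])
        series = q.ImageSeries(data, idx, 0.6, [])
        qpp = q.QPP(pattern=data[:, 44:50], seed_frame=0, stc=np.zeros(45),
                    occurrences=np.array([44]), n_iterations=1, converged=True)
        segs = q.occurrence_segments(series, qpp)
        assert segs.shape[0] == 1
        assert np.array_equal(segs[0], data[:, 44:50])
        qpp_empty = q.QPP(pattern=data[:, :6], seed_frame=0,
                          stc=np.zeros(45), occurrences=np.array([], int),
                          n_iterations=1, converged=False)
        with pytest.raises(ValueError, match="zero occurrences"):
            q.occurrence_segments(series, qpp_empty)


class TestActivationTmap:
    def test_t_matches_per_voxel_oracle(self):
        rng = np.random.default_rng(3)
        shape = (6, 6, 3)
        mi, _ = box_mask_index(shape)
        segments = 0.3 + rng.standard_normal((12, mi.shape[0], 4))
        smap = q.activation_tmap(segments, mi, shape)
        t_oracle, p_oracle = stats.ttest_1samp(segments, 0.0, axis=0)
        assert np.max(np.abs(smap.stat - t_oracle)) < 1e-10
        assert np.max(np.abs(smap.p - p_oracle)) < 1e-10

    def test_zero_variance_voxelframe_gets_p_one(self, caplog):
        rng = np.random.default_rng(4)
        shape = (4, 4, 2)
        mi, _ = box_mask_index(shape)
        segments = rng.standard_normal((8, mi.shape[0], 3))
        segments[:, 0, 0] = 5.0  # identical nonzero constant
        with caplog.at_level("WARNING"):
            smap = q.activation_tmap(segments, mi, shape)
        assert smap.p[0, 0] == 1.0
        assert smap.stat[0, 0] == 0.0
        assert not smap.significant[0, 0]

    def test_extent_filter_removes_small_blobs(self):
        rng = np.random.default_rng(5)
        shape = (8, 8, 4)
        mi, _ = box_mask_index(shape)
        V = mi.shape[0]
        segments = rng.standard_normal((20, V, 2))
        # 12-voxel 6-connected slab survives, 8-voxel slab removed
        rows_big = [i for i, (x, y, z) in enumerate(mi)
                    if x < 3 and y < 2 and z < 2]       # 3*2*2 = 12
        rows_small = [i for i, (x, y, z) in enumerate(mi)
                      if x >= 6 and y >= 6 and z < 2]   # 2*2*2 = 8
        segments[:, rows_big, 0] += 6.0
        segments[:, rows_small, 0] += 6.0
        smap = q.activation_tmap(segments, mi, shape)
        assert smap.significant[rows_big, 0].all()
        assert not smap.significant[rows_small, 0].any()

    def test_needs_three_segments(self):
        mi, _ = box_mask_index((2, 2, 1))
        with pytest.raises(ValueError, match=">= 3"):
            q.activation_tmap(np.zeros((2, 4, 3)), mi, (2, 2, 1))


class TestGroupDifferenceTmap:
    def test_swapping_groups_flips_sign_exactly(self):
        rng = np.random.default_rng(6)
        shape = (4, 4, 2)
        mi, _ = box_mask_index(shape)
        a = rng.standard_normal((10, mi.shape[0], 3))
        b = rng.standard_normal((12, mi.shape[0], 3))
        ab = q.group_difference_tmap(a, b, mi, shape)
        ba = q.group_difference_tmap(b, a, mi, shape)
        assert np.max(np.abs(ab.stat + ba.stat)) < 1e-12
        assert np.max(np.abs(ab.p - ba.p)) < 1e-12

    def test_pooled_t_matches_scipy(self):
        rng = np.random.default_rng(7)
        shape = (4, 4, 2)
        mi, _ = box_mask_index(shape)
        a = rng.standard_normal((9, mi.shape[0], 3))
        b = 0.5 + rng.standard_normal((11, mi.shape[0], 3))
        smap = q.group_difference_tmap(a, b, mi, shape)
        t_o, p_o = stats.ttest_ind(a, b, axis=0, equal_var=True)
        assert np.max(np.abs(smap.stat - t_o)) < 1e-10
        assert np.max(np.abs(smap.p - p_o)) < 1e-10

    def test_planted_roi_difference_localises(self, atlas):
        # one ROI has amplitude 1 vs 0, CNR 1, 30 segments/group: significant
        # voxels concentrate (>= 80%) in that ROI
        rng = np.random.default_rng(8)
        V = atlas.n_voxels
        W = 6
        wave = q.raised_cosine(W)
        roi = atlas.roi_rows(3)  # the small BFB-like region
        a = rng.standard_normal((30, V, W))
        a[:, roi, :] += wave
        b = rng.standard_normal((30, V, W))
        smap = q.group_difference_tmap(a, b, atlas.mask_index,
                                       atlas.mask.shape,
                                       min_cluster_voxels=1)
        hits = np.flatnonzero(smap.significant.any(axis=1))
        assert hits.size > 0
        frac_in_roi = np.isin(hits, roi).mean()
        assert frac_in_roi >= 0.8


class TestCohensD:
    def test_identical_groups_zero(self):
        rng = np.random.default_rng(9)
        tc = {1: rng.standard_normal((20, 6))}
        d = q.cohens_d_profile(tc, {1: tc[1].copy()})
        assert np.allclose(d[1], 0.0)

    def test_unit_effect_recovered(self):
        rng = np.random.default_rng(10)
        a = {1: 1.0 + rng.standard_normal((100, 6))}
        b = {1: rng.standard_normal((100, 6))}
        d = q.cohens_d_profile(a, b)
        assert np.all(np.abs(d[1] - 1.0) < 0.35)
        assert abs(d[1].mean() - 1.0) < 0.1

    def test_scale_invariance(self):
        rng = np.random.default_rng(11)
        a = {1: 2.0 + rng.standard_normal((30, 6))}
        b = {1: rng.standard_normal((30, 6))}
        d1 = q.cohens_d_profile(a, b)[1]
        d2 = q.cohens_d_profile({1: 3.7 * a[1]}, {1: 3.7 * b[1]})[1]
        assert np.allclose(d1, d2, atol=1e-12)


class TestOccurrenceRates:
    def test_counts_and_rate_normalisation(self, wt_study, atlas):
        table = q.occurrence_rates(wt_study["zscored"],
                                   wt_study["planted_filtered"], "wt")
        assert len(table) == 6
        assert (table["count"] > 0).all()
        # rate = count / (frames * TR / 60); 500 frames at 0.6 s = 5 min
        assert np.allclose(table["rate"], table["count"] / 5.0)

    def test_never_crossing_threshold_counts_zero(self):
        rng = np.random.default_rng(12)
        data = rng.standard_normal((2000, 300))
        idx = np.column_stack([np.arange(2000), np.zeros(2000, int),
                               np.zeros(2000, int)])
        series = q.ImageSeries(data, idx, 0.6, [])
        template = rng.standard_normal((2000, 6))
        table = q.occurrence_rates(series, template, "x")
        assert table["count"].tolist() == [0]

    def test_identical_rates_give_t_zero_p_one(self):
        rows = [{"subject_id": f"s{i}", "group": g, "cluster_id": 0,
                 "count": 10, "rate": 2.0}
                for g in ("a", "b") for i in range(4)]
        res = q.compare_occurrence_rates(pd.DataFrame(rows))
        assert res.loc[0, "t"] == 0.0
        assert res.loc[0, "p"] == 1.0
        assert not res.loc[0, "significant"]

    def test_small_group_raises(self):
        rows = [{"subject_id": "s", "group": "a", "cluster_id": 0,
                 "count": 1, "rate": 0.2},
                {"subject_id": "t", "group": "b", "cluster_id": 0,
                 "count": 1, "rate": 0.2},
                {"subject_id": "u", "group": "b", "cluster_id": 0,
                 "count": 2, "rate": 0.4}]
        with pytest.raises(ValueError, match=">= 2 subjects"):
            q.compare_occurrence_rates(pd.DataFrame(rows))


class TestStaticFc:
    def test_known_correlation_maps_to_fisher_z(self, atlas):
        # build ROI-mean courses with exact r = 0.5 between ROIs 1 and 2
        rng = np.random.default_rng(13)
        n = 400
        u = rng.standard_normal(n)
        u = (u - u.mean()) / u.std()
        v = rng.standard_normal(n)
        v -= v.mean()
        v -= (v @ u) / (u @ u) * u
        v /= v.std()
        data = np.zeros((atlas.n_voxels, n))
        data[atlas.roi_rows(1)] = u
        data[atlas.roi_rows(2)] = 0.5 * u + np.sqrt(0.75) * v
        data[atlas.roi_rows(3)] = rng.standard_normal(n)
        series = q.ImageSeries(data, atlas.mask_index, 0.6, [])
        (z,) = q.static_fc(series, atlas).values()
        assert np.isnan(z[0, 0])  # diagonal excluded
        assert z[0, 1] == pytest.approx(np.arctanh(0.5), abs=1e-10)
        assert z[0, 1] == pytest.approx(0.5493, abs=1e-4)

    def test_independent_noise_has_near_zero_mean_z(self, atlas):
        rng = np.random.default_rng(14)
        zs = []
        for i in range(6):
            data = rng.standard_normal((atlas.n_voxels, 1000))
            series = q.ImageSeries(data, atlas.mask_index, 0.6,
                                   [(f"s{i}", 0, 1000)])
            z = list(q.static_fc(series, atlas).values())[0]
            np.fill_diagonal(z, 0.0)
            zs.append(z)
        mean_z = np.stack(zs).mean(axis=0)
        assert np.max(np.abs(mean_z)) < 0.1

    def test_perfect_correlation_clipped_not_infinite(self, atlas, caplog):
        rng = np.random.default_rng(15)
        u = rng.standard_normal(100)
        data = np.tile(u, (atlas.n_voxels, 1))
        series = q.ImageSeries(data, atlas.mask_index, 0.6, [])
        with caplog.at_level("WARNING"):
            (z,) = q.static_fc(series, atlas).values()
        off_diag = z[~np.isnan(z)]
        assert np.all(np.isfinite(off_diag))

    def test_compare_fc_identical_groups_not_significant(self, atlas):
        rng = np.random.default_rng(16)
        fc = {}
        for i in range(4):
            data = rng.standard_normal((atlas.n_voxels, 200))
            series = q.ImageSeries(data, atlas.mask_index, 0.6, [])
            fc[f"s{i}"] = list(q.static_fc(series, atlas).values())[0]
        res = q.compare_fc(fc, fc, atlas.roi_labels)
        assert (res["t"] == 0).all()
        assert not res["significant"].any()
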