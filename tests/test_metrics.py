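"""QPP statistics: contrast, selection, projection, rates, matching,
window extension, significance maps."""

import numpy as np
import pytest

from qppdyn.detect import (QppRecord, QppTemplate, StcSeries,
                           sliding_template_correlation)
from qppdyn.metrics import (compare_rates, extend_template,
                            inter_area_correlation, match_qpps,
                            occurrence_rates, project_stc, qpp_contrast,
                            qpp_significance_map, select_qpp,
                            template_similarity)
from qppdyn.simulate import make_template


class TestContrast:
    def test_uniform_template_has_zero_contrast(self):
        assert qpp_contrast(np.ones((5, 4))) == 0.0

    def test_two_voxel_hand_computation(self):
        # frames [1,3] and [3,1]: mean 2, sample sd sqrt(2) -> Cv sqrt(2)/2
        t = np.array([[1.0, 3.0], [3.0, 1.0]])
        assert qpp_contrast(t) == pytest.approx(np.sqrt(2) / 2)

    def test_zero_mean_frame_hits_cap(self):
        t = np.array([[1.0, 1.0], [-1.0, 1.0]])
        # frame 0 has mean 0, sd > 0 -> capped at 1e6; frame 1 constant -> 0
        assert qpp_contrast(t) == pytest.approx(5e5)

    def test_global_pattern_less_contrasted_than_antagonistic(self, atlas_geom):
        atlas, _ = atlas_geom
        gs = make_template("GS_like", atlas, 12)
        wt = make_template("WT_like", atlas, 6)
        assert qpp_contrast(gs) < qpp_contrast(wt)


def _record(peak_vals, seed=0, converged=True, tr=0.5):
    n = 30
    values = np.zeros(n)
    peaks = (np.arange(len(peak_vals)) * 7 + 1).astype(int)
    values[peaks] = peak_vals
    stc = StcSeries(values=values, valid=np.ones(n, bool), peaks=peaks)
    return QppRecord(template=QppTemplate(data=np.random.default_rng(seed).standard_normal((4, 3)), tr_seconds=tr),
                     stc=stc, start_frame_seed=seed, iterations=3, converged=converged)


class TestSelection:
    def test_argmax_peak_sum(self):
        recs = [_record([1.2], 0), _record([3.4], 1), _record([0.9], 2)]
        assert select_qpp(recs) is recs[1]

    def test_single_record_returned(self):
        recs = [_record([0.5], 7)]
        assert select_qpp(recs) is recs[0]

    def test_tie_prefers_more_peaks_then_earlier_seed(self):
        a = _record([0.5, 0.5, 0.5], seed=5)
        b = _record([0.3, 0.3, 0.3, 0.3, 0.3], seed=9)
        assert select_qpp([a, b]) is b
        c = _record([0.5, 0.5], seed=2)
        d = _record([0.5, 0.5], seed=1)
        assert select_qpp([c, d]) is d

    def test_unconverged_records_excluded(self):
        recs = [_record([9.0], converged=False), _record([0.1])]
        assert select_qpp(recs) is recs[1]
        with pytest.raises(ValueError):
            select_qpp([_record([9.0], converged=False)])


class TestProjection:
    def test_projection_onto_source_reproduces_stc(self, rng):
        data = rng.standard_normal((6, 80))
        tmpl = data[:, 10:16].copy()
        stc = sliding_template_correlation(tmpl, data)
        pstc = project_stc(QppTemplate(data=tmpl, tr_seconds=0.5), data)
        np.testing.assert_array_equal(pstc.values, stc.values)

    def test_projection_peaks_at_planted_frames(self, atlas_geom, rng):
        atlas, _ = atlas_geom
        tmpl = make_template("WT_like", atlas, 6)
        data = np.zeros((atlas.geometry.n_voxels, 200))
        planted = [20, 60, 120]
        for p in planted:
            data[:, p : p + 6] += tmpl.data
        data += 1e-6 * rng.standard_normal(data.shape)
        pstc = project_stc(tmpl, data, min_separation=6)
        assert sorted(pstc.peaks.tolist()) == planted


class TestRates:
    def test_simple_arithmetic(self):
        stc = StcSeries(values=np.zeros(480), valid=np.ones(480, bool),
                        peaks=np.array([10, 50, 90, 130]))
        rates = occurrence_rates(stc, [("s", 0, 240), ("t", 240, 480)], 0.5)
        assert rates == {"s": 2.0, "t": 0.0}

    def test_full_length_scan_units(self):
        peaks = np.arange(20) * 120
        stc = StcSeries(values=np.zeros(2400), valid=np.ones(2400, bool), peaks=peaks)
        rates = occurrence_rates(stc, [("s", 0, 2400)], 0.5)
        assert rates["s"] == pytest.approx(1.0)  # 20 peaks in 20 minutes

    def test_identical_groups_p_one(self):
        t, p = compare_rates([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_zero_variance_distinct_means_flagged_infinite(self):
        t, p = compare_rates([1, 1, 1], [2, 2, 2])
        assert np.isinf(t) and p == 0.0

    def test_matches_textbook_pooled_formula(self, rng):
        a, b = rng.standard_normal(8) + 0.3, rng.standard_normal(10)
        t, p = compare_rates(a, b)
        na, nb = len(a), len(b)
        sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
        t_oracle = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
        assert t == pytest.approx(t_oracle, abs=1e-10)


class TestMatching:
    def _rec_from_stc(self, values, tr=0.5):
        stc = StcSeries(values=np.asarray(values, float),
                        valid=np.ones(len(values), bool))
        return QppRecord(template=QppTemplate(data=np.zeros((2, 4)) + np.arange(4),
                                              tr_seconds=tr),
                         stc=stc, start_frame_seed=0, iterations=1, converged=True)

    def test_self_match_sign_plus_lag_zero(self, rng):
        v = rng.standard_normal(60)
        rec = self._rec_from_stc(v)
        pstc = StcSeries(values=v.copy(), valid=np.ones(60, bool))
        best, sign, lag = match_qpps(pstc, [rec, self._rec_from_stc(rng.standard_normal(60))])
        assert best is rec and sign == 1 and lag == 0

    def test_sign_flip_detected(self, rng):
        v = rng.standard_normal(60)
        rec = self._rec_from_stc(-v)
        pstc = StcSeries(values=v, valid=np.ones(60, bool))
        _, sign, lag = match_qpps(pstc, [rec])
        assert sign == -1 and lag == 0

    def test_constructed_shift_recovered(self, rng):
        v = rng.standard_normal(80)
        shifted = np.roll(v, 2)  # target STC delayed by 2 frames
        rec = self._rec_from_stc(shifted)
        pstc = StcSeries(values=v, valid=np.ones(80, bool))
        _, sign, lag = match_qpps(pstc, [rec])
        assert (sign, lag) == (1, 2)

    def test_empty_target_list_raises(self, rng):
        pstc = StcSeries(values=rng.standard_normal(10), valid=np.ones(10, bool))
        with pytest.raises(ValueError):
            match_qpps(pstc, [])


class TestInterArea:
    def test_planted_pattern_pairings(self, atlas_geom):
        atlas, _ = atlas_geom
        wt = make_template("WT_like", atlas, 6)
        assert inter_area_correlation(wt, atlas, [("Cg_L", "Cpu_d_R")]) == pytest.approx(1.0)
        assert inter_area_correlation(wt, atlas, [("Cg_L", "S1_L"), ("Cg_R", "Ins_R")]) == pytest.approx(-1.0)
        gs = make_template("GS_like", atlas, 12)
        pairs = [("Cg_L", "S1_L"), ("Cpu_d_L", "S2_R"), ("Ins_L", "Cpu_vl_R")]
        assert inter_area_correlation(gs, atlas, pairs) == pytest.approx(1.0)

    def test_constant_course_pairs_skipped(self, atlas_geom):
        atlas, _ = atlas_geom
        tg = make_template("TG_like", atlas, 6)  # TPN ROIs are silent
        out = inter_area_correlation(tg, atlas, [("S1_L", "S2_L")])
        assert np.isnan(out)

    def test_matches_direct_pairwise_oracle(self, atlas_geom, rng):
        atlas, _ = atlas_geom
        data = rng.standard_normal((atlas.geometry.n_voxels, 8))
        pairs = [("Cg_L", "S1_L"), ("S2_R", "Ins_L"), ("Cpu_d_L", "Cpu_vl_R")]
        expect = np.mean([
            np.corrcoef(data[atlas.labels[a]].mean(0), data[atlas.labels[b]].mean(0))[0, 1]
            for a, b in pairs])
        got = inter_area_correlation(QppTemplate(data=data, tr_seconds=0.5), atlas, pairs)
        assert got == pytest.approx(expect, abs=1e-12)


class TestTemplateSimilarity:
    def test_identity_and_sign(self, rng):
        t = rng.standard_normal((10, 6))
        r, lag, sign = template_similarity(t, t)
        assert (r, lag, sign) == (pytest.approx(1.0), 0, 1)
        r, lag, sign = template_similarity(t, -t)
        assert (pytest.approx(-1.0), 0, -1) == (r, lag, sign)

    def test_shift_recovered(self, rng):
        t = rng.standard_normal((10, 8))
        shifted = np.roll(t, 2, axis=1)
        r, lag, _ = template_similarity(t, shifted, max_lag=3)
        assert abs(lag) == 2 and abs(r) > 0.5


class TestExtension:
    def _planted(self, env, W, n_occ=10, spacing=40, L=30, rng=None):
        rng = rng or np.random.default_rng(0)
        u = rng.standard_normal(L)
        T = spacing * (n_occ + 1)
        data = np.zeros((L, T))
        occs = []
        for i in range(n_occ):
            p = spacing * (i + 1)
            data[:, p : p + W] += np.outer(u, env)
            occs.append(p)
        data += 1e-8 * rng.standard_normal(data.shape)
        return data, np.array(occs), u

    def test_monophasic_length_estimate(self):
        from qppdyn.simulate import bandlimited_bump

        env = bandlimited_bump(6, 0.5)  # the generator's default burst shape
        data, occs, _ = self._planted(env, 6)
        ext, length = extend_template(data, occs, 6, extension=6)
        assert ext.shape[1] == 18
        assert abs(length - 6) <= 1

    def test_biphasic_pattern_found_beyond_short_window(self):
        env12 = np.sin(2 * np.pi * np.arange(12) / 11)  # + then - phase
        data, occs, u = self._planted(env12, 12, spacing=50)
        # detection at W=6 sees only the positive phase; extension reveals both
        ext, length = extend_template(data, occs, 6, extension=6)
        first = ext[:, 6:9].mean(axis=1)
        second = ext[:, 13:16].mean(axis=1)
        assert np.corrcoef(first, second)[0, 1] < -0.8
        assert 10 <= length <= 14

    def test_edge_occurrences_dropped(self):
        env = np.sin(np.pi * np.arange(6) / 5)
        data, occs, _ = self._planted(env, 6, n_occ=5, spacing=30)
        occs_with_edge = np.concatenate([[2], occs])  # too close to the start
        ext, _ = extend_template(data, occs_with_edge, 6, extension=6)
        ext2, _ = extend_template(data, occs, 6, extension=6)
        np.testing.assert_allclose(ext, ext2)

    def test_too_few_occurrences_raises(self):
        env = np.sin(np.pi * np.arange(6) / 5)
        data, occs, _ = self._planted(env, 6, n_occ=2)
        with pytest.raises(ValueError):
            extend_template(data, occs[:2], 6, extension=6)


class TestSignificanceMap:
    def test_noise_free_pattern_voxels_significant(self, rng):
        L, W = 40, 5
        u = np.zeros(L)
        u[:15] = rng.standard_normal(15)
        env = np.sin(np.pi * np.arange(W) / (W - 1)) + 0.3
        data = np.zeros((L, 400))
        occs = np.arange(10) * 37 + 5
        for p in occs:
            data[:, p : p + W] += np.outer(u, env)
        data[:15] += 1e-9 * rng.standard_normal((15, 400))
        t, reject = qpp_significance_map(data, occs, W)
        assert t.shape == (L, W)
        strong = np.flatnonzero(np.abs(u) > 0.5)
        assert reject[strong].any(axis=1).all()
        assert not reject[15:].any()

    def test_two_occurrences_raise(self, rng):
        data = rng.standard_normal((10, 100))
        with pytest.raises(ValueError):
            qpp_significance_map(data, [10, 40], 6)

    def test_null_false_discovery_proportion_controlled(self):
        rng = np.random.default_rng(0)
        fdps = []
        for _ in range(200):
            data = rng.standard_normal((12, 200))
            occs = np.arange(8) * 24 + 3
            _, reject = qpp_significance_map(data, occs, 4, q=0.05)
            # complete null: every discovery is false, FDP is 1 iff any rejection
            fdps.append(1.0 if reject.any() else 0.0)
        assert np.mean(fdps) <= 0.05 + 0.03  # q plus Monte-Carlo slack
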