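"""Peak picking, m/z alignment, spline normalization, replicate
averaging and the QC report, each checked against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import uromics as u
from uromics.preprocess import PeakList, Peak, Spectrum


def brute_force_pick(mz, y, threshold=3.0, window=101):
    """Point-by-point application of the local-max + MAD S/N rule."""
    h = window // 2
    out = []
    for i in range(1, len(y) - 1):
        if not (y[i] > y[i - 1] and y[i] > y[i + 1]):
            continue
        seg = y[max(0, i - h): i + h + 1]
        med = np.median(seg)
        noise = 1.4826 * np.median(np.abs(seg - med))
        height = y[i] - med
        if noise > 0:
            ok = height / noise > threshold
        else:
            ok = height > 0
        if ok:
            out.append(mz[i])
    return out


class TestPickPeaks:
    def test_single_spike_recovered_exactly(self):
        mz = np.arange(100.0, 110.0, 0.01)
        rng = np.random.default_rng(0)
        y = np.maximum(3 + rng.normal(0, 1, mz.size), 0)
        i = int(np.argmin(np.abs(mz - 104.03)))
        y[i] += 50.0
        peaks = u.pick_peaks(Spectrum(mz=mz, intensity=y))
        strong = [p for p in peaks.peaks if p.snr > 20]
        assert len(strong) == 1
        assert abs(strong[0].mz - 104.03) <= 0.01

    def test_all_zero_trace_gives_no_peaks(self):
        mz = np.arange(0, 100, 1.0)
        peaks = u.pick_peaks(Spectrum(mz=mz, intensity=np.zeros(100)))
        assert len(peaks) == 0

    def test_matches_brute_force_on_gaussian_noise(self, rng):
        mz = np.arange(10000) * 0.01 + 50
        y = np.maximum(5 + rng.normal(0, 1, 10000), 0)
        y[::517] += rng.uniform(0, 8, len(y[::517]))  # some mid-size bumps
        got = sorted(p.mz for p in u.pick_peaks(Spectrum(mz=mz, intensity=y)).peaks)
        expect = sorted(brute_force_pick(mz, y))
        assert got == expect

    def test_lowering_threshold_never_removes_peaks(self, rng):
        mz = np.arange(2000) * 0.01
        y = np.maximum(3 + rng.normal(0, 1, 2000), 0)
        high = {p.mz for p in u.pick_peaks(Spectrum(mz=mz, intensity=y),
                                           snr_threshold=4).peaks}
        low = {p.mz for p in u.pick_peaks(Spectrum(mz=mz, intensity=y),
                                          snr_threshold=2).peaks}
        assert high <= low

    def test_noise_only_short_traces_rarely_fire(self, rng):
        """Monte-Carlo false-positive rate of the S/N > 3 rule on pure
        noise: most short traces yield zero peaks (the rate is bounded by
        the rule's own MC behaviour, ~0.9 zero-peak fraction)."""
        zero = 0
        for _ in range(300):
            y = np.maximum(3 + rng.normal(0, 1, 25), 0)
            zero += len(u.pick_peaks(Spectrum(mz=np.arange(25.0) + 20, intensity=y))) == 0
        assert zero / 300 >= 0.85


class TestAlignFeatures:
    @staticmethod
    def _pl(sample, mzs):
        return PeakList([Peak(m, 100.0, 10.0) for m in mzs], sample_id=sample)

    def test_within_tolerance_merges(self):
        mat = u.align_features([self._pl("a", [100.000]),
                                self._pl("b", [100.004])], tolerance=0.01)
        assert mat.shape == (2, 1)
        assert mat.notna().sum().iloc[0] == 2

    def test_beyond_tolerance_splits(self):
        mat = u.align_features([self._pl("a", [100.00]),
                                self._pl("b", [100.20])], tolerance=0.01)
        assert mat.shape[1] == 2

    def test_matches_single_linkage_oracle(self, rng):
        lists = [self._pl(f"s{i}", np.sort(rng.uniform(50, 60, 30)))
                 for i in range(50)]
        tol = 0.01
        mat = u.align_features(lists, tolerance=tol)
        # brute-force single-linkage: union-find over all within-tol pairs
        allmz = np.concatenate([[p.mz for p in pl.peaks] for pl in lists])
        parent = list(range(len(allmz)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(allmz)):
            for j in range(i + 1, len(allmz)):
                if abs(allmz[i] - allmz[j]) <= tol:
                    parent[find(i)] = find(j)
        n_clusters = len({find(i) for i in range(len(allmz))})
        assert mat.shape[1] == n_clusters

    def test_permutation_invariant(self, rng):
        lists = [self._pl(f"s{i}", np.sort(rng.uniform(100, 105, 20)))
                 for i in range(8)]
        a = u.align_features(lists, tolerance=0.02)
        b = u.align_features(lists[::-1], tolerance=0.02)
        assert sorted(a.columns) == sorted(b.columns)
        pd.testing.assert_frame_equal(
            a.sort_index(axis=0).sort_index(axis=1),
            b.sort_index(axis=0).sort_index(axis=1))

    def test_bad_tolerance_rejected(self):
        with pytest.raises(ValueError):
            u.align_features([self._pl("a", [100.0])], tolerance=0.0)


class TestCubicSplineNormalize:
    @staticmethod
    def _matrix(rng, n=20, p=120):
        base = rng.uniform(8, 16, p)
        rows = [2.0 ** (base + rng.normal(0, 0.3, p)) for _ in range(n)]
        return pd.DataFrame(rows, index=[f"s{i}" for i in range(n)],
                            columns=[f"f{j}" for j in range(p)])

    def test_identity_when_sample_equals_reference(self, rng):
        mat = self._matrix(rng)
        ref = mat.iloc[0]
        out = u.cubic_spline_normalize(pd.DataFrame([ref, ref]), reference=ref)
        np.testing.assert_allclose(out.to_numpy(),
                                   np.vstack([ref, ref]), rtol=1e-9)

    def test_constant_multiplicative_shift_removed(self, rng):
        mat = self._matrix(rng, n=4)
        shifted = mat.copy()
        shifted.iloc[1] = mat.iloc[0] * 2.0
        shifted.iloc[2] = mat.iloc[0]
        out = u.cubic_spline_normalize(shifted, reference=mat.iloc[0])
        rel = np.abs(out.iloc[1] / mat.iloc[0] - 1.0)
        assert np.median(rel) < 0.01

    def test_idempotent(self, rng):
        mat = self._matrix(rng)
        once = u.cubic_spline_normalize(mat)
        ref = mat.median(axis=0)
        once = u.cubic_spline_normalize(mat, reference=ref)
        twice = u.cubic_spline_normalize(once, reference=ref)
        rel = np.abs(twice.to_numpy() / once.to_numpy() - 1.0)
        assert rel.max() < 1e-6

    def test_rank_order_preserved(self, rng):
        mat = self._matrix(rng)
        out = u.cubic_spline_normalize(mat)
        for i in range(len(mat)):
            a = mat.iloc[i].to_numpy()
            b = out.iloc[i].to_numpy()
            assert stats.spearmanr(a, b).statistic > 0.999999

    def test_sparse_sample_falls_back_to_median_scaling(self, rng):
        mat = self._matrix(rng, n=3, p=50)
        sparse = mat.copy()
        sparse.iloc[2, 5:] = np.nan          # 5 observed < knots + 1
        out = u.cubic_spline_normalize(sparse)
        obs = out.iloc[2, :5]
        assert np.isfinite(obs).all()


class TestAverageReplicates:
    def test_mean_of_three(self):
        idx = pd.MultiIndex.from_tuples(
            [("s1", 1), ("s1", 2), ("s1", 3)], names=["sample_id", "replicate"])
        mat = pd.DataFrame({"f": [10.0, 20.0, 30.0]}, index=idx)
        out = u.average_replicates(mat)
        assert out.loc["s1", "f"] == 20.0

    def test_single_replicate_passthrough(self):
        idx = pd.MultiIndex.from_tuples([("s1", 1)],
                                        names=["sample_id", "replicate"])
        mat = pd.DataFrame({"f": [7.0]}, index=idx)
        assert u.average_replicates(mat).loc["s1", "f"] == 7.0

    def test_matches_groupby_oracle(self, rng, small_cohort):
        out = u.average_replicates(small_cohort.intensities)
        oracle = small_cohort.intensities.groupby(level=0, sort=False).mean()
        np.testing.assert_allclose(out.to_numpy(), oracle.to_numpy())

    def test_bad_replicate_map_rejected(self):
        mat = pd.DataFrame({"f": [1.0, 2.0]}, index=["r1", "r2"])
        with pytest.raises(ValueError):
            u.average_replicates(mat, pd.Series({"r1": "s1"}))


class TestQcReport:
    def test_identical_replicates_perfect_spearman(self):
        row = np.random.default_rng(0).uniform(10, 100, 50)
        mat = pd.DataFrame([row, row], index=["q1", "q2"])
        rep = u.qc_report(mat, ["q1", "q2"])
        assert rep.replicate_spearman == pytest.approx(1.0)

    def test_rsd_hand_example(self):
        mat = pd.DataFrame({"f": [90.0, 100.0, 110.0]},
                           index=["q1", "q2", "q3"])
        rep = u.qc_report(mat, ["q1", "q2", "q3"],
                          batch_labels=pd.Series(1, index=mat.index))
        assert rep.intra_batch_rsd_median == pytest.approx(10.0)

    def test_single_qc_replicate_flagged(self):
        mat = pd.DataFrame({"f": [1.0, 2.0]}, index=["q1", "s1"])
        rep = u.qc_report(mat, ["q1"])
        assert np.isnan(rep.replicate_spearman)
        assert any("Spearman" in n for n in rep.notes)

    def test_metrics_match_brute_force(self, rng):
        vals = rng.uniform(50, 150, (6, 30))
        mat = pd.DataFrame(vals, index=[f"q{i}" for i in range(6)])
        batches = pd.Series([1, 1, 1, 2, 2, 2], index=mat.index)
        rep = u.qc_report(mat, list(mat.index), batch_labels=batches)
        rsds = []
        for b in (0, 3):
            grp = vals[b:b + 3]
            rsds.append(100 * grp.std(axis=0, ddof=1) / grp.mean(axis=0))
        assert rep.intra_batch_rsd_median == pytest.approx(
            np.median(np.concatenate(rsds)))
        bm = np.vstack([vals[:3].mean(axis=0), vals[3:].mean(axis=0)])
        inter = 100 * bm.std(axis=0, ddof=1) / bm.mean(axis=0)
        assert rep.inter_batch_rsd_median == pytest.approx(np.median(inter))
        cors = [stats.spearmanr(vals[i], vals[j]).statistic
                for i in range(6) for j in range(i + 1, 6)]
        assert rep.replicate_spearman == pytest.approx(np.mean(cors))


def test_filter_and_impute_rules():
    mat = pd.DataFrame({
        "keep": [1.0, 2.0, np.nan, 4.0],      # 75% present
        "drop": [1.0, np.nan, np.nan, np.nan],  # 25% present
    })
    out = u.filter_and_impute(mat, min_presence=0.7)
    assert list(out.columns) == ["keep"]
    assert out["keep"].iloc[2] == pytest.approx(0.5)   # half of min observed
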