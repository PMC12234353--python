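"""Feature cleaning cascade: filters, merge, normalization, dedup, DF."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from exposomekit.feature_processing import (
    NEGATIVE,
    POSITIVE,
    PROTON_MASS,
    RawFeatureTable,
    blank_subtract_floor,
    clean_feature_tables,
    dedup_correlated,
    detection_frequency_filter,
    is_pca_correction,
    max_blank_ratio_filter,
    merge_esi_modes,
    normalize_by_is_pca,
    read_feature_table,
)


def make_table(rows, n_samples=6, n_blanks=2, n_qc=1, mode=POSITIVE):
    """Build a table from dicts with keys id, mz, rt, samples, blanks, qc."""
    sample_cols = [f"s{i}" for i in range(n_samples)]
    blank_cols = [f"b{i}" for i in range(n_blanks)]
    qc_cols = [f"q{i}" for i in range(n_qc)]
    meta, areas = [], []
    for r in rows:
        meta.append(
            dict(feature_id=r["id"], mz=r.get("mz", 200.0), rt=r.get("rt", 5.0),
                 mode=r.get("mode", mode), ms2=r.get("ms2", "100.0:10.0"))
        )
        areas.append(
            list(r.get("samples", [1e6] * n_samples))
            + list(r.get("blanks", [0.0] * n_blanks))
            + list(r.get("qc", [1e6] * n_qc))
        )
    columns = ["feature_id", "mz", "rt", "mode", "ms2"]
    meta = pd.DataFrame(meta, columns=columns).set_index("feature_id")
    areas = pd.DataFrame(areas, index=meta.index, columns=sample_cols + blank_cols + qc_cols)
    return RawFeatureTable(meta, areas, sample_cols, blank_cols, qc_cols)


class TestBlankRatioFilter:
    def test_stated_rule(self):
        t = make_table([
            {"id": "keep", "samples": [6e5, 0, 0, 0, 0, 0], "blanks": [1e5, 1e5]},
            {"id": "drop", "samples": [4.5e5, 0, 0, 0, 0, 0], "blanks": [1e5, 1e5]},
        ])
        out = max_blank_ratio_filter(t)
        assert list(out.meta.index) == ["keep"]

    def test_zero_blank_mean_retains_detected(self):
        t = make_table([{"id": "a", "samples": [1e5, 0, 0, 0, 0, 0], "blanks": [0, 0]}])
        assert max_blank_ratio_filter(t).n_features == 1

    def test_no_blank_columns_rejected(self):
        t = make_table([{"id": "a"}], n_blanks=0)
        with pytest.raises(ValueError, match="blank"):
            max_blank_ratio_filter(t)

    def test_idempotent(self):
        t = make_table([
            {"id": "a", "samples": [6e5] * 6, "blanks": [1e5, 1e5]},
            {"id": "b", "samples": [1e5] * 6, "blanks": [1e5, 1e5]},
        ])
        once = max_blank_ratio_filter(t)
        twice = max_blank_ratio_filter(once)
        pd.testing.assert_frame_equal(once.areas, twice.areas)


class TestMergeEsiModes:
    def _pair(self, rt_neg=4.95, area_scale_neg=0.5):
        neutral = 194.0804  # caffeine-like neutral mass
        pos = make_table([
            {"id": "p1", "mz": neutral + PROTON_MASS, "rt": 5.00,
             "samples": [2e6] * 6},
        ], mode=POSITIVE)
        neg = make_table([
            {"id": "n1", "mz": neutral - PROTON_MASS, "rt": rt_neg,
             "samples": [2e6 * area_scale_neg] * 6},
        ], mode=NEGATIVE)
        return pos, neg

    def test_cross_mode_duplicate_lower_area_discarded(self):
        pos, neg = self._pair()
        merged = merge_esi_modes(pos, neg)
        assert list(merged.meta.index) == ["p1"]

    def test_rt_gate(self):
        pos, neg = self._pair(rt_neg=4.70)  # dRT 0.30 > 0.2
        merged = merge_esi_modes(pos, neg)
        assert set(merged.meta.index) == {"p1", "n1"}

    def test_higher_negative_area_discards_positive(self):
        pos, neg = self._pair(area_scale_neg=2.0)
        merged = merge_esi_modes(pos, neg)
        assert list(merged.meta.index) == ["n1"]

    def test_empty_negative_is_identity(self):
        pos, _ = self._pair()
        neg = make_table([], mode=NEGATIVE)
        merged = merge_esi_modes(pos, neg)
        pd.testing.assert_frame_equal(merged.meta, pos.meta)

    def test_agrees_with_brute_force_oracle(self):
        # exhaustive O(n^2) reimplementation on random 50-feature tables
        rng = np.random.default_rng(12)
        n = 25
        rows_p, rows_n = [], []
        for i in range(n):
            neutral = rng.uniform(100, 400)
            rt = rng.uniform(1, 10)
            rows_p.append({"id": f"p{i:02d}", "mz": neutral + PROTON_MASS, "rt": rt,
                           "samples": rng.uniform(1e5, 1e7, 6).tolist()})
            # half the negative features are twins of a positive feature
            if i % 2 == 0:
                rows_n.append({"id": f"n{i:02d}",
                               "mz": neutral - PROTON_MASS + rng.uniform(-1e-3, 1e-3),
                               "rt": rt + rng.uniform(-0.15, 0.15),
                               "samples": rng.uniform(1e5, 1e7, 6).tolist()})
            else:
                rows_n.append({"id": f"n{i:02d}", "mz": rng.uniform(100, 400),
                               "rt": rng.uniform(1, 10),
                               "samples": rng.uniform(1e5, 1e7, 6).tolist()})
        pos = make_table(rows_p, mode=POSITIVE)
        neg = make_table(rows_n, mode=NEGATIVE)

        drop_p, drop_n = set(), set()
        pavg = pos.average_sample_area()
        navg = neg.average_sample_area()
        for pid in pos.meta.index:
            if pid in drop_p:
                continue
            for nid in neg.meta.index:
                if nid in drop_n:
                    continue
                d_m = abs((pos.meta.loc[pid, "mz"] - PROTON_MASS)
                          - (neg.meta.loc[nid, "mz"] + PROTON_MASS))
                d_rt = abs(pos.meta.loc[pid, "rt"] - neg.meta.loc[nid, "rt"])
                if d_m <= 0.002 and d_rt <= 0.2:
                    if pavg.loc[pid] >= navg.loc[nid]:
                        drop_n.add(nid)
                    else:
                        drop_p.add(pid)
                        break
        expected = (set(pos.meta.index) - drop_p) | (set(neg.meta.index) - drop_n)
        merged = merge_esi_modes(pos, neg)
        assert set(merged.meta.index) == expected


class TestIsPcaNormalization:
    def _drifted(self, factor=2.0, n_samples=8, n_is=5, n_features=10, seed=3):
        rng = np.random.default_rng(seed)
        sample_cols = [f"s{i}" for i in range(n_samples)]
        half = n_samples // 2
        drift = np.array([factor] * half + [1.0] * (n_samples - half))
        is_matrix = pd.DataFrame(
            np.exp(rng.normal(13, 0.01, (n_is, n_samples))) * drift,
            index=[f"IS{i}" for i in range(n_is)], columns=sample_cols,
        )
        rows = [{"id": f"f{i}",
                 "samples": (np.exp(rng.normal(13, 0.01, n_samples)) * drift).tolist()}
                for i in range(n_features)]
        return make_table(rows, n_samples=n_samples), is_matrix, half

    def test_identical_is_areas_identity(self):
        t, _, _ = self._drifted(factor=1.0)
        is_matrix = pd.DataFrame(1e6, index=["IS0", "IS1"], columns=t.sample_cols)
        out, _ = normalize_by_is_pca(t, is_matrix)
        pd.testing.assert_frame_equal(out.areas, t.areas)

    def test_planted_batch_drift_removed(self):
        t, is_matrix, half = self._drifted(factor=2.0)
        log_areas = np.log(t.areas[t.sample_cols])
        gap_before = abs(
            log_areas.iloc[:, :half].mean().mean() - log_areas.iloc[:, half:].mean().mean()
        )
        out, _ = normalize_by_is_pca(t, is_matrix, n_components=2)
        log_after = np.log(out.areas[out.sample_cols])
        gap_after = abs(
            log_after.iloc[:, :half].mean().mean() - log_after.iloc[:, half:].mean().mean()
        )
        assert gap_after < 0.05 * gap_before

    def test_zero_components_identity(self):
        t, is_matrix, _ = self._drifted()
        out, _ = normalize_by_is_pca(t, is_matrix, n_components=0)
        pd.testing.assert_frame_equal(out.areas, t.areas)

    def test_sample_without_is_signal_rejected(self):
        t, is_matrix, _ = self._drifted()
        is_matrix.iloc[:, 0] = 0.0
        with pytest.raises(ValueError, match="s0"):
            normalize_by_is_pca(t, is_matrix)

    def test_geometric_mean_preserved(self):
        t, is_matrix, _ = self._drifted()
        correction = is_pca_correction(is_matrix, 2)
        assert correction.mean() == pytest.approx(0.0, abs=1e-12)

    def test_median_method_also_removes_drift(self):
        t, is_matrix, half = self._drifted(factor=2.0)
        out, _ = normalize_by_is_pca(t, is_matrix, method="median")
        log_after = np.log(out.areas[out.sample_cols])
        gap = abs(log_after.iloc[:, :half].mean().mean()
                  - log_after.iloc[:, half:].mean().mean())
        assert gap < 0.05 * np.log(2.0)


class TestBlankSubtractFloor:
    def test_stated_rules(self):
        t = make_table([
            {"id": "pass", "samples": [1e6] * 6, "blanks": [1e5, 1e5]},
            {"id": "zero_blank", "samples": [1e6] * 6, "blanks": [0, 0]},
            {"id": "floored", "samples": [1.8e5] * 6, "blanks": [2e4, 2e4]},
        ])
        out = blank_subtract_floor(t)
        assert (out.areas.loc["pass", out.sample_cols] == 9e5).all()
        assert (out.areas.loc["zero_blank", out.sample_cols] == 1e6).all()
        # 1.8e5 passes the 5x gate (ratio 9) but 1.8e5 - 2e4 = 1.6e5 > 90k stays;
        # make a literal below-floor case too
        t2 = make_table([{"id": "f", "samples": [1.0e5] * 6, "blanks": [2e4, 2e4]}])
        out2 = blank_subtract_floor(t2)
        # 1.0e5 - 2e4 = 8e4 < 90,000 -> zeroed
        assert (out2.areas.loc["f", out2.sample_cols] == 0).all()

    def test_gate_below_factor_zeroed(self):
        t = make_table([{"id": "a", "samples": [4e5] * 6, "blanks": [1e5, 1e5]}])
        out = blank_subtract_floor(t)
        assert (out.areas.loc["a", out.sample_cols] == 0).all()

    def test_idempotent(self):
        t = make_table([
            {"id": "a", "samples": [1e6, 4e5, 0, 2e6, 9.5e4, 1e5], "blanks": [1e4, 3e4]},
        ])
        once = blank_subtract_floor(t)
        twice = blank_subtract_floor(once)
        pd.testing.assert_frame_equal(once.areas, twice.areas)


class TestDedupCorrelated:
    def test_perfect_correlation_lower_avg_discarded(self):
        base = [1e6, 2e6, 3e6, 4e6, 5e6, 6e6]
        t = make_table([
            {"id": "hi", "rt": 5.0, "samples": base},
            {"id": "lo", "rt": 5.05, "samples": [v * 0.5 for v in base]},
        ])
        out = dedup_correlated(t)
        assert list(out.meta.index) == ["hi"]

    def test_rt_gate_keeps_both(self):
        base = [1e6, 2e6, 3e6, 4e6, 5e6, 6e6]
        t = make_table([
            {"id": "hi", "rt": 5.0, "samples": base},
            {"id": "lo", "rt": 5.15, "samples": [v * 0.5 for v in base]},
        ])
        out = dedup_correlated(t)
        assert set(out.meta.index) == {"hi", "lo"}

    def test_three_mutually_correlated_one_survivor(self):
        base = np.array([1e6, 2e6, 3e6, 4e6, 5e6, 6e6])
        t = make_table([
            {"id": "a", "rt": 5.0, "samples": (base * 1.2).tolist()},
            {"id": "b", "rt": 5.02, "samples": base.tolist()},
            {"id": "c", "rt": 5.04, "samples": (base * 0.8).tolist()},
        ])
        out = dedup_correlated(t)
        assert list(out.meta.index) == ["a"]

    def test_too_few_shared_samples_skipped(self):
        t = make_table([
            {"id": "a", "rt": 5.0, "samples": [1e6, 2e6, 0, 0, 0, 0]},
            {"id": "b", "rt": 5.0, "samples": [1e6, 2e6, 0, 0, 0, 0]},
        ])
        out = dedup_correlated(t)  # only 2 co-detected samples: pair skipped
        assert set(out.meta.index) == {"a", "b"}

    def test_agrees_with_brute_force_oracle(self):
        # independent all-pairs oracle with the same descending-area rule
        rng = np.random.default_rng(21)
        rows = []
        for i in range(20):
            if i < 8 and i % 2 == 1:  # make correlated twins of the previous
                prev = np.array(rows[-1]["samples"])
                samples = (prev * rng.uniform(0.3, 0.9)).tolist()
                rt = rows[-1]["rt"] + rng.uniform(-0.08, 0.08)
            else:
                samples = rng.uniform(1e5, 5e6, 12).tolist()
                rt = rng.uniform(1, 10)
            rows.append({"id": f"f{i:02d}", "rt": rt, "samples": samples})
        t = make_table(rows, n_samples=12)

        avg = t.average_sample_area()
        order = sorted(t.meta.index, key=lambda f: (-avg.loc[f], f))
        removed = set()
        for fi, fj in itertools.combinations(order, 2):
            if fi in removed or fj in removed:
                continue
            if abs(t.meta.loc[fi, "rt"] - t.meta.loc[fj, "rt"]) > 0.1:
                continue
            x = t.areas.loc[fi, t.sample_cols].to_numpy(float)
            y = t.areas.loc[fj, t.sample_cols].to_numpy(float)
            mask = (x > 0) & (y > 0)
            if mask.sum() < 3:
                continue
            r, p = stats.pearsonr(x[mask], y[mask])
            if r > 0.95 and p < 0.001:
                removed.add(fj)
        expected = [f for f in t.meta.index if f not in removed]
        out = dedup_correlated(t)
        assert list(out.meta.index) == expected


class TestDetectionFrequencyFilter:
    def _table_with_detections(self, k, n=161):
        samples = [1e6] * k + [0.0] * (n - k)
        return make_table([{"id": "a", "samples": samples}], n_samples=n)

    def test_boundary_arithmetic(self):
        assert detection_frequency_filter(self._table_with_detections(113)).n_features == 1
        assert detection_frequency_filter(self._table_with_detections(112)).n_features == 0

    def test_all_zero_removed(self):
        out = detection_frequency_filter(self._table_with_detections(0))
        assert out.n_features == 0

    def test_df_stored_for_survivors(self):
        out = detection_frequency_filter(self._table_with_detections(161))
        assert out.df.loc["a"] == pytest.approx(1.0)


class TestPipelineProperties:
    def test_counts_non_increasing_and_provenance_complete(self, cohort):
        from exposomekit.synthetic_data import generate_untargeted_tables

        pos, neg, is_matrix = generate_untargeted_tables(
            cohort, {"pos": 40, "neg": 30}, seed=17
        )
        cleaned, counts = clean_feature_tables(pos, neg, is_matrix)
        stages = list(counts.values())
        assert all(a >= b for a, b in zip(stages, stages[1:]))
        removals = [p for p in cleaned.provenance if p["feature_id"] is not None]
        assert len(removals) == counts["input"] - counts["detection_frequency"]

    def test_write_read_round_trip(self, tmp_path):
        t = make_table([
            {"id": "a", "samples": [1e6, 2e6, 0, 4e6, 5e6, 6e6]},
            {"id": "b", "rt": 7.7, "mz": 321.0123},
        ])
        path = tmp_path / "table.tsv"
        t.write(path)
        back = read_feature_table(path)
        assert back.sample_cols == t.sample_cols
        assert back.blank_cols == t.blank_cols
        assert back.qc_cols == t.qc_cols
        pd.testing.assert_frame_equal(back.areas, t.areas)
        pd.testing.assert_frame_equal(back.meta, t.meta)
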