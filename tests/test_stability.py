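"""Stability distances and their Gaussian-GEE group contrasts."""

import numpy as np
import pandas as pd
import pytest

from cstlong import (CountTable, cst4_centroid_distance, instability_distances,
                     js_distance, stability_contrast, subject_mean_state)
from cstlong.stability import stability_table


def build_table(counts_by_subject, groups):
    """counts_by_subject: dict subject -> list of count rows."""
    rows, ids, meta = [], [], []
    for subject, samples in counts_by_subject.items():
        for v, counts in enumerate(samples):
            sid = f"{subject}_v{v}"
            ids.append(sid)
            rows.append(counts)
            meta.append((sid, subject, groups[subject], float(v)))
    counts = pd.DataFrame(np.asarray(rows), index=ids,
                          columns=[f"t{j}" for j in range(len(rows[0]))])
    md = pd.DataFrame(meta, columns=["sample_id", "subject_id", "group", "week"]
                      ).set_index("sample_id")
    return CountTable(counts, md)


class TestSubjectMean:
    def test_single_state_is_itself(self):
        s = np.array([0.2, 0.8])
        assert np.allclose(subject_mean_state(s), s)

    def test_two_disjoint_states_average(self):
        out = subject_mean_state(np.array([[1.0, 0.0], [0.0, 1.0]]))
        assert np.allclose(out, [0.5, 0.5])

    def test_random_set_sums_to_one(self, rng):
        states = rng.dirichlet([1] * 5, size=8)
        assert subject_mean_state(states).sum() == pytest.approx(1.0)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            subject_mean_state(np.empty((0, 3)))


class TestInstabilityDistances:
    def test_identical_samples_zero_distance(self):
        table = build_table({"a": [[10, 10], [20, 20], [5, 5]]},
                            {"a": "pregnant"})
        out = instability_distances(table)
        assert np.allclose(out["d_subject_mean"], 0.0)

    def test_alternating_disjoint_closed_form(self):
        table = build_table({"a": [[100, 0], [0, 100], [100, 0], [0, 100]]},
                            {"a": "non_pregnant"})
        out = instability_distances(table)
        expected = js_distance([1.0, 0.0], [0.5, 0.5], 2)  # = 0.5579...
        assert np.allclose(out["d_subject_mean"], expected, atol=1e-9)
        assert expected == pytest.approx(0.5579, abs=5e-5)

    def test_matches_brute_force(self, rng):
        counts = {s: rng.integers(1, 100, size=(4, 5)).tolist()
                  for s in ("a", "b")}
        table = build_table(counts, {"a": "pregnant", "b": "non_pregnant"})
        out = instability_distances(table)
        for subject in ("a", "b"):
            arr = np.asarray(counts[subject], dtype=float)
            states = arr / arr.sum(axis=1, keepdims=True)
            mean = states.mean(axis=0)
            mean = mean / mean.sum()
            for v in range(4):
                got = out.loc[f"{subject}_v{v}", "d_subject_mean"]
                assert got == pytest.approx(js_distance(states[v], mean), abs=1e-9)

    def test_permuting_samples_leaves_distance_multiset(self, rng):
        samples = rng.integers(1, 50, size=(5, 4)).tolist()
        t1 = build_table({"a": samples}, {"a": "pregnant"})
        t2 = build_table({"a": samples[::-1]}, {"a": "pregnant"})
        d1 = sorted(instability_distances(t1)["d_subject_mean"])
        d2 = sorted(instability_distances(t2)["d_subject_mean"])
        assert np.allclose(d1, d2)

    def test_single_sample_subject_flagged(self):
        table = build_table({"a": [[5, 5]], "b": [[1, 2], [3, 4]]},
                            {"a": "pregnant", "b": "pregnant"})
        out = instability_distances(table)
        assert out.loc["a_v0", "single_sample"]
        assert out.loc["a_v0", "d_subject_mean"] == 0.0

    def test_adding_mean_copy_decreases_mean_distance(self, rng):
        samples = rng.integers(1, 60, size=(4, 3)).astype(float)
        states = samples / samples.sum(axis=1, keepdims=True)
        mean = states.mean(axis=0)
        base = build_table({"a": samples.astype(int).tolist()}, {"a": "pregnant"})
        d_base = instability_distances(base)["d_subject_mean"].mean()
        scaled = np.round(mean * 100000).astype(int)
        augmented = build_table({"a": samples.astype(int).tolist() + [scaled.tolist()]},
                                {"a": "pregnant"})
        d_aug = instability_distances(augmented)["d_subject_mean"].mean()
        assert d_aug <= d_base + 1e-6


class TestCst4Distance:
    def test_sample_equal_to_centroid_is_zero(self):
        table = build_table({"a": [[10, 30, 60], [10, 30, 60]]}, {"a": "pregnant"})
        labels = pd.Series(["IV-B", "IV-B"], index=table.sample_ids)
        out = cst4_centroid_distance(table, labels)
        assert np.allclose(out["d_cst4"], 0.0, atol=1e-9)

    def test_matches_brute_force_pooled_centroid(self, rng):
        counts = {"a": rng.integers(1, 50, size=(3, 4)).tolist(),
                  "b": rng.integers(1, 50, size=(3, 4)).tolist()}
        table = build_table(counts, {"a": "pregnant", "b": "non_pregnant"})
        labels = pd.Series(["IV-A", "I", "IV-B", "III", "IV-B", "I"],
                           index=table.sample_ids)
        out = cst4_centroid_distance(table, labels)
        arr = table.counts.to_numpy(dtype=float)
        states = arr / arr.sum(axis=1, keepdims=True)
        iv = states[np.asarray(labels.isin(["IV-A", "IV-B"]))]
        centroid = iv.mean(axis=0)
        centroid /= centroid.sum()
        for i, sid in enumerate(table.sample_ids):
            assert out.loc[sid, "d_cst4"] == pytest.approx(
                js_distance(states[i], centroid), abs=1e-9)

    def test_lactobacillus_state_far_from_anaerobe_centroid(self):
        # one pure-Lactobacillus sample vs an even anaerobe-heavy IV centroid
        table = build_table({"a": [[1000, 0, 0, 0], [0, 300, 350, 350]]},
                            {"a": "non_pregnant"})
        labels = pd.Series(["I", "IV-A"], index=table.sample_ids)
        out = cst4_centroid_distance(table, labels)
        assert out.loc["a_v0", "d_cst4"] > 0.5

    def test_no_iv_samples_raises(self):
        table = build_table({"a": [[1, 2], [3, 4]]}, {"a": "pregnant"})
        labels = pd.Series(["I", "III"], index=table.sample_ids)
        with pytest.raises(ValueError, match="reference centroid"):
            cst4_centroid_distance(table, labels)


class TestContrast:
    def simulated_stab(self, rng, delta, n_subjects=50, n_visits=8, sd=0.3):
        """Log-distances with subject random effects and a group mean shift."""
        rows = []
        for g, group in enumerate(["non_pregnant", "pregnant"]):
            for s in range(n_subjects):
                subj = f"{group[:2]}{s}"
                b = rng.normal(0, 0.2)
                for v in range(n_visits):
                    y = -1.0 + delta * g + b + rng.normal(0, sd)
                    rows.append((f"{subj}_v{v}", subj, group, y))
        return pd.DataFrame(rows, columns=["sample_id", "subject_id", "group",
                                           "log_d_subject_mean"]).set_index("sample_id")

    def test_recovers_planted_log_difference(self, rng):
        stab = self.simulated_stab(rng, delta=-0.473)
        res = stability_contrast(stab, "log_d_subject_mean")
        assert res.coefficient == pytest.approx(-0.473, abs=0.05)
        assert res.p_value < 0.001

    def test_null_difference_near_zero(self, rng):
        stab = self.simulated_stab(rng, delta=0.0)
        res = stability_contrast(stab, "log_d_subject_mean")
        assert abs(res.coefficient) < 0.1
        assert res.p_value > 0.01

    def test_fold_conversion_matches_log_difference(self, rng):
        stab = self.simulated_stab(rng, delta=-0.473, sd=0.05)
        res = stability_contrast(stab, "log_d_subject_mean")
        assert res.fold == pytest.approx(np.exp(abs(res.coefficient)))
        assert res.fold == pytest.approx(1.6, abs=0.15)

    def test_degenerate_response_raises(self):
        stab = pd.DataFrame({"subject_id": ["a", "b"], "group":
                             ["pregnant", "non_pregnant"],
                             "log_d_subject_mean": [1.0, 1.0]})
        with pytest.raises(ValueError, match="degenerate"):
            stability_contrast(stab, "log_d_subject_mean")

    def test_group_sign_recovery_on_cohort(self, small_table):
        # pregnant chains persist more, so their within-subject distances are lower
        states_labels = small_table.metadata["true_cst"]
        stab = stability_table(small_table, states_labels)
        res = stability_contrast(stab, "log_d_subject_mean")
        assert res.coefficient < 0
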