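"""Delta statistic and permutation monotonicity Z-score."""

import itertools

import numpy as np
import pandas as pd
import pytest

from spliceclip.monotonicity import (
    MissingPairsError, call_monotonic, delta_statistic, monotonicity_table,
    monotonicity_z,
)
from spliceclip.psi import pairwise_comparisons, psi_table


def comp_df(rows):
    return pd.DataFrame(rows, columns=["sample_a", "sample_b", "delta_psi",
                                       "bayes_factor"])


def oracle_delta(comparisons, time_order, bf_threshold=5.0):
    """Independent double-loop tally of significant oriented changes."""
    lookup = {}
    for r in comparisons.itertuples(index=False):
        lookup[(r.sample_a, r.sample_b)] = (r.delta_psi, r.bayes_factor)
        lookup[(r.sample_b, r.sample_a)] = (-r.delta_psi, r.bayes_factor)
    delta = 0
    samples = sorted(time_order)
    for a, b in itertools.combinations(samples, 2):
        if time_order[a] == time_order[b]:
            continue
        early, late = (a, b) if time_order[a] < time_order[b] else (b, a)
        dpsi, bf = lookup[(early, late)]
        if bf > bf_threshold:
            if dpsi > 0:
                delta += 1
            elif dpsi < 0:
                delta -= 1
    return delta


class TestDelta:
    def test_all_positive_pairs(self):
        comp = comp_df([("s1", "s2", 0.2, 10), ("s1", "s3", 0.4, 10),
                        ("s2", "s3", 0.2, 10)])
        order = {"s1": 0, "s2": 1, "s3": 2}
        assert delta_statistic(comp, order) == 3

    def test_no_significant_pairs(self):
        comp = comp_df([("s1", "s2", 0.2, 1), ("s1", "s3", 0.4, 2),
                        ("s2", "s3", 0.2, 0.5)])
        assert delta_statistic(comp, {"s1": 0, "s2": 1, "s3": 2}) == 0

    def test_zero_delta_psi_counts_in_neither_tally(self):
        comp = comp_df([("s1", "s2", 0.0, 10)])
        assert delta_statistic(comp, {"s1": 0, "s2": 1}) == 0

    def test_missing_pairs_listed(self):
        comp = comp_df([("s1", "s2", 0.2, 10)])
        with pytest.raises(MissingPairsError) as exc:
            delta_statistic(comp, {"s1": 0, "s2": 1, "s3": 2})
        assert ("s1", "s3") in exc.value.pairs and ("s2", "s3") in exc.value.pairs

    def test_staircase_matches_double_loop_oracle(self):
        """Planted increasing PSI staircase, 5 time points x 3 replicates."""
        rng = np.random.default_rng(11)
        depth = 500
        rows = []
        order = {}
        for t, psi in enumerate(np.linspace(0.2, 0.8, 5)):
            for r in range(3):
                sid = f"t{t}_r{r}"
                order[sid] = t
                inc = rng.binomial(depth, psi)
                rows.append(("ev", sid, inc, depth - inc))
        counts = pd.DataFrame(rows, columns=["event_id", "sample_id",
                                             "inclusion", "exclusion"])
        table, _ = psi_table(counts)
        comp = pairwise_comparisons(table)
        assert delta_statistic(comp, order) == oracle_delta(comp, order)

    def test_reversing_time_negates_delta(self):
        comp = comp_df([("s1", "s2", 0.2, 10), ("s1", "s3", -0.3, 10),
                        ("s2", "s3", -0.5, 10)])
        order = {"s1": 0, "s2": 1, "s3": 2}
        rev = {s: -t for s, t in order.items()}
        assert delta_statistic(comp, rev) == -delta_statistic(comp, order)

    def test_bf_scale_invariance_above_threshold(self):
        """Scaling all BFs on the same side of the threshold leaves delta fixed."""
        rows = [("s1", "s2", 0.2, 10), ("s1", "s3", 0.4, 50), ("s2", "s3", -0.2, 2)]
        order = {"s1": 0, "s2": 1, "s3": 2}
        base = delta_statistic(comp_df(rows), order)
        scaled = [(a, b, d, bf * 7 if bf > 5 else bf * 0.5) for a, b, d, bf in rows]
        assert delta_statistic(comp_df(scaled), order) == base


def oracle_exhaustive_mz(comparisons, time_order, bf_threshold=5.0):
    """Brute-force enumeration over all labelings of the time multiset."""
    samples = sorted(time_order)
    labels = [time_order[s] for s in samples]
    deltas = []
    for perm in set(itertools.permutations(labels)):
        order = dict(zip(samples, perm))
        deltas.append(oracle_delta(comparisons, order, bf_threshold))
    # weight by multiplicity of each distinct labelling
    weighted = []
    for perm in itertools.permutations(labels):
        order = dict(zip(samples, perm))
        weighted.append(oracle_delta(comparisons, order, bf_threshold))
    arr = np.array(weighted, dtype=float)
    observed = oracle_delta(comparisons, time_order, bf_threshold)
    sd = arr.std(ddof=0)
    if sd == 0:
        return 0.0
    return (observed - arr.mean()) / sd


class TestMonotonicityZ:
    def test_degenerate_null_flagged(self):
        comp = comp_df([("s1", "s2", 0.1, 1), ("s1", "s3", 0.1, 1),
                        ("s2", "s3", 0.1, 1)])
        res = monotonicity_z("ev", comp, {"s1": 0, "s2": 1, "s3": 2})
        assert res.mz == 0.0 and res.flag == "degenerate_null"

    def test_exhaustive_matches_enumeration_oracle(self):
        comp = comp_df([("s1", "s2", 0.3, 10), ("s1", "s3", 0.5, 20),
                        ("s2", "s3", 0.2, 8)])
        order = {"s1": 0, "s2": 1, "s3": 2}
        res = monotonicity_z("ev", comp, order, method="exhaustive")
        assert res.mz == pytest.approx(oracle_exhaustive_mz(comp, order))

    def test_sampled_close_to_exhaustive(self):
        rng = np.random.default_rng(4)
        samples = [f"s{i}" for i in range(6)]
        order = {s: i // 2 for i, s in enumerate(samples)}  # 3 time points x 2
        rows = []
        for i, a in enumerate(samples):
            for b in samples[i + 1:]:
                rows.append((a, b, float(rng.normal()), float(rng.uniform(0, 20))))
        comp = comp_df(rows)
        exact = monotonicity_z("ev", comp, order, method="exhaustive")
        approx = monotonicity_z("ev", comp, order, n_perm=1000, seed=9)
        assert abs(exact.mz - approx.mz) < 0.3

    def test_planted_monotone_event_called(self):
        """A strong planted trend exceeds the 1.8 calling threshold."""
        rng = np.random.default_rng(21)
        depth = 500
        rows, order = [], {}
        for t, psi in enumerate(np.linspace(0.25, 0.65, 5)):
            for r in range(3):
                sid = f"t{t}_r{r}"
                order[sid] = t
                inc = rng.binomial(depth, psi)
                rows.append(("ev", sid, inc, depth - inc))
        counts = pd.DataFrame(rows, columns=["event_id", "sample_id",
                                             "inclusion", "exclusion"])
        table, _ = psi_table(counts)
        comp = pairwise_comparisons(table)
        res = monotonicity_z("ev", comp.drop(columns="event_id"), order, seed=0)
        assert res.mz > 1.8

    def test_within_replicate_permutation_mode(self):
        comp = comp_df([("s1", "s2", 0.3, 10), ("s1", "s3", 0.5, 20),
                        ("s2", "s3", 0.2, 8)])
        order = {"s1": 0, "s2": 1, "s3": 2}
        # singleton replicate lines: nothing can move, so the null is frozen
        frozen = monotonicity_z("ev", comp, order, seed=1,
                                replicate_of={"s1": "a", "s2": "b", "s3": "c"})
        assert frozen.flag == "degenerate_null"
        # one replicate line spanning all time points behaves like joint
        joint = monotonicity_z("ev", comp, order, seed=1, n_perm=500,
                               replicate_of={"s1": "a", "s2": "a", "s3": "a"})
        ref = monotonicity_z("ev", comp, order, seed=1, n_perm=500)
        assert abs(joint.mz - ref.mz) < 0.5

    def test_deterministic_under_seed(self):
        comp = comp_df([("s1", "s2", 0.3, 10), ("s1", "s3", 0.5, 20),
                        ("s2", "s3", 0.2, 8)])
        order = {"s1": 0, "s2": 1, "s3": 2}
        a = monotonicity_z("ev", comp, order, seed=5)
        b = monotonicity_z("ev", comp, order, seed=5)
        assert a == b


class TestCallMonotonic:
    def _results(self, mzs, classes=None):
        df = pd.DataFrame({"event_id": [f"e{i}" for i in range(len(mzs))],
                           "mz": mzs})
        return df, classes

    def test_strict_threshold(self):
        df, _ = self._results([1.79, 1.8, 1.81])
        called = call_monotonic(df, 1.8)
        assert list(called["event_id"]) == ["e2"]

    def test_negative_mz_called_down(self):
        df, _ = self._results([-2.5])
        called = call_monotonic(df, 1.8)
        assert called.iloc[0]["direction"] == "down"

    def test_per_class_thresholds(self):
        df = pd.DataFrame({"event_id": ["a", "b"], "mz": [1.7, 1.7]})
        classes = {"a": "SE", "b": "TandemUTR"}
        called = call_monotonic(df, event_classes=classes)
        assert list(called["event_id"]) == ["b"]  # 1.7 > 1.6 but not > 1.8


def test_table_reproducible_and_order_free(counts_small):
    splice, _genes, order = counts_small
    table, _ = psi_table(splice)
    comp = pairwise_comparisons(table)
    a = monotonicity_table(comp, order, n_perm=30, seed=7)
    b = monotonicity_table(comp, order, n_perm=30, seed=7)
    pd.testing.assert_frame_equal(a, b)
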