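import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import comb

from consig import consensus_signature as cs
from consig.io_model import DEGCollection, DEGRecord, GeneSet, ValidationError
from consig.synthetic_data import DEGGenConfig, gen_deg_collection


def pairwise_gmcs_oracle(k: int, d: int) -> float:
    """Brute-force GMCS: enumerate all unordered dataset pairs explicitly."""
    detected = [i < k for i in range(d)]
    both = either = 0
    for i, j in itertools.combinations(range(d), 2):
        if detected[i] or detected[j]:
            either += 1
            if detected[i] and detected[j]:
                both += 1
    return both / either if either else 0.0


class TestGMCS:
    @pytest.mark.parametrize("d", range(2, 11))
    def test_closed_form_equals_pair_enumeration(self, d):
        for k in range(1, d + 1):
            assert cs.gmcs_closed_form(k, d) == pytest.approx(
                pairwise_gmcs_oracle(k, d), abs=1e-12
            )

    @pytest.mark.parametrize(
        "k,d,expected",
        [(5, 5, 1.0), (1, 26, 0.0), (2, 3, 1 / 3), (6, 26, 5 / 45)],
    )
    def test_reference_values(self, k, d, expected):
        assert cs.gmcs_closed_form(k, d) == pytest.approx(expected, abs=1e-12)

    @settings(derandomize=True, max_examples=200)
    @given(d=st.integers(2, 60), data=st.data())
    def test_bounds_and_monotonicity_property(self, d, data):
        """0 <= GMCS < GMCS' <= 1 whenever k < k' for any cohort count."""
        k = data.draw(st.integers(1, d - 1))
        lo, hi = cs.gmcs_closed_form(k, d), cs.gmcs_closed_form(k + 1, d)
        assert 0.0 <= lo < hi <= 1.0

    def test_strictly_increasing_in_occurrence(self):
        for d in range(2, 11):
            vals = [cs.gmcs_closed_form(k, d) for k in range(1, d + 1)]
            assert all(b > a for a, b in zip(vals, vals[1:]))
            assert all(0.0 <= v <= 1.0 for v in vals)

    def test_montecarlo_converges_to_exact(self):
        exact = cs.gmcs_closed_form(6, 26)
        approx = cs.gmcs_montecarlo(6, 26, n_subsets=40_000, seed=0)
        assert approx == pytest.approx(exact, abs=0.01)

    def test_single_dataset_rejected(self, tiny_collection):
        profile = cs.count_occurrence(
            DEGCollection(datasets=tiny_collection.datasets[:1])
        )
        with pytest.raises(ValidationError):
            cs.compute_gmcs(profile)


class TestOccurrence:
    def test_counts_on_hand_collection(self, tiny_collection):
        profile = cs.count_occurrence(tiny_collection)
        assert profile.occurrence == {"JUN": 3, "MPO": 2, "FOS": 2, "IL1B": 1, "THBS1": 1}
        assert profile.supporting["MPO"] == frozenset({"AML1", "AML2"})

    def test_union_matches_set_oracle_on_synthetic(self):
        coll = gen_deg_collection(DEGGenConfig(seed=1))
        profile = cs.count_occurrence(coll)
        oracle_union = set()
        for _, recs in coll.datasets:
            oracle_union |= {r.gene for r in recs}
        assert set(profile.occurrence) == oracle_union

    def test_empty_collection_rejected(self):
        with pytest.raises(ValidationError):
            cs.count_occurrence(DEGCollection(datasets=[]))


class TestEffectCV:
    def test_constant_effect_zero_cv(self):
        coll = DEGCollection(datasets=[
            (f"D{i}", [DEGRecord("A", 2.0 * s, 0.01)])
            for i, s in enumerate((1, -1, 1))
        ])
        assert cs.compute_effect_cv(coll, "A") == pytest.approx(0.0)

    def test_hand_value(self):
        coll = DEGCollection(datasets=[
            ("D0", [DEGRecord("A", 1.0, 0.01)]),
            ("D1", [DEGRecord("A", -2.0, 0.01)]),
            ("D2", [DEGRecord("A", 3.0, 0.01)]),
        ])
        # |logfc| = {1,2,3}: sd(ddof=1)=1, mean=2
        assert cs.compute_effect_cv(coll, "A") == pytest.approx(0.5)

    def test_singleton_undefined(self, tiny_collection):
        assert cs.compute_effect_cv(tiny_collection, "IL1B") is None

    def test_absent_gene_rejected(self, tiny_collection):
        with pytest.raises(ValidationError):
            cs.compute_effect_cv(tiny_collection, "NOPE")


class TestThresholdScanAndSelection:
    def test_scan_size_monotone_and_full_at_one(self, tiny_collection):
        scan = cs.threshold_scan(tiny_collection)
        assert scan.loc[1, "size"] == 5
        sizes = scan["size"].to_numpy()
        assert (np.diff(sizes) <= 0).all()

    def test_mean_gmcs_rises_with_threshold_on_synthetic(self):
        coll = gen_deg_collection(DEGGenConfig(seed=1))
        scan = cs.threshold_scan(coll)
        assert scan.loc[6, "mean_gmcs"] > scan.loc[1, "mean_gmcs"]

    def test_selection_respects_threshold(self):
        coll = DEGCollection(datasets=[
            (f"D{i}", [DEGRecord(g, 1.0, 0.01) for g, kmax in
                       (("gA", 7), ("gB", 6), ("gC", 5)) if i < kmax])
            for i in range(7)
        ])
        sig = cs.select_signature(coll, 6)
        assert sig.genes.genes == frozenset({"gA", "gB"})

    def test_threshold_one_returns_universe(self, tiny_collection):
        sig = cs.select_signature(tiny_collection, 1)
        assert sig.genes.genes == tiny_collection.all_genes()

    def test_out_of_range_threshold_rejected(self, tiny_collection):
        with pytest.raises(ValidationError):
            cs.select_signature(tiny_collection, 4)

    def test_matches_brute_force_filter_on_synthetic(self):
        coll = gen_deg_collection(DEGGenConfig(seed=1))
        sig = cs.select_signature(coll, 6)
        counts = {}
        for _, recs in coll.datasets:
            for r in recs:
                counts[r.gene] = counts.get(r.gene, 0) + 1
        oracle = {g for g, k in counts.items() if k >= 6}
        assert sig.genes.genes == oracle

    def test_deterministic_ordering(self, tiny_collection):
        sig = cs.select_signature(tiny_collection, 1)
        order = [s.gene for s in sig.stats]
        ranks = [(-s.occurrence, s.gene) for s in sig.stats]
        assert ranks == sorted(ranks)
        assert order[0] == "JUN"


class TestDatasetScores:
    sig = GeneSet("sig", frozenset({"a", "b", "c", "d", "e"}))

    def test_rs_disjoint_and_superset(self):
        assert cs.score_dataset_rs({"x", "y"}, self.sig) == 0
        assert cs.score_dataset_rs({"a", "b", "c", "d", "e", "x"}, self.sig) == 5

    def test_rs_intersection_oracle(self):
        rng = np.random.default_rng(0)
        universe = [f"u{i}" for i in range(1000)]
        sig = GeneSet("s", frozenset(rng.choice(universe, 200, replace=False)))
        deg = set(rng.choice(universe, 500, replace=False))
        assert cs.score_dataset_rs(deg, sig) == len(deg & sig.genes)

    def test_dgse_identity_and_zero_overlap(self):
        prop, _ = cs.score_dataset_dgse(set(self.sig.genes), self.sig, universe=20)
        assert prop == 1.0
        _, p = cs.score_dataset_dgse({"x", "y"}, self.sig, universe=20)
        assert p == pytest.approx(1.0)

    def test_dgse_exact_hypergeometric_hand_value(self):
        # universe 20, signature 5, deg 4, overlap 3:
        # p = [C(5,3) C(15,1) + C(5,4) C(15,0)] / C(20,4) = 155/4845
        sig = GeneSet("s", frozenset({"a", "b", "c", "d", "e"}))
        deg = {"a", "b", "c", "x"}
        _, p = cs.score_dataset_dgse(deg, sig, universe=20)
        expected = (comb(5, 3) * comb(15, 1) + comb(5, 4)) / comb(20, 4)
        assert expected == pytest.approx(155 / 4845)
        assert p == pytest.approx(expected, rel=1e-10)

    def test_universe_too_small_rejected(self):
        with pytest.raises(ValidationError):
            cs.score_dataset_dgse({"a", "x"}, self.sig, universe=5)

    def test_empty_deg_rejected(self):
        with pytest.raises(ValidationError):
            cs.score_dataset_dgse(set(), self.sig, universe=20)

    @settings(derandomize=True, max_examples=100)
    @given(deg=st.sets(st.sampled_from(list("abcdefghijkl")), min_size=1),
           universe=st.integers(40, 200))
    def test_dgse_properties_hold_for_arbitrary_deg_sets(self, deg, universe):
        """Proportion in [0,1], p in (0,1], and rs bounded by both set sizes."""
        rs = cs.score_dataset_rs(deg, self.sig)
        prop, p = cs.score_dataset_dgse(deg, self.sig, universe)
        assert rs <= min(len(deg), len(self.sig))
        assert prop == pytest.approx(rs / len(deg))
        assert 0.0 <= prop <= 1.0 and 0.0 < p <= 1.0

    def test_scores_invariant_to_input_order(self):
        deg_list = ["a", "x", "c", "y"]
        for perm in itertools.permutations(deg_list):
            assert cs.score_dataset_rs(set(perm), self.sig) == 2
            prop, p = cs.score_dataset_dgse(set(perm), self.sig, universe=30)
            assert (prop, p) == cs.score_dataset_dgse(set(deg_list), self.sig, 30)


def test_signature_recovery_on_default_conditions():
    """Planted 200-gene core at detection rate 0.85 is recovered almost
    perfectly by the >=6-of-26 occurrence rule (single-seed check)."""
    coll = gen_deg_collection(DEGGenConfig(seed=1))
    sig = cs.select_signature(coll, 6)
    core = set(f"CORE{i + 1:04d}" for i in range(200))
    hit = sig.genes.genes & core
    assert len(hit) / len(core) >= 0.99
    assert len(hit) / len(sig.genes.genes) >= 0.90
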