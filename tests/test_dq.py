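import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rnaconcord import (DQCriteria, dq_threshold_sweep, find_dq_genes,
                        min_discordant_samples, pair_discordant, set_summary)

from conftest import make_matrix, random_tpm_dataset
from oracles import brute_dq, brute_set_summary
from rnaconcord.matrix import MultiSourceDataset


class TestMinDiscordantSamples:
    @pytest.mark.parametrize("n,frac,expected", [
        (4800, 0.01, 48),
        (1890, 0.01, 19),  # ceiling of 18.9
        (50, 0.01, 1),     # floor of the rule is 1
        (100, 0.01, 1),
        (101, 0.01, 2),
    ])
    def test_ceiling_rule(self, n, frac, expected):
        assert min_discordant_samples(n, frac) == expected

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            min_discordant_samples(0, 0.01)
        with pytest.raises(ValueError):
            min_discordant_samples(10, 0.0)


class TestPairDiscordant:
    @pytest.mark.parametrize("a,b,expected", [
        (33, 7, True),     # both cuts crossed
        (32, 8, False),    # strict boundaries
        (100, 30, False),  # 30 is not < 8 under the default absolute rule
        (100, 7.9, True),
        (31.9, 0.0, False),
    ])
    def test_default_rule(self, a, b, expected):
        assert pair_discordant(a, b) is expected

    def test_methods_mode_differs_on_middle_band(self):
        """(100, 20): 5-fold apart but 20 is not < 8 — the two published
        phrasings of the rule disagree exactly on this band."""
        assert pair_discordant(100, 20) is False
        methods = DQCriteria(mode="methods")
        assert pair_discordant(100, 20, methods) is True
        assert pair_discordant(100, 30, methods) is False  # < 4-fold

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(a=st.floats(0, 200, allow_nan=False), b=st.floats(0, 200, allow_nan=False))
    def test_symmetric(self, a, b):
        crit = DQCriteria()
        assert pair_discordant(a, b, crit) == pair_discordant(b, a, crit)
        if pair_discordant(a, b, crit):
            assert max(a, b) > crit.high_tpm and min(a, b) < crit.low_tpm


class TestFindDQGenes:
    def test_identical_sources_give_no_dq(self, rng):
        vals = rng.uniform(0, 100, size=(10, 20))
        ds = MultiSourceDataset([
            make_matrix(vals, source="A"), make_matrix(vals, source="B")])
        res = find_dq_genes(ds)
        assert res.dq_genes == set()
        assert (res.union_counts == 0).all()

    def test_uniform_disagreement_flags_gene(self):
        n = 100
        a = make_matrix(np.full((1, n), 40.0), source="A")
        b = make_matrix(np.full((1, n), 5.0), source="B")
        res = find_dq_genes(MultiSourceDataset([a, b]))
        assert res.union_counts["g1"] == n
        assert res.dq_genes == {"g1"}
        assert res.per_source_membership == {"A": {"g1"}, "B": {"g1"}}

    def test_rejects_fpkm_units(self, small_fpkm):
        from rnaconcord import ExpressionMatrix, Unit
        other = ExpressionMatrix(data=small_fpkm.data.copy(), unit=Unit.FPKM,
                                 source="B")
        ds = MultiSourceDataset([small_fpkm, other])
        with pytest.raises(ValueError, match="expects TPM"):
            find_dq_genes(ds)

    @pytest.mark.parametrize("mode", ["results", "methods"])
    def test_matches_brute_force_oracle(self, rng, mode):
        crit = DQCriteria(mode=mode)
        for _ in range(25):
            ds = random_tpm_dataset(rng)
            res = find_dq_genes(ds, crit)
            pair_counts, union_counts, involved = brute_dq(
                ds.stack(), ds.source_labels, crit)
            for key, counts in pair_counts.items():
                assert res.pair_counts[key].tolist() == counts
            assert res.union_counts.tolist() == union_counts
            gene_list = list(ds.gene_ids)
            for lab in ds.source_labels:
                expected = {gene_list[g] for g in involved[lab]
                            if res.dq_flags.iloc[g]}
                assert res.per_source_membership[lab] == expected

    def test_union_bounds_pair_counts(self, rng):
        ds = random_tpm_dataset(rng, n_sources=4, n_genes=15, n_samples=25)
        res = find_dq_genes(ds)
        assert (res.union_counts >= res.pair_counts.max(axis=1)).all()
        assert (res.union_counts <= len(ds.sample_ids)).all()

    def test_source_relabeling_preserves_flags(self, rng):
        ds = random_tpm_dataset(rng, n_sources=3, n_genes=12, n_samples=30)
        res = find_dq_genes(ds)
        relabeled = MultiSourceDataset(list(reversed([
            m.with_data(m.data) for m in ds.sources])))
        res2 = find_dq_genes(relabeled)
        assert res.dq_flags.equals(res2.dq_flags)
        assert res.per_source_membership == res2.per_source_membership


class TestThresholdSweep:
    def test_nesting_over_folds(self, rng):
        for _ in range(10):
            ds = random_tpm_dataset(rng)
            sweep = dq_threshold_sweep(ds, [4, 3, 2])
            assert sweep[4.0].dq_genes <= sweep[3.0].dq_genes <= sweep[2.0].dq_genes

    def test_identical_sources_all_empty(self, rng):
        vals = rng.uniform(0, 100, size=(8, 20))
        ds = MultiSourceDataset([
            make_matrix(vals, source="A"), make_matrix(vals, source="B")])
        sweep = dq_threshold_sweep(ds, [4, 3, 2])
        assert all(r.dq_genes == set() for r in sweep.values())

    def test_intermediate_scaling_lands_between_folds(self):
        """A clean 3.5x disagreement is caught at fold 3 and 2 but not 4."""
        n = 100
        a = make_matrix(np.full((1, n), 35.0), source="A")
        b = make_matrix(np.full((1, n), 10.0), source="B")
        sweep = dq_threshold_sweep(MultiSourceDataset([a, b]), [4, 3, 2])
        assert sweep[4.0].dq_genes == set()        # 10 not < 8
        assert sweep[3.0].dq_genes == {"g1"}       # 10 < 32/3
        assert sweep[2.0].dq_genes == {"g1"}

    def test_invalid_fold(self, rng):
        ds = random_tpm_dataset(rng, n_sources=2, n_genes=3, n_samples=4)
        with pytest.raises(ValueError):
            dq_threshold_sweep(ds, [4, 1.0])


class TestSetSummary:
    def test_two_set_enumeration(self):
        out = set_summary({"A": {"g1", "g2"}, "B": {"g2"}})
        assert out["exclusive"][("A",)] == 1
        assert out["exclusive"][("A", "B")] == 1
        assert out["exclusive"][("B",)] == 0
        assert out["totals"] == {"A": 2, "B": 1}
        assert out["union_size"] == 2

    def test_single_set(self):
        out = set_summary({"A": {"x", "y"}})
        assert out["exclusive"][("A",)] == 2

    def test_matches_exhaustive_partition(self, rng):
        universe = [f"g{i}" for i in range(30)]
        for _ in range(25):
            n_sets = rng.integers(2, 5)
            membership = {
                f"S{k}": {g for g in universe if rng.random() < 0.4}
                for k in range(n_sets)
            }
            if not any(membership.values()):
                membership["S0"] = {"g0"}
            assert set_summary(membership)["exclusive"] == \
                brute_set_summary(membership)

    def test_exclusive_counts_partition_the_union(self, rng):
        membership = {"A": {"1", "2", "3"}, "B": {"2", "4"}, "C": {"3", "4", "5"}}
        out = set_summary(membership)
        assert sum(out["exclusive"].values()) == out["union_size"]
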