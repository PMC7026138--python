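import numpy as np
import pytest

from rnaconcord import (DQCriteria, FCCriteria, SyntheticConfig, dataset_to_tpm,
                        find_dq_genes, foldchange_discordance, generate,
                        per_gene_correlation, recovery_report)

SMALL = dict(n_genes=250, n_samples=120, n_scaling=5, n_sample_specific=5,
             n_uncorrelated=5)


class TestGenerate:
    def test_deterministic_given_seed(self):
        ds1, t1 = generate(SyntheticConfig(**SMALL, seed=7))
        ds2, t2 = generate(SyntheticConfig(**SMALL, seed=7))
        for a, b in zip(ds1.sources, ds2.sources):
            assert a.data.equals(b.data)
        assert t1.planted == t2.planted

    def test_seed_changes_output(self):
        ds1, _ = generate(SyntheticConfig(**SMALL, seed=7))
        ds2, _ = generate(SyntheticConfig(**SMALL, seed=8))
        assert not ds1.sources[0].data.equals(ds2.sources[0].data)

    def test_no_planting_no_noise_gives_identical_tpm(self):
        cfg = SyntheticConfig(n_genes=100, n_samples=30, noise_sd=0.0,
                              n_scaling=0, n_sample_specific=0,
                              n_uncorrelated=0, seed=3)
        ds, truth = generate(cfg)
        assert truth.planted == []
        # library skew makes FPKM differ between sources ...
        assert not np.allclose(ds.sources[0].values, ds.sources[1].values)
        # ... but TPM conversion removes it entirely
        tpm = dataset_to_tpm(ds)
        for m in tpm.sources[1:]:
            np.testing.assert_allclose(m.values, tpm.sources[0].values,
                                       rtol=1e-9)

    def test_planted_counts_and_disjoint_modes(self):
        ds, truth = generate(SyntheticConfig(**SMALL, seed=1))
        assert len(truth.planted) == 15
        by_mode = [truth.genes_by_mode(m)
                   for m in ("scaling", "sample_specific", "uncorrelated")]
        assert all(len(s) == 5 for s in by_mode)
        assert not (by_mode[0] & by_mode[1] | by_mode[0] & by_mode[2]
                    | by_mode[1] & by_mode[2])

    def test_overfull_planting_rejected(self):
        with pytest.raises(ValueError, match="planted counts"):
            SyntheticConfig(n_genes=10, n_scaling=5, n_sample_specific=5,
                            n_uncorrelated=5)

    def test_baseline_columns_sum_to_million_before_skew(self):
        cfg = SyntheticConfig(n_genes=150, n_samples=20, noise_sd=0.0,
                              n_scaling=0, n_sample_specific=0,
                              n_uncorrelated=0,
                              library_skew=(1.0, 1.0), n_sources=2, seed=9)
        ds, _ = generate(cfg)
        np.testing.assert_allclose(ds.sources[0].values.sum(axis=0), 1e6,
                                   rtol=1e-9)


class TestRecovery:
    @pytest.fixture(scope="class")
    def noiseless_run(self):
        cfg = SyntheticConfig(**SMALL, noise_sd=0.0, seed=17)
        ds, truth = generate(cfg)
        tpm = dataset_to_tpm(ds)
        dq = find_dq_genes(tpm)
        fc = foldchange_discordance(tpm, truth.planted_genes,
                                    FCCriteria(max_sample_pairs=2000, seed=17))
        return truth, tpm, dq, fc

    def test_noiseless_sensitivity_and_specificity(self, noiseless_run):
        truth, _, dq, fc = noiseless_run
        rep = recovery_report(truth, dq, fc)
        assert rep["sensitivity"] == 1.0
        assert rep["specificity"] == 1.0

    def test_scaling_mode_is_fc_concordant(self, noiseless_run):
        """Constant scaling is abundance-discordant but cancels in ratios."""
        truth, _, dq, fc = noiseless_run
        rep = recovery_report(truth, dq, fc)
        assert rep["per_mode_fc_rate"]["scaling"] == 0.0
        assert rep["per_mode_fc_rate"]["uncorrelated"] == 1.0

    def test_library_skew_has_no_downstream_effect(self):
        base = SyntheticConfig(**SMALL, seed=21, library_skew=None)
        flat = SyntheticConfig(**SMALL, seed=21,
                               library_skew=(1.0,) * base.n_sources)
        dq_a = find_dq_genes(dataset_to_tpm(generate(base)[0]))
        dq_b = find_dq_genes(dataset_to_tpm(generate(flat)[0]))
        assert dq_a.union_counts.equals(dq_b.union_counts)

    def test_subthreshold_effects_make_no_dq_calls(self):
        cfg = SyntheticConfig(n_genes=200, n_samples=60, noise_sd=0.0,
                              n_scaling=6, scaling_factor=2.0,
                              n_sample_specific=0, n_uncorrelated=0,
                              planted_baseline_log2_range=(3.0, 4.0),
                              seed=5)
        # 8-16 TPM baselines scaled 2x down can cross neither cut
        ds, truth = generate(cfg)
        dq = find_dq_genes(dataset_to_tpm(ds))
        assert dq.dq_genes == set()

    def test_empty_dq_set_with_planted_positives(self, noiseless_run):
        truth, tpm, _, _ = noiseless_run
        strict = find_dq_genes(tpm, DQCriteria(high_tpm=1e9, fold=4.0))
        rep = recovery_report(truth, strict)
        assert rep["sensitivity"] == 0.0
        assert rep["n_called"] == 0

    def test_mode_separation_in_correlation(self):
        cfg = SyntheticConfig(n_genes=300, n_samples=200, noise_sd=0.0, seed=17)
        ds, truth = generate(cfg)
        tpm = dataset_to_tpm(ds)
        for p in truth.planted:
            other = next(s for s in tpm.source_labels
                         if s != p.affected_source)
            r = per_gene_correlation(tpm, p.affected_source, other)
            coeff = r.coefficients[p.gene_id]
            if p.mode == "scaling":
                assert coeff > 0.999
            elif p.mode == "uncorrelated":
                assert abs(coeff) < 0.3

    def test_mode_classifier_recovers_planted_modes(self, noiseless_run):
        """The per-gene disagreement heuristic labels each planted gene
        with its true mode on the affected source pair, and a clean gene
        as concordant."""
        from rnaconcord import classify_discordance_mode
        truth, tpm, _, _ = noiseless_run
        for p in truth.planted:
            other = next(s for s in tpm.source_labels
                         if s != p.affected_source)
            label = classify_discordance_mode(tpm, p.gene_id,
                                              p.affected_source, other)
            assert label == p.mode
        clean = next(g for g in tpm.gene_ids
                     if g not in truth.planted_genes)
        assert classify_discordance_mode(
            tpm, clean, *tpm.source_labels[:2]) == "concordant"

    def test_mismatched_universe_rejected(self, noiseless_run):
        truth, tpm, dq, _ = noiseless_run
        other = dataset_to_tpm(generate(
            SyntheticConfig(n_genes=50, n_samples=30, n_scaling=1,
                            n_sample_specific=1, n_uncorrelated=1, seed=2))[0])
        with pytest.raises(ValueError, match="different gene universes"):
            recovery_report(truth, find_dq_genes(other))
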