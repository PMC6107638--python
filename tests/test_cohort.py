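import numpy as np
import pandas as pd
import pytest

import lipidwgs as lw
from lipidwgs import io as lio
from lipidwgs.cohort import carrier_flags


class TestGenotypes:
    def test_same_seed_is_byte_identical(self):
        cfg = lw.CohortConfig(n_samples={"EA": 100}, n_variants=30, seed=42)
        a = lw.simulate_genotypes(cfg)
        b = lw.simulate_genotypes(cfg)
        assert np.array_equal(a.dosages, b.dosages)
        assert a.variants.equals(b.variants)
        assert np.array_equal(a.ad_alt, b.ad_alt)

    def test_observed_frequency_tracks_configured_frequency(self):
        # at f = 0.5 and n = 10,000 the folded frequency stays within
        # three binomial standard deviations of 0.5
        cfg = lw.CohortConfig(n_samples={"EA": 10_000}, n_variants=20,
                              maf_spectrum=(0.0, 0.0, 1.0), seed=9, monogenic=[])
        gm = lw.simulate_genotypes(cfg)
        # reconstruct the drawn per-variant frequencies from metadata-free
        # genotypes: compare observed to expected binomial spread instead
        af = gm.alt_frequency()
        n_chrom = 2 * gm.n_samples
        sd = np.sqrt(af * (1 - af) / n_chrom)
        # internal consistency: every AF within its own 3-sd band of the
        # empirical mean (weak), plus the HWE genotype-frequency identity
        hets = (gm.dosages == 1).mean(axis=0)
        expected_het = 2 * af * (1 - af)
        assert np.all(np.abs(hets - expected_het) < 3 * np.sqrt(expected_het / gm.n_samples) + 0.01)
        assert np.all(sd < 0.01)

    def test_zero_sample_config_rejected(self):
        with pytest.raises(ValueError):
            lw.CohortConfig(n_samples={"EA": 0})
        with pytest.raises(ValueError):
            lw.CohortConfig(n_samples={"EA": 10}, n_variants=0)

    def test_callsets_partition_samples(self, small_cohort):
        _, gm, _ = small_cohort
        assert set(gm.samples["callset"]) <= {1, 2, 3}
        assert gm.samples["sample_id"].is_unique


class TestPhenotypes:
    def test_noise_free_phenotype_is_exact_linear_model(self):
        cfg = lw.CohortConfig(n_samples={"EA": 200}, n_variants=10, noise_sd=0.0,
                              polygenic_weights=np.zeros(10), monogenic=[], seed=3)
        gm = lw.simulate_genotypes(cfg)
        ph = lw.simulate_phenotypes(gm, cfg)
        pred = (cfg.intercept + cfg.beta_age * ph["age"] + cfg.beta_age2 * ph["age"] ** 2
                + cfg.beta_sex * ph["sex"])
        assert np.allclose(ph["ldl_true"], pred)

    def test_single_causal_variant_dosage_difference(self):
        w = np.zeros(10)
        w[0] = 5.0
        cfg = lw.CohortConfig(n_samples={"EA": 500}, n_variants=10, noise_sd=0.0,
                              polygenic_weights=w, monogenic=[],
                              maf_spectrum=(0.0, 0.0, 1.0), seed=4)
        gm = lw.simulate_genotypes(cfg)
        ph = lw.simulate_phenotypes(gm, cfg)
        resid = ph["ldl_true"] - (cfg.intercept + cfg.beta_age * ph["age"]
                                  + cfg.beta_age2 * ph["age"] ** 2 + cfg.beta_sex * ph["sex"])
        g = gm.dosages[:, 0]
        assert resid[g == 2].mean() - resid[g == 0].mean() == pytest.approx(10.0)

    def test_ols_recovers_carrier_effect(self, covariates):
        cfg = lw.CohortConfig(
            n_samples={"EA": 5000}, n_variants=10, noise_sd=15.0,
            polygenic_weights=np.zeros(10),
            monogenic=[lw.MonogenicGene("LDLR", "dominant", 30.0, 0.05)], seed=5)
        gm = lw.simulate_genotypes(cfg)
        ph = lw.simulate_phenotypes(gm, cfg)
        import statsmodels.api as sm
        X = sm.add_constant(pd.concat(
            [covariates(ph), ph["carrier_LDLR"]], axis=1).to_numpy(dtype=float))
        beta = sm.OLS(ph["ldl_true"].to_numpy(), X).fit().params[-1]
        assert beta == pytest.approx(30.0, abs=3.0)

    def test_weight_length_mismatch_rejected(self):
        cfg = lw.CohortConfig(n_samples={"EA": 50}, n_variants=10, seed=1,
                              polygenic_weights=np.zeros(7))
        gm = lw.simulate_genotypes(cfg)
        with pytest.raises(ValueError, match="weights"):
            lw.simulate_phenotypes(gm, cfg)

    def test_statin_observation_model_inverts_under_adjustment(self, small_cohort):
        _, _, ph = small_cohort
        prep = lw.prepare_phenotypes(ph)
        treated = prep["on_statin"] == 1
        # the observation model scales treated LDL by 0.7; dividing by 0.7
        # during preparation must recover the generative value exactly
        assert np.allclose(prep.loc[treated, "ldl_adj"], prep.loc[treated, "ldl_true"])
        # untreated samples with valid triglycerides: Friedewald-derived
        # LDL equals the generative value (TG >= 400 yields missing LDL)
        untreated = ~treated & (prep["tg"] < 400)
        assert np.allclose(prep.loc[untreated, "ldl"], prep.loc[untreated, "ldl_true"])
        assert prep.loc[~treated & (prep["tg"] >= 400), "ldl"].isna().all()

    def test_carrier_flags_match_inheritance(self):
        cfg = lw.CohortConfig(
            n_samples={"EA": 3000}, n_variants=5, seed=6,
            monogenic=[lw.MonogenicGene("LDLR", "dominant", 30.0, 0.02),
                       lw.MonogenicGene("LDLRAP1", "recessive", 40.0, 0.01)])
        gm = lw.simulate_genotypes(cfg)
        flags = carrier_flags(gm, cfg)
        dom_col = gm.variants.index[gm.variants["gene"] == "LDLR"][0]
        assert np.array_equal(flags["LDLR"], (gm.dosages[:, dom_col] >= 1).astype(int))
        rec_col = gm.variants.index[gm.variants["gene"] == "LDLRAP1"][0]
        assert np.array_equal(flags["LDLRAP1"], (gm.dosages[:, rec_col] >= 2).astype(int))


class TestLandscape:
    def test_planted_links_have_high_correlation(self, small_landscape):
        cfg, ls = small_landscape
        gidx = {g: i for i, g in enumerate(ls.genes["gene"])}
        from lipidwgs.linking import mark_expression_correlations
        corrs = [mark_expression_correlations(ls.signal, ls.expression, b, gidx[g])
                 for b, g in zip(ls.true_links["bin_index"], ls.true_links["gene"])]
        assert np.nanmean(corrs) > 0.75  # rho_true = 0.9 less sampling noise

    def test_perfect_rho_without_noise_gives_unit_correlation(self):
        cfg = lw.LandscapeConfig(n_cell_types=12, n_genes=4, n_bins=80,
                                 rho_true=1.0, seed=2)
        ls = lw.simulate_regulatory_landscape(cfg)
        from lipidwgs.linking import mark_expression_correlations
        gidx = {g: i for i, g in enumerate(ls.genes["gene"])}
        b, g = ls.true_links.iloc[0]
        feats = mark_expression_correlations(ls.signal, ls.expression, int(b), gidx[g])
        assert np.allclose(feats, 1.0, atol=1e-9)

    def test_decoy_pairs_average_null_correlation(self, small_landscape):
        _, ls = small_landscape
        from lipidwgs.linking import CorrelationLinker
        linker = CorrelationLinker(ls)
        truth = set(zip(ls.true_links["bin_index"],
                        [list(ls.genes["gene"]).index(g) for g in ls.true_links["gene"]]))
        decoy_feats = []
        enh_bins = sorted({b for b in ls.true_links["bin_index"]})
        for b in range(ls.signal.shape[0]):
            for g in range(len(ls.genes)):
                if (b, g) not in truth and ls.states[b, 0] == "7_Enh":
                    decoy_feats.append(linker.features(b, g))
        assert abs(np.nanmean(decoy_feats)) < 0.05

    def test_contact_decays_monotonically(self, small_landscape):
        _, ls = small_landscape
        assert ls.contact(5_000) >= ls.contact(50_000)
        d = np.logspace(2, 6, 40)
        c = ls.contact(d)
        assert np.all(np.diff(c) <= 0)

    def test_signal_and_expression_nonnegative(self, small_landscape):
        _, ls = small_landscape
        assert (ls.signal >= 0).all()
        assert (ls.expression >= 0).all()

    def test_too_few_cell_types_rejected(self):
        with pytest.raises(ValueError):
            lw.LandscapeConfig(n_cell_types=2)


class TestRoundTrip:
    def test_write_then_read_reproduces_cohort(self, tmp_path):
        cfg = lw.CohortConfig(n_samples={"EA": 40, "AA": 30}, n_variants=15, seed=8)
        cohort = lw.simulate_cohort(cfg, lw.LandscapeConfig(
            n_cell_types=10, n_genes=4, n_bins=60, seed=8))
        paths = lw.write_cohort(cohort, tmp_path)
        gm2 = lio.read_vcf(paths["vcf"])
        assert np.array_equal(gm2.dosages, cohort.genotypes.dosages, equal_nan=True)
        bed = lio.read_bed(paths["annotations"])
        assert (bed["start"] < bed["end"]).all()
        orig = cohort.landscape.intervals.sort_values(["chrom", "start", "end"])
        assert sorted(bed["start"]) == sorted(orig["start"])
        pheno = lio.read_tsv(paths["phenotypes"])
        assert len(pheno) == cohort.genotypes.n_samples
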