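import numpy as np
import pandas as pd
import pytest

import lipidwgs as lw
from lipidwgs.containers import GenotypeMatrix
from lipidwgs.extremes import (MendelianGeneConfig, ScoreModel, apply_score,
                               attributable_fraction, build_score_lead,
                               build_score_pt, build_score_shrunk,
                               classify_monogenic, classify_polygenic,
                               define_extremes, extreme_association,
                               relative_r2_gain, select_best_score)

# published per-ancestry contingency inputs for the extreme-LDL strata:
# (exposed among cases, n cases, adjusted OR) -> printed PAF %
PUBLISHED_PAF_CASES = [
    ("ea_high_monogenic", 5, 284, 10.92, 1.60),
    ("ea_high_polygenic", 64, 284, 7.65, 19.6),
    ("aa_high_monogenic", 7, 217, 7.43, 2.79),
    ("aa_high_polygenic", 29, 217, 3.2, 9.2),
    ("ea_low_monogenic", 6, 286, 21.73, 2.00),
    ("ea_low_polygenic", 82, 286, 10.38, 25.9),
    ("aa_low_monogenic", 11, 218, 13.83, 4.68),
    ("aa_low_polygenic", 32, 218, 3.7, 10.7),
]


def _decimals(x: float) -> int:
    s = f"{x}"
    return len(s.split(".")[1]) if "." in s else 0


class TestAttributableFraction:
    @pytest.mark.parametrize("name,k,n,orr,printed", PUBLISHED_PAF_CASES)
    def test_case_based_formula_reproduces_published_values(self, name, k, n, orr, printed):
        value = attributable_fraction(k, n, orr)
        assert round(value, _decimals(printed)) == pytest.approx(printed)

    def test_null_odds_ratio_gives_zero(self):
        assert attributable_fraction(50, 100, 1.0) == 0.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            attributable_fraction(5, 100, 0.0)
        with pytest.raises(ValueError):
            attributable_fraction(101, 100, 2.0)


def test_relative_r2_gain_worked_example():
    assert relative_r2_gain(0.245, 0.298) == pytest.approx(21.6, abs=0.05)


class TestDefineExtremes:
    def test_interpolated_quantiles_on_1_to_100(self):
        vals = np.arange(1.0, 101.0)
        labels, cutoffs = define_extremes(vals, ["X"] * 100)
        assert cutoffs["high_cutoff"].iloc[0] == pytest.approx(95.05)
        assert cutoffs["low_cutoff"].iloc[0] == pytest.approx(5.95)
        assert (labels == "extreme_high").sum() == 5
        assert (labels == "extreme_low").sum() == 5

    def test_constant_values_flag_nothing(self):
        labels, _ = define_extremes(np.full(50, 130.0), ["X"] * 50)
        assert (labels == "neither").all()

    def test_cutoffs_are_ancestry_specific(self, rng):
        ldl = np.r_[rng.normal(130, 30, 500), rng.normal(150, 30, 500)]
        anc = ["EA"] * 500 + ["AA"] * 500
        _, cutoffs = define_extremes(ldl, anc)
        c = cutoffs.set_index("ancestry")
        assert c.loc["AA", "high_cutoff"] > c.loc["EA", "high_cutoff"]

    def test_data_matching_published_percentiles_reproduces_cutoffs(self, rng):
        # construct a sample whose 5th/95th percentiles sit at the
        # published European-ancestry cutoffs 72.9 and 183 mg/dl
        base = rng.normal(128, 33.5, 20_001)
        ranks = (np.argsort(np.argsort(base)) / 20_000)
        ldl = np.interp(ranks, [0, 0.05, 0.95, 1.0], [20.0, 72.9, 183.0, 320.0])
        _, cutoffs = define_extremes(ldl, ["EA"] * len(ldl))
        assert cutoffs["low_cutoff"].iloc[0] == pytest.approx(72.9, abs=0.2)
        assert cutoffs["high_cutoff"].iloc[0] == pytest.approx(183.0, abs=0.2)

    def test_small_ancestry_rejected(self):
        with pytest.raises(ValueError):
            define_extremes(np.arange(10.0), ["X"] * 10)


def _geno(dosage_rows, genes, clinvar, consequence, afs=None):
    dos = np.asarray(dosage_rows, dtype=float)
    n_s, m = dos.shape
    if afs is not None:
        # pad rows so the observed ALT frequency matches the target
        pass
    v = pd.DataFrame({"vid": [f"v{j}" for j in range(m)], "chrom": "1",
                      "pos": np.arange(m) * 10, "ref": "A", "alt": "G",
                      "gene": genes, "clinvar": clinvar, "consequence": consequence})
    return GenotypeMatrix(dosages=dos, variants=v,
                          samples=pd.DataFrame({"sample_id": [f"s{i}" for i in range(n_s)]}))


class TestMonogenicClassification:
    def _pad(self, rows, n=1000):
        """Append hom-ref samples so pathogenic allele frequencies stay rare."""
        rows = np.asarray(rows, dtype=float)
        return np.vstack([rows, np.zeros((n - rows.shape[0], rows.shape[1]))])

    def test_het_pathogenic_dominant_variant_flags_carrier(self):
        gm = _geno(self._pad([[1.0]]), ["LDLR"], ["pathogenic"], [""])
        flags = classify_monogenic(gm)
        assert flags["carrier_LDLR"].iloc[0] == 1
        assert flags["carrier_LDLR"].iloc[1:].sum() == 0

    def test_single_het_recessive_variant_is_not_carrier(self):
        gm = _geno(self._pad([[1.0]]), ["LDLRAP1"], ["pathogenic"], [""])
        assert classify_monogenic(gm)["carrier_LDLRAP1"].iloc[0] == 0

    def test_recessive_homozygote_and_compound_het_are_carriers(self):
        gm = _geno(self._pad([[2.0, 0.0], [1.0, 1.0], [1.0, 0.0]]),
                   ["LDLRAP1"] * 2, ["pathogenic"] * 2, [""] * 2)
        flags = classify_monogenic(gm)["carrier_LDLRAP1"]
        assert flags.iloc[0] == 1  # homozygous
        assert flags.iloc[1] == 1  # two distinct het qualifying variants
        assert flags.iloc[2] == 0  # one het only

    def test_conflicting_benign_assertion_excludes_variant(self):
        gm = _geno(self._pad([[1.0]]), ["LDLR"], ["pathogenic;benign"], [""])
        assert classify_monogenic(gm)["carrier_LDLR"].sum() == 0

    def test_lof_without_clinvar_label_qualifies(self):
        gm = _geno(self._pad([[1.0]]), ["LDLR"], [""], ["lof"])
        assert classify_monogenic(gm)["carrier_LDLR"].iloc[0] == 1

    def test_frequency_bound_by_inheritance(self):
        # 5% ALT frequency: above the 1% dominant bound, below the 10%
        # recessive bound
        n = 1000
        dos = np.zeros((n, 1))
        dos[:100, 0] = 1.0  # AF 5%
        gm_dom = _geno(dos, ["LDLR"], ["pathogenic"], [""])
        assert classify_monogenic(gm_dom)["carrier_LDLR"].sum() == 0
        dos2 = dos.copy()
        dos2[0, 0] = 2.0
        gm_rec = _geno(dos2, ["LDLRAP1"], ["pathogenic"], [""])
        assert classify_monogenic(gm_rec)["carrier_LDLRAP1"].iloc[0] == 1

    def test_classification_is_monotone_in_qualifying_variants(self):
        base = self._pad([[1.0, 0.0]])
        gm1 = _geno(base, ["LDLR", "LDLR"], ["pathogenic", "pathogenic"], ["", ""])
        more = base.copy()
        more[0, 1] = 1.0
        gm2 = _geno(more, ["LDLR", "LDLR"], ["pathogenic", "pathogenic"], ["", ""])
        f1 = classify_monogenic(gm1)["carrier_LDLR"]
        f2 = classify_monogenic(gm2)["carrier_LDLR"]
        assert (f2 >= f1).all()


def _stats(vids, betas, ps, pos=None, ea=None, oa=None):
    m = len(vids)
    return pd.DataFrame({
        "vid": vids, "chrom": "1",
        "pos": pos if pos is not None else np.arange(m) * 1000,
        "effect_allele": ea if ea is not None else ["G"] * m,
        "other_allele": oa if oa is not None else ["A"] * m,
        "beta": betas, "se": [0.1] * m, "p": ps,
    })


class TestScoreBuilders:
    def test_lead_variant_pruning_keeps_most_significant(self):
        s = _stats(["a", "b"], [0.5, 0.4], [1e-10, 1e-9])
        ld = pd.DataFrame([[1.0, 0.9], [0.9, 1.0]], index=["a", "b"], columns=["a", "b"])
        model = build_score_lead(s, ld)
        assert model.table["vid"].tolist() == ["a"]

    def test_no_genomewide_hit_is_error(self):
        s = _stats(["a"], [0.5], [1e-6])
        ld = pd.DataFrame([[1.0]], index=["a"], columns=["a"])
        with pytest.raises(ValueError):
            build_score_lead(s, ld)

    def test_constructed_59_independent_hits_yield_model_of_59(self, rng):
        m = 59
        vids = [f"v{j}" for j in range(m)]
        s = _stats(vids, rng.normal(0.3, 0.05, m), np.full(m, 1e-10),
                   pos=np.arange(m) * 500_000)
        ld = pd.DataFrame(np.eye(m), index=vids, columns=vids)
        assert build_score_lead(s, ld).n_variants == 59

    def test_permissive_grid_cell_retains_all_variants(self):
        s = _stats(["a", "b", "c"], [0.1, 0.2, 0.3], [0.5, 0.01, 1e-9])
        ld = pd.DataFrame(np.eye(3), index=list("abc"), columns=list("abc"))
        models = build_score_pt(s, ld, p_grid=[1.0], r2_grid=[1.1])
        assert models[0].n_variants == 3

    def test_unreachable_p_threshold_flags_empty_model(self):
        s = _stats(["a"], [0.1], [0.5])
        ld = pd.DataFrame([[1.0]], index=["a"], columns=["a"])
        models = build_score_pt(s, ld, p_grid=[1e-20], r2_grid=[0.5])
        assert models[0].n_variants == 0 and models[0].provenance["empty"]

    def test_nested_p_thresholds_give_nested_sets(self, rng):
        m = 30
        vids = [f"v{j}" for j in range(m)]
        s = _stats(vids, rng.normal(0, 0.2, m), rng.uniform(1e-12, 1, m))
        r = rng.uniform(0, 0.6, (m, m)); r = (r + r.T) / 2; np.fill_diagonal(r, 1.0)
        ld = pd.DataFrame(r, index=vids, columns=vids)
        models = build_score_pt(s, ld, p_grid=[1e-6, 1e-3, 1e-1, 1.0], r2_grid=[0.3])
        sets = [set(mo.table["vid"]) for mo in models]
        for small, big in zip(sets, sets[1:]):
            assert small <= big

    def test_identity_ld_unit_shrinkage_halves_weights(self):
        s = _stats(["a", "b"], [0.4, -0.2], [1e-5, 1e-4])
        ld = pd.DataFrame(np.eye(2), index=["a", "b"], columns=["a", "b"])
        # M / (N h^2) = 1  ->  (I + I)^-1 beta = beta / 2
        models = build_score_shrunk(s, ld, [1.0], n_gwas=8, h2=0.25)
        assert models[0].table["weight"].tolist() == pytest.approx([0.2, -0.1])

    def test_vanishing_shrinkage_recovers_discovery_betas(self):
        s = _stats(["a", "b"], [0.4, -0.2], [1e-5, 1e-4])
        ld = pd.DataFrame(np.eye(2), index=["a", "b"], columns=["a", "b"])
        models = build_score_shrunk(s, ld, [1.0], n_gwas=10**9, h2=0.5)
        assert models[0].table["weight"].tolist() == pytest.approx([0.4, -0.2], rel=1e-6)

    def test_ambiguous_variants_never_enter_models(self):
        s = _stats(["a", "b"], [0.4, 0.2], [1e-10, 1e-10],
                   ea=["A", "G"], oa=["T", "A"])
        ld = pd.DataFrame(np.eye(2), index=["a", "b"], columns=["a", "b"])
        model = build_score_lead(s, ld)
        assert model.table["vid"].tolist() == ["b"]

    def test_score_model_rejects_ambiguous_table(self):
        t = _stats(["a"], [0.4], [1e-10], ea=["C"], oa=["G"]).rename(
            columns={"beta": "weight"})
        with pytest.raises(ValueError, match="ambiguous"):
            ScoreModel(method="lead_variants", table=t)


class TestApplyScore:
    def _gm(self, dosages, ref="A", alt="G"):
        dos = np.asarray(dosages, dtype=float)
        m = dos.shape[1]
        v = pd.DataFrame({"vid": [f"v{j}" for j in range(m)], "chrom": "1",
                          "pos": np.arange(m) * 1000, "ref": ref, "alt": alt})
        return GenotypeMatrix(dosages=dos, variants=v,
                              samples=pd.DataFrame({"sample_id": [f"s{i}" for i in range(dos.shape[0])]}))

    def test_weighted_dosage_arithmetic(self):
        gm = self._gm([[0.0, 1.0, 2.0]])
        t = _stats(["v0", "v1", "v2"], [0.5, -0.2, 0.1], [1e-9] * 3).rename(columns={"beta": "weight"})
        model = ScoreModel("lead_variants", t)
        assert apply_score(model, gm)[0] == pytest.approx(0.0 * 0.5 - 0.2 * 1.0 + 0.1 * 2.0)

    def test_swapped_alleles_flip_dosage(self):
        gm = self._gm([[2.0]])
        t = _stats(["v0"], [1.0], [1e-9], ea=["A"], oa=["G"]).rename(columns={"beta": "weight"})
        model = ScoreModel("lead_variants", t)
        assert apply_score(model, gm)[0] == pytest.approx(0.0)  # 2 - 2

    def test_all_zero_weights_give_zero_scores(self):
        gm = self._gm([[1.0, 2.0], [0.0, 1.0]])
        t = _stats(["v0", "v1"], [0.0, 0.0], [1e-9] * 2).rename(columns={"beta": "weight"})
        assert np.allclose(apply_score(ScoreModel("lead_variants", t), gm), 0.0)

    def test_no_matching_variant_is_error(self):
        gm = self._gm([[1.0]])
        t = _stats(["x"], [1.0], [1e-9], pos=[999_999]).rename(columns={"beta": "weight"})
        with pytest.raises(ValueError, match="matched"):
            apply_score(ScoreModel("lead_variants", t), gm)


class TestSelectBestScore:
    def test_truth_weight_model_beats_noise_models(self, rng):
        n, m = 2000, 20
        g = rng.binomial(2, 0.3, (n, m)).astype(float)
        w_true = rng.normal(0, 1, m)
        y = g @ w_true + rng.normal(0, 2, n)
        v = pd.DataFrame({"vid": [f"v{j}" for j in range(m)], "chrom": "1",
                          "pos": np.arange(m) * 1000, "ref": "A", "alt": "G"})
        gm = GenotypeMatrix(dosages=g, variants=v,
                            samples=pd.DataFrame({"sample_id": [f"s{i}" for i in range(n)]}))
        def model(w, method="p_r2_threshold"):
            t = _stats(v["vid"], w, np.full(m, 1e-9)).rename(columns={"beta": "weight"})
            return ScoreModel(method, t)
        truth = model(w_true, "lead_variants")
        noise = [model(rng.normal(0, 1, m)) for _ in range(3)]
        best, table = select_best_score([truth] + noise, gm, y)
        assert best is truth
        assert table["r2"].iloc[0] == table["r2"].max()

    def test_single_model_returned(self, rng):
        n = 100
        g = rng.binomial(2, 0.3, (n, 1)).astype(float)
        v = pd.DataFrame({"vid": ["v0"], "chrom": "1", "pos": [0], "ref": "A", "alt": "G"})
        gm = GenotypeMatrix(dosages=g, variants=v,
                            samples=pd.DataFrame({"sample_id": [f"s{i}" for i in range(n)]}))
        t = _stats(["v0"], [1.0], [1e-9]).rename(columns={"beta": "weight"})
        only = ScoreModel("lead_variants", t)
        best, _ = select_best_score([only], gm, rng.normal(size=n))
        assert best is only


class TestClassifyPolygenic:
    def test_exact_counts_with_distinct_scores(self):
        flags = classify_polygenic(np.arange(100.0), ["X"] * 100)
        assert flags["high_score"].sum() == 5
        assert flags["low_score"].sum() == 5

    def test_flags_are_ancestry_specific(self, rng):
        s = np.r_[rng.normal(0, 1, 200), rng.normal(10, 1, 200)]
        anc = ["EA"] * 200 + ["AA"] * 200
        flags = classify_polygenic(s, anc)
        assert flags["high_score"][:200].sum() == 10
        assert flags["high_score"][200:].sum() == 10

    def test_ties_at_cutoff_stay_unflagged(self):
        s = np.r_[np.zeros(95), np.full(5, 1.0)]
        flags = classify_polygenic(s, ["X"] * 100)
        # the 95th percentile falls among the tied top values; the
        # strictly-greater rule leaves ties unflagged
        assert flags["high_score"].sum() <= 5


class TestExtremeAssociation:
    def test_recovers_simulated_carrier_effect(self, rng):
        n = 6000
        carrier = rng.binomial(1, 0.05, n)
        age = rng.normal(50, 10, n)
        sex = rng.binomial(1, 0.5, n)
        ldl = 130 + 0.4 * age + 30.0 * carrier + rng.normal(0, 15, n)
        labels, _ = define_extremes(ldl, ["EA"] * n)
        flags = rng.binomial(1, 0.05, n)
        cov = pd.DataFrame({"age": age, "age2": age ** 2, "sex": sex})
        res = extreme_association((labels == "extreme_high").to_numpy(), carrier,
                                  flags, cov, ldl, ["EA"] * n)
        assert res[0].beta_carrier == pytest.approx(30.0, abs=3.0)
        assert res[0].or_carrier > 1.0

    def test_zero_carrier_ancestry_reports_missing_or_with_counts(self, rng):
        n = 200
        ldl = rng.normal(130, 30, n)
        labels, _ = define_extremes(ldl, ["X"] * n)
        cov = pd.DataFrame({"age": rng.normal(50, 10, n)})
        cov["age2"] = cov["age"] ** 2
        cov["sex"] = rng.binomial(1, .5, n)
        res = extreme_association((labels == "extreme_high").to_numpy(),
                                  np.zeros(n, int), rng.binomial(1, .05, n),
                                  cov, ldl, ["X"] * n)
        assert np.isnan(res[0].or_carrier)
        assert res[0].n_extreme > 0

    def test_per_sd_score_effect_attached(self, rng):
        n = 3000
        score = rng.normal(0, 1, n)
        age = rng.normal(50, 10, n)
        ldl = 130 + 15.5 * score + rng.normal(0, 10, n)
        labels, _ = define_extremes(ldl, ["EA"] * n)
        flags = classify_polygenic(score, ["EA"] * n)
        cov = pd.DataFrame({"age": age, "age2": age ** 2,
                            "sex": rng.binomial(1, .5, n)})
        res = extreme_association((labels == "extreme_high").to_numpy(),
                                  rng.binomial(1, 0.02, n),
                                  flags["high_score"].to_numpy(), cov, ldl,
                                  ["EA"] * n, scores=score)
        assert res[0].beta_per_sd == pytest.approx(15.5, abs=1.0)


def test_mendelian_config_defaults():
    assert MendelianGeneConfig("LDLR", "dominant").max_af == 0.01
    assert MendelianGeneConfig("ABCG5", "recessive").max_af == 0.10
    with pytest.raises(ValueError):
        MendelianGeneConfig("X", "codominant")
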