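import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from grazekit import association as assoc
from grazekit.association import (
    Design,
    back_transform,
    bh_adjust,
    compact_letters,
    correlation_matrix,
    encode_genotypes,
    enumerate_random_structures,
    fit_mixed_model,
    marginal_means,
    posthoc_bh,
    residual_diagnostics,
    select_fixed_structure,
    select_random_structure,
    transform_responses,
)


def herd_metadata(n=306, seed=0):
    """Metadata with the observed genotype counts spread over 4 farms."""
    counts = {"AA": 3, "AB": 18, "AC": 31, "BB": 38, "BC": 109, "CC": 107}
    rng = np.random.default_rng(seed)
    if n == 306:
        geno = np.repeat(list(counts), list(counts.values()))
        rng.shuffle(geno)
    else:
        p = np.array(list(counts.values()), float)
        geno = rng.choice(list(counts), size=n, p=p / p.sum())
    return pd.DataFrame({
        "cow_id": [f"C{i:04d}" for i in range(n)],
        "genotype": geno,
        "age_class": rng.integers(1, 4, n),
        "farm": rng.integers(1, 5, n),
        "mob": rng.integers(0, 14, n),
        "sire": rng.integers(0, 73, n),
        "year": rng.integers(2019, 2021, n),
    })


class TestGenotypes:
    def test_presence_coding(self):
        rec, _ = encode_genotypes(pd.DataFrame({"cow_id": ["a"], "genotype": ["BC"]}))
        row = rec.iloc[0]
        assert (row["has_A"], row["has_B"], row["has_C"]) == (False, True, True)

    def test_observed_herd_frequencies_and_exclusion(self):
        rec, report = encode_genotypes(herd_metadata())
        assert report["percent"] == {"AA": 1, "AB": 6, "AC": 10, "BB": 12,
                                     "BC": 36, "CC": 35}
        assert report["excluded_genotypes"] == ["AA"]
        assert report["n_analysed"] == 303
        assert report["per_farm_counts"].to_numpy().sum() == 306

    def test_invalid_genotype_rejected(self):
        with pytest.raises(assoc.GenotypeError):
            encode_genotypes(pd.DataFrame({"cow_id": ["a"], "genotype": ["AD"]}))


class TestTransforms:
    def test_log_and_bounded(self):
        t = transform_responses(pd.DataFrame({
            "hr_mcp": [1.0, 0.0], "rel_ele": [0.5, 0.2], "slope85": [40.0, 80.0]}))
        assert t["resp_hr_mcp"].iloc[0] == pytest.approx(0.0)
        assert np.isnan(t["resp_hr_mcp"].iloc[1])  # non-positive flagged
        assert t["resp_rel_ele"].iloc[0] == 0.5
        assert t["resp_slope85"].iloc[1] == pytest.approx(0.8)

    def test_back_transform_round_trip(self):
        for link, fwd in (("log", np.log), ("logit", special.logit)):
            eta = 0.37
            mean, _ = back_transform(eta, 0.1, link)
            assert fwd(mean) == pytest.approx(eta, abs=1e-10)

    def test_delta_method_se(self):
        mean, se = back_transform(1.0, 0.2, "log")
        assert se == pytest.approx(np.exp(1.0) * 0.2)
        mean, se = back_transform(0.0, 0.2, "logit")
        assert se == pytest.approx(0.25 * 0.2)


class TestCorrelations:
    def test_diagonal_and_antisymmetric_pair(self):
        df = pd.DataFrame({"ho_dist": [1.0, 2, 3, 4], "hr_mcp": [-1.0, -2, -3, -4]})
        pairs, m = correlation_matrix(df, ["ho_dist", "hr_mcp"])
        assert m.loc["ho_dist", "ho_dist"] == 1.0
        assert m.loc["ho_dist", "hr_mcp"] == pytest.approx(-1.0)

    def test_oracle_from_definition(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=50)
        y = 0.5 * x + rng.normal(size=50)
        pairs, _ = correlation_matrix(
            pd.DataFrame({"ho_dist": x, "hr_mcp": y}), ["ho_dist", "hr_mcp"])
        r = pairs["r"].iloc[0]
        # brute force: covariance over sd product, p from the t distribution
        r_oracle = (np.mean((x - x.mean()) * (y - y.mean()))
                    / (x.std() * y.std()))
        t = r_oracle * np.sqrt(48 / (1 - r_oracle**2))
        p_oracle = 2 * stats.t.sf(abs(t), 48)
        assert r == pytest.approx(r_oracle, abs=1e-12)
        assert pairs["p"].iloc[0] == pytest.approx(p_oracle, rel=1e-9)

    def test_pairwise_complete_n(self):
        df = pd.DataFrame({"ho_dist": [1.0, 2, 3, np.nan, 5, 1],
                           "hr_mcp": [2.0, 1, 4, 4, np.nan, 3]})
        pairs, _ = correlation_matrix(df, ["ho_dist", "hr_mcp"])
        assert pairs["n"].iloc[0] == 4

    def test_stars_thresholds(self):
        assert assoc._stars(0.04) == "*"
        assert assoc._stars(0.009) == "**"
        assert assoc._stars(0.0009) == "***"
        assert assoc._stars(0.2) == ""


class TestRandomStructures:
    def test_twelve_candidates_with_winners(self):
        cands = enumerate_random_structures()
        assert len(cands) == 12
        terms = [set(t) for _, t in cands]
        assert {"year", "farm_year"} in terms   # distances winner
        assert {"mob"} in terms                  # elevation winner
        assert {"mob", "sire"} in terms          # remaining-behaviour winner

    def test_cow_always_included(self):
        data = herd_metadata(40)
        for _, terms in enumerate_random_structures():
            factors = assoc._random_factors(data, terms)
            assert "cow_id" in factors

    def test_mob_effect_selected(self):
        """Data generated with a mob effect and no sire effect -> mob chosen."""
        rng = np.random.default_rng(11)
        meta = herd_metadata(280, seed=11)
        days = 6
        cow = np.repeat(np.arange(len(meta)), days)
        data = meta.iloc[cow].reset_index(drop=True)
        u_mob = rng.normal(0, 0.8, 14)
        u_cow = rng.normal(0, 0.3, len(meta))
        data["resp"] = (u_mob[data["mob"].to_numpy()] + u_cow[cow]
                        + rng.normal(0, 0.5, len(data)))
        terms, ranking = select_random_structure(data, "resp")
        assert "mob" in terms
        assert "sire" not in terms
        assert len(ranking) >= 10

    def test_aic_tie_break_prefers_fewer_parameters(self):
        # ranking cascade on a synthetic table is exercised through the
        # deterministic sort; identical AICs must fall back to df then order
        df = pd.DataFrame({
            "structure": ["X", "Y"], "terms": ["a", "b"], "order": [0, 1],
            "df": [4, 3], "logLik": [-100.0, -101.0],
            "AIC": [208.0, 208.0], "BIC": [210.0, 209.0], "singular": False,
        })
        short = df.sort_values(["df", "BIC", "order"], kind="mergesort")
        assert short.iloc[0]["structure"] == "Y"


class TestFixedSelection:
    def _panel(self, age_effect, seed):
        rng = np.random.default_rng(seed)
        meta = herd_metadata(300, seed=seed)
        meta = meta[meta["genotype"] != "AA"].reset_index(drop=True)
        days = 6
        cow = np.repeat(np.arange(len(meta)), days)
        data = meta.iloc[cow].reset_index(drop=True)
        data["resp"] = (age_effect * (data["age_class"].to_numpy() - 2)
                        + rng.normal(0, 0.3, len(meta))[cow]
                        + rng.normal(0, 0.5, len(data)))
        return data

    def test_null_age_effect_dropped(self):
        data = self._panel(0.0, 21)
        cols, p = select_fixed_structure(data, "resp", ("mob",), "genotype")
        assert "age_class" not in cols
        assert "genotype" in cols

    def test_strong_age_effect_retained(self):
        data = self._panel(0.5, 22)
        cols, p = select_fixed_structure(data, "resp", ("mob",), "genotype")
        assert "age_class" in cols
        assert p < 0.001


class TestMarginalMeans:
    def _fit(self, link="identity"):
        rng = np.random.default_rng(30)
        meta = herd_metadata(240, seed=30)
        meta = meta[meta["genotype"] != "AA"].reset_index(drop=True)
        days = 4
        cow = np.repeat(np.arange(len(meta)), days)
        data = meta.iloc[cow].reset_index(drop=True)
        eff = {"AB": 0.4, "AC": 0.3, "BB": 0.0, "BC": 0.1, "CC": 0.1}
        eta = (1.0 + data["genotype"].map(eff).to_numpy()
               + rng.normal(0, 0.2, len(meta))[cow]
               + rng.normal(0, 0.3, len(data)))
        data["resp"] = special.expit(eta) if link == "logit" else eta
        fit = fit_mixed_model(data, "resp", ["genotype", "age_class"],
                              ("mob",), link=("logit" if link == "logit" else "identity"))
        if link == "log":
            fit.link = "log"
        return fit, data

    def test_intercept_only_back_transform(self):
        rng = np.random.default_rng(31)
        data = pd.DataFrame({"cow_id": np.repeat(np.arange(50), 3),
                             "resp": rng.normal(2.0, 0.3, 150)})
        fit = fit_mixed_model(data, "resp", [], ("cow_id",) if False else (),
                              link="identity")
        fit.link = "log"
        mm = marginal_means(fit, [])
        assert mm["mean"].iloc[0] == pytest.approx(np.exp(fit.beta[0]))

    def test_balanced_two_factor_average(self):
        fit, data = self._fit()
        mm = marginal_means(fit, "genotype")
        grid_mm = marginal_means(fit, ["genotype", "age_class"])
        for g in mm["genotype"]:
            cells = grid_mm[grid_mm["genotype"] == g]["emm_link"]
            assert mm[mm["genotype"] == g]["emm_link"].iloc[0] == pytest.approx(
                cells.mean(), abs=1e-10)

    def test_log_link_exp_of_linear_predictor(self):
        fit, _ = self._fit()
        fit.link = "log"
        mm = marginal_means(fit, "genotype")
        np.testing.assert_allclose(mm["mean"], np.exp(mm["emm_link"]), rtol=1e-12)

    def test_grouping_must_be_fixed_factor(self):
        fit, _ = self._fit()
        with pytest.raises(ValueError):
            marginal_means(fit, "farm")


class TestBH:
    def test_worked_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04])

    def test_matches_statsmodels_up_to_m100(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(5)
        for m in (1, 2, 7, 40, 100):
            p = rng.uniform(0, 1, m)
            got = bh_adjust(p)
            _, expected, _, _ = multipletests(p, method="fdr_bh")
            np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_monotone_and_capped(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(0, 1, 30)
        adj = bh_adjust(p)
        assert (adj <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestLetters:
    def test_all_identical_single_letter(self):
        letters = compact_letters(["a", "b", "c"], [])
        assert set(letters.values()) == {"a"}

    def test_soundness_random_patterns(self):
        """Share a letter  <=>  pair not significantly different."""
        rng = np.random.default_rng(7)
        for trial in range(30):
            k = rng.integers(3, 8)
            groups = [f"g{i}" for i in range(k)]
            sig = [pair for pair in itertools.combinations(groups, 2)
                   if rng.random() < 0.4]
            letters = compact_letters(groups, sig)
            for g1, g2 in itertools.combinations(groups, 2):
                share = bool(set(letters[g1]) & set(letters[g2]))
                assert share == ((g1, g2) not in sig), (trial, g1, g2, letters, sig)

    def test_posthoc_letters_consistent_with_adjusted_p(self):
        rng = np.random.default_rng(40)
        meta = herd_metadata(240, seed=40)
        meta = meta[meta["genotype"] != "AA"].reset_index(drop=True)
        cow = np.repeat(np.arange(len(meta)), 4)
        data = meta.iloc[cow].reset_index(drop=True)
        eff = {"AB": 0.8, "AC": 0.7, "BB": 0.0, "BC": 0.1, "CC": 0.1}
        data["resp"] = (data["genotype"].map(eff).to_numpy()
                        + rng.normal(0, 0.2, len(meta))[cow]
                        + rng.normal(0, 0.3, len(data)))
        fit = fit_mixed_model(data, "resp", ["genotype"], ("mob",))
        mm = marginal_means(fit, "genotype")
        pairs, letters = posthoc_bh(fit, mm, "genotype")
        for row in pairs.itertuples():
            share = bool(set(letters[row.group_1]) & set(letters[row.group_2]))
            assert share == (row.p_adj >= 0.05)


class TestDiagnostics:
    def test_gaussian_data_passes(self):
        rng = np.random.default_rng(50)
        cow = np.repeat(np.arange(100), 5)
        data = pd.DataFrame({"cow_id": cow,
                             "resp": rng.normal(0, 1, 500)})
        fit = fit_mixed_model(data, "resp", [], ("cow_id",))
        d = residual_diagnostics(fit)
        assert d["passed"]
        assert d["fraction_beyond"] < 0.02

    def test_contaminated_data_fails(self):
        rng = np.random.default_rng(51)
        cow = np.repeat(np.arange(100), 5)
        y = rng.normal(0, 0.3, 500)
        bad = rng.random(500) < 0.10
        y[bad] += rng.choice([-8, 8], bad.sum())
        data = pd.DataFrame({"cow_id": cow, "resp": y})
        fit = fit_mixed_model(data, "resp", [], ("cow_id",))
        assert not residual_diagnostics(fit)["passed"]
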