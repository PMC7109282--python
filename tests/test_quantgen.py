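"""Unit tests for mixed-mating quantitative genetics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from landqgen import quantgen
from landqgen._reml import anova_oneway, reml_oneway
from landqgen.datatypes import ProgenyTrialTable
from landqgen.simulate import TraitSimSpec, simulate_progeny_trial

from conftest import progeny_from_values
from oracles import brute_ols_slope


class TestMatingConstants:
    @pytest.mark.parametrize("f,s,theta,c", [
        (0.0, 0.0, 0.125, 0.25),
        (1.0, 1.0, 1.0, 2.0),
        (0.2, 1.0 / 3.0, 4.0 / 15.0, 8.0 / 15.0),
    ])
    def test_reference_points(self, f, s, theta, c):
        mc = quantgen.mating_constants(f)
        assert mc.s == pytest.approx(s, abs=1e-12)
        assert mc.theta == pytest.approx(theta, abs=1e-12)
        assert mc.c == pytest.approx(c, abs=1e-12)

    @given(st.floats(min_value=0.0, max_value=0.99))
    @settings(derandomize=True, max_examples=200, deadline=None)
    def test_c_identity_everywhere(self, f):
        mc = quantgen.mating_constants(f)
        alt = (1 + mc.s) ** 2 / (2 * (2 - mc.s))
        assert mc.c == pytest.approx(2 * mc.theta, abs=1e-12)
        assert mc.c == pytest.approx(alt, abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            quantgen.mating_constants(-0.1)
        with pytest.raises(ValueError):
            quantgen.mating_constants(1.2)


class TestGrowthRate:
    def test_flat_series_gives_zero(self):
        assert quantgen.growth_rate([76, 116, 133, 145], [10, 10, 10, 10]) == 0.0

    def test_exact_line_recovered(self):
        days = [76, 116, 133, 145]
        vals = [0.5 * d for d in days]
        assert quantgen.growth_rate(days, vals) == pytest.approx(0.5, abs=1e-12)

    def test_noisy_line_matches_normal_equations(self, rng):
        days = [76, 116, 133, 145]
        vals = [0.3 * d + 2 + rng.normal() for d in days]
        got = quantgen.growth_rate(days, vals)
        assert got == pytest.approx(brute_ols_slope(days, vals), abs=1e-12)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            quantgen.growth_rate([76], [10])


class TestGermination:
    def _table(self, flags):
        rows = []
        for i, g in enumerate(flags):
            rows.append(("L1", "S1", "F1", f"seed{i}", "germinated", float(g)))
            if g:
                rows.append(("L1", "S1", "F1", f"seed{i}", "TG", 10.0 + i))
        return ProgenyTrialTable(pd.DataFrame(
            rows, columns=["landscape", "site", "family", "individual",
                           "trait", "value"]))

    def test_proportion_germinated(self):
        tg, pg = quantgen.germination_summaries(self._table([1] * 7 + [0] * 3))
        assert pg["PG"].iloc[0] == pytest.approx(0.7)
        assert len(tg) == 7

    def test_none_germinated(self):
        tg, pg = quantgen.germination_summaries(self._table([0] * 5))
        assert pg["PG"].iloc[0] == 0.0
        assert tg.empty


class TestPruning:
    def test_perfect_pair_keeps_one(self, rng):
        x = rng.normal(size=60)
        wide = pd.DataFrame({"a": x, "b": 2 * x + 1, "c": rng.normal(size=60)})
        kept = quantgen.prune_correlated_traits(wide, threshold=0.5, keep=())
        assert len([t for t in kept if t in ("a", "b")]) == 1
        assert "c" in kept

    def test_uncorrelated_all_kept(self, rng):
        wide = pd.DataFrame(rng.normal(size=(80, 4)), columns=list("abcd"))
        kept = quantgen.prune_correlated_traits(wide, threshold=0.5, keep=())
        assert sorted(kept) == list("abcd")

    def test_greedy_matches_minimal_removal_on_toy(self, rng):
        # 4 traits with a known correlation cluster: exhaustive search over
        # removal subsets gives the smallest valid removal
        x = rng.normal(size=200)
        wide = pd.DataFrame({
            "a": x,
            "b": x + 0.1 * rng.normal(size=200),
            "c": x + 0.1 * rng.normal(size=200),
            "d": rng.normal(size=200),
        })
        kept = set(quantgen.prune_correlated_traits(wide, threshold=0.5, keep=()))
        best = None
        cols = list(wide.columns)
        for r in range(len(cols) + 1):
            for drop in itertools.combinations(cols, r):
                remain = [c for c in cols if c not in drop]
                corr = wide[remain].corr().abs().values
                np.fill_diagonal(corr, 0)
                if (corr <= 0.5).all():
                    best = set(remain)
                    break
            if best is not None:
                break
        assert len(kept) == len(best)

    def test_keep_list_never_dropped(self, rng):
        x = rng.normal(size=50)
        wide = pd.DataFrame({"a": x, "b": 2 * x})
        kept = quantgen.prune_correlated_traits(wide, threshold=0.5, keep=("b",))
        assert "b" in kept


class TestFamilyModel:
    def test_zero_family_effect(self):
        t = simulate_progeny_trial(TraitSimSpec(
            n_sites=1, families_per_site=25, offspring_per_family=10,
            var_between_pops=0, target_Va=0.0, var_residual=5.0, rng_seed=0))
        vd = quantgen.fit_family_model(t, "trait", f=0.0)
        assert vd.Va < 0.5
        assert vd.h2 < 0.1

    def test_reml_equals_anova_on_balanced_interior(self):
        t = simulate_progeny_trial(TraitSimSpec(
            n_sites=1, families_per_site=30, offspring_per_family=12,
            var_between_pops=0, target_Va=8.0, var_residual=6.0, rng_seed=3))
        sub = t.trait_frame("trait")
        y = sub["value"].to_numpy()
        fams = sub["family"].to_numpy()
        reml = reml_oneway(y, fams)
        mom = anova_oneway(y, fams)
        assert mom.sigma2_group > 0  # interior case
        assert reml.sigma2_group == pytest.approx(mom.sigma2_group, abs=1e-6)
        assert reml.sigma2_res == pytest.approx(mom.sigma2_res, abs=1e-6)

    def test_reml_matches_statsmodels_mixedlm(self):
        import statsmodels.formula.api as smf
        t = simulate_progeny_trial(TraitSimSpec(
            n_sites=1, families_per_site=20, offspring_per_family=8,
            target_Va=8.0, var_residual=6.0, rng_seed=12))
        sub = t.trait_frame("trait")
        mine = reml_oneway(sub["value"].to_numpy(), sub["family"].to_numpy())
        res = smf.mixedlm("value ~ 1", sub, groups="family").fit(reml=True)
        assert mine.sigma2_group == pytest.approx(float(res.cov_re.iloc[0, 0]),
                                                  rel=1e-4, abs=1e-6)
        assert mine.sigma2_res == pytest.approx(res.scale, rel=1e-4)
        assert mine.loglik == pytest.approx(res.llf, abs=1e-4)

    def test_va_scaling_at_f_zero(self):
        # Va = sigma2_fam/(2*theta) with theta(0) = 1/8, i.e. Va = 4 s2f
        t = simulate_progeny_trial(TraitSimSpec(
            n_sites=1, families_per_site=20, offspring_per_family=8,
            target_Va=4.0, var_residual=3.0, rng_seed=1))
        vd = quantgen.fit_family_model(t, "trait", f=0.0)
        assert vd.Va == pytest.approx(4.0 * vd.sigma2_fam, rel=1e-12)

    def test_family_variance_set_by_theta(self):
        spec = TraitSimSpec(target_Va=4.0, inbreeding_f=0.0)
        assert spec.sigma2_family == pytest.approx(1.0)

    def test_cva_scale_invariance_and_shift_sensitivity(self):
        t = simulate_progeny_trial(TraitSimSpec(
            n_sites=1, families_per_site=20, offspring_per_family=8,
            trait_mean=10.0, target_Va=4.0, var_residual=3.0, rng_seed=6))
        vd = quantgen.fit_family_model(t, "trait", f=0.0)
        scaled = ProgenyTrialTable(t.data.assign(value=t.data["value"] * 3.0))
        vd_scaled = quantgen.fit_family_model(scaled, "trait", f=0.0)
        assert vd_scaled.CVa_pct == pytest.approx(vd.CVa_pct, rel=1e-6)
        shifted = ProgenyTrialTable(t.data.assign(value=t.data["value"] + 50.0))
        vd_shifted = quantgen.fit_family_model(shifted, "trait", f=0.0)
        assert vd_shifted.CVa_pct != pytest.approx(vd.CVa_pct, rel=0.01)


class TestQstPst:
    def test_identical_population_means_near_zero(self):
        t = simulate_progeny_trial(TraitSimSpec(
            n_sites=6, families_per_site=15, offspring_per_family=8,
            var_between_pops=0.0, target_Va=2.0, var_residual=3.0, rng_seed=2))
        assert quantgen.qst(t, "trait", f=0.0) < 0.1

    def test_qst_affine_invariance(self):
        t = simulate_progeny_trial(TraitSimSpec(
            n_sites=4, families_per_site=10, offspring_per_family=8,
            var_between_pops=1.0, target_Va=2.0, var_residual=3.0, rng_seed=4))
        q = quantgen.qst(t, "trait", f=0.0)
        t2 = ProgenyTrialTable(t.data.assign(value=2.5 * t.data["value"] - 7.0))
        q2 = quantgen.qst(t2, "trait", f=0.0)
        assert q2 == pytest.approx(q, rel=1e-4)

    def test_pst_matches_direct_variance_ratio(self):
        # balanced toy where the one-way ANOVA components are exact
        t = progeny_from_values({
            "S1": {"F1": [1, 2, 3], "F2": [2, 3, 4]},
            "S2": {"F1": [5, 6, 7], "F2": [6, 7, 8]},
        })
        sub = t.trait_frame("trait")
        fit = anova_oneway(sub["value"].to_numpy(), sub["site"].to_numpy())
        want = fit.sigma2_group / (fit.sigma2_group + 2 * fit.sigma2_res)
        got = quantgen.pst(t, "trait")
        assert got == pytest.approx(want, abs=1e-6)

    def test_pst_equal_components_third(self):
        # large balanced sample with sigma2_pop == sigma2_within -> ~1/3
        rng = np.random.default_rng(11)
        vals = {}
        for i in range(24):
            site = f"S{i + 1}"
            mu = rng.normal(0, 1.0)
            vals[site] = {"F1": (mu + rng.normal(0, 1.0, 50)).tolist()}
        t = progeny_from_values(vals)
        assert quantgen.pst(t, "trait") == pytest.approx(1.0 / 3.0, abs=0.12)

    def test_additive_proportion_parameter(self):
        t = progeny_from_values({
            "S1": {"F1": [1, 2, 3, 4]}, "S2": {"F1": [6, 7, 8, 9]},
        })
        p_half = quantgen.pst(t, "trait", additive_proportion=0.5)
        p_one = quantgen.pst(t, "trait", additive_proportion=1.0)
        assert p_half < p_one


class TestDerivedTraits:
    def test_growth_series_expansion(self):
        rows = []
        for day, h in zip((76, 116, 133, 145), (10.0, 14.0, 15.7, 16.9)):
            rows.append(("L1", "S1", "F1", "o1", f"H@{day}", h))
        t = ProgenyTrialTable(pd.DataFrame(
            rows, columns=["landscape", "site", "family", "individual",
                           "trait", "value"]))
        out = quantgen.derive_growth_traits(t)
        wide = out.wide()
        assert wide["IH"].iloc[0] == 10.0
        assert wide["FH"].iloc[0] == 16.9
        days = [76, 116, 133, 145]
        vals = [10.0, 14.0, 15.7, 16.9]
        assert wide["HGR"].iloc[0] == pytest.approx(brute_ols_slope(days, vals))
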