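import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from agavenet.abundance import CountMatrix, aggregate_to_rank, relative_abundance
from agavenet.errors import ParameterError
from agavenet.stats import (
    CellSummary,
    anova2_from_summaries,
    anova2_raw,
    compare_guilds,
    guild_abundance,
)


def random_balanced(rng, n=6, effect_a=0.0, effect_b=0.0, effect_ab=0.0):
    rows = []
    for a in ("a0", "a1"):
        for b in ("b0", "b1"):
            mu = (
                effect_a * (a == "a1")
                + effect_b * (b == "b1")
                + effect_ab * (a == "a1") * (b == "b1")
            )
            for _ in range(n):
                rows.append((rng.normal(mu, 1.0), a, b))
    df = pd.DataFrame(rows, columns=["y", "A", "B"])
    return df["y"].to_numpy(), df["A"].to_numpy(), df["B"].to_numpy()


def summarize(values, fa, fb):
    cells = []
    for a in sorted(set(fa)):
        for b in sorted(set(fb)):
            v = values[(fa == a) & (fb == b)]
            cells.append(CellSummary(a, b, float(v.mean()), float(v.std(ddof=1)), len(v)))
    return cells


class TestAnova:
    def test_equal_cell_means_give_zero_f(self):
        cells = [
            CellSummary("a0", "b0", 5.0, 1.0, 4),
            CellSummary("a0", "b1", 5.0, 1.2, 4),
            CellSummary("a1", "b0", 5.0, 0.8, 4),
            CellSummary("a1", "b1", 5.0, 1.1, 4),
        ]
        res = anova2_from_summaries(cells)
        assert res.F_a == res.F_b == res.F_ab == 0.0

    def test_constant_raw_values_give_zero_f(self):
        y = np.full(8, 3.0)
        fa = np.array(["a0", "a0", "a0", "a0", "a1", "a1", "a1", "a1"])
        fb = np.tile(["b0", "b0", "b1", "b1"], 2)
        res = anova2_raw(y, fa, fb)
        assert res.F_a == res.F_b == res.F_ab == 0.0

    @pytest.mark.parametrize("seed", range(8))
    def test_summary_route_equals_raw_route(self, seed):
        rng = np.random.default_rng(seed)
        y, fa, fb = random_balanced(rng, n=5, effect_a=1.0, effect_ab=0.5)
        raw = anova2_raw(y, fa, fb)
        summ = anova2_from_summaries(summarize(y, fa, fb))
        for attr in ("F_a", "F_b", "F_ab"):
            assert getattr(raw, attr) == pytest.approx(getattr(summ, attr), abs=1e-9)

    def test_matches_statsmodels_decomposition(self):
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        rng = np.random.default_rng(3)
        y, fa, fb = random_balanced(rng, n=6, effect_a=2.0, effect_b=-1.0, effect_ab=1.0)
        res = anova2_raw(y, fa, fb)
        df = pd.DataFrame({"y": y, "A": fa, "B": fb})
        tab = sm.stats.anova_lm(ols("y ~ C(A) * C(B)", data=df).fit(), typ=2)
        assert res.F_a == pytest.approx(tab.loc["C(A)", "F"], rel=1e-9)
        assert res.F_b == pytest.approx(tab.loc["C(B)", "F"], rel=1e-9)
        assert res.F_ab == pytest.approx(tab.loc["C(A):C(B)", "F"], rel=1e-9)

    def test_sum_of_squares_additivity(self):
        rng = np.random.default_rng(5)
        y, fa, fb = random_balanced(rng, n=7, effect_a=1.5)
        res = anova2_raw(y, fa, fb)
        ss_total = float(((y - y.mean()) ** 2).sum())
        assert sum(res.ss.values()) == pytest.approx(ss_total, abs=1e-9)

    def test_null_f_mean_near_theoretical(self):
        # under H0, E[F] = df2 / (df2 - 2)
        rng = np.random.default_rng(11)
        fs = []
        for _ in range(500):
            y, fa, fb = random_balanced(rng, n=4)
            fs.append(anova2_raw(y, fa, fb).F_a)
        df2 = 4 * (4 - 1)
        expect = df2 / (df2 - 2)
        assert np.mean(fs) == pytest.approx(expect, rel=0.2)

    def test_factor_effect_raises_only_its_f(self):
        rng = np.random.default_rng(2)
        fa_med, fb_med = [], []
        for _ in range(100):
            y, fa, fb = random_balanced(rng, n=6, effect_a=3.0)
            r = anova2_raw(y, fa, fb)
            fa_med.append(r.F_a)
            fb_med.append(r.F_b)
        assert np.median(fa_med) > 20
        assert np.median(fb_med) < 5

    def test_unbalanced_cells_rejected(self):
        cells = [
            CellSummary("a0", "b0", 1, 1, 4),
            CellSummary("a0", "b1", 1, 1, 4),
            CellSummary("a1", "b0", 1, 1, 4),
            CellSummary("a1", "b1", 1, 1, 5),
        ]
        with pytest.raises(ParameterError, match="nbalanced"):
            anova2_from_summaries(cells)

    def test_incomplete_grid_rejected(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        with pytest.raises(ParameterError):
            anova2_raw(y, ["a0", "a0", "a1", "a1"], ["b0", "b0", "b0", "b0"])

    def test_log_transform_requires_positive_values(self):
        y = np.array([1.0, -2.0, 3.0, 4.0, 1, 1, 1, 1])
        fa = ["a0"] * 4 + ["a1"] * 4
        fb = ["b0", "b0", "b1", "b1"] * 2
        with pytest.raises(ParameterError, match="positive"):
            anova2_raw(y, fa, fb, log_transform=True)


class TestGuilds:
    def traits(self):
        return pd.DataFrame(
            {
                "genus": ["gA", "gB", "gB", "gC"],
                "category": ["N_fixation", "N_fixation", "EPS", "EPS"],
                "class": ["nutrient_cycling"] * 2 + ["environmental_adaptation"] * 2,
            }
        )

    def test_additivity_of_member_proportions(self):
        relab = pd.DataFrame({"s0": [0.10, 0.05, 0.85]}, index=["gA", "gB", "gC"])
        g, _ = guild_abundance(relab, self.traits())
        assert g.loc["N_fixation", "s0"] == pytest.approx(0.15)

    def test_multi_category_genus_counts_in_each(self):
        relab = pd.DataFrame({"s0": [0.2, 0.8]}, index=["gB", "gC"])
        g, _ = guild_abundance(relab, self.traits())
        assert g.loc["N_fixation", "s0"] == pytest.approx(0.2)
        assert g.loc["EPS", "s0"] == pytest.approx(1.0)

    def test_unmapped_genus_reported_not_fatal(self):
        relab = pd.DataFrame({"s0": [0.4, 0.6]}, index=["gA", "gX"])
        g, rep = guild_abundance(relab, self.traits())
        assert rep["unmapped_genera"] == ["gX"]
        assert rep["unmapped_fraction"] == pytest.approx(0.6)

    def test_matches_brute_force_double_loop(self, rng):
        genera = [f"g{i}" for i in range(12)]
        relab = pd.DataFrame(rng.dirichlet(np.ones(12), size=4).T, index=genera)
        rows = [
            (g, c)
            for g in genera
            for c in ("c1", "c2", "c3")
            if rng.random() < 0.4
        ]
        traits = pd.DataFrame(rows, columns=["genus", "category"])
        traits["class"] = "x"
        g, _ = guild_abundance(relab, traits)
        for cat in g.index:
            for s in relab.columns:
                expect = sum(
                    relab.loc[gen, s]
                    for gen, c in rows
                    if c == cat
                )
                assert g.loc[cat, s] == pytest.approx(expect, abs=1e-12)

    def test_empty_trait_table_rejected(self):
        with pytest.raises(ParameterError):
            guild_abundance(pd.DataFrame({"s": [1.0]}), pd.DataFrame())

    def test_constant_category_not_significant(self, small_bundle):
        meta = small_bundle.metadata
        guilds = pd.DataFrame(
            {s: [0.25] for s in meta.index}, index=["flat"]
        )
        out = compare_guilds(guilds, meta)
        assert out.loc["flat", "F_soil_type"] == 0.0
        assert not out.loc["flat", "significant_soil_type"]

    def test_boosted_guild_detected_in_most_simulations(self):
        # rhizosphere boosts N-fixer growth; the soil-type F for that guild
        # should clear the 95% F quantile in the large majority of studies
        from agavenet.simulate import StudyDesign, make_study

        hits = n = 0
        crit = sps.f(1, 4 * (4 - 1)).ppf(0.95)  # n=4 per cell in this design
        for seed in range(25):
            d = StudyDesign(n_sites=2, n_replicates=2, depth_range=(3000, 5000))
            b = make_study(design=d, n_taxa=30, n_genera=20, effect_size=0.5, seed=seed)
            cm = aggregate_to_rank(CountMatrix(b.counts), b.taxonomy)
            relab = relative_abundance(cm)
            g, _ = guild_abundance(relab, b.traits)
            if "N_fixation" not in g.index or g.loc["N_fixation"].sum() == 0:
                continue
            res = anova2_raw(
                g.loc["N_fixation"].to_numpy(),
                b.metadata["soil_type"].to_numpy(),
                b.metadata["season"].to_numpy(),
            )
            hits += res.F_a > crit
            n += 1
        assert n >= 20
        assert hits / n >= 0.8

    def test_shuffled_labels_flag_near_nominal_rate(self, small_bundle):
        rng = np.random.default_rng(17)
        meta = small_bundle.metadata
        cm = aggregate_to_rank(CountMatrix(small_bundle.counts), small_bundle.taxonomy)
        relab = relative_abundance(cm)
        g, _ = guild_abundance(relab, small_bundle.traits)
        g = g.loc[g.sum(axis=1) > 0]
        sig = tot = 0
        for _ in range(20):
            shuffled = meta.copy()
            perm = rng.permutation(len(meta))
            shuffled[["soil_type", "season"]] = meta[["soil_type", "season"]].to_numpy()[perm]
            out = compare_guilds(g, shuffled)
            sig += int((out["p_soil_type"] <= 0.05).sum())
            tot += len(out)
        # raw-p positive rate should be near 5%; guild overlap makes tests
        # dependent, so allow a wide band
        assert sig / tot < 0.15
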