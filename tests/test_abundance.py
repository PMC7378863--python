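import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import bruteforce as bf
from agavenet.abundance import (
    CountMatrix,
    aggregate_to_rank,
    alpha_diversity,
    filter_by_bootstrap,
    filter_min_relabund,
    rarefy,
    read_count_table,
    relative_abundance,
    write_count_table,
)
from agavenet.errors import FormatError, ParameterError


def toy_cm(data, taxa=None, samples=None):
    taxa = taxa or [f"t{i}" for i in range(len(data))]
    samples = samples or [f"s{j}" for j in range(len(data[0]))]
    return CountMatrix(pd.DataFrame(data, index=taxa, columns=samples))


class TestIO:
    def test_round_trip_identity(self, small_bundle, tmp_path):
        cm = CountMatrix(small_bundle.counts)
        p = tmp_path / "c.tsv"
        write_count_table(cm, p)
        back = read_count_table(p)
        pd.testing.assert_frame_equal(back.counts, cm.counts)

    def test_toy_parse(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("taxon\ts1\ts2\na\t1\t2\nb\t3\t4\n")
        cm = read_count_table(p)
        assert cm.counts.loc["b", "s2"] == 4

    def test_duplicate_sample_column_errors_with_name(self, tmp_path):
        p = tmp_path / "d.tsv"
        p.write_text("taxon\ts1\ts1\na\t1\t2\n")
        with pytest.raises(FormatError, match="s1"):
            read_count_table(p)

    def test_negative_cell_errors_with_coordinates(self, tmp_path):
        p = tmp_path / "n.tsv"
        p.write_text("taxon\ts1\na\t-3\n")
        with pytest.raises(FormatError, match="a"):
            read_count_table(p)

    def test_fractional_cell_rejected(self, tmp_path):
        p = tmp_path / "f.tsv"
        p.write_text("taxon\ts1\na\t1.5\n")
        with pytest.raises(FormatError, match="s1"):
            read_count_table(p)


class TestRarefy:
    def test_columns_sum_exactly_to_depth(self, small_bundle):
        cm = CountMatrix(small_bundle.counts)
        r = rarefy(cm, depth=1500, seed=1)
        assert (r.counts.sum(axis=0) == 1500).all()

    def test_default_depth_is_min_library(self, small_bundle):
        cm = CountMatrix(small_bundle.counts)
        r = rarefy(cm, seed=0)
        assert (r.counts.sum(axis=0) == cm.library_sizes.min()).all()

    def test_full_depth_returns_library_unchanged(self):
        cm = toy_cm([[60], [40]])
        r = rarefy(cm, depth=100, seed=3)
        pd.testing.assert_frame_equal(r.counts, cm.counts)

    def test_seed_determinism(self, small_bundle):
        cm = CountMatrix(small_bundle.counts)
        a = rarefy(cm, depth=1000, seed=9).counts
        b = rarefy(cm, depth=1000, seed=9).counts
        pd.testing.assert_frame_equal(a, b)

    def test_excess_depth_lists_offending_samples(self):
        cm = toy_cm([[60, 5], [40, 5]])
        with pytest.raises(ParameterError, match="s1"):
            rarefy(cm, depth=50)

    def test_mean_matches_hypergeometric_expectation(self):
        # 9000/1000 reads, subsample 1000: E[taxon0] = 900, exact variance known
        cm = toy_cm([[9000], [1000]])
        n_rep = 500
        draws = np.array(
            [rarefy(cm, depth=1000, seed=s).counts.iloc[0, 0] for s in range(n_rep)]
        )
        var = sps.hypergeom(10_000, 9000, 1000).var()
        half = sps.norm.ppf(0.9995) * np.sqrt(var / n_rep)
        assert abs(draws.mean() - 900) < half


class TestRelativeAbundance:
    def test_direct_normalization(self):
        rel = relative_abundance(toy_cm([[3], [1]]).counts)
        assert np.allclose(rel.to_numpy().ravel(), [0.75, 0.25])

    def test_columns_sum_to_one(self, small_bundle):
        rel = relative_abundance(small_bundle.counts)
        assert np.allclose(rel.sum(axis=0), 1.0, atol=1e-12)

    def test_idempotent_on_normalized_input(self, small_bundle):
        rel = relative_abundance(small_bundle.counts)
        again = relative_abundance(rel)
        assert np.allclose(rel.to_numpy(), again.to_numpy(), atol=1e-12)

    def test_zero_column_rejected(self):
        with pytest.raises(ParameterError, match="s0"):
            relative_abundance(toy_cm([[0], [0]]).counts)


class TestBootstrapFilter:
    def make_tax(self, confs):
        return pd.DataFrame(
            {"genus": [f"g{i}" for i in range(len(confs))], "genus_conf": confs},
            index=[f"t{i}" for i in range(len(confs))],
        )

    def test_full_confidence_keeps_everything(self):
        cm = toy_cm([[1], [2], [3]])
        out, rep = filter_by_bootstrap(cm, self.make_tax([1.0, 1.0, 1.0]))
        assert out.counts.shape[0] == 3 and rep["discarded_fraction"] == 0

    def test_threshold_boundary_is_inclusive(self):
        cm = toy_cm([[1], [1], [1]])
        out, rep = filter_by_bootstrap(cm, self.make_tax([0.79, 0.80, 0.81]))
        assert out.taxa == ["t1", "t2"]
        assert rep["discarded_taxa"] == ["t0"]

    def test_discarded_fraction_reports_read_share(self):
        # dropped taxon holds 5 of 100 reads
        cm = toy_cm([[50], [45], [5]])
        out, rep = filter_by_bootstrap(cm, self.make_tax([0.99, 0.95, 0.5]))
        assert rep["discarded_fraction"] == pytest.approx(0.05)

    def test_unknown_rank_rejected(self):
        cm = toy_cm([[1]])
        with pytest.raises(ParameterError, match="family"):
            filter_by_bootstrap(cm, self.make_tax([1.0]), rank="family")


class TestMinRelabundFilter:
    def test_below_threshold_removed_inclusive_boundary_kept(self):
        rel = pd.DataFrame(
            {"s0": [0.009, 0.01, 0.981]}, index=["low", "edge", "big"]
        )
        out = filter_min_relabund(rel, 0.01)
        assert list(out.index) == ["edge", "big"]

    def test_matches_row_max_scan(self, rng):
        rel = pd.DataFrame(rng.dirichlet(np.ones(25) * 0.3, size=6).T)
        out = filter_min_relabund(rel, 0.01)
        expect = [i for i in rel.index if rel.loc[i].max() >= 0.01]
        assert list(out.index) == expect

    def test_mean_scope(self):
        rel = pd.DataFrame({"s0": [0.5, 0.5], "s1": [0.995, 0.005]}, index=["a", "b"])
        out = filter_min_relabund(rel, 0.3, scope="mean")
        assert list(out.index) == ["a"]

    def test_no_renormalization_applied(self):
        rel = pd.DataFrame({"s0": [0.6, 0.3, 0.1]}, index=["a", "b", "c"])
        out = filter_min_relabund(rel, 0.2)
        assert out["s0"].sum() == pytest.approx(0.9)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 2.0])
    def test_threshold_domain(self, bad):
        with pytest.raises(ParameterError):
            filter_min_relabund(pd.DataFrame({"s": [1.0]}), bad)


class TestAggregate:
    def make_tax(self, genera):
        return pd.DataFrame(
            {"genus": genera, "genus_conf": [1.0] * len(genera)},
            index=[f"t{i}" for i in range(len(genera))],
        )

    def test_same_genus_counts_add(self):
        cm = toy_cm([[3], [4]])
        out = aggregate_to_rank(cm, self.make_tax(["g", "g"]))
        assert out.counts.loc["g", "s0"] == 7

    def test_column_totals_conserved(self, small_bundle):
        cm = CountMatrix(small_bundle.counts)
        out = aggregate_to_rank(cm, small_bundle.taxonomy)
        assert (out.counts.sum(axis=0) == cm.counts.sum(axis=0)).all()

    def test_matches_brute_force_groupby(self, rng):
        data = rng.integers(0, 50, size=(5, 3))
        genera = ["gA", "gB", "gA", "gC", "gB"]
        cm = toy_cm(data.tolist())
        out = aggregate_to_rank(cm, self.make_tax(genera))
        for g in ("gA", "gB", "gC"):
            rows = [i for i, x in enumerate(genera) if x == g]
            assert np.array_equal(out.counts.loc[g].to_numpy(), data[rows].sum(axis=0))

    def test_commutes_with_bootstrap_filter(self, small_bundle):
        cm = CountMatrix(small_bundle.counts)
        tax = small_bundle.taxonomy
        a = aggregate_to_rank(filter_by_bootstrap(cm, tax)[0], tax).counts
        keep = tax.index[tax["genus_conf"] >= 0.80]
        pre = cm.with_counts(cm.counts.loc[cm.counts.index.intersection(keep)])
        b = aggregate_to_rank(pre, tax).counts
        pd.testing.assert_frame_equal(a, b)


class TestAlphaDiversity:
    def test_uniform_sample_reaches_maximum_entropy(self):
        rec = alpha_diversity(toy_cm([[5]] * 8)).iloc[0]
        assert rec["shannon"] == pytest.approx(np.log(8), abs=1e-12)

    def test_single_taxon_degenerate_values(self):
        rec = alpha_diversity(toy_cm([[17]])).iloc[0]
        assert rec["observed"] == 1 and rec["shannon"] == 0
        assert rec["simpson"] == 0 and rec["chao1"] == 1

    def test_chao1_closed_form_with_singletons_and_doubletons(self):
        # F1=3, F2=1: chao1 = 6 + 3*2/(2*2) = 7.5
        rec = alpha_diversity(toy_cm([[5], [5], [2], [1], [1], [1]])).iloc[0]
        assert rec["chao1"] == pytest.approx(7.5)

    def test_matches_direct_formulas_on_random_vectors(self, rng):
        for _ in range(20):
            v = rng.integers(0, 20, size=30)
            if v.sum() == 0:
                continue
            rec = alpha_diversity(toy_cm([[x] for x in v])).iloc[0]
            assert rec["shannon"] == pytest.approx(bf.shannon(v), abs=1e-10)
            assert rec["chao1"] == pytest.approx(bf.chao1(v), abs=1e-10)
            assert rec["simpson"] == pytest.approx(bf.simpson(v), abs=1e-10)

    def test_chao1_never_below_observed(self, small_bundle):
        div = alpha_diversity(CountMatrix(small_bundle.counts))
        assert (div["chao1"] >= div["observed"] - 1e-9).all()

    def test_shannon_invariant_to_merging_identical_samples(self):
        one = alpha_diversity(toy_cm([[10], [30], [60]])).iloc[0]["shannon"]
        merged = alpha_diversity(toy_cm([[20], [60], [120]])).iloc[0]["shannon"]
        assert one == pytest.approx(merged, abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ParameterError):
            alpha_diversity(toy_cm([[0]]))
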