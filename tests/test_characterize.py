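"""Rarefaction, filters, moment estimation and rank aggregation."""

import numpy as np
import pandas as pd
import pytest

from microzinb import (
    ZinbParams,
    aggregate_to_rank,
    characterize_cohort,
    estimate_taxon_zinb_moments,
    filter_low_abundance,
    rarefy,
    zinb_rvs,
)


def _matrix(rows, index=None, columns=None):
    return pd.DataFrame(rows, index=index, columns=columns)


class TestRarefy:
    def test_retained_columns_sum_to_depth_exactly(self):
        counts = _matrix({"a": [9000, 1000], "b": [3000, 2500]}, index=["t1", "t2"])
        r, dropped = rarefy(counts, depth=5000, seed=1)
        assert (r.sum(axis=0) == 5000).all()
        assert dropped == []

    def test_shallow_sample_is_dropped_and_reported(self):
        counts = _matrix({"deep": [4000, 2000], "shallow": [2500, 2499]}, index=["t1", "t2"])
        r, dropped = rarefy(counts, depth=5000, seed=2)
        assert dropped == ["shallow"]
        assert list(r.columns) == ["deep"]

    def test_cells_never_exceed_original_counts(self):
        counts = _matrix({"a": [5000, 100, 900]}, index=["t1", "t2", "t3"])
        r, _ = rarefy(counts, depth=5000, seed=3)
        assert (r["a"] <= counts["a"]).all() and (r["a"] >= 0).all()

    def test_subsampling_matches_hypergeometric_oracle(self):
        # (9000, 1000) at depth 5000: taxon 2 count ~ Hypergeom(N=10000, K=1000, n=5000)
        counts = _matrix({"s": [9000, 1000]}, index=["t1", "t2"])
        draws = []
        for seed in range(2000):
            r, _ = rarefy(counts, depth=5000, seed=seed)
            draws.append(int(r.loc["t2", "s"]))
        mean = 5000 * 1000 / 10000
        var = 5000 * 0.1 * 0.9 * (10000 - 5000) / (10000 - 1)
        assert abs(np.mean(draws) - mean) < 3 * np.sqrt(var / len(draws))

    def test_nonpositive_depth_is_an_error(self):
        with pytest.raises(ValueError):
            rarefy(_matrix({"a": [10]}), depth=0)


class TestFilter:
    def test_strict_less_than_boundary_at_15(self):
        counts = _matrix(
            {"s1": [14, 15, 100]}, index=["low", "edge", "high"]
        )
        kept = filter_low_abundance(counts, 15)
        assert list(kept.index) == ["edge", "high"]

    def test_toy_matrix_at_30(self):
        counts = _matrix({"s1": [1, 29, 30, 31, 500]}, index=list("abcde"))
        kept = filter_low_abundance(counts, 30)
        assert list(kept.index) == ["c", "d", "e"]

    def test_zero_threshold_is_identity_and_order_preserving(self):
        counts = _matrix({"s1": [5, 0, 2]}, index=["z", "a", "m"])
        pd.testing.assert_frame_equal(filter_low_abundance(counts, 0), counts)


class TestMomentEstimator:
    def test_recovers_zinb_truth(self):
        rng = np.random.default_rng(41)
        y = zinb_rvs(ZinbParams(mu=10, theta=1, phi=0.4), 5000, rng)
        c = estimate_taxon_zinb_moments(y)
        assert c.phi_hat == pytest.approx(0.4, abs=0.05)
        assert c.inv_theta_hat == pytest.approx(1.0, abs=0.3)
        assert c.zero_inflated

    def test_plain_nb_is_not_called_zero_inflated(self):
        rng = np.random.default_rng(42)
        y = zinb_rvs(ZinbParams(mu=10, theta=0.5, phi=0.0), 5000, rng)
        c = estimate_taxon_zinb_moments(y)
        assert c.phi_hat < 0.05
        assert not c.zero_inflated

    def test_nb_part_dispersion_not_above_whole_part(self):
        rng = np.random.default_rng(43)
        y = zinb_rvs(ZinbParams(mu=10, theta=1, phi=0.5), 5000, rng)
        c = estimate_taxon_zinb_moments(y)
        assert c.inv_theta_nb_hat <= c.inv_theta_hat + 0.15

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError):
            estimate_taxon_zinb_moments(np.zeros(100, dtype=int))
        with pytest.raises(ValueError):
            estimate_taxon_zinb_moments(np.full(100, 7))

    def test_sampling_noise_shrinks_with_n(self):
        # doubling n should roughly halve the sd of phi_hat (rate ~ 1/sqrt(n))
        sds = []
        for n in (2500, 5000, 10000):
            ests = []
            for rep in range(25):
                rng = np.random.default_rng(1000 * n + rep)
                y = zinb_rvs(ZinbParams(mu=10, theta=1, phi=0.3), n, rng)
                ests.append(estimate_taxon_zinb_moments(y).phi_hat)
            sds.append(np.std(ests))
        assert sds[0] > sds[2]
        ratio = sds[0] / sds[2]  # expected ~2 for a root-n estimator
        assert 1.2 < ratio < 3.5


class TestAggregate:
    taxonomy = pd.Series(
        {
            "a1": "d:Bacteria,p:Firmicutes,f:Lachnospiraceae,g:Blautia",
            "a2": "d:Bacteria,p:Firmicutes,f:Lachnospiraceae,g:Blautia",
            "a3": "d:Bacteria,p:Firmicutes,f:Lachnospiraceae,g:Roseburia",
            "a4": "d:Bacteria,p:Bacteroidota,f:Bacteroidaceae,g:Bacteroides",
            "a5": "d:Bacteria,p:Bacteroidota,f:Bacteroidaceae,g:Bacteroides",
            "a6": "d:Bacteria,p:Bacteroidota,f:Bacteroidaceae,g:Bacteroides",
        }
    )
    counts = pd.DataFrame(
        np.arange(12).reshape(6, 2), index=["a1", "a2", "a3", "a4", "a5", "a6"], columns=["s1", "s2"]
    )

    def test_same_genus_rows_are_summed(self):
        g = aggregate_to_rank(self.counts, self.taxonomy, "genus")
        assert g.loc["Blautia"].tolist() == [0 + 2, 1 + 3]

    def test_rank_counts_match_hand_aggregation(self):
        assert len(aggregate_to_rank(self.counts, self.taxonomy, "genus")) == 3
        assert len(aggregate_to_rank(self.counts, self.taxonomy, "family")) == 2

    def test_totals_conserved_per_sample(self):
        for rank in ("genus", "family", "phylum"):
            agg = aggregate_to_rank(self.counts, self.taxonomy, rank)
            pd.testing.assert_series_equal(agg.sum(axis=0), self.counts.sum(axis=0))

    def test_asv_rank_is_identity(self):
        pd.testing.assert_frame_equal(aggregate_to_rank(self.counts, self.taxonomy, "asv"), self.counts)

    def test_unassigned_rank_pools_to_unclassified(self):
        tax = self.taxonomy.copy()
        tax["a1"] = "d:Bacteria,p:Firmicutes"
        g = aggregate_to_rank(self.counts, tax, "genus")
        assert "unclassified" in g.index

    def test_missing_lineage_is_an_error_naming_taxa(self):
        with pytest.raises(ValueError, match="a6"):
            aggregate_to_rank(self.counts, self.taxonomy.drop("a6"), "genus")


def _synthetic_cohort_counts(n_nb=30, n_zinb=10, n_samples=300, phi=0.9, seed=44):
    rng = np.random.default_rng(seed)
    rows, names = [], []
    for i in range(n_nb):
        rows.append(zinb_rvs(ZinbParams(mu=20, theta=0.8, phi=0.0), n_samples, rng))
        names.append(f"nb{i}")
    for i in range(n_zinb):
        rows.append(zinb_rvs(ZinbParams(mu=20, theta=0.8, phi=phi), n_samples, rng))
        names.append(f"zi{i}")
    return pd.DataFrame(rows, index=names), names[n_nb:]


class TestCohort:
    def test_recovers_built_in_zero_inflation_structure(self):
        counts, zi_names = _synthetic_cohort_counts()
        res = characterize_cohort(counts)
        assert res["summary"]["zero_inflated_fraction"] == pytest.approx(0.25, abs=0.1)
        assert res["summary"]["mean_phi_zero_inflated"] == pytest.approx(0.9, abs=0.05)

    def test_poisson_cohort_shows_no_overdispersion(self):
        rng = np.random.default_rng(45)
        counts = pd.DataFrame(rng.poisson(15.0, size=(20, 300)))
        counts.index = [f"t{i}" for i in range(20)]
        res = characterize_cohort(counts)
        assert res["summary"]["overdispersed_fraction"] == 0.0

    def test_single_taxon_matrix(self):
        rng = np.random.default_rng(46)
        counts = pd.DataFrame([rng.poisson(5.0, 100)], index=["only"])
        res = characterize_cohort(counts)
        assert res["summary"]["n_taxa"] == 1

    def test_empty_matrix_is_an_error(self):
        with pytest.raises(ValueError):
            characterize_cohort(pd.DataFrame())


def test_zero_inflation_fraction_decreases_with_rank_on_built_in_fixture():
    # independent extra zeros on each ASV: pooling to genus/phylum multiplies the
    # chance that all members dropped out, so aggregated counts are less inflated
    rng = np.random.default_rng(47)
    n_samples = 400
    rows, lineages = [], {}
    for p in range(2):
        for g in range(3):
            for a in range(3):
                name = f"p{p}g{g}a{a}"
                rows.append((name, zinb_rvs(ZinbParams(mu=15, theta=1.5, phi=0.5), n_samples, rng)))
                lineages[name] = f"d:Bacteria,p:Phy{p},g:Genus{p}{g}"
    counts = pd.DataFrame(dict(rows)).T
    taxonomy = pd.Series(lineages)
    fracs = []
    for rank in ("asv", "genus", "phylum"):
        agg = aggregate_to_rank(counts, taxonomy, rank)
        fracs.append(characterize_cohort(agg)["summary"]["zero_inflated_fraction"])
    assert fracs[0] >= fracs[1] >= fracs[2]
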