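"""KING-robust kinship, classification, networks, trios, sibling expectations."""

import numpy as np
import pytest

from genokit import relatedness
from genokit.relatedness import KinshipRecord, classify_pair
from genokit.simdata import SimConfig, sim_pedigree_cohort
from oracles import mom_ibd_kinship


def _pedigree(n_families, templates, seed=0, n_sites=20_000, error=0.0, **kw):
    config = SimConfig(seed=seed, n_sites=n_sites, genotype_error_rate=error)
    return sim_pedigree_cohort(n_families, templates, config, **kw)


class TestKingEstimator:
    def test_duplicate_pair_is_exactly_half(self):
        cohort, truth = _pedigree(2, ["duplicate"], n_sites=5000)
        recs = relatedness.king_kinship(cohort, report_all=True)
        dups = [r for r in recs if frozenset((r.i, r.j)) in truth.kinship]
        assert len(dups) == 2
        for r in dups:
            assert r.kinship == 0.5
            assert r.ibs0 == 0.0
            assert r.klass == "duplicate/MZ"

    def test_parent_offspring_unbiased_with_zero_ibs0(self):
        cohort, truth = _pedigree(20, ["parent-offspring"], seed=5, n_sites=50_000)
        pairs = [tuple(sorted(k)) for k in truth.kinship]
        recs = relatedness.king_kinship(cohort, pairs=pairs)
        assert len(recs) == 20
        phis = np.array([r.kinship for r in recs])
        assert abs(phis.mean() - 0.25) < 0.01
        for r in recs:
            assert r.ibs0 == 0.0     # Mendelian transmission forbids opposite homs
            assert r.klass == "parent-offspring"

    def test_unrelated_pairs_in_structured_cohort_stay_near_zero(self):
        # two diverged subpopulations; the estimator never pools frequencies,
        # so unrelated same-population pairs are unbiased despite structure
        rng = np.random.default_rng(7)
        from test_pca import _cohort_from_calls
        n_sites = 20_000
        fa = rng.beta(0.5, 0.5, n_sites)
        fb = rng.beta(0.5, 0.5, n_sites)
        calls = np.vstack([rng.binomial(2, fa, size=(6, n_sites)),
                           rng.binomial(2, fb, size=(6, n_sites))])
        cohort = _cohort_from_calls(calls)
        ids = cohort.samples["sample_id"].tolist()
        same_pop = [(ids[i], ids[j]) for g in (range(6), range(6, 12))
                    for k, i in enumerate(g) for j in list(g)[k + 1:]]
        recs = relatedness.king_kinship(cohort, pairs=same_pop, report_all=True)
        assert len(recs) == 30
        for r in recs:
            assert abs(r.kinship) < 0.02

    def test_symmetry_and_allele_swap_invariance(self):
        cohort, _ = _pedigree(3, ["full-sib"], n_sites=3000)
        ids = cohort.samples["sample_id"].tolist()
        fwd = relatedness.king_kinship(cohort, pairs=[(ids[0], ids[1])])
        rev = relatedness.king_kinship(cohort, pairs=[(ids[1], ids[0])])
        assert fwd[0].kinship == rev[0].kinship
        swapped = cohort.copy()
        flip = np.arange(0, cohort.n_markers, 3)
        keep_missing = swapped.calls[:, flip] < 0
        swapped.calls[:, flip] = np.where(keep_missing, swapped.calls[:, flip],
                                          2 - swapped.calls[:, flip])
        again = relatedness.king_kinship(swapped, pairs=[(ids[0], ids[1])])
        assert again[0].kinship == pytest.approx(fwd[0].kinship, abs=1e-12)
        assert again[0].ibs0 == pytest.approx(fwd[0].ibs0, abs=1e-12)

    def test_block_size_independence(self):
        cohort, _ = _pedigree(4, ["half-sib"], n_sites=5000)
        a = relatedness.king_kinship(cohort, report_all=True, block_size=7)
        b = relatedness.king_kinship(cohort, report_all=True, block_size=100000)
        assert [(r.i, r.j, r.kinship, r.ibs0) for r in a] \
            == [(r.i, r.j, r.kinship, r.ibs0) for r in b]

    def test_agrees_with_frequency_based_ibd_oracle(self):
        templates = ["duplicate", "parent-offspring", "full-sib", "half-sib",
                     "grandparent", "avuncular", "first-cousin", "unrelated"]
        cohort, truth = _pedigree(40, templates, seed=13, n_sites=20_000)
        pairs = [tuple(sorted(k)) for k in truth.kinship]
        recs = relatedness.king_kinship(cohort, pairs=pairs)
        rec_of = {frozenset((r.i, r.j)): r for r in recs}
        freqs = cohort.alt_allele_frequency()
        idx = {s: k for k, s in enumerate(cohort.samples["sample_id"])}
        agree = 0
        for (a, b) in pairs:
            r = rec_of.get(frozenset((a, b)))
            phi_king = r.kinship if r is not None else 0.0
            ibs0 = r.ibs0 if r is not None else \
                float(((cohort.calls[idx[a]] - cohort.calls[idx[b]]) ** 2 == 4).mean())
            phi_mom = mom_ibd_kinship(cohort.calls[idx[a]], cohort.calls[idx[b]], freqs)
            if classify_pair(phi_king, ibs0) == classify_pair(phi_mom, ibs0):
                agree += 1
        assert agree / len(pairs) >= 0.99


class TestClassification:
    def test_first_degree_split_by_ibs0(self):
        assert classify_pair(0.26, 0.0001) == "parent-offspring"
        assert classify_pair(0.26, 0.01) == "full-sib"

    def test_boundaries_partition_the_kinship_axis(self, rng):
        for phi in np.concatenate([rng.uniform(0, 0.5, 200),
                                   2.0 ** -np.array([1.5, 2.5, 3.5, 4.5])]):
            klass = classify_pair(phi, 0.05)
            assert klass in relatedness.CLASS_ORDER
        # band edges belong to the closer class
        assert classify_pair(2 ** -1.5 + 1e-12, 0.05) == "duplicate/MZ"
        assert classify_pair(2 ** -1.5, 0.05) == "full-sib"
        assert classify_pair(2 ** -3.5, 0.05) == "third-degree"

    def test_template_cohort_classified_correctly(self):
        templates = ["duplicate", "parent-offspring", "full-sib", "half-sib",
                     "grandparent", "avuncular", "first-cousin"]
        expected = {0.5: "duplicate/MZ", 0.25: ("parent-offspring", "full-sib"),
                    0.125: "second-degree", 0.0625: "third-degree"}
        cohort, truth = _pedigree(70, templates, seed=3, n_sites=50_000)
        pairs = {tuple(sorted(k)): v for k, v in truth.kinship.items()}
        recs = relatedness.king_kinship(cohort, pairs=list(pairs))
        assert len(recs) == 70
        good = sum(
            1 for r in recs
            if r.klass in np.atleast_1d(expected[pairs[tuple(sorted((r.i, r.j)))]])
        )
        assert good / 70 >= 0.99


class TestNetworks:
    def _records(self, edges):
        return [KinshipRecord(a, b, k, 0.01, 1000, c) for a, b, k, c in edges]

    def test_no_records_no_networks(self):
        nets, counts = relatedness.build_networks([])
        assert nets == [] and counts.empty

    def test_sibling_chain_is_one_component(self):
        recs = self._records([("A", "B", 0.25, "full-sib"),
                              ("B", "C", 0.25, "full-sib")])
        nets, counts = relatedness.build_networks(recs)
        assert len(nets) == 1 and nets[0].size == 3
        assert nets[0].signature == ("full-sib", "full-sib")
        assert counts.loc["B", "full-sib"] == 2

    def test_census_counts_configurations(self):
        recs = self._records([("A", "B", 0.25, "full-sib"),
                              ("C", "D", 0.25, "full-sib"),
                              ("E", "F", 0.25, "parent-offspring")])
        nets, _ = relatedness.build_networks(recs)
        census = relatedness.network_census(nets)
        assert census[("full-sib",)] == 2
        assert census[("parent-offspring",)] == 1

    def test_min_class_filters_third_degree(self):
        recs = self._records([("A", "B", 0.07, "third-degree"),
                              ("C", "D", 0.25, "full-sib")])
        nets, _ = relatedness.build_networks(recs, min_class="second-degree")
        assert len(nets) == 1 and nets[0].members == ("C", "D")


class TestTriosQuartets:
    def test_quartet_family_yields_two_trios_one_quartet(self):
        cohort, truth = _pedigree(1, ["full-sib"], n_sites=20_000,
                                  include_parents=True)
        recs = relatedness.king_kinship(cohort)
        ages = dict(zip(cohort.samples["sample_id"], cohort.samples["age"]))
        sexes = dict(zip(cohort.samples["sample_id"], cohort.samples["inferred_sex"]))
        found = relatedness.find_trios_quartets(recs, ages, sexes)
        assert len(found["trios"]) == 2
        assert len(found["unique_parent_pairs"]) == 1
        assert len(found["quartets"]) == 1

    def test_child_older_than_parents_rejected(self):
        recs = [KinshipRecord("F", "C", 0.25, 0.0001, 1000, "parent-offspring"),
                KinshipRecord("M", "C", 0.25, 0.0001, 1000, "parent-offspring")]
        ages = {"F": 40, "M": 41, "C": 70}
        sexes = {"F": "M", "M": "F", "C": "M"}
        found = relatedness.find_trios_quartets(recs, ages, sexes)
        assert found["trios"] == []

    def test_mixed_families_recover_only_true_trios(self):
        templates = ["full-sib", "parent-offspring", "half-sib", "unrelated"]
        cohort, truth = _pedigree(12, templates, seed=23, n_sites=20_000,
                                  include_parents=True)
        recs = relatedness.king_kinship(cohort)
        ages = dict(zip(cohort.samples["sample_id"], cohort.samples["age"]))
        sexes = dict(zip(cohort.samples["sample_id"], cohort.samples["inferred_sex"]))
        found = relatedness.find_trios_quartets(recs, ages, sexes)
        # only the full-sib families carry both parents: 2 trios each
        assert len(found["trios"]) == 6
        assert len(found["quartets"]) == 3
        for father, mother, child in found["trios"]:
            assert truth.parents[child] == (father, mother)


class TestExpectedSiblingPairs:
    def test_all_singletons(self):
        assert relatedness.expected_sibling_pairs(100, 10_000, {1: 1.0}) == 0.0

    def test_census_of_two_sib_pairs(self):
        # N=4 arranged as two sibling pairs, full sample: exactly 2 pairs
        assert relatedness.expected_sibling_pairs(4, 4, {2: 1.0}) == pytest.approx(2.0)

    def test_matches_monte_carlo_sampling(self, rng):
        big_n, n = 3000, 400
        # build a concrete population of sibships, then use its realized
        # individual-level sibship-size distribution in the formula
        sib_ids = []
        sid = 0
        sizes_p = np.array([0.3, 0.2, 0.1]) / 0.6   # sibship-level mixture
        while len(sib_ids) < big_n:
            s = rng.choice([1, 2, 3], p=sizes_p)
            sib_ids.extend([sid] * s)
            sid += 1
        sib_ids = np.array(sib_ids[:big_n])
        _, member_counts = np.unique(sib_ids, return_counts=True)
        q = {s: (member_counts[member_counts == s] * 1.0).sum() / big_n
             for s in (1, 2, 3)}
        expected = relatedness.expected_sibling_pairs(n, big_n, q)
        draws = []
        for _ in range(2000):
            take = rng.choice(big_n, n, replace=False)
            _, counts = np.unique(sib_ids[take], return_counts=True)
            draws.append((counts * (counts - 1) / 2).sum())
        mc = np.mean(draws)
        se = np.std(draws) / np.sqrt(len(draws))
        assert abs(mc - expected) < 3 * se

    def test_invalid_distribution_rejected(self):
        with pytest.raises(ValueError):
            relatedness.expected_sibling_pairs(10, 100, {2: 0.7})


class TestUnrelatedSubset:
    def test_one_member_of_each_pair_dropped(self):
        recs = [KinshipRecord("A", "B", 0.25, 0.01, 100, "full-sib"),
                KinshipRecord("C", "D", 0.25, 0.01, 100, "full-sib")]
        kept = relatedness.unrelated_subset(recs, ["A", "B", "C", "D", "E"])
        assert "E" in kept
        assert len(kept) == 3
        assert not ({"A", "B"} <= set(kept)) and not ({"C", "D"} <= set(kept))
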