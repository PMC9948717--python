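import logging

import numpy as np
import pytest

from betabef import (
    DegenerateNullError,
    ValidationError,
    beta_mpti,
    build_pair_table,
    cophenetic_distances,
    mpd_between,
    pairwise_assembly,
    simulate_phylogeny,
)
from betabef.assembly import PhyloDistances, exhaustive_null

from conftest import make_metadata, make_table, tree_from_newick


def naive_mpd(dist, taxa_a, taxa_b, pair_set):
    """Double-loop oracle for the mean pairwise phylogenetic distance."""
    if pair_set == "between":
        vals = [dist.matrix[dist.index[a], dist.index[b]]
                for a in taxa_a for b in taxa_b]
        return float(np.mean(vals))
    union = sorted(set(taxa_a) | set(taxa_b))
    vals = [dist.matrix[dist.index[a], dist.index[b]]
            for i, a in enumerate(union) for b in union[i + 1:]]
    return float(np.mean(vals))


class TestCopheneticDistances:
    def test_hand_computed_path_sums(self, three_tip_dist):
        d = three_tip_dist
        i = d.index
        assert d.matrix[i["A"], i["B"]] == pytest.approx(2.0)
        assert d.matrix[i["A"], i["C"]] == pytest.approx(4.0)
        assert d.matrix[i["B"], i["C"]] == pytest.approx(4.0)
        assert np.all(np.diag(d.matrix) == 0)
        np.testing.assert_allclose(d.matrix, d.matrix.T)


class TestMPD:
    @pytest.mark.parametrize(
        "taxa_a, taxa_b, pair_set, expected",
        [
            (["A", "B"], ["C"], "between", 4.0),
            (["A"], ["A"], "between", 0.0),
            (["A", "B"], ["A", "C"], "between", 2.5),  # mean of 0,4,2,4
            (["A", "B"], ["C"], "union", 10.0 / 3.0),  # pairs AB,AC,BC
        ],
    )
    def test_known_values(self, three_tip_dist, taxa_a, taxa_b, pair_set, expected):
        assert mpd_between(three_tip_dist, taxa_a, taxa_b, pair_set) == \
            pytest.approx(expected)

    def test_empty_set_rejected(self, three_tip_dist):
        with pytest.raises(ValidationError):
            mpd_between(three_tip_dist, [], ["A"])

    def test_matches_naive_oracle_random_cases(self):
        rng = np.random.default_rng(0)
        for case in range(30):
            n = int(rng.integers(4, 21))
            dist = cophenetic_distances(simulate_phylogeny(n, case))
            for pair_set in ("between", "union"):
                a = list(rng.choice(dist.labels, rng.integers(1, n), replace=False))
                b = list(rng.choice(dist.labels, rng.integers(1, n), replace=False))
                assert mpd_between(dist, a, b, pair_set) == pytest.approx(
                    naive_mpd(dist, a, b, pair_set), abs=1e-9
                )


class TestBetaMPTI:
    def test_seeded_determinism(self):
        dist = cophenetic_distances(simulate_phylogeny(20, 4))
        a, b = dist.labels[:6], dist.labels[8:14]
        r1 = beta_mpti(dist, a, b, n_rand=199, seed=5)
        r2 = beta_mpti(dist, a, b, n_rand=199, seed=5)
        assert r1.beta_mpti == r2.beta_mpti
        assert r1.beta_mpti != beta_mpti(dist, a, b, n_rand=199, seed=6).beta_mpti

    def test_clustered_clade_is_negative(self):
        """Both communities drawn from one shallow clade hanging off a long
        stem: their MPD is far below a shuffle across the whole tree, and the
        sign agrees with the exhaustive enumeration of all tip permutations."""
        tree = tree_from_newick(
            "(((A:0.1,B:0.1):0.05,(C:0.1,D:0.1):0.05):5.0,(E:2,(F:1,G:1):1):3);"
        )
        dist = cophenetic_distances(tree)
        res = beta_mpti(dist, ["A", "B"], ["C", "D"], n_rand=999, pool="all", seed=0)
        assert res.beta_mpti < 0
        exact = exhaustive_null(dist, ["A", "B"], ["C", "D"], dist.labels)
        z_exact = (res.mpd_obs - exact.mean()) / exact.std()
        assert z_exact < 0
        assert res.beta_mpti == pytest.approx(z_exact, abs=0.3)

    def test_sampled_null_matches_exhaustive_enumeration(self):
        """999-draw null mean/sd agree with the full permutation distribution
        on a 7-tip pool within 3 Monte Carlo standard errors."""
        dist = cophenetic_distances(simulate_phylogeny(7, 2))
        a, b = dist.labels[:3], dist.labels[3:6]
        res = beta_mpti(dist, a, b, n_rand=999, pool="all", seed=0)
        exact = exhaustive_null(dist, a, b, dist.labels)
        n = len(res.null.mpd_values)
        se_mean = exact.std() / np.sqrt(n)
        se_sd = exact.std() / np.sqrt(2 * n)
        assert abs(res.null.mean - exact.mean()) < 3 * se_mean
        assert abs(res.null.sd - exact.std()) < 3 * se_sd

    def test_scale_invariance_exact(self):
        dist = cophenetic_distances(simulate_phylogeny(15, 3))
        scaled = PhyloDistances(labels=dist.labels, matrix=dist.matrix * 10.0)
        a, b = dist.labels[:5], dist.labels[7:12]
        z1 = beta_mpti(dist, a, b, n_rand=299, seed=1).beta_mpti
        z2 = beta_mpti(scaled, a, b, n_rand=299, seed=1).beta_mpti
        assert z1 == pytest.approx(z2, abs=1e-9)

    def test_relabel_invariance_within_mc_error(self):
        dist = cophenetic_distances(simulate_phylogeny(15, 3))
        relabeled = PhyloDistances(
            labels=[f"x_{l}" for l in dist.labels], matrix=dist.matrix.copy()
        )
        a, b = dist.labels[:5], dist.labels[7:12]
        z1 = beta_mpti(dist, a, b, n_rand=999, seed=1).beta_mpti
        z2 = beta_mpti(
            relabeled, [f"x_{t}" for t in a], [f"x_{t}" for t in b],
            n_rand=999, seed=1,
        ).beta_mpti
        assert z1 == pytest.approx(z2, abs=0.25)

    def test_degenerate_null_raises(self, three_tip_dist):
        # both communities hold every pooled taxon: shuffling cannot move MPD
        labels = three_tip_dist.labels
        with pytest.raises(DegenerateNullError):
            beta_mpti(three_tip_dist, labels, labels, n_rand=99, pool="all")


class TestPairwiseAssembly:
    def _pairs(self, tables):
        return build_pair_table(tables, make_metadata(tables))

    def test_fifteen_pairs_per_six_site_cruise(self):
        dist = cophenetic_distances(simulate_phylogeny(30, 5))
        rng = np.random.default_rng(5)
        counts = rng.multinomial(40, np.full(30, 1 / 30), size=6)
        t = make_table("c01", counts, taxa=dist.labels)
        pairs = self._pairs([t])
        filled, summary = pairwise_assembly(pairs, [t], dist, n_rand=199, seed=5)
        assert len(filled) == 15
        assert filled["beta_mpti"].notna().all()
        assert summary.loc[0, "n_pairs"] == 15

    def test_identical_compositions_share_one_value(self):
        dist = cophenetic_distances(simulate_phylogeny(30, 6))
        row = np.zeros(30, dtype=int)
        row[:10] = 50
        t = make_table("c01", np.tile(row, (4, 1)), taxa=dist.labels)
        pairs = self._pairs([t])
        filled, _ = pairwise_assembly(pairs, [t], dist, n_rand=199, seed=6)
        assert filled["beta_mpti"].nunique() == 1

    def test_presence_absence_only(self):
        dist = cophenetic_distances(simulate_phylogeny(25, 7))
        rng = np.random.default_rng(7)
        counts = rng.multinomial(30, np.full(25, 1 / 25), size=4)
        t1 = make_table("c01", counts, taxa=dist.labels)
        t2 = make_table("c01", counts * 10, taxa=dist.labels)
        p1, _ = pairwise_assembly(self._pairs([t1]), [t1], dist, n_rand=199, seed=7)
        p2, _ = pairwise_assembly(self._pairs([t2]), [t2], dist, n_rand=199, seed=7)
        np.testing.assert_array_equal(
            p1["beta_mpti"].to_numpy(), p2["beta_mpti"].to_numpy()
        )

    def test_degenerate_null_recorded_missing(self, caplog):
        dist = cophenetic_distances(simulate_phylogeny(5, 8))
        t = make_table("c01", np.ones((3, 5), dtype=int), taxa=dist.labels)
        pairs = self._pairs([t])
        with caplog.at_level(logging.WARNING, logger="betabef.assembly"):
            filled, summary = pairwise_assembly(pairs, [t], dist, n_rand=99, seed=8)
        assert filled["beta_mpti"].isna().all()
        assert summary.loc[0, "n_missing"] == 3
        assert "degenerate" in caplog.text
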