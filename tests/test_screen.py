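"""Reversal screens: rank statistics against brute-force oracles."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import drugrev as dr
from drugrev.screen import (
    EXACT_MW_MAX_N,
    mw_reverser_score,
    sigcom_screen,
    spearman_reversal,
    spearman_screen,
    top_fraction_genes,
    updown_sets,
)


def _sig(values, tissue="brain"):
    genes = [f"g{i:03d}" for i in range(len(values))]
    return dr.TissueSignature(tissue, pd.Series(values, index=genes, dtype=float))


def _prof(values, sid="s1", name="pert1", genes=None):
    genes = genes or [f"g{i:03d}" for i in range(len(values))]
    return dr.PerturbagenProfile(sid, name, pd.Series(values, index=genes,
                                                      dtype=float))


def _library(matrix: np.ndarray, names=None):
    sids = [f"s{j:03d}" for j in range(matrix.shape[1])]
    names = names or [f"pert{j:03d}" for j in range(matrix.shape[1])]
    genes = [f"g{i:03d}" for i in range(matrix.shape[0])]
    return dr.PerturbagenLibrary(
        pd.DataFrame(matrix, index=genes, columns=sids),
        pd.DataFrame({"signature_id": sids, "perturbagen": names,
                      "cell_line": "c"}),
    )


class TestTopFractionGenes:
    def test_fraction_of_hundred_gives_ten(self):
        sig = _sig(np.arange(100))
        assert len(top_fraction_genes(sig, 0.10, min_genes=5)) == 10

    def test_selects_largest_absolute_scores(self):
        sig = _sig([5.0, -4.0, 3.0, 1.0, -2.0, 0.5, 0.1, -0.2, 0.3, 0.4])
        out = top_fraction_genes(sig, 0.2, min_genes=1)
        assert sig.z[out].abs().tolist() == [5.0, 4.0]

    def test_below_minimum_raises_with_context(self):
        sig = _sig(np.arange(25))
        with pytest.raises(ValueError, match="25 genes.*2 genes"):
            top_fraction_genes(sig, 0.10, min_genes=20)


def _enumerate_spearman(a: np.ndarray, b: np.ndarray):
    """Independent oracle: rho and lower-tail p over all permutations."""
    rho_obs = stats.spearmanr(a, b).statistic
    rb = stats.rankdata(b)
    count = total = 0
    for perm in itertools.permutations(range(len(b))):
        rho = np.corrcoef(stats.rankdata(a), rb[list(perm)])[0, 1]
        total += 1
        if rho <= rho_obs + 1e-12:
            count += 1
    return rho_obs, count / total


class TestSpearmanReversal:
    def test_perfect_reversal_has_exact_permutation_p(self):
        sig = _sig([1, 2, 3, 4, 5])
        prof = _prof([5, 4, 3, 2, 1])
        res = spearman_reversal(sig, prof, sig.genes, min_genes=2)
        assert res.rho == pytest.approx(-1.0)
        assert res.p_one_sided == pytest.approx(1.0 / math.factorial(5))

    def test_identical_profile_has_p_one(self):
        sig = _sig([1, 2, 3, 4, 5])
        res = spearman_reversal(sig, _prof([1, 2, 3, 4, 5]), sig.genes,
                                min_genes=2)
        assert res.rho == pytest.approx(1.0)
        assert res.p_one_sided == pytest.approx(1.0)

    @pytest.mark.parametrize("values", [
        [0.3, 0.3, -1.0, 2.0, 0.7, -0.2],        # one tie pair
        [1.0, -0.5, 0.2, 0.9, -1.4, 0.0],        # no ties
    ])
    def test_small_n_matches_permutation_oracle(self, values):
        sig = _sig([2.0, -1.0, 0.5, 1.5, -0.5, 0.1])
        prof = _prof(values)
        res = spearman_reversal(sig, prof, sig.genes, min_genes=2)
        rho_oracle, p_oracle = _enumerate_spearman(sig.z.to_numpy(),
                                                   np.array(values))
        assert res.rho == pytest.approx(rho_oracle, rel=1e-12)
        assert res.p_one_sided == pytest.approx(p_oracle, rel=1e-12)

    def test_too_few_shared_genes_skips_pair(self):
        sig = _sig([1, 2, 3])
        prof = _prof([1.0, 2.0], genes=["g000", "g001"])
        assert spearman_reversal(sig, prof, sig.genes, min_genes=3) is None

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=-50, max_value=50), min_size=12,
                    max_size=12, unique=True))
    def test_antisymmetric_under_profile_negation(self, values):
        sig = _sig(np.linspace(-2, 2, 12))
        r1 = spearman_reversal(sig, _prof(values), sig.genes, min_genes=5)
        r2 = spearman_reversal(sig, _prof([-v for v in values]), sig.genes,
                               min_genes=5)
        assert r1.rho == pytest.approx(-r2.rho, abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=40)
        sig = _sig(rng.normal(size=40))
        r1 = spearman_reversal(sig, _prof(vals), sig.genes)
        r2 = spearman_reversal(sig, _prof(np.exp(vals / 2)), sig.genes)
        assert r1.rho == pytest.approx(r2.rho)
        assert r1.p_one_sided == pytest.approx(r2.p_one_sided)

    def test_t_approximation_matches_sampled_permutation_null_at_n30(self):
        """At n=30 the t tail agrees with a Monte-Carlo permutation tail."""
        rng = np.random.default_rng(17)
        n = 30
        a = rng.normal(size=n)
        b = -0.2 * (a - a.mean()) / a.std() + rng.normal(size=n)
        sig = _sig(a)
        res = spearman_reversal(sig, _prof(b), sig.genes)
        ra = stats.rankdata(a)
        rb = stats.rankdata(b)
        ra_c = ra - ra.mean()
        n_perm = 200_000
        perms = np.argsort(rng.random((n_perm, n)), axis=1)
        rho_perm = (rb[perms] @ ra_c) / (n * ra.std() * rb.std())
        p_mc = float(np.mean(rho_perm <= res.rho + 1e-12))
        assert 0.01 < p_mc < 0.5  # keep the check in an informative range
        assert res.p_one_sided == pytest.approx(p_mc, rel=0.10)

    def test_t_approximation_close_to_exact_at_n9(self):
        """The two p-value methods agree near the switch point."""
        rng = np.random.default_rng(8)
        for _ in range(5):
            vals = rng.normal(size=9)
            sig = _sig(rng.normal(size=9))
            res_exact = spearman_reversal(sig, _prof(vals), sig.genes,
                                          min_genes=2)
            res_t = spearman_reversal(sig, _prof(vals), sig.genes,
                                      min_genes=2, exact_max_n=0)
            if 0.05 < res_exact.p_one_sided < 0.95:
                assert res_t.p_one_sided == pytest.approx(
                    res_exact.p_one_sided, rel=0.25)


class TestSpearmanScreen:
    def test_vectorized_screen_matches_pairwise_path(self, disease_signature):
        lib, _ = dr.simulate_perturbagen_library(
            disease_signature, 20, 2, 2, strength=0.6, noise_sd=1.0, seed=4)
        hits, table = spearman_screen([disease_signature], lib)
        genes = top_fraction_genes(disease_signature, 0.10)
        for prof in lib.profiles():
            row = table[table["signature_id"] == prof.signature_id].iloc[0]
            res = spearman_reversal(disease_signature, prof, genes)
            assert row["rho"] == pytest.approx(res.rho, rel=1e-10)
            assert row["p_one_sided"] == pytest.approx(res.p_one_sided,
                                                       rel=1e-10)

    def test_perfect_reversers_qualify_and_mimickers_do_not(
            self, disease_signature):
        lib, truth = dr.simulate_perturbagen_library(
            disease_signature, 10, 3, 3, strength=1.0, noise_sd=0.0, seed=5)
        hits, _ = spearman_screen([disease_signature], lib)
        assert hits == truth.reverser_ids

    def test_empty_library_rejected(self, disease_signature):
        lib = _library(np.empty((len(disease_signature), 0)))
        with pytest.raises(ValueError, match="empty"):
            spearman_screen([disease_signature], lib)


class TestUpdownSets:
    def test_signed_extremes_selected(self):
        sig = _sig([3.0, 2.0, 1.0, -1.0, -2.0, -3.0])
        up, down = updown_sets(sig, n=2)
        assert sig.z[up].tolist() == [3.0, 2.0]
        assert sorted(sig.z[down].tolist()) == [-3.0, -2.0]

    def test_all_equal_scores_tie_break_by_id_and_stay_disjoint(self):
        sig = _sig([1.0] * 6)
        up, down = updown_sets(sig, n=3)
        assert up == ["g000", "g001", "g002"]
        assert down == ["g003", "g004", "g005"]

    def test_small_signature_halves_n_with_warning(self):
        sig = _sig(np.arange(250))
        with pytest.warns(UserWarning, match="reduced to 125"):
            up, down = updown_sets(sig, n=150)
        assert len(up) == len(down) == 125
        assert not set(up) & set(down)


def _oracle_mw_score(values: np.ndarray, up_idx, down_idx) -> float:
    """Independent reverser score via scipy.stats.mannwhitneyu."""
    up_vals = values[list(up_idx)]
    down_vals = values[list(down_idx)]
    rest_up = np.delete(values, list(up_idx))
    rest_down = np.delete(values, list(down_idx))

    def z_from_u(x, y, alternative):
        n1, n2 = len(x), len(y)
        u = stats.mannwhitneyu(x, y, alternative=alternative,
                               method="asymptotic").statistic
        # scipy reports U of x vs y; convert to the directional z by hand
        pooled = stats.rankdata(np.concatenate([x, y]))
        tie = float(np.sum([c ** 3 - c for c in
                            np.unique(pooled, return_counts=True)[1]]))
        n = n1 + n2
        var = n1 * n2 / 12.0 * ((n + 1) - tie / (n * (n - 1)))
        mu = n1 * n2 / 2.0
        if alternative == "less":
            return (mu - u - 0.5) / math.sqrt(var)
        return (u - mu - 0.5) / math.sqrt(var)

    z1 = z_from_u(up_vals, rest_up, "less")
    z2 = z_from_u(down_vals, rest_down, "greater")
    return (z1 + z2) / math.sqrt(2.0)


class TestMWReverserScore:
    def test_extreme_configuration_attains_maximum_score(self):
        """Up genes at the exact bottom, down genes at the exact top."""
        values = np.arange(20, dtype=float)
        genes = [f"g{i:03d}" for i in range(20)]
        prof = _prof(values)
        up = genes[:3]       # lowest profile values
        down = genes[-3:]    # highest profile values
        score, p = mw_reverser_score(up, down, prof, min_set=2)
        # U1 = 0 and U2 = n1*n2 give the largest attainable directional z's
        n1, n2 = 3, 17
        var = n1 * n2 * (20 + 1) / 12.0
        zmax = (n1 * n2 / 2.0 - 0.5) / math.sqrt(var)
        assert score == pytest.approx(2 * zmax / math.sqrt(2.0), rel=1e-12)
        assert p < 0.01

    def test_score_matches_scipy_based_oracle(self):
        rng = np.random.default_rng(12)
        values = rng.normal(size=60)
        prof = _prof(values)
        genes = prof.z.index.tolist()
        perm = rng.permutation(60)
        up = [genes[i] for i in perm[:8]]
        down = [genes[i] for i in perm[8:16]]
        score, _ = mw_reverser_score(up, down, prof, min_set=5)
        oracle = _oracle_mw_score(values, perm[:8], perm[8:16])
        assert score == pytest.approx(oracle, rel=1e-10)

    def test_exact_p_matches_brute_force_enumeration(self):
        """8-gene profile, 2+2 sets: p equals the full label enumeration."""
        values = np.array([0.5, -1.2, 0.3, 2.1, -0.7, 1.4, -2.0, 0.9])
        prof = _prof(values)
        genes = prof.z.index.tolist()
        up, down = [genes[3], genes[5]], [genes[6], genes[1]]
        score, p = mw_reverser_score(up, down, prof, min_set=2)
        assert len(values) <= EXACT_MW_MAX_N
        hits = total = 0
        for up_c in itertools.combinations(range(8), 2):
            rest = [i for i in range(8) if i not in up_c]
            for down_c in itertools.combinations(rest, 2):
                s = _oracle_mw_score(values, up_c, down_c)
                total += 1
                hits += s >= score - 1e-12
        assert p == pytest.approx(hits / total, rel=1e-12)

    def test_null_permutation_calibration(self):
        """Random gene labels give score mean ~0 and variance ~1."""
        rng = np.random.default_rng(23)
        values = rng.normal(size=400)
        prof = _prof(values)
        genes = prof.z.index.tolist()
        scores = []
        for _ in range(2000):
            perm = rng.permutation(400)
            up = [genes[i] for i in perm[:40]]
            down = [genes[i] for i in perm[40:80]]
            s, _ = mw_reverser_score(up, down, prof)
            scores.append(s)
        scores = np.asarray(scores)
        assert abs(scores.mean()) < 0.08
        assert 0.8 < scores.var() < 1.2

    def test_overlapping_sets_rejected(self):
        prof = _prof(np.arange(30, dtype=float))
        genes = prof.z.index.tolist()
        with pytest.raises(ValueError, match="overlap"):
            mw_reverser_score(genes[:12], genes[10:22], prof)


class TestSigcomScreen:
    def test_small_library_returned_whole_with_warning(self, disease_signature):
        lib, _ = dr.simulate_perturbagen_library(
            disease_signature, 5, 1, 0, strength=0.8, noise_sd=0.5, seed=6)
        with pytest.warns(UserWarning, match="5 profiles"):
            names, table = sigcom_screen([disease_signature], lib, n=40,
                                         top_k=200)
        assert len(names) == 5

    def test_planted_reversers_rank_first(self, disease_signature):
        lib, truth = dr.simulate_perturbagen_library(
            disease_signature, 50, 5, 5, strength=1.0, noise_sd=0.0, seed=9)
        names, table = sigcom_screen([disease_signature], lib, n=40, top_k=5)
        assert names == truth.reverser_ids
        # mimickers sit at the very bottom of the ranking
        worst = set(table.nlargest(5, "rank")["perturbagen"])
        assert worst == truth.mimicker_ids

    def test_equal_scores_tie_break_by_signature_id(self):
        rng = np.random.default_rng(31)
        col = rng.normal(size=120)
        lib = _library(np.column_stack([col, col, rng.normal(size=120)]),
                       names=["dup_b", "dup_a", "other"])
        sig = _sig(rng.normal(size=120))
        _, table = sigcom_screen([sig], lib, n=20, top_k=200, min_set=5)
        dup = table[table["perturbagen"].str.startswith("dup")]
        assert dup.sort_values("rank")["signature_id"].tolist() == ["s000", "s001"]


class TestIntersectCandidates:
    def test_plain_intersection(self):
        cs = dr.intersect_candidates({"a", "b", "c"}, {"b", "c", "d"})
        assert cs.intersection == {"b", "c"}

    def test_empty_side_gives_empty_results(self):
        cs = dr.intersect_candidates({"a", "b"}, set())
        assert cs.intersection == set()
        assert cs.approved == []

    def test_approved_mapping_deduplicates_by_drug_name(self):
        drug_map = pd.DataFrame({
            "perturbagen": ["a", "b", "c", "d"],
            "approved": ["yes", "yes", "no", "yes"],
            "drug_name": ["metformin", "metformin", "x", "statin"],
            "drug_class": ["biguanide", "biguanide", "x", "statin"],
        })
        cs = dr.intersect_candidates({"a", "b", "c", "d"}, {"a", "b", "c", "d"},
                                     drug_map)
        assert cs.approved == [("metformin", "biguanide"), ("statin", "statin")]
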