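"""LD estimation, pruning, BH FDR and adaptive permutation."""

import numpy as np
import pytest

from helpers import bh_naive_oracle, greedy_prune_oracle, logit_newton_oracle
from pedphewas import multiplicity as mult
from pedphewas import simulate as sim
from pedphewas.exceptions import ParameterError, UndefinedLdError


class TestLdStats:
    def test_identical_loci_have_full_ld(self, rng):
        g = rng.binomial(2, 0.3, 500).astype(float)
        ld = mult.ld_stats(g, g)
        assert ld.r2 == pytest.approx(1.0, abs=1e-9)
        assert ld.d_prime == pytest.approx(1.0, abs=1e-9)

    def test_independent_loci_near_zero(self, rng):
        g1 = rng.binomial(2, 0.4, 10_000).astype(float)
        g2 = rng.binomial(2, 0.3, 10_000).astype(float)
        assert mult.ld_stats(g1, g2).r2 < 0.01

    def test_em_matches_phased_counts_when_phase_unambiguous(self):
        """With no double heterozygotes the likelihood is free of phase
        ambiguity and EM must reproduce the phased haplotype counts."""
        # hand-built phased haplotype pairs, none producing (het, het)
        pairs = [
            (("A", "B"), ("A", "B")),
            (("A", "B"), ("a", "B")),
            (("a", "b"), ("a", "b")),
            (("A", "B"), ("A", "b")),
            (("a", "B"), ("a", "B")),
            (("A", "B"), ("a", "B")),
            (("a", "b"), ("a", "B")),
            (("A", "b"), ("A", "b")),
        ]
        g1 = np.array([(h1[0] == "A") + (h2[0] == "A") for h1, h2 in pairs], float)
        g2 = np.array([(h1[1] == "B") + (h2[1] == "B") for h1, h2 in pairs], float)
        counts = np.zeros(4)
        key = {("A", "B"): 0, ("A", "b"): 1, ("a", "B"): 2, ("a", "b"): 3}
        for h1, h2 in pairs:
            counts[key[h1]] += 1
            counts[key[h2]] += 1
        ld = mult.ld_stats(g1, g2)
        np.testing.assert_allclose(ld.hap_freqs, counts / counts.sum(), atol=1e-6)

    def test_em_likelihood_not_below_phased_counts(self, rng):
        """On ambiguous data the EM haplotype frequencies must attain a
        log-likelihood at least as high as the phased truth."""
        hf = np.array([0.45, 0.15, 0.25, 0.15])
        hap = rng.choice(4, size=(2000, 2), p=hf)
        g1 = np.isin(hap, [0, 1]).sum(axis=1).astype(float)
        g2 = np.isin(hap, [0, 2]).sum(axis=1).astype(float)
        ld = mult.ld_stats(g1, g2)
        phased = np.array([(hap == k).sum() for k in range(4)]) / (2 * len(hap))

        def ll(p):
            out = 0.0
            gmat = {}
            for a, b in zip(g1.astype(int), g2.astype(int)):
                gmat[(a, b)] = gmat.get((a, b), 0) + 1
            probs = {  # genotype probability from haplotype freqs
                (2, 2): p[0] ** 2, (2, 1): 2 * p[0] * p[1], (2, 0): p[1] ** 2,
                (1, 2): 2 * p[0] * p[2], (0, 2): p[2] ** 2,
                (1, 1): 2 * p[0] * p[3] + 2 * p[1] * p[2],
                (1, 0): 2 * p[1] * p[3], (0, 1): 2 * p[2] * p[3],
                (0, 0): p[3] ** 2,
            }
            for k, c in gmat.items():
                out += c * np.log(max(probs[k], 1e-300))
            return out

        assert ll(ld.hap_freqs) >= ll(phased) - 1e-6

    def test_monomorphic_rejected(self, rng):
        g = rng.binomial(2, 0.3, 100).astype(float)
        with pytest.raises(UndefinedLdError):
            mult.ld_stats(g, np.zeros(100))

    def test_block_simulation_exceeds_pruning_threshold(self):
        spec = sim.CohortSpec(
            n_subjects=2000, fst=0.0, missing_rate=0.0,
            variant_specs=(
                sim.VariantSpec(maf=0.3, ld_block=0, copy_prob=0.9),
                sim.VariantSpec(maf=0.3, ld_block=0, copy_prob=0.9),
            ),
            phenotype_specs=(), seed=23,
        )
        G, _ = sim.simulate_genotypes(spec)
        assert mult.ld_stats(G.dosages[:, 0], G.dosages[:, 1]).r2 > 0.5


class TestPrune:
    def test_duplicate_variants_collapse_to_one(self, make_G, rng):
        g = rng.binomial(2, 0.3, 300).astype(float)
        G = make_G(np.column_stack([g, g, g]))
        kept, report = mult.prune(G)
        assert kept == ["rs0"]
        assert report.kept.sum() == 1

    def test_threshold_one_keeps_everything(self, make_G, rng):
        g = rng.binomial(2, 0.3, 300).astype(float)
        G = make_G(np.column_stack([g, g, g]))
        kept, _ = mult.prune(G, r2_threshold=1.0)
        assert len(kept) == 3

    def test_outside_window_not_compared(self, make_G, rng):
        g = rng.binomial(2, 0.3, 300).astype(float)
        G = make_G(np.column_stack([g, g]), pos=np.array([1000, 2_000_000]))
        kept, _ = mult.prune(G, window_kb=500)
        assert len(kept) == 2

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_bruteforce_greedy_oracle(self, make_G, seed):
        rng = np.random.default_rng(seed)
        n, m = 500, 18
        base = rng.binomial(2, 0.3, size=(n, 4)).astype(float)
        cols = []
        for j in range(m):
            src = base[:, j % 4].copy()
            flip = rng.random(n) < rng.uniform(0.0, 0.5)
            src[flip] = rng.binomial(2, 0.3, flip.sum())
            cols.append(src)
        d = np.column_stack(cols)
        pos = np.sort(rng.choice(10_000_000, size=m, replace=False))
        G = make_G(d, pos=pos)
        kept, _ = mult.prune(G, r2_threshold=0.5, window_kb=500)
        want = greedy_prune_oracle(d, pos, 0.5, 500_000.0)
        assert kept == [f"rs{j}" for j in want]


class TestBh:
    def test_single_p_is_its_own_q(self):
        assert mult.bh_qvalues(np.array([0.03]))[0] == pytest.approx(0.03)

    def test_stepup_arithmetic(self):
        q = mult.bh_qvalues(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_naive_oracle_and_statsmodels(self, seed):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(seed)
        p = rng.uniform(1e-6, 1.0, size=200)
        q = mult.bh_qvalues(p)
        np.testing.assert_allclose(q, bh_naive_oracle(p), atol=1e-12)
        np.testing.assert_allclose(
            q, multipletests(p, method="fdr_bh")[1], atol=1e-12
        )

    def test_invalid_p_rejected(self):
        with pytest.raises(ParameterError):
            mult.bh_qvalues(np.array([0.0, 0.5]))
        with pytest.raises(ParameterError):
            mult.bh_qvalues(np.array([0.5, 1.5]))


class TestAdaptivePermutation:
    def test_exhaustive_matches_enumeration_oracle_at_n8(self):
        """n = 8 with 4 cases: all 70 label assignments enumerated; the
        empirical p must match an independent Newton-oracle enumeration
        to within 1/71."""
        from itertools import combinations as comb_iter
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0], float)
        # five carriers / three non-carriers: no 4-case labeling can
        # separate, so the MLE is finite for every assignment
        g = np.array([1, 1, 1, 0, 1, 0, 1, 0], float)
        res = mult.adaptive_permutation(y, g, max_trials=1000)
        assert res.exhaustive and res.n_trials == 70

        x_cols = np.column_stack([np.ones(8), g])
        def z_of(yv):
            # separated assignments have Wald z -> 0 (Hauck-Donner)
            try:
                beta, se = logit_newton_oracle(yv, x_cols)
            except np.linalg.LinAlgError:
                return 0.0
            return 0.0 if abs(beta[1]) > 10 else abs(beta[1] / se[1])
        obs = z_of(y)
        count = sum(
            1 for idx in comb_iter(range(8), 4)
            if z_of(np.isin(np.arange(8), idx).astype(float)) >= obs - 1e-9
        )
        assert abs(res.p_perm - count / 70) <= 1 / 71

    def test_null_statistic_stops_early_with_p_near_one(self, rng):
        g = rng.binomial(2, 0.5, 200).astype(float)
        y = rng.integers(0, 2, 200).astype(float)
        # make the observed statistic tiny by construction: permute y so
        # it is independent of g, then find typical behavior
        res = mult.adaptive_permutation(
            y, g, max_trials=5000, early_stop_exceedances=10, seed=3
        )
        assert res.stopped_early
        assert res.n_trials <= 1000
        assert res.p_perm > 0.005

    def test_seeded_runs_reproducible(self, rng):
        g = rng.binomial(2, 0.3, 300).astype(float)
        y = rng.integers(0, 2, 300).astype(float)
        a = mult.adaptive_permutation(y, g, max_trials=500, seed=42)
        b = mult.adaptive_permutation(y, g, max_trials=500, seed=42)
        assert a == b

    def test_agrees_with_wald_p_under_null(self):
        """For a moderate signal the permutation p should sit within
        binomial error of the asymptotic Wald p."""
        rng = np.random.default_rng(8)
        n = 2000
        g = rng.binomial(2, 0.3, n).astype(float)
        eta = -1.0 + 0.13 * g
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        from pedphewas.assoc import fit_logistic
        wald = fit_logistic(y, g).p
        res = mult.adaptive_permutation(
            y, g, max_trials=3000, early_stop_exceedances=30, seed=5
        )
        se = np.sqrt(wald * (1 - wald) / res.n_trials)
        assert abs(res.p_perm - wald) < max(4 * se, 0.02)


def test_fdr_over_pruned_assigns_q_only_on_grid(rng, make_G):
    import pandas as pd
    assoc_df = pd.DataFrame({
        "phecode": ["100.1"] * 4,
        "variant": ["rs0", "rs1", "rs2", "rs3"],
        "p": [0.001, 0.5, 0.02, np.nan],
    })
    out = mult.fdr_over_pruned(assoc_df, ["rs0", "rs2", "rs3"])
    assert np.isnan(out.q[1]) and np.isnan(out.q[3])
    np.testing.assert_allclose(out.q[[0, 2]], [0.002, 0.02])
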