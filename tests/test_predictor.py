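"""Allele PWMs with BLOSUM62 pseudocounts, scoring, backgrounds,
neo-antigen enumeration/ranking and benchmark metrics."""

import math

import numpy as np
import pytest

from hlamotifs.alphabet import AA_INDEX, AMINO_ACIDS, N_AA
from hlamotifs.blosum import (BLOSUM62_CONDITIONAL, BLOSUM62_JOINT,
                              BLOSUM62_MARGINAL)
from hlamotifs.predictor import (AlleleModel, MutationRecord,
                                 PseudocountParams, build_allele_pwm,
                                 empirical_pvalues,
                                 enumerate_missense_candidates,
                                 estimate_ms_background, evaluate,
                                 filter_tryptic_signature, pearson_r,
                                 predict, proteome_frequencies,
                                 rank_neoantigens, score_peptide)
from hlamotifs.types import (AlleleName, BackgroundFrequencies, PWM,
                             count_matrix)


class TestBlosumTable:
    def test_joint_symmetric_and_conditional_rows_normalized(self):
        assert np.allclose(BLOSUM62_JOINT, BLOSUM62_JOINT.T)
        assert np.allclose(BLOSUM62_CONDITIONAL.sum(axis=1), 1.0)
        assert abs(BLOSUM62_MARGINAL.sum() - 1.0) < 1e-12

    def test_self_substitution_most_likely(self):
        # staying put is the modal substitution for every residue except
        # methionine, whose modal target is leucine (a known BLOSUM62
        # property reflecting M/L exchangeability)
        modal = BLOSUM62_CONDITIONAL.argmax(axis=1)
        for i, j in enumerate(modal):
            if AMINO_ACIDS[i] == "M":
                assert AMINO_ACIDS[j] == "L"
            else:
                assert i == j


class TestMsBackground:
    def _pool(self, p4to7: str, n=30):
        """9-mers whose P4-P7 window cycles through the given residues."""
        return {f"ACDEFGHIK"[:3] + (p4to7 * 4)[i:i + 4] + "KLM"
                for i in range(n)}

    def test_identical_pools_recovered(self):
        peps = {"AAAWWDDAA", "AAAWWDDAA"[::-1]}
        pools = {AlleleName.parse("A0101"): {"AAAWWDDAA"},
                 AlleleName.parse("B0702"): {"AAAWWDDAA"}}
        q = estimate_ms_background(pools, excluded=frozenset())
        counts = count_matrix(["AAAWWDDAA"]).counts[3:7].sum(axis=0)
        expected = np.maximum(counts / counts.sum(), 1e-4)
        assert np.allclose(q.q, expected / expected.sum())

    def test_unweighted_mean_across_alleles(self):
        pools = {AlleleName.parse("A0101"): {"AAAWWWWAA"},
                 AlleleName.parse("B0702"): {"AAADDDDAA"}}
        q = estimate_ms_background(pools, excluded=frozenset())
        assert q.q[AA_INDEX["W"]] == pytest.approx(q.q[AA_INDEX["D"]])

    def test_excluded_allele_ignored(self):
        pools = {AlleleName.parse("A0201"): {"AAAWWWWAA"},
                 AlleleName.parse("B0702"): {"AAADDDDAA"}}
        q = estimate_ms_background(pools)     # A0201 is on the default list
        assert q.q[AA_INDEX["W"]] == pytest.approx(1e-4 / (1 + 19e-4))

    def test_all_excluded_rejected(self):
        pools = {AlleleName.parse("A0201"): {"AAAWWWWAA"}}
        with pytest.raises(ValueError):
            estimate_ms_background(pools)


class TestProteomeFrequencies:
    def test_pearson_identity_and_affine_invariance(self):
        q1 = BackgroundFrequencies(np.linspace(1, 39, 20) / 400)
        assert pearson_r(q1, q1) == pytest.approx(1.0)
        v = 0.5 * q1.q + 0.025
        assert pearson_r(q1, BackgroundFrequencies(v / v.sum())) \
            == pytest.approx(1.0)

    def test_cysteine_depletion_lowers_correlation(self):
        from hlamotifs.alphabet import HUMAN_PROTEOME_FREQS
        q1 = BackgroundFrequencies(HUMAN_PROTEOME_FREQS)
        depleted = HUMAN_PROTEOME_FREQS.copy()
        depleted[AA_INDEX["C"]] *= 0.2
        q2 = BackgroundFrequencies(depleted / depleted.sum())
        r = pearson_r(q1, q2)
        v1, v2 = q1.q, q2.q
        oracle = (np.mean(v1 * v2) - v1.mean() * v2.mean()) / (
            v1.std() * v2.std())
        assert r == pytest.approx(oracle, abs=1e-12)
        assert r < 1.0

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_r(BackgroundFrequencies.uniform(),
                      BackgroundFrequencies.uniform())


class TestPseudocounts:
    def test_symmetric_weights_average_f_and_g(self):
        rng = np.random.default_rng(0)
        peps = ["".join(rng.choice(list(AMINO_ACIDS), size=9))
                for _ in range(201)]
        pwm = build_allele_pwm(peps, PseudocountParams(beta=200))
        f = count_matrix(peps).counts / 201
        g = f @ BLOSUM62_CONDITIONAL
        assert np.abs(pwm.matrix - (f + g) / 2).max() < 1e-12

    def test_single_peptide_gives_pure_pseudocounts(self):
        pwm = build_allele_pwm(["AAAAAAAAA"])
        g = BLOSUM62_CONDITIONAL[AA_INDEX["A"]]
        assert np.allclose(pwm.matrix, np.tile(g, (9, 1)))

    def test_large_n_dominated_by_data(self):
        peps = ["A" + "LMNPQRST"[i % 8] * 8 for i in range(20001)]
        pwm = build_allele_pwm(peps)
        g_a = (count_matrix(peps).counts / 20001 @
               BLOSUM62_CONDITIONAL)[0, AA_INDEX["A"]]
        expected = (20000 * 1.0 + 200 * g_a) / 20200
        assert pwm.matrix[0, AA_INDEX["A"]] == pytest.approx(expected,
                                                             abs=1e-9)
        assert pwm.matrix[0, AA_INDEX["A"]] > 0.98


class TestScore:
    def test_zero_when_pwm_equals_background(self):
        pwm = PWM.uniform(9)
        q = BackgroundFrequencies.uniform()
        assert score_peptide("ACDEFGHIK", pwm, q) == pytest.approx(0.0)

    def test_uniform_ratio_two_gives_ln2(self):
        m = np.full((9, N_AA), 0.9 / 19)
        m[:, AA_INDEX["A"]] = 0.1
        pwm = PWM(m)
        q = BackgroundFrequencies.uniform()
        assert score_peptide("A" * 9, pwm, q) == pytest.approx(math.log(2))

    def test_single_position_ratio_four(self):
        m = np.full((9, N_AA), 0.05)
        m[0] = (1 - 0.2) / 19
        m[0, AA_INDEX["A"]] = 0.2
        pwm = PWM(m)
        q = BackgroundFrequencies.uniform()
        assert score_peptide("A" * 9, pwm, q) \
            == pytest.approx(math.log(4) / 9)

    def test_matches_per_position_oracle(self):
        rng = np.random.default_rng(1)
        pwm = PWM(rng.dirichlet(np.ones(20), size=9))
        q = BackgroundFrequencies(rng.dirichlet(np.ones(20)))
        pep = "".join(rng.choice(list(AMINO_ACIDS), size=9))
        oracle = sum(math.log(pwm.matrix[i, AA_INDEX[c]] / q[c])
                     for i, c in enumerate(pep)) / 9
        assert score_peptide(pep, pwm, q) == pytest.approx(oracle,
                                                           abs=1e-10)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            score_peptide("ACDEFGHIKL", PWM.uniform(9),
                          BackgroundFrequencies.uniform())


def _strong_model(allele, residue="W", length=9):
    m = np.full((length, N_AA), 0.1 / 19)
    m[:, AA_INDEX[residue]] = 0.9
    return AlleleModel(AlleleName.parse(allele), {length: PWM(m)},
                       {length: 100})


class TestPredict:
    def test_single_allele_is_always_best(self):
        model = _strong_model("A0101")
        q = BackgroundFrequencies.uniform()
        bg = {9: np.sort(np.linspace(-1, 1, 100))}
        records = predict(["WWWWWWWWW", "ACDEFGHIK"], [model], q, bg)
        assert all(r.best_allele == model.allele for r in records)
        assert records[0].peptide == "WWWWWWWWW"   # sorted by score

    def test_max_over_alleles(self):
        models = [_strong_model("A0101", "W"), _strong_model("B0702", "D")]
        q = BackgroundFrequencies.uniform()
        bg = {9: np.sort(np.linspace(-1, 1, 100))}
        (rec,) = predict(["DDDDDDDDD"], models, q, bg)
        assert rec.best_allele == AlleleName.parse("B0702")

    def test_pvalue_above_all_background(self):
        model = _strong_model("A0101")
        q = BackgroundFrequencies.uniform()
        bg = {9: np.sort(np.full(100_000, -5.0))}
        (rec,) = predict(["WWWWWWWWW"], [model], q, bg)
        assert rec.empirical_p == pytest.approx(1 / 100_001)

    def test_add_one_estimator(self):
        assert empirical_pvalues(np.array([0.0]),
                                 np.sort(np.array([-1., 0., 1., 2.])))[0] \
            == pytest.approx(4 / 5)


class TestEnumerate:
    def _mut(self, pos, length=100):
        seq = "A" * length
        return MutationRecord("p", seq, pos, "A", "W")

    def test_mid_protein_counts(self):
        assert len(enumerate_missense_candidates(self._mut(50))) == 19

    def test_left_edge(self):
        assert len(enumerate_missense_candidates(self._mut(3))) == 6

    def test_terminal_residue(self):
        assert len(enumerate_missense_candidates(self._mut(100))) == 2

    def test_short_protein_empty(self):
        assert enumerate_missense_candidates(self._mut(5, length=8)) == []

    def test_alt_substituted_in_every_candidate(self):
        for pep in enumerate_missense_candidates(self._mut(50)):
            assert "W" in pep

    def test_record_invariants(self):
        with pytest.raises(ValueError):
            MutationRecord("p", "AAAA", 2, "C", "W")   # ref mismatch
        with pytest.raises(ValueError):
            MutationRecord("p", "AAAA", 2, "A", "A")   # silent


class TestRankNeoantigens:
    def test_planted_strong_binder_ranks_first_and_ties_deterministic(self):
        model = _strong_model("A0101", "W")
        q = BackgroundFrequencies.uniform()
        bg = {9: np.sort(np.linspace(-1, 1, 1000))}
        seq = "ACDEFGHIKLMNPQRSTVYACDEFGHIKL"
        muts = [MutationRecord("p", seq, 10, seq[9], "W")]
        records = rank_neoantigens(muts, [model], q, bg, lengths=(9,))
        assert records[0].rank == 1
        assert [r.rank for r in records] == list(range(1, len(records) + 1))
        # lexicographic tie-break: equal scores sort by peptide
        scores = [round(r.best_score, 12) for r in records]
        for s in set(scores):
            group = [r.peptide for r in records if round(r.best_score,
                                                         12) == s]
            assert group == sorted(group)

    def test_hla_c_excluded_by_default(self):
        model_c = _strong_model("C0702", "W")
        q = BackgroundFrequencies.uniform()
        bg = {9: np.sort(np.linspace(-1, 1, 100))}
        muts = [MutationRecord("p", "A" * 30, 15, "A", "W")]
        with pytest.raises(ValueError):
            rank_neoantigens(muts, [model_c], q, bg, lengths=(9,))
        records = rank_neoantigens(muts, [model_c], q, bg, lengths=(9,),
                                   include_c=True)
        assert records


class TestEvaluate:
    def test_perfect_separation(self):
        scored = [(1.0 + i * 1e-3, True) for i in range(100)] + \
                 [(-1.0 - i * 1e-3, False) for i in range(9900)]
        result = evaluate(scored)
        assert result.auc == 1.0
        assert result.pp1 == 1.0

    def test_partial_top_list(self):
        scored = ([(2.0, True)] * 80 + [(1.0, False)] * 20
                  + [(0.5, True)] * 20 + [(-1.0, False)] * 9880)
        assert evaluate(scored).pp1 == pytest.approx(0.80)

    def test_random_scores_auc_half(self):
        rng = np.random.default_rng(0)
        scored = [(float(s), bool(l)) for s, l in
                  zip(rng.normal(size=10_000),
                      rng.random(10_000) < 0.5)]
        assert evaluate(scored).auc == pytest.approx(0.5, abs=0.02)

    def test_degenerate_labels_rejected(self):
        with pytest.raises(ValueError):
            evaluate([(1.0, True)])


class TestBackgroundRenormalization:
    def test_ordering_stable_for_peptides_without_changed_residue(self):
        """Swapping in a background that differs only at cysteine (then
        renormalized) must not reorder cysteine-free peptides scored
        under one allele."""
        rng = np.random.default_rng(5)
        pwm = PWM(rng.dirichlet(np.ones(20), size=9))
        from hlamotifs.alphabet import HUMAN_PROTEOME_FREQS
        q1 = BackgroundFrequencies(HUMAN_PROTEOME_FREQS)
        depleted = HUMAN_PROTEOME_FREQS.copy()
        depleted[AA_INDEX["C"]] *= 0.2
        q2 = BackgroundFrequencies(depleted / depleted.sum())
        residues = [a for a in AMINO_ACIDS if a != "C"]
        peps = ["".join(rng.choice(residues, size=9)) for _ in range(50)]
        s1 = [score_peptide(p, pwm, q1) for p in peps]
        s2 = [score_peptide(p, pwm, q2) for p in peps]
        assert np.argsort(s1).tolist() == np.argsort(s2).tolist()


class TestTenMers:
    def test_mixture_and_scoring_handle_length_ten(self):
        from hlamotifs.mixture import DeconvConfig, fit_mixture
        from hlamotifs.synth import _draw_peptides, generate_truth
        truth = generate_truth(n_alleles=2, lengths=(10,), seed=40)
        rng = np.random.default_rng(40)
        peps = []
        for a in truth.alleles:
            peps += _draw_peptides(truth.pwm(a, 10).matrix, 400, rng)
        model = fit_mixture(peps, 2, DeconvConfig(seed=40, n_restarts=2))
        assert model.pwms[0].length == 10
        q = BackgroundFrequencies.uniform()
        s = score_peptide(peps[0], model.pwms[0], q)
        assert np.isfinite(s)


class TestTrypticFilter:
    def test_rk_terminal_removed(self):
        out = filter_tryptic_signature(["AAAAAAAAK", "AAAAAAAAL"],
                                       AlleleName.parse("B0702"))
        assert out == ["AAAAAAAAL"]

    @pytest.mark.parametrize("allele", ["A0301", "A3101"])
    def test_exceptions_untouched(self, allele):
        peps = ["AAAAAAAAK", "AAAAAAAAL"]
        assert filter_tryptic_signature(peps, AlleleName.parse(allele)) \
            == peps

    def test_empty_input(self):
        assert filter_tryptic_signature([], AlleleName.parse("B0702")) == []
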