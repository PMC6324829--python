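"""Alignment path space, column tables, and the pair likelihood DP."""

import math

import numpy as np
import pytest

from jemge.evo_models import (
    EvoParams,
    IndelParams,
    LocalEquilibria,
    MarkParams,
    NucleotideDistribution,
    epi_switch_prob,
    phi_marginal,
    tkf_quantities,
)
from jemge.likelihood import (
    GAP,
    AlignmentColumn,
    AlignmentPath,
    HomologousPair,
    MarkTrack,
    ModelKind,
    ancestor_log_prob,
    column_cond_probs,
    enumerate_alignments,
    oracle_pair_log_likelihood,
    pair_log_likelihood,
    path_log_prob,
)
from conftest import random_pair, random_params

PARAMS = EvoParams(
    nuc=NucleotideDistribution(),
    marks=(MarkParams(1, 0.1, 0.75),),
    indel=IndelParams(0.02, 0.04),
    s=0.07,
)
PHI = LocalEquilibria((0.5,), (0.3,))


class TestPathSpace:
    @pytest.mark.parametrize("sA,sB,count", [
        (1, 1, 3), (2, 2, 13), (0, 4, 1), (3, 0, 1), (3, 4, 129),
    ])
    def test_delannoy_counts(self, sA, sB, count):
        assert len(enumerate_alignments(sA, sB)) == count

    def test_size_guard(self):
        with pytest.raises(ValueError):
            enumerate_alignments(7, 2)

    def test_paths_project_back(self, rng):
        pair = random_pair(rng, 3, 2)
        for path in enumerate_alignments(3, 2):
            cols = path.columns(pair)
            projA = "".join(c.a0 for c in cols if c.a0 != GAP)
            projB = "".join(c.b0 for c in cols if c.b0 != GAP)
            assert projA == pair.seqA and projB == pair.seqB

    def test_double_gap_rejected(self):
        with pytest.raises(ValueError):
            AlignmentColumn(GAP, GAP)


class TestColumnTables:
    def test_model_I_match(self):
        col = AlignmentColumn("A", "A", (1,), (1,))
        pA, pB = column_cond_probs(ModelKind.I, col, PARAMS, None)
        assert pA == pytest.approx(0.1)
        assert pB == pytest.approx(epi_switch_prob(1, 1, 0.75, 1.0, 0.1))

    def test_model_B_mismatch_uses_equilibrium(self):
        col = AlignmentColumn("A", "C", (1,), (0,))
        pA, pB = column_cond_probs(ModelKind.B, col, PARAMS, None)
        assert (pA, pB) == (pytest.approx(0.1), pytest.approx(0.9))

    def test_model_N_insert_uses_phi(self):
        col = AlignmentColumn(GAP, "C", (), (1,))
        pA, pB = column_cond_probs(ModelKind.N, col, PARAMS, PHI)
        assert pA == 1.0
        assert pB == pytest.approx(phi_marginal(1, 0.5, 0.75, 1.0, 0.1))

    def test_indel_free_columns_agree_N_vs_I_and_M_vs_B(self, rng):
        # the case tables differ only on gap columns
        for _ in range(20):
            a, b = rng.choice(list("ACGT"), 2)
            am, bm = int(rng.integers(0, 2)), int(rng.integers(0, 2))
            col = AlignmentColumn(str(a), str(b), (am,), (bm,))
            assert column_cond_probs(ModelKind.N, col, PARAMS, PHI) == \
                column_cond_probs(ModelKind.I, col, PARAMS, None)
            assert column_cond_probs(ModelKind.M, col, PARAMS, PHI) == \
                column_cond_probs(ModelKind.B, col, PARAMS, None)

    @pytest.mark.parametrize("model", list(ModelKind))
    def test_descendant_normalization(self, model, rng):
        # sum over b_h of the b-factor is 1 on diagonal and insert columns
        for a0, b0 in [("A", "A"), ("A", "C"), (GAP, "C")]:
            a_marks = () if a0 == GAP else (1,)
            total = 0.0
            for bh in (0, 1):
                col = AlignmentColumn(a0, b0, a_marks, (bh,))
                total += column_cond_probs(model, col, PARAMS, PHI)[1]
            assert total == pytest.approx(1.0, abs=1e-12)


class TestPathAndAncestorFactors:
    def test_single_delete_path_weight(self):
        q = tkf_quantities(0.02, 0.04, 1.0)
        col = AlignmentColumn("A", GAP, (0,), ())
        expected = math.log(q.p_double_prime(1) * q.p0_prime)
        assert path_log_prob([col], PARAMS) == pytest.approx(expected, abs=1e-12)

    def test_single_insert_path_weight(self):
        q = tkf_quantities(0.02, 0.04, 1.0)
        col = AlignmentColumn(GAP, "C", (), (1,))
        expected = math.log(q.p_double_prime(2) * 0.25)
        assert path_log_prob([col], PARAMS) == pytest.approx(expected, abs=1e-12)

    def test_path_weight_is_log_probability(self, rng):
        pair = random_pair(rng, 3, 3)
        for path in enumerate_alignments(3, 3)[:20]:
            assert path_log_prob(path.columns(pair), PARAMS) <= 0.0

    def test_ancestor_single_base(self):
        pair = HomologousPair("x", "A", "C",
                              (MarkTrack(1, [1]),), (MarkTrack(1, [0]),),
                              phi=PHI)
        ratio = 0.02 / 0.04
        base = math.log(1 - ratio) + math.log(ratio) + math.log(0.25)
        assert ancestor_log_prob(pair, ModelKind.I, PARAMS) == pytest.approx(
            base + math.log(0.1), abs=1e-12)
        # N defers the mark equilibrium factor to the recursion
        assert ancestor_log_prob(pair, ModelKind.N, PARAMS) == pytest.approx(
            base, abs=1e-12)


class TestPairLikelihood:
    def test_requires_phi_for_local_models(self, rng):
        pair = random_pair(rng, 3, 3)
        bare = HomologousPair(pair.identifier, pair.seqA, pair.seqB,
                              pair.tracksA, pair.tracksB, phi=None)
        with pytest.raises(ValueError):
            pair_log_likelihood(bare, ModelKind.N, PARAMS)
        # I and B do not need phi
        assert math.isfinite(pair_log_likelihood(bare, ModelKind.I, PARAMS))

    def test_track_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            HomologousPair("x", "ACG", "ACG",
                           (MarkTrack(1, [0, 1]),), (MarkTrack(1, [0, 1, 0]),))

    def test_smallest_pair_matches_oracle_closed_form(self):
        # sA = sB = 1: exactly three paths; check against the oracle
        pair = HomologousPair("x", "A", "A",
                              (MarkTrack(1, [1]),), (MarkTrack(1, [1]),),
                              phi=PHI)
        for model in ModelKind:
            dp = pair_log_likelihood(pair, model, PARAMS)
            oracle = oracle_pair_log_likelihood(pair, model, PARAMS)
            assert dp == pytest.approx(oracle, abs=1e-9)

    def test_second_equilibrium_mark_factorizes_per_column(self, rng):
        # conditional independence across marks within a fixed path
        pair2 = random_pair(rng, 2, 2, H=2)
        path = enumerate_alignments(2, 2)[0]
        params2 = random_params(rng, H=2)
        params1a = EvoParams(nuc=params2.nuc, marks=(params2.marks[0],),
                             indel=params2.indel, s=params2.s)
        params1b = EvoParams(nuc=params2.nuc, marks=(params2.marks[1],),
                             indel=params2.indel, s=params2.s)
        phi = pair2.phi
        phi_a = LocalEquilibria((phi.phi_A1[0],), (phi.phi_B1[0],))
        phi_b = LocalEquilibria((phi.phi_A1[1],), (phi.phi_B1[1],))
        for col in path.columns(pair2):
            ca = AlignmentColumn(col.a0, col.b0, col.a_marks[:1], col.b_marks[:1])
            cb = AlignmentColumn(col.a0, col.b0, col.a_marks[1:], col.b_marks[1:])
            for model in ModelKind:
                pA2, pB2 = column_cond_probs(model, col, params2, phi)
                pAa, pBa = column_cond_probs(model, ca, params1a, phi_a)
                pAb, pBb = column_cond_probs(model, cb, params1b, phi_b)
                assert pA2 == pytest.approx(pAa * pAb, rel=1e-12)
                assert pB2 == pytest.approx(pBa * pBb, rel=1e-12)

    def test_likelihood_finite_at_scale(self, rng):
        # 500-bp products underflow naive double precision; the scaled DP must not
        pair = random_pair(rng, 500, 480)
        params = random_params(rng)
        for model in ModelKind:
            val = pair_log_likelihood(pair, model, params)
            assert math.isfinite(val) and val < 0
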