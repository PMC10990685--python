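"""Event normalization, extinction fixed points and the likelihood DP."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dtlrec.ccp import GeneSpeciesMap, TreeSample, build_ccp
from dtlrec.likelihood import (
    PrecisionPolicy,
    _check_mapping,
    _dp_float_pure,
    clade_probabilities,
    compute_extinction,
    compute_family,
    family_likelihood,
    joint_likelihood,
)
from dtlrec.rates import RateError, RateModel, normalize_rates
from dtlrec.trees import SpeciesTree

from conftest import deep_multicopy_family


class TestNormalizeRates:
    @pytest.mark.parametrize(
        "rates, expected",
        [
            ((0.0, 0.0, 0.0), (1.0, 0.0, 0.0, 0.0)),
            ((1.0, 1.0, 1.0), (0.25, 0.25, 0.25, 0.25)),
            ((0.2, 0.1, 0.1), (1 / 1.4, 0.2 / 1.4, 0.1 / 1.4, 0.1 / 1.4)),
        ],
    )
    def test_normalization(self, rates, expected):
        ep = normalize_rates(*rates, n_branches=3)
        got = (ep.p_S[0], ep.p_D[0], ep.p_T[0], ep.p_L[0])
        assert got == pytest.approx(expected, abs=1e-15)
        ep.validate()

    def test_negative_rate_rejected(self):
        with pytest.raises(RateError, match="negative"):
            normalize_rates(-0.1, 0.0, 0.0, n_branches=1)

    def test_non_finite_rejected(self):
        with pytest.raises(RateError, match="non-finite"):
            normalize_rates(float("nan"), 0.0, 0.0, n_branches=1)


class TestExtinction:
    def test_zero_loss_gives_zero_extinction(self, three_species_tree):
        ep = normalize_rates(0.5, 0.5, 0.0, n_branches=5)
        E = compute_extinction(ep, three_species_tree)
        assert np.all(E.E == 0.0)
        assert E.converged

    def test_single_leaf_closed_form(self):
        """E = λ/(1+λ) on an isolated species branch with δ=τ=0."""
        S = SpeciesTree.from_newick("A;")
        for lam in (0.5, 1.0, 2.0):
            ep = normalize_rates(0.0, 0.0, lam, n_branches=1)
            E = compute_extinction(ep, S)
            assert E.E[0] == pytest.approx(lam / (1 + lam), abs=1e-10)

    def test_two_leaf_closed_form(self):
        """Root extinction 0.625 at δ=τ=0, λ=1 (E_leaf=1/2, E_root=1/2+1/2·1/4)."""
        S = SpeciesTree.from_newick("(A,B);")
        ep = normalize_rates(0.0, 0.0, 1.0, n_branches=3)
        E = compute_extinction(ep, S)
        leaves = [int(i) for i in S.leaf_nodes]
        assert all(E.E[i] == pytest.approx(0.5, abs=1e-10) for i in leaves)
        assert E.E[S.root] == pytest.approx(0.625, abs=1e-10)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        lam1=st.floats(0.0, 2.0),
        lam2=st.floats(0.0, 2.0),
        delta=st.floats(0.0, 0.5),
        tau=st.floats(0.0, 0.5),
    )
    def test_monotone_in_loss_rate(self, lam1, lam2, delta, tau):
        S = SpeciesTree.from_newick("((A,B),C);")
        lo, hi = sorted((lam1, lam2))
        E_lo = compute_extinction(normalize_rates(delta, tau, lo, n_branches=5), S)
        E_hi = compute_extinction(normalize_rates(delta, tau, hi, n_branches=5), S)
        assert np.all(E_hi.E >= E_lo.E - 1e-12)
        assert np.all((E_lo.E >= 0) & (E_lo.E <= 1))


class TestCladeProbabilities:
    def test_single_gene_single_species(self):
        S = SpeciesTree.from_newick("X;")
        ccp = build_ccp(
            TreeSample("f", ["x"], rooted=True), GeneSpeciesMap({"x": "X"})
        )
        fl, M = compute_family(ccp, S, 0.0, 0.0, 0.0)
        assert np.asarray(M.root_vector())[0] == pytest.approx(1.0)
        assert fl.log_likelihood == pytest.approx(0.0)

    def test_congruent_family_pure_speciation(self, three_species_tree, congruent_ccp):
        """Only the history that originates at the root and speciates survives."""
        fl, M = compute_family(congruent_ccp, three_species_tree, 0.0, 0.0, 0.0)
        root = np.asarray(M.root_vector())
        assert root[three_species_tree.root] == pytest.approx(1.0)
        assert np.all(root[: three_species_tree.root] == 0.0)

    def test_survival_conditioning_closed_form(self):
        """Single gene, λ=1: P=p_S=1/2 and 1−E=1/2, so the conditioned
        probability is exactly one."""
        S = SpeciesTree.from_newick("X;")
        ccp = build_ccp(TreeSample("f", ["x"], rooted=True), GeneSpeciesMap({"x": "X"}))
        fl, M = compute_family(ccp, S, 0.0, 0.0, 1.0)
        assert np.asarray(M.root_vector())[0] == pytest.approx(0.5)
        assert fl.log_likelihood == pytest.approx(0.0, abs=1e-12)

    def test_unmapped_species_rejected(self, congruent_ccp):
        S = SpeciesTree.from_newick("((A,B),D);")
        from dtlrec.likelihood import MappingError

        with pytest.raises(MappingError, match="absent from the species tree"):
            compute_family(congruent_ccp, S, 0.1, 0.1, 0.1)

    def test_jit_and_pure_paths_agree(self, three_species_tree, mixed_ccp):
        ep = normalize_rates(0.2, 0.15, 0.1, n_branches=5)
        E = compute_extinction(ep, three_species_tree)
        policy = PrecisionPolicy(allow_extended=False)
        ltn = _check_mapping(mixed_ccp, three_species_tree)
        M_pure, _ = _dp_float_pure(
            mixed_ccp, three_species_tree, ep, E, ltn, policy, 4, 1e-12
        )
        M_any = clade_probabilities(mixed_ccp, three_species_tree, ep, E, policy)
        for mask in M_pure.P:
            np.testing.assert_allclose(
                np.asarray(M_any.P[mask]), M_pure.P[mask], rtol=1e-12
            )

    def test_relabeling_invariance(self, mixed_ccp):
        """Consistently permuting species names leaves likelihoods unchanged."""
        S1 = SpeciesTree.from_newick("((A,B),C);")
        fl1, _ = compute_family(mixed_ccp, S1, 0.2, 0.1, 0.15)
        # rename A<->C everywhere (tree and mapping)
        S2 = SpeciesTree.from_newick("((C,B),A);")
        trees = (
            [(("a", "b"), "c")] * 60 + [(("a", "c"), "b")] * 30 + [(("b", "c"), "a")] * 10
        )
        ccp2 = build_ccp(
            TreeSample("fam1", trees, rooted=True),
            GeneSpeciesMap({"a": "C", "b": "B", "c": "A"}),
        )
        fl2, _ = compute_family(ccp2, S2, 0.2, 0.1, 0.15)
        assert fl1.log_likelihood == pytest.approx(fl2.log_likelihood, rel=1e-12)


class TestJointLikelihood:
    def test_two_identical_families_double_one(self, three_species_tree, mixed_ccp):
        from dataclasses import replace

        ccp_b = replace(mixed_ccp, family_id="fam2")
        rm = RateModel.global_rates(0.2, 0.1, 0.1)
        single = joint_likelihood([mixed_ccp], three_species_tree, rm)
        double = joint_likelihood([mixed_ccp, ccp_b], three_species_tree, rm)
        assert double == pytest.approx(2.0 * single, rel=1e-15)

    def test_order_invariance_is_bitwise(self, three_species_tree, mixed_ccp, congruent_ccp):
        from dataclasses import replace

        fams = [replace(mixed_ccp, family_id="x"), replace(congruent_ccp, family_id="y")]
        rm = RateModel.global_rates(0.15, 0.05, 0.1)
        a = joint_likelihood(fams, three_species_tree, rm)
        b = joint_likelihood(list(reversed(fams)), three_species_tree, rm)
        assert a == b  # identical reduction order, bitwise equal


class TestPrecisionPolicy:
    def test_deep_multicopy_family_switches_to_extended(self):
        S, ccp = deep_multicopy_family(48, copies=4)
        fl, M = compute_family(ccp, S, 0.01, 0.0, 0.01)
        assert M.representation == "extended"
        assert math.isfinite(fl.log_likelihood)

    def test_extended_agrees_with_standard_on_small_instance(self):
        S, ccp = deep_multicopy_family(6, copies=4)
        fl_std, M_std = compute_family(
            ccp, S, 0.01, 0.0, 0.01, policy=PrecisionPolicy(allow_extended=False)
        )
        fl_ext, _ = compute_family(
            ccp, S, 0.01, 0.0, 0.01, policy=PrecisionPolicy(force_extended=True)
        )
        assert M_std.representation == "standard"
        assert fl_ext.log_likelihood == pytest.approx(
            fl_std.log_likelihood, rel=1e-6
        )
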