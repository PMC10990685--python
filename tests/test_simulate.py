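"""Forward simulation and pseudo-posterior generation."""

import numpy as np
import pytest

from dtlrec.ccp import build_ccp, tree_probability
from dtlrec.sampling import summarize_events
from dtlrec.simulate import (
    SimulationConfig,
    make_pseudo_sample,
    nni_perturb,
    simulate_dataset,
    simulate_family,
)
from dtlrec.trees import SpeciesTree, canonical_nested, nested_leaves


@pytest.fixture
def five_species_tree():
    return SpeciesTree.from_newick("(((A,B),(C,D)),E);")


def big_enough_family(S, rng, min_leaves=4):
    """Redraw event-free families until the gene tree supports NNI moves."""
    while True:
        fam = simulate_family(S, (0.0, 0.0, 0.0), rng)
        if len(nested_leaves(fam.true_tree)) >= min_leaves:
            return fam


class TestSimulateFamily:
    def test_event_free_family_is_congruent(self, five_species_tree):
        rng = np.random.default_rng(0)
        fam = simulate_family(five_species_tree, (0.0, 0.0, 0.0), rng)
        # single copy per species below the origination branch, no D/T/L
        table = summarize_events([fam.true_reconciliation], five_species_tree)
        assert table[["D", "T", "TL", "L"]].to_numpy().sum() == 0.0
        species = sorted(set(fam.mapping.pairs.values()))
        assert len(fam.mapping.pairs) == len(species)  # single-copy

    def test_loss_only_families_never_duplicate(self, five_species_tree):
        rng = np.random.default_rng(1)
        for _ in range(20):
            fam = simulate_family(five_species_tree, (0.0, 0.0, 0.9), rng)
            per_species: dict = {}
            for g, s in fam.mapping.pairs.items():
                per_species[s] = per_species.get(s, 0) + 1
            assert all(v == 1 for v in per_species.values())
            table = summarize_events([fam.true_reconciliation], five_species_tree)
            assert table[["D", "T"]].to_numpy().sum() == 0.0

    def test_rejection_redraws_extinct_families(self, five_species_tree):
        rng = np.random.default_rng(2)
        fam = simulate_family(five_species_tree, (0.0, 0.0, 2.0), rng)
        assert len(fam.mapping.pairs) >= 1
        assert fam.rejected_draws >= 0  # extinct draws are counted, not returned

    def test_runaway_growth_guard(self):
        S = SpeciesTree.from_newick("(A,B);")
        rng = np.random.default_rng(3)
        from dtlrec.simulate import SimulationError

        with pytest.raises(SimulationError, match="runaway"):
            for _ in range(50):
                simulate_family(S, (30.0, 0.0, 0.0), rng)

    def test_generative_counts_match_inferential_sampler(self):
        """Mean duplication count of forward-simulated families agrees with
        the mean over reconciliations sampled from the DP posterior on the
        same data (within Monte-Carlo error)."""
        from dtlrec.likelihood import clade_probabilities, compute_extinction
        from dtlrec.rates import normalize_rates
        from dtlrec.sampling import sample_reconciliations
        from dtlrec.ccp import TreeSample

        S = SpeciesTree.from_newick("((A,B),C);")
        rates = (0.1, 0.0, 0.0)
        rng = np.random.default_rng(4)
        n_rep = 400
        gen_d = []
        inf_d = []
        ep = normalize_rates(*rates, n_branches=S.n_branches)
        E = compute_extinction(ep, S)
        for i in range(n_rep):
            fam = simulate_family(S, rates, rng, family_id=f"f{i}")
            t = summarize_events([fam.true_reconciliation], S)
            gen_d.append(t["D"].sum())
            ccp = build_ccp(
                TreeSample(f"f{i}", [fam.true_tree], rooted=True), fam.mapping
            )
            M = clade_probabilities(ccp, S, ep, E)
            recs = sample_reconciliations(M, r=3, rng=rng)
            ti = summarize_events(recs, S)
            inf_d.append(ti["D"].sum())
        gen = np.mean(gen_d)
        inf = np.mean(inf_d)
        se = np.sqrt(np.var(gen_d) / n_rep + np.var(inf_d) / n_rep)
        assert abs(gen - inf) <= 3 * se + 1e-9


class TestPseudoSample:
    def test_no_perturbation_concentrates_on_truth(self, five_species_tree):
        rng = np.random.default_rng(5)
        fam = big_enough_family(five_species_tree, rng)
        sample = make_pseudo_sample(fam.true_tree, m=50, p=0.0, rng=rng)
        ccp = build_ccp(sample, fam.mapping)
        assert tree_probability(ccp, fam.true_tree) == pytest.approx(1.0)

    def test_perturbation_keeps_truth_as_mode(self, five_species_tree):
        rng = np.random.default_rng(6)
        fam = big_enough_family(five_species_tree, rng)
        sample = make_pseudo_sample(fam.true_tree, m=1000, p=0.3, rng=rng)
        counts: dict = {}
        for t in sample.trees:
            key = canonical_nested(t)
            counts[key] = counts.get(key, 0) + 1
        truth = canonical_nested(fam.true_tree)
        assert counts[truth] == max(counts.values())

    def test_small_tree_warns_and_replicates(self):
        rng = np.random.default_rng(7)
        with pytest.warns(UserWarning, match="fewer than 4 leaves"):
            sample = make_pseudo_sample(("a", "b"), m=5, p=0.5, rng=rng)
        assert sample.trees == [("a", "b")] * 5

    def test_seed_reproducibility(self, five_species_tree):
        fam = simulate_family(
            five_species_tree, (0.0, 0.0, 0.0), np.random.default_rng(8)
        )
        s1 = make_pseudo_sample(fam.true_tree, 30, 0.4, np.random.default_rng(9))
        s2 = make_pseudo_sample(fam.true_tree, 30, 0.4, np.random.default_rng(9))
        assert s1.trees == s2.trees

    def test_nni_preserves_leaf_set(self):
        rng = np.random.default_rng(10)
        t = ((("a", "b"), ("c", "d")), ("e", "f"))
        for _ in range(20):
            t2 = nni_perturb(t, 3, rng)
            assert sorted(nested_leaves(t2)) == sorted(nested_leaves(t))


class TestSimulateDataset:
    def test_reproducible_and_complete(self):
        cfg = SimulationConfig(
            n_species=5, rates=(0.1, 0.05, 0.1), n_families=6,
            sample_size=10, perturbation=0.2, seed=13,
        )
        ds1 = simulate_dataset(cfg)
        ds2 = simulate_dataset(cfg)
        assert ds1.species_tree == ds2.species_tree
        assert len(ds1.families) == 6
        for f1, f2 in zip(ds1.families, ds2.families):
            assert f1.true_tree == f2.true_tree
            assert f1.sample.trees == f2.sample.trees
            for g, s in f1.mapping.pairs.items():
                assert s in ds1.species_tree.leaf_labels
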