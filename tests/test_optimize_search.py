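"""Branch-length/shape optimization, SPR search, bootstrap, model selection."""

import numpy as np
import pytest

from sinaphy.core_io import Alignment, SequenceRecord, read_newick
from sinaphy.phylo import (aicc, bootstrap, infer_ml_tree, log_likelihood,
                           optimize_branch_lengths, optimize_shape,
                           robinson_foulds, select_model, spr_search, unroot)
from sinaphy.simulate import SimulationConfig, simulate_family
from sinaphy.substitution import SubstitutionModel

SPECIES_6 = "(((A:0.12,B:0.2):0.1,(C:0.15,D:0.08):0.12):0.06,(E:0.25,F:0.1):0.06);"
SPECIES_8 = ("((((A:0.1,B:0.12):0.08,(C:0.1,D:0.14):0.06):0.07,"
             "(E:0.1,F:0.18):0.09):0.05,(G:0.2,H:0.11):0.05);")


def _simulate(species, sites, seed, shape=0.8, freqs=None):
    cfg = SimulationConfig(species_tree=species, duplications=(),
                           paralog_rates={"SINA": 1.0},
                           domain_lengths=(("RING", sites),),
                           domain_rates={"RING": 1.0},
                           insertion_rate=0.0, deletion_rate=0.0,
                           gamma_shape=shape, frequencies=freqs, seed=seed)
    return simulate_family(cfg)


class TestBranchOptimization:
    def test_recovers_simulated_branch_lengths(self):
        """6-taxon tree, 5,000 sites: optimized lengths within 15% of the
        generating lengths (longer branches; short ones get an absolute
        floor)."""
        truth = _simulate(SPECIES_6, 5000, seed=21)
        result = optimize_branch_lengths(truth.tree, truth.alignment,
                                         SubstitutionModel("LG", gamma_shape=0.8))
        true_bl = {frozenset(n.leaf_names()): n.length
                   for n in unroot(truth.tree).root.postorder()
                   if n.parent is not None}
        est_bl = {frozenset(n.leaf_names()): n.length
                  for n in unroot(result.tree).root.postorder()
                  if n.parent is not None}
        for key, t in true_bl.items():
            assert est_bl[key] == pytest.approx(t, rel=0.15, abs=0.015)

    def test_monotone_trace_and_fixed_point(self):
        truth = _simulate(SPECIES_6, 800, seed=22)
        model = SubstitutionModel("LG", gamma_shape=0.8)
        first = optimize_branch_lengths(truth.tree, truth.alignment, model)
        assert all(np.diff(first.trace) >= -1e-9)
        again = optimize_branch_lengths(first.tree, truth.alignment, model)
        assert abs(again.log_likelihood - first.log_likelihood) < 1e-4


class TestShapeOptimization:
    def test_recovers_simulated_shape(self):
        """Data generated with gamma shape 0.6: the estimate lands in
        [0.45, 0.8]."""
        truth = _simulate(SPECIES_8, 3000, seed=23, shape=0.6)
        model, lnl = optimize_shape(truth.tree, truth.alignment,
                                    SubstitutionModel("LG", gamma_shape=1.0))
        assert 0.45 <= model.gamma_shape <= 0.8
        assert lnl >= log_likelihood(truth.tree, truth.alignment,
                                     SubstitutionModel("LG", gamma_shape=1.0))


class TestSPR:
    def test_true_topology_is_a_local_optimum(self):
        truth = _simulate(SPECIES_6, 2000, seed=24)
        model = SubstitutionModel("LG", gamma_shape=0.8)
        result = spr_search(truth.tree, truth.alignment, model, level=5)
        assert robinson_foulds(result.tree, truth.tree) == 0
        assert len(result.trace) == 1   # no improving move accepted

    def test_final_likelihood_never_below_start(self):
        truth = _simulate(SPECIES_6, 300, seed=25)
        model = SubstitutionModel("LG", gamma_shape=0.8)
        scrambled = read_newick(
            "((A_SINA:0.1,F_SINA:0.1):0.1,((C_SINA:0.1,E_SINA:0.1):0.1,"
            "(B_SINA:0.1,D_SINA:0.1):0.1):0.1);")
        start_lnl = log_likelihood(scrambled, truth.alignment, model)
        result = spr_search(scrambled, truth.alignment, model, level=5)
        assert result.log_likelihood >= start_lnl
        assert all(np.diff(result.trace) > 0)

    @pytest.mark.parametrize("seed", range(5))
    def test_recovers_topology_from_scrambled_start(self, seed):
        """8-taxon simulated data, deliberately wrong starting topology:
        SPR level 5 finds the generating topology."""
        truth = _simulate(SPECIES_8, 1000, seed=100 + seed)
        model = SubstitutionModel("LG", gamma_shape=0.8)
        scrambled = read_newick(
            "((A_SINA:0.1,C_SINA:0.1):0.1,((B_SINA:0.1,(D_SINA:0.1,"
            "(E_SINA:0.1,G_SINA:0.1):0.1):0.1):0.1,"
            "(F_SINA:0.1,H_SINA:0.1):0.1):0.1);")
        result = spr_search(scrambled, truth.alignment, model, level=5)
        assert robinson_foulds(result.tree, truth.tree) == 0


class TestBootstrap:
    def test_same_seed_reproduces_supports(self):
        truth = _simulate(SPECIES_6, 400, seed=26)
        model = SubstitutionModel("LG", gamma_shape=0.8)
        main = infer_ml_tree(truth.alignment, model, do_spr=False).tree
        t1 = bootstrap(truth.alignment, model, n_replicates=20, seed=7,
                       main_tree=main)
        t2 = bootstrap(truth.alignment, model, n_replicates=20, seed=7,
                       main_tree=main)
        assert t1.newick() == t2.newick()

    def test_strong_branch_gets_high_support(self):
        """A long internal branch separating two clades is recovered with
        >= 90% support at 50 replicates."""
        species = "(((A:0.1,B:0.1):0.5,(C:0.1,D:0.1):0.5):0.05,(E:0.3,F:0.3):0.05);"
        truth = _simulate(species, 1000, seed=27)
        model = SubstitutionModel("LG", gamma_shape=0.8)
        tree = bootstrap(truth.alignment, model, n_replicates=50, seed=3,
                         main_tree=truth.tree)
        target = frozenset({"A_SINA", "B_SINA"})
        supports = {n.leaf_names(): n.support for n in tree.root.postorder()
                    if n.support is not None}
        side = next(s for s in supports
                    if s == target or s == frozenset(tree.leaf_names) - target)
        assert supports[side] >= 90

    def test_no_signal_leaves_supports_absent(self):
        """Four identical sequences: no resolved bipartition, so no support
        values are reported."""
        aln = Alignment([SequenceRecord(id=f"s{i}", residues="ACDEFGHIKL" * 3)
                         for i in range(4)])
        model = SubstitutionModel("LG", gamma_shape=None)
        tree = bootstrap(aln, model, n_replicates=10, seed=1)
        assert all(n.support is None for n in tree.root.postorder())


class TestModelSelection:
    def test_aicc_formula(self):
        k, lnl, n = 13, -2345.6789, 305
        expected = 2 * k - 2 * lnl + 2 * k * (k + 1) / (n - k - 1)
        assert aicc(k, lnl, n) == pytest.approx(expected, abs=1e-9)

    def test_equal_likelihood_prefers_fewer_parameters(self):
        assert aicc(10, -100.0, 500) < aicc(11, -100.0, 500)

    def test_insufficient_columns_flagged(self):
        assert aicc(50, -10.0, 40) == np.inf

    def test_generating_model_ranks_first(self):
        """3,000 sites simulated under LG+G with skewed frequencies: the
        16-candidate grid ranks LG+G+F first."""
        from sinaphy.substitution import load_exchangeabilities
        _, jtt_freqs = load_exchangeabilities("JTT")
        skew = jtt_freqs ** 1.5
        skew /= skew.sum()
        truth = _simulate(SPECIES_8, 3000, seed=28, shape=0.6, freqs=skew)
        table, records = select_model(truth.alignment, truth.tree)
        assert table.iloc[0]["model"] == "LG+G+F"
        assert records[0].aicc <= records[1].aicc
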