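"""Synthetic gene-family generator: determinism, rate structure, indels."""

import numpy as np
import pytest

from sinaphy.conservation import build_consensus
from sinaphy.core_io import Alignment
from sinaphy.simulate import (DEFAULT_DOMAIN_LENGTHS, SimulationConfig,
                              build_gene_tree, leaf_paralog, make_fixture_suite,
                              simulate_family, write_truth)


class TestGeneTree:
    def test_duplications_create_three_paralog_lineages(self, small_family):
        labels = {leaf_paralog(n)[1] for n in small_family.tree.leaf_names}
        assert labels == {"SIAH1", "SIAH2", "SIAH3", "SINA"}
        # every ingroup species carries all three paralogs
        per_species = {}
        for name in small_family.tree.leaf_names:
            sp, lab = leaf_paralog(name)
            per_species.setdefault(sp, set()).add(lab)
        assert per_species["sp1"] == {"SIAH1", "SIAH2", "SIAH3"}
        assert per_species["out"] == {"SINA"}

    def test_rate_multipliers_scale_branch_lengths(self):
        cfg = SimulationConfig()
        tree = build_gene_tree(cfg)
        # tip branches of sp-level leaves: SIAH3 10x longer than SIAH1
        tips = {n.name: n.length for n in tree.root.leaves()}
        assert tips["sp1_SIAH3"] == pytest.approx(10 * tips["sp1_SIAH1"])
        assert tips["sp1_SIAH2"] == pytest.approx(2 * tips["sp1_SIAH1"])

    def test_unknown_duplication_clade_rejected(self):
        cfg = SimulationConfig(duplications=((("sp1", "out"), "SINA",
                                              ("A", "B")),))
        with pytest.raises(ValueError, match="not a.*clade"):
            build_gene_tree(cfg)

    def test_invalid_multiplier_rejected(self):
        with pytest.raises(ValueError, match="> 0"):
            SimulationConfig(paralog_rates={"SINA": 0.0})


class TestDeterminism:
    def test_same_seed_byte_identical_outputs(self, tmp_path):
        cfg = dict(seed=9, domain_lengths=(("NTERM", 30), ("RING", 20)),
                   domain_rates={"NTERM": 2.0, "RING": 0.5})
        p1 = write_truth(simulate_family(SimulationConfig(**cfg)), tmp_path / "a")
        p2 = write_truth(simulate_family(SimulationConfig(**cfg)), tmp_path / "b")
        for key in p1:
            assert open(p1[key], "rb").read() == open(p2[key], "rb").read()

    def test_different_seeds_differ(self):
        a = simulate_family(SimulationConfig(seed=1))
        b = simulate_family(SimulationConfig(seed=2))
        assert a.alignment.records[0].residues != b.alignment.records[0].residues


class TestFrozenDomain:
    def test_zero_rate_domain_is_invariant(self):
        cfg = SimulationConfig(seed=4, domain_rates={"NTERM": 2.0, "RING": 0.5,
                                                     "SZF": 0.8, "SBS": 0.0,
                                                     "DIMER": 0.6})
        truth = simulate_family(cfg)
        sbs_cols = [i for i, d in enumerate(truth.column_domains) if d == "SBS"]
        root_sbs_start = sum(L for n, L in DEFAULT_DOMAIN_LENGTHS
                             if n in ("NTERM", "RING", "SZF"))
        expected = truth.root_sequence[root_sbs_start:root_sbs_start + 25]
        for rec in truth.alignment.records:
            observed = "".join(rec.residues[c] for c in sbs_cols)
            assert observed == expected
        sub = Alignment([rec for rec in truth.alignment.records])
        cons = build_consensus(sub)
        in_sbs = [r for r, c in zip(cons.residues, cons.columns)
                  if truth.column_domains[int(c) - 1] == "SBS"]
        assert "X" not in in_sbs


class TestAlignmentStructure:
    def test_column_count_is_root_length_plus_insertions(self, small_family):
        cfg = small_family.config
        assert small_family.alignment.n_columns >= cfg.root_length
        inserted = small_family.alignment.n_columns - cfg.root_length
        nterm_cols = sum(1 for d in small_family.column_domains if d == "NTERM")
        assert nterm_cols == cfg.domain_lengths[0][1] + inserted

    def test_indels_confined_to_nterm(self, small_family):
        for rec in small_family.alignment.records:
            for j, dom in enumerate(small_family.column_domains):
                if dom != "NTERM":
                    assert rec.residues[j] != "-", \
                        f"gap outside the N-terminal region in {rec.id}"

    def test_nterm_lengths_vary(self, small_family):
        lengths = []
        for rec in small_family.alignment.records:
            n = sum(1 for j, dom in enumerate(small_family.column_domains)
                    if dom == "NTERM" and rec.residues[j] != "-")
            lengths.append(n)
        assert max(lengths) - min(lengths) > 10

    def test_domain_maps_match_ungapped_coordinates(self, small_family):
        rec = small_family.alignment.records[0]
        dmap = small_family.domain_maps[rec.id]
        lo, hi = dmap.spans["SBS"]
        assert hi - lo + 1 == 25


class TestSiteRates:
    def test_category_variance_matches_discrete_gamma(self):
        """Moment check at 10,000 sites: the empirical variance of assigned
        category rates matches the discrete-gamma variance within 15%."""
        cfg = SimulationConfig(seed=5, domain_lengths=(("RING", 10_000),),
                               domain_rates={"RING": 1.0}, duplications=(),
                               paralog_rates={"SINA": 1.0},
                               insertion_rate=0.0, deletion_rate=0.0,
                               species_tree="((A:0.2,B:0.2):0.1,C:0.3);",
                               gamma_shape=0.5852)
        from sinaphy.simulate import _Evolver
        rng = np.random.default_rng(cfg.seed)
        evo = _Evolver(cfg, rng)
        evo.root_sequence()
        rates = evo.rates
        assigned = np.array([rates[evo.col_cat[c]] for c in evo.master])
        analytic_var = float(np.mean(rates ** 2) - np.mean(rates) ** 2)
        assert np.var(assigned) == pytest.approx(analytic_var, rel=0.15)

    def test_substitution_counts_scale_with_domain_rate(self):
        """Fraction of changed sites per domain grows with the domain
        multiplier and tracks the model's expected change probability."""
        lengths = (("RING", 3000), ("SZF", 3000), ("SBS", 3000))
        rates = {"RING": 0.25, "SZF": 1.0, "SBS": 2.0}
        cfg = SimulationConfig(seed=6, domain_lengths=lengths,
                               domain_rates=rates, duplications=(),
                               paralog_rates={"SINA": 1.0},
                               insertion_rate=0.0, deletion_rate=0.0,
                               species_tree="((A:0.5,B:0.5):0.01,C:0.5);",
                               gamma_shape=None)
        truth = simulate_family(cfg)
        model = cfg.model()
        pi = model.frequencies
        rec = truth.alignment.record("A_SINA")
        # branch A root->tip ~ 0.51
        t = 0.51
        observed, expected = {}, {}
        for dom, g in rates.items():
            cols = [i for i, d in enumerate(truth.column_domains) if d == dom]
            diff = sum(truth.root_sequence[i] != rec.residues[i] for i in cols)
            observed[dom] = diff / len(cols)
            P = model.transition_matrix(t * g)
            expected[dom] = float(1 - np.dot(pi, np.diag(P)))
        assert observed["RING"] < observed["SZF"] < observed["SBS"]
        for dom in rates:
            assert observed[dom] == pytest.approx(expected[dom], rel=0.2)


class TestFixtures:
    def test_tiny_suite_contents(self, tmp_path):
        paths = make_fixture_suite("tiny", seed=1, outdir=tmp_path)
        assert (tmp_path / "toy_gappy.fasta").exists()
        assert (tmp_path / "additive_matrix.tsv").exists()
        from sinaphy.core_io import read_fasta
        aln = read_fasta(paths["alignment"], aligned=True)
        assert aln.n_records == 4 and aln.n_columns == 12

    def test_fixture_hashes_stable_under_seed(self, tmp_path):
        import hashlib
        p1 = make_fixture_suite("tiny", seed=3, outdir=tmp_path / "x")
        p2 = make_fixture_suite("tiny", seed=3, outdir=tmp_path / "y")
        h = lambda p: hashlib.sha256(open(p, "rb").read()).hexdigest()
        assert h(p1["alignment"]) == h(p2["alignment"])
        assert h(p1["tree"]) == h(p2["tree"])
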