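"""Synthetic-data generator: Yule trees, planted hybrids, sequence evolution."""

import math
from pathlib import Path

import dendropy
import numpy as np
import pytest

from cytodisc import msa
from cytodisc.simulate import (
    RegionSpec,
    SimulationConfig,
    SimulationError,
    evolve_alignment,
    make_benchmark,
    plant_hybrids,
    simulate_bundle,
    simulate_species_tree,
    yule_lineage_count,
)
from cytodisc.trees import Tree, rf_distance
from tests.conftest import small_config


class TestSpeciesTree:
    def test_minimum_size_enforced(self):
        with pytest.raises(SimulationError):
            simulate_species_tree(2, 1.0, seed=1)

    def test_edge_count(self):
        tree = simulate_species_tree(10, 1.0, seed=1)
        # unrooted binary: 2n - 3 edges
        assert tree.n_edges() == 17
        assert tree.is_binary_unrooted()

    def test_yule_lineage_expectation(self):
        # E[N(t)] = 2 e^{lambda t} for a pure-birth process from 2 lineages
        rng = np.random.default_rng(99)
        lam, t, n = 1.0, 0.8, 500
        draws = [yule_lineage_count(t, lam, rng) for _ in range(n)]
        mean = np.mean(draws)
        se = np.std(draws, ddof=1) / math.sqrt(n)
        assert abs(mean - 2 * math.exp(lam * t)) <= 3 * se


class TestPlantHybrids:
    def test_noop_hybrid_keeps_species_tree(self):
        cfg = small_config(seed=13)
        rng = np.random.default_rng(13)
        species = simulate_species_tree(cfg.n_taxa, cfg.birth_rate, rng=rng)
        label = sorted(species.leaf_labels())[0]
        core = species.leaf_labels() - {label}
        leaf = species.find_leaf(label)
        # donor = the hybrid's original edge in both classes
        side = frozenset(
            l.label for l in _leaves(leaf.parent)
        ) & core
        gene_trees, truth = plant_hybrids(
            species, cfg, rng, donors={label: (side, side)}
        )
        assert rf_distance(gene_trees[msa.PLASTID], species) == 0
        assert rf_distance(gene_trees[msa.NUCLEAR], species) == 0

    def test_distinct_donors_give_discordant_gene_trees(self, small_bundle):
        truth = small_bundle.truth
        t_pl = truth.gene_trees[msa.PLASTID]
        t_its = truth.gene_trees[msa.NUCLEAR]
        # independent RF oracle via dendropy
        ns = dendropy.TaxonNamespace()
        d1 = t_pl.to_dendropy(ns)
        d2 = t_its.to_dendropy(ns)
        d1.encode_bipartitions()
        d2.encode_bipartitions()
        rf = dendropy.calculate.treecompare.symmetric_difference(d1, d2)
        assert rf > 0
        assert rf == rf_distance(t_pl, t_its)

    def test_nonhybrid_backbone_identical_across_gene_trees(self, small_bundle):
        truth = small_bundle.truth
        core = truth.species_tree.leaf_labels() - truth.hybrid_labels
        a = truth.gene_trees[msa.PLASTID].restrict(core)
        b = truth.gene_trees[msa.NUCLEAR].restrict(core)
        c = truth.species_tree.restrict(core)
        assert a.split_set() == b.split_set() == c.split_set()

    def test_donor_separation_respected(self, small_bundle):
        truth = small_bundle.truth
        cfg = truth.config
        core = truth.species_tree.leaf_labels() - truth.hybrid_labels
        backbone = truth.species_tree.restrict(core)
        clades = backbone.clades()
        for h in truth.hybrids:
            nodes = []
            for want in (h.plastid_donor, h.its_donor):
                for n in backbone.postorder():
                    if n is backbone.root:
                        continue
                    if clades[n] == want or (core - clades[n]) == want:
                        nodes.append(n)
                        break
            assert len(nodes) == 2
            assert (
                backbone.edge_distance(nodes[0], nodes[1])
                >= cfg.min_donor_separation
            )

    def test_shared_its_scenario_builds_hybrid_cherry(self):
        cfg = small_config(
            n_taxa=16, n_hybrids=2, scenario="shared_its", seed=23
        )
        bundle = simulate_bundle(cfg)
        truth = bundle.truth
        h1, h2 = sorted(truth.hybrid_labels)
        assert truth.donor_edges(h1)[1] == truth.donor_edges(h2)[1]
        assert truth.donor_edges(h1)[0] != truth.donor_edges(h2)[0]
        nuc = truth.gene_trees[msa.NUCLEAR]
        cherry = {
            frozenset(l.label for l in n.children)
            for n in nuc.postorder()
            if len(n.children) == 2 and all(c.is_leaf() for c in n.children)
        }
        assert frozenset([h1, h2]) in cherry


class TestEvolveAlignment:
    def test_zero_lengths_copy_root_state(self):
        tree = Tree.from_newick("(a:0,b:0,c:0,d:0);")
        cfg = small_config(
            n_taxa=4, n_hybrids=0,
            regions=(RegionSpec("r", 200, msa.PLASTID, 1.0),),
            seed=2,
        )
        aln, _ = evolve_alignment(
            {msa.PLASTID: tree, msa.NUCLEAR: tree}, cfg,
            np.random.default_rng(2),
        )
        seqs = {aln.sequence(t) for t in aln.taxa}
        assert len(seqs) == 1

    def test_jc_pairwise_mismatch_expectation(self):
        d = 0.2
        tree = Tree.from_newick(f"(a:{d / 2},b:{d / 2},c:0.01,e:0.01);")
        L = 10000
        cfg = small_config(
            n_taxa=4, n_hybrids=0,
            regions=(RegionSpec("r", L, msa.PLASTID, 1.0),),
            exchangeabilities=(1.0,) * 6, base_freqs=(0.25,) * 4,
            gamma_shape=None, seed=3,
        )
        aln, _ = evolve_alignment(
            {msa.PLASTID: tree, msa.NUCLEAR: tree}, cfg,
            np.random.default_rng(3),
        )
        p_hat = sum(
            x != y for x, y in zip(aln.sequence("a"), aln.sequence("b"))
        ) / L
        p = 0.75 * (1 - math.exp(-4 * d / 3))
        se = math.sqrt(p * (1 - p) / L)
        assert abs(p_hat - p) <= 3 * se

    def test_base_composition_matches_pi(self):
        bundle = simulate_bundle(small_config(seed=17, n_hybrids=0))
        pi = np.asarray(bundle.config.base_freqs)
        seq = "".join(bundle.alignment.matrix.values())
        N = len(seq)
        for i, base in enumerate("ACGT"):
            p_hat = seq.count(base) / N
            se = math.sqrt(pi[i] * (1 - pi[i]) / N)
            # sites along a tree are correlated; allow a generous margin
            assert abs(p_hat - pi[i]) <= max(6 * se, 0.01)

    def test_missing_fraction_masks_whole_regions(self):
        cfg = small_config(seed=19, n_hybrids=0, missing_fraction=0.3)
        bundle = simulate_bundle(cfg)
        aln, scheme = bundle.alignment, bundle.scheme
        masked = 0
        total = 0
        for t in aln.taxa:
            for r in scheme.regions:
                cols = r.columns()
                chunk = "".join(aln.sequence(t)[c] for c in cols)
                total += 1
                if set(chunk) == {"?"}:
                    masked += 1
                else:
                    assert "?" not in chunk
        assert 0 < masked < total


class TestBundles:
    def test_byte_identical_given_seed(self, tmp_path):
        cfg = small_config(seed=29)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        make_benchmark(cfg, d1)
        make_benchmark(cfg, d2)
        files = sorted(p.name for p in d1.iterdir())
        assert files == sorted(p.name for p in d2.iterdir())
        for name in files:
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_seed_changes_alignment_not_shape(self, tmp_path):
        b1 = simulate_bundle(small_config(seed=1))
        b2 = simulate_bundle(small_config(seed=2))
        assert b1.alignment.n_columns == b2.alignment.n_columns
        assert b1.alignment.taxa == b2.alignment.taxa
        assert b1.alignment.matrix != b2.alignment.matrix

    def test_bundle_reload_passes_validation(self, tmp_path):
        cfg = small_config(seed=31)
        out = tmp_path / "bundle"
        bundle = make_benchmark(cfg, out)
        aln = msa.read_alignment(out / "alignment.fasta")
        scheme = msa.read_partitions(out / "partitions.txt")
        scheme.validate_against(aln)
        assert aln == bundle.alignment
        nuc = msa.subset(aln, scheme, msa.NUCLEAR)
        assert nuc.n_columns == 500

    def test_hybrid_cap_enforced(self):
        with pytest.raises(SimulationError):
            SimulationConfig(n_taxa=8, n_hybrids=3)


def _leaves(node):
    out = []
    stack = [node]
    while stack:
        n = stack.pop()
        if n.is_leaf():
            out.append(n)
        stack.extend(n.children)
    return out
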