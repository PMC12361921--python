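"""Pruning likelihood against brute-force enumeration, plus engine props."""

import itertools
import math

import numpy as np
import pytest

from cytodisc import msa
from cytodisc.likelihood import (
    CHAR_MASKS,
    Engine,
    PatternData,
    TreeIndex,
    optimize_edges,
)
from cytodisc.inference import log_likelihood, optimize_branch_lengths
from cytodisc.models import SubstitutionModel, transition_matrix
from cytodisc.trees import Tree, random_binary_tree


def brute_force_lnl(aln, tree, model):
    """Exhaustive sum over internal-node state assignments (oracle)."""
    nodes = list(tree.postorder())
    internals = [n for n in nodes if not n.is_leaf()]
    cats = model.category_rates()
    pi = model.pi
    total = 0.0
    for site in range(aln.n_columns):
        site_l = 0.0
        for rate in cats:
            Ps = {
                id(n): transition_matrix(model, n.length, float(rate))
                for n in nodes if n.parent is not None
            }
            acc = 0.0
            for assign in itertools.product(range(4), repeat=len(internals)):
                amap = {id(n): a for n, a in zip(internals, assign)}
                p = pi[amap[id(tree.root)]]
                for n in nodes:
                    if n.parent is None:
                        continue
                    pa = amap[id(n.parent)]
                    if n.is_leaf():
                        mask = CHAR_MASKS[aln.sequence(n.label)[site]]
                        p *= sum(
                            Ps[id(n)][pa, b] for b in range(4) if mask & (1 << b)
                        )
                    else:
                        p *= Ps[id(n)][pa, amap[id(n)]]
                acc += p
            site_l += acc / len(cats)
        total += math.log(site_l)
    return total


def random_instance(rng, max_taxa=5, max_sites=12):
    n = int(rng.integers(4, max_taxa + 1))
    labels = [f"s{i}" for i in range(n)]
    tree = random_binary_tree(labels, rng, 0.02, 1.0)
    L = int(rng.integers(4, max_sites + 1))
    alphabet = list("ACGT") + ["-", "R", "Y", "N"]
    recs = [(l, "".join(rng.choice(alphabet, size=L))) for l in labels]
    aln = msa.Alignment.from_records(recs)
    pick = rng.integers(3)
    if pick == 0:
        model = SubstitutionModel.jc()
    elif pick == 1:
        model = SubstitutionModel.hky(2.5, (0.3, 0.2, 0.2, 0.3), 0.5)
    else:
        model = SubstitutionModel.gtr(
            (1.2, 3.0, 0.8, 1.1, 3.5, 1.0), (0.28, 0.22, 0.22, 0.28), 0.7
        )
    return aln, tree, model


class TestPruningOracle:
    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        aln, tree, model = random_instance(rng)
        assert log_likelihood(aln, tree, model) == pytest.approx(
            brute_force_lnl(aln, tree, model), abs=1e-8
        )

    def test_single_site_stationary_pair(self):
        aln = msa.Alignment.from_records([("a", "C"), ("b", "C")])
        tree = Tree.from_newick("(a:0,b:0);")
        lnl = log_likelihood(aln, tree, SubstitutionModel.jc())
        assert lnl == pytest.approx(math.log(0.25), abs=1e-12)

    def test_independence_at_saturation(self):
        aln = msa.Alignment.from_records([("a", "C"), ("b", "G")])
        tree = Tree.from_newick("(a:25,b:25);")
        lnl = log_likelihood(aln, tree, SubstitutionModel.jc())
        assert lnl == pytest.approx(math.log(0.0625), abs=1e-6)

    def test_root_invariance(self):
        aln = msa.Alignment.from_records([
            ("a", "ACGTTGCA"), ("b", "ACGTTGCC"),
            ("c", "ACGATGCA"), ("d", "CCGTTGAA"), ("e", "ACGTTACA"),
        ])
        model = SubstitutionModel.gtr(
            (1.2, 3.0, 0.8, 1.1, 3.5, 1.0), (0.28, 0.22, 0.22, 0.28), 0.7
        )
        rootings = [
            "((a:0.1,b:0.2):0.05,(c:0.3,d:0.1):0.07,e:0.2);",
            "((c:0.3,d:0.1):0.07,(a:0.1,b:0.2):0.05,e:0.2);",
            "(c:0.3,d:0.1,((a:0.1,b:0.2):0.05,e:0.2):0.07);",
        ]
        vals = [
            log_likelihood(aln, Tree.from_newick(nwk), model)
            for nwk in rootings
        ]
        assert max(vals) - min(vals) < 1e-9

    def test_missing_leaf_sequence_rejected(self):
        aln = msa.Alignment.from_records([("a", "AC"), ("b", "AC")])
        tree = Tree.from_newick("((a:0.1,b:0.1):0.1,c:0.1,d:0.1);")
        with pytest.raises(KeyError):
            log_likelihood(aln, tree, SubstitutionModel.jc())


class TestPatternData:
    def test_weights_sum_to_sites(self, small_bundle):
        data = PatternData(
            small_bundle.alignment,
            np.arange(small_bundle.alignment.n_columns),
        )
        assert data.weights.sum() == small_bundle.alignment.n_columns

    def test_ambiguity_indicator_vectors(self):
        aln = msa.Alignment.from_records([("a", "R"), ("b", "N")])
        data = PatternData(aln, [0])
        assert data.leaf_clv("a")[:, 0].tolist() == [1.0, 0.0, 1.0, 0.0]
        assert data.leaf_clv("b")[:, 0].tolist() == [1.0, 1.0, 1.0, 1.0]


class TestBranchOptimization:
    def test_lnl_non_decreasing(self, rng):
        for _ in range(3):
            aln, tree, model = random_instance(
                np.random.default_rng(int(rng.integers(1000)))
            )
            before = log_likelihood(aln, tree, model)
            out = optimize_branch_lengths(aln, tree, model)
            after = log_likelihood(aln, out, model)
            assert after >= before - 1e-9

    def test_fixed_point_at_optimum(self, rng):
        aln, tree, model = random_instance(np.random.default_rng(42))
        once = optimize_branch_lengths(aln, tree, model)
        twice = optimize_branch_lengths(aln, once, model)
        l1 = sorted(n.length for n in once.postorder() if n.parent)
        l2 = sorted(n.length for n in twice.postorder() if n.parent)
        assert np.allclose(l1, l2, atol=1e-3)
        assert log_likelihood(aln, twice, model) == pytest.approx(
            log_likelihood(aln, once, model), abs=1e-4
        )

    def test_length_recovery_on_long_alignment(self):
        # 5 taxa, 10 kb JC: recovered lengths within 10%
        from cytodisc.simulate import RegionSpec, evolve_alignment
        from tests.conftest import small_config

        nwk = "((a:0.12,b:0.08):0.06,(c:0.1,d:0.15):0.09,e:0.2);"
        tree = Tree.from_newick(nwk)
        cfg = small_config(
            n_taxa=5, n_hybrids=0,
            regions=(RegionSpec("r1", 10000, msa.PLASTID, 1.0),),
            exchangeabilities=(1.0,) * 6, base_freqs=(0.25,) * 4,
            gamma_shape=None, seed=9,
        )
        aln, _ = evolve_alignment(
            {msa.PLASTID: tree, msa.NUCLEAR: tree}, cfg,
            np.random.default_rng(9),
        )
        start = Tree.from_newick(nwk)
        for n in start.postorder():
            if n.parent is not None:
                n.length = 0.05
        fitted = optimize_branch_lengths(
            aln, start, SubstitutionModel.jc(), max_sweeps=12
        )
        true_l = {
            frozenset(
                l.label for l in _leaves_below(n)
            ): n.length
            for n in tree.postorder() if n.parent
        }
        fit_l = {
            frozenset(l.label for l in _leaves_below(n)): n.length
            for n in fitted.postorder() if n.parent
        }
        for key, tv in true_l.items():
            assert fit_l[key] == pytest.approx(tv, rel=0.10)


def _leaves_below(node):
    out = []
    stack = [node]
    while stack:
        n = stack.pop()
        if n.is_leaf():
            out.append(n)
        stack.extend(n.children)
    return out


class TestPartitionedAdditivity:
    def test_combined_lnl_is_sum_of_region_lnls(self, small_bundle):
        """Partitioned likelihood additivity at a fixed topology."""
        from cytodisc.inference import neighbor_joining, distance_matrix
        from cytodisc.models import SubstitutionModel

        aln, scheme = small_bundle.alignment, small_bundle.scheme
        data = PatternData(aln, np.arange(aln.n_columns))
        tree = neighbor_joining(distance_matrix(data), aln.taxa)
        model = SubstitutionModel.jc(0.5)
        total = log_likelihood(aln, tree, model)
        parts = sum(
            log_likelihood(aln, tree, model, columns=r.columns())
            for r in scheme.regions
        )
        assert total == pytest.approx(parts, abs=1e-8)
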