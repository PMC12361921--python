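"""Distances, neighbor joining, NNI search and branch supports."""

import math

import numpy as np
import pytest

from cytodisc import msa
from cytodisc.inference import (
    InferenceSettings,
    MissingDistanceError,
    abayes_from_lnls,
    abayes_supports,
    bootstrap_supports,
    infer_tree,
    ml_distance,
    neighbor_joining,
    nni_search,
)
from cytodisc.models import SubstitutionModel, transition_matrix
from cytodisc.simulate import RegionSpec, evolve_alignment
from cytodisc.trees import Tree, random_binary_tree, rf_distance
from tests.conftest import small_config


def path_length(tree, a, b):
    na, nb = tree.find_leaf(a), tree.find_leaf(b)
    anc = {}
    n, d = na, 0.0
    while n is not None:
        anc[id(n)] = d
        d += n.length
        n = n.parent
    n, d = nb, 0.0
    while id(n) not in anc:
        d += n.length
        n = n.parent
    return d + anc[id(n)]


def additive_matrix(tree):
    labels = sorted(tree.leaf_labels())
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = path_length(tree, labels[i], labels[j])
    return D, labels


class TestMlDistance:
    def test_identical_sequences(self):
        assert ml_distance("ACGTAC", "ACGTAC", SubstitutionModel.jc()) == 0.0

    def test_jc_closed_form(self):
        # 3 mismatches over 10 shared columns -> p = 0.3
        a = "AAAAAAAAAA"
        b = "AAAAAAACGT"
        d = ml_distance(a, b, SubstitutionModel.jc())
        assert d == pytest.approx(-0.75 * math.log(0.6), abs=1e-12)

    def test_saturation_cap(self):
        a = "ACGT" * 5
        b = "GTAC" * 5
        assert ml_distance(a, b, SubstitutionModel.jc()) == 5.0

    def test_no_shared_columns_signalled(self):
        with pytest.raises(MissingDistanceError):
            ml_distance("AC??", "??AC", SubstitutionModel.jc())

    def test_hky_matches_grid_oracle(self, rng):
        model = SubstitutionModel.hky(3.0, (0.3, 0.2, 0.2, 0.3))
        seqs = []
        # simulate a pair at t=0.3 under the model
        P = transition_matrix(model, 0.3)
        pi = model.pi
        n = 2000
        x = rng.choice(4, size=n, p=pi)
        cum = P.cumsum(axis=1)
        y = (rng.random(n)[:, None] > cum[x]).sum(axis=1)
        a = "".join("ACGT"[i] for i in x)
        b = "".join("ACGT"[i] for i in y)
        d = ml_distance(a, b, model)
        # independent grid search over the pairwise likelihood
        counts = np.zeros((4, 4))
        for i, j in zip(x, y):
            counts[i, j] += 1
        grid = np.linspace(1e-4, 2.0, 20001)
        lnls = []
        for t in grid:
            Pt = transition_matrix(model, float(t))
            lnls.append((counts * np.log(pi[:, None] * Pt)).sum())
        assert d == pytest.approx(grid[int(np.argmax(lnls))], abs=1e-4)


class TestNeighborJoining:
    def test_three_taxon_formulas(self):
        D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = neighbor_joining(D, ["a", "b", "c"])
        la = tree.find_leaf("a").length
        lb = tree.find_leaf("b").length
        lc = tree.find_leaf("c").length
        assert la == pytest.approx((3 + 4 - 5) / 2)
        assert lb == pytest.approx((3 + 5 - 4) / 2)
        assert lc == pytest.approx((4 + 5 - 3) / 2)

    @pytest.mark.parametrize("seed", range(10))
    def test_exact_on_additive_matrices(self, seed):
        rng = np.random.default_rng(seed)
        labels = [f"x{i}" for i in range(8)]
        true = random_binary_tree(labels, rng, 0.1, 1.0)
        D, labs = additive_matrix(true)
        nj = neighbor_joining(D, labs)
        assert rf_distance(nj, true) == 0
        for i, a in enumerate(labs):
            for b in labs[i + 1:]:
                assert path_length(nj, a, b) == pytest.approx(
                    path_length(true, a, b), abs=1e-9
                )

    def test_tie_broken_to_lowest_pair(self):
        # fully symmetric distances: every Q equal; expect (a, b) joined
        D = np.ones((4, 4)) - np.eye(4)
        tree = neighbor_joining(D, ["a", "b", "c", "d"])
        cherry = {
            frozenset(l.label for l in n.children)
            for n in tree.postorder()
            if len(n.children) == 2 and all(c.is_leaf() for c in n.children)
        }
        assert frozenset(["a", "b"]) in cherry

    def test_asymmetric_rejected(self):
        D = np.array([[0, 1.0], [2.0, 0]])
        with pytest.raises(Exception):
            neighbor_joining(D, ["a", "b"])


def _strong_instance(seed=0, n=8, length=2000):
    rng = np.random.default_rng(seed)
    labels = [f"s{i}" for i in range(n)]
    tree = random_binary_tree(labels, rng, 0.04, 0.25)
    cfg = small_config(
        n_taxa=n, n_hybrids=0,
        regions=(RegionSpec("r1", length, msa.PLASTID, 1.0),),
        exchangeabilities=(1.0,) * 6, base_freqs=(0.25,) * 4,
        gamma_shape=None, seed=seed,
    )
    aln, _ = evolve_alignment(
        {msa.PLASTID: tree, msa.NUCLEAR: tree}, cfg, rng
    )
    return aln, tree


class TestNniSearch:
    def test_true_tree_is_local_optimum(self):
        aln, true = _strong_instance(seed=2)
        out = nni_search(aln, true, SubstitutionModel.jc())
        assert rf_distance(out, true) == 0

    def test_recovers_from_one_swap(self):
        aln, true = _strong_instance(seed=3)
        start = true.copy()
        from cytodisc.inference import _apply_swap
        v = next(iter(start.internal_edges()))
        sibling = next(c for c in v.parent.children if c is not v)
        _apply_swap(v.children[0], sibling)
        assert rf_distance(start, true) > 0
        out = nni_search(aln, start, SubstitutionModel.jc())
        assert rf_distance(out, true) == 0


class TestSupports:
    def test_abayes_equal_lnls_is_one_third(self):
        assert abayes_from_lnls([-50.0, -50.0, -50.0]) == pytest.approx(
            1.0 / 3.0, abs=1e-12
        )

    def test_abayes_softmax_closed_form(self):
        val = abayes_from_lnls([-100.0, -110.0, -110.0])
        assert val == pytest.approx(1.0 / (1.0 + 2.0 * math.exp(-10)), abs=1e-12)

    def test_abayes_bounds(self, rng):
        for _ in range(50):
            lnls = rng.uniform(-500, -100, size=3)
            v = abayes_from_lnls(lnls)
            assert 1.0 / 3.0 - 1e-12 <= v <= 1.0

    def test_abayes_high_on_clean_data(self):
        aln, true = _strong_instance(seed=4, length=4000)
        tree = abayes_supports(aln, true, SubstitutionModel.jc())
        values = [n.abayes for n in tree.internal_edges() if n.abayes]
        assert values and min(values) > 0.9

    def test_bootstrap_identity_resample_gives_100(self):
        aln, true = _strong_instance(seed=5, length=500)
        tree = bootstrap_supports(
            aln, None, true, SubstitutionModel.jc(), B=1, seed=0,
            resample_fn=lambda d, rng: d,
        )
        values = [n.bs for n in tree.internal_edges() if n.bs is not None]
        assert values and all(v == 100.0 for v in values)

    def test_bootstrap_rejects_zero_replicates(self):
        aln, true = _strong_instance(seed=5, length=200)
        with pytest.raises(Exception):
            bootstrap_supports(
                aln, None, true, SubstitutionModel.jc(), B=0, seed=0
            )


class TestInferTree:
    def test_recovers_clean_topology_and_order_invariance(self, small_bundle):
        cfg = small_config(n_hybrids=0, seed=21)
        from cytodisc.simulate import simulate_bundle

        bundle = simulate_bundle(cfg)
        settings = InferenceSettings(candidates=("GTR+G",))
        tree, models = infer_tree(
            bundle.alignment, bundle.scheme, klass=msa.PLASTID,
            settings=settings, seed=0,
        )
        true = bundle.truth.gene_trees[msa.PLASTID]
        assert rf_distance(tree, true) == 0
        # permuted taxon input order -> identical split set
        aln2 = bundle.alignment.subset_taxa(
            list(reversed(bundle.alignment.taxa))
        )
        tree2, _ = infer_tree(
            aln2, bundle.scheme, klass=msa.PLASTID,
            settings=settings, seed=0,
        )
        assert tree2.split_set() == tree.split_set()

    def test_region_rate_recovery(self):
        # two regions simulated at rates 1x and 3x
        rng = np.random.default_rng(31)
        labels = [f"s{i}" for i in range(8)]
        tree = random_binary_tree(labels, rng, 0.04, 0.2)
        cfg = small_config(
            n_taxa=8, n_hybrids=0,
            regions=(
                RegionSpec("slow", 3000, msa.PLASTID, 1.0),
                RegionSpec("fast", 3000, msa.NUCLEAR, 3.0),
            ),
            exchangeabilities=(1.0,) * 6, base_freqs=(0.25,) * 4,
            gamma_shape=None, seed=31,
        )
        aln, scheme = evolve_alignment(
            {msa.PLASTID: tree, msa.NUCLEAR: tree}, cfg, rng
        )
        settings = InferenceSettings(candidates=("JC",))
        _, models = infer_tree(
            aln, scheme, regions=["slow", "fast"], settings=settings, seed=0,
            with_supports=False,
        )
        rates = {rm.region: rm.rate for rm in models}
        assert rates["fast"] / rates["slow"] == pytest.approx(3.0, rel=0.15)

    def test_too_few_taxa_rejected(self, small_bundle):
        with pytest.raises(Exception):
            infer_tree(
                small_bundle.alignment, small_bundle.scheme,
                klass=msa.PLASTID, taxa=small_bundle.alignment.taxa[:3],
            )
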