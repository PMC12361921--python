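"""Tree inference: distances, neighbor-joining, NNI search, supports.

The search strategy is deliberately simple and deterministic: a
neighbor-joining starting tree from maximum-likelihood pairwise distances,
coordinate-wise branch-length optimization, then a steepest-ascent NNI
hill-climb (best improving move per iteration, locally re-optimizing the
five branch lengths around each candidate swap).  Branch support comes from
the nonparametric bootstrap (columns resampled within each partition
region) and the approximate-Bayes (aBayes) test: the posterior of the best
of the three NNI resolutions of an edge under a uniform prior, so aBayes
values always lie in [1/3, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from . import msa
from .likelihood import (
    Engine,
    LikelihoodError,
    PatternData,
    TreeIndex,
    optimize_edges,
)
from .models import (
    ModelFit,
    SubstitutionModel,
    candidate_models,
    empirical_frequencies,
    transition_matrices,
)
from .trees import Node, Tree

D_MAX = 5.0  # documented cap for saturated pairwise distances


class InferenceError(ValueError):
    pass


class MissingDistanceError(InferenceError):
    """Raised when two sequences share no defined columns."""


# ----------------------------------------------------------------- settings


@dataclass
class RegionModel:
    """A fitted substitution model plus rate multiplier for one region."""

    region: str
    model: SubstitutionModel
    rate: float = 1.0
    log_likelihood: Optional[float] = None

    @property
    def aic(self) -> Optional[float]:
        if self.log_likelihood is None:
            return None
        return 2 * self.model.k_free_parameters() - 2 * self.log_likelihood


@dataclass
class InferenceSettings:
    """Knobs shared by every inference run in a pipeline."""

    candidates: tuple[str, ...] = ("JC", "JC+G", "HKY+G", "GTR+G")
    bootstrap_replicates: int = 0  # 0 = aBayes-only supports
    mode: str = "or"
    bs_min: float = 95.0
    ab_min: float = 0.95
    nni_max_iters: int = 30
    nni_tol: float = 1e-6
    branch_sweeps: int = 3
    fit_rounds: int = 1  # branch/parameter alternations during model fits
    fixed_models: Optional[dict[str, RegionModel]] = None


# ---------------------------------------------------------------- distances


def ml_distance(seq_a: str, seq_b: str, model: SubstitutionModel) -> float:
    """Pairwise ML distance; JC uses its closed form, others 1-D search."""
    if len(seq_a) != len(seq_b):
        raise InferenceError("sequences differ in length")
    counts = _pair_counts(seq_a, seq_b)
    n = counts.sum()
    if n == 0:
        raise MissingDistanceError("no shared defined columns")
    if model.name == "JC" and model.gamma_shape is None:
        p = (counts.sum() - np.trace(counts)) / n
        if p >= 0.75:
            return D_MAX
        d = -0.75 * math.log(1.0 - 4.0 * p / 3.0)
        return min(d, D_MAX)
    eig = model.eigensystem()
    cats = model.category_rates()
    pi = model.pi

    def neg_lnl(t: float) -> float:
        P = transition_matrices(eig, [t], cats)[0]  # (K,4,4)
        joint = (pi[None, :, None] * P).mean(axis=0)
        joint = np.maximum(joint, 1e-300)
        return -float((counts * np.log(joint)).sum())

    res = minimize_scalar(
        neg_lnl, bounds=(1e-8, D_MAX), method="bounded",
        options={"xatol": 1e-6},
    )
    return float(res.x)


def _pair_counts(seq_a: str, seq_b: str) -> np.ndarray:
    index = {"A": 0, "C": 1, "G": 2, "T": 3}
    counts = np.zeros((4, 4))
    for ca, cb in zip(seq_a.upper(), seq_b.upper()):
        ia, ib = index.get(ca), index.get(cb)
        if ia is not None and ib is not None:
            counts[ia, ib] += 1
    return counts


def distance_matrix(
    data: PatternData, correction: str = "jc"
) -> np.ndarray:
    """Pairwise distances from pattern data (unambiguous columns only)."""
    taxa = data.taxa
    codes = np.stack([data.pure_codes(t) for t in taxa])
    w = data.weights
    n = len(taxa)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            valid = (codes[i] >= 0) & (codes[j] >= 0)
            denom = w[valid].sum()
            if denom == 0:
                raise MissingDistanceError(
                    f"taxa {taxa[i]!r} and {taxa[j]!r} share no defined columns"
                )
            p = w[valid & (codes[i] != codes[j])].sum() / denom
            if correction == "jc":
                d = D_MAX if p >= 0.75 else min(
                    -0.75 * math.log(1.0 - 4.0 * p / 3.0), D_MAX
                )
            else:
                d = p
            D[i, j] = D[j, i] = d
    return D


# ----------------------------------------------------------- neighbor joining


def neighbor_joining(D: np.ndarray, labels: Sequence[str]) -> Tree:
    """Saitou–Nei neighbor joining.

    Exact on additive matrices.  Q-criterion ties are broken toward the
    lexicographically lowest cluster-index pair; negative branch-length
    estimates are clamped to zero (the clamp deficit is discarded, not
    redistributed).
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise InferenceError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-8):
        raise InferenceError("distance matrix must be symmetric")
    if np.abs(np.diag(D)).max() > 1e-12:
        raise InferenceError("distance matrix must have a zero diagonal")
    if np.isnan(D).any():
        raise MissingDistanceError("distance matrix has missing entries")
    n = D.shape[0]
    if n < 3:
        raise InferenceError("need at least 3 taxa")
    if len(labels) != n:
        raise InferenceError("labels do not match matrix size")

    nodes: list[Node] = [Node(lab) for lab in labels]
    active = list(range(n))
    D = D.copy()

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # lowest-index tie break: scan in order
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                q = Q[a, b]
                if best is None or q < best[0] - 1e-12:
                    best = (q, a, b)
        _, a, b = best
        i, j = active[a], active[b]
        d_ij = D[i, j]
        li = 0.5 * d_ij + (r[a] - r[b]) / (2.0 * (m - 2))
        lj = d_ij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = Node()
        ni, nj = nodes[i], nodes[j]
        ni.length, nj.length = li, lj
        parent.add_child(ni)
        parent.add_child(nj)
        nodes.append(parent)
        u = len(nodes) - 1
        D = np.pad(D, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            D[u, k] = D[k, u] = max(0.5 * (D[i, k] + D[j, k] - d_ij), 0.0)
        active = [k for k in active if k not in (i, j)] + [u]

    i, j, k = active
    root = Node()
    d = D
    nodes[i].length = max(0.5 * (d[i, j] + d[i, k] - d[j, k]), 0.0)
    nodes[j].length = max(0.5 * (d[i, j] + d[j, k] - d[i, k]), 0.0)
    nodes[k].length = max(0.5 * (d[i, k] + d[j, k] - d[i, j]), 0.0)
    for idx in (i, j, k):
        root.add_child(nodes[idx])
    return Tree(root)


# --------------------------------------------------------------- likelihood


def _engine_factory(
    aln,
    regions: Sequence[tuple[np.ndarray, SubstitutionModel, float]],
    taxa: Sequence[str],
) -> Callable[[TreeIndex], list[Engine]]:
    datas = [
        (PatternData(aln, cols, taxa), model, rate)
        for cols, model, rate in regions
    ]

    def make(index: TreeIndex) -> list[Engine]:
        return [Engine(index, d, m, r) for d, m, r in datas]

    return make


def log_likelihood(
    aln,
    tree: Tree,
    model: SubstitutionModel,
    columns: Optional[np.ndarray] = None,
    rate: float = 1.0,
) -> float:
    """Pruning log-likelihood of ``aln`` on ``tree`` (fixed lengths)."""
    labels = tree.leaf_labels()
    missing = labels - set(aln.taxa)
    if missing:
        raise KeyError(f"tree leaves missing from alignment: {sorted(missing)}")
    cols = columns if columns is not None else np.arange(aln.n_columns)
    data = PatternData(aln, cols, sorted(labels))
    return Engine(TreeIndex(tree), data, model, rate).lnl()


def optimize_branch_lengths(
    aln,
    tree: Tree,
    model: SubstitutionModel,
    columns: Optional[np.ndarray] = None,
    max_sweeps: int = 8,
    tol: float = 1e-6,
) -> Tree:
    """Coordinate-wise branch-length optimization; returns a new tree."""
    out = tree.copy()
    cols = columns if columns is not None else np.arange(aln.n_columns)
    index = TreeIndex(out)
    data = PatternData(aln, cols, sorted(out.leaf_labels()))
    engine = Engine(index, data, model)
    optimize_edges(index, [engine], max_sweeps=max_sweeps, tol=tol)
    return out


# ---------------------------------------------------------------- NNI search


def _apply_swap(child: Node, sibling: Node) -> None:
    """Exchange two nodes between their parents (lengths travel along)."""
    pc, ps = child.parent, sibling.parent
    ic, isb = pc.children.index(child), ps.children.index(sibling)
    pc.children[ic], ps.children[isb] = sibling, child
    child.parent, sibling.parent = ps, pc


def _optimize_config(
    engines: Sequence[Engine],
    envs,
    v: int,
    which: int,
    t0: float,
    maxiter: int = 12,
) -> tuple[float, float]:
    """Best lnL (and length) of one NNI resolution of edge v."""
    fns = [
        e.nni_config_fn(v, env, which) for e, env in zip(engines, envs)
    ]
    if len(fns) == 1:
        f1 = fns[0]
        neg = lambda t: -f1(t)
    else:
        neg = lambda t: -sum(f(t) for f in fns)
    res = minimize_scalar(
        neg, bounds=(0.0, 10.0), method="bounded",
        options={"xatol": 1e-3, "maxiter": maxiter},
    )
    lnl0 = -neg(t0)
    if -res.fun >= lnl0:
        return float(-res.fun), float(res.x)
    return lnl0, t0


def nni_search(
    aln,
    start: Tree,
    model: Optional[SubstitutionModel] = None,
    columns: Optional[np.ndarray] = None,
    make_engines: Optional[Callable[[TreeIndex], list[Engine]]] = None,
    max_iters: int = 30,
    tol: float = 1e-6,
    fast: bool = False,
    final_optimize: bool = True,
) -> Tree:
    """Steepest-ascent NNI hill climb.

    Both alternatives of every internal edge are scored from the four
    message vectors around the edge with the central branch length
    re-optimized; the best improving move is applied and the process
    repeats until no move improves the log-likelihood by more than
    ``tol``.  Deterministic given input order.  ``fast`` trims the 1-D
    searches and skips the final full branch-length pass (used inside the
    bootstrap).
    """
    tree = start.copy()
    tree.unroot()
    if make_engines is None:
        if model is None:
            raise InferenceError("need a model or an engine factory")
        cols = columns if columns is not None else np.arange(aln.n_columns)
        make_engines = _engine_factory(
            aln, [(cols, model, 1.0)], sorted(tree.leaf_labels())
        )
    maxiter_1d = 6 if fast else 12

    for _ in range(max_iters):
        index = TreeIndex(tree)
        engines = make_engines(index)
        current = sum(e.lnl() for e in engines)
        best = None  # (lnl, node, which, t)
        for v_node in tree.internal_edges():
            if len(v_node.children) != 2:
                continue
            v = index.index[id(v_node)]
            u = index.parent[v]
            if not index.children[u] or len(index.children[u]) < 2:
                continue
            envs = [e.nni_env(v) for e in engines]
            for which in (1, 2):
                lnl, t_opt = _optimize_config(
                    engines, envs, v, which, index.brlen[v], maxiter_1d
                )
                if lnl > current + tol and (best is None or lnl > best[0]):
                    best = (lnl, v_node, which, t_opt)
        if best is None:
            break
        _, v_node, which, t_opt = best
        x, y = v_node.children
        sibling = next(c for c in v_node.parent.children if c is not v_node)
        _apply_swap(x if which == 1 else y, sibling)
        v_node.length = t_opt
    if final_optimize and not fast:
        index = TreeIndex(tree)
        engines = make_engines(index)
        optimize_edges(index, engines, max_sweeps=2, tol=tol,
                       xatol=1e-4, maxiter=16)
    return tree


# ------------------------------------------------------------------ supports


def abayes_from_lnls(lnls: Sequence[float]) -> float:
    """aBayes posterior of the best NNI resolution (uniform prior)."""
    arr = np.asarray(lnls, dtype=float)
    m = arr.max()
    w = np.exp(arr - m)
    return float(w.max() / w.sum())


def abayes_supports(
    aln,
    tree: Tree,
    model: Optional[SubstitutionModel] = None,
    columns: Optional[np.ndarray] = None,
    make_engines: Optional[Callable[[TreeIndex], list[Engine]]] = None,
) -> Tree:
    """Annotate each internal edge with its aBayes posterior.

    Each internal edge's three NNI resolutions are scored from the four
    message vectors around the edge: the two alternatives get the central
    branch length re-optimized, while the current resolution keeps its
    globally optimized length.  The support is the softmax weight of the
    best resolution under a uniform prior, hence always in [1/3, 1].
    """
    tree = tree.copy()
    tree.unroot()
    if make_engines is None:
        if model is None:
            raise InferenceError("need a model or an engine factory")
        cols = columns if columns is not None else np.arange(aln.n_columns)
        make_engines = _engine_factory(
            aln, [(cols, model, 1.0)], sorted(tree.leaf_labels())
        )
    index = TreeIndex(tree)
    engines = make_engines(index)
    base = sum(e.lnl() for e in engines)
    for v_node in tree.internal_edges():
        if len(v_node.children) != 2:
            continue
        v = index.index[id(v_node)]
        envs = [e.nni_env(v) for e in engines]
        lnls = [base]
        for which in (1, 2):
            lnl, _ = _optimize_config(
                engines, envs, v, which, index.brlen[v]
            )
            lnls.append(lnl)
        v_node.abayes = abayes_from_lnls(lnls)
    return tree


def bootstrap_supports(
    aln,
    scheme: Optional[msa.PartitionScheme],
    tree: Tree,
    region_models: Sequence[RegionModel] | SubstitutionModel,
    B: int,
    seed: int,
    columns: Optional[np.ndarray] = None,
    resample_fn: Optional[Callable] = None,
) -> Tree:
    """Nonparametric bootstrap: columns resampled within each region.

    Each replicate is re-inferred (JC distances -> NJ -> fast NNI) and each
    internal edge of the reference tree is annotated with the percentage of
    replicate trees displaying its split.
    """
    if B < 1:
        raise InferenceError("need at least one bootstrap replicate")
    rng = np.random.default_rng(seed)
    tree = tree.copy()
    tree.unroot()
    taxa = sorted(tree.leaf_labels())

    if isinstance(region_models, SubstitutionModel):
        cols = columns if columns is not None else np.arange(aln.n_columns)
        region_specs = [(cols, region_models, 1.0)]
    else:
        region_specs = [
            (scheme.region(rm.region).columns(), rm.model, rm.rate)
            for rm in region_models
        ]
    datas = [PatternData(aln, cols, taxa) for cols, _, _ in region_specs]

    ref_splits = tree.bipartitions()
    counts = {split: 0 for split in ref_splits}
    for _ in range(B):
        if resample_fn is None:
            rdatas = [d.resample(rng) for d in datas]
        else:
            rdatas = [resample_fn(d, rng) for d in datas]
        rep = _infer_replicate(rdatas, region_specs, taxa)
        rep_splits = rep.split_set()
        for split in counts:
            if split in rep_splits:
                counts[split] += 1
    for split, node in ref_splits.items():
        node.bs = 100.0 * counts[split] / B
    return tree


def _infer_replicate(rdatas, region_specs, taxa) -> Tree:
    D = _combined_distance(rdatas)
    start = neighbor_joining(D, taxa)

    def make(index: TreeIndex) -> list[Engine]:
        return [
            Engine(index, d, m, r)
            for d, (_, m, r) in zip(rdatas, region_specs)
        ]

    return nni_search(
        None, start, make_engines=make, max_iters=8, tol=1e-4,
        fast=True, final_optimize=False,
    )


def _combined_distance(datas: Sequence[PatternData]) -> np.ndarray:
    taxa = datas[0].taxa
    codes = [np.stack([d.pure_codes(t) for t in taxa]) for d in datas]
    n = len(taxa)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            num = den = 0.0
            for d, c in zip(datas, codes):
                valid = (c[i] >= 0) & (c[j] >= 0)
                den += d.weights[valid].sum()
                num += d.weights[valid & (c[i] != c[j])].sum()
            if den == 0:
                raise MissingDistanceError(
                    f"taxa {taxa[i]!r} and {taxa[j]!r} share no defined columns"
                )
            p = num / den
            D[i, j] = D[j, i] = D_MAX if p >= 0.75 else min(
                -0.75 * math.log(1 - 4 * p / 3), D_MAX
            )
    return D


# ------------------------------------------------------------ model fitting


def fit_candidates(
    aln,
    tree: Tree,
    candidates: Sequence[str],
    columns: Optional[np.ndarray] = None,
    rounds: int = 2,
) -> list[ModelFit]:
    """ML-fit each candidate model on a fixed topology.

    Alternates branch-length sweeps with Nelder-Mead optimization of the
    model's free parameters (log-transformed).  Branch lengths are excluded
    from the AIC parameter count (all candidates share the same branch set).
    """
    cols = columns if columns is not None else np.arange(aln.n_columns)
    taxa = sorted(tree.leaf_labels())
    freqs = empirical_frequencies([aln.sequence(t) for t in taxa])
    fits = []
    for start in candidate_models(candidates, freqs):
        fits.append(_fit_one(aln, tree, start, cols, taxa, rounds))
    return fits


def _fit_one(aln, tree, model, cols, taxa, rounds) -> ModelFit:
    work = tree.copy()
    data = PatternData(aln, cols, taxa)
    converged = True
    message = ""
    for _ in range(rounds):
        index = TreeIndex(work)
        engine = Engine(index, data, model)
        optimize_edges(index, [engine], max_sweeps=3, tol=1e-4)
        theta0, unpack = _pack_params(model)
        if len(theta0):
            def neg(theta):
                m = unpack(theta)
                return -Engine(index, data, m).lnl()

            res = minimize(
                neg, theta0, method="Nelder-Mead",
                options={"xatol": 1e-3, "fatol": 1e-2, "maxiter": 120},
            )
            model = unpack(res.x)
            if not res.success:
                converged = False
                message = str(res.message)
    index = TreeIndex(work)
    engine = Engine(index, data, model)
    lnl = optimize_edges(index, [engine], max_sweeps=3, tol=1e-5)
    return ModelFit(
        model=model,
        log_likelihood=lnl,
        k=model.k_free_parameters(),
        converged=converged,
        message=message,
    )


def _pack_params(model: SubstitutionModel):
    """Log-parameterization of a model's free parameters for Nelder-Mead."""
    names = []
    values = []
    if model.name in ("K80", "HKY"):
        names.append("kappa")
        values.append(model.exchangeabilities[1])
    elif model.name == "GTR":
        for i in range(5):  # GT fixed to 1
            names.append(f"ex{i}")
            values.append(max(model.exchangeabilities[i], 1e-6))
    if model.gamma_shape is not None:
        names.append("alpha")
        values.append(model.gamma_shape)
    theta0 = np.log(np.asarray(values, dtype=float)) if values else np.empty(0)

    def unpack(theta: np.ndarray) -> SubstitutionModel:
        vals = dict(zip(names, np.exp(np.asarray(theta, dtype=float))))
        gamma = vals.pop("alpha", None)
        if gamma is not None:
            gamma = float(np.clip(gamma, 0.02, 100.0))
        if model.name == "JC":
            return SubstitutionModel.jc(gamma)
        if model.name == "K80":
            return SubstitutionModel.k80(vals["kappa"], gamma)
        if model.name == "HKY":
            return SubstitutionModel.hky(
                vals["kappa"], model.base_freqs, gamma
            )
        ex = tuple(float(vals[f"ex{i}"]) for i in range(5)) + (1.0,)
        return SubstitutionModel.gtr(ex, model.base_freqs, gamma)

    return theta0, unpack


# ------------------------------------------------------------- full pipeline


def infer_tree(
    aln,
    scheme: msa.PartitionScheme,
    klass: Optional[str] = None,
    regions: Optional[Sequence[str]] = None,
    settings: Optional[InferenceSettings] = None,
    seed: int = 0,
    taxa: Optional[Sequence[str]] = None,
    with_supports: bool = True,
    start_tree: Optional[Tree] = None,
) -> tuple[Tree, list[RegionModel]]:
    """Partitioned ML inference for a class (or explicit region list).

    Pipeline: per-region model selection (AIC) -> JC/NJ starting tree ->
    joint branch-length optimization with per-region rate multipliers ->
    NNI search -> aBayes (and optionally bootstrap) supports.
    """
    settings = settings or InferenceSettings()
    region_list = _resolve_regions(scheme, klass, regions)
    all_cols = np.concatenate([r.columns() for r in region_list])
    if taxa is None:
        taxa = msa.taxa_with_data(aln, all_cols)
    taxa = sorted(taxa)
    if len(taxa) < 4:
        raise InferenceError("need at least 4 taxa with data")

    # Starting tree: caller-provided (e.g. the full-data tree restricted to
    # the current taxon set) or NJ from combined JC distances.
    datas = [PatternData(aln, r.columns(), taxa) for r in region_list]
    if start_tree is not None:
        start = start_tree.restrict(taxa)
        start.unroot()
    else:
        D = _combined_distance(datas)
        start = neighbor_joining(D, taxa)

    # Per-region models: fixed (from a prior full-data fit) or AIC-selected.
    region_models: list[RegionModel] = []
    for r in region_list:
        if settings.fixed_models and r.name in settings.fixed_models:
            rm = settings.fixed_models[r.name]
            region_models.append(RegionModel(r.name, rm.model, rm.rate))
        else:
            fits = fit_candidates(
                aln.subset_taxa(taxa), start, settings.candidates,
                columns=r.columns(), rounds=settings.fit_rounds,
            )
            best = min(fits, key=lambda f: (round(f.aic, 9), f.k))
            region_models.append(
                RegionModel(r.name, best.model, 1.0, best.log_likelihood)
            )

    def make_engines(index: TreeIndex) -> list[Engine]:
        return [
            Engine(index, d, rm.model, rm.rate)
            for d, rm in zip(datas, region_models)
        ]

    # Branch lengths + per-region rates on the starting tree.
    start.unroot()
    index = TreeIndex(start)
    engines = make_engines(index)
    optimize_edges(index, engines, max_sweeps=2, tol=1e-3, xatol=1e-4,
                   maxiter=16)
    _optimize_region_rates(index, engines, region_models, datas)

    tree = nni_search(
        None, start, make_engines=make_engines,
        max_iters=settings.nni_max_iters, tol=settings.nni_tol,
    )
    index = TreeIndex(tree)
    engines = make_engines(index)
    optimize_edges(index, engines, max_sweeps=settings.branch_sweeps,
                   tol=settings.nni_tol, xatol=1e-4, maxiter=16)
    _optimize_region_rates(index, engines, region_models, datas)
    optimize_edges(index, engines, max_sweeps=1, tol=settings.nni_tol,
                   xatol=1e-4, maxiter=16)
    for rm, e in zip(region_models, engines):
        rm.log_likelihood = e.lnl()

    if with_supports:
        tree = abayes_supports(aln, tree, make_engines=make_engines)
        if settings.bootstrap_replicates > 0:
            tree = bootstrap_supports(
                aln, scheme, tree, region_models,
                settings.bootstrap_replicates, seed,
            )
    return tree, region_models


def _resolve_regions(scheme, klass, regions):
    if regions is not None:
        return [scheme.region(name) for name in regions]
    if klass is not None:
        region_list = scheme.class_regions(klass)
        if not region_list:
            raise InferenceError(f"no regions of class {klass!r}")
        return region_list
    return list(scheme.regions)


def _optimize_region_rates(index, engines, region_models, datas) -> None:
    """1-D per-region rate multipliers, renormalized to weighted mean 1."""
    if len(engines) < 2:
        return
    for e, rm in zip(engines, region_models):
        def neg(log_m: float) -> float:
            e.rate = float(np.exp(log_m))
            return -e.full_pass()

        res = minimize_scalar(
            neg, bounds=(np.log(0.05), np.log(20.0)), method="bounded",
            options={"xatol": 1e-3},
        )
        e.rate = float(np.exp(res.x))
        rm.rate = e.rate
    # Renormalize: weighted mean rate (by region length) = 1.
    lengths = np.array([d.n_sites for d in datas], dtype=float)
    rates = np.array([rm.rate for rm in region_models])
    mu = float((lengths * rates).sum() / lengths.sum())
    for i in index.edge_indices():
        index.set_length(i, index.brlen[i] * mu)
    for e, rm in zip(engines, region_models):
        e.rate = e.rate / mu
        rm.rate = e.rate
        e.full_pass()
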