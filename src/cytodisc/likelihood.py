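"""Felsenstein pruning likelihood with underflow rescaling.

The engine computes the phylogenetic log-likelihood of an alignment region
under a reversible substitution model with discrete-gamma rate categories,
and supports fast per-edge branch-length optimization via two-directional
conditional likelihoods ("messages"):

* ``down[v]`` — probability of the data below node ``v`` given the state at
  ``v`` (the classic pruning vector);
* an *outside* vector at any node, assembled on demand by walking the path
  from the (arbitrary) root, so that the likelihood as a function of one
  branch length costs a single 4x4 contraction per evaluation.

Ambiguity codes are encoded as indicator vectors over their compatible
states; ``-``/``?``/``N`` are all-ones (missing).  Per-node rescaling with a
per-pattern log accumulator prevents underflow; the total log-likelihood is
invariant to the choice of traversal root (tested property).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .models import SubstitutionModel, transition_matrices
from .trees import Node, Tree

# 4-bit state masks, bit order A=1, C=2, G=4, T=8.
CHAR_MASKS = {
    "A": 1, "C": 2, "G": 4, "T": 8,
    "R": 1 | 4, "Y": 2 | 8, "S": 2 | 4, "W": 1 | 8,
    "K": 4 | 8, "M": 1 | 2,
    "B": 2 | 4 | 8, "D": 1 | 4 | 8, "H": 1 | 2 | 8, "V": 1 | 2 | 4,
    "N": 15, "-": 15, "?": 15,
}

_MASK_TABLE = np.zeros(256, dtype=np.uint8)
for ch, m in CHAR_MASKS.items():
    _MASK_TABLE[ord(ch)] = m

_MASK_TO_VEC = np.zeros((16, 4))
for m in range(1, 16):
    for b in range(4):
        _MASK_TO_VEC[m, b] = float(bool(m & (1 << b)))

_PURE_CODE = np.full(16, -1, dtype=np.int8)
for b in range(4):
    _PURE_CODE[1 << b] = b

BRANCH_MIN = 0.0
BRANCH_MAX = 10.0


class LikelihoodError(ValueError):
    pass


class PatternData:
    """Site-pattern-compressed view of selected alignment columns."""

    def __init__(self, aln, columns, taxa: Optional[Sequence[str]] = None):
        self.taxa = list(taxa) if taxa is not None else list(aln.taxa)
        cols = np.asarray(columns, dtype=int)
        if len(cols) == 0:
            raise LikelihoodError("no columns selected")
        raw = np.empty((len(self.taxa), len(cols)), dtype=np.uint8)
        for i, t in enumerate(self.taxa):
            seq = np.frombuffer(aln.sequence(t).encode("ascii"), dtype=np.uint8)
            raw[i] = _MASK_TABLE[seq[cols]]
        if (raw == 0).any():
            raise LikelihoodError("invalid character in alignment")
        patterns, weights = np.unique(raw, axis=1, return_counts=True)
        self.masks = patterns  # (ntaxa, npat) uint8
        self.weights = weights.astype(float)
        self.n_sites = int(len(cols))
        self.n_patterns = patterns.shape[1]
        self._row = {t: i for i, t in enumerate(self.taxa)}
        self._clv_cache: dict[str, np.ndarray] = {}

    def row(self, label: str) -> np.ndarray:
        try:
            return self.masks[self._row[label]]
        except KeyError:
            raise KeyError(f"taxon {label!r} has no data row") from None

    def leaf_clv(self, label: str) -> np.ndarray:
        clv = self._clv_cache.get(label)
        if clv is None:
            clv = _MASK_TO_VEC[self.row(label)].T.copy()  # (4, npat)
            self._clv_cache[label] = clv
        return clv

    def pure_codes(self, label: str) -> np.ndarray:
        """-1 for missing/ambiguous, else 0..3."""
        return _PURE_CODE[self.row(label)]

    def resample(self, rng) -> "PatternData":
        """Bootstrap resample of the underlying columns (same patterns,
        multinomial weights)."""
        new = object.__new__(PatternData)
        new.taxa = self.taxa
        new.masks = self.masks
        new.weights = rng.multinomial(
            self.n_sites, self.weights / self.n_sites
        ).astype(float)
        new.n_sites = self.n_sites
        new.n_patterns = self.n_patterns
        new._row = self._row
        new._clv_cache = self._clv_cache
        return new


class TreeIndex:
    """Flattened postorder view of a Tree shared by per-region engines."""

    def __init__(self, tree: Tree):
        self.tree = tree
        self.nodes: list[Node] = list(tree.postorder())  # root last
        self.index = {id(n): i for i, n in enumerate(self.nodes)}
        n = len(self.nodes)
        self.parent = np.full(n, -1, dtype=int)
        self.children: list[list[int]] = [[] for _ in range(n)]
        for i, node in enumerate(self.nodes):
            for c in node.children:
                j = self.index[id(c)]
                self.parent[j] = i
                self.children[i].append(j)
        self.brlen = np.array([n_.length for n_ in self.nodes], dtype=float)
        self.root = n - 1
        self.is_leaf = np.array([n_.is_leaf() for n_ in self.nodes])

    def set_length(self, i: int, t: float) -> None:
        self.brlen[i] = t
        self.nodes[i].length = t

    def edge_indices(self) -> list[int]:
        return [i for i in range(len(self.nodes)) if i != self.root]

    def ancestors(self, i: int) -> list[int]:
        out = []
        while self.parent[i] != -1:
            i = self.parent[i]
            out.append(i)
        return out

    def path_from_root(self, i: int) -> list[int]:
        """Nodes from the root down to ``i`` inclusive."""
        chain = [i] + self.ancestors(i)
        return chain[::-1]


class Engine:
    """Pruning likelihood for one region on a shared TreeIndex."""

    def __init__(
        self,
        index: TreeIndex,
        data: PatternData,
        model: SubstitutionModel,
        rate: float = 1.0,
    ):
        self.index = index
        self.data = data
        self.model = model
        self.rate = float(rate)
        self.eig = model.eigensystem()
        self.pi = model.pi
        self.cats = model.category_rates()
        self.K = len(self.cats)
        n = len(index.nodes)
        self.down: list[Optional[np.ndarray]] = [None] * n
        self.msg: list[Optional[np.ndarray]] = [None] * n
        self.scale = np.zeros((n, data.n_patterns))
        self.full_pass()

    # ------------------------------------------------------------ pruning

    def _pmat(self, i: int, t: Optional[float] = None) -> np.ndarray:
        # Engine-internal P(t); skips the row renormalization of the public
        # transition_matrix (eigh roundoff is ~1e-15 and site likelihoods
        # are floored downstream).
        t = self.index.brlen[i] if t is None else t
        w, U, U_inv = self.eig
        E = np.exp((t * self.rate) * self.cats[:, None] * w[None, :])
        return (U[None, :, :] * E[:, None, :]) @ U_inv

    def _pmats_all(self) -> np.ndarray:
        return transition_matrices(
            self.eig, self.index.brlen * self.rate, self.cats
        )

    def _leaf_down(self, i: int) -> np.ndarray:
        label = self.index.nodes[i].label
        clv = self.data.leaf_clv(label)  # (4, npat)
        return np.broadcast_to(clv, (self.K, 4, self.data.n_patterns))

    def _compute_node(self, i: int, P: Optional[np.ndarray] = None) -> None:
        idx = self.index
        if idx.is_leaf[i]:
            self.down[i] = self._leaf_down(i)
            self.scale[i] = 0.0
        else:
            prod = None
            sc = np.zeros(self.data.n_patterns)
            for c in idx.children[i]:
                prod = self.msg[c] if prod is None else prod * self.msg[c]
                sc = sc + self.scale[c]
            norm = prod.max(axis=(0, 1))
            norm = np.where(norm > 0, norm, 1.0)
            self.down[i] = prod / norm
            self.scale[i] = sc + np.log(norm)
        if i != idx.root:
            if P is None:
                P = self._pmat(i)
            self.msg[i] = np.matmul(P, self.down[i])

    def full_pass(self) -> float:
        P_all = self._pmats_all()
        for i in range(len(self.index.nodes)):
            self._compute_node(i, P_all[i])
        return self.lnl()

    def lnl(self) -> float:
        r = self.index.root
        site = (self.pi[None, :, None] * self.down[r]).sum(axis=(0, 1)) / self.K
        return float(
            np.dot(self.data.weights, np.log(site) + self.scale[r])
        )

    # ---------------------------------------------- per-edge optimization

    def _outside(self, v: int):
        """Outside partial at parent(v) excluding v, plus its log-scale."""
        idx = self.index
        path = idx.path_from_root(v)  # root ... parent(v), v
        G = None  # None == all-ones with zero scale
        gscale = 0.0
        for a, b in zip(path[:-1], path[1:]):
            pre = G
            sc = gscale
            for c in idx.children[a]:
                if c == b:
                    continue
                pre = self.msg[c] if pre is None else pre * self.msg[c]
                sc = sc + self.scale[c]
            if pre is None:
                pre = np.ones((self.K, 4, self.data.n_patterns))
            if b == v:
                return pre, sc
            G = np.matmul(self._pmat(b), pre)
            norm = G.max(axis=(0, 1))
            norm = np.where(norm > 0, norm, 1.0)
            G = G / norm
            gscale = sc + np.log(norm)
        raise AssertionError("unreachable")

    def edge_lnl_function(self, v: int) -> Callable[[float], float]:
        """lnL as a function of the length of the edge above node v."""
        A, sa = self._outside(v)
        B, sb = self.down[v], self.scale[v]
        piB = self.pi[None, :, None] * B
        const = sa + sb
        w = self.data.weights

        def f(t: float) -> float:
            PA = np.matmul(self._pmat(v, t), A)
            site = (piB * PA).sum(axis=(0, 1)) / self.K
            site = np.maximum(site, 1e-300)
            return float(np.dot(w, np.log(site) + const))

        return f

    # ------------------------------------------------- NNI quartet scoring

    def outside_at(self, u: int):
        """Outside partial at node u (everything above, through u's edge)."""
        idx = self.index
        if u == idx.root:
            return (
                np.ones((self.K, 4, self.data.n_patterns)),
                np.zeros(self.data.n_patterns),
            )
        pre, sc = self._outside(u)
        G = np.matmul(self._pmat(u), pre)
        norm = G.max(axis=(0, 1))
        norm = np.where(norm > 0, norm, 1.0)
        return G / norm, sc + np.log(norm)

    def nni_env(self, v: int):
        """Messages of the four subtrees around internal edge v.

        Returns ((Mx,sx),(My,sy),(Mw,sw),(Mr,sr)) where x,y are v's
        children, w is the first sibling subtree and r the remainder of the
        tree; all message vectors are exchangeable across the junction, so
        every NNI resolution of the edge is a different pairing of them.
        """
        idx = self.index
        u = idx.parent[v]
        x, y = idx.children[v]
        others = [c for c in idx.children[u] if c != v]
        w = others[0]
        Mr, sr = self.outside_at(u)
        for c in others[1:]:
            Mr = Mr * self.msg[c]
            sr = sr + self.scale[c]
        return (
            (self.msg[x], self.scale[x]),
            (self.msg[y], self.scale[y]),
            (self.msg[w], self.scale[w]),
            (Mr, sr),
        )

    def nni_config_fn(self, v: int, env, which: int) -> Callable[[float], float]:
        """lnL(t) of one NNI resolution of edge v as a function of its length.

        which=0 keeps ((x,y)|(w,r)); which=1 swaps x with w; which=2 swaps
        y with w.
        """
        (Mx, sx), (My, sy), (Mw, sw), (Mr, sr) = env
        if which == 0:
            a, b, c, d = (Mx, My, Mw, Mr)
            const = sx + sy + sw + sr
        elif which == 1:
            a, b, c, d = (Mw, My, Mx, Mr)
            const = sw + sy + sx + sr
        elif which == 2:
            a, b, c, d = (Mx, Mw, My, Mr)
            const = sx + sw + sy + sr
        else:
            raise ValueError("which must be 0, 1 or 2")
        AB = a * b
        piCD = self.pi[None, :, None] * (c * d)
        wts = self.data.weights

        def f(t: float) -> float:
            PAB = np.matmul(self._pmat(v, t), AB)
            site = (piCD * PAB).sum(axis=(0, 1)) / self.K
            site = np.maximum(site, 1e-300)
            return float(np.dot(wts, np.log(site) + const))

        return f

    def apply_length(self, v: int) -> None:
        """Refresh cached vectors after the edge above v changed."""
        self.msg[v] = np.matmul(self._pmat(v), self.down[v])
        for a in self.index.ancestors(v):
            self._compute_node(a)


def optimize_edges(
    index: TreeIndex,
    engines: Sequence[Engine],
    edge_ids: Optional[Sequence[int]] = None,
    max_sweeps: int = 5,
    tol: float = 1e-6,
    xatol: float = 1e-6,
    maxiter: int = 50,
) -> float:
    """Coordinate-wise branch-length optimization over one or more regions.

    Each 1-D problem is solved by bounded Brent search on the summed
    per-region edge likelihoods; sweeps repeat until the total lnL improves
    by less than ``tol``.  The lnL is non-decreasing across updates because
    every 1-D step is accepted only if it does not lower the objective.
    """
    ids = list(edge_ids) if edge_ids is not None else index.edge_indices()
    last = sum(e.lnl() for e in engines)
    for _ in range(max_sweeps):
        for v in ids:
            fs = [e.edge_lnl_function(v) for e in engines]
            t0 = index.brlen[v]
            f0 = sum(f(t0) for f in fs)
            if len(fs) == 1:
                f1 = fs[0]
                neg = lambda t: -f1(t)
            else:
                neg = lambda t: -sum(f(t) for f in fs)
            res = minimize_scalar(
                neg,
                bounds=(BRANCH_MIN, BRANCH_MAX),
                method="bounded",
                options={"xatol": xatol, "maxiter": maxiter},
            )
            if -res.fun > f0:
                index.set_length(v, float(res.x))
                for e in engines:
                    e.apply_length(v)
        current = sum(e.lnl() for e in engines)
        if current - last < tol:
            return current
        last = current
    return last


def log_likelihood_multi(engines: Sequence[Engine]) -> float:
    return sum(e.lnl() for e in engines)
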