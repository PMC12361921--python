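"""Synthetic benchmark generator with planted reticulation events.

Emulates a concatenated two-class (plastid + nuclear/ITS) supermatrix
evolved on a Yule species tree in which designated hybrid taxa carry
plastid and nuclear characters descended from *different* donor lineages.
Hybridization is modelled as clean tip regrafting ("chloroplast capture" /
ITS homogenization): per class, the hybrid tip is pruned from the species
tree and reattached at the midpoint of its donor edge with a short pendant
branch, so the ground truth is unambiguous.  All four plastid regions share
one gene tree (a single non-recombining plastid); ITS has its own.

Scenarios
---------
``capture``     each hybrid keeps its original nuclear position and its
                plastid jumps to a random donor edge (default);
``shared_its``  hybrids also move their ITS to one shared donor edge while
                their plastid donors stay distinct (floating-ITS setup);
``shared_all``  both classes move, and hybrids share both donor edges.

Every draw is taken from one seeded generator, so a bundle is byte-identical
under a fixed seed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from . import msa
from .models import SubstitutionModel, discrete_gamma, transition_matrix
from .trees import Node, Tree

SCENARIOS = ("capture", "shared_its", "shared_all")


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class RegionSpec:
    name: str
    length: int
    klass: str
    rate: float = 1.0

    def __post_init__(self):
        if self.length < 100:
            raise SimulationError("region length must be >= 100")


def _default_regions() -> tuple[RegionSpec, ...]:
    # Shape mirrors a four-region plastid set plus one nuclear ITS region,
    # with the nuclear region evolving faster (it carries roughly half the
    # informative sites at a fifth of the columns in real matrices).
    return (
        RegionSpec("rps16-trnK", 500, msa.PLASTID, 1.0),
        RegionSpec("rps16-intron", 500, msa.PLASTID, 1.0),
        RegionSpec("rpl32-trnL", 500, msa.PLASTID, 1.0),
        RegionSpec("ndhA-intron", 500, msa.PLASTID, 1.0),
        RegionSpec("ITS", 800, msa.NUCLEAR, 2.0),
    )


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic benchmark."""

    n_taxa: int = 24
    birth_rate: float = 1.0
    n_hybrids: int = 2
    min_donor_separation: int = 4  # midpoint edge distance between donors
    scenario: str = "capture"
    regions: tuple[RegionSpec, ...] = field(default_factory=_default_regions)
    # GTR+G4 with mildly uneven exchangeabilities and AT-rich composition.
    exchangeabilities: tuple[float, ...] = (1.2, 3.0, 0.8, 1.1, 3.5, 1.0)
    base_freqs: tuple[float, ...] = (0.30, 0.20, 0.20, 0.30)
    gamma_shape: Optional[float] = 0.8
    n_rate_categories: int = 4
    tree_height: float = 0.15  # mean root-to-tip, substitutions/site
    min_branch_length: float = 0.01  # strong-signal floor
    hybrid_pendant: float = 0.02
    missing_fraction: float = 0.0
    branch_jitter: float = 0.0  # optional lognormal ILS-like noise, off
    seed: int = 0

    def __post_init__(self):
        if self.n_taxa < 4:
            raise SimulationError("need at least 4 taxa")
        if self.n_hybrids > self.n_taxa / 4:
            raise SimulationError("n_hybrids must be <= n_taxa/4")
        if self.scenario not in SCENARIOS:
            raise SimulationError(f"scenario must be one of {SCENARIOS}")
        if self.birth_rate <= 0:
            raise SimulationError("birth rate must be positive")

    def model(self) -> SubstitutionModel:
        if self.gamma_shape is None:
            return SubstitutionModel.gtr(
                self.exchangeabilities, self.base_freqs
            )
        return SubstitutionModel.gtr(
            self.exchangeabilities, self.base_freqs,
            self.gamma_shape, self.n_rate_categories,
        )

    def partition_scheme(self) -> msa.PartitionScheme:
        regions = []
        offset = 0
        for r in self.regions:
            regions.append(
                msa.Region(r.name, ((offset, offset + r.length),), r.klass)
            )
            offset += r.length
        return msa.PartitionScheme(regions=regions)


@dataclass
class HybridTruth:
    label: str
    plastid_donor: frozenset  # core-taxon side of the donor edge
    its_donor: frozenset


@dataclass
class TruthTable:
    species_tree: Tree
    gene_trees: dict  # klass -> Tree
    hybrids: list[HybridTruth]
    config: SimulationConfig

    @property
    def hybrid_labels(self) -> frozenset:
        return frozenset(h.label for h in self.hybrids)

    def donor_edges(self, label: str) -> tuple[frozenset, frozenset]:
        for h in self.hybrids:
            if h.label == label:
                return h.plastid_donor, h.its_donor
        raise KeyError(label)


@dataclass
class Bundle:
    alignment: msa.Alignment
    scheme: msa.PartitionScheme
    truth: TruthTable
    config: SimulationConfig


# ------------------------------------------------------------- species tree


def yule_lineage_count(t: float, birth_rate: float, rng) -> int:
    """Number of lineages after time t starting from 2 (diagnostic)."""
    k, now = 2, 0.0
    while True:
        now += rng.exponential(1.0 / (birth_rate * k))
        if now > t:
            return k
        k += 1


def simulate_species_tree(
    n: int, birth_rate: float, seed=None, rng=None
) -> Tree:
    """Yule process from 2 lineages until n tips; ultrametric in time units."""
    if n < 4:
        raise SimulationError("need at least 4 taxa")
    if rng is None:
        rng = np.random.default_rng(seed)
    # Active lineages carry their birth time.
    t = 0.0
    births = [0.0, 0.0]
    nodes = [Node(), Node()]
    root = Node()
    for nd in nodes:
        root.add_child(nd)
    while len(nodes) < n:
        k = len(nodes)
        t += rng.exponential(1.0 / (birth_rate * k))
        i = int(rng.integers(k))
        parent = nodes[i]
        parent.length = t - births[i]
        left, right = Node(), Node()
        parent.add_child(left)
        parent.add_child(right)
        nodes[i] = left
        births[i] = t
        nodes.append(right)
        births.append(t)
    # Extend all tips to the final time and label them.
    t_end = t + rng.exponential(1.0 / (birth_rate * n))
    order = list(range(len(nodes)))
    for i in order:
        nodes[i].length = t_end - births[i]
        nodes[i].label = f"t{i + 1:02d}"
    tree = Tree(root)
    tree.unroot()
    return tree


def _scale_tree(tree: Tree, config: SimulationConfig) -> None:
    depths = []
    # mean root-to-tip path length
    def walk(node, acc):
        acc += node.length
        if node.is_leaf():
            depths.append(acc)
        for c in node.children:
            walk(c, acc)

    walk(tree.root, 0.0)
    mean_depth = float(np.mean(depths))
    if mean_depth <= 0:
        raise SimulationError("degenerate species tree")
    factor = config.tree_height / mean_depth
    for node in tree.postorder():
        if node is not tree.root:
            node.length = max(node.length * factor, config.min_branch_length)


# ------------------------------------------------------------ hybrid planting


def _core_side(tree: Tree, node: Node, core_taxa: frozenset) -> frozenset:
    below = set()

    def walk(n):
        if n.is_leaf():
            below.add(n.label)
        for c in n.children:
            walk(c)

    walk(node)
    return frozenset(below) & core_taxa


def plant_hybrids(
    species: Tree,
    config: SimulationConfig,
    rng,
    hybrid_labels: Optional[Sequence[str]] = None,
    donors: Optional[dict] = None,
) -> tuple[dict, TruthTable]:
    """Regraft hybrid tips per class; returns gene trees and ground truth.

    ``donors`` may pin choices explicitly as a map
    ``label -> (plastid_side, its_side)`` of core-taxon clades; otherwise
    donor edges are drawn uniformly among edges satisfying the separation
    constraint for the configured scenario.
    """
    leaves = sorted(species.leaf_labels())
    if hybrid_labels is None:
        hybrid_labels = (
            sorted(donors) if donors else
            _draw_hybrids(species, config, rng, leaves)
        )
    hybrids = list(hybrid_labels)
    core_taxa = frozenset(leaves) - frozenset(hybrids)

    gene_trees = {msa.PLASTID: species.copy(), msa.NUCLEAR: species.copy()}
    truths: list[HybridTruth] = []

    # Original attachment edge of each hybrid in the hybrid-free backbone,
    # keyed by the core-taxon side below it.
    shared: dict[str, frozenset] = {}
    donor_sets: dict[str, dict[str, frozenset]] = {msa.PLASTID: {}, msa.NUCLEAR: {}}
    backbone = species.copy()
    for h in hybrids:
        backbone.prune_leaf(h)

    for h in hybrids:
        original = _original_edge(species, h, core_taxa)
        if donors is not None:
            plastid_donor, its_donor = donors[h]
        else:
            its_donor = original
            if config.scenario in ("shared_its", "shared_all"):
                if "its" not in shared:
                    shared["its"] = _draw_donor(
                        backbone, core_taxa, rng, config,
                        apart_from=[original],
                    )
                its_donor = shared["its"]
            if config.scenario == "shared_all":
                if "plastid" not in shared:
                    shared["plastid"] = _draw_donor(
                        backbone, core_taxa, rng, config,
                        apart_from=[its_donor],
                    )
                plastid_donor = shared["plastid"]
            else:
                apart = [its_donor]
                apart += list(donor_sets[msa.PLASTID].values())
                plastid_donor = _draw_donor(
                    backbone, core_taxa, rng, config, apart_from=apart
                )
        donor_sets[msa.PLASTID][h] = plastid_donor
        donor_sets[msa.NUCLEAR][h] = its_donor
        truths.append(HybridTruth(h, plastid_donor, its_donor))

    for klass in (msa.PLASTID, msa.NUCLEAR):
        _regraft_class(gene_trees[klass], donor_sets[klass], core_taxa, config)

    if config.branch_jitter > 0:
        for tree in gene_trees.values():
            for node in tree.postorder():
                if node is not tree.root:
                    node.length *= float(
                        rng.lognormal(0.0, config.branch_jitter)
                    )

    truth = TruthTable(
        species_tree=species, gene_trees=gene_trees,
        hybrids=truths, config=config,
    )
    return gene_trees, truth


def _draw_hybrids(species, config, rng, leaves) -> list[str]:
    """Hybrid tips drawn uniformly, rejecting sister pairs of hybrids."""
    for _ in range(200):
        pick = sorted(
            rng.choice(len(leaves), size=config.n_hybrids, replace=False)
        )
        labels = [leaves[i] for i in pick]
        nodes = [species.find_leaf(l) for l in labels]
        ok = all(
            a.parent is not b.parent
            for i, a in enumerate(nodes)
            for b in nodes[i + 1:]
        )
        if ok:
            return labels
    raise SimulationError("could not draw non-sister hybrid tips")


def _original_edge(species, label, core_taxa) -> frozenset:
    """Core-side clade of the edge the hybrid originally hangs from."""
    leaf = species.find_leaf(label)
    parent = leaf.parent
    side = _core_side(species, parent, core_taxa)
    if not side:  # parent subtends only hybrids; fall back to grandparent
        side = _core_side(species, parent.parent or species.root, core_taxa)
    return side


def _draw_donor(backbone, core_taxa, rng, config, apart_from) -> frozenset:
    """Uniform draw among backbone edges far enough from given edges."""
    edges = [n for n in backbone.postorder() if n is not backbone.root]
    keys = [_core_side(backbone, n, core_taxa) for n in edges]
    ref_nodes = []
    for side in apart_from:
        for n, k in zip(edges, keys):
            if k == side or (core_taxa - k) == side:
                ref_nodes.append(n)
                break
    eligible = []
    for n, k in zip(edges, keys):
        if not k or k == core_taxa:
            continue
        if all(
            backbone.edge_distance(n, ref) >= config.min_donor_separation
            for ref in ref_nodes
        ):
            eligible.append((n, k))
    if not eligible:
        raise SimulationError(
            "no eligible donor edges under the separation constraint"
        )
    idx = int(rng.integers(len(eligible)))
    return eligible[idx][1]


def _regraft_class(tree: Tree, donors: dict[str, frozenset], core_taxa, config):
    placed: dict[frozenset, str] = {}  # donor side -> earlier hybrid there
    for h in sorted(donors):
        donor = donors[h]
        original = _original_edge(tree, h, core_taxa)
        if donor == original:
            continue
        tree.prune_leaf(h)
        if donor in placed:
            # Same donor edge: stack onto the earlier hybrid's pendant edge
            # so shared-donor hybrids form their own local clade.
            target = tree.find_leaf(placed[donor])
        else:
            target = _find_edge(tree, donor, core_taxa)
        tree.attach_at_edge(target, h, config.hybrid_pendant)
        placed[donor] = h


def _find_edge(tree: Tree, core_side: frozenset, core_taxa) -> Node:
    """Edge of a (possibly already regrafted) tree matching a donor clade.

    Matches on the core-taxon side below the edge; if an earlier regraft
    subdivided the donor edge, the deepest (fewest extra tips) match wins.
    """
    candidates = []
    for n in tree.postorder():
        if n is tree.root:
            continue
        side = _core_side(tree, n, frozenset(core_taxa))
        if side == core_side:
            full = _core_side(tree, n, tree.leaf_labels())
            candidates.append((len(full), n))
    if not candidates:
        raise SimulationError("donor edge not found in gene tree")
    candidates.sort(key=lambda c: c[0])
    return candidates[0][1]


# ------------------------------------------------------------- site evolution


def evolve_alignment(
    gene_trees: dict,
    config: SimulationConfig,
    rng,
) -> tuple[msa.Alignment, msa.PartitionScheme]:
    """Markov simulation of every region along its class gene tree."""
    model = config.model()
    pi = model.pi
    cats = model.category_rates()
    taxa = sorted(gene_trees[msa.PLASTID].leaf_labels())
    chunks: dict[str, list[str]] = {t: [] for t in taxa}

    for region in config.regions:
        tree = gene_trees[region.klass]
        L = region.length
        cat_idx = rng.integers(len(cats), size=L)
        states: dict[int, np.ndarray] = {}
        root_states = _draw_states(pi[None, :].repeat(L, axis=0), rng)
        states[id(tree.root)] = root_states
        for node in tree.preorder():
            if node is tree.root:
                continue
            parent_states = states[id(node.parent)]
            child = np.empty(L, dtype=np.int8)
            for k, rate in enumerate(cats):
                sites = np.where(cat_idx == k)[0]
                if not len(sites):
                    continue
                P = transition_matrix(
                    model, node.length * region.rate, float(rate)
                )
                child[sites] = _draw_states(P[parent_states[sites]], rng)
            states[id(node)] = child
            if node.is_leaf():
                seq = "".join("ACGT"[s] for s in child)
                chunks[node.label].append(seq)
        # Tips of this gene tree cover all taxa; nothing else to do.

    # Whole-region missing-data masking.
    records = []
    for t in taxa:
        parts = []
        for i, region in enumerate(config.regions):
            seq = chunks[t][i]
            if config.missing_fraction > 0 and rng.random() < config.missing_fraction:
                seq = "?" * len(seq)
            parts.append(seq)
        records.append((t, "".join(parts)))
    aln = msa.Alignment.from_records(records)
    return aln, config.partition_scheme()


def _draw_states(probs: np.ndarray, rng) -> np.ndarray:
    """Vectorized categorical draw; probs shape (n, 4)."""
    cum = probs.cumsum(axis=1)
    cum /= cum[:, -1:]
    u = rng.random(probs.shape[0])
    return (u[:, None] > cum).sum(axis=1).astype(np.int8)


# ------------------------------------------------------------------ bundles


def simulate_bundle(config: SimulationConfig) -> Bundle:
    """End-to-end in-memory benchmark (species tree -> hybrids -> data)."""
    rng = np.random.default_rng(config.seed)
    species = simulate_species_tree(config.n_taxa, config.birth_rate, rng=rng)
    _scale_tree(species, config)
    gene_trees, truth = plant_hybrids(species, config, rng)
    aln, scheme = evolve_alignment(gene_trees, config, rng)
    return Bundle(alignment=aln, scheme=scheme, truth=truth, config=config)


def make_benchmark(config: SimulationConfig, outdir) -> Bundle:
    """Write a self-describing benchmark bundle to disk."""
    bundle = simulate_bundle(config)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    msa.write_alignment(bundle.alignment, out / "alignment.fasta")
    msa.write_partitions(bundle.scheme, out / "partitions.txt")
    _write_truth(bundle.truth, out / "truth.tsv")
    with open(out / "config.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(_config_dict(config), fh, sort_keys=True)
    bundle.truth.species_tree.write(out / "species_tree.nwk", supports=False)
    for klass, tree in bundle.truth.gene_trees.items():
        tree.write(out / f"gene_tree_{klass}.nwk", supports=False)
    return bundle


def _write_truth(truth: TruthTable, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("hybrid\tplastid_donor\tits_donor\n")
        for h in truth.hybrids:
            fh.write(
                f"{h.label}\t{','.join(sorted(h.plastid_donor))}\t"
                f"{','.join(sorted(h.its_donor))}\n"
            )


def _config_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["regions"] = [asdict(r) for r in config.regions]
    return d


def load_truth(path) -> list[HybridTruth]:
    out = []
    with open(path, "r", encoding="utf-8") as fh:
        next(fh)
        for line in fh:
            label, pl, its = line.rstrip("\n").split("\t")
            out.append(
                HybridTruth(
                    label,
                    frozenset(pl.split(",")) if pl else frozenset(),
                    frozenset(its.split(",")) if its else frozenset(),
                )
            )
    return out
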