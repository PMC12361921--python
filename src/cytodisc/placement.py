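"""Taxon duplication and phylogenetic placement against the core tree.

Each incongruent specimen re-enters the analysis as two single-class
entries — ``<label>_ITS`` carrying only nuclear characters and
``<label>_PL`` carrying only plastid characters — so the affinity of each
genome can be located independently.  The default screen holds the core
topology and branch lengths fixed: the entry is attached at the midpoint of
every core edge in turn, only its pendant branch length is optimized, and
the per-edge likelihoods are normalized into likelihood weight ratios
(LWR).  ``expanded_inference`` is the full re-search mode used for
figure-grade trees of each discordance group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import msa
from .conflict import SpecimenFlag
from .coretree import CoreResult
from .inference import InferenceSettings, infer_tree, nni_search, abayes_supports
from .likelihood import Engine, PatternData, TreeIndex, optimize_edges
from .trees import Node, Tree

logger = logging.getLogger(__name__)

ITS_SUFFIX = "_ITS"
PL_SUFFIX = "_PL"


class PlacementError(ValueError):
    pass


@dataclass(frozen=True)
class DuplicatedEntry:
    parent: str
    label: str
    klass: str


@dataclass
class PlacementResult:
    entry: DuplicatedEntry
    best_edge: frozenset  # core-taxon side below the edge
    pendant_length: float
    log_likelihood: float
    lwr: dict  # edge side -> likelihood weight ratio
    uniform: bool = False  # True when the entry had no informative columns


def make_duplicates(
    aln: msa.Alignment,
    scheme: msa.PartitionScheme,
    flags: Sequence[SpecimenFlag],
) -> list[DuplicatedEntry]:
    """Two single-class entries per flagged specimen (one if a class is empty)."""
    entries = []
    suffix = {msa.NUCLEAR: ITS_SUFFIX, msa.PLASTID: PL_SUFFIX}
    for flag in flags:
        if flag.verdict != "incongruent":
            continue
        label = flag.label
        if label not in aln.matrix:
            raise KeyError(f"specimen {label!r} not in alignment")
        for klass in (msa.PLASTID, msa.NUCLEAR):
            cols = scheme.columns(klass)
            seq = aln.sequence(label)
            if any(seq[c] not in "-?N" for c in cols):
                entries.append(
                    DuplicatedEntry(label, label + suffix[klass], klass)
                )
            else:
                logger.info(
                    "specimen %s has no %s data; entry skipped", label, klass
                )
    return entries


def entry_sequence(
    aln: msa.Alignment, scheme: msa.PartitionScheme, entry: DuplicatedEntry
) -> str:
    """Full-width sequence with the complementary class coded missing."""
    seq = list("?" * aln.n_columns)
    source = aln.sequence(entry.parent)
    for c in scheme.columns(entry.klass):
        seq[c] = source[c]
    return "".join(seq)


def place_entry(
    entry: DuplicatedEntry,
    core: CoreResult,
    aln: msa.Alignment,
    scheme: msa.PartitionScheme,
) -> PlacementResult:
    """Attach the entry to every core edge; report per-edge LWRs.

    The core topology and branch lengths stay fixed; only the pendant
    branch is optimized (bounded 1-D search at each candidate edge).
    """
    regions = [
        rm for rm in core.region_models
        if scheme.region(rm.region).klass == entry.klass
    ]
    if not regions:
        raise PlacementError(f"core has no fitted models for {entry.klass}")
    ext = aln.with_rows({entry.label: entry_sequence(aln, scheme, entry)})
    taxa = sorted(core.core_taxa) + [entry.label]
    datas = [
        (PatternData(ext, scheme.region(rm.region).columns(), taxa), rm)
        for rm in regions
    ]
    informative = any(
        (d.pure_codes(entry.label) >= 0).any() for d, _ in datas
    )

    core_clades = core.core_tree.clades()
    edges = [
        (core_clades[n], n)
        for n in core.core_tree.postorder()
        if n is not core.core_tree.root
    ]
    lnls: dict[frozenset, tuple[float, float]] = {}
    for side, node in edges:
        work = core.core_tree.copy()
        target = _node_for_side(work, side)
        leaf = work.attach_at_edge(target, entry.label, 0.05)
        index = TreeIndex(work)
        engines = [Engine(index, d, rm.model, rm.rate) for d, rm in datas]
        pendant = index.index[id(leaf)]
        lnl = optimize_edges(
            index, engines, [pendant], max_sweeps=1, tol=1e-6,
            xatol=1e-6, maxiter=40,
        )
        lnls[side] = (lnl, index.brlen[pendant])

    sides = list(lnls)
    arr = np.array([lnls[s][0] for s in sides])
    if not informative:
        lwr = {s: 1.0 / len(sides) for s in sides}
        best = sides[0]
        logger.warning("entry %s has no informative columns", entry.label)
        return PlacementResult(
            entry, best, lnls[best][1], float(arr[0]), lwr, uniform=True
        )
    weights = np.exp(arr - arr.max())
    weights /= weights.sum()
    lwr = {s: float(w) for s, w in zip(sides, weights)}
    best_i = int(np.argmax(weights))
    best = sides[best_i]
    return PlacementResult(
        entry, best, lnls[best][1], float(arr[best_i]), lwr
    )


def _node_for_side(tree: Tree, side: frozenset) -> Node:
    clades = tree.clades()
    for n in tree.postorder():
        if n is not tree.root and clades[n] == side:
            return n
    raise PlacementError(f"no edge with side {sorted(side)}")


@dataclass
class IndividualAnalysis:
    placements: dict[str, dict[str, PlacementResult]]  # parent -> klass -> result

    def pair(self, parent: str) -> tuple[PlacementResult, PlacementResult]:
        d = self.placements[parent]
        return d[msa.PLASTID], d[msa.NUCLEAR]


def analyze_individually(
    entries: Sequence[DuplicatedEntry],
    core: CoreResult,
    aln: msa.Alignment,
    scheme: msa.PartitionScheme,
) -> IndividualAnalysis:
    """Place each specimen's entries with no other flagged specimen present.

    Placement against the fixed core tree involves one entry at a time by
    construction, so results are independent of processing order.
    """
    placements: dict[str, dict[str, PlacementResult]] = {}
    for entry in entries:
        res = place_entry(entry, core, aln, scheme)
        placements.setdefault(entry.parent, {})[entry.klass] = res
    return IndividualAnalysis(placements)


def expanded_inference(
    core: CoreResult,
    group: Sequence[str],
    entries: Sequence[DuplicatedEntry],
    aln: msa.Alignment,
    scheme: msa.PartitionScheme,
    settings: Optional[InferenceSettings] = None,
    seed: int = 0,
    placements: Optional[IndividualAnalysis] = None,
) -> Tree:
    """Full re-inference of core taxa plus one group's duplicated entries.

    The starting tree grafts each entry onto its best placement edge (the
    individual-analysis screen), then runs the standard NNI search with
    branch-length and support re-estimation over all regions.
    """
    settings = settings or InferenceSettings()
    group = list(group)
    if not group:
        return core.core_tree.copy()
    group_entries = [e for e in entries if e.parent in group]
    if not group_entries:
        raise PlacementError("no duplicated entries for the requested group")

    extra = {
        e.label: entry_sequence(aln, scheme, e) for e in group_entries
    }
    ext = aln.with_rows(extra)
    taxa = sorted(core.core_taxa) + sorted(extra)

    start = core.core_tree.copy()
    for e in group_entries:
        if placements is not None:
            side = placements.placements[e.parent][e.klass].best_edge
            target = _node_for_side_loose(start, side, core.core_taxa)
        else:
            target = next(
                n for n in start.postorder() if n is not start.root
            )
        start.attach_at_edge(target, e.label, 0.05)

    fixed = {rm.region: rm for rm in core.region_models}
    run_settings = InferenceSettings(
        candidates=settings.candidates,
        bootstrap_replicates=settings.bootstrap_replicates,
        mode=settings.mode,
        bs_min=settings.bs_min,
        ab_min=settings.ab_min,
        nni_max_iters=settings.nni_max_iters,
        nni_tol=settings.nni_tol,
        branch_sweeps=settings.branch_sweeps,
        fixed_models=fixed,
    )
    tree, _ = infer_tree(
        ext, scheme, regions=[r.name for r in scheme.regions],
        settings=run_settings, seed=seed, taxa=taxa, start_tree=start,
    )
    return tree


def _node_for_side_loose(tree: Tree, side: frozenset, core_taxa) -> Node:
    """Edge whose core-taxon side matches (tolerates earlier grafts)."""
    clades = tree.clades()
    best = None
    for n in tree.postorder():
        if n is tree.root:
            continue
        restricted = clades[n] & core_taxa
        if restricted == side:
            size = len(clades[n])
            if best is None or size < best[0]:
                best = (size, n)
    if best is None:
        raise PlacementError(f"no edge with core side {sorted(side)}")
    return best[1]
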