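"""Hard-incongruence detection between nuclear and plastid trees.

A *hard conflict* is a pair of strongly supported splits — one from each
class tree — that cannot be displayed on a single tree over the shared
taxon set (all four intersection blocks non-empty).  The strong-support
rule follows the conventional thresholds (bootstrap >= 95%, aBayes >= 0.95);
``mode="or"`` accepts either support type, ``mode="and"`` requires both.

Specimens are attributed to conflicts by greedy leave-one-out re-inference:
the candidate set is bounded to taxa appearing in a *minority block* (one of
the smallest of the four intersection blocks) of at least one conflict, and
each round removes the specimen whose deletion resolves the most conflicts
(ties broken lexicographically) until no hard conflicts remain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

from . import msa
from .inference import InferenceSettings, infer_tree
from .trees import Tree


class ConflictError(ValueError):
    pass


@dataclass(frozen=True)
class Bipartition:
    """A non-trivial split of a tree's taxon set with its edge supports."""

    universe: frozenset
    side: frozenset  # canonical: lexicographically smaller sorted side
    bs: Optional[float]
    abayes: Optional[float]
    klass: str = ""

    @classmethod
    def from_node(cls, tree_universe, node_side, bs, abayes, klass=""):
        side = frozenset(node_side)
        other = frozenset(tree_universe) - side
        canon = min(side, other, key=lambda s: sorted(s))
        return cls(frozenset(tree_universe), canon, bs, abayes, klass)

    @property
    def other_side(self) -> frozenset:
        return self.universe - self.side

    def support_score(self) -> float:
        """Scalar support for ordering: max of bs/100 and aBayes."""
        vals = []
        if self.bs is not None:
            vals.append(self.bs / 100.0)
        if self.abayes is not None:
            vals.append(self.abayes)
        return max(vals) if vals else 0.0

    def is_strong(self, mode="or", bs_min=95.0, ab_min=0.95) -> bool:
        bs_ok = self.bs is not None and self.bs >= bs_min
        ab_ok = self.abayes is not None and self.abayes >= ab_min
        if mode == "or":
            return bs_ok or ab_ok
        if mode == "and":
            return bs_ok and ab_ok
        raise ConflictError(f"unknown support mode {mode!r}")

    def sort_key(self):
        return (tuple(sorted(self.side)), tuple(sorted(self.other_side)))


@dataclass
class ConflictRecord:
    split_nuclear: Bipartition
    split_plastid: Bipartition
    shared: frozenset
    blocks: tuple[frozenset, frozenset, frozenset, frozenset]

    @property
    def min_support(self) -> float:
        return min(
            self.split_nuclear.support_score(),
            self.split_plastid.support_score(),
        )

    def minority_blocks(self) -> list[frozenset]:
        """The smallest intersection block(s) of this conflict."""
        smallest = min(len(b) for b in self.blocks)
        return [b for b in self.blocks if len(b) == smallest]

    def key(self):
        return (
            self.split_nuclear.sort_key(),
            self.split_plastid.sort_key(),
        )


@dataclass
class SpecimenFlag:
    label: str
    verdict: str  # "congruent" | "incongruent"
    conflicts_resolved: list[int] = field(default_factory=list)

    def __post_init__(self):
        incongruent = self.verdict == "incongruent"
        if incongruent != bool(self.conflicts_resolved):
            raise ConflictError(
                "verdict must be 'incongruent' iff conflicts were resolved"
            )


def strong_splits(
    tree: Tree,
    mode: str = "or",
    bs_min: float = 95.0,
    ab_min: float = 0.95,
    klass: str = "",
) -> list[Bipartition]:
    """Non-trivial splits passing the strong-support rule."""
    universe = tree.leaf_labels()
    clades = tree.clades()
    any_support = False
    out = []
    for node in tree.internal_edges():
        if node.bs is not None or node.abayes is not None:
            any_support = True
        side = clades[node]
        if len(side) < 2 or len(universe - side) < 2:
            continue
        bp = Bipartition.from_node(universe, side, node.bs, node.abayes, klass)
        if bp.is_strong(mode, bs_min, ab_min):
            out.append(bp)
    if not any_support:
        warnings.warn("tree carries no support values; no strong splits")
        return []
    out.sort(key=lambda b: (-b.support_score(), b.sort_key()))
    return out


def incompatible(a: Bipartition, b: Bipartition, shared: frozenset) -> bool:
    """Standard four-block split incompatibility on a shared taxon set."""
    A = a.side & shared
    B = a.other_side & shared
    C = b.side & shared
    D = b.other_side & shared
    if min(len(A), len(B)) < 2 or min(len(C), len(D)) < 2:
        return False  # trivial after restriction: displayable on any tree
    return bool(A & C) and bool(A & D) and bool(B & C) and bool(B & D)


def detect_hard_conflicts(
    t_nuc: Tree,
    t_pla: Tree,
    mode: str = "or",
    bs_min: float = 95.0,
    ab_min: float = 0.95,
) -> list[ConflictRecord]:
    """All incompatible pairs of strong nuclear/plastid splits."""
    shared = t_nuc.leaf_labels() & t_pla.leaf_labels()
    if len(shared) < 4:
        raise ConflictError("trees share fewer than 4 taxa")
    nuc = strong_splits(t_nuc, mode, bs_min, ab_min, klass=msa.NUCLEAR)
    pla = strong_splits(t_pla, mode, bs_min, ab_min, klass=msa.PLASTID)
    records = []
    for sn in nuc:
        for sp in pla:
            if incompatible(sn, sp, shared):
                blocks = (
                    sn.side & sp.side & shared,
                    sn.side & sp.other_side & shared,
                    sn.other_side & sp.side & shared,
                    sn.other_side & sp.other_side & shared,
                )
                records.append(ConflictRecord(sn, sp, frozenset(shared), blocks))
    records.sort(key=lambda r: (-r.min_support, r.key()))
    return records


@dataclass
class AttributionResult:
    flags: list[SpecimenFlag]
    converged: bool
    remaining: list[ConflictRecord]
    # Class trees re-inferred on the congruent taxon set during the final
    # greedy round (reusable by core construction); empty if no removals.
    class_trees: dict = field(default_factory=dict)

    @property
    def flagged(self) -> list[str]:
        return [f.label for f in self.flags if f.verdict == "incongruent"]


def attribute_specimens(
    aln: msa.Alignment,
    scheme: msa.PartitionScheme,
    conflicts: Sequence[ConflictRecord],
    t_nuc: Tree,
    t_pla: Tree,
    settings: Optional[InferenceSettings] = None,
    seed: int = 0,
) -> AttributionResult:
    """Greedy leave-one-out attribution of conflicts to specimens.

    Re-inference reuses the per-region models fixed from the full-data fit
    (``settings.fixed_models``) and starts each search from the current
    class tree with the candidate removed.
    """
    if not conflicts:
        taxa = sorted(t_nuc.leaf_labels() | t_pla.leaf_labels())
        return AttributionResult(
            [SpecimenFlag(t, "congruent") for t in taxa], True, []
        )
    settings = settings or InferenceSettings()
    removed: list[str] = []
    resolved_by: dict[str, list[int]] = {}
    current = {"nuc": t_nuc, "pla": t_pla, "conflicts": list(conflicts)}
    conflict_ids = {rec.key(): i for i, rec in enumerate(conflicts)}
    cache: dict[frozenset, tuple] = {}

    def reinfer(taxa_removed: frozenset):
        key = taxa_removed
        if key in cache:
            return cache[key]
        keep_nuc = sorted(t_nuc.leaf_labels() - taxa_removed)
        keep_pla = sorted(t_pla.leaf_labels() - taxa_removed)
        tn, _ = infer_tree(
            aln, scheme, klass=msa.NUCLEAR, settings=settings, seed=seed,
            taxa=keep_nuc, start_tree=current["nuc"],
        )
        tp, _ = infer_tree(
            aln, scheme, klass=msa.PLASTID, settings=settings, seed=seed,
            taxa=keep_pla, start_tree=current["pla"],
        )
        recs = detect_hard_conflicts(
            tn, tp, settings.mode, settings.bs_min, settings.ab_min
        )
        cache[key] = (tn, tp, recs)
        return cache[key]

    while current["conflicts"]:
        candidates = sorted(
            {
                taxon
                for rec in current["conflicts"]
                for block in rec.minority_blocks()
                for taxon in block
            }
        )
        best = None
        n_current = len(current["conflicts"])
        for cand in candidates:
            _, _, after = reinfer(frozenset(removed) | {cand})
            keep = current["conflicts"][0].shared - {cand}
            after_keys = {rec.key() for rec in after}
            gone = {
                rec.key()
                for rec in current["conflicts"]
                if _restricted_key(rec, keep) not in after_keys
            }
            if gone and (best is None or len(gone) > len(best[1])):
                best = (cand, gone)
                if len(gone) == n_current:
                    # Scanning lexicographically: no later candidate can
                    # resolve more, and equal counts lose the tie-break.
                    break
        if best is None:
            # No candidate's removal resolves anything further: report the
            # rest as unattributable rather than forcing removals.
            final_trees = (
                {msa.NUCLEAR: current["nuc"], msa.PLASTID: current["pla"]}
                if removed else {}
            )
            return AttributionResult(
                _make_flags(t_nuc, t_pla, removed, resolved_by),
                False,
                current["conflicts"],
                class_trees=final_trees,
            )
        cand, gone = best
        removed.append(cand)
        resolved_by[cand] = sorted(
            conflict_ids.get(k, -1) for k in gone
        )
        tn, tp, recs = reinfer(frozenset(removed))
        current = {"nuc": tn, "pla": tp, "conflicts": recs}
    final_trees = (
        {msa.NUCLEAR: current["nuc"], msa.PLASTID: current["pla"]}
        if removed else {}
    )
    return AttributionResult(
        _make_flags(t_nuc, t_pla, removed, resolved_by), True, [],
        class_trees=final_trees,
    )


def _restricted_key(rec: ConflictRecord, keep: frozenset):
    """The conflict's key after restriction to a surviving taxon set.

    Returns None when either split becomes trivial (or the restricted pair
    compatible), i.e. the conflict cannot persist at all.
    """

    def restrict(bp: Bipartition):
        s = bp.side & keep
        o = bp.other_side & keep
        if len(s) < 2 or len(o) < 2:
            return None
        canon = min(s, o, key=lambda x: sorted(x))
        other = o if canon is s else s
        return (tuple(sorted(canon)), tuple(sorted(other)))

    a = restrict(rec.split_nuclear)
    b = restrict(rec.split_plastid)
    if a is None or b is None:
        return None
    ra = Bipartition(frozenset(keep), frozenset(a[0]), None, None)
    rb = Bipartition(frozenset(keep), frozenset(b[0]), None, None)
    if not incompatible(ra, rb, frozenset(keep)):
        return None
    return (a, b)


def _make_flags(t_nuc, t_pla, removed, resolved_by) -> list[SpecimenFlag]:
    taxa = sorted(t_nuc.leaf_labels() | t_pla.leaf_labels())
    flags = []
    for t in taxa:
        if t in resolved_by:
            flags.append(SpecimenFlag(t, "incongruent", resolved_by[t]))
        else:
            flags.append(SpecimenFlag(t, "congruent"))
    return flags
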