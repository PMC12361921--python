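"""Discordance-pattern classification and floating ITS groups.

Phase 3 labels each incongruent specimen by the pair of named core clades
its plastid and ITS placements fall into, groups specimens with identical
patterns, and scans expanded trees for *floating ITS groups*: strongly
supported clades made only of duplicated ITS entries whose plastid copies
attach to at least two different named clades — the signature of a
homogenized nuclear signal shared by hybrids with divergent plastid
donors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import yaml

from . import msa
from .coretree import CoreResult
from .placement import ITS_SUFFIX, PL_SUFFIX, IndividualAnalysis, PlacementResult
from .trees import Node, Tree


class ClassifyError(ValueError):
    pass


@dataclass
class CladeMap:
    """Named clades of the core tree (user-supplied or auto-generated)."""

    clades: dict[str, frozenset]

    def __post_init__(self):
        if len(set(self.clades)) != len(self.clades):
            raise ClassifyError("clade names must be unique")

    @classmethod
    def auto(
        cls,
        core_tree: Tree,
        mode: str = "or",
        bs_min: float = 95.0,
        ab_min: float = 0.95,
    ) -> "CladeMap":
        """Maximal disjoint strongly supported clades, largest first."""
        universe = core_tree.leaf_labels()
        clades = core_tree.clades()
        strong = []
        for node in core_tree.internal_edges():
            side = clades[node]
            if len(side) < 2 or len(universe - side) < 2:
                continue
            bs_ok = node.bs is not None and node.bs >= bs_min
            ab_ok = node.abayes is not None and node.abayes >= ab_min
            ok = (bs_ok or ab_ok) if mode == "or" else (bs_ok and ab_ok)
            if ok:
                strong.append(side)
        strong.sort(key=lambda s: (-len(s), sorted(s)))
        chosen: list[frozenset] = []
        for side in strong:
            if all(not (side & c) for c in chosen):
                chosen.append(side)
        named = {f"C{i + 1}": side for i, side in enumerate(chosen)}
        return cls(named)

    @classmethod
    def from_exemplars(
        cls, core_tree: Tree, exemplars: dict[str, Sequence[str]]
    ) -> "CladeMap":
        """Name clades by exemplar leaf pairs (smallest split side containing
        all exemplars — the unrooted MRCA convention)."""
        universe = core_tree.leaf_labels()
        clades = core_tree.clades()
        sides = [
            clades[n]
            for n in core_tree.postorder()
            if n is not core_tree.root
        ]
        sides += [universe - s for s in sides]
        named = {}
        for name, leaves in exemplars.items():
            want = set(leaves)
            if not want <= universe:
                raise ClassifyError(
                    f"clade {name!r}: exemplars {sorted(want - universe)} "
                    "not in core tree"
                )
            fitting = [s for s in sides if want <= s and len(s) < len(universe)]
            if not fitting:
                raise ClassifyError(f"clade {name!r}: no split contains exemplars")
            named[name] = min(fitting, key=len)
        return cls(named)

    @classmethod
    def from_yaml(cls, core_tree: Tree, path) -> "CladeMap":
        with open(path, "r", encoding="utf-8") as fh:
            spec = yaml.safe_load(fh)
        return cls.from_exemplars(core_tree, spec)

    def validate_against(self, core_tree: Tree) -> None:
        universe = core_tree.leaf_labels()
        clades = core_tree.clades()
        sides = {
            frozenset(clades[n])
            for n in core_tree.postorder()
            if n is not core_tree.root
        }
        sides |= {universe - s for s in sides}
        for name, members in self.clades.items():
            if frozenset(members) not in sides:
                raise ClassifyError(f"{name!r} is not a clade of the core tree")


@dataclass(frozen=True)
class DiscordancePattern:
    specimen: str
    plastid_clade: str
    its_clade: str

    @property
    def pattern(self) -> tuple[str, str]:
        return (self.plastid_clade, self.its_clade)

    @property
    def discordant(self) -> bool:
        return self.plastid_clade != self.its_clade


@dataclass
class FloatingGroup:
    members: frozenset  # ITS entry labels
    bs: Optional[float]
    abayes: Optional[float]
    plastid_clades: frozenset  # distinct named destinations of members' PL


def assign_clade(
    placement: PlacementResult, clade_map: CladeMap, core: CoreResult
) -> str:
    """Clade label of a placement edge, or ``between(X,Y)`` for stems."""
    return _assign_side(placement.best_edge, clade_map, core)


def _assign_side(side: frozenset, clade_map: CladeMap, core: CoreResult) -> str:
    universe = frozenset(core.core_taxa)
    for name in sorted(
        clade_map.clades, key=lambda n: len(clade_map.clades[n])
    ):
        members = clade_map.clades[name]
        if side <= members or (universe - side) <= members:
            return name
    # Stem/backbone edge: find the two nearest named clades.
    tree = core.core_tree
    clades = tree.clades()
    node = None
    for n in tree.postorder():
        if n is not tree.root and (clades[n] == side or clades[n] == universe - side):
            node = n
            break
    if node is None:
        raise ClassifyError(f"edge {sorted(side)} not found on core tree")
    dists = []
    for name, members in clade_map.clades.items():
        stem = None
        for n in tree.postorder():
            if n is tree.root:
                continue
            if clades[n] == members or clades[n] == universe - members:
                stem = n
                break
        if stem is None:
            continue
        dists.append((tree.edge_distance(node, stem), name))
    dists.sort()
    if len(dists) >= 2:
        pair = sorted([dists[0][1], dists[1][1]])
        return f"between({pair[0]},{pair[1]})"
    if dists:
        return f"between({dists[0][1]},?)"
    return "unplaced"


def classify_patterns(
    analysis: IndividualAnalysis,
    clade_map: Optional[CladeMap],
    core: CoreResult,
    mode: str = "or",
    bs_min: float = 95.0,
    ab_min: float = 0.95,
) -> tuple[list[DiscordancePattern], dict[tuple, list[str]]]:
    """Label every specimen's (plastid, ITS) pattern and group by equality.

    Returns the pattern list and pattern -> specimens groups, largest
    group first; the groups partition the flagged specimens.
    """
    if clade_map is None or not clade_map.clades:
        clade_map = CladeMap.auto(core.core_tree, mode, bs_min, ab_min)
    patterns = []
    for specimen in sorted(analysis.placements):
        both = analysis.placements[specimen]
        if msa.PLASTID not in both or msa.NUCLEAR not in both:
            continue
        patterns.append(
            DiscordancePattern(
                specimen,
                assign_clade(both[msa.PLASTID], clade_map, core),
                assign_clade(both[msa.NUCLEAR], clade_map, core),
            )
        )
    groups: dict[tuple, list[str]] = {}
    for p in patterns:
        groups.setdefault(p.pattern, []).append(p.specimen)
    ordered = dict(
        sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    )
    return patterns, ordered


def expansion_groups(patterns: Sequence[DiscordancePattern]) -> list[list[str]]:
    """Group specimens into expanded datasets by *similar* discordance.

    Specimens belong to the same expanded dataset when they share a clade
    destination in either class (connected components of that relation).
    This is deliberately coarser than exact pattern equality: hybrids with
    one shared donor and one divergent donor must co-occur in an expanded
    tree for floating ITS groups to be observable.
    """
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    by_label: dict[tuple, list[str]] = {}
    for p in patterns:
        parent[p.specimen] = p.specimen
        by_label.setdefault(("PL", p.plastid_clade), []).append(p.specimen)
        by_label.setdefault(("ITS", p.its_clade), []).append(p.specimen)
    for members in by_label.values():
        for other in members[1:]:
            union(members[0], other)
    groups: dict[str, list[str]] = {}
    for p in patterns:
        groups.setdefault(find(p.specimen), []).append(p.specimen)
    return sorted(
        (sorted(g) for g in groups.values()), key=lambda g: (-len(g), g)
    )


def find_floating_groups(
    expanded: Tree,
    analysis: IndividualAnalysis,
    clade_map: Optional[CladeMap],
    core: CoreResult,
    mode: str = "or",
    bs_min: float = 95.0,
    ab_min: float = 0.95,
) -> list[FloatingGroup]:
    """Maximal strong clades of ITS entries with divergent plastid donors.

    A floating ITS group must (a) pass the strong-support rule in the
    expanded tree, (b) contain >= 2 duplicated ITS entries and no core
    taxa, and (c) have member plastid entries assigned to >= 2 distinct
    named clades.
    """
    if clade_map is None or not clade_map.clades:
        clade_map = CladeMap.auto(core.core_tree, mode, bs_min, ab_min)
    clades = expanded.clades()
    universe = expanded.leaf_labels()
    candidates = []
    for node in expanded.internal_edges():
        side = clades[node]
        if len(side) < 2 or len(universe - side) < 2:
            continue
        for group_side in (side, universe - side):
            if not all(lab.endswith(ITS_SUFFIX) for lab in group_side):
                continue
            bs_ok = node.bs is not None and node.bs >= bs_min
            ab_ok = node.abayes is not None and node.abayes >= ab_min
            ok = (bs_ok or ab_ok) if mode == "or" else (bs_ok and ab_ok)
            if not ok:
                continue
            candidates.append((frozenset(group_side), node.bs, node.abayes))
    # maximality: drop candidates contained in a larger candidate
    candidates.sort(key=lambda c: -len(c[0]))
    maximal: list[tuple[frozenset, Optional[float], Optional[float]]] = []
    for side, bs, ab in candidates:
        if any(side <= m[0] for m in maximal):
            continue
        maximal.append((side, bs, ab))
    out = []
    for side, bs, ab in maximal:
        dests = set()
        for lab in side:
            parent = lab[: -len(ITS_SUFFIX)]
            both = analysis.placements.get(parent, {})
            if msa.PLASTID in both:
                dests.add(assign_clade(both[msa.PLASTID], clade_map, core))
        if len(dests) >= 2:
            out.append(FloatingGroup(side, bs, ab, frozenset(dests)))
    return out
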