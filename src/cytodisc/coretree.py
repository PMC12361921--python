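"""Core-phylogeny construction: congruent specimens, combined data.

The core dataset keeps only specimens whose plastid and nuclear signals are
congruent; the combine-only-if-congruent rule is enforced as a hard
invariant — if the reduced class trees still show a strongly supported
conflict, building the core fails loudly rather than combining discordant
data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import warnings

from . import msa
from .conflict import SpecimenFlag, _restricted_key, detect_hard_conflicts
from .inference import InferenceSettings, RegionModel, infer_tree
from .trees import Tree


class CoreError(ValueError):
    pass


@dataclass
class CoreResult:
    core_taxa: frozenset
    excluded: dict[str, str]  # label -> reason
    core_tree: Tree
    region_models: list[RegionModel]
    class_trees: dict[str, Tree] = field(default_factory=dict)
    # Conflicts declared unattributable upstream and knowingly tolerated
    # when combining (reported, never silent).
    unattributable: list = field(default_factory=list)

    def edge_by_side(self) -> dict[frozenset, object]:
        """Map core-taxon side below each edge -> owning node."""
        clades = self.core_tree.clades()
        return {
            clades[n]: n
            for n in self.core_tree.postorder()
            if n is not self.core_tree.root
        }


def build_core(
    aln: msa.Alignment,
    scheme: msa.PartitionScheme,
    flags: Sequence[SpecimenFlag],
    settings: Optional[InferenceSettings] = None,
    seed: int = 0,
    start_trees: Optional[dict] = None,
    verified_class_trees: Optional[dict] = None,
    tolerated_conflicts: Optional[list] = None,
) -> CoreResult:
    """Drop incongruent specimens, verify congruence, infer the core tree.

    ``verified_class_trees`` lets the caller supply class trees already
    inferred on exactly the congruent taxon set (e.g. from the final
    attribution round); they are re-checked, not trusted.
    ``tolerated_conflicts`` are conflicts the attribution stage reported
    as unattributable to any specimen: residual conflicts matching them
    are recorded on the result (with a warning) instead of aborting;
    any *other* residual conflict is still a hard failure.
    """
    settings = settings or InferenceSettings()
    excluded = {
        f.label: f"resolves conflicts {f.conflicts_resolved}"
        for f in flags
        if f.verdict == "incongruent"
    }
    core_taxa = sorted(
        {f.label for f in flags if f.verdict == "congruent"}
    )
    if len(core_taxa) < 4:
        raise CoreError("fewer than 4 congruent specimens remain")

    # Verify the zero-conflict invariant on the reduced class trees.
    class_trees = {}
    for klass in (msa.NUCLEAR, msa.PLASTID):
        supplied = (verified_class_trees or {}).get(klass)
        if supplied is not None and supplied.leaf_labels() == frozenset(core_taxa):
            class_trees[klass] = supplied
            continue
        start = (start_trees or {}).get(klass)
        tree, _ = infer_tree(
            aln, scheme, klass=klass, settings=settings, seed=seed,
            taxa=core_taxa, start_tree=start,
        )
        class_trees[klass] = tree
    residual = detect_hard_conflicts(
        class_trees[msa.NUCLEAR], class_trees[msa.PLASTID],
        settings.mode, settings.bs_min, settings.ab_min,
    )
    unattributable: list = []
    if residual:
        keep = frozenset(core_taxa)
        tolerated_keys = {
            _restricted_key(rec, keep)
            for rec in (tolerated_conflicts or [])
        }
        tolerated_keys.discard(None)
        for rec in residual:
            if _restricted_key(rec, keep) in tolerated_keys:
                unattributable.append(rec)
            else:
                raise CoreError(
                    "residual hard conflict among supposedly congruent "
                    f"specimens: nuclear {sorted(rec.split_nuclear.side)} "
                    f"vs plastid {sorted(rec.split_plastid.side)}"
                )
        warnings.warn(
            f"combining despite {len(unattributable)} unattributable "
            "conflict(s); see CoreResult.unattributable"
        )

    core_tree, region_models = infer_tree(
        aln, scheme, regions=[r.name for r in scheme.regions],
        settings=settings, seed=seed, taxa=core_taxa,
        start_tree=class_trees[msa.PLASTID],
    )
    return CoreResult(
        core_taxa=frozenset(core_taxa),
        excluded=excluded,
        core_tree=core_tree,
        region_models=region_models,
        class_trees=class_trees,
        unattributable=unattributable,
    )
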