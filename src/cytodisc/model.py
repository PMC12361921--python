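"""Model/Results facade for the three-phase discordance analysis.

``DiscordanceModel`` wraps a two-class partitioned alignment the way a
statsmodels model wraps a design matrix: construct it from data (files, a
synthetic bundle, or in-memory objects), call :meth:`fit`, and receive a
:class:`DiscordanceResults` carrying the class trees, conflict records,
specimen flags, core phylogeny, per-entry placements, discordance patterns
and floating ITS groups, with a ``summary()`` table for human reading.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

from . import classify, conflict, coretree, msa, placement
from .inference import InferenceSettings, RegionModel, infer_tree
from .simulate import Bundle, SimulationConfig, simulate_bundle
from .trees import Tree


class DiscordanceModel:
    """Three-phase cytonuclear discordance analysis of one alignment.

    Parameters
    ----------
    alignment
        Aligned character matrix with both plastid- and nuclear-class data.
    partitions
        Partition scheme labelling column ranges with region names and
        classes; at least one region per class.
    settings
        Inference settings (support thresholds and mode, model candidates,
        bootstrap replicates, search depth).  Defaults follow the
        conventional strong-support thresholds bs >= 95, aBayes >= 0.95
        with "or" semantics for conflict inspection.
    clade_exemplars
        Optional named clades for pattern labelling, given as
        ``{name: [exemplar_leaf, ...]}``; auto-generated from strongly
        supported core clades when omitted.
    """

    def __init__(
        self,
        alignment: msa.Alignment,
        partitions: msa.PartitionScheme,
        settings: Optional[InferenceSettings] = None,
        clade_exemplars: Optional[dict] = None,
    ):
        partitions.validate_against(alignment)
        for klass in (msa.PLASTID, msa.NUCLEAR):
            if not partitions.class_regions(klass):
                raise msa.PartitionError(f"no {klass} regions in scheme")
        self.alignment = alignment
        self.partitions = partitions
        self.settings = settings or InferenceSettings()
        self.clade_exemplars = clade_exemplars
        self.truth = None  # populated by from_simulation

    # -------------------------------------------------------- constructors

    @classmethod
    def from_files(
        cls,
        alignment_path,
        partitions_path,
        settings: Optional[InferenceSettings] = None,
        clade_exemplars: Optional[dict] = None,
    ) -> "DiscordanceModel":
        aln = msa.read_alignment(alignment_path)
        scheme = msa.read_partitions(partitions_path)
        return cls(aln, scheme, settings, clade_exemplars)

    @classmethod
    def from_simulation(
        cls,
        config: Optional[SimulationConfig] = None,
        settings: Optional[InferenceSettings] = None,
        **config_kwargs,
    ) -> "DiscordanceModel":
        """Model over a synthetic bundle; ground truth kept on ``.truth``."""
        if config is None:
            config = SimulationConfig(**config_kwargs)
        bundle = simulate_bundle(config)
        return cls.from_bundle(bundle, settings)

    @classmethod
    def from_bundle(
        cls, bundle: Bundle, settings: Optional[InferenceSettings] = None
    ) -> "DiscordanceModel":
        model = cls(bundle.alignment, bundle.scheme, settings)
        model.truth = bundle.truth
        return model

    # ---------------------------------------------------------------- fit

    def fit(
        self,
        seed: int = 0,
        expanded: bool = True,
    ) -> "DiscordanceResults":
        """Run phases 1-3 and return the results object.

        Phase 1: class trees with supports, hard-conflict scan, greedy
        specimen attribution, core phylogeny on congruent specimens.
        Phase 2: taxon duplication and individual placement of every
        flagged specimen against the fixed core tree.
        Phase 3: discordance-pattern grouping, per-group expanded
        re-inference (unless ``expanded=False``) and floating-ITS-group
        detection.
        """
        s = self.settings
        aln, scheme = self.alignment, self.partitions

        # Phase 1 — class trees and conflict scan.
        class_trees: dict[str, Tree] = {}
        class_models: dict[str, list[RegionModel]] = {}
        for klass in (msa.NUCLEAR, msa.PLASTID):
            tree, rms = infer_tree(
                aln, scheme, klass=klass, settings=s, seed=seed
            )
            class_trees[klass] = tree
            class_models[klass] = rms
        fixed = {
            rm.region: rm
            for rms in class_models.values()
            for rm in rms
        }
        refit = replace(s, fixed_models=fixed)

        conflicts = conflict.detect_hard_conflicts(
            class_trees[msa.NUCLEAR], class_trees[msa.PLASTID],
            s.mode, s.bs_min, s.ab_min,
        )
        attribution = conflict.attribute_specimens(
            aln, scheme, conflicts,
            class_trees[msa.NUCLEAR], class_trees[msa.PLASTID],
            settings=refit, seed=seed,
        )
        verified = attribution.class_trees if attribution.flagged else class_trees
        core = coretree.build_core(
            aln, scheme, attribution.flags, settings=refit, seed=seed,
            start_trees=class_trees, verified_class_trees=verified,
            tolerated_conflicts=attribution.remaining,
        )

        # Phase 2 — taxon duplication and individual placement.
        entries = placement.make_duplicates(aln, scheme, attribution.flags)
        analysis = placement.analyze_individually(entries, core, aln, scheme)

        # Phase 3 — patterns, expanded trees, floating groups.
        clade_map = (
            classify.CladeMap.from_exemplars(core.core_tree, self.clade_exemplars)
            if self.clade_exemplars
            else classify.CladeMap.auto(
                core.core_tree, s.mode, s.bs_min, s.ab_min
            )
        )
        patterns, groups = classify.classify_patterns(
            analysis, clade_map, core, s.mode, s.bs_min, s.ab_min
        )
        # Expanded datasets merge specimens sharing either clade
        # destination, so e.g. a homogenized ITS clade spanning divergent
        # plastid donors ends up in one expanded tree.
        expansion = classify.expansion_groups(patterns)
        expanded_trees: dict[tuple, Tree] = {}
        floating: list[classify.FloatingGroup] = []
        if expanded and expansion:
            for members in expansion:
                tree = placement.expanded_inference(
                    core, members, entries, aln, scheme,
                    settings=refit, seed=seed, placements=analysis,
                )
                expanded_trees[tuple(members)] = tree
                floating.extend(
                    classify.find_floating_groups(
                        tree, analysis, clade_map, core,
                        s.mode, s.bs_min, s.ab_min,
                    )
                )
        return DiscordanceResults(
            model=self,
            seed=seed,
            class_trees=class_trees,
            region_models=fixed,
            conflicts=conflicts,
            attribution=attribution,
            core=core,
            entries=entries,
            analysis=analysis,
            clade_map=clade_map,
            patterns=patterns,
            groups=groups,
            expanded_trees=expanded_trees,
            floating_groups=floating,
        )


@dataclass
class DiscordanceResults:
    """Everything the three phases produced, with reporting helpers."""

    model: DiscordanceModel
    seed: int
    class_trees: dict
    region_models: dict
    conflicts: list
    attribution: conflict.AttributionResult
    core: coretree.CoreResult
    entries: list
    analysis: placement.IndividualAnalysis
    clade_map: classify.CladeMap
    patterns: list
    groups: dict
    expanded_trees: dict
    floating_groups: list

    @property
    def flagged(self) -> list[str]:
        return self.attribution.flagged

    def placement_for(self, parent: str, klass: str):
        return self.analysis.placements[parent][klass]

    # ------------------------------------------------------------ reporting

    def summary(self) -> str:
        lines = []
        aln = self.model.alignment
        lines.append("Cytonuclear discordance analysis")
        lines.append("=" * 56)
        lines.append(
            f"Specimens: {len(aln.taxa)}   Columns: {aln.n_columns}   "
            f"Seed: {self.seed}"
        )
        lines.append("")
        lines.append("Per-region models")
        lines.append("-" * 56)
        lines.append(f"{'region':<16}{'model':<10}{'rate':>8}{'lnL':>14}")
        for name, rm in self.region_models.items():
            lnl = f"{rm.log_likelihood:.1f}" if rm.log_likelihood else "-"
            lines.append(
                f"{name:<16}{rm.model.display_name:<10}{rm.rate:>8.3f}{lnl:>14}"
            )
        lines.append("")
        lines.append(
            f"Hard conflicts: {len(self.conflicts)}   "
            f"Flagged specimens: {len(self.flagged)}   "
            f"Converged: {self.attribution.converged}"
        )
        if self.flagged:
            lines.append("  flagged: " + ", ".join(self.flagged))
        lines.append(
            f"Core: {len(self.core.core_taxa)} taxa "
            f"({len(self.core.excluded)} excluded)"
        )
        if self.core.unattributable:
            lines.append(
                f"WARNING: {len(self.core.unattributable)} unattributable "
                "conflict(s) tolerated when combining"
            )
        lines.append("")
        if self.patterns:
            lines.append("Discordance patterns (plastid -> ITS)")
            lines.append("-" * 56)
            for pattern, members in self.groups.items():
                lines.append(
                    f"  PL={pattern[0]:<18} ITS={pattern[1]:<18} "
                    f"n={len(members)}: {', '.join(members)}"
                )
        else:
            lines.append("No discordant specimens; core = full dataset.")
        if self.floating_groups:
            lines.append("")
            lines.append("Floating ITS groups")
            lines.append("-" * 56)
            for g in self.floating_groups:
                sup = []
                if g.bs is not None:
                    sup.append(f"BS={g.bs:.0f}")
                if g.abayes is not None:
                    sup.append(f"aBayes={g.abayes:.2f}")
                lines.append(
                    f"  {{{', '.join(sorted(g.members))}}} "
                    f"[{'; '.join(sup)}] plastid donors: "
                    f"{', '.join(sorted(g.plastid_clades))}"
                )
        return "\n".join(lines)
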