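"""Taxon duplication and placement against the core tree."""

import numpy as np
import pytest

from cytodisc import msa
from cytodisc.conflict import SpecimenFlag
from cytodisc.likelihood import Engine, PatternData, TreeIndex
from cytodisc.placement import (
    DuplicatedEntry,
    analyze_individually,
    entry_sequence,
    expanded_inference,
    make_duplicates,
    place_entry,
)
from cytodisc.trees import rf_distance
from tests.conftest import small_config


def flag(label):
    return SpecimenFlag(label, "incongruent", [0])


class TestMakeDuplicates:
    def test_two_entries_per_flagged_specimen(self, small_bundle):
        aln, scheme = small_bundle.alignment, small_bundle.scheme
        flags = [flag(aln.taxa[0])]
        entries = make_duplicates(aln, scheme, flags)
        assert [e.label for e in entries] == [
            aln.taxa[0] + "_PL", aln.taxa[0] + "_ITS"
        ]

    def test_specimen_without_plastid_data_gets_one_entry(self):
        scheme = msa.parse_partitions(
            "pl, plastid, 1-8\nits, nuclear, 9-16"
        )
        aln = msa.Alignment.from_records([
            ("a", "ACGTACGTACGTACGT"),
            ("b", "????????ACGTACGT"),
            ("c", "ACGTACGTACGTACGT"),
        ])
        entries = make_duplicates(aln, scheme, [flag("b")])
        assert [e.label for e in entries] == ["b_ITS"]

    def test_twenty_six_specimens_give_52_entries(self, rng):
        scheme = msa.parse_partitions("pl, plastid, 1-4\nits, nuclear, 5-8")
        records = [
            (f"sp{i:02d}", "".join(rng.choice(list("ACGT"), size=8)))
            for i in range(30)
        ]
        aln = msa.Alignment.from_records(records)
        flags = [flag(f"sp{i:02d}") for i in range(26)]
        assert len(make_duplicates(aln, scheme, flags)) == 52

    def test_unknown_specimen_rejected(self, small_bundle):
        with pytest.raises(KeyError):
            make_duplicates(
                small_bundle.alignment, small_bundle.scheme, [flag("nope")]
            )

    def test_entry_sequence_masks_other_class(self, small_bundle):
        aln, scheme = small_bundle.alignment, small_bundle.scheme
        entry = DuplicatedEntry(aln.taxa[0], aln.taxa[0] + "_ITS", msa.NUCLEAR)
        seq = entry_sequence(aln, scheme, entry)
        nuc_cols = set(scheme.columns(msa.NUCLEAR).tolist())
        for c, ch in enumerate(seq):
            if c in nuc_cols:
                assert ch == aln.sequence(aln.taxa[0])[c]
            else:
                assert ch == "?"


class TestPlacement:
    def test_lwr_normalized(self, fitted_small):
        _, results = fitted_small
        for parent, both in results.analysis.placements.items():
            for p in both.values():
                assert sum(p.lwr.values()) == pytest.approx(1.0, abs=1e-8)
                assert min(p.lwr.values()) >= 0.0
                assert p.lwr[p.best_edge] == max(p.lwr.values())

    def test_core_leaf_copy_places_on_its_pendant_edge(self, fitted_small):
        model, results = fitted_small
        core = results.core
        leaf = sorted(core.core_taxa)[0]
        entry = DuplicatedEntry(leaf, leaf + "_ITS", msa.NUCLEAR)
        res = place_entry(
            entry, core, model.alignment, model.partitions
        )
        assert res.best_edge == frozenset([leaf])
        assert res.lwr[res.best_edge] > 0.9

    def test_best_edge_matches_grid_oracle(self, fitted_small):
        model, results = fitted_small
        core = results.core
        hybrid = results.flagged[0]
        entry = DuplicatedEntry(hybrid, hybrid + "_PL", msa.PLASTID)
        res = place_entry(entry, core, model.alignment, model.partitions)
        # brute force: every edge x a fine pendant-length grid
        aln, scheme = model.alignment, model.partitions
        ext = aln.with_rows(
            {entry.label: entry_sequence(aln, scheme, entry)}
        )
        taxa = sorted(core.core_taxa) + [entry.label]
        regions = [
            rm for rm in core.region_models
            if scheme.region(rm.region).klass == msa.PLASTID
        ]
        datas = [
            (PatternData(ext, scheme.region(rm.region).columns(), taxa), rm)
            for rm in regions
        ]
        clades = core.core_tree.clades()
        best = (None, -np.inf)
        for node in core.core_tree.postorder():
            if node is core.core_tree.root:
                continue
            side = clades[node]
            work = core.core_tree.copy()
            wclades = work.clades()
            target = next(
                n for n in work.postorder()
                if n is not work.root and wclades[n] == side
            )
            leaf = work.attach_at_edge(target, entry.label, 0.0)
            for pend in np.linspace(0.0, 0.4, 41):
                leaf.length = float(pend)
                index = TreeIndex(work)
                lnl = sum(
                    Engine(index, d, rm.model, rm.rate).lnl()
                    for d, rm in datas
                )
                if lnl > best[1]:
                    best = (side, lnl)
        assert res.best_edge == best[0]

    def test_hybrid_entries_recover_donor_edges(self, fitted_small):
        model, results = fitted_small
        truth = model.truth
        core = results.core
        edge_by_side = core.edge_by_side()
        universe = frozenset(core.core_taxa)
        for h in truth.hybrids:
            for klass, want in (
                (msa.PLASTID, h.plastid_donor),
                (msa.NUCLEAR, h.its_donor),
            ):
                got = results.analysis.placements[h.label][klass].best_edge
                n_got = edge_by_side.get(got) or edge_by_side.get(universe - got)
                n_want = edge_by_side.get(want) or edge_by_side.get(
                    universe - want
                )
                assert n_got is not None and n_want is not None
                dist = core.core_tree.edge_distance(n_got, n_want)
                assert dist <= 1  # true donor edge or adjacent


class TestExpandedInference:
    def test_empty_group_returns_core(self, fitted_small):
        model, results = fitted_small
        out = expanded_inference(
            results.core, [], results.entries,
            model.alignment, model.partitions,
        )
        assert out.split_set() == results.core.core_tree.split_set()

    def test_entries_attach_near_donors(self, fitted_small):
        model, results = fitted_small
        truth = model.truth
        hybrid = results.flagged[0]
        tree = results.expanded_trees[
            next(k for k in results.expanded_trees if hybrid in k)
        ]
        labels = tree.leaf_labels()
        assert hybrid + "_PL" in labels and hybrid + "_ITS" in labels
        # the PL entry is within distance 2 of its true donor clade
        pl_donor, _ = truth.donor_edges(hybrid)
        clades = tree.clades()
        entry_leaf = tree.find_leaf(hybrid + "_PL")
        donor_node = None
        for n in tree.postorder():
            if n is tree.root:
                continue
            side = clades[n] & frozenset(results.core.core_taxa)
            if side == pl_donor and not (
                clades[n] - pl_donor - {hybrid + "_PL", hybrid + "_ITS"}
            ):
                donor_node = n
                break
        assert donor_node is not None
        assert tree.edge_distance(entry_leaf, donor_node) <= 3


class TestOrderInvariance:
    def test_individual_analysis_independent_of_entry_order(self, fitted_small):
        model, results = fitted_small
        entries = list(results.entries)
        redo = analyze_individually(
            list(reversed(entries)), results.core,
            model.alignment, model.partitions,
        )
        for parent, both in results.analysis.placements.items():
            for klass, orig in both.items():
                got = redo.placements[parent][klass]
                assert got.best_edge == orig.best_edge
                assert got.log_likelihood == pytest.approx(
                    orig.log_likelihood, abs=1e-9
                )
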