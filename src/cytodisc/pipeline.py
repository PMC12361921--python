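"""Run-directory orchestration of the three phases.

``run_all`` executes the whole analysis on an alignment + partition file,
writing every stage's artifacts (trees, conflict and flag tables,
placement and pattern tables) plus a manifest with versions, seeds,
thresholds and output checksums, so a re-run with the same config is
checksum-identical.  ``report`` renders a human-readable summary of a run
directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import yaml

from . import __version__, msa
from .inference import InferenceSettings
from .model import DiscordanceModel

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    alignment: str
    partitions: str
    output: str
    bs_min: float = 95.0
    ab_min: float = 0.95
    mode: str = "or"
    # Desk-scale default; raise toward 10000 for publication-grade
    # supports, or set 0 for aBayes-only support (fast screens).
    bootstrap_replicates: int = 200
    candidates: tuple[str, ...] = ("JC", "JC+G", "HKY+G", "GTR+G")
    seed: int = 0
    expanded: bool = True
    clade_exemplars: Optional[dict] = None

    def __post_init__(self):
        if not (0 <= self.bs_min <= 100):
            raise ValueError("bs_min must be in [0, 100]")
        if not (0 <= self.ab_min <= 1):
            raise ValueError("ab_min must be in [0, 1]")
        if self.bootstrap_replicates < 0:
            raise ValueError("bootstrap_replicates must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        if "candidates" in raw:
            raw["candidates"] = tuple(raw["candidates"])
        return cls(**raw)

    def settings(self) -> InferenceSettings:
        return InferenceSettings(
            candidates=tuple(self.candidates),
            bootstrap_replicates=self.bootstrap_replicates,
            mode=self.mode,
            bs_min=self.bs_min,
            ab_min=self.ab_min,
        )


def run_all(config: RunConfig) -> Path:
    """Execute phases 1-3 and write a self-describing run directory."""
    out = Path(config.output)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    model = DiscordanceModel.from_files(
        config.alignment, config.partitions,
        settings=config.settings(),
        clade_exemplars=config.clade_exemplars,
    )
    logger.info(
        "run-all: %d taxa, %d columns, seed %d",
        len(model.alignment.taxa), model.alignment.n_columns, config.seed,
    )
    results = model.fit(seed=config.seed, expanded=config.expanded)
    write_results(results, out)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": {
            **{k: v for k, v in asdict(config).items()},
            "candidates": list(config.candidates),
        },
        "wall_time_s": round(time.time() - t0, 2),
        "checksums": {
            p.name: _sha256(p)
            for p in sorted(out.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out


def write_results(results, out: Path) -> None:
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    for klass, tree in results.class_trees.items():
        tree.write(out / f"tree_{klass}.nwk")
    results.core.core_tree.write(out / "tree_core.nwk")

    with open(out / "models.tsv", "w", encoding="utf-8") as fh:
        fh.write("region\tmodel\trate\tlnL\tk\taic\n")
        for name, rm in results.region_models.items():
            lnl = rm.log_likelihood
            fh.write(
                f"{name}\t{rm.model.display_name}\t{rm.rate:.6g}\t"
                f"{'' if lnl is None else f'{lnl:.4f}'}\t"
                f"{rm.model.k_free_parameters()}\t"
                f"{'' if rm.aic is None else f'{rm.aic:.4f}'}\n"
            )

    with open(out / "conflicts.tsv", "w", encoding="utf-8") as fh:
        fh.write(
            "id\tnuclear_side\tnuclear_bs\tnuclear_abayes\t"
            "plastid_side\tplastid_bs\tplastid_abayes\tmin_support\n"
        )
        for i, rec in enumerate(results.conflicts):
            sn, sp = rec.split_nuclear, rec.split_plastid
            fh.write(
                f"{i}\t{','.join(sorted(sn.side))}\t{_fmt(sn.bs)}\t"
                f"{_fmt(sn.abayes)}\t{','.join(sorted(sp.side))}\t"
                f"{_fmt(sp.bs)}\t{_fmt(sp.abayes)}\t{rec.min_support:.4f}\n"
            )

    with open(out / "flags.tsv", "w", encoding="utf-8") as fh:
        fh.write("specimen\tverdict\tconflicts_resolved\n")
        for flag in results.attribution.flags:
            fh.write(
                f"{flag.label}\t{flag.verdict}\t"
                f"{','.join(map(str, flag.conflicts_resolved))}\n"
            )

    with open(out / "exclusions.tsv", "w", encoding="utf-8") as fh:
        fh.write("specimen\treason\n")
        for label, reason in sorted(results.core.excluded.items()):
            fh.write(f"{label}\t{reason}\n")

    with open(out / "placements.tsv", "w", encoding="utf-8") as fh:
        fh.write(
            "entry\tclass\tbest_edge\tpendant_length\tlnL\tbest_lwr\n"
        )
        for parent in sorted(results.analysis.placements):
            for klass, p in sorted(results.analysis.placements[parent].items()):
                fh.write(
                    f"{p.entry.label}\t{klass}\t"
                    f"{','.join(sorted(p.best_edge))}\t"
                    f"{p.pendant_length:.6g}\t{p.log_likelihood:.4f}\t"
                    f"{max(p.lwr.values()):.4f}\n"
                )

    with open(out / "patterns.tsv", "w", encoding="utf-8") as fh:
        fh.write("specimen\tplastid_clade\tits_clade\tgroup_size\n")
        sizes = {
            p: len(members) for p, members in results.groups.items()
        }
        for pat in results.patterns:
            fh.write(
                f"{pat.specimen}\t{pat.plastid_clade}\t{pat.its_clade}\t"
                f"{sizes.get(pat.pattern, 1)}\n"
            )

    with open(out / "clades.tsv", "w", encoding="utf-8") as fh:
        fh.write("name\tmembers\n")
        for name, members in results.clade_map.clades.items():
            fh.write(f"{name}\t{','.join(sorted(members))}\n")

    for i, (pattern, tree) in enumerate(results.expanded_trees.items(), 1):
        tree.write(out / f"tree_expanded_{i}.nwk")

    with open(out / "floating_groups.tsv", "w", encoding="utf-8") as fh:
        fh.write("members\tbs\tabayes\tplastid_clades\n")
        for g in results.floating_groups:
            fh.write(
                f"{','.join(sorted(g.members))}\t{_fmt(g.bs)}\t"
                f"{_fmt(g.abayes)}\t{','.join(sorted(g.plastid_clades))}\n"
            )

    save_region_models(results.region_models, out / "region_models.json")
    save_placements(results.analysis, out / "placements.json")

    with open(out / "summary.txt", "w", encoding="utf-8") as fh:
        fh.write(results.summary() + "\n")


# ------------------------------------------- stage (de)serialization


def save_region_models(region_models: dict, path) -> None:
    payload = {}
    for name, rm in region_models.items():
        m = rm.model
        payload[name] = {
            "model": m.name,
            "exchangeabilities": list(m.exchangeabilities),
            "base_freqs": list(m.base_freqs),
            "gamma_shape": m.gamma_shape,
            "n_rate_categories": m.n_rate_categories,
            "rate": rm.rate,
            "log_likelihood": rm.log_likelihood,
        }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)


def load_region_models(path) -> dict:
    from .inference import RegionModel
    from .models import SubstitutionModel

    with open(path, "r", encoding="utf-8") as fh:
        payload = json.load(fh)
    out = {}
    for name, d in payload.items():
        model = SubstitutionModel(
            d["model"],
            tuple(d["exchangeabilities"]),
            tuple(d["base_freqs"]),
            d["gamma_shape"],
            d["n_rate_categories"],
        )
        out[name] = RegionModel(name, model, d["rate"], d["log_likelihood"])
    return out


def save_placements(analysis, path) -> None:
    from dataclasses import asdict as _asdict

    payload = {}
    for parent, both in analysis.placements.items():
        payload[parent] = {
            klass: {
                "entry": _asdict(p.entry),
                "best_edge": sorted(p.best_edge),
                "pendant_length": p.pendant_length,
                "log_likelihood": p.log_likelihood,
                "lwr": {",".join(sorted(k)): v for k, v in p.lwr.items()},
                "uniform": p.uniform,
            }
            for klass, p in both.items()
        }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)


def load_placements(path):
    from .placement import DuplicatedEntry, IndividualAnalysis, PlacementResult

    with open(path, "r", encoding="utf-8") as fh:
        payload = json.load(fh)
    placements = {}
    for parent, both in payload.items():
        placements[parent] = {}
        for klass, d in both.items():
            entry = DuplicatedEntry(**d["entry"])
            placements[parent][klass] = PlacementResult(
                entry=entry,
                best_edge=frozenset(d["best_edge"]),
                pendant_length=d["pendant_length"],
                log_likelihood=d["log_likelihood"],
                lwr={
                    frozenset(k.split(",")): v for k, v in d["lwr"].items()
                },
                uniform=d["uniform"],
            )
    return IndividualAnalysis(placements)


def load_flags(path) -> list:
    from .conflict import SpecimenFlag

    flags = []
    with open(path, "r", encoding="utf-8") as fh:
        next(fh)
        for line in fh:
            label, verdict, resolved = (line.rstrip("\n").split("\t") + [""])[:3]
            ids = [int(x) for x in resolved.split(",") if x]
            flags.append(SpecimenFlag(label, verdict, ids))
    return flags


def report(run_dir) -> str:
    """Summarize a (possibly partial) run directory."""
    run_dir = Path(run_dir)
    lines = [f"Run directory: {run_dir}"]
    manifest = run_dir / "manifest.json"
    if manifest.exists():
        with open(manifest, "r", encoding="utf-8") as fh:
            m = json.load(fh)
        lines.append(
            f"version {m.get('version')}  seed {m.get('seed')}  "
            f"wall time {m.get('wall_time_s')}s"
        )
    else:
        lines.append("manifest: not found (partial run?)")
    stages = [
        ("class trees", ["tree_nuclear.nwk", "tree_plastid.nwk"]),
        ("conflict scan", ["conflicts.tsv", "flags.tsv"]),
        ("core phylogeny", ["tree_core.nwk", "exclusions.tsv", "models.tsv"]),
        ("placement", ["placements.tsv"]),
        ("classification", ["patterns.tsv", "floating_groups.tsv"]),
    ]
    if not any(
        (run_dir / f).exists() for _, files in stages for f in files
    ):
        lines.append("no stages have produced output")
        return "\n".join(lines)
    for stage, files in stages:
        present = [f for f in files if (run_dir / f).exists()]
        if not present:
            lines.append(f"{stage}: not run")
            continue
        counts = []
        for f in present:
            p = run_dir / f
            if f.endswith(".tsv"):
                with open(p, "r", encoding="utf-8") as fh:
                    n = max(sum(1 for _ in fh) - 1, 0)
                counts.append(f"{f}: {n} rows")
            else:
                counts.append(f)
        lines.append(f"{stage}: " + "; ".join(counts))
    summary = run_dir / "summary.txt"
    if summary.exists():
        lines.append("")
        lines.append(summary.read_text(encoding="utf-8").rstrip())
    return "\n".join(lines)


def _fmt(x) -> str:
    return "" if x is None else f"{x:.4f}"


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
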