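"""End-to-end analysis runner: sequences → composition stats → statistics,
plus optional conservation and gene-loss stages, with a reproducibility
manifest.

Every stage is optional and driven by which inputs the :class:`RunConfig`
names.  Identical inputs and config produce byte-identical outputs; any stage
error aborts the run with a stage-named message and removes partial outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .conservation import conservation_profile
from .dyad_analysis import DyadParams, SequenceStats, profile_sequences
from .genome_screen import dollo_loss_events, genes_lost_anywhere
from .io_formats import (
    Category,
    FormatError,
    read_copy_matrix,
    read_fasta,
    read_msa,
    read_species_tree,
    write_table,
)
from .stats import compare_groups, kendall_tau

logger = logging.getLogger("centrodyad")

__all__ = ["RunConfig", "PipelineError", "run_full_analysis"]


class PipelineError(RuntimeError):
    """A stage failure; the message names the stage."""


@dataclass
class RunConfig:
    """Inputs, parameters and output location for a full analysis run."""

    output_dir: str
    sequences: str | None = None
    categories: str | None = None  # optional sidecar TSV: id, species, category
    msa: str | None = None
    copy_matrix: str | None = None
    species_tree: str | None = None
    min_arm: int = 5
    max_arm: int = 100
    max_spacer: int = 20
    allow_overlap: bool = True
    include_spacer: bool = False
    correlation_x: str = "gc_percent"
    correlation_y: str = "dyad_density"
    compare_value: str = "gc_percent"
    compare_family: str = "within_species"  # or "all_pairs"
    conservation_measures: list[str] = field(
        default_factory=lambda: ["entropy:unweighted"]
    )
    gap_threshold: float = 0.5
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def dyad_params(self) -> DyadParams:
        return DyadParams(
            min_arm=self.min_arm,
            max_arm=self.max_arm,
            max_spacer=self.max_spacer,
            allow_overlap=self.allow_overlap,
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_categories(path: str) -> tuple[dict[str, Category], dict[str, str]]:
    categories: dict[str, Category] = {}
    species: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        try:
            id_i, sp_i, cat_i = (
                header.index("id"),
                header.index("species"),
                header.index("category"),
            )
        except ValueError as exc:
            raise FormatError(
                f"{path}: category sidecar needs id/species/category columns"
            ) from exc
        for line in fh:
            cells = line.rstrip("\n").split("\t")
            categories[cells[id_i]] = Category(cells[cat_i])
            species[cells[id_i]] = cells[sp_i]
    return categories, species


def _stats_rows(stats: list[SequenceStats]) -> list[dict]:
    return [
        {
            "id": s.id,
            "species": s.species or "",
            "category": s.category.value,
            "length": s.length,
            "gc_percent": s.gc_percent,
            "dyad_density": s.dyad_density,
            "n_dyads": s.n_dyads,
        }
        for s in stats
    ]


def _within_species_pairs(stats: list[SequenceStats]) -> tuple[dict, list]:
    """Group label per id (species:category) and the old-vs-new pair family."""
    grouping = {}
    species_seen: dict[str, set[str]] = {}
    for s in stats:
        if s.category in (Category.OLD_CENTROMERE, Category.NEW_CENTROMERE) and s.species:
            label = f"{s.species}:{s.category.value}"
            grouping[s.id] = label
            species_seen.setdefault(s.species, set()).add(s.category.value)
    pairs = [
        (f"{sp}:old_centromere", f"{sp}:new_centromere")
        for sp in sorted(species_seen)
        if species_seen[sp] == {"old_centromere", "new_centromere"}
    ]
    return grouping, pairs


def run_full_analysis(config: RunConfig) -> dict:
    """Run every configured stage; return a bundle of results and output paths.

    Outputs (as configured): ``stats.tsv``, ``correlation.tsv``,
    ``comparisons.tsv``, ``conservation.tsv``, ``losses.tsv`` and
    ``manifest.json`` in ``config.output_dir``.
    """
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    bundle: dict = {"outputs": {}}
    inputs = {
        name: Path(p)
        for name, p in (
            ("sequences", config.sequences),
            ("categories", config.categories),
            ("msa", config.msa),
            ("copy_matrix", config.copy_matrix),
            ("species_tree", config.species_tree),
        )
        if p
    }
    for name, p in inputs.items():
        if not p.exists():
            raise PipelineError(f"input: missing {name} file {p}")

    def emit(name: str, rows: list[dict], columns: list[str]) -> Path:
        path = outdir / name
        write_table(rows, path, columns)
        written.append(path)
        bundle["outputs"][name] = str(path)
        return path

    try:
        if config.sequences:
            category_map: dict[str, Category] | None = None
            species_map: dict[str, str] = {}
            if config.categories:
                category_map, species_map = _load_categories(config.categories)
            try:
                records = read_fasta(config.sequences, category_map=category_map)
            except FormatError as exc:
                raise PipelineError(f"sequences: {exc}") from exc
            for rec in records:
                if rec.id in species_map:
                    rec.species = species_map[rec.id]
            stats = profile_sequences(
                records, config.dyad_params(), include_spacer=config.include_spacer
            )
            bundle["stats"] = stats
            emit(
                "stats.tsv",
                _stats_rows(stats),
                ["id", "species", "category", "length", "gc_percent",
                 "dyad_density", "n_dyads"],
            )

            try:
                corr = kendall_tau(
                    [getattr(s, config.correlation_x) for s in stats],
                    [getattr(s, config.correlation_y) for s in stats],
                )
            except ValueError as exc:
                raise PipelineError(f"correlation: {exc}") from exc
            bundle["correlation"] = corr
            emit(
                "correlation.tsv",
                [{
                    "x": config.correlation_x, "y": config.correlation_y,
                    "n": corr.n, "tau": corr.tau, "p_value": corr.p_value,
                    "method": corr.method.value,
                }],
                ["x", "y", "n", "tau", "p_value", "method"],
            )

            if config.compare_family == "within_species":
                grouping, pairs = _within_species_pairs(stats)
            else:
                grouping = {
                    s.id: s.category.value for s in stats
                }
                pairs = None
            if grouping and (pairs is None or pairs):
                comps = compare_groups(
                    stats, grouping, value=config.compare_value, pairs=pairs
                )
                bundle["comparisons"] = comps
                emit(
                    "comparisons.tsv",
                    [{
                        "pair": f"{c.group_a} vs {c.group_b}",
                        "n_a": c.n_a, "n_b": c.n_b, "statistic": c.statistic,
                        "p_raw": c.p_raw, "q_holm": c.q_holm,
                        "method": c.method.value,
                    } for c in comps],
                    ["pair", "n_a", "n_b", "statistic", "p_raw", "q_holm", "method"],
                )
            else:
                logger.info("comparisons skipped: no eligible old/new groups")

        if config.msa:
            try:
                msa = read_msa(config.msa)
                profile = conservation_profile(
                    msa,
                    measures=list(config.conservation_measures),
                    gap_threshold=config.gap_threshold,
                )
            except (FormatError, ValueError) as exc:
                raise PipelineError(f"conservation: {exc}") from exc
            bundle["conservation"] = profile
            measure_names = [f"{s.value}:{w.value}" for s, w in profile.scores]
            rows = []
            for i in range(profile.n_columns):
                row = {
                    "position": i + 1,
                    "gap_fraction": float(profile.gap_fraction[i]),
                    "masked": int(profile.masked[i]),
                }
                for (s, w), arr in profile.scores.items():
                    row[f"{s.value}:{w.value}"] = (
                        float(arr[i]) if not np.isnan(arr[i]) else float("nan")
                    )
                rows.append(row)
            emit(
                "conservation.tsv",
                rows,
                ["position", "gap_fraction", "masked", *measure_names],
            )

        if config.copy_matrix:
            if not config.species_tree:
                raise PipelineError("losses: a species tree is required")
            try:
                matrix = read_copy_matrix(config.copy_matrix)
                tree = read_species_tree(config.species_tree)
                lost = genes_lost_anywhere(matrix)
                reports = [dollo_loss_events(matrix, tree, g) for g in lost]
            except (FormatError, ValueError) as exc:
                raise PipelineError(f"losses: {exc}") from exc
            bundle["losses"] = reports
            emit(
                "losses.tsv",
                [{
                    "gene": r.gene,
                    "n_species_lost": len(r.species_lost),
                    "species_lost": ",".join(sorted(r.species_lost)),
                    "n_loss_events": r.n_events,
                    "loss_branches": ";".join(sorted(r.loss_branches)),
                    "lost_in_pre": int(r.lost_in_pre),
                    "lost_in_post": int(r.lost_in_post),
                } for r in reports],
                ["gene", "n_species_lost", "species_lost", "n_loss_events",
                 "loss_branches", "lost_in_pre", "lost_in_post"],
            )

        manifest = {
            "package": "centrodyad",
            "version": __version__,
            "config": asdict(config),
            "inputs": {name: _sha256(p) for name, p in inputs.items()},
        }
        manifest_path = outdir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        bundle["outputs"]["manifest.json"] = str(manifest_path)
    except PipelineError:
        for path in written:
            path.unlink(missing_ok=True)
        raise
    return bundle
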