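"""End-to-end orchestration: orthology -> filter -> sites -> stats.

Stages communicate through files under the configured output directory, so
running them one by one produces byte-identical outputs to a monolithic
run. A stage that fails leaves a ``<stage>.partial`` marker next to its
outputs and aborts with a stage-named error.
"""
from __future__ import annotations

import json
import logging
import platform
import time
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .column_quality import filter_columns, score_columns, write_index_map
from .io_formats import SpeciesPartition, read_alignment_fasta, read_hit_table, write_alignment_fasta
from .orthology import (
    assign_reference_orthologs,
    build_orthology_groups,
    check_group_consistency,
    read_group_table,
    read_pair_table,
    write_assignments,
    write_groups,
    write_rejections,
)
from .substitution_stats import (
    SubstitutionSite,
    accumulate_matrix,
    detect_concordant_sites,
    global_composition,
    global_usage_chi2,
    pool_sites,
    site_composition,
    test_directional_imbalance,
    test_usage_bias,
)

log = logging.getLogger(__name__)

ALIGNMENT_GLOBS = ("*.fasta", "*.fa", "*.faa")
STAGES = ("orthology", "filter", "sites", "stats")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Validated configuration for a pipeline run."""

    outdir: str
    foreground: list[str]
    references: list[str]
    alignments: str | None = None
    hits_a: dict[str, str] = field(default_factory=dict)  # species -> outfmt6 TSV vs ref A
    hits_b: dict[str, str] = field(default_factory=dict)
    pair_table: str | None = None
    independent_groups: str | None = None  # optional clustering for the consistency check
    evalue_max: float = 1e-40
    min_species: int = 2
    min_score: int = 8
    max_gap_fraction: float = 0.0
    alpha_bonferroni: float = 1e-15
    q_threshold: float = 0.05
    imbalance_method: str = "exact"
    overlap_mode: str = "equality"
    require_all_foreground: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        hits = raw.pop("hits", {}) or {}
        raw["hits_a"] = {sp: spec["a"] for sp, spec in hits.items()}
        raw["hits_b"] = {sp: spec["b"] for sp, spec in hits.items()}
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown configuration keys {sorted(unknown)}")
        return cls(**raw)

    def partition(self) -> SpeciesPartition:
        return SpeciesPartition(self.foreground, self.references)

    def validate(self) -> None:
        self.partition()  # raises on a bad species split
        if not 0 <= self.max_gap_fraction <= 1:
            raise ValueError(f"max_gap_fraction={self.max_gap_fraction} outside [0, 1]")
        if not 0 <= self.min_score <= 9:
            raise ValueError(f"min_score={self.min_score} outside [0, 9]")
        if not 0 < self.q_threshold < 1:
            raise ValueError(f"q_threshold={self.q_threshold} outside (0, 1)")
        if not 0 < self.alpha_bonferroni <= 1:
            raise ValueError(f"alpha_bonferroni={self.alpha_bonferroni} outside (0, 1]")
        if self.evalue_max < 0:
            raise ValueError("evalue_max must be >= 0")
        if self.imbalance_method not in ("exact", "normal"):
            raise ValueError(f"unknown imbalance_method {self.imbalance_method!r}")
        if self.overlap_mode not in ("equality", "subset"):
            raise ValueError(f"unknown overlap_mode {self.overlap_mode!r}")
        if set(self.hits_a) != set(self.hits_b):
            raise ValueError("hits must provide both reference tables for every species")
        for path in [
            self.alignments,
            self.pair_table,
            self.independent_groups,
            *self.hits_a.values(),
            *self.hits_b.values(),
        ]:
            if path is not None and not Path(path).exists():
                raise ValueError(f"input path does not exist: {path}")


@dataclass
class RunReport:
    counts: dict[str, int] = field(default_factory=dict)


def _alignment_files(directory: str | Path) -> list[Path]:
    files: list[Path] = []
    for pattern in ALIGNMENT_GLOBS:
        files.extend(Path(directory).glob(pattern))
    return sorted(set(files))


@contextmanager
def _stage(name: str, outdir: Path) -> Iterator[None]:
    marker = outdir / f"{name}.partial"
    marker.touch()
    t0 = time.perf_counter()
    log.info("stage %s: started", name)
    try:
        yield
    except Exception as exc:
        raise PipelineError(f"stage {name!r} failed: {exc}") from exc
    marker.unlink(missing_ok=True)
    log.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)


def run_orthology_stage(config: RunConfig) -> dict[str, int]:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    with _stage("orthology", outdir):
        if not config.hits_a or config.pair_table is None:
            raise ValueError("orthology stage needs hit tables and a pair table")
        pairs = read_pair_table(config.pair_table)
        assignments_by_species = {}
        rejections_by_species = {}
        for sp in sorted(config.hits_a):
            hits_a = read_hit_table(config.hits_a[sp])
            hits_b = read_hit_table(config.hits_b[sp])
            assigned, rejected = assign_reference_orthologs(
                hits_a, hits_b, pairs, evalue_max=config.evalue_max
            )
            assignments_by_species[sp] = assigned
            rejections_by_species[sp] = rejected
        write_assignments(assignments_by_species, outdir / "assignments.tsv")
        write_rejections(rejections_by_species, outdir / "rejections.tsv")
        build = build_orthology_groups(assignments_by_species, min_species=config.min_species)
        write_groups(build.groups, outdir / "groups.tsv")
        counts["transcripts_assigned"] = sum(len(v) for v in assignments_by_species.values())
        counts["transcripts_rejected"] = sum(len(v) for v in rejections_by_species.values())
        counts["groups_built"] = len(build.groups)
        if config.independent_groups:
            independent = read_group_table(config.independent_groups)
            report = check_group_consistency(
                build.groups, independent, overlap_mode=config.overlap_mode
            )
            with open(outdir / "consistency.tsv", "w") as fh:
                fh.write("n_groups\tn_consistent\tfraction\n")
                fh.write(f"{report.n_groups_a}\t{report.n_consistent}\t{report.fraction:.6f}\n")
            counts["groups_consistent"] = report.n_consistent
    return counts


def run_filter_stage(config: RunConfig) -> dict[str, int]:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts = {"columns_total": 0, "columns_retained": 0}
    with _stage("filter", outdir):
        if config.alignments is None:
            raise ValueError("filter stage needs an alignment directory")
        files = _alignment_files(config.alignments)
        if not files:
            raise ValueError(f"no alignment files found under {config.alignments}")
        filtered_dir = outdir / "filtered"
        colmap_dir = outdir / "colmaps"
        filtered_dir.mkdir(exist_ok=True)
        colmap_dir.mkdir(exist_ok=True)
        for path in files:
            aln = read_alignment_fasta(path)
            track = score_columns(aln)
            filt, index_map = filter_columns(
                aln, track, min_score=config.min_score, max_gap_fraction=config.max_gap_fraction
            )
            counts["columns_total"] += aln.n_columns
            counts["columns_retained"] += len(index_map)
            if index_map.size:
                write_alignment_fasta(filt, filtered_dir / f"{aln.group_id}.fasta")
            write_index_map(index_map, colmap_dir / f"{aln.group_id}.tsv")
    return counts


def _read_index_map(path: Path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    return df["original_column"].to_numpy() - 1


def run_sites_stage(config: RunConfig) -> dict[str, int]:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts = {"sites_detected": 0, "groups_skipped_missing_species": 0}
    with _stage("sites", outdir):
        filtered_dir = outdir / "filtered"
        colmap_dir = outdir / "colmaps"
        if not filtered_dir.is_dir():
            raise ValueError("sites stage needs the filter stage outputs (filtered/)")
        partition = config.partition()
        all_sites: list[SubstitutionSite] = []
        for path in _alignment_files(filtered_dir):
            aln = read_alignment_fasta(path)
            if config.require_all_foreground:
                missing = (partition.foreground | partition.references) - aln.species
                if missing:
                    counts["groups_skipped_missing_species"] += 1
                    log.info("skipping %s: missing species %s", aln.group_id, sorted(missing))
                    continue
            column_map = _read_index_map(colmap_dir / f"{aln.group_id}.tsv")
            all_sites.extend(
                detect_concordant_sites(
                    aln,
                    partition,
                    require_all_foreground=config.require_all_foreground,
                    column_map=column_map,
                )
            )
        write_sites(all_sites, outdir / "sites.tsv")
        counts["sites_detected"] = len(all_sites)
    return counts


def run_stats_stage(config: RunConfig) -> dict[str, int]:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    with _stage("stats", outdir):
        sites = read_sites(outdir / "sites.tsv")
        matrix = accumulate_matrix(sites)
        matrix.counts.to_csv(outdir / "matrix_counts.tsv", sep="\t")
        matrix.percentages().round(6).to_csv(outdir / "matrix_percent.tsv", sep="\t")
        ref_prof, fg_prof = site_composition(sites)
        comp = pd.DataFrame(
            {
                "count_ref": ref_prof.counts,
                "count_fg": fg_prof.counts,
                "freq_ref": ref_prof.freqs if ref_prof.total else np.nan,
                "freq_fg": fg_prof.freqs if fg_prof.total else np.nan,
            }
        )
        comp.to_csv(outdir / "site_composition.tsv", sep="\t", index_label="residue")
        if config.alignments is not None:
            alns = [read_alignment_fasta(p) for p in _alignment_files(config.alignments)]
            rows = {}
            for sp in sorted(set(config.foreground) | set(config.references)):
                try:
                    rows[sp] = global_composition(alns, sp).freqs
                except ValueError:
                    log.warning("species %s absent from all alignments; skipped", sp)
            if rows:
                pd.DataFrame(rows).to_csv(
                    outdir / "global_composition.tsv", sep="\t", index_label="residue"
                )
        if ref_prof.total and fg_prof.total:
            usage = test_usage_bias(ref_prof, fg_prof, alpha=config.alpha_bonferroni)
            pd.DataFrame([vars(u) for u in usage]).to_csv(
                outdir / "usage_bias.tsv", sep="\t", index=False
            )
            chi2, p, dof = global_usage_chi2(ref_prof, fg_prof)
            with open(outdir / "usage_global_chi2.tsv", "w") as fh:
                fh.write("chi2\tp\tdof\n")
                fh.write(f"{chi2:.6f}\t{p:.6g}\t{dof}\n")
        imbalance = test_directional_imbalance(
            matrix, q_threshold=config.q_threshold, method=config.imbalance_method
        )
        pd.DataFrame([vars(r) for r in imbalance]).to_csv(
            outdir / "imbalance.tsv", sep="\t", index=False
        )
        counts["pairs_tested"] = len(imbalance)
        counts["pairs_significant"] = sum(r.significant for r in imbalance)
    return counts


def write_sites(sites: list[SubstitutionSite], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("group_id\tcolumn\tref_residue\tfg_residue\n")
        for s in sites:
            fh.write(f"{s.group_id}\t{s.column}\t{s.ref_residue}\t{s.fg_residue}\n")


def read_sites(path: str | Path) -> list[SubstitutionSite]:
    sites: list[SubstitutionSite] = []
    with open(path) as fh:
        header = fh.readline()
        if header.strip() and not header.startswith("group_id\t"):
            raise ValueError(f"{path}: unexpected sites header {header!r}")
        for line in fh:
            if not line.strip():
                continue
            gid, col, ref, fg = line.rstrip("\n").split("\t")
            sites.append(SubstitutionSite(gid, int(col), ref, fg))
    return sites


def run_pipeline(config: RunConfig, stages: tuple[str, ...] = STAGES) -> RunReport:
    """Run the requested stages in order and write the run report."""
    for s in stages:
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r}")
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport()
    wants_orthology = "orthology" in stages and config.hits_a and config.pair_table
    if wants_orthology:
        report.counts.update(run_orthology_stage(config))
    if "filter" in stages and config.alignments is not None:
        report.counts.update(run_filter_stage(config))
    if "sites" in stages:
        report.counts.update(run_sites_stage(config))
    if "stats" in stages:
        report.counts.update(run_stats_stage(config))
    if stages == STAGES:
        _write_report(config, report, outdir)
    return report


def _write_report(config: RunConfig, report: RunReport, outdir: Path) -> None:
    payload = {
        "protshift_version": __version__,
        "python_version": platform.python_version(),
        "seed": config.seed,
        "config": {
            k: v for k, v in vars(config).items() if not isinstance(v, (dict,)) or v
        },
        "counts": report.counts,
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
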