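"""Orchestration: run the full analysis chain from one declarative config.

Stages run in dependency order — conservation, selection (+consensus),
surface, charge, climate — each consuming validated inputs from
:mod:`hemocharge.io`. Stages whose inputs are absent are skipped with an
explicit reason; a stage failure marks downstream dependants skipped and
the run as failed. Given identical config and inputs the machine-readable
report is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .charge import PkaTable, polar_census, titration_curve
from .climate import (
    composition_matrix,
    kendall_climate_correlation,
    pca_composition,
    site_composition_by_climate,
)
from .conservation import conservation_profile
from .io import (
    read_fasta_alignment,
    read_newick,
    read_pdb,
    read_species_table,
    read_test_table,
)
from .selection import CodonAlignment, ConsensusConfig, consensus_calls, slac_analysis
from .surface import exposure_profile, map_alignment_to_structure

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Input paths and stage parameters for one analysis run."""

    out_dir: Path
    protein_alignment: Path | None = None
    codon_alignment: Path | None = None
    tree: Path | None = None
    pdb: Path | None = None
    species_table: Path | None = None
    external_tests: list[Path] = field(default_factory=list)
    surface_positions: list[int] = field(default_factory=list)
    canonical_start: int = 1
    window_size: int = 3
    window_weight: float = 0.5
    probe_radius: float = 1.4
    sasa_points: int = 960
    reference_ph: float = 7.27
    min_tests: int = 3
    focal_site: int | None = None

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        raw = tomllib.loads(Path(path).read_text())
        base = Path(path).parent

        def p(key):
            return (base / raw[key]) if key in raw else None

        cfg = cls(
            out_dir=base / raw.get("out_dir", "hemocharge_out"),
            protein_alignment=p("protein_alignment"),
            codon_alignment=p("codon_alignment"),
            tree=p("tree"),
            pdb=p("pdb"),
            species_table=p("species_table"),
            external_tests=[base / x for x in raw.get("external_tests", [])],
            surface_positions=list(raw.get("surface_positions", [])),
            canonical_start=int(raw.get("canonical_start", 1)),
            window_size=int(raw.get("window_size", 3)),
            window_weight=float(raw.get("window_weight", 0.5)),
            probe_radius=float(raw.get("probe_radius", 1.4)),
            sasa_points=int(raw.get("sasa_points", 960)),
            reference_ph=float(raw.get("reference_ph", 7.27)),
            min_tests=int(raw.get("min_tests", 3)),
            focal_site=raw.get("focal_site"),
        )
        for attr in ("protein_alignment", "codon_alignment", "tree", "pdb", "species_table"):
            val = getattr(cfg, attr)
            if val is not None and not Path(val).exists():
                raise FileNotFoundError(f"config path for {attr} does not exist: {val}")
        return cfg


@dataclass
class AnalysisReport:
    """Joined per-site and per-record outputs plus a provenance block."""

    stages: dict[str, str]  # stage -> "ok" | "skipped: reason" | "failed: reason"
    per_site: pd.DataFrame | None = None
    per_record: pd.DataFrame | None = None
    correlations: pd.DataFrame | None = None
    pca_loadings: pd.DataFrame | None = None
    pca_scores: pd.DataFrame | None = None
    site_composition: pd.DataFrame | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not any(v.startswith("failed") for v in self.stages.values())


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_full_analysis(config: PipelineConfig) -> AnalysisReport:
    stages: dict[str, str] = {}
    report = AnalysisReport(stages=stages)
    t0 = time.time()
    config.out_dir.mkdir(parents=True, exist_ok=True)

    protein = codon = tree = species = structure = None
    per_site_frames: list[pd.DataFrame] = []

    # --- conservation -----------------------------------------------------
    if config.protein_alignment is None:
        stages["conservation"] = "skipped: no protein alignment supplied"
    else:
        try:
            protein = read_fasta_alignment(
                config.protein_alignment, "protein", canonical_start=config.canonical_start
            )
            profile = conservation_profile(
                protein, window_size=config.window_size, window_weight=config.window_weight
            )
            cons = profile.to_frame().dropna(subset=["canonical_position"])
            cons["canonical_position"] = cons.canonical_position.astype(int)
            per_site_frames.append(
                cons[["canonical_position", "jsd", "windowed_jsd", "gap_fraction"]]
            )
            stages["conservation"] = "ok"
        except Exception as exc:
            stages["conservation"] = f"failed: {exc}"
            log.exception("conservation stage failed")

    # --- selection --------------------------------------------------------
    if config.codon_alignment is None or config.tree is None:
        stages["selection"] = "skipped: codon alignment and tree both required"
    else:
        try:
            codon_mult = read_fasta_alignment(
                config.codon_alignment, "nucleotide", canonical_start=config.canonical_start
            )
            codon = CodonAlignment(codon_mult)
            tree = read_newick(config.tree)
            counts, slac_tests = slac_analysis(codon, tree)
            site_numbers = {
                s: config.canonical_start + s - 1 for s in range(1, codon.codon_count + 1)
            }
            externals = [read_test_table(p) for p in config.external_tests]
            consensus = consensus_calls(
                internal_slac=slac_tests,
                external_tables=externals,
                config=ConsensusConfig(min_tests=config.min_tests),
                site_numbers=site_numbers,
            )
            sel = counts.table.copy()
            sel["canonical_position"] = sel.site.map(site_numbers)
            sel = sel.merge(
                slac_tests.assign(canonical_position=slac_tests.site.map(site_numbers)).drop(
                    columns="site"
                ),
                on="canonical_position",
            )
            sel = sel.merge(
                consensus.rename(columns={"site": "canonical_position"}),
                on="canonical_position", how="left",
            )
            per_site_frames.append(sel.drop(columns=["site"]))
            stages["selection"] = "ok"
        except Exception as exc:
            stages["selection"] = f"failed: {exc}"
            log.exception("selection stage failed")

    # --- surface ----------------------------------------------------------
    surface_positions = list(config.surface_positions)
    if config.pdb is None:
        stages["surface"] = "skipped: no structure supplied"
    else:
        try:
            structure = read_pdb(config.pdb)
            prof = exposure_profile(
                structure, probe_radius=config.probe_radius, n_points=config.sasa_points
            )
            surf = prof.table.copy()
            if protein is not None:
                try:
                    mapping = map_alignment_to_structure(protein, structure)
                    inv = {v[1]: k for k, v in mapping.canonical_to_structure.items()}
                    surf["canonical_position"] = surf.residue_number.map(inv)
                except ValueError as exc:
                    log.warning("alignment/structure mapping unavailable: %s", exc)
                    surf["canonical_position"] = np.nan
            exposed = surf[surf.exposure == "exposed"]
            if not surface_positions and "canonical_position" in surf:
                surface_positions = sorted(
                    int(x) for x in exposed.canonical_position.dropna()
                )
            surf.to_csv(config.out_dir / "exposure.tsv", sep="\t", index=False)
            if "canonical_position" in surf.columns and surf.canonical_position.notna().any():
                keep = surf.dropna(subset=["canonical_position"]).copy()
                keep["canonical_position"] = keep.canonical_position.astype(int)
                per_site_frames.append(
                    keep[["canonical_position", "sasa", "ratio", "exposure"]]
                )
            stages["surface"] = "ok"
        except Exception as exc:
            stages["surface"] = f"failed: {exc}"
            log.exception("surface stage failed")

    # --- charge -----------------------------------------------------------
    census = None
    if protein is None:
        stages["charge"] = "skipped: no protein alignment supplied"
    elif not surface_positions:
        stages["charge"] = "skipped: no surface position set (supply surface_positions or a structure)"
    else:
        try:
            census = polar_census(protein, surface_positions, config.reference_ph)
            report.per_record = census.table
            census.table.to_csv(config.out_dir / "census.tsv", sep="\t", index=False)
            stages["charge"] = "ok"
        except Exception as exc:
            stages["charge"] = f"failed: {exc}"
            log.exception("charge stage failed")

    # --- climate ----------------------------------------------------------
    if census is None or config.species_table is None:
        stages["climate"] = "skipped: census and species table both required"
    else:
        try:
            species = read_species_table(config.species_table)
            matrix = composition_matrix(census, species)
            pca = pca_composition(matrix)
            corr = kendall_climate_correlation(
                matrix.data.net_charge.values, matrix.annotations.climate_ordinal.values
            )
            report.correlations = pd.DataFrame(
                [{"variable": "net_charge", "tau_b": corr.tau_b,
                  "p_value": corr.p_value, "n": corr.n}]
            )
            report.pca_loadings = pca.loadings
            report.pca_scores = pca.scores
            if config.focal_site is not None:
                report.site_composition = site_composition_by_climate(
                    protein, config.focal_site, species
                )
            stages["climate"] = "ok"
        except Exception as exc:
            stages["climate"] = f"failed: {exc}"
            log.exception("climate stage failed")

    # --- join per-site table ---------------------------------------------
    if per_site_frames:
        joined = per_site_frames[0]
        for frame in per_site_frames[1:]:
            joined = joined.merge(frame, on="canonical_position", how="outer")
        report.per_site = joined.sort_values("canonical_position").reset_index(drop=True)

    input_hashes = {
        name: _hash_file(Path(p))
        for name, p in (
            ("protein_alignment", config.protein_alignment),
            ("codon_alignment", config.codon_alignment),
            ("tree", config.tree),
            ("pdb", config.pdb),
            ("species_table", config.species_table),
        )
        if p is not None
    }
    log.info("analysis finished in %.2f s", time.time() - t0)
    report.provenance = {
        "version": __version__,
        "input_sha256_16": input_hashes,
        "stages": stages,
    }
    return report


def render_report(report: AnalysisReport, out_dir: str | Path, fmt: str = "tsv_bundle") -> list[Path]:
    """Write the report as a TSV bundle or a single HTML page.

    The TSV bundle contains stages.json plus one TSV per populated table;
    HTML mode embeds the same tables (and notes stages that did not run)
    together with the standard diagnostic plots.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    tables = {
        "per_site": report.per_site,
        "per_record": report.per_record,
        "correlations": report.correlations,
        "pca_loadings": report.pca_loadings,
        "pca_scores": report.pca_scores,
        "site_composition": report.site_composition,
    }
    stages_path = out / "stages.json"
    stages_path.write_text(
        json.dumps({"stages": report.stages, "provenance": report.provenance},
                   indent=2, sort_keys=True) + "\n"
    )
    written.append(stages_path)
    if fmt == "tsv_bundle":
        for name, table in tables.items():
            if table is None:
                continue
            path = out / f"{name}.tsv"
            if name == "pca_loadings":
                table.to_csv(path, sep="\t")
            else:
                table.to_csv(path, sep="\t", index=False)
            written.append(path)
        return written
    if fmt == "html":
        from . import plotting

        parts = ["<html><head><title>hemocharge report</title></head><body>"]
        parts.append("<h1>Analysis report</h1><h2>Stages</h2><ul>")
        for stage, status in report.stages.items():
            parts.append(f"<li>{stage}: {status}</li>")
        parts.append("</ul>")
        plot_files = plotting.report_plots(report, out)
        for pf in plot_files:
            parts.append(f'<img src="{pf.name}" width="640"/>')
            written.append(pf)
        for name, table in tables.items():
            if table is None:
                parts.append(f"<h2>{name}</h2><p>not run</p>")
            else:
                parts.append(f"<h2>{name}</h2>")
                parts.append(table.to_html(index=(name == "pca_loadings")))
        parts.append("</body></html>")
        html_path = out / "report.html"
        html_path.write_text("\n".join(parts))
        written.append(html_path)
        return written
    raise ValueError(f"unknown report format {fmt!r}")
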