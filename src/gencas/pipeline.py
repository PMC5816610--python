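"""End-to-end pipeline runs driven by a structured YAML config.

Stages: build-db (annotations -> cassette database), match / search
(functional comparison), footprint (ortholog FASTA -> ranked sites), ddct
(Ct table -> fold changes).  Every stage is a pure function of (inputs,
config, seed); the run report records parameters, seeds and per-stage
record counts, and timestamps appear only in the log.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any

import yaml

import gencas
from gencas.annotation_io import read_annotation, write_table
from gencas.cassette_assembly import AssemblyParams, assemble_cassettes, cassettes_to_frame
from gencas.cassette_compare import (
    combinations_to_frame,
    match_cassettes,
    match_to_frame,
    search_conserved_combinations,
)
from gencas.ddct import ddct_fold_changes, fold_changes_to_frame
from gencas.fixtures import load_cassette_fixtures, load_crp_motif
from gencas.motifs import MotifModel
from gencas.regulatory import TssAnchor, hits_to_frame, phylogenetic_footprint

log = logging.getLogger("gencas")


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


_KNOWN_KEYS = {
    "seed",
    "outdir",
    "annotations",
    "use_fixture_db",
    "assembly",
    "match",
    "search",
    "footprint",
    "ddct",
}
_ASSEMBLY_KEYS = {"max_gap", "min_genes", "circular"}
_MATCH_KEYS = {"cassette_a", "cassette_b"}
_SEARCH_KEYS = {"min_size", "min_groups"}
_FOOTPRINT_KEYS = {
    "orthologs_fasta",
    "motif",
    "tss_position",
    "strand",
    "window_up",
    "window_down",
    "threshold_fraction",
    "region_id",
}
_DDCT_KEYS = {"table", "reference_condition"}


def load_config(path: str | Path) -> dict[str, Any]:
    config = yaml.safe_load(Path(path).read_text())
    if not isinstance(config, dict):
        raise ConfigError("config must be a mapping")
    validate_config(config)
    return config


def validate_config(config: dict[str, Any]) -> None:
    unknown = set(config) - _KNOWN_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    for key, allowed in (
        ("assembly", _ASSEMBLY_KEYS),
        ("match", _MATCH_KEYS),
        ("search", _SEARCH_KEYS),
        ("footprint", _FOOTPRINT_KEYS),
        ("ddct", _DDCT_KEYS),
    ):
        section = config.get(key)
        if section is None:
            continue
        if not isinstance(section, dict):
            raise ConfigError(f"config section {key!r} must be a mapping")
        bad = set(section) - allowed
        if bad:
            raise ConfigError(f"unknown keys in {key!r}: {sorted(bad)}")
    if not any(
        k in config for k in ("annotations", "use_fixture_db", "footprint", "ddct")
    ):
        raise ConfigError("config declares no inputs (annotations / fixtures / footprint / ddct)")
    if "annotations" in config and not config["annotations"]:
        raise ConfigError("annotations list is empty")


def _read_fasta_seqs(path: str | Path) -> list[str]:
    from Bio import SeqIO

    return [str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")]


def run_pipeline(config: dict[str, Any], outdir: str | Path | None = None) -> dict[str, Any]:
    """Run the configured stages; write tables under the output directory.

    Returns the run report (also written as ``report.json``).
    """
    validate_config(config)
    outdir = Path(outdir or config.get("outdir", "gencas_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "version": gencas.__version__,
        "seed": config.get("seed"),
        "parameters": {k: config[k] for k in config if k not in ("annotations",)},
        "stages": {},
    }

    db = []
    stage = "build-db"
    try:
        if config.get("annotations"):
            params = AssemblyParams(**(config.get("assembly") or {}))
            for entry in config["annotations"]:
                replicon, genes = read_annotation(
                    entry["path"],
                    fmt=entry.get("format"),
                    fasta=entry.get("fasta"),
                    species=entry.get("species"),
                    taxon_group=entry.get("taxon_group"),
                )
                db.extend(
                    assemble_cassettes(genes, params, replicon_length=replicon.length)
                )
            log.info("build-db: %d cassettes from %d files", len(db), len(config["annotations"]))
        if config.get("use_fixture_db"):
            db.extend(load_cassette_fixtures())
        if db:
            write_table(cassettes_to_frame(db), outdir / "cassettes.tsv")
            report["stages"]["build-db"] = {"cassettes": len(db)}

        if config.get("match"):
            stage = "match"
            section = config["match"]
            by_id = {c.cassette_id: c for c in db}
            a, b = by_id[section["cassette_a"]], by_id[section["cassette_b"]]
            result = match_cassettes(a, b)
            write_table(match_to_frame(result, a, b), outdir / "match.tsv")
            report["stages"]["match"] = {
                "cassette_a": result.cassette_a,
                "cassette_b": result.cassette_b,
                "match_size": result.match_size,
                "matched_combination": [str(l) for l in result.matched_combination],
            }

        if config.get("search") is not None and db:
            stage = "search"
            section = config.get("search") or {}
            combos = search_conserved_combinations(
                db,
                min_size=section.get("min_size", 4),
                min_groups=section.get("min_groups", 2),
            )
            write_table(combinations_to_frame(combos), outdir / "combinations.tsv")
            report["stages"]["search"] = {"combinations": len(combos)}

        if config.get("footprint"):
            stage = "footprint"
            section = config["footprint"]
            seqs = _read_fasta_seqs(section["orthologs_fasta"])
            motif = (
                MotifModel.from_file(section["motif"])
                if section.get("motif")
                else load_crp_motif()
            )
            anchor = TssAnchor(
                tss_position=int(section["tss_position"]),
                strand=section.get("strand", "+"),
                window_up=int(section.get("window_up", 250)),
                window_down=int(section.get("window_down", 50)),
            )
            _, hits = phylogenetic_footprint(
                seqs,
                anchor,
                motif,
                region_id=section.get("region_id", "region"),
                threshold_fraction=float(section.get("threshold_fraction", 0.6)),
            )
            write_table(hits_to_frame(hits), outdir / "sites.tsv")
            report["stages"]["footprint"] = {"hits": len(hits)}

        if config.get("ddct"):
            stage = "ddct"
            import pandas as pd

            section = config["ddct"]
            table = pd.read_csv(section["table"], sep="\t")
            results = ddct_fold_changes(
                table, reference_condition=section.get("reference_condition", "glucose")
            )
            write_table(fold_changes_to_frame(results), outdir / "fold_changes.tsv")
            report["stages"]["ddct"] = {"fold_changes": len(results)}
    except ConfigError:
        raise
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    (outdir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report
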