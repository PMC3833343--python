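"""End-to-end orchestration: thin composition of the analysis stages.

``run_pipeline`` reads a :class:`PipelineConfig` (YAML on disk), runs
whichever stages have inputs configured — pseudo-reference substitution,
expression/fold change, divergence, orthogroups, receptivity — in
dependency order, and writes a report directory of TSV/JSON tables plus a
provenance block (config hash, seeds, package version). Stages with
missing inputs are skipped with a warning; everything is deterministic
given the config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .divergence import RegionAnnotation, analyze_pair, prepare_pair
from .expression import CountTable, compute_rpkm, fold_change_table
from .orthogroups import GeneTree, delineate_forest, summarize_repertoire
from .pseudoref import apply_fixed_differences, load_reference, load_variants, write_reference
from .receptivity import (
    class_enrichment,
    compute_receptivity,
    filter_matrix,
    map_orthologs,
    receptivity_change,
)

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]

DEFAULT_THRESHOLDS = {
    "support": 90.0,        # bootstrap % a clade must exceed to be an OG
    "response": 100.0,      # spikes/s retention threshold for SSR data
    "band_percent": 10.0,   # receptivity-change band treated as unchanged
    "min_depth": 5,         # fixed-difference read-depth filter
    "min_quality": 60.0,    # fixed-difference variant-quality filter
    "credibility": 0.99,    # reliable fold-change credibility level
}


@dataclass
class PipelineConfig:
    inputs: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)
    seed: int = 0
    draws: int = 100_000
    output_dir: str = "olfdiverge_report"

    def __post_init__(self) -> None:
        merged = dict(DEFAULT_THRESHOLDS)
        merged.update(self.thresholds)
        self.thresholds = merged

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "inputs": self.inputs,
            "thresholds": self.thresholds,
            "seed": self.seed,
            "draws": self.draws,
            "output_dir": self.output_dir,
        }

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _read_pair_fasta(path: Path):
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 2:
        raise ValueError(f"{path} must contain exactly two aligned CDS records")
    return prepare_pair(
        str(records[0].seq), str(records[1].seq),
        gene_id_a=records[0].id, gene_id_b=records[1].id,
    )


def _stage_divergence(cfg: PipelineConfig, outdir: Path) -> str | None:
    pair_dir = cfg.inputs.get("pairs_dir")
    if pair_dir is None:
        return None
    regions = {}
    regions_tsv = cfg.inputs.get("regions_tsv")
    if regions_tsv:
        rframe = pd.read_csv(regions_tsv, sep="\t", dtype=str)
        for _, row in rframe.iterrows():
            regions[row["gene_id"]] = RegionAnnotation.from_string(
                row["gene_id"], row["labels"]
            )
    rows = []
    for fasta in sorted(Path(pair_dir).glob("*.fasta")) + sorted(Path(pair_dir).glob("*.fa")):
        pair = _read_pair_fasta(fasta)
        est = analyze_pair(pair, regions=regions.get(pair.gene_id_a))
        rows.append(est.to_row())
    frame = pd.DataFrame(rows)
    frame.to_csv(outdir / "divergence.tsv", sep="\t", index=False)
    return "divergence"


def _stage_orthogroups(cfg: PipelineConfig, outdir: Path) -> str | None:
    trees_path = cfg.inputs.get("gene_trees")
    map_path = cfg.inputs.get("species_map")
    if trees_path is None or map_path is None:
        return None
    species_map = dict(
        pd.read_csv(map_path, sep="\t", header=None, names=["gene", "species"]).values
    )
    newicks = [ln.strip() for ln in Path(trees_path).read_text().splitlines() if ln.strip()]
    trees = [GeneTree(newick=nwk, species_map=species_map) for nwk in newicks]
    ogs = delineate_forest(trees, support_threshold=cfg.thresholds["support"])
    pd.DataFrame([og.to_row() for og in ogs]).to_csv(
        outdir / "orthogroups.tsv", sep="\t", index=False
    )
    summary = summarize_repertoire({"all": ogs})
    (outdir / "orthogroups_summary.json").write_text(
        json.dumps(summary.to_dict(), indent=2, sort_keys=True)
    )
    return "orthogroups"


def _stage_expression(cfg: PipelineConfig, outdir: Path) -> pd.DataFrame | None:
    counts_path = cfg.inputs.get("counts_tsv")
    if counts_path is None:
        return None
    libs = cfg.inputs.get("library_sizes", {})
    table = CountTable.from_tsv(counts_path, lib_a=int(libs["a"]), lib_b=int(libs["b"]))
    frame = fold_change_table(
        table, c=cfg.thresholds["credibility"], draws=cfg.draws, seed=cfg.seed
    )
    frame.to_csv(outdir / "expression.tsv", sep="\t")
    return frame


def _stage_pseudoref(cfg: PipelineConfig, outdir: Path) -> str | None:
    ref_path = cfg.inputs.get("reference_fasta")
    vcf_path = cfg.inputs.get("variants_vcf")
    if ref_path is None or vcf_path is None:
        return None
    reference = load_reference(ref_path)
    variants = load_variants(vcf_path)
    modified, report = apply_fixed_differences(
        reference, variants,
        min_depth=cfg.thresholds["min_depth"],
        min_quality=cfg.thresholds["min_quality"],
    )
    write_reference(modified, outdir / "pseudoref.fasta")
    (outdir / "pseudoref_report.json").write_text(json.dumps(report.to_dict(), indent=2))
    return "pseudoref"


def _stage_receptivity(cfg: PipelineConfig, outdir: Path) -> str | None:
    matrix_path = cfg.inputs.get("response_matrix")
    meta_path = cfg.inputs.get("odorant_metadata")
    rpkm_path = cfg.inputs.get("receptor_rpkm")
    if matrix_path is None or meta_path is None or rpkm_path is None:
        return None
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    rpkm = pd.read_csv(rpkm_path, sep="\t", index_col=0)
    ortho_path = cfg.inputs.get("ortholog_map")
    filtered = filter_matrix(matrix, threshold=cfg.thresholds["response"])
    rpkm_1 = rpkm.iloc[:, 0]
    rpkm_2 = rpkm.iloc[:, 1]
    if ortho_path:
        omap = pd.read_csv(ortho_path, sep="\t", index_col=0).iloc[:, 0]
        rpkm_2 = map_orthologs(rpkm_2, omap)
    prof_1 = compute_receptivity(filtered, rpkm_1)
    prof_2 = compute_receptivity(filtered, rpkm_2)
    changes = receptivity_change(prof_1, prof_2, band_percent=cfg.thresholds["band_percent"])
    table = changes.join(meta, how="left")
    table.to_csv(outdir / "receptivity.tsv", sep="\t")
    tests = {
        grouping: class_enrichment(changes, meta, grouping=grouping).to_dict("records")
        for grouping in ("chemical_class", "human_associated")
        if grouping in meta.columns
    }
    (outdir / "enrichment.json").write_text(json.dumps(tests, indent=2, default=str))
    return "receptivity"


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all configured stages and write the report directory.

    Returns a manifest of the sections written. Stages whose inputs are
    absent from the config are skipped with a warning; a failing stage
    aborts with a stage-tagged error, preserving earlier outputs.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    sections: list[str] = []
    stages = [
        ("pseudoref", _stage_pseudoref),
        ("expression", _stage_expression),
        ("divergence", _stage_divergence),
        ("orthogroups", _stage_orthogroups),
        ("receptivity", _stage_receptivity),
    ]
    for name, fn in stages:
        try:
            result = fn(config, outdir)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        if result is None:
            log.warning("stage %s skipped: inputs not configured", name)
        else:
            sections.append(name)
    provenance = {
        "package_version": __version__,
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "thresholds": config.thresholds,
        "sections": sections,
    }
    (outdir / "provenance.json").write_text(json.dumps(provenance, indent=2, sort_keys=True))
    return provenance
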