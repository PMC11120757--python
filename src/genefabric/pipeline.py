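"""End-to-end pipeline: load/simulate -> characteristics -> regulation ->
pathway summaries -> coordination networks and diffs, with a run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .characteristics import (
    ALPHA,
    IND_THRESHOLD,
    SYN_THRESHOLD,
    condition_characteristics,
)
from .io import ExpressionSet, read_expression, read_sample_map
from .networks import build_network, annotate_regulation, compare_networks, network_edge_frame, write_graphml
from .pathways import read_gmt, render_markdown, summaries_frame, summarize_pathway
from .regulation import regulation_table

log = logging.getLogger("genefabric")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run (YAML-serializable)."""

    inputs: tuple[str, ...]  # expression matrices (TSV or series-matrix)
    reference: str
    fmt: str = "tsv"
    sample_map: Mapping[str, Sequence[str]] | None = None
    alpha: float = ALPHA
    syn_threshold: float = SYN_THRESHOLD
    ind_threshold: float = IND_THRESHOLD
    gene_sets: str | None = None  # GMT path
    coord_universe: str = "all"  # "all" or "sets" (restrict COORD to set members)
    outdir: str = "gfp_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        for name in ("syn_threshold", "ind_threshold"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.coord_universe not in ("all", "sets"):
            raise ValueError("coord_universe must be 'all' or 'sets'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["inputs"] = tuple(raw.get("inputs", ()))
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        d = asdict(self)
        d["inputs"] = list(d["inputs"])
        path.write_text(yaml.safe_dump(d, sort_keys=True))
        return path

    def config_hash(self) -> str:
        d = asdict(self)
        d["inputs"] = list(d["inputs"])
        return hashlib.sha256(json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(
    config: PipelineConfig,
    esets: Mapping[str, ExpressionSet] | None = None,
) -> dict[str, Path]:
    """Run the full analysis and write all outputs under ``config.outdir``.

    ``esets`` may inject already-loaded expression sets (e.g. from the
    synthetic generator); otherwise ``config.inputs`` are read. The
    reference condition must be present. Returns the paths written; a
    ``manifest.json`` records config hash, input checksums and row counts
    so reruns can be verified byte-for-byte.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if esets is None:
        if not config.inputs:
            raise ValueError("no expression inputs configured")
        sample_map = config.sample_map
        if isinstance(sample_map, (str, Path)):
            sample_map = read_sample_map(sample_map)
        esets = read_expression(list(config.inputs), config.fmt, sample_map=sample_map)
    if config.reference not in esets:
        raise ValueError(
            f"reference condition {config.reference!r} not among conditions {sorted(esets)}"
        )

    gene_sets = read_gmt(config.gene_sets) if config.gene_sets else []
    coord_universe = None
    if config.coord_universe == "sets" and gene_sets:
        coord_universe = sorted({g for s in gene_sets for g in s.members})

    thresholds = dict(
        alpha=config.alpha,
        syn_threshold=config.syn_threshold,
        ind_threshold=config.ind_threshold,
    )

    paths: dict[str, Path] = {}

    log.info("conditions: %s (reference %s), %d genes",
             sorted(esets), config.reference, len(next(iter(esets.values())).genes))

    # per-condition characteristics
    chars = {
        cond: condition_characteristics(e, coord_universe=coord_universe, **thresholds)
        for cond, e in esets.items()
    }
    chars_frame = pd.concat(chars.values()).reset_index().set_index(["gene", "condition"])
    p = outdir / "characteristics.tsv"
    chars_frame.to_csv(p, sep="\t")
    paths["characteristics"] = p

    # regulation vs reference
    ref = config.reference
    regs: dict[str, pd.DataFrame] = {}
    for cond in esets:
        if cond == ref:
            continue
        table = regulation_table(esets[cond], esets[ref], chars[cond], chars[ref], alpha=config.alpha)
        regs[cond] = table
        p = outdir / f"regulation_{cond}_vs_{ref}.tsv"
        table.to_csv(p, sep="\t")
        paths[f"regulation_{cond}"] = p
        log.info("%s vs %s: %d up, %d down of %d genes", cond, ref,
                 (table["status"] == "up").sum(), (table["status"] == "down").sum(), len(table))

    # pathway summaries
    if gene_sets:
        summaries = []
        for cond, table in regs.items():
            for s in gene_sets:
                summaries.append(summarize_pathway(s, table, condition_pair=f"{cond}_vs_{ref}"))
        frame = summaries_frame(summaries)
        p = outdir / "pathway_summaries.tsv"
        frame.to_csv(p, sep="\t", index=False)
        paths["pathway_summaries"] = p
        p = outdir / "pathway_regulated_genes.md"
        p.write_text(render_markdown(summaries))
        paths["pathway_markdown"] = p

    # coordination networks per condition per set, and diffs vs reference
    if gene_sets:
        for s in gene_sets:
            graphs = {}
            for cond, e in esets.items():
                quantified = e.data.index.intersection(pd.Index(s.members))
                if len(quantified) < 2:
                    log.warning("gene set %s: <2 quantified genes in %s; skipped", s.id, cond)
                    continue
                g = build_network(e, s.members, **thresholds)
                if cond in regs:
                    annotate_regulation(g, regs[cond]["status"])
                graphs[cond] = g
                p = outdir / f"network_{cond}_{s.id}.tsv"
                network_edge_frame(g).to_csv(p, sep="\t", index=False)
                paths[f"network_{cond}_{s.id}"] = p
                paths[f"graphml_{cond}_{s.id}"] = write_graphml(g, outdir / f"network_{cond}_{s.id}.graphml")
            if ref in graphs:
                for cond, g in graphs.items():
                    if cond == ref:
                        continue
                    diff = compare_networks(graphs[ref], g)
                    p = outdir / f"diff_{cond}_vs_{ref}_{s.id}.tsv"
                    diff.to_frame().to_csv(p, sep="\t", index=False)
                    paths[f"diff_{cond}_{s.id}"] = p
                    log.info("network %s, %s vs %s: %d gained, %d lost, %d flipped",
                             s.id, cond, ref, diff.n_gained, diff.n_lost, diff.n_flipped)

    manifest = {
        "genefabric_version": __version__,
        "config_hash": config.config_hash(),
        "inputs": {str(p): _sha256(Path(p)) for p in config.inputs if Path(p).exists()},
        "conditions": sorted(esets),
        "reference": ref,
        "n_genes": int(len(next(iter(esets.values())).genes)),
        "outputs": {k: str(v) for k, v in sorted(paths.items())},
    }
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    paths["manifest"] = mpath
    return paths
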