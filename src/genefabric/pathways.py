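"""KEGG-style gene sets and pathway-level aggregation of regulation results."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "GeneSet",
    "PathwaySummary",
    "read_gmt",
    "write_gmt",
    "summarize_pathway",
    "summaries_frame",
    "render_markdown",
]


@dataclass(frozen=True)
class GeneSet:
    """A named gene set (e.g. one KEGG pathway). Sets may overlap."""

    id: str
    label: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.id!r} has no members")


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file (id, description, then member symbols, tab separated).

    Duplicate members within a line are removed with a warning; malformed
    lines raise with their line number.
    """
    sets = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line needs id, description and >=1 member")
        sid, label, *members = parts
        members = [m for m in members if m]
        unique = list(dict.fromkeys(members))
        if len(unique) != len(members):
            warnings.warn(f"{path}:{lineno}: duplicate members in gene set {sid!r} removed")
        sets.append(GeneSet(sid, label, tuple(unique)))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> Path:
    path = Path(path)
    lines = ["\t".join((s.id, s.label) + s.members) for s in sets]
    path.write_text("\n".join(lines) + "\n")
    return path


@dataclass
class PathwaySummary:
    """Regulation of one gene set in one condition-vs-reference comparison.

    Percentages use the quantified members (those present in the regulation
    table) as denominator; means are over quantified members.
    """

    pathway_id: str
    label: str
    condition_pair: str
    n_members: int
    n_quantified: int
    percent_up: float
    percent_down: float
    mean_wir: float
    mean_drec: float
    mean_dcoord: float
    mean_td: float
    up_genes: tuple[str, ...]
    down_genes: tuple[str, ...]
    unquantified: tuple[str, ...]


def summarize_pathway(
    gene_set: GeneSet,
    records: pd.DataFrame,
    condition_pair: str = "",
) -> PathwaySummary:
    """Aggregate a per-gene regulation table over one gene set.

    ``records`` is the frame produced by
    :func:`genefabric.regulation.regulation_table` (indexed by gene, with
    columns ``status``, ``WIR``, ``dREC``, ``dCOORD``, ``TD``). Members
    absent from the table are reported as unquantified.
    """
    members = pd.Index(gene_set.members)
    quantified = members.intersection(records.index)
    unquantified = tuple(sorted(members.difference(records.index)))
    if len(quantified) == 0:
        warnings.warn(f"gene set {gene_set.id!r} has no quantified members")
        return PathwaySummary(
            gene_set.id, gene_set.label, condition_pair, len(members), 0,
            float("nan"), float("nan"), float("nan"), float("nan"), float("nan"),
            float("nan"), (), (), unquantified,
        )
    sub = records.loc[quantified]
    up = tuple(sorted(sub.index[sub["status"] == "up"]))
    down = tuple(sorted(sub.index[sub["status"] == "down"]))
    n = len(quantified)
    return PathwaySummary(
        pathway_id=gene_set.id,
        label=gene_set.label,
        condition_pair=condition_pair,
        n_members=len(members),
        n_quantified=n,
        percent_up=100.0 * len(up) / n,
        percent_down=100.0 * len(down) / n,
        mean_wir=float(sub["WIR"].mean()),
        mean_drec=float(sub["dREC"].mean()),
        mean_dcoord=float(sub["dCOORD"].mean()),
        mean_td=float(sub["TD"].mean()),
        up_genes=up,
        down_genes=down,
        unquantified=unquantified,
    )


def summaries_frame(summaries: Sequence[PathwaySummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        rows.append(
            {
                "pathway": s.pathway_id,
                "label": s.label,
                "condition_pair": s.condition_pair,
                "n_members": s.n_members,
                "n_quantified": s.n_quantified,
                "percent_up": s.percent_up,
                "percent_down": s.percent_down,
                "mean_WIR": s.mean_wir,
                "mean_dREC": s.mean_drec,
                "mean_dCOORD": s.mean_dcoord,
                "mean_TD": s.mean_td,
                "up_genes": ",".join(s.up_genes),
                "down_genes": ",".join(s.down_genes),
            }
        )
    return pd.DataFrame(rows)


def render_markdown(summaries: Sequence[PathwaySummary]) -> str:
    """Table of up/down gene lists per pathway; up-regulated genes in bold."""
    lines = ["| Pathway | Regulated genes (bold = up) |", "|---|---|"]
    for s in summaries:
        genes = [f"**{g}**" for g in s.up_genes] + [f"*{g}*" for g in s.down_genes]
        lines.append(f"| {s.label} ({s.pathway_id}) | {', '.join(genes) or '—'} |")
    return "\n".join(lines) + "\n"
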