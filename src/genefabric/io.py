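"""Reading, filtering and summarising replicated expression tables.

Two levels of data are handled:

* spot level — two-channel-microarray-like tables with per-spot foreground
  and background intensities, possibly several spots (redundant probes) per
  gene;
* gene level — normalized genes x replicas matrices (:class:`ExpressionSet`),
  the input of every downstream statistic.

The processing order is: validity filter (foreground at least twice the
background on every array), per-array median normalization at the spot
level, probe-to-gene averaging, and a final per-array median normalization
at the gene level so that expression is measured in units of the median
gene of the condition.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SpotTable",
    "ExpressionSet",
    "FilterResult",
    "filter_spots",
    "normalize_to_median",
    "normalize_spot_table",
    "summarize_probes",
    "spots_to_expression",
    "read_expression",
    "write_expression",
    "read_sample_map",
]

#: factor by which foreground must exceed background for a spot to be valid
VALIDITY_FACTOR = 2.0


@dataclass
class SpotTable:
    """Spot-level intensities for one condition.

    ``foreground`` and ``background`` are indexed by spot id and share the
    replica columns (named ``<condition>_<k>``); ``genes`` maps each spot id
    to at most one gene symbol.
    """

    condition: str
    genes: pd.Series
    foreground: pd.DataFrame
    background: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.foreground.index.equals(self.background.index):
            raise ValueError("foreground and background must share spot ids")
        if list(self.foreground.columns) != list(self.background.columns):
            raise ValueError("foreground and background must share arrays")
        if not self.genes.index.equals(self.foreground.index):
            raise ValueError("gene map must cover exactly the spot ids")

    @property
    def arrays(self) -> list[str]:
        return list(self.foreground.columns)

    @property
    def n_spots(self) -> int:
        return len(self.foreground)


@dataclass
class ExpressionSet:
    """Normalized genes x replicas matrix for one condition.

    ``data`` rows are adequately quantified genes, columns biological
    replicas; values are in units of the condition's median gene (the
    per-replica median over genes equals 1 after normalization).
    ``probe_counts`` records how many surviving spots were averaged per gene.
    """

    condition: str
    data: pd.DataFrame
    probe_counts: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.probe_counts is None:
            self.probe_counts = pd.Series(1, index=self.data.index)
        if self.data.isna().any().any():
            raise ValueError(f"expression matrix for {self.condition!r} has missing values")

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    @property
    def n_replicas(self) -> int:
        return self.data.shape[1]

    def restrict(self, genes: Iterable[str]) -> "ExpressionSet":
        idx = self.data.index.intersection(pd.Index(genes))
        return ExpressionSet(self.condition, self.data.loc[idx], self.probe_counts.loc[idx])


@dataclass
class FilterResult:
    tables: list[SpotTable]
    removal_log: pd.DataFrame  # columns: spot, gene, array, foreground, background

    @property
    def n_removed(self) -> int:
        return self.removal_log["spot"].nunique()


def _check_complete(table: SpotTable) -> None:
    for frame, kind in ((table.foreground, "foreground"), (table.background, "background")):
        if frame.isna().any().any():
            bad = frame.isna().stack()
            spot, array = bad[bad].index[0]
            raise ValueError(f"missing {kind} intensity for spot {spot!r} on array {array!r}")


def filter_spots(
    tables: Sequence[SpotTable] | SpotTable,
    *,
    joint: bool = True,
    factor: float = VALIDITY_FACTOR,
) -> FilterResult:
    """Remove spots with foreground below ``factor`` x background on any array.

    A failing spot is eliminated from *all* arrays of *all* conditions when
    ``joint`` is true (the default: one disqualifying array removes the spot
    experiment-wide); with ``joint=False`` each condition is filtered against
    its own arrays only. Returns the surviving tables plus a removal log with
    one row per offending (spot, array) cell.
    """
    if isinstance(tables, SpotTable):
        tables = [tables]
    tables = list(tables)
    for t in tables:
        _check_complete(t)

    log_rows = []
    bad_by_table: list[set] = []
    for t in tables:
        invalid = t.foreground < factor * t.background
        cells = invalid.stack()
        cells = cells[cells]
        for (spot, array) in cells.index:
            log_rows.append(
                {
                    "spot": spot,
                    "gene": t.genes.loc[spot],
                    "array": array,
                    "foreground": t.foreground.at[spot, array],
                    "background": t.background.at[spot, array],
                }
            )
        bad_by_table.append(set(invalid.index[invalid.any(axis=1)]))

    out = []
    if joint:
        bad_all = set().union(*bad_by_table) if bad_by_table else set()
        per_table = [bad_all] * len(tables)
    else:
        per_table = bad_by_table
    for t, bad in zip(tables, per_table):
        keep = t.foreground.index[~t.foreground.index.isin(bad)]
        out.append(
            SpotTable(t.condition, t.genes.loc[keep], t.foreground.loc[keep], t.background.loc[keep])
        )
    log = pd.DataFrame(log_rows, columns=["spot", "gene", "array", "foreground", "background"])
    return FilterResult(out, log)


def normalize_to_median(values: np.ndarray | pd.Series) -> np.ndarray | pd.Series:
    """Divide one array's valid values by their median (median becomes 1)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot normalize an empty array")
    if np.any(arr <= 0):
        raise ValueError("normalization requires strictly positive values")
    out = values / np.median(arr)
    return out


def normalize_spot_table(table: SpotTable) -> SpotTable:
    """Normalize each array's foreground to the median over its valid spots."""
    fg = table.foreground.apply(normalize_to_median, axis=0)
    return replace(table, foreground=fg)


def summarize_probes(table: SpotTable, *, renormalize: bool = True) -> ExpressionSet:
    """Collapse redundant probes to genes by the arithmetic mean.

    Spots without a gene symbol are dropped. With ``renormalize`` (default)
    the gene-level matrix is re-normalized per replica to the median gene,
    which defines the expression unit used by all downstream statistics.
    """
    keep = table.genes.notna()
    fg = table.foreground.loc[keep]
    genes = table.genes.loc[keep]
    grouped = fg.groupby(genes)
    data = grouped.mean()
    counts = grouped.size()
    if renormalize:
        data = data.apply(normalize_to_median, axis=0)
    return ExpressionSet(table.condition, data, counts)


def spots_to_expression(
    tables: Sequence[SpotTable],
    *,
    joint: bool = True,
) -> tuple[dict[str, ExpressionSet], FilterResult]:
    """Full spot pipeline: filter, per-array normalize, collapse probes.

    Genes are restricted to those quantified in every condition, so all
    downstream between-condition comparisons share one gene universe.
    """
    result = filter_spots(tables, joint=joint)
    esets = {}
    for t in result.tables:
        eset = summarize_probes(normalize_spot_table(t))
        esets[t.condition] = eset
    common = intersect_genes(esets.values())
    esets = {c: e.restrict(common) for c, e in esets.items()}
    return esets, result


def intersect_genes(esets: Iterable[ExpressionSet]) -> pd.Index:
    esets = list(esets)
    common = esets[0].genes
    for e in esets[1:]:
        common = common.intersection(e.genes)
    return common


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------

def read_sample_map(path: str | Path) -> dict[str, list[str]]:
    """Read a YAML mapping ``{condition: [sample/column ids]}``."""
    with open(path) as fh:
        mapping = yaml.safe_load(fh)
    if not isinstance(mapping, dict) or not mapping:
        raise ValueError(f"sample map {path} must be a non-empty mapping")
    return {str(k): [str(v) for v in vals] for k, vals in mapping.items()}


def _split_condition_columns(columns: Sequence[str]) -> dict[str, list[str]]:
    """Group ``<cond>_<k>`` replica columns by condition prefix."""
    groups: dict[str, list[str]] = {}
    for col in columns:
        cond, _, rep = str(col).rpartition("_")
        if not cond or not rep.isdigit():
            raise ValueError(
                f"column {col!r} does not follow the <condition>_<replica> convention; "
                "provide a sample map instead"
            )
        groups.setdefault(cond, []).append(col)
    return groups


def _read_series_matrix_table(path: str | Path) -> pd.DataFrame:
    """Parse the data table of a GEO series-matrix text file."""
    lines = Path(path).read_text().splitlines()
    try:
        start = next(i for i, l in enumerate(lines) if l.startswith("!series_matrix_table_begin"))
        end = next(i for i, l in enumerate(lines) if l.startswith("!series_matrix_table_end"))
    except StopIteration:
        raise ValueError(f"{path} is not a series-matrix file (table markers missing)") from None
    rows = [l.split("\t") for l in lines[start + 1 : end] if l]
    header = [c.strip('"') for c in rows[0]]
    body = [[c.strip('"') for c in r] for r in rows[1:]]
    df = pd.DataFrame(body, columns=header).set_index(header[0])
    return df.apply(pd.to_numeric, errors="coerce")


def read_expression(
    paths: str | Path | Sequence[str | Path],
    fmt: str = "tsv",
    *,
    sample_map: Mapping[str, Sequence[str]] | str | Path | None = None,
    gene_symbols: Mapping[str, str] | pd.Series | None = None,
    min_replicas: int = 3,
) -> dict[str, ExpressionSet]:
    """Load gene-level expression matrices as one :class:`ExpressionSet` per condition.

    ``fmt`` is ``"tsv"`` (genes in rows, replica columns) or
    ``"geo-series-matrix"``. Condition/replica assignment comes from
    ``sample_map`` (``{condition: [column or GSM ids]}``, or a YAML path);
    for TSV input it may be omitted when columns follow the
    ``<condition>_<replica>`` convention. ``gene_symbols`` optionally maps
    probe ids to gene symbols, with redundant probes averaged. Genes are
    restricted to the intersection across conditions and rows with missing
    values are dropped.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    if isinstance(sample_map, (str, Path)):
        sample_map = read_sample_map(sample_map)

    if fmt == "tsv":
        frames = [pd.read_csv(p, sep="\t", index_col=0) for p in paths]
    elif fmt == "geo-series-matrix":
        frames = [_read_series_matrix_table(p) for p in paths]
        if sample_map is None:
            raise ValueError("series-matrix input requires a sample map of GSM ids")
    else:
        raise ValueError(f"unknown expression format {fmt!r}")

    wide = pd.concat(frames, axis=1)
    if sample_map is None:
        sample_map = _split_condition_columns(wide.columns)
    for cond, cols in sample_map.items():
        missing = [c for c in cols if c not in wide.columns]
        if missing:
            raise ValueError(f"sample map for condition {cond!r} references missing samples {missing}")
        if len(cols) < min_replicas:
            raise ValueError(
                f"condition {cond!r} has {len(cols)} replicas; at least {min_replicas} required"
            )

    esets: dict[str, ExpressionSet] = {}
    for cond, cols in sample_map.items():
        data = wide[list(cols)].dropna()
        data.columns = [f"{cond}_{k + 1}" for k in range(len(cols))]
        if gene_symbols is not None:
            sym = pd.Series(gene_symbols).reindex(data.index)
            data = data.groupby(sym).mean()
        esets[cond] = ExpressionSet(cond, data)

    common = intersect_genes(esets.values())
    return {c: e.restrict(common) for c, e in esets.items()}


def write_expression(esets: Mapping[str, ExpressionSet], path: str | Path) -> Path:
    """Write all conditions side by side as one TSV with ``<cond>_<k>`` columns."""
    path = Path(path)
    wide = pd.concat([e.data for e in esets.values()], axis=1)
    wide.index.name = "gene"
    wide.to_csv(path, sep="\t")
    return path
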