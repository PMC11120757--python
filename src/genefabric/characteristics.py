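"""Per-gene transcriptome characteristics within one condition.

Three independent primary characteristics describe each gene:

* **AVE** — mean normalized expression across biological replicas, in units
  of the condition's median gene;
* **REV** (Relative Expression Variation, %) — the chi-square mid-interval
  corrected coefficient of variation across replicas,

  ``REV = 100 * (s/m) * 1/2 * [sqrt((r-1)/chi2_{0.975,r-1})
                               + sqrt((r-1)/chi2_{0.025,r-1})]``,

  where ``s/m`` is the sample CV and ``chi2_q`` the q-quantile of the
  chi-square distribution with r-1 degrees of freedom. Low REV = tight
  homeostatic control of transcript abundance;
* **COR** — Pearson correlation of two genes' replica profiles, with the
  two-tailed p-value from the t-transform on r-2 degrees of freedom.

Two derived characteristics follow: **REC** (Relative Expression Control, %)
compares a gene's REV to the condition-wide median REV, and **COORD**
(Coordination Degree, %) is the fraction of the gene universe significantly
coordinated (synergistically or antagonistically) with the gene.

Significance classes for a pair: *synergistic* (COR above the positive
threshold, p < alpha), *antagonistic* (below the negative threshold,
p < alpha), *independent* (|COR| inside the independence band), otherwise
*unclassified*. With 4 replicas the 0.950 threshold and the p < 0.05
criterion coincide to three decimals.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionSet

__all__ = [
    "SYNERGISTIC",
    "ANTAGONISTIC",
    "INDEPENDENT",
    "UNCLASSIFIED",
    "PairCorrelation",
    "compute_ave",
    "compute_rev",
    "rev_correction_factor",
    "compute_cor",
    "correlation_matrix",
    "correlation_pvalues",
    "classify_correlations",
    "pair_correlations",
    "significant_partners",
    "coordination_counts",
    "compute_rec",
    "compute_coord",
    "condition_characteristics",
    "critical_correlation",
    "characteristic_count",
]

SYNERGISTIC = "synergistic"
ANTAGONISTIC = "antagonistic"
INDEPENDENT = "independent"
UNCLASSIFIED = "unclassified"

#: printed significance thresholds for 4-replica designs
SYN_THRESHOLD = 0.950
IND_THRESHOLD = 0.050
ALPHA = 0.05


# ---------------------------------------------------------------------------
# AVE / REV
# ---------------------------------------------------------------------------


def compute_ave(values: np.ndarray | pd.Series | pd.DataFrame) -> float | pd.Series:
    """Arithmetic mean of the normalized replica values (rows of a frame)."""
    if isinstance(values, pd.DataFrame):
        return values.mean(axis=1)
    arr = np.asarray(values, dtype=float)
    return float(arr.mean())


@lru_cache(maxsize=None)
def rev_correction_factor(n_replicas: int, *, coverage: float = 0.95) -> float:
    """Mid-point of the chi-square interval correction for the CV at small r.

    Equals ``1/2 * [sqrt((r-1)/chi2_{1-a/2}) + sqrt((r-1)/chi2_{a/2})]`` with
    ``a = 1 - coverage``; ~2.1475 for r = 4.
    """
    if n_replicas < 3:
        raise ValueError("REV needs at least 3 replicas (2 degrees of freedom)")
    df = n_replicas - 1
    a = 1.0 - coverage
    hi = stats.chi2.ppf(1 - a / 2, df)
    lo = stats.chi2.ppf(a / 2, df)
    return 0.5 * (np.sqrt(df / hi) + np.sqrt(df / lo))


def compute_rev(values: np.ndarray | pd.Series | pd.DataFrame) -> float | pd.Series:
    """Relative Expression Variation in percent (rows of a frame, or one vector)."""
    if isinstance(values, pd.DataFrame):
        n = values.shape[1]
        mean = values.mean(axis=1)
        if (mean == 0).any():
            raise ValueError("REV undefined for zero-mean expression")
        cv = values.std(axis=1, ddof=1) / mean
        return 100.0 * rev_correction_factor(n) * cv
    arr = np.asarray(values, dtype=float)
    if arr.mean() == 0:
        raise ValueError("REV undefined for zero-mean expression")
    cv = arr.std(ddof=1) / arr.mean()
    return float(100.0 * rev_correction_factor(arr.size) * cv)


# ---------------------------------------------------------------------------
# COR
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PairCorrelation:
    gene_i: str
    gene_j: str
    cor: float
    p: float
    classification: str


def _t_pvalue(r: np.ndarray, n: int) -> np.ndarray:
    """Two-tailed p-value of a Pearson correlation via the t-transform (df = n-2)."""
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(r) * np.sqrt(df / (1.0 - r * r))
    p = 2.0 * stats.t.sf(t, df)
    return np.where(np.abs(r) >= 1.0, 0.0, p)


def critical_correlation(n_replicas: int, alpha: float = ALPHA) -> float:
    """Two-tailed critical |Pearson r| at level ``alpha`` for n paired replicas."""
    df = n_replicas - 2
    if df < 1:
        raise ValueError("need at least 3 replicas")
    t = stats.t.ppf(1 - alpha / 2, df)
    return float(t / np.sqrt(df + t * t))


def _classify(cor: np.ndarray, p: np.ndarray, alpha: float, syn: float, ind: float) -> np.ndarray:
    out = np.full(cor.shape, UNCLASSIFIED, dtype=object)
    sig = p < alpha
    out[(cor > syn) & sig] = SYNERGISTIC
    out[(cor < -syn) & sig] = ANTAGONISTIC
    out[np.abs(cor) < ind] = INDEPENDENT
    out[np.isnan(cor)] = UNCLASSIFIED
    return out


def compute_cor(
    values_i: np.ndarray | pd.Series,
    values_j: np.ndarray | pd.Series,
    *,
    alpha: float = ALPHA,
    syn_threshold: float = SYN_THRESHOLD,
    ind_threshold: float = IND_THRESHOLD,
    gene_i: str = "i",
    gene_j: str = "j",
) -> PairCorrelation:
    """Expression coordination of two genes across paired replicas."""
    a = np.asarray(values_i, dtype=float)
    b = np.asarray(values_j, dtype=float)
    if a.size != b.size or a.size < 3:
        raise ValueError("paired replica vectors of equal length >= 3 required")
    if a.std(ddof=1) == 0 or b.std(ddof=1) == 0:
        return PairCorrelation(gene_i, gene_j, float("nan"), float("nan"), UNCLASSIFIED)
    r = float(np.corrcoef(a, b)[0, 1])
    p = float(_t_pvalue(np.array(r), a.size))
    cls = str(_classify(np.array(r), np.array(p), alpha, syn_threshold, ind_threshold))
    return PairCorrelation(gene_i, gene_j, r, p, cls)


def _standardize_rows(data: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Rows centered and scaled to unit norm; zero-variance rows flagged."""
    x = data.to_numpy(dtype=float)
    x = x - x.mean(axis=1, keepdims=True)
    norm = np.sqrt((x * x).sum(axis=1))
    degenerate = norm == 0
    norm[degenerate] = 1.0
    return x / norm[:, None], degenerate


def correlation_matrix(data: pd.DataFrame) -> pd.DataFrame:
    """All pairwise Pearson correlations across replicas (genes x genes).

    Zero-variance genes yield NaN rows/columns (coordination undefined).
    """
    z, degenerate = _standardize_rows(data)
    cor = np.clip(z @ z.T, -1.0, 1.0)
    cor[degenerate, :] = np.nan
    cor[:, degenerate] = np.nan
    np.fill_diagonal(cor, 1.0)
    cor[np.ix_(degenerate, degenerate)] = np.nan
    return pd.DataFrame(cor, index=data.index, columns=data.index)


def correlation_pvalues(cor: pd.DataFrame, n_replicas: int) -> pd.DataFrame:
    return pd.DataFrame(_t_pvalue(cor.to_numpy(), n_replicas), index=cor.index, columns=cor.columns)


def classify_correlations(
    cor: pd.DataFrame,
    n_replicas: int,
    *,
    alpha: float = ALPHA,
    syn_threshold: float = SYN_THRESHOLD,
    ind_threshold: float = IND_THRESHOLD,
) -> pd.DataFrame:
    p = _t_pvalue(cor.to_numpy(), n_replicas)
    cls = _classify(cor.to_numpy(), p, alpha, syn_threshold, ind_threshold)
    return pd.DataFrame(cls, index=cor.index, columns=cor.columns)


def pair_correlations(
    data: pd.DataFrame,
    *,
    alpha: float = ALPHA,
    syn_threshold: float = SYN_THRESHOLD,
    ind_threshold: float = IND_THRESHOLD,
    classified_only: bool = False,
) -> pd.DataFrame:
    """Tidy edge list of the distinct gene pairs (i < j in index order).

    Columns: ``gene_i, gene_j, COR, p, class``. Degenerate (zero-variance)
    pairs are excluded. With ``classified_only`` only synergistic,
    antagonistic or independent pairs are kept.
    """
    cor = correlation_matrix(data)
    n = data.shape[1]
    genes = data.index.to_numpy()
    iu = np.triu_indices(len(genes), k=1)
    r = cor.to_numpy()[iu]
    p = _t_pvalue(r, n)
    cls = _classify(r, p, alpha, syn_threshold, ind_threshold)
    frame = pd.DataFrame(
        {"gene_i": genes[iu[0]], "gene_j": genes[iu[1]], "COR": r, "p": p, "class": cls}
    )
    frame = frame[~np.isnan(r)]
    if classified_only:
        frame = frame[frame["class"] != UNCLASSIFIED]
    return frame.reset_index(drop=True)


def significant_partners(
    gene: str,
    data: pd.DataFrame,
    *,
    alpha: float = ALPHA,
    syn_threshold: float = SYN_THRESHOLD,
    ind_threshold: float = IND_THRESHOLD,
) -> tuple[int, int]:
    """Counts of (synergistic, antagonistic) partners of ``gene`` in the set."""
    if gene not in data.index:
        raise KeyError(f"gene {gene!r} is not in the gene set")
    cor = correlation_matrix(data)
    cls = classify_correlations(
        cor, data.shape[1], alpha=alpha, syn_threshold=syn_threshold, ind_threshold=ind_threshold
    )
    row = cls.loc[gene].drop(gene)
    return int((row == SYNERGISTIC).sum()), int((row == ANTAGONISTIC).sum())


def coordination_counts(
    data: pd.DataFrame,
    *,
    alpha: float = ALPHA,
    syn_threshold: float = SYN_THRESHOLD,
    ind_threshold: float = IND_THRESHOLD,
    block_size: int = 512,
) -> pd.DataFrame:
    """Per-gene counts of synergistic/antagonistic/independent partners.

    Computed blockwise so the dense gene x gene correlation matrix is never
    materialized for large universes.
    """
    z, degenerate = _standardize_rows(data)
    n = data.shape[1]
    g = len(data)
    counts = np.zeros((g, 3), dtype=int)
    for start in range(0, g, block_size):
        stop = min(start + block_size, g)
        block = np.clip(z[start:stop] @ z.T, -1.0, 1.0)
        p = _t_pvalue(block, n)
        sig = p < alpha
        syn = (block > syn_threshold) & sig
        ant = (block < -syn_threshold) & sig
        ind = np.abs(block) < ind_threshold
        rows = np.arange(start, stop)
        # mask self-pairs and degenerate partners
        for m in (syn, ant, ind):
            m[:, degenerate] = False
            m[np.arange(stop - start), rows] = False
        if degenerate.any():
            syn[degenerate[start:stop], :] = False
            ant[degenerate[start:stop], :] = False
            ind[degenerate[start:stop], :] = False
        counts[start:stop, 0] = syn.sum(axis=1)
        counts[start:stop, 1] = ant.sum(axis=1)
        counts[start:stop, 2] = ind.sum(axis=1)
    return pd.DataFrame(counts, index=data.index, columns=["n_syn", "n_ant", "n_ind"])


# ---------------------------------------------------------------------------
# REC / COORD
# ---------------------------------------------------------------------------


def compute_rec(rev: float | pd.Series, reference_median: float | None = None) -> float | pd.Series:
    """Relative Expression Control in percent.

    ``REC = 100 * (median REV over all quantified genes / REV_gene - 1)``;
    positive REC = stricter-than-typical homeostatic control. With a Series
    argument the condition-wide median is taken over the Series itself
    unless ``reference_median`` is given. Zero REV yields NaN (flagged
    undefined rather than infinite control).
    """
    if isinstance(rev, pd.Series):
        med = float(rev.median()) if reference_median is None else float(reference_median)
        if med <= 0:
            raise ValueError("condition-wide median REV must be positive")
        with np.errstate(divide="ignore"):
            out = 100.0 * (med / rev - 1.0)
        return out.replace([np.inf, -np.inf], np.nan)
    if reference_median is None:
        raise ValueError("scalar REC needs the condition-wide median REV")
    if rev == 0:
        return float("nan")
    return float(100.0 * (reference_median / rev - 1.0))


def compute_coord(n_significant: int | pd.Series, universe_size: int) -> float | pd.Series:
    """Coordination Degree: percent of the universe significantly coordinated."""
    if universe_size < 2:
        raise ValueError("COORD needs a universe of at least 2 genes")
    return 100.0 * n_significant / (universe_size - 1)


def condition_characteristics(
    eset: ExpressionSet,
    *,
    coord_universe: Sequence[str] | None = None,
    alpha: float = ALPHA,
    syn_threshold: float = SYN_THRESHOLD,
    ind_threshold: float = IND_THRESHOLD,
    block_size: int = 512,
) -> pd.DataFrame:
    """AVE, REV, REC and COORD for every gene of one condition.

    ``coord_universe`` restricts the COORD partner universe (e.g. to one
    pathway); by default the whole quantified transcriptome is used. REC is
    always referenced to the condition-wide median REV of all quantified
    genes.
    """
    data = eset.data
    ave = compute_ave(data)
    rev = compute_rev(data)
    rec = compute_rec(rev)
    universe = data if coord_universe is None else data.loc[data.index.intersection(pd.Index(coord_universe))]
    counts = coordination_counts(
        universe,
        alpha=alpha,
        syn_threshold=syn_threshold,
        ind_threshold=ind_threshold,
        block_size=block_size,
    )
    coord = compute_coord(counts["n_syn"] + counts["n_ant"], len(universe))
    frame = pd.DataFrame(
        {
            "condition": eset.condition,
            "AVE": ave,
            "REV": rev,
            "REC": rec,
            "COORD": coord.reindex(data.index),
        }
    )
    frame.index.name = "gene"
    return frame


def characteristic_count(n_genes: int) -> tuple[int, float]:
    """Total characteristics (AVEs + REVs + distinct CORs) and ratio to n_genes.

    ``total = 2G + G(G-1)/2``; the ratio measures the information gain over
    an analysis limited to the G average expression levels.
    """
    total = 2 * n_genes + n_genes * (n_genes - 1) // 2
    return total, total / n_genes
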