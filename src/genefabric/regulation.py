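"""Condition-versus-reference regulation calling and alteration measures.

For each gene the comparison against the reference condition produces:

* ``x`` — signed expression ratio (``AVE_cond/AVE_ref`` if >= 1, else
  ``-AVE_ref/AVE_cond``; negative = down-regulation, |x| >= 1 always);
* ``p`` — two-tailed Welch (heteroscedastic) t-test p-value on the
  normalized replica values;
* ``CUT`` — the gene-specific absolute fold-change cut-off combining the
  replicate variability of both conditions,
  ``CUT = 1 + sqrt((REV_ref/100)^2 + (REV_cond/100)^2)``, replacing fixed
  1.5x/2x thresholds: stably expressed genes get a stricter cut-off,
  noisy genes a laxer one;
* ``status`` — up if ``x > CUT`` and ``p < alpha``, down if ``x < -CUT``
  and ``p < alpha``, otherwise not-regulated;
* ``WIR`` — Weighted Individual Regulation,
  ``WIR = AVE_ref * (|x| - 1) * sign(x) * (1 - p)``: the gene's signed
  contribution to the transcriptomic alteration, in median-gene expression
  units, scaling the net expression change by statistical confidence;
* ``dREC`` / ``dCOORD`` — change of expression control and coordination
  degree (condition minus reference, percent);
* ``TD`` — Transcriptomic Distance, the Euclidean length of the
  ``(WIR, dREC, dCOORD)`` vector.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionSet

__all__ = [
    "UP",
    "DOWN",
    "NOT_REGULATED",
    "expression_ratio",
    "regulation_pvalue",
    "compute_cut",
    "classify_regulation",
    "compute_wir",
    "delta_rec",
    "delta_coord",
    "transcriptomic_distance",
    "regulation_table",
]

UP = "up"
DOWN = "down"
NOT_REGULATED = "not-regulated"
ALPHA = 0.05


def expression_ratio(ave_cond, ave_ref):
    """Signed fold change: >= 1 for up-, <= -1 for down-regulation."""
    a = np.asarray(ave_cond, dtype=float)
    b = np.asarray(ave_ref, dtype=float)
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("expression ratio needs positive AVEs")
    ratio = a / b
    x = np.where(ratio >= 1.0, ratio, -1.0 / ratio)
    if isinstance(ave_cond, pd.Series):
        return pd.Series(x, index=ave_cond.index, name="x")
    return float(x) if x.ndim == 0 else x


def regulation_pvalue(replicas_cond, replicas_ref):
    """Two-tailed Welch t-test p-value of means equality.

    Accepts 1-D vectors or aligned frames (genes in rows). Degenerate
    zero-variance cases: equal means give p = 1, different means p = 0.
    """
    a = np.atleast_2d(np.asarray(replicas_cond, dtype=float))
    b = np.atleast_2d(np.asarray(replicas_ref, dtype=float))
    if a.shape[1] < 3 or b.shape[1] < 3:
        raise ValueError("at least 3 replicas per condition are required")
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # near-constant replica vectors trigger a precision warning from the
        # t statistic; the degenerate cases are resolved explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        p = stats.ttest_ind(a, b, axis=1, equal_var=False).pvalue
    p = np.asarray(p, dtype=float)
    degenerate = (a.std(axis=1, ddof=1) == 0) & (b.std(axis=1, ddof=1) == 0)
    equal = np.isclose(a.mean(axis=1), b.mean(axis=1))
    p[degenerate & equal] = 1.0
    p[degenerate & ~equal] = 0.0
    if isinstance(replicas_cond, pd.DataFrame):
        return pd.Series(p, index=replicas_cond.index, name="p")
    return float(p[0]) if p.size == 1 else p


def compute_cut(rev_ref, rev_cond):
    """Gene-specific absolute fold-change cut-off (> 1 whenever REV > 0)."""
    a = np.asarray(rev_ref, dtype=float) / 100.0
    b = np.asarray(rev_cond, dtype=float) / 100.0
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("REV values must be non-negative percentages")
    cut = 1.0 + np.sqrt(a * a + b * b)
    if isinstance(rev_ref, pd.Series):
        return pd.Series(cut, index=rev_ref.index, name="CUT")
    return float(cut) if cut.ndim == 0 else cut


def classify_regulation(x, p, cut, alpha: float = ALPHA):
    """up / down / not-regulated from the signed ratio, p-value and cut-off."""
    xv = np.asarray(x, dtype=float)
    pv = np.asarray(p, dtype=float)
    cv = np.asarray(cut, dtype=float)
    status = np.full(np.broadcast(xv, pv, cv).shape, NOT_REGULATED, dtype=object)
    sig = pv < alpha
    status[(xv > cv) & sig] = UP
    status[(xv < -cv) & sig] = DOWN
    if isinstance(x, pd.Series):
        return pd.Series(status, index=x.index, name="status")
    return str(status) if status.ndim == 0 else status


def compute_wir(ave_ref, x, p):
    """Weighted Individual Regulation in median-gene expression units."""
    a = np.asarray(ave_ref, dtype=float)
    xv = np.asarray(x, dtype=float)
    pv = np.asarray(p, dtype=float)
    if np.any(np.abs(xv) < 1):
        raise ValueError("signed expression ratio must satisfy |x| >= 1")
    wir = a * (np.abs(xv) - 1.0) * np.sign(xv) * (1.0 - pv)
    if isinstance(ave_ref, pd.Series):
        return pd.Series(wir, index=ave_ref.index, name="WIR")
    return float(wir) if wir.ndim == 0 else wir


def _aligned_difference(cond, ref, name):
    if isinstance(cond, pd.Series) and isinstance(ref, pd.Series):
        if not cond.index.equals(ref.index):
            raise ValueError(f"{name}: condition and reference gene universes differ")
        return (cond - ref).rename(name)
    return np.asarray(cond, dtype=float) - np.asarray(ref, dtype=float)


def delta_rec(rec_cond, rec_ref):
    """Change of Relative Expression Control (condition minus reference, %)."""
    return _aligned_difference(rec_cond, rec_ref, "dREC")


def delta_coord(coord_cond, coord_ref):
    """Change of Coordination Degree (condition minus reference, %)."""
    return _aligned_difference(coord_cond, coord_ref, "dCOORD")


def transcriptomic_distance(wir, drec, dcoord):
    """Euclidean distance in the (WIR, dREC, dCOORD) alteration space.

    The most comprehensive single-gene measure of transcriptomic change:
    it is zero only when expression level, control and coordination are all
    unchanged.
    """
    w = np.asarray(wir, dtype=float)
    r = np.asarray(drec, dtype=float)
    c = np.asarray(dcoord, dtype=float)
    td = np.sqrt(w * w + r * r + c * c)
    if isinstance(wir, pd.Series):
        return pd.Series(td, index=wir.index, name="TD")
    return float(td) if td.ndim == 0 else td


def regulation_table(
    eset_cond: ExpressionSet,
    eset_ref: ExpressionSet,
    chars_cond: pd.DataFrame,
    chars_ref: pd.DataFrame,
    *,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Full per-gene regulation record for one condition-vs-reference pair.

    ``chars_*`` are the frames from
    :func:`genefabric.characteristics.condition_characteristics` (they
    supply AVE, REV, REC and COORD); both conditions must cover the same
    gene universe. Returns a frame indexed by gene with columns
    ``x, p, CUT, status, WIR, dREC, dCOORD, TD``.
    """
    if not eset_cond.genes.equals(eset_ref.genes):
        raise ValueError("condition and reference expression sets cover different genes")
    genes = eset_cond.genes
    cc = chars_cond.loc[genes]
    cr = chars_ref.loc[genes]
    x = expression_ratio(cc["AVE"], cr["AVE"])
    p = regulation_pvalue(eset_cond.data, eset_ref.data)
    cut = compute_cut(cr["REV"], cc["REV"])
    status = classify_regulation(x, p, cut, alpha=alpha)
    wir = compute_wir(cr["AVE"], x, p)
    drec = delta_rec(cc["REC"], cr["REC"])
    dcoord = delta_coord(cc["COORD"], cr["COORD"])
    td = transcriptomic_distance(wir, drec, dcoord)
    frame = pd.DataFrame(
        {
            "x": x,
            "p": p,
            "CUT": cut,
            "status": status,
            "WIR": wir,
            "dREC": drec,
            "dCOORD": dcoord,
            "TD": td,
        }
    )
    frame.index.name = "gene"
    return frame
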