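"""qPCR relative quantification and expression correlation.

Covers three steps: 2^-ddCt relative expression against a reference gene
and a calibrator sample; row scaling (z-scores) for heatmap export; and
an all-pairs correlation screen between a transcription-factor panel and
a target-gene panel, reporting signed significant edges.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .records import ExpressionTable

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class CorrelationEdge:
    gene_a: str
    gene_b: str
    n: int
    r: float
    p: float
    sign: str | None
    significant: bool


def delta_delta_ct(
    ct: ExpressionTable,
    reference_gene: str,
    calibrator_sample: str,
    targets: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Relative expression by the 2^-ddCt method.

    dCt_s = Ct(target, s) - Ct(reference, s); ddCt = dCt_s - dCt_cal;
    fold = 2^-ddCt (100% amplification efficiency assumed).  Samples with
    a missing reference Ct are excluded with a warning; targets with a
    missing Ct yield missing (NaN) results for that sample.
    """
    if ct.kind != "ct":
        raise ValueError("delta_delta_ct requires a Ct table")
    if reference_gene not in ct.values.index:
        raise KeyError(f"reference gene {reference_gene!r} not in table")
    if calibrator_sample not in ct.values.columns:
        raise KeyError(f"calibrator sample {calibrator_sample!r} not in table")
    ref = ct.values.loc[reference_gene]
    if math.isnan(ref[calibrator_sample]):
        raise ValueError(
            f"reference gene {reference_gene!r} has no Ct in calibrator "
            f"sample {calibrator_sample!r}"
        )
    usable = [s for s in ct.samples if not math.isnan(ref[s])]
    dropped = [s for s in ct.samples if s not in usable]
    if dropped:
        logger.warning("samples without reference Ct excluded: %s", ", ".join(dropped))
    if targets is None:
        targets = [g for g in ct.genes if g != reference_gene]
    rows = []
    for gene in targets:
        if gene not in ct.values.index:
            raise KeyError(f"target gene {gene!r} not in table")
        tgt = ct.values.loc[gene]
        dct_cal = tgt[calibrator_sample] - ref[calibrator_sample]
        for s in usable:
            dct = tgt[s] - ref[s]
            ddct = dct - dct_cal
            rows.append(
                {
                    "gene": gene,
                    "sample": s,
                    "calibrator": calibrator_sample,
                    "delta_ct_sample": dct,
                    "delta_ct_calibrator": dct_cal,
                    "ddct": ddct,
                    "fold_change": 2.0 ** (-ddct) if not math.isnan(ddct) else float("nan"),
                }
            )
    return pd.DataFrame(rows)


def fold_table(ddct: pd.DataFrame) -> ExpressionTable:
    """Pivot a ddCt result into a gene x sample fold-change matrix."""
    wide = ddct.pivot(index="gene", columns="sample", values="fold_change")
    return ExpressionTable(values=wide, kind="relative")


def scale_rows(table: ExpressionTable) -> ExpressionTable:
    """Center each row to mean 0 and scale to sample SD 1 (n-1
    denominator), the usual heatmap row scaling.  Missing values
    propagate; rows with fewer than 2 observed values or zero variance
    become all-missing with a warning."""
    values = table.values.copy()
    out = pd.DataFrame(index=values.index, columns=values.columns, dtype=float)
    for gene, row in values.iterrows():
        obs = row.dropna()
        sd = obs.std(ddof=1) if len(obs) >= 2 else float("nan")
        if len(obs) < 2 or not sd > 0:
            logger.warning("row %r has <2 values or zero variance; emitted as missing", gene)
            out.loc[gene] = float("nan")
            continue
        out.loc[gene] = (row - obs.mean()) / sd
    return ExpressionTable(values=out, kind="normalized")


def pair_correlation(x: np.ndarray, y: np.ndarray, method: str = "pearson") -> tuple[int, float, float]:
    """(n, r, p) for one pair of sample vectors: complete pairs only,
    two-sided p from the t transform with n-2 df.  r/p are NaN when
    fewer than 3 complete pairs remain or a vector has zero variance."""
    mask = ~(np.isnan(x) | np.isnan(y))
    n = int(mask.sum())
    if n < 3:
        return n, float("nan"), float("nan")
    xv, yv = x[mask], y[mask]
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        return n, float("nan"), float("nan")
    if method == "pearson":
        res = stats.pearsonr(xv, yv)
    elif method == "spearman":
        res = stats.spearmanr(xv, yv)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return n, float(res.statistic), float(res.pvalue)


def correlate(
    tf_expr: ExpressionTable,
    lpg_expr: ExpressionTable,
    alpha: float = DEFAULT_ALPHA,
    method: str = "pearson",
    adjust: str | None = None,
    log2_transform: bool = False,
) -> list[CorrelationEdge]:
    """All-pairs correlation between two expression panels.

    One edge per (TF gene, target gene) pair: Pearson r over samples
    shared by both tables (p from the t transform with n-2 df,
    two-sided).  Pairs with fewer than 3 complete observations or a
    zero-variance vector get missing r/p.  ``adjust='bh'`` applies
    Benjamini-Hochberg before thresholding at alpha.
    """
    if set(tf_expr.samples) != set(lpg_expr.samples):
        raise ValueError("TF and target tables must share the same sample set")
    samples = tf_expr.samples
    a = tf_expr.values[samples].to_numpy(dtype=float)
    b = lpg_expr.values[samples].to_numpy(dtype=float)
    if log2_transform:
        a, b = np.log2(a), np.log2(b)
    raw = []
    for i, ga in enumerate(tf_expr.genes):
        for j, gb in enumerate(lpg_expr.genes):
            n, r, p = pair_correlation(a[i], b[j], method)
            raw.append((ga, gb, n, r, p))
    pvals = np.array([p for *_, p in raw])
    if adjust == "bh":
        finite = ~np.isnan(pvals)
        adj = np.full_like(pvals, np.nan)
        if finite.any():
            adj[finite] = multipletests(pvals[finite], method="fdr_bh")[1]
        pvals = adj
    elif adjust is not None:
        raise ValueError(f"unknown p-value adjustment {adjust!r}")
    edges = []
    for (ga, gb, n, r, p0), p in zip(raw, pvals):
        sign = None if math.isnan(r) or r == 0 else ("positive" if r > 0 else "negative")
        significant = bool(not math.isnan(p) and p < alpha)
        edges.append(CorrelationEdge(ga, gb, n, r, float(p), sign, significant))
    return edges


def edges_to_frame(edges: Sequence[CorrelationEdge]) -> pd.DataFrame:
    return pd.DataFrame([e.__dict__ for e in edges])
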