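"""Two-group differential expression with empirical-Bayes moderated t.

Per gene, the model is a two-group linear fit (global mean plus a condition
effect), so the OLS estimates are the group means and the pooled residual
variance on n - 2 degrees of freedom.  Variances are then shrunk toward a
common prior by matching the first two moments of log s^2 (digamma /
trigamma identities), giving a moderated t on d0 + d_g degrees of freedom.
If the trigamma moment equation has no positive solution the prior df is
infinite and every variance collapses to the prior (normal reference).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma

from infomod.dataset import ExpressionDataset

__all__ = [
    "GeneStats",
    "fit_gene_models",
    "ebayes_moderate",
    "bh_adjust",
    "call_degs",
    "write_deg_table",
]

#: DEG thresholds used by the source analysis.
DEFAULT_FDR = 1e-5
DEFAULT_LFC = 1.0

_VAR_FLOOR = 1e-12  # avoid infinite t on degenerate (noise-free) genes


@dataclass
class GeneStats:
    gene: str
    mean_tumor: float
    mean_normal: float
    log2fc: float
    s2: float  # pooled residual variance
    df: int  # n_tumor + n_normal - 2


def fit_gene_models(data: ExpressionDataset) -> list[GeneStats]:
    """OLS fit of the two-group model for every gene."""
    tumor = data.condition_mask("tumor")
    normal = data.condition_mask("normal")
    n_t, n_n = int(tumor.sum()), int(normal.sum())
    if n_t < 2 or n_n < 2:
        raise ValueError("each condition needs at least 2 samples")
    df = n_t + n_n - 2
    xt, xn = data.matrix[:, tumor], data.matrix[:, normal]
    mt, mn = xt.mean(axis=1), xn.mean(axis=1)
    rss = ((xt - mt[:, None]) ** 2).sum(axis=1) + ((xn - mn[:, None]) ** 2).sum(axis=1)
    s2 = rss / df
    return [
        GeneStats(g, float(mt[i]), float(mn[i]), float(mt[i] - mn[i]), float(s2[i]), df)
        for i, g in enumerate(data.gene_ids)
    ]


def _trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration on 1/trigamma."""
    if y <= 0:
        return np.inf
    x = 0.5 + 1.0 / y  # asymptotic start: trigamma(x) ~ 1/x + 1/(2x^2)
    for _ in range(max_iter):
        tri = float(polygamma(1, x))
        tetra = float(polygamma(2, x))
        delta = tri * (1.0 - tri / y) / tetra
        x += delta
        if abs(delta) < tol * x:
            break
    return x


def _estimate_prior(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Moment estimates (d0, s0^2) from the spread of log variances."""
    if len(np.unique(s2)) < 2:
        raise ValueError("moment matching needs at least 2 distinct variances")
    z = np.log(s2)
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    n = len(z)
    mean_e = float(e.mean())
    # spread of e beyond what sampling noise (trigamma of the residual df) explains
    excess = float(((e - mean_e) ** 2).sum() / (n - 1) - np.mean(polygamma(1, df / 2.0)))
    if excess <= 0:
        return np.inf, float(np.exp(mean_e))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = float(np.exp(mean_e + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def ebayes_moderate(
    gene_stats: list[GeneStats],
    n_tumor: int | None = None,
    n_normal: int | None = None,
    d0_override: float | None = None,
) -> pd.DataFrame:
    """Moderated t, p-value per gene.

    ``d0_override`` pins the prior df (0 = no shrinkage, ordinary pooled t;
    ``inf`` = complete shrinkage to the prior variance) — mainly for testing
    the shrinkage limits.
    """
    if len(gene_stats) < 10 and d0_override is None:
        raise ValueError("need >= 10 genes to estimate the variance prior")
    s2 = np.maximum(np.array([g.s2 for g in gene_stats]), _VAR_FLOOR)
    df = np.array([g.df for g in gene_stats], dtype=float)
    lfc = np.array([g.log2fc for g in gene_stats])
    if n_tumor is None or n_normal is None:
        # two-group df identity: df = n_t + n_n - 2, group sizes needed for SE
        raise ValueError("pass n_tumor and n_normal for the standard error")

    if d0_override is not None:
        d0 = float(d0_override)
        if d0 > 0:
            _, s0_sq = _estimate_prior(s2, df)
        else:
            s0_sq = float(np.exp(np.mean(np.log(s2))))  # unused when d0 == 0
    else:
        d0, s0_sq = _estimate_prior(s2, df)

    if np.isinf(d0):
        s2_mod = np.full_like(s2, s0_sq)
        df_total = np.full_like(df, np.inf)
    else:
        s2_mod = (d0 * s0_sq + df * s2) / (d0 + df)
        df_total = d0 + df
    se = np.sqrt(s2_mod * (1.0 / n_tumor + 1.0 / n_normal))
    t = lfc / se
    finite = np.isfinite(df_total)
    p = np.empty_like(t)
    p[finite] = 2.0 * stats.t.sf(np.abs(t[finite]), df_total[finite])
    p[~finite] = 2.0 * stats.norm.sf(np.abs(t[~finite]))
    return pd.DataFrame(
        {
            "gene": [g.gene for g in gene_stats],
            "log2FC": lfc,
            "s2_moderated": s2_mod,
            "t": t,
            "p": p,
        }
    )


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in the input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty_like(p)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def call_degs(
    table: pd.DataFrame,
    fdr_threshold: float = DEFAULT_FDR,
    lfc_threshold: float = DEFAULT_LFC,
) -> pd.DataFrame:
    """Add q-values (BH) and the DEG call to a moderated-t table."""
    if fdr_threshold <= 0 or lfc_threshold <= 0:
        raise ValueError("thresholds must be positive")
    out = table.copy()
    if "q" not in out.columns:
        out["q"] = bh_adjust(out["p"].to_numpy())
    out["is_deg"] = (out["q"] < fdr_threshold) & (out["log2FC"].abs() > lfc_threshold)
    return out


def run_de(
    data: ExpressionDataset,
    fdr_threshold: float = DEFAULT_FDR,
    lfc_threshold: float = DEFAULT_LFC,
) -> pd.DataFrame:
    """fit -> moderate -> BH -> call, in one step."""
    n_t = int(data.condition_mask("tumor").sum())
    n_n = int(data.condition_mask("normal").sum())
    table = ebayes_moderate(fit_gene_models(data), n_tumor=n_t, n_normal=n_n)
    return call_degs(table, fdr_threshold, lfc_threshold)


def write_deg_table(table: pd.DataFrame, path: str | Path) -> None:
    cols = ["gene", "log2FC", "t", "p", "q", "is_deg"]
    table[cols].to_csv(path, sep="\t", index=False)
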