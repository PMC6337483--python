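"""Differential expression via linear models with empirical-Bayes moderation.

Per gene a two-group linear model gives the group-mean difference (reported
as ``logFC`` since the data are on a log scale) and a pooled residual
variance ``s2`` with ``df = n_case + n_control - 2`` residual degrees of
freedom. The per-gene variances are shrunk toward a common prior:

    s2_post = (d0 * s0^2 + df * s2) / (d0 + df)

where the prior degrees of freedom ``d0`` and prior variance ``s0^2`` are
estimated from the observed variance distribution by the standard
method-of-moments on log variances (a scaled F / scaled inverse-chi-square
hierarchy). The moderated t is

    t = logFC / sqrt(s2_post * (1/n_case + 1/n_control))

referred to a t distribution with ``d0 + df`` degrees of freedom. A gene is
called differential when |logFC| exceeds log2 of the fold-change threshold
AND the Benjamini-Hochberg adjusted p-value is below alpha.

Note on scale: after per-array z-scoring the "logFC" is a difference of
standardized group means, not literally a log fold change; the conventional
column name is kept because the dual threshold is applied on this processed
scale throughout.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from ddipipe.integration import IntegratedDataset

logger = logging.getLogger(__name__)

DEFAULT_FC = 1.5
DEFAULT_ALPHA = 0.05


@dataclass
class EBayesParams:
    """Prior of the variance hierarchy: d0 (prior df, may be inf), s0_sq (prior variance)."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 > 0):
            raise ValueError("d0 must be positive (or inf)")
        if not (self.s0_sq > 0):
            raise ValueError("s0_sq must be positive")


def _trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 60) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration on the log scale."""
    if y <= 0:
        return math.inf
    # starting value from the asymptotic expansion trigamma(x) ~ 1/x + 1/(2x^2)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < tol * x:
            break
    return float(x)


def estimate_ebayes(s2: np.ndarray, df: float) -> EBayesParams:
    """Method-of-moments fit of (d0, s0^2) from per-gene sample variances.

    Works on z = log(s2): E[z] and Var[z] under the scaled-F hierarchy are
    digamma/trigamma expressions in d0 and df, inverted in closed form plus
    one Newton solve. Zero variances are excluded from estimation (guard,
    logged); if the trigamma equation has no positive solution d0 = inf
    (full shrinkage to the common variance).
    """
    s2 = np.asarray(s2, dtype=float)
    positive = s2[s2 > 0]
    if positive.size < 2:
        raise ValueError("need at least 2 genes with positive variance to fit the prior")
    if positive.size < s2.size:
        logger.info("excluded %d zero-variance gene(s) from prior estimation", s2.size - positive.size)
    z = np.log(positive)
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    e_mean = float(e.mean())
    n = e.size
    e_var = float(((e - e_mean) ** 2).sum() / (n - 1))
    excess = e_var - float(special.polygamma(1, df / 2.0))
    if excess > 0:
        d0 = 2.0 * _trigamma_inverse(excess)
        s0_sq = math.exp(e_mean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    else:
        # no excess dispersion beyond sampling noise: fully shared variance,
        # whose natural estimate is the plain mean of the sample variances
        d0 = math.inf
        s0_sq = float(positive.mean())
    return EBayesParams(d0=d0, s0_sq=s0_sq)


def fit_moderated_t(
    data: IntegratedDataset,
    ebayes: bool = True,
    fc_threshold: float = DEFAULT_FC,
    alpha: float = DEFAULT_ALPHA,
    d0_override: float | None = None,
) -> pd.DataFrame:
    """Two-group moderated-t table for every gene of an integrated dataset.

    Returns a DataFrame indexed by gene with columns ``logFC`` (case mean
    minus control mean), ``s2``, ``df_resid``, ``t``, ``p``, ``p_adj`` and
    ``is_deg``, sorted by (p_adj, p, -|logFC|, gene id).

    ``ebayes=False`` (or ``d0_override=0``) gives the classical pooled
    two-sample t. ``d0_override=inf`` forces full shrinkage to the prior.
    """
    groups = data.groups
    case = data.values.loc[:, (groups == "case").to_numpy()]
    control = data.values.loc[:, (groups == "control").to_numpy()]
    n1, n2 = case.shape[1], control.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError(f"need >= 2 samples per group, got {n1} case / {n2} control")

    x1 = case.to_numpy(dtype=float)
    x2 = control.to_numpy(dtype=float)
    logfc = x1.mean(axis=1) - x2.mean(axis=1)
    df_resid = n1 + n2 - 2
    ss = ((x1 - x1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (x2 - x2.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s2 = ss / df_resid

    d0 = 0.0
    s0_sq = float("nan")
    if ebayes:
        if data.values.shape[0] < 2:
            raise ValueError("empirical Bayes moderation needs >= 2 genes")
        if d0_override is not None:
            d0 = float(d0_override)
            s0_sq = float(estimate_ebayes(s2, df_resid).s0_sq) if d0 != 0 else float("nan")
        else:
            prior = estimate_ebayes(s2, df_resid)
            d0, s0_sq = prior.d0, prior.s0_sq

    if d0 == 0:
        s2_post = s2.copy()
        df_total = float(df_resid)
    elif math.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        # cap at the pooled df across genes (the conventional guard against
        # overstating certainty of the fully shrunk variance)
        df_total = float(len(s2) * df_resid)
    else:
        s2_guard = np.where(s2 > 0, s2, s0_sq)  # zero-variance guard
        if (s2 == 0).any():
            logger.info("replaced %d zero variances by the prior variance", int((s2 == 0).sum()))
        s2_post = (d0 * s0_sq + df_resid * s2_guard) / (d0 + df_resid)
        df_total = d0 + df_resid

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, logfc / se, 0.0)
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df=df_total)

    table = pd.DataFrame(
        {
            "logFC": logfc,
            "s2": s2,
            "df_resid": float(df_resid),
            "t": t,
            "p": p,
        },
        index=data.values.index,
    )
    table["p_adj"] = adjust_bh(table["p"].to_numpy())
    _validate_thresholds(fc_threshold, alpha)
    table["is_deg"] = (np.abs(table["logFC"]) > np.log2(fc_threshold)) & (
        table["p_adj"] < alpha
    )
    table = _sort_deg_table(table)
    table.attrs["ebayes"] = EBayesParams(d0=d0, s0_sq=s0_sq) if d0 > 0 else None
    table.attrs["n_case"] = n1
    table.attrs["n_control"] = n2
    return table


def _sort_deg_table(table: pd.DataFrame) -> pd.DataFrame:
    order = table.assign(
        _abs_fc=-table["logFC"].abs(), _gene=table.index.astype(str)
    ).sort_values(by=["p_adj", "p", "_abs_fc", "_gene"], kind="mergesort")
    return table.loc[order.index]


def adjust_bh(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m, dtype=float)
    out[order] = adjusted
    return out


def _validate_thresholds(fc_threshold: float, alpha: float) -> None:
    if not fc_threshold > 1.0:
        raise ValueError(f"fc_threshold must exceed 1.0, got {fc_threshold}")
    if not (0.0 < alpha <= 1.0):
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")


def call_degs(
    table: pd.DataFrame, fc_threshold: float = DEFAULT_FC, alpha: float = DEFAULT_ALPHA
) -> list[str]:
    """Genes with |logFC| > log2(fc_threshold) and adjusted p < alpha.

    Returned in the deterministic table order (p_adj, p, -|logFC|, gene id).
    """
    _validate_thresholds(fc_threshold, alpha)
    mask = (table["logFC"].abs() > np.log2(fc_threshold)) & (table["p_adj"] < alpha)
    return list(_sort_deg_table(table[mask]).index.astype(str))
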