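"""Moderated two-group differential expression.

A limma-style empirical-Bayes test: per-gene ordinary least squares between
two sample groups on log2-CPM, with residual variances shrunk toward a
common prior estimated by method of moments on log s^2, giving a moderated
t statistic on augmented degrees of freedom. The d0 -> infinity limit (all
variances forced to the prior) and the no-shrinkage limit are exact and
serve as test oracles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from pbscreen.enrichment import bh_adjust, classify_volcano
from pbscreen.errors import ValidationError


@dataclass
class DgeRecord:
    gene_id: str
    log2fc: float
    t_mod: float
    p: float
    adj_p: float
    status: str = "unchanged"


def log_cpm(counts: pd.DataFrame, library_sizes) -> pd.DataFrame:
    """log2((count + 0.5) / (library_size + 1) * 1e6) per gene and sample."""
    sizes = pd.Series(library_sizes).reindex(counts.columns)
    if sizes.isna().any() or (sizes <= 0).any():
        raise ValidationError("library sizes must be positive for all samples")
    return np.log2((counts + 0.5).div(sizes + 1.0, axis=1) * 1e6)


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (monotone decreasing)."""
    if y <= 0:
        raise ValidationError("trigamma inverse needs y > 0")
    return float(
        optimize.brentq(lambda x: special.polygamma(1, x) - y, 1e-8, 1e8, xtol=1e-12)
    )


def fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the variance prior (s0^2, d0).

    Models s_g^2 ~ s0^2 * F(df, d0) via z = log s^2; matches the mean and
    variance of z using digamma/trigamma identities. Returns d0 = inf when
    the observed spread of z is no larger than chi-square sampling noise
    alone (no evidence of variance heterogeneity).
    """
    s2 = np.maximum(np.asarray(s2, dtype=float), 0.0)
    m = np.median(s2)
    s2 = np.maximum(s2, 1e-5 * m if m > 0 else 1e-300)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    n = z.size
    if n < 2:
        return float(s2.mean()), np.inf
    evar = np.var(e, ddof=1) - special.polygamma(1, df / 2.0)
    if evar <= 0:
        # no excess spread beyond chi-square noise: one shared variance,
        # estimated by the arithmetic mean
        return float(s2.mean()), np.inf
    d0 = 2.0 * trigamma_inverse(evar)
    s0_2 = np.exp(np.mean(e) + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    return float(s0_2), float(d0)


def moderated_de_test(
    log_expr: pd.DataFrame,
    group_labels: pd.Series,
    case: str,
    control: str,
    *,
    prior_df: float | None = None,
) -> list[DgeRecord]:
    """Moderated t test of ``case`` vs ``control`` samples per gene.

    log2fc is the case-minus-control mean difference. Pass
    ``prior_df=np.inf`` to force full shrinkage to the prior variance, or 0
    to disable shrinkage (ordinary t test); by default the prior degrees of
    freedom d0 are estimated from the data.
    """
    labels = pd.Series(group_labels)
    idx_case = labels.index[labels == case]
    idx_ctrl = labels.index[labels == control]
    n1, n0 = len(idx_case), len(idx_ctrl)
    if n1 < 2 or n0 < 2:
        raise ValidationError(
            f"both groups need >= 2 samples (got {case}: {n1}, {control}: {n0})"
        )
    x1 = log_expr[idx_case].to_numpy()
    x0 = log_expr[idx_ctrl].to_numpy()
    lfc = x1.mean(axis=1) - x0.mean(axis=1)
    df = n1 + n0 - 2
    ss = ((x1 - x1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (x0 - x0.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s2 = np.maximum(ss / df, 1e-300)

    if prior_df is None:
        s0_2, d0 = fit_f_dist(s2, df)
    elif prior_df == 0:
        s0_2, d0 = 0.0, 0.0
    else:
        s0_2 = fit_f_dist(s2, df)[0]
        d0 = float(prior_df)

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
    else:
        s2_post = (d0 * s0_2 + df * s2) / (d0 + df)
    # total df capped at the pooled residual df over all genes
    df_total = min(d0 + df, s2.size * df)

    denom = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n0))
    t_mod = lfc / denom
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df=df_total)
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    adj = bh_adjust(p)
    records = [
        DgeRecord(g, float(l), float(tm), float(pv), float(ap))
        for g, l, tm, pv, ap in zip(log_expr.index, lfc, t_mod, p, adj)
    ]
    return classify_deg(records)


def classify_deg(records: list[DgeRecord], lfc_thresh=1.0, logp_thresh=2.0):
    """Same volcano thresholds as the screen arm: |log2FC| > 1, -log10 adjP > 2."""
    return classify_volcano(records, lfc_thresh, logp_thresh)


def records_to_frame(records: list[DgeRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "log2fc": [r.log2fc for r in records],
            "t_mod": [r.t_mod for r in records],
            "p": [r.p for r in records],
            "adj_p": [r.adj_p for r in records],
            "status": [r.status for r in records],
        }
    )
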