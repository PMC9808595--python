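"""Per-gene enrichment of selected libraries versus control.

Each gene's insertion-read count in a screened library is compared with the
unselected control library by a two-sided Fisher exact test on read
proportions, with Benjamini–Hochberg FDR adjustment across all tested genes
and volcano classification at log2FC and -log10 adjusted-p thresholds. The
overlap gene set intersects the up-called genes of the dose arms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from pbscreen.errors import ValidationError
from pbscreen.sites import GeneCountMatrix

#: volcano thresholds: |log2FC| > 1 and -log10(adjusted p) > 2
LFC_THRESH = 1.0
LOGP_THRESH = 2.0


@dataclass
class EnrichmentRecord:
    gene_id: str
    count_ctrl: int
    count_screen: int
    log2fc: float
    p: float
    adj_p: float
    status: str = "unchanged"


@dataclass
class OverlapResult:
    up_sets: dict[str, set[str]]
    intersection: list[str]


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values.

    adj_(i) = min_{j >= i} p_(j) * m / j, capped at 1; monotone in ranks.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValidationError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    # p * m / j with m == j can round a hair below p; adj >= p holds exactly
    return np.maximum(adj, p)


def enrichment_test(
    matrix: GeneCountMatrix, ctrl_lib: str, screen_lib: str
) -> list[EnrichmentRecord]:
    """Fisher exact enrichment of screen vs control read counts per gene.

    Tested genes are those with a read in either library; log2FC is computed
    on CPM with a 0.5 pseudocount so zero-count genes stay finite. The 2x2
    table per gene is [screen in-gene, screen elsewhere; ctrl in-gene, ctrl
    elsewhere].
    """
    for lib in (ctrl_lib, screen_lib):
        if lib not in matrix.library_ids:
            raise ValidationError(f"library {lib!r} not in matrix")
    size_c = int(matrix.library_sizes[ctrl_lib])
    size_s = int(matrix.library_sizes[screen_lib])
    if size_c <= 0 or size_s <= 0:
        raise ValidationError("library sizes must be positive")
    counts = matrix.counts
    tested = counts.index[(counts[ctrl_lib] > 0) | (counts[screen_lib] > 0)]
    records = []
    for gene in tested:
        c = int(counts.at[gene, ctrl_lib])
        s = int(counts.at[gene, screen_lib])
        cpm_c = c / size_c * 1e6
        cpm_s = s / size_s * 1e6
        log2fc = float(np.log2((cpm_s + 0.5) / (cpm_c + 0.5)))
        _, p = stats.fisher_exact([[s, size_s - s], [c, size_c - c]])
        records.append(EnrichmentRecord(gene, c, s, log2fc, float(min(p, 1.0)), 1.0))
    if records:
        adj = bh_adjust([max(r.p, np.nextafter(0, 1)) for r in records])
        for r, a in zip(records, adj):
            r.adj_p = float(a)
    return classify_volcano(records)


def classify_volcano(
    records: list[EnrichmentRecord],
    lfc_thresh: float = LFC_THRESH,
    logp_thresh: float = LOGP_THRESH,
) -> list[EnrichmentRecord]:
    """Status: up / down / unchanged at the volcano thresholds."""
    for r in records:
        significant = -np.log10(r.adj_p) > logp_thresh if r.adj_p > 0 else True
        if significant and r.log2fc > lfc_thresh:
            r.status = "up"
        elif significant and r.log2fc < -lfc_thresh:
            r.status = "down"
        else:
            r.status = "unchanged"
    return records


def overlap_genes(*up_sets: set[str], labels: list[str] | None = None) -> OverlapResult:
    """Exact intersection of up-called gene sets, sorted for determinism."""
    if len(up_sets) < 2:
        raise ValidationError("need at least two gene sets to overlap")
    if labels is None:
        labels = [f"set{i + 1}" for i in range(len(up_sets))]
    inter = set(up_sets[0])
    for s in up_sets[1:]:
        inter &= set(s)
    return OverlapResult(
        up_sets={lab: set(s) for lab, s in zip(labels, up_sets)},
        intersection=sorted(inter),
    )


def records_to_frame(records: list[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "count_ctrl": [r.count_ctrl for r in records],
            "count_screen": [r.count_screen for r in records],
            "log2fc": [r.log2fc for r in records],
            "p": [r.p for r in records],
            "adj_p": [r.adj_p for r in records],
            "status": [r.status for r in records],
        }
    )
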