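"""Shared fixtures: small simulated screens and cohorts with known truth."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pbscreen import synthetic
from pbscreen.sites import GeneCountMatrix


@pytest.fixture(scope="session")
def small_genome() -> synthetic.SyntheticGenome:
    return synthetic.generate_genome(10, 30000, rng_seed=1)


@pytest.fixture(scope="session")
def screen_truth():
    """A compact selection screen with designated resistance genes.

    Returns (genome, selection config, pre-selection library, selected
    libraries keyed C0L/C5L/C10L).
    """
    genome = synthetic.generate_genome(40, 90000, rng_seed=11)
    rng = np.random.default_rng(12)
    resistance = set(
        rng.choice([g.gene_id for g in genome.genes], size=8, replace=False).tolist()
    )
    cfg = synthetic.SelectionConfig(resistance_genes=resistance, rng_seed=13)
    library = synthetic.simulate_library(genome, 1500, rng_seed=14)
    selected = {
        f"C{d}L": synthetic.apply_selection(library, genome, cfg, d) for d in cfg.doses
    }
    return genome, cfg, library, selected


def counts_from_clones(selected: dict, genome) -> GeneCountMatrix:
    """Gene x library read-count matrix straight from clone abundances.

    Deterministic stand-in for the read-level pipeline: each insertion
    contributes abundance x 2 reads (both ITR sides) to every gene
    containing it; library size is the total over all insertions.
    """
    libs = list(selected)
    rows: dict[str, dict[str, int]] = {}
    sizes = {lib: 0 for lib in libs}
    for lib, clones in selected.items():
        for clone in clones:
            for pos, _orient in clone.insertions:
                reads = clone.abundance * 2
                sizes[lib] += reads
                for g in genome.genes:
                    if g.contains(pos):
                        row = rows.setdefault(g.gene_id, {x: 0 for x in libs})
                        row[lib] += reads
    counts = (
        pd.DataFrame.from_dict(rows, orient="index").reindex(columns=libs).fillna(0)
    )
    return GeneCountMatrix(counts.sort_index(), pd.Series(sizes))


@pytest.fixture(scope="session")
def four_gene_cohort() -> synthetic.SurvivalCohort:
    """A cohort with the four-gene signature coefficients planted."""
    return synthetic.simulate_survival_cohort(
        300, 4, [0.4193, 0.1222, 0.1394, 0.291], 0.35, 7,
        gene_ids=["ZNF720", "REEP3", "CNNM2", "CGREF1"],
    )
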