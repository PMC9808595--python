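"""Synthetic inputs with known ground truth.

Everything the pipeline consumes can be generated here: a toy genome with
gene models and TTAA tetranucleotides (the piggyBac integration motif), a
clone library carrying transposon insertions, cisplatin-selection of that
library with designated resistance genes, paired splinkerette junction
reads, and an expression + disease-free-survival cohort drawn from a
proportional-hazards model with known coefficients.

All randomness flows through :func:`numpy.random.default_rng` seeded from the
caller; identical seeds give byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from pbscreen.errors import DomainError, SizingError, ValidationError

PB5_TAG = "CGTCAATTTTACGCAGACTA"
PB3_TAG = "GAGATGTCCTAAATGCACAG"
ADAPTER = "AGATCGGAAGAGCACACGTC"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def scan_ttaa(sequence: str) -> list[int]:
    """All 0-based start positions p with ``sequence[p:p+4] == 'TTAA'``."""
    sites = []
    p = sequence.find("TTAA")
    while p != -1:
        sites.append(p)
        p = sequence.find("TTAA", p + 1)
    return sites


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneModel:
    """A gene interval with exons, 0-based half-open coordinates."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValidationError(f"{self.gene_id}: start must be < end")
        if self.strand not in "+-":
            raise ValidationError(f"{self.gene_id}: strand must be + or -")
        if not self.exons:
            raise ValidationError(f"{self.gene_id}: at least one exon required")
        prev_end = self.start
        for s, e in self.exons:
            if s < prev_end or e > self.end or s >= e:
                raise ValidationError(
                    f"{self.gene_id}: exons must be sorted, non-overlapping "
                    f"and contained in the gene span"
                )
            prev_end = e

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass
class SyntheticGenome:
    """A single-chromosome toy genome with genes and TTAA sites."""

    chrom: str
    sequence: str
    genes: list[GeneModel]
    ttaa_sites: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.ttaa_sites:
            self.ttaa_sites = scan_ttaa(self.sequence)
        for g in self.genes:
            if g.end > len(self.sequence):
                raise ValidationError(f"{g.gene_id} extends past the sequence end")

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f">{self.chrom}\n")
            seq = self.sequence
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")

    def genes_to_bed(self, path) -> None:
        """BED6 + block columns (BED12-like exon structure)."""
        with open(path, "w") as fh:
            for g in self.genes:
                sizes = ",".join(str(e - s) for s, e in g.exons)
                starts = ",".join(str(s - g.start) for s, e in g.exons)
                fh.write(
                    f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\t"
                    f"{len(g.exons)}\t{sizes}\t{starts}\n"
                )


@dataclass
class Clone:
    """One cell clone: transposon insertions plus a cell count."""

    clone_id: str
    insertions: list[tuple[int, str]]
    abundance: int


@dataclass
class SelectionConfig:
    """Cisplatin selection conditions for the screen simulation.

    ``base_survival`` maps each dose label to the survival probability of a
    cell with no activating insertion; clones with a sense-orientation
    insertion inside a resistance gene survive at
    ``min(1, base_survival * resistance_boost)``.
    """

    doses: list[int] = field(default_factory=lambda: [0, 5, 10])
    base_survival: dict[int, float] = field(
        default_factory=lambda: {0: 1.0, 5: 0.01, 10: 0.005}
    )
    resistance_genes: set[str] = field(default_factory=set)
    resistance_boost: float = 10.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for d in self.doses:
            if d not in self.base_survival:
                raise ValidationError(f"no base_survival for dose {d}")
            if not 0.0 <= self.base_survival[d] <= 1.0:
                raise ValidationError(f"base_survival[{d}] outside [0,1]")
        if self.resistance_boost < 1.0:
            raise ValidationError("resistance_boost must be >= 1")

    def survival(self, dose: int, activating: bool) -> float:
        p = self.base_survival[dose]
        if activating:
            p = min(1.0, p * self.resistance_boost)
        return p

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "doses": self.doses,
                    "base_survival": {str(k): v for k, v in self.base_survival.items()},
                    "resistance_genes": sorted(self.resistance_genes),
                    "resistance_boost": self.resistance_boost,
                    "rng_seed": self.rng_seed,
                },
                fh,
                indent=2,
            )


@dataclass
class SurvivalCohort:
    """Expression matrix (genes x samples, log2 scale) with DFS records."""

    sample_ids: list[str]
    expression: pd.DataFrame
    time_years: np.ndarray
    event: np.ndarray
    true_beta: pd.Series

    def survival_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "time_years": self.time_years,
                "event": self.event,
            }
        )


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------


def generate_genome(
    n_genes: int,
    genome_length: int,
    rng_seed: int,
    *,
    chrom: str = "chrT",
    gene_length: int = 1200,
    planted_ttaa_per_gene: int = 2,
) -> SyntheticGenome:
    """Random genome with ``n_genes`` non-overlapping genes on one chromosome.

    Each gene is guaranteed at least one internal TTAA: the generator plants
    ``planted_ttaa_per_gene`` motifs at random interior positions on top of
    whatever TTAAs the random background already contains.
    """
    rng = np.random.default_rng(rng_seed)
    min_gap = 200
    needed = n_genes * (gene_length + min_gap) + min_gap
    if n_genes and genome_length < needed:
        raise SizingError(
            f"genome_length={genome_length} cannot hold {n_genes} genes of "
            f"{gene_length} bp with {min_gap} bp gaps (need >= {needed} bp)"
        )
    seq = rng.choice(list("ACGT"), size=genome_length)

    genes: list[GeneModel] = []
    if n_genes:
        slot = genome_length // n_genes
        for i in range(n_genes):
            jitter_max = max(1, slot - gene_length - min_gap)
            start = i * slot + min_gap // 2 + int(rng.integers(0, jitter_max))
            end = start + gene_length
            strand = "+" if rng.random() < 0.5 else "-"
            # 2-3 exons separated by introns, all inside [start, end)
            n_exons = int(rng.integers(2, 4))
            bounds = np.sort(rng.choice(np.arange(50, gene_length - 50), size=2 * n_exons - 2, replace=False))
            edges = [0, *bounds.tolist(), gene_length]
            exons = tuple(
                (start + edges[2 * k], start + edges[2 * k + 1]) for k in range(n_exons)
            )
            genes.append(GeneModel(f"G{i + 1:04d}", chrom, start, end, strand, exons))
            for _ in range(planted_ttaa_per_gene):
                p = start + int(rng.integers(4, gene_length - 8))
                seq[p : p + 4] = list("TTAA")

    return SyntheticGenome(chrom=chrom, sequence="".join(seq), genes=genes)


# ---------------------------------------------------------------------------
# clone library and selection
# ---------------------------------------------------------------------------


def simulate_library(
    genome: SyntheticGenome,
    n_clones: int,
    rng_seed: int,
    *,
    abundance_scale: float = 20.0,
) -> list[Clone]:
    """Clones with 1-3 insertions uniform over TTAA sites, random orientation.

    Cell counts follow a log-normal(0, 1) scaled by ``abundance_scale`` and
    rounded to at least one cell, reproducing the clonal-expansion skew of a
    real library.
    """
    if not genome.ttaa_sites:
        raise DomainError("genome has no TTAA sites; cannot place insertions")
    rng = np.random.default_rng(rng_seed)
    sites = np.asarray(genome.ttaa_sites)
    clones = []
    for i in range(n_clones):
        k = int(rng.integers(1, 4))
        k = min(k, len(sites))
        pos = rng.choice(sites, size=k, replace=False)
        orient = rng.choice(["+", "-"], size=k)
        abundance = max(1, int(round(float(rng.lognormal(0.0, 1.0)) * abundance_scale)))
        clones.append(
            Clone(
                clone_id=f"clone{i + 1:05d}",
                insertions=[(int(p), str(o)) for p, o in zip(pos, orient)],
                abundance=abundance,
            )
        )
    return clones


def has_activating_insertion(
    clone: Clone, genes: Sequence[GeneModel], resistance_genes: set[str]
) -> bool:
    """Sense-orientation insertion inside a resistance gene's span.

    "Activating" means the transposon's orientation matches the gene strand so
    the CMV promoter + splice donor cargo reads into the gene.
    """
    for pos, orient in clone.insertions:
        for g in genes:
            if g.gene_id in resistance_genes and g.contains(pos) and g.strand == orient:
                return True
    return False


def apply_selection(
    library: list[Clone],
    genome: SyntheticGenome,
    cfg: SelectionConfig,
    dose: int,
) -> list[Clone]:
    """Binomially thin clone abundances under dose-dependent survival.

    Each cell survives independently; clones with an activating insertion in
    a resistance gene get the boosted survival probability. Clones whose
    abundance drops to zero are removed.
    """
    if dose not in cfg.doses:
        raise ValidationError(f"dose {dose} not in configured doses {cfg.doses}")
    rng = np.random.default_rng([cfg.rng_seed, cfg.doses.index(dose)])
    resistant = {
        c.clone_id: has_activating_insertion(c, genome.genes, cfg.resistance_genes)
        for c in library
    }
    survivors = []
    for c in library:
        p = cfg.survival(dose, resistant[c.clone_id])
        if p >= 1.0:
            new_abund = c.abundance
        else:
            new_abund = int(rng.binomial(c.abundance, p))
        if new_abund > 0:
            survivors.append(Clone(c.clone_id, list(c.insertions), new_abund))
    return survivors


def clones_to_tsv(clones: list[Clone], path) -> None:
    with open(path, "w") as fh:
        fh.write("clone_id\tabundance\tinsertions\n")
        for c in clones:
            ins = ";".join(f"{p}{o}" for p, o in c.insertions)
            fh.write(f"{c.clone_id}\t{c.abundance}\t{ins}\n")


# ---------------------------------------------------------------------------
# junction reads
# ---------------------------------------------------------------------------


def _flanks(genome: SyntheticGenome, pos: int, orient: str, length: int) -> dict[str, str]:
    """Genomic flank for each ITR side of an insertion.

    The base adjacent to the ITR is always the TTAA start itself, so an
    error-free read round-trips to the exact insertion coordinate. Flanks
    running off a genome end are truncated, never an error.
    """
    seq = genome.sequence
    fwd = seq[pos : min(len(seq), pos + length)]
    rev = revcomp(seq[max(0, pos - length + 1) : pos + 1])
    if orient == "+":
        return {"PB5": fwd, "PB3": rev}
    return {"PB5": rev, "PB3": fwd}


def simulate_reads(
    library: list[Clone],
    genome: SyntheticGenome,
    rng_seed: int,
    *,
    read_len: int = 125,
    depth: float = 1.0,
    frag_min: int = 60,
    frag_max: int = 300,
    pb5_tag: str = PB5_TAG,
    pb3_tag: str = PB3_TAG,
    adapter: str = ADAPTER,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Paired junction reads for every insertion in every clone.

    Read 1 carries the side's ITR tag followed by genomic flank; when the
    sheared fragment is shorter than the read the adapter is read through,
    then padding. The number of read pairs per insertion and side is
    Poisson(depth * abundance). Returns (read1, read2) lists of
    (read_id, sequence); read ids encode the ground-truth insertion.
    """
    min_needed = max(len(pb5_tag), len(pb3_tag)) + 20
    if read_len < min_needed:
        raise ValidationError(
            f"read_len={read_len} below tag length + 20 bp minimal flank"
        )
    rng = np.random.default_rng(rng_seed)
    tags = {"PB5": pb5_tag, "PB3": pb3_tag}
    reads1: list[tuple[str, str]] = []
    reads2: list[tuple[str, str]] = []
    for clone in library:
        for pos, orient in clone.insertions:
            for side in ("PB5", "PB3"):
                n = int(rng.poisson(depth * clone.abundance))
                for j in range(n):
                    frag_len = int(rng.integers(frag_min, frag_max + 1))
                    flank = _flanks(genome, pos, orient, frag_len)[side]
                    if len(flank) < 20:
                        continue  # genome-end truncation left no usable flank
                    r1 = tags[side] + flank
                    if len(r1) < read_len:
                        r1 += adapter
                    if len(r1) < read_len:
                        r1 += "A" * (read_len - len(r1))
                    r1 = r1[:read_len]
                    r2 = revcomp(flank) + revcomp(tags[side]) + adapter
                    if len(r2) < read_len:
                        r2 += "A" * (read_len - len(r2))
                    r2 = r2[:read_len]
                    rid = f"{clone.clone_id}:{pos}:{orient}:{side}:{j}"
                    reads1.append((rid, r1))
                    reads2.append((rid, r2))
    return reads1, reads2


def write_fastq(reads: list[tuple[str, str]], path) -> None:
    """Plain FASTQ with constant 'I' qualities."""
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# survival cohort
# ---------------------------------------------------------------------------


def _calibrate_censor_bound(rates: np.ndarray, censor_frac: float) -> float:
    """Upper bound b of Uniform(0, b) censoring giving ~censor_frac censored.

    For event time T ~ Exp(rate) and C ~ U(0, b), P(C < T) averaged over the
    cohort is monotone decreasing in b; solve by bisection.
    """

    def mean_censored(b: float) -> float:
        x = rates * b
        return float(np.mean(np.where(x < 1e-12, 1.0, (1.0 - np.exp(-x)) / x)))

    lo, hi = 1e-9, 1e9
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if mean_censored(mid) > censor_frac:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def simulate_survival_cohort(
    n_samples: int,
    n_genes: int,
    true_beta,
    censor_frac: float,
    rng_seed: int,
    *,
    gene_ids: list[str] | None = None,
    baseline_hazard: float = 0.12,
    expr_mean: float = 0.0,
    expr_sd: float = 1.5,
) -> SurvivalCohort:
    """Expression + DFS cohort under a proportional-hazards model.

    Expression is Normal(expr_mean, expr_sd) per gene on the log2 scale;
    event times are exponential with rate baseline_hazard * exp(beta . x);
    censoring is independent Uniform(0, b) with b calibrated so roughly
    ``censor_frac`` of samples are censored. ``censor_frac = 1`` censors
    everyone (administratively, at their would-be event time).
    """
    if n_samples < 10:
        raise ValidationError("n_samples must be >= 10")
    if not 0.0 < censor_frac <= 1.0:
        raise ValidationError("censor_frac must be in (0, 1]")
    beta = np.zeros(n_genes)
    tb = np.asarray(true_beta, dtype=float)
    if not np.all(np.isfinite(tb)):
        raise ValidationError("true_beta must be finite")
    if tb.size > n_genes:
        raise ValidationError("true_beta longer than n_genes")
    beta[: tb.size] = tb
    if gene_ids is None:
        gene_ids = [f"G{i + 1:03d}" for i in range(n_genes)]
    if len(gene_ids) != n_genes:
        raise ValidationError("gene_ids length must equal n_genes")

    rng = np.random.default_rng(rng_seed)
    x = rng.normal(expr_mean, expr_sd, size=(n_genes, n_samples))
    rates = baseline_hazard * np.exp(beta @ x)
    t_event = rng.exponential(1.0 / rates)
    if censor_frac >= 1.0:
        time = t_event
        event = np.zeros(n_samples, dtype=int)
    else:
        b = _calibrate_censor_bound(rates, censor_frac)
        t_censor = rng.uniform(0.0, b, size=n_samples)
        time = np.minimum(t_event, t_censor)
        event = (t_event <= t_censor).astype(int)

    sample_ids = [f"S{i + 1:03d}" for i in range(n_samples)]
    expr = pd.DataFrame(x, index=gene_ids, columns=sample_ids)
    return SurvivalCohort(
        sample_ids=sample_ids,
        expression=expr,
        time_years=time,
        event=event,
        true_beta=pd.Series(beta, index=gene_ids),
    )
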