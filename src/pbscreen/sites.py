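"""Mapping junction fragments to TTAA insertion sites and gene counts.

The internal aligner is an exact-substring, unique-hit search — adequate for
a toy reference and dependency-free; alignments produced by a real aligner
enter the pipeline through :func:`import_sam`. Fragment junction coordinates
are snapped to the nearest TTAA start (piggyBac's invariant integration
motif) and aggregated into strand-aware sites with per-library read support.
"""

from __future__ import annotations

import warnings
from bisect import bisect_left
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from pbscreen.errors import ParseError, ValidationError
from pbscreen.synthetic import SyntheticGenome, revcomp
from pbscreen.trim import JunctionFragment


@dataclass(frozen=True)
class Alignment:
    """One uniquely-placed fragment on the reference."""

    read_id: str
    chrom: str
    pos0: int
    strand: str
    matched_len: int
    source: str = "internal"


@dataclass
class AlignStats:
    mapped: int = 0
    unmapped: int = 0
    multimapped: int = 0


@dataclass
class InsertionSite:
    """A strand-aware TTAA integration coordinate with read support."""

    chrom: str
    pos0: int
    orientation: str
    side_support: dict[str, int] = field(default_factory=lambda: {"PB5": 0, "PB3": 0})
    read_count: dict[str, int] = field(default_factory=dict)

    @property
    def total_reads(self) -> int:
        return sum(self.read_count.values())


class GeneCountMatrix:
    """Genes x libraries integer insertion-read counts with library sizes."""

    def __init__(self, counts: pd.DataFrame, library_sizes: pd.Series):
        if counts.index.duplicated().any():
            raise ValidationError("duplicate gene ids in count matrix")
        if counts.columns.duplicated().any():
            raise ValidationError("duplicate library ids in count matrix")
        if (counts.to_numpy() < 0).any():
            raise ValidationError("negative counts")
        library_sizes = library_sizes.reindex(counts.columns)
        if library_sizes.isna().any():
            raise ValidationError("library_sizes missing for some libraries")
        self.counts = counts.astype(int)
        self.library_sizes = library_sizes.astype(int)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def library_ids(self) -> list[str]:
        return list(self.counts.columns)

    def mutant_gene_counts(self) -> pd.Series:
        """Genes with at least one read, per library (library gene coverage)."""
        return (self.counts > 0).sum(axis=0)

    def to_tsv(self, path) -> None:
        out = self.counts.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, library_sizes: pd.Series) -> "GeneCountMatrix":
        counts = pd.read_csv(path, sep="\t", index_col=0)
        return cls(counts, library_sizes)


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------


_SEED_LEN = 20


def _seed_index(seq: str) -> dict[str, list[int]]:
    """Positions of every overlapping 20-mer; makes exact search O(1)."""
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - _SEED_LEN + 1):
        index.setdefault(seq[i : i + _SEED_LEN], []).append(i)
    return index


def _occurrences(seq: str, frag: str, index: dict[str, list[int]]) -> list[int]:
    """All start positions of frag in seq (via the seed index)."""
    if len(frag) < _SEED_LEN:
        hits, p = [], seq.find(frag)
        while p != -1:
            hits.append(p)
            p = seq.find(frag, p + 1)
        return hits
    return [p for p in index.get(frag[:_SEED_LEN], []) if seq.startswith(frag, p)]


def _unique_hit(seq: str, frag: str, index: dict[str, list[int]]) -> int | None:
    """Position of the only occurrence of frag, None if absent, -1 if multi."""
    hits = _occurrences(seq, frag, index)
    if not hits:
        return None
    if len(hits) > 1:
        return -1
    return hits[0]


def align_fragments(
    fragments: list[JunctionFragment], genome: SyntheticGenome
) -> tuple[list[Alignment], AlignStats]:
    """Exact-substring unique-hit search of each fragment and its reverse
    complement against the reference; ambiguous or absent fragments are
    counted and dropped."""
    alignments: list[Alignment] = []
    stats = AlignStats()
    seq = genome.sequence
    index = _seed_index(seq)
    for f in fragments:
        fwd = _unique_hit(seq, f.genomic_seq, index)
        rev = _unique_hit(seq, revcomp(f.genomic_seq), index)
        if fwd == -1 or rev == -1 or (fwd is not None and rev is not None):
            stats.multimapped += 1
            continue
        if fwd is None and rev is None:
            stats.unmapped += 1
            continue
        if fwd is not None:
            aln = Alignment(f.read_id, genome.chrom, fwd, "+", len(f.genomic_seq))
        else:
            aln = Alignment(f.read_id, genome.chrom, rev, "-", len(f.genomic_seq))
        alignments.append(aln)
        stats.mapped += 1
    return alignments, stats


def export_sam(alignments: list[Alignment], genome: SyntheticGenome, path) -> None:
    """Write alignments as headered text SAM (1-based POS, 0x10 = minus)."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": genome.chrom, "LN": len(genome.sequence)}],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as fh:
        for aln in alignments:
            rec = pysam.AlignedSegment(fh.header)
            rec.query_name = aln.read_id
            rec.reference_id = 0
            rec.reference_start = aln.pos0
            rec.flag = 16 if aln.strand == "-" else 0
            rec.mapping_quality = 60
            rec.cigarstring = f"{aln.matched_len}M"
            fh.write(rec)


def import_sam(sam_path) -> list[Alignment]:
    """Primary mapped SAM records as alignments (POS converted to 0-based)."""
    alignments = []
    try:
        with pysam.AlignmentFile(str(sam_path), "r") as fh:
            if not fh.header.get("SQ"):
                raise ParseError(f"{sam_path}: SAM header has no @SQ lines")
            for rec in fh:
                if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                    continue
                alignments.append(
                    Alignment(
                        read_id=rec.query_name,
                        chrom=rec.reference_name,
                        pos0=rec.reference_start,
                        strand="-" if rec.is_reverse else "+",
                        matched_len=rec.reference_length or rec.query_length,
                        source="SAM",
                    )
                )
    except (ValueError, OSError) as exc:
        raise ParseError(f"{sam_path}: cannot parse SAM: {exc}") from exc
    return alignments


# ---------------------------------------------------------------------------
# site calling
# ---------------------------------------------------------------------------


def _snap_to_ttaa(pos: int, ttaa_sites: list[int], tolerance: int) -> int | None:
    i = bisect_left(ttaa_sites, pos)
    best, best_d = None, tolerance + 1
    for j in (i - 1, i, i + 1):
        if 0 <= j < len(ttaa_sites):
            d = abs(ttaa_sites[j] - pos)
            if d < best_d:
                best, best_d = ttaa_sites[j], d
    return best


def call_sites(
    alignments: list[Alignment],
    genome: SyntheticGenome,
    side: str,
    library_id: str,
    tolerance: int = 2,
) -> tuple[list[InsertionSite], int]:
    """Collapse one side's alignments for one library into TTAA sites.

    The junction coordinate is the ITR-adjacent fragment end: pos0 for a
    plus-strand alignment, pos0 + matched_len - 1 for minus. It is snapped
    to the nearest TTAA start within ``tolerance`` bp; alignments that fail
    the snap are dropped and counted (second return value). Transposon
    orientation follows the alignment strand on the PB5 side and its
    opposite on the PB3 side.
    """
    if side not in ("PB5", "PB3"):
        raise ValidationError(f"side must be PB5 or PB3, got {side!r}")
    flip = {"+": "-", "-": "+"}
    by_key: dict[tuple[str, int, str], InsertionSite] = {}
    dropped = 0
    for aln in alignments:
        junction = aln.pos0 if aln.strand == "+" else aln.pos0 + aln.matched_len - 1
        ttaa = _snap_to_ttaa(junction, genome.ttaa_sites, tolerance)
        if ttaa is None:
            dropped += 1
            continue
        orientation = aln.strand if side == "PB5" else flip[aln.strand]
        key = (aln.chrom, ttaa, orientation)
        site = by_key.get(key)
        if site is None:
            site = InsertionSite(aln.chrom, ttaa, orientation)
            by_key[key] = site
        site.side_support[side] += 1
        site.read_count[library_id] = site.read_count.get(library_id, 0) + 1
    return sorted(by_key.values(), key=lambda s: (s.chrom, s.pos0, s.orientation)), dropped


def merge_sites(*site_lists: list[InsertionSite]) -> list[InsertionSite]:
    """Aggregate sites from several calls (sides / libraries) by coordinate."""
    by_key: dict[tuple[str, int, str], InsertionSite] = {}
    for sites in site_lists:
        for s in sites:
            key = (s.chrom, s.pos0, s.orientation)
            tgt = by_key.get(key)
            if tgt is None:
                by_key[key] = InsertionSite(
                    s.chrom, s.pos0, s.orientation,
                    dict(s.side_support), dict(s.read_count),
                )
            else:
                for side, n in s.side_support.items():
                    tgt.side_support[side] = tgt.side_support.get(side, 0) + n
                for lib, n in s.read_count.items():
                    tgt.read_count[lib] = tgt.read_count.get(lib, 0) + n
    return sorted(by_key.values(), key=lambda s: (s.chrom, s.pos0, s.orientation))


def sites_to_bed(sites: list[InsertionSite], path) -> None:
    """BED6: name = site id, score = total reads, strand = orientation."""
    with open(path, "w") as fh:
        for i, s in enumerate(sites):
            fh.write(
                f"{s.chrom}\t{s.pos0}\t{s.pos0 + 4}\tsite{i + 1}\t"
                f"{s.total_reads}\t{s.orientation}\n"
            )


# ---------------------------------------------------------------------------
# gene counts and library summaries
# ---------------------------------------------------------------------------


def assign_to_genes(
    sites: list[InsertionSite],
    genes,
    library_sizes: dict[str, int] | pd.Series,
) -> GeneCountMatrix:
    """Per-gene, per-library read counts from called sites.

    A site contributes its reads to every gene whose span contains the TTAA
    start; orientation is recorded on the site but not filtered here. Only
    genes with at least one read in at least one library appear in the
    matrix. ``library_sizes`` should be the total mapped junction reads per
    library (aligned-read totals, not site totals).
    """
    library_sizes = pd.Series(library_sizes)
    libs = list(library_sizes.index)
    rows: dict[str, dict[str, int]] = {}
    gene_list = sorted(genes, key=lambda g: g.start)
    for s in sites:
        for g in gene_list:
            if g.chrom == s.chrom and g.contains(s.pos0):
                row = rows.setdefault(g.gene_id, {lib: 0 for lib in libs})
                for lib, n in s.read_count.items():
                    row[lib] = row.get(lib, 0) + n
    counts = pd.DataFrame.from_dict(rows, orient="index").reindex(columns=libs).fillna(0)
    counts = counts.sort_index()
    return GeneCountMatrix(counts, library_sizes)


def normalize_cpm(matrix: GeneCountMatrix) -> pd.DataFrame:
    """Counts per million mapped reads: counts / library_size * 1e6."""
    sizes = matrix.library_sizes
    if (sizes <= 0).any():
        raise ValidationError("library sizes must be positive for CPM")
    return matrix.counts / sizes * 1e6


def library_correlation(
    matrix: GeneCountMatrix,
) -> tuple[pd.DataFrame, list[str]]:
    """Pairwise Pearson r on log2(CPM + 0.5), plus a dendrogram leaf order.

    Average-linkage hierarchical clustering on distance 1 - r. A
    zero-variance library yields r = 0 against everything (with a warning)
    rather than NaN.
    """
    libs = matrix.library_ids
    if len(libs) < 2:
        raise ValidationError("need at least two libraries for correlation")
    x = np.log2(normalize_cpm(matrix).to_numpy() + 0.5)
    n = len(libs)
    corr = np.eye(n)
    sd = x.std(axis=0)
    if (sd == 0).any():
        warnings.warn("zero-variance library; correlations set to 0", stacklevel=2)
    for i in range(n):
        for j in range(i + 1, n):
            if sd[i] == 0 or sd[j] == 0:
                r = 0.0
            else:
                r = float(np.corrcoef(x[:, i], x[:, j])[0, 1])
            corr[i, j] = corr[j, i] = r
    corr_df = pd.DataFrame(corr, index=libs, columns=libs)
    dist = squareform(np.clip(1.0 - corr, 0.0, None), checks=False)
    link = hierarchy.linkage(dist, method="average")
    order = [libs[i] for i in hierarchy.leaves_list(link)]
    return corr_df, order
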