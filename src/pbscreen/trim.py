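"""Splinkerette junction-read processing.

Recognizes the PB5'/PB3' inverted-terminal-repeat tag at the 5' end of each
junction read, strips the tag and any read-through adapter, and emits the
genomic flank fragment used for insertion-site mapping. Rejections are
values with machine-readable reasons, never exceptions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import pysam

from pbscreen.errors import ConfigError, ParseError
from pbscreen.synthetic import ADAPTER, PB3_TAG, PB5_TAG

#: minimum exact overlap for an adapter prefix hanging off the read end;
#: 1 trims a lone first adapter base, as read-through truncated by the read
#: length can leave arbitrarily little adapter
ADAPTER_MIN_OVERLAP = 1

REJECT_REASONS = ("no_tag", "too_short", "adapter_only")


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


@dataclass
class TagLibraryConfig:
    """ITR tag and adapter sequences plus matching stringency.

    Tags must be mutually distinguishable: their Hamming distance over the
    shorter tag length must exceed twice ``max_tag_mismatches`` so that no
    read prefix can match both tags within tolerance.
    """

    pb5_tag: str = PB5_TAG
    pb3_tag: str = PB3_TAG
    adapter: str = ADAPTER
    max_tag_mismatches: int = 2
    min_flank_len: int = 20

    def __post_init__(self) -> None:
        if not self.pb5_tag or not self.pb3_tag or not self.adapter:
            raise ConfigError("tags and adapter must be non-empty")
        if self.pb5_tag == self.pb3_tag:
            raise ConfigError("PB5 and PB3 tags must be distinct")
        if self.min_flank_len < 1:
            raise ConfigError("min_flank_len must be >= 1")
        if self.max_tag_mismatches < 0:
            raise ConfigError("max_tag_mismatches must be >= 0")
        n = min(len(self.pb5_tag), len(self.pb3_tag))
        dist = _hamming(self.pb5_tag[:n], self.pb3_tag[:n])
        if dist < 2 * self.max_tag_mismatches + 1:
            raise ConfigError(
                f"tags are ambiguous: Hamming distance {dist} over the first "
                f"{n} bases allows a read to match both within "
                f"{self.max_tag_mismatches} mismatches"
            )


@dataclass(frozen=True)
class TagMatch:
    side: str
    length: int
    mismatches: int


@dataclass(frozen=True)
class JunctionFragment:
    """Genomic flank recovered from one junction read."""

    read_id: str
    side: str
    genomic_seq: str
    tag_mismatches: int


@dataclass(frozen=True)
class Rejection:
    read_id: str
    reason: str


@dataclass
class QCSummary:
    """Per-reason rejection counts and per-side acceptance totals."""

    total: int = 0
    accepted: int = 0
    rejected: dict[str, int] = field(
        default_factory=lambda: {r: 0 for r in REJECT_REASONS}
    )
    per_side: dict[str, int] = field(default_factory=lambda: {"PB5": 0, "PB3": 0})

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("metric\tcount\n")
            fh.write(f"total_reads\t{self.total}\n")
            fh.write(f"accepted\t{self.accepted}\n")
            for reason in REJECT_REASONS:
                fh.write(f"rejected_{reason}\t{self.rejected[reason]}\n")
            for side in ("PB5", "PB3"):
                fh.write(f"accepted_{side}\t{self.per_side[side]}\n")


def detect_pb_tag(read_seq: str, cfg: TagLibraryConfig) -> TagMatch | None:
    """Which ITR tag starts this read, if any.

    Matching is anchored at the read start, Hamming distance only — real
    splinkerette products place the ITR primer at the 5' end, so indel
    tolerance buys nothing. Returns None when neither tag matches within
    ``cfg.max_tag_mismatches``.
    """
    best: TagMatch | None = None
    for side, tag in (("PB5", cfg.pb5_tag), ("PB3", cfg.pb3_tag)):
        if len(read_seq) < len(tag):
            continue
        mm = _hamming(read_seq[: len(tag)], tag)
        if mm <= cfg.max_tag_mismatches and (best is None or mm < best.mismatches):
            best = TagMatch(side, len(tag), mm)
    return best


def find_adapter(seq: str, adapter: str) -> int:
    """Index where adapter read-through begins, or len(seq) if absent.

    Earliest exact occurrence wins; failing that, the earliest occurrence
    with one mismatch; failing that, an exact adapter *prefix* of at least
    ``ADAPTER_MIN_OVERLAP`` bases flush with the read end (short-fragment
    read-through truncated by the read length).
    """
    hit = seq.find(adapter)
    if hit != -1:
        return hit
    la = len(adapter)
    # pigeonhole: a <=1-mismatch occurrence matches one adapter half exactly
    half = la // 2
    candidates: set[int] = set()
    for part, offset in ((adapter[:half], 0), (adapter[half:], half)):
        p = seq.find(part)
        while p != -1:
            start = p - offset
            if 0 <= start <= len(seq) - la:
                candidates.add(start)
            p = seq.find(part, p + 1)
    for i in sorted(candidates):
        if _hamming(seq[i : i + la], adapter) <= 1:
            return i
    max_ov = min(la - 1, len(seq))
    for ov in range(max_ov, ADAPTER_MIN_OVERLAP - 1, -1):
        if seq.endswith(adapter[:ov]):
            return len(seq) - ov
    return len(seq)


def trim_junction_read(
    read_id: str, read_seq: str, cfg: TagLibraryConfig
) -> JunctionFragment | Rejection:
    """Strip the ITR tag and adapter, keeping the genomic flank."""
    match = detect_pb_tag(read_seq, cfg)
    if match is None:
        return Rejection(read_id, "no_tag")
    rest = read_seq[match.length :]
    cut = find_adapter(rest, cfg.adapter)
    frag = rest[:cut]
    if not frag:
        return Rejection(read_id, "adapter_only")
    if len(frag) < cfg.min_flank_len:
        return Rejection(read_id, "too_short")
    return JunctionFragment(read_id, match.side, frag, match.mismatches)


def _read_fastq(path) -> Iterable[tuple[str, str]]:
    i = -1
    try:
        with pysam.FastxFile(str(path)) as fh:
            for i, rec in enumerate(fh):
                yield rec.name, rec.sequence
    except (ValueError, OSError) as exc:
        raise ParseError(f"{path}: malformed FASTQ near record {i + 2}: {exc}") from exc


def process_fastq_pair(
    fastq1,
    fastq2=None,
    cfg: TagLibraryConfig | None = None,
) -> tuple[list[JunctionFragment], QCSummary]:
    """Trim every read-1 record; read 2 is only checked for pairing.

    Only read 1 carries the ITR junction, so site calling uses it alone.
    Conservation holds: accepted + rejected equals the input read count.
    """
    if cfg is None:
        cfg = TagLibraryConfig()
    fragments: list[JunctionFragment] = []
    summary = QCSummary()
    n1 = 0
    for rid, seq in _read_fastq(fastq1):
        n1 += 1
        summary.total += 1
        result = trim_junction_read(rid, seq, cfg)
        if isinstance(result, JunctionFragment):
            fragments.append(result)
            summary.accepted += 1
            summary.per_side[result.side] += 1
        else:
            summary.rejected[result.reason] += 1
    if fastq2 is not None:
        n2 = sum(1 for _ in _read_fastq(fastq2))
        if n2 != n1:
            raise ParseError(
                f"read pairing broken: {n1} records in read 1, {n2} in read 2"
            )
    return fragments, summary


def fragments_to_fasta(fragments: list[JunctionFragment], path) -> None:
    with open(path, "w") as fh:
        for f in fragments:
            fh.write(f">{f.read_id} side={f.side} tag_mm={f.tag_mismatches}\n")
            fh.write(f.genomic_seq + "\n")
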