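"""Raw small-RNA FASTQ -> unique tags with per-sample counts.

The processing chain mirrors standard small-RNA library handling: 3'
adapter trimming, a low-quality-read filter (a read is dropped when more
than ``max_low`` base calls fall below the quality threshold), an insert
length window matching the gel-excision range (17-35 nt), and collapsing
of identical sequences into unique tags carrying per-sample counts.
Collapsing partitions the surviving reads, so tag counts summed per
sample equal the number of surviving reads in that sample exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import pandas as pd

from ._seq import read_fastq

DEFAULT_Q_THRESHOLD = 20  # Phred score a base call must reach to count as "good"
DEFAULT_MAX_LOW = 3       # more than this many sub-threshold calls -> discard
DEFAULT_MIN_LEN = 17
DEFAULT_MAX_LEN = 35
DEFAULT_MIN_OVERLAP = 6
DEFAULT_MAX_MISMATCH_RATE = 0.10


@dataclass(frozen=True)
class SmallRNARead:
    sequence: str
    qualities: tuple[int, ...]
    sample_id: str = ""
    trimmed: bool = False

    def __post_init__(self):
        if len(self.sequence) != len(self.qualities):
            raise ValueError("sequence and qualities differ in length")


def trim_adapter(
    read: SmallRNARead,
    adapter: str,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_mismatch_rate: float = DEFAULT_MAX_MISMATCH_RATE,
) -> SmallRNARead:
    """Cut the insert upstream of the best 3' adapter match.

    The adapter prefix is slid over every start position left to right; the
    first (leftmost) window with overlap >= ``min_overlap`` and a mismatch
    fraction <= ``max_mismatch_rate`` wins. Without a qualifying match the
    read is returned unchanged with ``trimmed=False`` so that downstream
    stages can still see it (it will simply fail annotation).
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    seq = read.sequence
    n, m = len(seq), len(adapter)
    for i in range(0, n - min_overlap + 1):
        overlap = min(m, n - i)
        if overlap < min_overlap:
            break
        mismatches = sum(1 for a, b in zip(seq[i : i + overlap], adapter) if a != b)
        if mismatches <= max_mismatch_rate * overlap:
            return replace(
                read, sequence=seq[:i], qualities=read.qualities[:i], trimmed=True
            )
    return read


def quality_filter(
    read: SmallRNARead,
    q_threshold: int = DEFAULT_Q_THRESHOLD,
    max_low: int = DEFAULT_MAX_LOW,
) -> bool:
    """Keep unless the read has more than ``max_low`` calls below threshold."""
    if max_low < 0:
        raise ValueError("max_low must be >= 0")
    return sum(1 for q in read.qualities if q < q_threshold) <= max_low


def length_filter(
    read: SmallRNARead, min_len: int = DEFAULT_MIN_LEN, max_len: int = DEFAULT_MAX_LEN
) -> bool:
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    return min_len <= len(read.sequence) <= max_len


def collapse_reads(reads) -> dict[str, dict[str, int]]:
    """Collapse an iterable of trimmed/filtered reads into unique tags.

    Returns ``{sequence: {sample id: count}}``. Output is independent of
    input order and exactly conserves read counts per sample.
    """
    tags: dict[str, dict[str, int]] = {}
    for read in reads:
        counts = tags.setdefault(read.sequence, {})
        counts[read.sample_id] = counts.get(read.sample_id, 0) + 1
    return tags


def process_reads(
    reads,
    adapter: str,
    q_threshold: int = DEFAULT_Q_THRESHOLD,
    max_low: int = DEFAULT_MAX_LOW,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_mismatch_rate: float = DEFAULT_MAX_MISMATCH_RATE,
) -> tuple[dict[str, dict[str, int]], pd.DataFrame]:
    """Run trim -> quality filter -> length filter -> collapse.

    Returns the tag dictionary plus a per-sample accounting table with
    columns total / post_quality / post_length / unique (the read-count
    bookkeeping usually reported alongside small-RNA libraries).
    """
    surviving = []
    acct: dict[str, dict[str, int]] = {}
    for read in reads:
        row = acct.setdefault(
            read.sample_id, {"total": 0, "post_quality": 0, "post_length": 0}
        )
        row["total"] += 1
        if not quality_filter(read, q_threshold, max_low):
            continue
        row["post_quality"] += 1
        trimmed = trim_adapter(read, adapter, min_overlap, max_mismatch_rate)
        if not length_filter(trimmed, min_len, max_len):
            continue
        row["post_length"] += 1
        surviving.append(trimmed)
    tags = collapse_reads(surviving)
    summary = pd.DataFrame.from_dict(acct, orient="index").sort_index()
    uniques = {s: 0 for s in summary.index}
    for counts in tags.values():
        for s in counts:
            uniques[s] += 1
    summary["unique"] = pd.Series(uniques)
    return tags, summary


def process_fastq_files(sample_paths: dict[str, str | Path], adapter: str, **kwargs):
    """Process one FASTQ file per sample id; see :func:`process_reads`."""

    def _reads():
        for sample_id, path in sample_paths.items():
            for _, seq, quals in read_fastq(path):
                yield SmallRNARead(seq, tuple(quals), sample_id)

    return process_reads(_reads(), adapter, **kwargs)


def write_tag_table(path, tags: dict[str, dict[str, int]]) -> None:
    """Write collapsed tags as TSV: sequence, one count column per sample."""
    samples = sorted({s for c in tags.values() for s in c})
    df = pd.DataFrame.from_dict(tags, orient="index", columns=samples).fillna(0).astype(int)
    df = df.sort_index()
    df.index.name = "sequence"
    df.to_csv(path, sep="\t")
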