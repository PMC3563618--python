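"""IsomiR-aware assignment of unique small-RNA tags to known miRNAs.

Mature miRNAs are excised from their precursor hairpins with some
heterogeneity in the Drosha/Dicer cut sites, so a single miRNA is observed
as a family of terminal variants ("isomiRs"): 5'/3' trimmings, templated
extensions into the precursor, and non-templated single-base 3' additions.
Ignoring these variants undercounts the miRNA and misstates its abundance,
so assignment here enumerates every admissible terminal variant of each
reference mature sequence and matches tags by exact lookup. Tags with
internal mismatches stay unassigned and are candidates for novel-hairpin
discovery.

Variant labels
--------------
``canonical``            tag equals the reference mature sequence
``trim5:k`` / ``trim3:k``  k bases removed from the 5'/3' end
``ext5:k`` / ``ext3:k``    k templated bases added (read from the precursor)
``ntadd3:B``             one non-templated base B appended at the 3' end
                         (B differs from the precursor's templated
                         continuation, or no continuation exists)

Labels combine with ``|`` (e.g. ``trim3:1|ntadd3:A``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from ._seq import normalize

DEFAULT_WINDOW5 = 2
DEFAULT_WINDOW3 = 3
DEFAULT_MAX_NTADD = 1


@dataclass(frozen=True)
class MiRNAReference:
    """A miRBase-style mature/precursor pair with its genomic locus.

    ``locus`` is (chromosome, start, end), 1-based inclusive; star-strand
    names such as ``hsa-miR-363*`` are plain identifiers.
    """

    name: str
    mature: str
    precursor: str
    locus: tuple[str, int, int] | None = None
    strand: str = "+"

    def __post_init__(self):
        object.__setattr__(self, "mature", normalize(self.mature))
        object.__setattr__(self, "precursor", normalize(self.precursor))
        if self.mature not in self.precursor:
            raise ValueError(f"{self.name}: mature is not a substring of precursor")
        if self.locus is not None and self.locus[2] < self.locus[1]:
            raise ValueError(f"{self.name}: locus end < start")


@dataclass(frozen=True)
class IsomiRCall:
    """Assignment of one tag sequence to one miRNA with a variant label."""

    tag: str
    mirna: str
    variant_label: str
    templated: bool  # False iff the call includes a non-templated 3' addition
    ambiguous: bool = False


def _variant_complexity(d5: int, d3: int, ntadd: str | None) -> tuple:
    """Sort key: prefer canonical, then the fewest/smallest modifications."""
    n_parts = (d5 != 0) + (d3 != 0) + (ntadd is not None)
    return (n_parts, abs(d5) + abs(d3) + (ntadd is not None), d5, d3, ntadd or "")


def enumerate_isomirs(
    ref: MiRNAReference,
    window5: int = DEFAULT_WINDOW5,
    window3: int = DEFAULT_WINDOW3,
    max_ntadd: int = DEFAULT_MAX_NTADD,
) -> dict[str, str]:
    """All admissible isomiR sequences of one reference -> variant label.

    5' offsets range over trims/extensions of at most ``window5`` bases
    (extensions need precursor context upstream of the mature 5' end),
    3' offsets likewise within ``window3``; at most ``max_ntadd``
    non-templated bases may follow the (possibly shifted) 3' end. A
    sequence reachable through several modification paths keeps the
    simplest label.
    """
    if window5 < 0 or window3 < 0 or max_ntadd < 0:
        raise ValueError("isomiR windows must be non-negative")
    if max_ntadd > 1:
        raise NotImplementedError("at most one non-templated 3' addition is supported")
    pre, mat = ref.precursor, ref.mature
    start = pre.find(mat)
    out: dict[str, tuple] = {}  # seq -> (complexity key, label)
    for d5 in range(-window5, window5 + 1):
        s5 = start + d5  # d5 > 0: trim; d5 < 0: templated 5' extension
        if s5 < 0:
            continue
        for d3 in range(-window3, window3 + 1):
            e3 = start + len(mat) + d3  # d3 > 0: templated 3' extension
            if e3 > len(pre) or e3 - s5 < 1:
                continue
            core = pre[s5:e3]
            tail_choices: list[str | None] = [None]
            if max_ntadd:
                templated_next = pre[e3] if e3 < len(pre) else None
                tail_choices += [b for b in "ACGT" if b != templated_next]
            for tail in tail_choices:
                seq = core + tail if tail else core
                key = _variant_complexity(d5, d3, tail)
                parts = []
                if d5 > 0:
                    parts.append(f"trim5:{d5}")
                elif d5 < 0:
                    parts.append(f"ext5:{-d5}")
                if d3 < 0:
                    parts.append(f"trim3:{-d3}")
                elif d3 > 0:
                    parts.append(f"ext3:{d3}")
                if tail:
                    parts.append(f"ntadd3:{tail}")
                label = "|".join(parts) if parts else "canonical"
                if seq not in out or key < out[seq][0]:
                    out[seq] = (key, label)
    return {seq: label for seq, (_, label) in out.items()}


@dataclass
class ReferenceIndex:
    """Exact-lookup index from isomiR sequence to (miRNA, variant label)."""

    refs: dict[str, MiRNAReference]
    lookup: dict[str, list[tuple[str, str]]] = field(repr=False, default_factory=dict)
    window5: int = DEFAULT_WINDOW5
    window3: int = DEFAULT_WINDOW3
    max_ntadd: int = DEFAULT_MAX_NTADD


def build_reference_index(
    refs,
    window5: int = DEFAULT_WINDOW5,
    window3: int = DEFAULT_WINDOW3,
    max_ntadd: int = DEFAULT_MAX_NTADD,
) -> ReferenceIndex:
    by_name: dict[str, MiRNAReference] = {}
    for ref in refs:
        if ref.name in by_name:
            raise ValueError(f"duplicate miRNA name: {ref.name}")
        by_name[ref.name] = ref
    lookup: dict[str, list[tuple[str, str]]] = {}
    for name in sorted(by_name):
        for seq, label in enumerate_isomirs(by_name[name], window5, window3, max_ntadd).items():
            lookup.setdefault(seq, []).append((name, label))
    return ReferenceIndex(by_name, lookup, window5, window3, max_ntadd)


def assign_tag(tag_seq: str, index: ReferenceIndex) -> list[IsomiRCall]:
    """Assign one tag sequence; empty list means unassigned.

    A tag admissible for several miRNAs yields one call per matching
    reference, each flagged ambiguous; downstream tallies then count it
    once per miRNA.
    """
    seq = normalize(tag_seq)
    hits = index.lookup.get(seq, [])
    ambiguous = len(hits) > 1
    return [
        IsomiRCall(seq, name, label, templated="ntadd3" not in label, ambiguous=ambiguous)
        for name, label in hits
    ]


def tally_counts(
    tags: dict[str, dict[str, int]], index: ReferenceIndex
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, dict[str, int]]]:
    """Collapse tag counts into per-miRNA and per-isomiR count matrices.

    Parameters
    ----------
    tags
        ``{tag sequence: {sample id: count}}`` as produced by
        :func:`centomir.preprocess.collapse_reads`.

    Returns
    -------
    (mirna_matrix, isomir_matrix, unassigned)
        ``mirna_matrix``: miRNA x sample integer counts (rows with some
        positive count only). ``isomir_matrix``: rows indexed by
        (miRNA, variant label, sequence, ambiguous). ``unassigned``: tags
        with no call, forwarded to novel discovery.
    """
    samples = sorted({s for counts in tags.values() for s in counts})
    mirna_rows: dict[str, dict[str, int]] = {}
    iso_rows: dict[tuple, dict[str, int]] = {}
    unassigned: dict[str, dict[str, int]] = {}
    for seq in sorted(tags):
        calls = assign_tag(seq, index)
        if not calls:
            unassigned[seq] = dict(tags[seq])
            continue
        for call in calls:
            mrow = mirna_rows.setdefault(call.mirna, {})
            irow = iso_rows.setdefault(
                (call.mirna, call.variant_label, seq, call.ambiguous), {}
            )
            for sample, n in tags[seq].items():
                mrow[sample] = mrow.get(sample, 0) + n
                irow[sample] = irow.get(sample, 0) + n
    mirna_matrix = (
        pd.DataFrame.from_dict(mirna_rows, orient="index", columns=samples)
        .fillna(0)
        .astype(int)
        .sort_index()
    )
    iso_index = pd.MultiIndex.from_tuples(
        sorted(iso_rows), names=["mirna", "variant", "sequence", "ambiguous"]
    ) if iso_rows else pd.MultiIndex.from_tuples([], names=["mirna", "variant", "sequence", "ambiguous"])
    isomir_matrix = (
        pd.DataFrame([iso_rows[k] for k in sorted(iso_rows)], index=iso_index, columns=samples)
        .fillna(0)
        .astype(int)
    )
    return mirna_matrix, isomir_matrix, unassigned


def isomir_composition(
    isomir_matrix: pd.DataFrame, grouping: dict[str, str]
) -> pd.DataFrame:
    """Per-miRNA isomiR percentages within each sample group.

    The percentage of variant v of miRNA m in group g pools reads over the
    group's samples: ``100 * reads(m, v, g) / reads(m, g)``. A miRNA with
    zero pooled reads in a group gets NaN (composition undefined), not 0.
    The dominant variant per (miRNA, group) is flagged; it need not be the
    canonical reference sequence.
    """
    if isomir_matrix.empty:
        return pd.DataFrame(
            columns=["mirna", "variant", "sequence", "group", "percent", "dominant"]
        )
    groups = sorted(set(grouping.values()))
    records = []
    pooled = isomir_matrix.T.groupby(lambda s: grouping[s]).sum().T  # rows x group
    for mirna, block in pooled.groupby(level="mirna"):
        totals = block.sum(axis=0)
        for g in groups:
            total = totals[g]
            if total == 0:
                pct = pd.Series(float("nan"), index=block.index)
            else:
                pct = block[g] / total * 100.0
            top = pct.idxmax() if total > 0 else None
            for key, value in pct.items():
                records.append(
                    {
                        "mirna": mirna,
                        "variant": key[1],
                        "sequence": key[2],
                        "group": g,
                        "percent": value,
                        "dominant": key == top,
                    }
                )
    return pd.DataFrame.from_records(records)
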