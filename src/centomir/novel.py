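"""Novel miRNA hairpin discovery from unassigned tags.

Tags that fail isomiR-aware annotation may come from unannotated miRNA
genes. A genuine miRNA leaves a recognizable footprint: the tag maps to
few genomic locations, the surrounding window folds into a stable
stem-loop (minimum free energy below -25 kcal/mol), the window has
unexceptional GC content, and the supporting reads share a consistent
Drosha/Dicer 5' cut site. This module implements those criteria directly
with a purpose-built single-hairpin folding model:

* candidate precursors are, by construction, single stem-loops, so the
  folding dynamic program considers exactly one hairpin -- nested
  Watson-Crick and GU wobble pairs scored with nearest-neighbor stack
  energies plus hairpin/bulge/internal-loop penalties (no multiloops, no
  dangling ends);
* homology to known precursors is reported (maximum fraction identity by
  edit-distance alignment) but not gated, since the appropriate direction
  of a homology cutoff depends on whether one screens for miRNA-likeness
  or for novelty.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import edlib

from ._seq import gc_fraction, normalize, revcomp, VALID_BASES

DEFAULT_WINDOW = 110  # nt excised around a mapped tag, the usual pre-miRNA scale
DEFAULT_PAD5 = 5      # nt of flank left of the tag in the 5p-arm window
MAX_LOOP_SIDE = 6     # largest bulge/internal-loop side the fold model considers
_INF = float("inf")

# ---------------------------------------------------------------------------
# Nearest-neighbor energy parameters (kcal/mol, 37 C). Watson-Crick stack
# values follow the standard RNA nearest-neighbor table; stacks involving GU
# wobble pairs use flat class averages. Pair strings are DNA-alphabet
# (U normalized to T), read 5'->3' on the left arm: outer pair (i, j),
# inner pair (i+1, j-1).
# ---------------------------------------------------------------------------

_WC_STACK = {
    ("AT", "AT"): -0.93,
    ("AT", "TA"): -1.10,
    ("TA", "AT"): -1.33,
    ("TA", "TA"): -0.93,
    ("AT", "CG"): -2.24,
    ("AT", "GC"): -2.08,
    ("TA", "CG"): -2.35,
    ("TA", "GC"): -2.11,
    ("CG", "AT"): -2.11,
    ("CG", "TA"): -2.08,
    ("GC", "AT"): -2.35,
    ("GC", "TA"): -2.24,
    ("CG", "CG"): -3.26,
    ("CG", "GC"): -2.36,
    ("GC", "CG"): -3.42,
    ("GC", "GC"): -3.26,
}
# Stacks involving GU wobble pairs: markedly weaker than Watson-Crick,
# with tandem 5'GU/UG actually destabilizing. Values are the commonly
# tabulated nearest-neighbor wobble parameters; entries not listed are
# filled in by the strand-reversal symmetry stack(p, q) = stack(q', p')
# with X' the reversed pair.
_GU_STACK = {
    ("AT", "GT"): -0.55,
    ("AT", "TG"): -1.36,
    ("TA", "GT"): -1.00,
    ("TA", "TG"): -0.76,
    ("CG", "GT"): -1.41,
    ("CG", "TG"): -2.11,
    ("GC", "GT"): -1.53,
    ("GC", "TG"): -2.51,
    ("GT", "GT"): -0.25,
    ("GT", "TG"): +0.47,
    ("TG", "GT"): -0.30,
    ("TG", "TG"): -0.25,
}

_PAIRS = {"AT", "TA", "CG", "GC", "GT", "TG"}
_WOBBLE = {"GT", "TG"}


def _rev(pair: str) -> str:
    return pair[::-1]


def stack_energy(outer: str, inner: str) -> float:
    """Free energy of stacking ``inner`` on ``outer`` (both pair strings)."""
    for table in (_WC_STACK, _GU_STACK):
        e = table.get((outer, inner))
        if e is None:
            e = table.get((_rev(inner), _rev(outer)))
        if e is not None:
            return e
    raise KeyError(f"no stack parameters for {outer}/{inner}")


# weakly paired helix ends are penalized, as in the standard
# nearest-neighbor model (per AU/GU pair closing a loop)
_AU_GU_HAIRPIN_CLOSURE = 0.5
_AU_GU_LOOP_CLOSURE = 0.7
_WEAK_CLOSING = {"AT", "TA", "GT", "TG"}


def hairpin_loop_penalty(n: int, closing: str | None = None) -> float:
    table = {3: 5.4, 4: 5.6, 5: 5.7, 6: 5.4, 7: 6.0, 8: 5.5, 9: 6.4}
    e = table[n] if n in table else 6.4 + 1.08 * math.log(n / 9)
    if closing in _WEAK_CLOSING:
        e += _AU_GU_HAIRPIN_CLOSURE
    return e


def internal_loop_penalty(
    n1: int, n2: int, outer: str | None = None, inner: str | None = None
) -> float:
    """Bulge (one side empty) or internal loop initiation penalty, plus a
    closure penalty for each bounding AU/GU pair."""
    if n1 == 0 and n2 == 0:
        raise ValueError("zero-size loop is a stack, not a loop")
    closure = sum(p in _WEAK_CLOSING for p in (outer, inner)) * _AU_GU_LOOP_CLOSURE
    if n1 == 0 or n2 == 0:
        b = n1 + n2
        table = {1: 3.8, 2: 2.8, 3: 3.2, 4: 3.6, 5: 4.0, 6: 4.4}
        return table.get(b, 4.4 + 1.08 * math.log(b / 6)) + closure
    t = n1 + n2
    asym = min(3.0, 0.5 * abs(n1 - n2))
    return 1.7 + 1.08 * math.log(t / 2) + asym + closure


def fold_hairpin(sequence: str) -> tuple[float, str]:
    """Best single-hairpin fold of a candidate precursor.

    Dynamic program over closing pairs: ``E[i][j]`` is the minimum energy
    of a stem-loop closed by pair (i, j), built either directly as a
    hairpin loop (>= 3 unpaired bases) or by placing an inner pair (k, l)
    with at most :data:`MAX_LOOP_SIDE` unpaired bases on either side,
    adding the nearest-neighbor stack energy for contiguous pairs or a
    loop penalty otherwise. The returned MFE is ``min(0, best)`` -- an
    unfoldable sequence reports 0 with an all-dot structure. T and U are
    equivalent.
    """
    seq = normalize(sequence)
    bad = set(seq) - VALID_BASES
    if bad:
        raise ValueError(f"invalid characters in sequence: {sorted(bad)}")
    n = len(seq)
    if n < 40:
        raise ValueError(f"sequence too short to be a precursor ({n} < 40 nt)")
    pairable = [[seq[i] + seq[j] in _PAIRS for j in range(n)] for i in range(n)]
    E: list[dict[int, float]] = [dict() for _ in range(n)]
    back: dict[tuple[int, int], tuple[int, int] | None] = {}
    for span in range(4, n):  # j - i
        for i in range(0, n - span):
            j = i + span
            if not pairable[i][j]:
                continue
            loop = j - i - 1
            outer = seq[i] + seq[j]
            best = hairpin_loop_penalty(loop, outer) if loop >= 3 else _INF
            choice: tuple[int, int] | None = None
            for k in range(i + 1, min(i + 2 + MAX_LOOP_SIDE, j)):
                row = E[k]
                for l in range(max(k + 4, j - 1 - MAX_LOOP_SIDE), j):
                    inner_e = row.get(l)
                    if inner_e is None:
                        continue
                    if k == i + 1 and l == j - 1:
                        cand = inner_e + stack_energy(outer, seq[k] + seq[l])
                    else:
                        cand = inner_e + internal_loop_penalty(
                            k - i - 1, j - l - 1, outer, seq[k] + seq[l]
                        )
                    if cand < best:
                        best, choice = cand, (k, l)
            if best < _INF:
                E[i][j] = best
                back[(i, j)] = choice
    mfe, root = 0.0, None
    for i in range(n):
        for j, e in E[i].items():
            if e < mfe:
                mfe, root = e, (i, j)
    structure = ["."] * n
    node = root
    while node is not None:
        i, j = node
        structure[i], structure[j] = "(", ")"
        node = back[(i, j)]
    return mfe, "".join(structure)


# ---------------------------------------------------------------------------
# Genome mapping and precursor excision
# ---------------------------------------------------------------------------


def map_to_genome(tag_seq: str, genome: dict[str, str], max_loci: int | None = None):
    """Exact-match loci of a tag on both strands, 1-based inclusive.

    Returns a list of (chromosome, start, end, strand). Minus-strand hits
    are positions where the reverse complement of the tag occurs; the
    coordinates refer to the forward genome. ``max_loci`` only bounds the
    search effort (stops at max_loci + 1 hits); the multi-mapping decision
    belongs to :func:`score_candidate`.
    """
    if not genome or all(len(s) == 0 for s in genome.values()):
        raise ValueError("empty genome")
    seq = normalize(tag_seq)
    limit = None if max_loci is None else max_loci + 1
    loci = []
    for strand, query in (("+", seq), ("-", revcomp(seq))):
        for chrom in sorted(genome):
            text = genome[chrom]
            i = text.find(query)
            while i != -1:
                loci.append((chrom, i + 1, i + len(query), strand))
                if limit is not None and len(loci) >= limit:
                    return loci
                i = text.find(query, i + 1)
    return loci


def excise_precursor(
    locus: tuple[str, int, int, str],
    genome: dict[str, str],
    window: int = DEFAULT_WINDOW,
    pad5: int = DEFAULT_PAD5,
):
    """Two candidate precursor windows around a mapped tag.

    One window places the tag on the 5' arm (``pad5`` nt of 5' flank), the
    other on the 3' arm; the caller keeps whichever folds better. Windows
    running past the chromosome ends are truncated and flagged. Each entry
    is (sequence 5'->3', start, end, truncated, arm).
    """
    chrom, start, end, strand = locus
    text = genome[chrom]
    if strand == "+":
        spans = [(start - pad5, start - pad5 + window - 1, "5p"),
                 (end + pad5 - window + 1, end + pad5, "3p")]
    else:
        spans = [(end + pad5 - window + 1, end + pad5, "5p"),
                 (start - pad5, start - pad5 + window - 1, "3p")]
    out = []
    for lo, hi, arm in spans:
        tlo, thi = max(1, lo), min(len(text), hi)
        truncated = (tlo != lo) or (thi != hi)
        seq = text[tlo - 1 : thi]
        if strand == "-":
            seq = revcomp(seq)
        out.append((seq, tlo, thi, truncated, arm))
    return out


# ---------------------------------------------------------------------------
# Candidate scoring
# ---------------------------------------------------------------------------


@dataclass
class DiscoveryThresholds:
    mfe_max: float = -25.0  # accept only folds more stable than this
    gc_bounds: tuple[float, float] = (0.25, 0.75)
    max_loci: int = 5
    min_signature: float = 0.8  # fraction of locus reads sharing a 5' end +-1 nt
    min_reads: int = 10  # total read support required to form a candidate


@dataclass
class HairpinCandidate:
    tag: str
    counts: dict[str, int] = field(default_factory=dict)
    loci: list[tuple[str, int, int, str]] = field(default_factory=list)
    n_loci: int = 0
    precursor_window: str = ""
    window_span: tuple[str, int, int] | None = None
    arm: str = ""
    structure: str = ""
    truncated: bool = False
    mfe: float = 0.0
    gc: float = 0.0
    homology_to_known: float = 0.0
    signature_fraction: float = 1.0
    decision: str = "reject"
    failed: tuple[str, ...] = ()

    @property
    def total_reads(self) -> int:
        return sum(self.counts.values())


def homology_to_known(window: str, known_precursors) -> float:
    """Maximum fraction identity of the window against known precursors,
    from edit distance: 1 - dist / max(len)."""
    best = 0.0
    for ref in known_precursors:
        ref = normalize(ref)
        if not ref:
            continue
        d = edlib.align(normalize(window), ref, task="distance")["editDistance"]
        best = max(best, 1.0 - d / max(len(window), len(ref)))
    return best


def score_candidate(
    candidate: HairpinCandidate, thresholds: DiscoveryThresholds = DiscoveryThresholds()
) -> HairpinCandidate:
    """Apply the acceptance criteria; pure in the criteria fields, so
    re-scoring an already-scored candidate is a no-op."""
    failed = []
    if candidate.n_loci == 0:
        failed.append("unmapped")
    if candidate.n_loci > thresholds.max_loci:
        failed.append("multi-mapping")
    if not candidate.mfe < thresholds.mfe_max:
        failed.append("mfe")
    lo, hi = thresholds.gc_bounds
    if not (lo <= candidate.gc <= hi):
        failed.append("gc")
    if candidate.signature_fraction < thresholds.min_signature:
        failed.append("processing-signature")
    decision = "accept" if not failed else "reject"
    return replace(candidate, decision=decision, failed=tuple(failed))


def discover_novel(
    unassigned: dict[str, dict[str, int]],
    genome: dict[str, str],
    known_precursors=(),
    thresholds: DiscoveryThresholds = DiscoveryThresholds(),
    window: int = DEFAULT_WINDOW,
    pad5: int = DEFAULT_PAD5,
) -> list[HairpinCandidate]:
    """Full discovery pass over unassigned tags.

    Tags with at least ``thresholds.min_reads`` total reads are mapped to
    the genome; each mapped tag yields a candidate whose best-folding
    excision window is scored against the criteria. The processing
    signature pools all candidate tags mapping within 30 nt on the same
    strand and measures the read fraction whose 5' ends agree within
    +-1 nt of the modal cut site.
    """
    eligible = {
        seq: counts
        for seq, counts in unassigned.items()
        if sum(counts.values()) >= thresholds.min_reads
    }
    mapped: dict[str, list] = {
        seq: map_to_genome(seq, genome, thresholds.max_loci) for seq in sorted(eligible)
    }

    def five_prime(locus):
        chrom, start, end, strand = locus
        return (chrom, strand, start if strand == "+" else end)

    # group single-locus tags by proximity of their 5' ends for the signature
    anchors = {
        seq: five_prime(loci[0]) for seq, loci in mapped.items() if len(loci) >= 1
    }
    candidates = []
    for seq in sorted(eligible, key=lambda s: (-sum(eligible[s].values()), s)):
        loci = mapped[seq]
        cand = HairpinCandidate(
            tag=seq, counts=dict(eligible[seq]), loci=loci, n_loci=len(loci)
        )
        if 1 <= len(loci) <= thresholds.max_loci:
            chrom, strand, pos = anchors[seq]
            neighborhood = [
                (anchors[s][2], sum(eligible[s].values()))
                for s in anchors
                if anchors[s][0] == chrom
                and anchors[s][1] == strand
                and abs(anchors[s][2] - pos) <= 30
            ]
            total = sum(c for _, c in neighborhood)
            modal = max(neighborhood, key=lambda pc: (pc[1], -pc[0]))[0]
            near = sum(c for p, c in neighborhood if abs(p - modal) <= 1)
            cand.signature_fraction = near / total if total else 0.0
            windows = excise_precursor(loci[0], genome, window=window, pad5=pad5)
            folded = []
            for wseq, lo, hi, truncated, arm in windows:
                if len(wseq) < 40:
                    continue
                mfe, structure = fold_hairpin(wseq)
                folded.append((mfe, wseq, lo, hi, truncated, arm, structure))
            if folded:
                mfe, wseq, lo, hi, truncated, arm, structure = min(
                    folded, key=lambda t: t[0]
                )
                cand.mfe = mfe
                cand.precursor_window = wseq
                cand.window_span = (loci[0][0], lo, hi)
                cand.truncated = truncated
                cand.arm = arm
                cand.structure = structure
                cand.gc = gc_fraction(wseq)
                if known_precursors:
                    cand.homology_to_known = homology_to_known(wseq, known_precursors)
        candidates.append(score_candidate(cand, thresholds))
    return candidates


def write_candidate_table(path, candidates: list[HairpinCandidate]) -> None:
    """TSV in the usual novel-miRNA report layout: temporary name, genomic
    location, mature sequence, MFE, decision and failed criteria."""
    import pandas as pd

    rows = []
    for i, c in enumerate(candidates, start=1):
        loc = ";".join(f"{ch}:{s}-{e}({st})" for ch, s, e, st in c.loci) or "unmapped"
        rows.append(
            {
                "name": f"sRNA{i}",
                "genomic_location": loc,
                "mature_sequence": c.tag,
                "reads": c.total_reads,
                "mfe_kcal_mol": round(c.mfe, 2),
                "gc_fraction": round(c.gc, 3),
                "homology_to_known": round(c.homology_to_known, 3),
                "arm": c.arm,
                "decision": c.decision,
                "failed_criteria": ",".join(c.failed),
                "structure": c.structure,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
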