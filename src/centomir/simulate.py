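"""Synthetic small-RNA sequencing data with known planted truth.

This module generates every fixture the rest of the pipeline consumes: a
miRBase-style reference (mature + hairpin precursor + genomic locus), raw
FASTQ libraries with planted per-miRNA abundances, isomiR mixtures and
group fold changes, and cross-sectional age-series expression tables. The
defaults emulate a 3-vs-3 small-RNA study design: inserts of 17-35 nt with
a ligated 3' adapter, per-miRNA abundances spanning roughly 10 to 10^6
reads (the multi-decade dynamic range typical of saturated miRNA
sequencing), and an isomiR mixture per miRNA dominated by the canonical
sequence with minor single-base non-templated 3' additions.

Everything is driven by a single integer seed; a fixed seed yields
byte-identical FASTA/FASTQ output across runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seq import revcomp, write_fasta, write_fastq
from .quantify import MiRNAReference

# Illumina small-RNA 3' adapter (TruSeq small RNA kit)
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

# Canonical-dominated mixture with minor 3' non-templated additions,
# patterned on compositions observed for highly expressed miRNAs.
DEFAULT_ISOMIR_PROFILE: tuple[tuple[str, float], ...] = (
    ("canonical", 0.868),
    ("ntadd3:A", 0.093),
    ("ntadd3:T", 0.036),
    ("ntadd3:G", 0.004),
)

DEFAULT_AGE_GROUPS = ("50-60", "70-80", "80-90", ">100")


@dataclass
class SimConfig:
    """Parameters of a synthetic two-group small-RNA experiment."""

    n_mirnas: int = 50
    abundance_range: tuple[float, float] = (10.0, 1e6)  # log-uniform bounds
    # optional separate abundance range for miRNAs carrying planted fold
    # changes (differentially expressed miRNAs are typically of moderate
    # abundance, not the extremes of the dynamic range)
    de_abundance_range: tuple[float, float] | None = None
    isomir_profile: dict[str, tuple[tuple[str, float], ...]] | None = None
    de_plan: tuple[tuple[str, str, float], ...] = ()  # (miRNA, group, fold > 0)
    group_labels: tuple[str, str] = ("control", "centenarian")
    libraries_per_group: int = 3
    reads_per_library: int = 100_000
    adapter: str = DEFAULT_ADAPTER
    read_length_range: tuple[int, int] = (36, 36)  # instrument read length
    mature_length_range: tuple[int, int] = (20, 23)
    precursor_length: int = 110
    error_rate: float = 0.001  # per-base substitution probability
    low_q_fraction: float = 0.0  # fraction of reads given low-quality calls
    low_q_count: int = 4  # number of low-quality calls injected per such read
    seed: int = 0

    def __post_init__(self):
        if self.n_mirnas < 0:
            raise ValueError("n_mirnas must be >= 0")
        lo, hi = self.abundance_range
        if not (0 < lo <= hi):
            raise ValueError("abundance bounds must satisfy 0 < low <= high")
        for mirna, group, fold in self.de_plan:
            if fold <= 0:
                raise ValueError(f"fold change for {mirna} must be > 0, got {fold}")
            if group not in self.group_labels:
                raise ValueError(f"unknown group in de_plan: {group}")
        if self.isomir_profile is not None:
            for mirna, profile in self.isomir_profile.items():
                total = sum(p for _, p in profile)
                if abs(total - 1.0) > 1e-9:
                    raise ValueError(
                        f"isomiR proportions for {mirna} sum to {total}, expected 1"
                    )

    def profile_for(self, mirna: str) -> tuple[tuple[str, float], ...]:
        if self.isomir_profile is None:
            return DEFAULT_ISOMIR_PROFILE
        return self.isomir_profile.get(mirna, DEFAULT_ISOMIR_PROFILE)


@dataclass
class AgeSeriesConfig:
    """Parameters of a synthetic cross-sectional age series."""

    group_labels: tuple[str, ...] = DEFAULT_AGE_GROUPS
    n_per_group: tuple[int, ...] = (5, 5, 5, 12)
    mode: str = "longevity_associated"  # or "age_related", "flat"
    effect_size: float = 0.3  # relative change per age bin
    noise_sd: float = 0.1  # within-group coefficient of variation
    baseline: float = 1.0
    seed: int = 0

    MODES = ("age_related", "longevity_associated", "flat")

    def __post_init__(self):
        if self.mode not in self.MODES:
            raise ValueError(f"mode must be one of {self.MODES}, got {self.mode!r}")
        if len(self.group_labels) != len(self.n_per_group):
            raise ValueError("group_labels and n_per_group lengths differ")
        if any(n < 2 for n in self.n_per_group):
            raise ValueError("each age group needs n >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def generate_reference(
    config: SimConfig,
    chromosome: str = "chr1",
    genome_length: int | None = None,
    name_prefix: str = "syn-miR-",
) -> tuple[list[MiRNAReference], dict[str, str]]:
    """Build a synthetic miRNA reference set and the genome hosting it.

    Each mature sequence (18-25 nt window, default 20-23) is embedded near
    the 5' end of a precursor whose 3' arm is the reverse complement of
    the 5' arm (with two mutations for realism), so the excised window
    folds into a stable hairpin. The base immediately 3' of the mature
    sequence is fixed to C so that A/T/G 3' additions are guaranteed
    non-templated. Precursors are placed at non-overlapping 1-based
    inclusive loci on a single synthetic chromosome, on random strands.
    """
    rng = np.random.default_rng([config.seed, 17])
    refs: list[MiRNAReference] = []
    chrom_parts: list[str] = []
    pos = 0  # 0-based running position
    loop_len = 14
    arm_len = (config.precursor_length - loop_len) // 2
    for i in range(config.n_mirnas):
        mat_len = int(rng.integers(*config.mature_length_range, endpoint=True))
        flank5 = _random_dna(rng, 5)
        mature = _random_dna(rng, mat_len)
        filler = "C" + _random_dna(rng, arm_len - 5 - mat_len - 1)
        arm5 = flank5 + mature + filler
        arm3 = list(revcomp(arm5))
        for j in rng.choice(len(arm3), size=2, replace=False):  # imperfect stem
            arm3[j] = str(rng.choice([b for b in "ACGT" if b != arm3[j]]))
        loop = _random_dna(rng, config.precursor_length - 2 * arm_len)
        precursor = arm5 + loop + "".join(arm3)
        assert len(precursor) == config.precursor_length
        spacer = _random_dna(rng, int(rng.integers(60, 141)))
        chrom_parts.append(spacer)
        pos += len(spacer)
        strand = "+" if rng.random() < 0.5 else "-"
        chrom_parts.append(precursor if strand == "+" else revcomp(precursor))
        start, end = pos + 1, pos + len(precursor)  # 1-based inclusive
        pos += len(precursor)
        refs.append(
            MiRNAReference(
                name=f"{name_prefix}{i + 1}",
                mature=mature,
                precursor=precursor,
                locus=(chromosome, start, end),
                strand=strand,
            )
        )
    chrom_parts.append(_random_dna(rng, 100) if config.n_mirnas else "")
    genome_seq = "".join(chrom_parts)
    if genome_length is not None:
        if genome_length < len(genome_seq):
            raise ValueError(
                f"genome_length {genome_length} too short to host "
                f"{config.n_mirnas} precursors (need {len(genome_seq)})"
            )
        genome_seq += _random_dna(rng, genome_length - len(genome_seq))
    genome = {chromosome: genome_seq} if genome_seq else {}
    return refs, genome


def isomir_sequence(ref: MiRNAReference, label: str) -> str:
    """Realize the sequence of a labelled terminal variant of ``ref``."""
    pre, mat = ref.precursor, ref.mature
    start = pre.find(mat)
    s5, e3, tail = start, start + len(mat), ""
    for part in ([] if label == "canonical" else label.split("|")):
        kind, _, arg = part.partition(":")
        if kind == "trim5":
            s5 += int(arg)
        elif kind == "ext5":
            s5 -= int(arg)
        elif kind == "trim3":
            e3 -= int(arg)
        elif kind == "ext3":
            e3 += int(arg)
        elif kind == "ntadd3":
            tail = arg
        else:
            raise ValueError(f"unknown isomiR label part: {part!r}")
    if s5 < 0 or e3 > len(pre) or e3 - s5 < 1:
        raise ValueError(f"variant {label!r} leaves the precursor of {ref.name}")
    if tail and e3 < len(pre) and pre[e3] == tail:
        raise ValueError(
            f"{ref.name} {label!r}: addition {tail} is templated by the precursor"
        )
    return pre[s5:e3] + tail


def generate_truth(config: SimConfig, refs: list[MiRNAReference]) -> pd.DataFrame:
    """Planted per-miRNA truth: abundance, per-group folds and read shares.

    Abundances are log-uniform over ``config.abundance_range`` (miRNAs
    named in ``de_plan`` redraw from ``de_abundance_range`` when set).
    Fold changes are planted on *normalized read shares* -- the quantity
    the downstream pipeline estimates: a planted miRNA's expected share in
    the named group is its baseline share times the fold, and the
    compensating mass is spread proportionally over the non-planted
    miRNAs (shares must sum to 1, so planting folds on every miRNA's raw
    weight would shrink all realized folds by the compositional shift).
    The per-group sampling weights are returned in ``weight_<group>``
    columns, each summing to 1.
    """
    rng = np.random.default_rng([config.seed, 29])
    names = [r.name for r in refs]
    known = set(names)
    for mirna, _, _ in config.de_plan:
        if mirna not in known:
            raise ValueError(f"de_plan references absent miRNA: {mirna}")
    if config.isomir_profile:
        for mirna in config.isomir_profile:
            if mirna not in known:
                raise ValueError(f"isomir_profile references absent miRNA: {mirna}")
    lo, hi = config.abundance_range
    abundance = np.exp(rng.uniform(math.log(lo), math.log(hi), size=len(names)))
    idx = {n: i for i, n in enumerate(names)}
    planted = sorted({idx[mirna] for mirna, _, _ in config.de_plan})
    if config.de_abundance_range is not None and planted:
        dlo, dhi = config.de_abundance_range
        abundance[planted] = np.exp(
            rng.uniform(math.log(dlo), math.log(dhi), size=len(planted))
        )
    folds = {g: np.ones(len(names)) for g in config.group_labels}
    for mirna, group, fold in config.de_plan:
        folds[group][idx[mirna]] *= fold
    share = abundance / abundance.sum() if len(names) else abundance
    truth = pd.DataFrame({"mirna": names, "abundance": abundance}).set_index("mirna")
    mask = np.zeros(len(names), dtype=bool)
    mask[planted] = True
    for g in config.group_labels:
        q = share * folds[g]
        if mask.any() and not mask.all():
            s_pp, s_qp = share[mask].sum(), q[mask].sum()
            if s_qp >= 1.0:
                raise ValueError(
                    f"planted fold changes in group {g} exceed library capacity"
                )
            q[~mask] = share[~mask] * (1.0 - s_qp) / (1.0 - s_pp)
        if q.sum() > 0:
            q = q / q.sum()
        truth[f"fold_{g}"] = folds[g]
        truth[f"weight_{g}"] = q
    truth["isomir_profile"] = [
        ";".join(f"{lab}={p}" for lab, p in config.profile_for(n)) for n in names
    ]
    return truth


def simulate_library(
    config: SimConfig,
    refs: list[MiRNAReference],
    truth: pd.DataFrame,
    group: str,
    replicate: int,
) -> list[tuple[str, str, str]]:
    """One FASTQ library: (read id, sequence, quality) records.

    Reads are drawn multinomially over (miRNA, isomiR variant) categories
    with weights abundance x group fold x variant proportion, then the 3'
    adapter is appended and the read truncated/padded to the instrument
    read length. Per-base substitution errors occur at ``error_rate``.
    """
    if group not in config.group_labels:
        raise ValueError(f"unknown group label: {group}")
    if not (0 <= replicate < config.libraries_per_group):
        raise ValueError("replicate index out of range")
    gi = config.group_labels.index(group)
    rng = np.random.default_rng([config.seed, 101, gi, replicate])
    by_name = {r.name: r for r in refs}
    cats: list[str] = []
    weights: list[float] = []
    for name, row in truth.iterrows():
        base = row[f"weight_{group}"]
        for label, prop in config.profile_for(name):
            if prop <= 0:
                continue
            cats.append(isomir_sequence(by_name[name], label))
            weights.append(base * prop)
    if config.reads_per_library == 0 or not cats:
        return []
    w = np.asarray(weights)
    counts = rng.multinomial(config.reads_per_library, w / w.sum())
    lo, hi = config.read_length_range
    records: list[tuple[str, str, str]] = []
    i = 0
    for seq, n in zip(cats, counts):
        template = seq + config.adapter
        for _ in range(n):
            read_len = int(rng.integers(lo, hi, endpoint=True)) if hi > lo else lo
            read = (template + "A" * read_len)[:read_len]
            n_err = rng.binomial(read_len, config.error_rate)
            if n_err:
                read_chars = list(read)
                for p in rng.choice(read_len, size=n_err, replace=False):
                    read_chars[p] = str(rng.choice([b for b in "ACGT" if b != read_chars[p]]))
                read = "".join(read_chars)
            qual = ["I"] * read_len
            if config.low_q_fraction and rng.random() < config.low_q_fraction:
                for p in rng.choice(read_len, size=min(config.low_q_count, read_len), replace=False):
                    qual[p] = "#"  # Phred 2
            records.append((f"{group}_{replicate}_{i}", read, "".join(qual)))
            i += 1
    return records


def simulate_experiment(
    config: SimConfig, refs: list[MiRNAReference], truth: pd.DataFrame | None = None
) -> dict[str, list[tuple[str, str, str]]]:
    """All libraries of the two-group design, keyed by sample id."""
    if truth is None:
        truth = generate_truth(config, refs)
    libraries = {}
    for group in config.group_labels:
        for rep in range(config.libraries_per_group):
            libraries[f"{group}_{rep + 1}"] = simulate_library(config, refs, truth, group, rep)
    return libraries


def simulate_age_series(config: AgeSeriesConfig) -> pd.DataFrame:
    """Cross-sectional expression table: columns sample, age_group, value.

    Pre-noise group means by mode (m = baseline, e = effect_size, G bins):

    - ``flat``: all bins m.
    - ``age_related``: m, m(1+e), m(1+e)^2, ... monotone across all bins
      including the oldest.
    - ``longevity_associated``: controls decline geometrically,
      m, m(1-e), m(1-e)^2, ..., while the oldest (longevity) bin returns
      to the youngest bin's mean m -- youthful expression preserved.

    Noise multiplies each individual's mean by 1 + N(0, noise_sd), i.e.
    noise_sd acts as a within-group coefficient of variation.
    """
    rng = np.random.default_rng([config.seed, 43])
    G = len(config.group_labels)
    m, e = config.baseline, config.effect_size
    if config.mode == "flat":
        means = [m] * G
    elif config.mode == "age_related":
        means = [m * (1 + e) ** i for i in range(G)]
    else:  # longevity_associated
        means = [m * (1 - e) ** i for i in range(G - 1)] + [m]
    rows = []
    for label, n, mu in zip(config.group_labels, config.n_per_group, means):
        values = mu * (1 + rng.normal(0.0, config.noise_sd, size=n))
        for j, v in enumerate(values):
            rows.append({"sample": f"{label}_{j + 1}", "age_group": label, "value": float(v)})
    return pd.DataFrame(rows)


def simulate_count_matrix(
    config: SimConfig, refs: list[MiRNAReference] | None = None
) -> tuple[pd.DataFrame, dict[str, str], pd.DataFrame]:
    """Count-level shortcut past read simulation, for experiments where the
    sequence content is irrelevant: multinomial per-library counts with the
    same abundance/fold truth as :func:`simulate_library`.

    Returns (counts miRNA x sample, sample -> group mapping, truth).
    """
    if refs is None:
        names = [f"syn-miR-{i + 1}" for i in range(config.n_mirnas)]
        refs = [
            MiRNAReference(name=n, mature="ACGT", precursor="ACGTACGT") for n in names
        ]
    truth = generate_truth(config, refs)
    groups: dict[str, str] = {}
    data = {}
    for gi, group in enumerate(config.group_labels):
        p = truth[f"weight_{group}"].to_numpy()
        for rep in range(config.libraries_per_group):
            rng = np.random.default_rng([config.seed, 211, gi, rep])
            sample = f"{group}_{rep + 1}"
            data[sample] = rng.multinomial(config.reads_per_library, p)
            groups[sample] = group
    counts = pd.DataFrame(data, index=truth.index)
    return counts, groups, truth


def write_dataset(config: SimConfig, outdir) -> dict[str, object]:
    """Generate and write a complete dataset under ``outdir``.

    Writes mature.fasta, precursors.fasta, genome.fasta, one FASTQ per
    library, a groups.tsv sample sheet, and truth.tsv with the planted
    abundances, folds and isomiR profiles.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    refs, genome = generate_reference(config)
    truth = generate_truth(config, refs)
    write_fasta(outdir / "mature.fasta", [(r.name, r.mature) for r in refs])
    write_fasta(
        outdir / "precursors.fasta",
        [
            (f"{r.name} {r.locus[0]}:{r.locus[1]}-{r.locus[2]}({r.strand})", r.precursor)
            for r in refs
        ],
    )
    write_fasta(outdir / "genome.fasta", genome)
    libraries = simulate_experiment(config, refs, truth)
    groups = {}
    for sample, records in libraries.items():
        write_fastq(outdir / f"{sample}.fastq", records)
        groups[sample] = sample.rsplit("_", 1)[0]
    pd.Series(groups, name="group").rename_axis("sample").to_csv(
        outdir / "groups.tsv", sep="\t"
    )
    truth.to_csv(outdir / "truth.tsv", sep="\t")
    return {"refs": refs, "genome": genome, "truth": truth, "groups": groups}
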