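# centomir

Small RNA-seq miRNA profiling for two-group (e.g. centenarian-vs-control)
B-cell studies: raw FASTQ libraries → unique tags → isomiR-aware miRNA
counts → Fisher-exact differential expression → novel hairpin candidates →
cross-sectional longevity-trajectory classification → seed-match targets
and gene-set over-representation. A first-class synthetic-data generator
produces complete study datasets (reference, genome, FASTQ libraries, age
series) with known planted truth, so every stage is testable end to end.

## The analysis

**Quantification.** Reads are trimmed of the 3′ adapter (leftmost window
with ≥ 6 nt overlap and ≤ 10 % mismatches), dropped when more than 3 base
calls fall below Q20, restricted to 17–35 nt inserts, and collapsed into
unique tags with per-sample counts. Tags are assigned to miRNAs by exact
lookup against the enumerated set of admissible terminal variants
(isomiRs) of each mature sequence: 5′/3′ trimmings and templated
extensions within ±2/±3 nt plus one non-templated 3′ addition. Counting
isomiRs per miRNA matters because the most abundant variant is often not
the canonical reference sequence.

**Differential expression.** Counts are normalized per sample by the
total miRNA-assigned reads. A miRNA is tested only with > 10 reads in at
least half the libraries. For each miRNA *i* the pooled group counts form
a 2×2 table

```
        reads(i, group 1)   reads(other miRNAs, group 1)
        reads(i, group 2)   reads(other miRNAs, group 2)
```

tested with a two-sided Fisher's exact test (exact integer enumeration of
the hypergeometric support for small tables), Bonferroni-corrected over
the *m* miRNAs tested. A call requires adjusted *p* < 0.05 and a fold
change of group mean normalized counts > 2.

**Novel hairpins.** Unassigned tags with ≥ 10 reads are mapped exactly to
the genome (both strands); a 110-nt window is excised with the tag on
either arm, and the better-folding window is scored. Folding uses a
purpose-built single-hairpin dynamic program (nearest-neighbor stacks
over Watson–Crick + GU pairs, hairpin/bulge/internal-loop penalties).
Acceptance requires MFE < −25 kcal/mol, GC fraction within 0.25–0.75,
≤ 5 genomic loci, and a processing signature (≥ 80 % of locus reads share
a 5′ end within ±1 nt, the hallmark of Drosha/Dicer cutting). Homology to
known precursors is reported alongside.

**Trajectories.** Expression across ordered age bins (default 50–60,
70–80, 80–90, > 100 years with n = 5, 5, 5, 12) is classified by
two-sample t-tests as `age_related` (monotone across all bins, endpoints
differ), `longevity_associated` (controls decline monotonically while the
longevity group is indistinguishable from the youngest bin yet differs
from intermediate elderly bins — youthful expression preserved), or
`none`.

**Targets.** Exact seed matches (reverse complement of miRNA bases 2–8;
2–7 available) in 3′ UTRs, keeping genes with ≥ 2 sites and annotating
co-targeting across the query panel; gene-set over-representation by
one-sided hypergeometric test with Bonferroni correction.

## Worked example

```python
from centomir import run_pipeline

results = run_pipeline(
    {"seed": 11,
     "simulate": {"n_mirnas": 40, "reads_per_library": 50_000,
                  "de_plan": [["syn-miR-7", "centenarian", 4.9],
                              ["syn-miR-12", "control", 2.5]],
                  "de_abundance_range": [1e4, 1e5]}},
    "demo",
)
de = results["de"]
print(de[de.significant][["mirna", "up_in", "mean_g1", "mean_g2",
                          "fold_change", "p_bonferroni"]].round(2))
```

prints

```
     mirna       up_in  mean_g1  mean_g2  fold_change  p_bonferroni
 syn-miR-7 centenarian  3484.90   740.27         4.71           0.0
syn-miR-12     control  1239.72  3113.45         2.51           0.0
```

Exactly the two planted miRNAs are recalled among 40, with the correct
directions; the measured folds (4.71, 2.51) estimate the planted
normalized-share folds (4.9, 2.5), and the Bonferroni-adjusted p-values
underflow to 0 at these read depths. `mean_g1`/`mean_g2` are group mean
normalized counts on the mean-library scale (groups ordered
alphabetically: g1 = centenarian, g2 = control). The run directory
`demo/` holds the collapsed tags, read accounting, count matrices,
isomiR composition, the DE table, novel-hairpin candidates and a
provenance manifest; rerunning the same config reproduces every file
byte for byte.

The same stages are available as a CLI:

```bash
centomir simulate --outdir sim --seed 11 --n-mirnas 40
centomir run --config pipeline.yaml --outdir run1
centomir trajectory --table expr.tsv --group-order "50-60,70-80,80-90,>100" --out calls.tsv
```

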