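"""End-to-end pipeline orchestration with a provenance manifest.

Stages run in the fixed order preprocess -> quantify -> diffexp ->
novel discovery, with trajectory classification and target scanning as
optional add-ons. A YAML config (one block per stage) drives everything;
unknown keys are rejected so typos fail loudly. Rerunning the same config
and seed reproduces every output byte for byte; the manifest records the
package version, parameters, and SHA-256 checksums of all inputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from ._seq import read_fasta
from .quantify import MiRNAReference, build_reference_index, isomir_composition, tally_counts
from . import diffexp as de
from . import novel as nv
from . import preprocess as pp
from . import simulate as sim
from . import targets as tg
from . import trajectory as tj

_KNOWN_BLOCKS = {
    "simulate",
    "inputs",
    "preprocess",
    "quantify",
    "diffexp",
    "novel",
    "trajectory",
    "targets",
    "outdir",
    "seed",
}


class ConfigError(ValueError):
    pass


def load_config(path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh) or {}
    unknown = set(config) - _KNOWN_BLOCKS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return config


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _load_references(inputs: dict) -> list[MiRNAReference]:
    mature = read_fasta(inputs["mature_fasta"])
    precursors = read_fasta(inputs["precursor_fasta"])
    refs = []
    for name, mat in mature.items():
        if name not in precursors:
            raise ConfigError(f"mature {name} has no precursor record")
        refs.append(MiRNAReference(name=name, mature=mat, precursor=precursors[name]))
    return refs


def run_pipeline(config: dict, outdir=None) -> dict:
    """Execute the configured stages; returns in-memory stage results.

    Writes to ``outdir`` (or ``config['outdir']``): collapsed tags,
    read-accounting summary, count matrices, isomiR composition, the
    differential-expression table, the novel-candidate table, optional
    trajectory calls and target/enrichment tables, and manifest.json.
    """
    unknown = set(config) - _KNOWN_BLOCKS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    outdir = Path(outdir or config.get("outdir", "centomir_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "parameters": {k: v for k, v in config.items() if k not in ("inputs",)},
        "inputs": {},
        "stages": [],
    }
    results: dict = {}

    if "simulate" in config:
        sim_cfg = sim.SimConfig(seed=seed, **(config["simulate"] or {}))
        simdir = outdir / "simulated"
        dataset = sim.write_dataset(sim_cfg, simdir)
        refs, genome, groups = dataset["refs"], dataset["genome"], dataset["groups"]
        fastqs = {s: simdir / f"{s}.fastq" for s in groups}
        adapter = sim_cfg.adapter
        manifest["stages"].append("simulate")
    else:
        inputs = config.get("inputs")
        if not inputs:
            raise ConfigError("config needs either a 'simulate' or an 'inputs' block")
        for key in ("fastq", "mature_fasta", "precursor_fasta", "groups_tsv"):
            if key not in inputs:
                raise ConfigError(f"inputs block is missing {key!r}")
        for key, value in inputs.items():
            paths = value.values() if isinstance(value, dict) else [value]
            for p in paths:
                if not Path(p).exists():
                    raise ConfigError(f"input file not found: {p}")
                manifest["inputs"][str(p)] = _sha256(Path(p))
        refs = _load_references(inputs)
        genome = read_fasta(inputs["genome_fasta"]) if "genome_fasta" in inputs else {}
        groups = (
            pd.read_csv(inputs["groups_tsv"], sep="\t", index_col=0)["group"].to_dict()
        )
        fastqs = {s: Path(p) for s, p in inputs["fastq"].items()}
        adapter = (config.get("preprocess") or {}).get("adapter", sim.DEFAULT_ADAPTER)

    # --- preprocess ---------------------------------------------------
    pp_cfg = dict(config.get("preprocess") or {})
    pp_cfg.pop("adapter", None)
    tags, summary = pp.process_fastq_files(fastqs, adapter, **pp_cfg)
    pp.write_tag_table(outdir / "tags.tsv", tags)
    summary.rename_axis("sample").to_csv(outdir / "read_accounting.tsv", sep="\t")
    manifest["stages"].append("preprocess")
    results["tags"], results["summary"] = tags, summary

    # --- quantify -----------------------------------------------------
    index = build_reference_index(refs, **(config.get("quantify") or {}))
    counts, iso, unassigned = tally_counts(tags, index)
    counts.rename_axis("mirna").to_csv(outdir / "counts.tsv", sep="\t")
    iso.to_csv(outdir / "isomir_counts.tsv", sep="\t")
    comp = isomir_composition(iso, groups)
    comp.to_csv(outdir / "isomir_composition.tsv", sep="\t", index=False)
    manifest["stages"].append("quantify")
    results.update(counts=counts, isomir=iso, unassigned=unassigned, composition=comp)

    # --- diffexp ------------------------------------------------------
    de_cfg = dict(config.get("diffexp") or {})
    filtered = de.filter_expressed(
        counts,
        min_count=de_cfg.pop("min_count", de.DEFAULT_MIN_COUNT),
        min_fraction=de_cfg.pop("min_fraction", de.DEFAULT_MIN_FRACTION),
    )
    if filtered.shape[0] and len(set(groups.values())) == 2:
        de_table = de.fisher_de(filtered, groups, **de_cfg)
        de.write_de_table(outdir / "differential_expression.tsv", de_table)
        results["de"] = de_table
        manifest["stages"].append("diffexp")

    # --- novel discovery ----------------------------------------------
    nv_cfg = dict(config.get("novel") or {})
    if nv_cfg.pop("enabled", bool(genome)) and genome:
        thresholds = nv.DiscoveryThresholds(**nv_cfg)
        candidates = nv.discover_novel(
            unassigned, genome, [r.precursor for r in refs], thresholds
        )
        nv.write_candidate_table(outdir / "novel_candidates.tsv", candidates)
        results["novel"] = candidates
        manifest["stages"].append("novel")

    # --- trajectory (optional) ----------------------------------------
    tj_cfg = dict(config.get("trajectory") or {})
    if tj_cfg.pop("enabled", False):
        table = pd.read_csv(tj_cfg.pop("table"), sep="\t")
        calls = tj.classify_table(table, **tj_cfg)
        calls.to_csv(outdir / "trajectory_calls.tsv", sep="\t", index=False)
        results["trajectory"] = calls
        manifest["stages"].append("trajectory")

    # --- targets (optional) -------------------------------------------
    tg_cfg = dict(config.get("targets") or {})
    if tg_cfg.pop("enabled", False):
        utrs = read_fasta(tg_cfg.pop("utr_fasta"))
        query = tg_cfg.pop("mirnas", None)
        matures = {
            r.name: r.mature for r in refs if query is None or r.name in query
        }
        gmt = tg_cfg.pop("gene_sets_gmt", None)
        hits = tg.scan_targets(matures, utrs, **tg_cfg)
        tg.write_hits_table(outdir / "target_hits.tsv", hits)
        results["targets"] = hits
        if gmt:
            sets = tg.read_gmt(gmt)
            enr = tg.enrichment_test({h.gene for h in hits}, sets, utrs.keys())
            tg.write_enrichment_table(outdir / "target_enrichment.tsv", enr)
            results["enrichment"] = enr
        manifest["stages"].append("targets")

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str, sort_keys=True)
    results["manifest"] = manifest
    return results
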