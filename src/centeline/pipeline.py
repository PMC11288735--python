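"""End-to-end orchestration: simulate -> mine -> tsd -> date -> target -> chip.

Each stage reads only the previous stages' in-memory products and writes its
outputs under stable filenames in the run directory, so a run is fully
reproducible from its echoed configuration and seed.  All randomness derives
from one global seed via fixed per-stage offsets, so disabling one stage
does not perturb the draws of another.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

from . import chipseq, dating, junctions, mining, targeting
from .errors import ConfigError, StageError
from .seqio import write_bed, write_fasta, write_gff3
from .simulate import SimConfig, simulate, simulate_reads, truth_to_frame

log = logging.getLogger("centeline")

#: fixed per-stage seed offsets (all derived streams stay below 2**31)
STAGE_SEED_OFFSET = {"simulate": 0, "reads": 101, "target": 202}

_KNOWN_SECTIONS = {
    "seed",
    "stages",
    "simulate",
    "mine",
    "tsd",
    "date",
    "target",
    "nest",
    "chip",
}
_DEFAULT_STAGES = ["simulate", "mine", "tsd", "date", "target", "nest", "chip"]


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    unknown = set(cfg) - _KNOWN_SECTIONS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    sim_fields = {f.name for f in dataclasses.fields(SimConfig)}
    bad = set(cfg.get("simulate", {})) - sim_fields - {"enrichment_fold", "n_chip", "n_input"}
    if bad:
        raise ConfigError(f"unknown simulate keys: {sorted(bad)}")


def _stage_seed(seed: int, stage: str) -> int:
    return (seed + STAGE_SEED_OFFSET.get(stage, 0)) % (2**31 - 1)


def run_pipeline(
    config: dict | None = None,
    outdir: str | Path = "centeline_run",
    seed: int = 0,
) -> dict[str, Any]:
    """Run the enabled stages and return the summary report dictionary."""
    config = dict(config or {})
    validate_config(config)
    stages = config.get("stages", _DEFAULT_STAGES)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", seed))

    effective = {"seed": seed, "stages": stages, **{k: v for k, v in config.items() if k not in ("seed", "stages")}}
    with open(outdir / "config_used.yaml", "w") as fh:
        yaml.safe_dump(effective, fh, sort_keys=True)

    report: dict[str, Any] = {"seed": seed}
    sim = None

    def _fail(stage: str, exc: Exception) -> None:
        raise StageError(f"stage '{stage}' failed: {exc}") from exc

    # -- simulate -----------------------------------------------------------
    if "simulate" in stages:
        try:
            sim_kwargs = dict(config.get("simulate", {}))
            reads_kwargs = {
                "enrichment_fold": sim_kwargs.pop("enrichment_fold", 30.0),
                "n_chip": sim_kwargs.pop("n_chip", 100_000),
                "n_input": sim_kwargs.pop("n_input", 100_000),
            }
            sim_cfg = SimConfig(seed=_stage_seed(seed, "simulate"), **sim_kwargs)
            sim = simulate(sim_cfg)
            log.info("simulate: %d insertions planted", len(sim.truth))
            write_fasta(list(sim.genome), outdir / "genome.fa")
            write_fasta([("reference", sim.master.sequence)], outdir / "reference.fa")
            write_fasta(sim.donor_library.items(), outdir / "donors.fa")
            write_bed(
                sim.domains.intervals,
                outdir / "domains.bed",
                names=[f"domain{i+1}" for i in range(len(sim.domains.intervals))],
            )
            truth_to_frame(sim.truth).to_csv(outdir / "truth.tsv", sep="\t", index=False)
            chip_reads, input_reads = simulate_reads(
                sim.genome,
                sim.domains,
                seed=_stage_seed(seed, "reads"),
                **reads_kwargs,
            )
            chip_reads.to_csv(outdir / "reads_chip.tsv", sep="\t", index=False)
            input_reads.to_csv(outdir / "reads_input.tsv", sep="\t", index=False)
            report["n_planted"] = len(sim.truth)
        except Exception as exc:  # noqa: BLE001
            _fail("simulate", exc)
    if sim is None:
        raise ConfigError("pipeline currently requires the simulate stage")

    annotations: list[mining.ElementAnnotation] = []

    # -- mine ---------------------------------------------------------------
    if "mine" in stages:
        try:
            mcfg = config.get("mine", {})
            hits = mining.find_element_copies(
                sim.genome,
                sim.master.sequence,
                min_seed=mcfg.get("min_seed", 13),
                min_hit_len=mcfg.get("min_hit_len", 200),
                min_identity=mcfg.get("min_identity", 0.8),
            )
            for i, hit in enumerate(hits):
                annotations.append(
                    mining.classify_element(
                        hit, sim.genome, sim.master, element_id=f"copy{i+1:03d}"
                    )
                )
            write_gff3(
                [
                    (a.interval, "transposable_element", a.gff_attributes())
                    for a in annotations
                ],
                outdir / "elements.gff3",
            )
            counts = pd.Series([a.element_class for a in annotations]).value_counts()
            report["n_mined"] = len(annotations)
            report["copy_number"] = mining.copy_number(annotations)
            report["class_counts"] = counts.to_dict()
            report["pct_orf_intact_full_length"] = _pct(
                [a for a in annotations if a.element_class == "full_length"],
                lambda a: a.orf_status == "intact_both",
            )
            log.info("mine: %d copies", len(annotations))
        except Exception as exc:  # noqa: BLE001
            _fail("mine", exc)

    # -- tsd ----------------------------------------------------------------
    tsd_records: list[mining.TsdRecord] = []
    if "tsd" in stages and annotations:
        try:
            tcfg = config.get("tsd", {})
            for a in annotations:
                left, right = junctions.extract_flanks(sim.genome, a.interval, width=40)
                # flanks reach 2 bp into the interval, so the expected
                # junction offset (inner) is 2
                rec = junctions.detect_tsd(
                    left,
                    right,
                    max_tsd=tcfg.get("max_tsd", 30),
                    min_report=tcfg.get("min_report", 5),
                    slack=tcfg.get("slack", 2),
                    inner=2,
                    element_id=a.element_id,
                )
                if rec is not None:
                    a.tsd = rec
                    tsd_records.append(rec)
            pd.DataFrame(
                [dataclasses.asdict(r) for r in tsd_records]
            ).to_csv(outdir / "tsd.tsv", sep="\t", index=False)
            high = [r for r in tsd_records if r.high_confidence]
            if high:
                junctions.junction_matrix(high, side="five_prime").to_csv(
                    outdir / "junction5.tsv", sep="\t", index=False
                )
                junctions.junction_matrix(high, side="three_prime").to_csv(
                    outdir / "junction3.tsv", sep="\t", index=False
                )
                report["junction_gc_pct"] = round(
                    100.0
                    * junctions.gc_content(
                        [r.flank5 + r.tsd_sequence + r.flank3 for r in high]
                    ),
                    1,
                )
            report["n_tsd_high_confidence"] = len(high)
            report["tsd_mean_length"] = (
                float(np.mean([r.length for r in high])) if high else None
            )
        except Exception as exc:  # noqa: BLE001
            _fail("tsd", exc)

    # -- date ---------------------------------------------------------------
    if "date" in stages and annotations:
        try:
            dcfg = config.get("date", {})
            mu = dcfg.get("mu", dating.DEFAULT_MU)
            full = [a for a in annotations if a.element_class == "full_length"]
            seqs = {a.element_id: sim.genome.fetch(a.interval) for a in full}
            if len(seqs) >= 2:
                ages = dating.estimate_ages(seqs, mu=mu)
                pd.DataFrame([dataclasses.asdict(a) for a in ages]).to_csv(
                    outdir / "ages.tsv", sep="\t", index=False
                )
                age_values = [a.age_years for a in ages]
                dating.age_spectrum(
                    age_values, bin_years=dcfg.get("histogram_bin", 1.0e5)
                ).to_csv(outdir / "age_spectrum.tsv", sep="\t", index=False)
                report["n_dated"] = len(ages)
                report["pct_younger_than_1My"] = dating.percent_below(age_values, 1.0e6)
        except Exception as exc:  # noqa: BLE001
            _fail("date", exc)

    # -- target -------------------------------------------------------------
    if "target" in stages and annotations:
        try:
            gcfg = config.get("target", {})
            ivs = [a.interval for a in annotations]
            relations = [
                targeting.assign_domain_relation(
                    iv, sim.domains, flank=gcfg.get("flank", 20_000)
                )
                for iv in ivs
            ]
            pd.DataFrame(
                {
                    "element_id": [a.element_id for a in annotations],
                    "relation": relations,
                }
            ).to_csv(outdir / "relations.tsv", sep="\t", index=False)
            pct = targeting.percent_in_domains(ivs, sim.domains)
            null = targeting.random_placement_null(
                sim.genome,
                sim.domains,
                ivs,
                n_replicates=gcfg.get("n_replicates", 100),
                seed=_stage_seed(seed, "target"),
            )
            pd.DataFrame({"replicate_pct": null.replicates}).to_csv(
                outdir / "null_replicates.tsv", sep="\t", index=False
            )
            targeting.binned_density(
                ivs, sim.genome, bin_size=gcfg.get("bin", 100_000)
            ).to_csv(outdir / "binned_density.tsv", sep="\t", index=False)
            report["pct_in_domains"] = round(pct, 1)
            report["null_mean_pct"] = round(null.mean, 2)
        except Exception as exc:  # noqa: BLE001
            _fail("target", exc)

    # -- nest ---------------------------------------------------------------
    if "nest" in stages and annotations:
        try:
            ncfg = config.get("nest", {})
            labels = targeting.detect_nested(
                [a.interval for a in annotations],
                sim.donor_library,
                sim.genome,
                flank=ncfg.get("flank", 150),
                min_identity=ncfg.get("min_identity", 0.8),
                min_len=ncfg.get("min_len", 50),
            )
            for a, lab in zip(annotations, labels):
                a.nested_into = lab
            pd.DataFrame(
                {
                    "element_id": [a.element_id for a in annotations],
                    "nested_into": [lab or "" for lab in labels],
                }
            ).to_csv(outdir / "nesting.tsv", sep="\t", index=False)
            report["pct_nested"] = _pct(annotations, lambda a: a.nested_into)
        except Exception as exc:  # noqa: BLE001
            _fail("nest", exc)

    # -- chip ---------------------------------------------------------------
    if "chip" in stages:
        try:
            ccfg = config.get("chip", {})
            chip_reads = pd.read_csv(outdir / "reads_chip.tsv", sep="\t")
            input_reads = pd.read_csv(outdir / "reads_input.tsv", sep="\t")
            chip_track = chipseq.window_density(chip_reads, sim.genome)
            input_track = chipseq.window_density(input_reads, sim.genome)
            islands = chipseq.call_domains(
                chip_track,
                input_track,
                fold_min=ccfg.get("fold_min", 5.0),
                fdr_max=ccfg.get("fdr_max", 0.001),
                gap=ccfg.get("gap", 1),
            )
            write_bed(
                [isl.interval for isl in islands],
                outdir / "islands.bed",
                names=[f"island{i+1}" for i in range(len(islands))],
            )
            jac = [
                max(
                    (chipseq.jaccard(isl.interval, dom) for isl in islands),
                    default=0.0,
                )
                for dom in sim.domains.intervals
            ]
            report["n_islands"] = len(islands)
            report["island_jaccard_mean"] = round(float(np.mean(jac)), 3) if jac else None
        except Exception as exc:  # noqa: BLE001
            _fail("chip", exc)

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def _pct(items, predicate) -> Optional[float]:
    items = list(items)
    if not items:
        return None
    return round(100.0 * sum(1 for x in items if predicate(x)) / len(items), 1)
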