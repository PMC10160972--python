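"""Configuration handling and the end-to-end pipeline.

The pipeline chains the stages simulate -> deconvolve -> score ->
classify -> evo-stats and writes every intermediate as a TSV, plus a
machine-readable JSON summary.  A single YAML configuration file is the
source of truth for a run; it is schema-checked before any work starts
and echoed (with its hash and the seed) into every output header.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__, deconvolve as dec, evostats, io as hio, scoring, simulate as sim
from .library import DomainRegion, enumerate_single_substitutions

log = logging.getLogger("hkscan")

_KNOWN_SECTIONS = {"seed", "outdir", "region", "sort", "truth", "scoring", "evo", "inputs"}


@dataclass
class PipelineConfig:
    """Validated run configuration (see ``load_config``)."""

    seed: int = 0
    outdir: Path = Path("hkscan_out")
    region: Optional[dict] = None  # {"fasta":..., "protein_id":..., "start":..., "nt_fasta":...}
    sort: dict = field(default_factory=dict)
    truth: dict = field(default_factory=dict)
    scoring: dict = field(default_factory=dict)
    evo: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        thresholds = self.scoring.get("thresholds", list(scoring.DEFAULT_THRESHOLDS))
        if any(t <= 1 for t in thresholds):
            raise ValueError("scoring thresholds must exceed 1-fold")
        self.scoring.setdefault("thresholds", thresholds)
        self.scoring.setdefault("norm_mode", "clip")
        self.scoring.setdefault("fi_mode", "linear")
        self.scoring.setdefault("min_reads", dec.DEFAULT_MIN_READS)
        if self.scoring["norm_mode"] not in ("clip", "raw"):
            raise ValueError(f"unknown norm_mode {self.scoring['norm_mode']!r}")
        if self.scoring["fi_mode"] not in ("linear", "literal"):
            raise ValueError(f"unknown fi_mode {self.scoring['fi_mode']!r}")
        for path_key in ("counts", "bins", "alignment_fasta", "species"):
            p = self.inputs.get(path_key)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"inputs.{path_key}: {p} does not exist")

    def as_dict(self) -> dict:
        d = asdict(self)
        d["outdir"] = str(d["outdir"])
        return d


def load_config(path: Optional[str] = None, **overrides) -> PipelineConfig:
    """Load and validate a YAML configuration file.

    Unknown top-level keys are an error (typo safety).  Keyword
    overrides (e.g. from CLI flags) take precedence over the file.
    """
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - _KNOWN_SECTIONS
        if unknown:
            raise ValueError(f"unknown config sections {sorted(unknown)}")
    for k, v in overrides.items():
        if v is None:
            continue
        if k in ("norm_mode", "fi_mode", "min_reads"):
            data.setdefault("scoring", {})[k] = v
        elif k == "thresholds":
            data.setdefault("scoring", {})["thresholds"] = list(v)
        else:
            data[k] = v
    return PipelineConfig(**data)


def resolve_region(cfg: PipelineConfig) -> DomainRegion:
    if cfg.region is None:
        return sim.default_reference_region()
    spec = dict(cfg.region)
    return hio.read_region_fasta(
        spec["fasta"], spec["protein_id"], int(spec["start"]), nt_path=spec.get("nt_fasta")
    )


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage and return the machine-readable summary.

    Writes, under ``cfg.outdir``: ground truth (when simulating), the
    bin-count TSVs, per-variant measurements, cross-talk scores and
    calls, heatmap matrices, evo-stat results, and ``summary.json``.
    """
    out = cfg.outdir
    out.mkdir(parents=True, exist_ok=True)
    conf = cfg.as_dict()
    seed = cfg.seed
    summary: dict = {"version": __version__, "seed": seed, "config_hash": hio.config_hash(conf)}

    def stage(name):
        log.info("stage: %s", name)

    try:
        stage("region")
        region = resolve_region(cfg)
        summary["region"] = {"protein_id": region.protein_id, "start": region.start,
                             "end": region.end, "length": region.length}
        variants = enumerate_single_substitutions(region)
        summary["n_variants"] = len(variants)

        stage("counts")
        truth = None
        if cfg.inputs.get("counts"):
            table = hio.read_count_table(cfg.inputs["counts"], cfg.inputs["bins"])
        else:
            truth = sim.generate_ground_truth(
                region,
                class_fractions=cfg.truth.get("class_fractions"),
                effect_sizes=cfg.truth.get("effect_sizes"),
                seed=seed,
            )
            truth_tsv = truth.true_mu.copy()
            truth_tsv.columns = [f"true_mu_{r}_{c}" for r, c in truth_tsv.columns]
            truth_tsv["class_label"] = truth.class_label.reindex(truth_tsv.index).fillna("WT")
            hio.write_tsv(truth_tsv.reset_index(), out / "ground_truth.tsv", seed=seed, config=conf)
            sort_cfg = sim.SortConfig(seed=seed, **cfg.sort)
            table = sim.simulate_sort_experiment(truth, sort_cfg)
            hio.write_count_table(table, out / "counts.tsv", out / "bins.tsv",
                                  seed=seed, config=conf)

        stage("deconvolve")
        measurements = dec.deconvolve(
            table, min_reads=cfg.scoring["min_reads"], fi_mode=cfg.scoring["fi_mode"]
        )
        hio.write_measurements(measurements, out / "measurements.tsv", seed=seed, config=conf)

        stage("score")
        thresholds = cfg.scoring["thresholds"]
        scores = {}
        calls = {}
        for reporter in sim.NONCOGNATE_REPORTERS:
            s = scoring.crosstalk_scores(
                measurements, reporter, norm_mode=cfg.scoring["norm_mode"],
                min_reads=cfg.scoring["min_reads"],
            )
            scores[reporter] = s
            calls[reporter] = scoring.classify_crosstalk(s, thresholds)
            matrix, _ = scoring.build_position_profiles(s, region)
            hio.write_tsv(matrix.reset_index(), out / f"score_matrix_{reporter}.tsv",
                          seed=seed, config=conf, index=False)
        call_frame = pd.concat(
            {r: pd.concat([scores[r].rename("score"), calls[r]], axis=1)
             for r in sim.NONCOGNATE_REPORTERS},
            names=["reporter", "variant"],
        )
        hio.write_tsv(call_frame.reset_index(), out / "crosstalk_calls.tsv",
                      seed=seed, config=conf)

        stage("classify")
        summary["overlap"] = {}
        for t in thresholds:
            only1, only2, both = scoring.classify_and_overlap(
                calls["CpxR"][t], calls["RstA"][t]
            )
            summary["overlap"][str(t)] = {"CpxR_only": only1, "RstA_only": only2, "both": both}
        summary["cognate_within_5fold"] = scoring.cognate_within_fold_fraction(measurements)
        summary["reduced_fold_induction"] = scoring.reduced_fold_induction_fraction(measurements)

        stage("evostats")
        five = 5.0 if 5.0 in thresholds else thresholds[0]
        ct_mask = calls["CpxR"][five].fillna(False) | calls["RstA"][five].reindex(
            calls["CpxR"].index, fill_value=False
        ).fillna(False)
        ct_labels = list(ct_mask.index[ct_mask])
        if cfg.inputs.get("alignment_fasta"):
            aln = hio.read_alignment(cfg.inputs["alignment_fasta"], cfg.inputs["species"],
                                     cfg.evo.get("reference_id", "reference"))
        else:
            evo_kwargs = {k: v for k, v in cfg.evo.items() if k != "reference_id"}
            aln = sim.simulate_ortholog_alignment(region, ct_labels, seed=seed, **evo_kwargs)
            hio.write_alignment(aln, out / "ortholog_alignment.fasta", out / "species.tsv",
                                seed=seed, config=conf)
        mapping = evostats.map_reference_columns(aln, region)
        both_ids = aln.species.index[aln.species["has_RstBA"] & aln.species["has_CpxAR"]]
        counts = evostats.count_substitutions(aln, mapping, variants, species_filter=both_ids)
        is_ct = pd.Series(False, index=counts.index)
        is_ct.loc[[l for l in ct_labels if l in is_ct.index]] = True
        results = {}
        if is_ct.any() and (~is_ct).any():
            ks, fisher = evostats.constraint_tests(counts, is_ct)
            results["constraint_ks"] = ks
            results["presence_absence_fisher"] = fisher
            summary["constraint_ks"] = {"D": ks.statistic, "p": ks.p_value}
            summary["presence_absence_fisher"] = {"OR": fisher.statistic, "p": fisher.p_value}
        without_ids = aln.species.index.difference(both_ids)
        counts_without = evostats.count_substitutions(
            aln, mapping, variants, species_filter=without_ids
        )
        if ct_labels:
            summary["mean_enrichment_crosstalk"] = float(
                np.mean([
                    evostats.enrichment(counts_without[l], counts[l],
                                        len(without_ids), len(both_ids))
                    for l in ct_labels
                ])
            )
        other_regions = sim.default_other_kinase_regions(region)
        corr = evostats.corresponding_residue_test(
            {r: calls[r][five].fillna(False) for r in sim.NONCOGNATE_REPORTERS},
            region, other_regions,
        )
        results["corresponding_residue"] = corr
        summary["corresponding_residue"] = {"OR": corr.statistic, "p": corr.p_value}
        sp = aln.species
        dup_table = [
            [int((~sp["has_RstBA"] & sp["has_duplication"]).sum()),
             int((~sp["has_RstBA"] & ~sp["has_duplication"]).sum())],
            [int((sp["has_RstBA"] & sp["has_duplication"]).sum()),
             int((sp["has_RstBA"] & ~sp["has_duplication"]).sum())],
        ]
        dup = evostats.fisher_exact(dup_table)
        results["duplication_rstba_fisher"] = dup
        summary["duplication_rstba_fisher"] = {"OR": dup.statistic, "p": dup.p_value}
        hio.write_test_results(results, out / "evostats.tsv", seed=seed, config=conf)

        if truth is not None:
            planted = set(truth.planted_crosstalk("CpxR")) | set(truth.planted_crosstalk("RstA"))
            summary["planted_crosstalk"] = len(planted)

        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        log.info("pipeline complete: %s", out / "summary.json")
        return summary
    except Exception:
        log.exception("pipeline aborted")
        raise
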