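"""End-to-end orchestration: simulate -> count -> IRS -> transitions ->
PTC -> stratified statistics -> JSON report.

One mandatory seed governs every stochastic stage through independently
spawned substreams (``numpy.random.SeedSequence``), so adding a stage
never perturbs the draws of earlier ones.  Stages communicate only
through files written under the run directory; re-running with the same
config and seed reproduces every output byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .io_formats import ValidationError, write_counts, write_report
from .irs import apply_filters, compute_irs
from .ptc import classify_ptc, ptc_enrichment
from .strata import (
    count_ratio_by_size_class,
    epi_enrichment,
    label_strata,
    median_irs_by_size_class,
    ptc_fold,
    exclusive_overlap,
)
from .synthetic import SimulationConfig, simulate_counts, simulate_truth
from .transitions import call_transitions, summarize_transitions

logger = logging.getLogger("iesretention")

__all__ = ["RunConfig", "run", "EXIT_OK", "EXIT_VALIDATION", "EXIT_RUNTIME"]

EXIT_OK, EXIT_VALIDATION, EXIT_RUNTIME = 0, 1, 2


@dataclass
class RunConfig:
    """Thresholds and paths for one pipeline run.

    Defaults follow the study-wide conventions: coverage filter >= 20
    reads, IES length > 25 nt, incomplete-excision threshold IRS > 0.1,
    75% reference confidence interval, alpha 0.05 with Benjamini-Hochberg
    adjustment, small/large boundary at 32 nt, ciliate genetic code.
    """

    out_dir: str = "run"
    seed: int = 0
    irs_threshold: float = 0.1
    ci_level: float = 0.75
    alpha: float = 0.05
    adjust: str = "bh"  # or "none"
    min_reads: int = 20
    min_length: int = 26
    small_max_length: int = 32
    genetic_code: str = "ciliate"
    n_perm: int = 10_000
    mean_coverage: float = 100.0
    f0_condition: str = "F0_25C"
    f1_conditions: tuple = ("F1_25C", "F1_18C", "F1_32C", "F1_25C_HS")
    simulate: bool = True
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "f1_conditions" in raw:
            raw["f1_conditions"] = tuple(raw["f1_conditions"])
        cfg = cls(**raw)
        if sim is not None:
            sim.setdefault("seed", cfg.seed)
            for key in ("baseline_beta", "conditions"):
                if key in sim and isinstance(sim[key], list):
                    sim[key] = tuple(sim[key])
            cfg.simulation = SimulationConfig(**sim)
        return cfg

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError(f"alpha {self.alpha} outside (0, 1)")
        if not 0 < self.ci_level < 1:
            raise ValidationError(f"ci_level {self.ci_level} outside (0, 1)")
        if self.adjust not in ("bh", "none"):
            raise ValidationError(f"unknown adjustment {self.adjust!r}")
        if self.min_reads < 1 or self.min_length < 1 or self.n_perm < 1:
            raise ValidationError("thresholds must be positive")
        if self.genetic_code not in ("ciliate", "standard"):
            raise ValidationError(f"unknown genetic code {self.genetic_code!r}")

    def config_hash(self) -> str:
        """Hash of every analysis-relevant setting (output paths excluded)."""
        blob = dataclasses.asdict(self)
        blob.pop("out_dir", None)
        return hashlib.sha256(
            json.dumps(blob, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _spawned_seed(seed: int, label: str) -> np.random.Generator:
    # stable per-stage substream: hash the label into the spawn key
    key = int(hashlib.sha256(label.encode()).hexdigest()[:8], 16)
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


def run(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the report dict.

    All stage outputs land under ``config.out_dir``; the JSON report
    aggregates every statistic together with the thresholds applied.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info(
        "run start: seed=%d hash=%s irs_threshold=%g ci_level=%g alpha=%g "
        "adjust=%s min_reads=%d min_length=%d small_max_length=%d code=%s n_perm=%d",
        config.seed, config.config_hash(), config.irs_threshold, config.ci_level,
        config.alpha, config.adjust, config.min_reads, config.min_length,
        config.small_max_length, config.genetic_code, config.n_perm,
    )

    if not config.simulate:
        raise ValidationError(
            "file-based runs need the per-stage CLI; the run() orchestrator "
            "drives the simulated cohort"
        )

    # --- simulate ------------------------------------------------------------
    sim_cfg = config.simulation
    truth = simulate_truth(sim_cfg, seed=config.seed)
    truth.write_fixtures(out / "fixtures")

    # --- counts and IRS per condition ----------------------------------------
    conditions = (config.f0_condition,) + tuple(config.f1_conditions)
    counts = {}
    filtered = {}
    for cond in conditions:
        rng = _spawned_seed(config.seed, f"counts:{cond}")
        cc = simulate_counts(truth, cond, config.mean_coverage, seed=rng)
        write_counts(cc, out / f"counts_{cond}.tsv")
        counts[cond] = cc
        records = [compute_irs(c) for c in cc]
        filtered[cond] = apply_filters(
            records, truth.ies_loci, min_reads=config.min_reads, min_length=config.min_length
        )

    def passed(cond):
        return {r.ies_id: r for r in filtered[cond] if r.passed_filters}

    # --- transitions per F1 line ----------------------------------------------
    f0_pass = passed(config.f0_condition)
    transitions = {}
    for cond in config.f1_conditions:
        f1_pass = passed(cond)
        shared = set(f0_pass) & set(f1_pass)
        f0c = [c for c in counts[config.f0_condition] if c.ies_id in shared]
        f1c = [c for c in counts[cond] if c.ies_id in shared]
        calls = call_transitions(
            f0c, f1c, level=config.ci_level, alpha=config.alpha, adjust=config.adjust
        )
        transitions[cond] = calls
        with open(out / f"transitions_{cond}.tsv", "w") as fh:
            fh.write("ies_id\tdirection\tp_value_up\tp_value_down\tp_adjusted\tsignificant\n")
            for c in sorted(calls, key=lambda c: c.ies_id):
                fh.write(
                    f"{c.ies_id}\t{c.direction}\t{c.p_value_up:.6g}\t"
                    f"{c.p_value_down:.6g}\t{c.p_adjusted:.6g}\t{int(c.significant)}\n"
                )

    # --- PTC annotation of exon IESs ------------------------------------------
    gene_by_id = {g.gene_id: g for g in truth.genes}
    annotations = {}
    for locus in truth.ies_loci:
        if locus.location_class != "exon":
            continue
        ann = classify_ptc(
            gene_by_id[locus.host_gene_id], locus, truth.mac_genome, config.genetic_code
        )
        annotations[locus.ies_id] = ann
    with open(out / "ptc_annotation.tsv", "w") as fh:
        fh.write("ies_id\thost_gene_id\tconsequence\tframe_shift\tfirst_stop_codon_index\n")
        for ies_id in sorted(annotations):
            a = annotations[ies_id]
            idx = "" if a.first_stop_codon_index is None else a.first_stop_codon_index
            fh.write(f"{a.ies_id}\t{a.host_gene_id}\t{a.consequence}\t{a.frame_shift}\t{idx}\n")

    # --- stratified statistics -------------------------------------------------
    labels = label_strata(
        truth.ies_loci, truth.expression, small_max_length=config.small_max_length
    )
    results: dict = {
        "thresholds": {
            "irs_threshold": config.irs_threshold,
            "ci_level": config.ci_level,
            "alpha": config.alpha,
            "adjust": config.adjust,
            "min_reads": config.min_reads,
            "min_length": config.min_length,
            "small_max_length": config.small_max_length,
            "genetic_code": config.genetic_code,
            "n_perm": config.n_perm,
            "mean_coverage": config.mean_coverage,
        },
        "transitions": {c: summarize_transitions(t) for c, t in transitions.items()},
        "clamp_warnings": truth.clamp_warnings,
    }

    f0_records = filtered[config.f0_condition]
    size_ratios = {}
    medians = {"f0": median_irs_by_size_class(f0_records, labels, irs_threshold=config.irs_threshold)}
    retained_sets = {}
    for cond in config.f1_conditions:
        size_ratios[cond] = count_ratio_by_size_class(
            f0_records,
            filtered[cond],
            labels,
            irs_threshold=config.irs_threshold,
            small_max_length=config.small_max_length,
        )
        medians[cond] = median_irs_by_size_class(
            filtered[cond], labels, irs_threshold=config.irs_threshold
        )
        retained_sets[cond] = {
            r.ies_id
            for r in filtered[cond]
            if r.passed_filters and r.irs is not None and r.irs > config.irs_threshold
        }
    results["count_ratio_by_size_class"] = size_ratios
    results["median_irs_by_size_class"] = medians

    # epi enrichment among retained exon IESs per condition
    exon_background = [l.ies_id for l in truth.ies_loci if l.location_class == "exon"]
    epi_stats = {}
    for cond in config.f1_conditions:
        retained_exon = sorted(retained_sets[cond] & set(exon_background))
        if retained_exon:
            obs, exp, p = epi_enrichment(retained_exon, exon_background, labels, "DCL2/3")
            epi_stats[cond] = {"observed": obs, "expected": exp, "fisher_p": p}
    results["dcl23_enrichment"] = epi_stats

    # PTC fold among retained exon IESs (pooled over shifted conditions)
    shifted = [c for c in config.f1_conditions if c != config.f0_condition.replace("F0", "F1")]
    pooled_retained = set().union(*(retained_sets[c] for c in shifted)) if shifted else set()
    pooled_exon = [i for i in sorted(pooled_retained) if i in annotations]
    n_ptc = sum(1 for i in pooled_exon if annotations[i].ptc_inducing)
    n_free = len(pooled_exon) - n_ptc
    results["ptc_fold_retained_exon"] = ptc_fold(n_ptc, n_free) if pooled_exon else None

    # PTC enrichment of retained small exon IESs vs the small-exon stratum
    small_exon_bg = [
        i for i in exon_background if labels[i].small_or_large == "small"
    ]
    obs_small = [i for i in pooled_exon if labels[i].small_or_large == "small"]
    if obs_small and len(small_exon_bg) > len(obs_small):
        rng = _spawned_seed(config.seed, "ptc_enrichment")
        obs, exp, p = ptc_enrichment(
            obs_small, small_exon_bg, annotations, n_perm=config.n_perm, seed=rng
        )
        results["ptc_enrichment_small_exon"] = {
            "observed": obs, "expected": exp, "p_empirical": p,
        }

    # exclusive overlap of retained sets across shifted lines
    if len(shifted) >= 2:
        control = [c for c in config.f1_conditions if c not in shifted]
        results["exclusive_overlap_shifted"] = exclusive_overlap(
            {c: retained_sets[c] for c in shifted},
            {c: retained_sets[c] for c in control},
            labels,
        )

    metadata = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
    }
    write_report(results, out / "report.json", metadata=metadata)
    logger.info("run complete: %s", out / "report.json")
    return {"metadata": metadata, "results": results}
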