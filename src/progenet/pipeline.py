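"""End-to-end orchestration: simulate -> programs -> overrep -> gsea ->
denovo -> sc profiles, with deterministic, re-runnable outputs.

Every stage writes its table under ``outdir`` and into a
:class:`~progenet.io_formats.ResultsBundle`; re-running with an identical
config reproduces byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import denovo as dn
from . import gsea, overrep, sc_profiles
from .io_formats import GeneSetCollection, ResultsBundle, write_cell_matrix, write_gmt
from .programs import (
    EARLY_LABELS,
    GeneUniverse,
    ProgramPartition,
    call_deg,
    classify_programs,
    partition_by_set,
    split_by_ko,
)
from .synthetic import (
    CONTRASTS,
    DEFAULT_STAGE_PAIRS,
    SimulationConfig,
    simulate_deg_tables,
    simulate_denovo,
    simulate_gene_stats,
    simulate_sc,
    simulate_universe,
)

__all__ = ["PipelineConfig", "run_all", "validate_config", "simulate_inputs"]

log = logging.getLogger("progenet")


@dataclass
class PipelineConfig:
    """One config drives the whole run; the synthetic generator supplies the
    inputs and every stage parameter is explicit."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    outdir: str = "progenet_out"
    alpha_deg: float = 0.05
    alpha_overrep: float = 0.05
    gsea_sidedness: str = "greater"
    gsea_conditioning: list[str] = field(default_factory=list)
    gsea_min_genes: int = 10
    exempt_programs: tuple[str, ...] = ("late",)
    stage_pairs: tuple[tuple[str, str], ...] = DEFAULT_STAGE_PAIRS
    sc_min_frac_genes: float = 0.05
    sc_min_frac_cells: float = 0.05
    n_decoy_terms: int = 5
    decoy_term_size: int = 100

    @property
    def seed(self) -> int:
        return self.simulation.seed

    @classmethod
    def from_dict(cls, raw: Mapping) -> "PipelineConfig":
        data = dict(raw)
        if "simulation" in data:
            data["simulation"] = SimulationConfig.from_dict(data["simulation"])
        if "stage_pairs" in data:
            data["stage_pairs"] = tuple(
                (a, b) for a, b in data["stage_pairs"]
            )
        if "exempt_programs" in data:
            data["exempt_programs"] = tuple(data["exempt_programs"])
        return cls(**data)


def validate_config(config: PipelineConfig) -> list[str]:
    """Collect all detectable problems; an empty list means runnable."""
    issues: list[str] = []
    for name in ("alpha_deg", "alpha_overrep"):
        alpha = getattr(config, name)
        if not 0 < alpha <= 1:
            issues.append(f"{name} out of range (0, 1]: {alpha}")
    if config.gsea_sidedness not in ("greater", "two-sided"):
        issues.append(f"unknown gsea_sidedness: {config.gsea_sidedness!r}")
    known_sets = _known_set_names(config.simulation)
    for name in config.gsea_conditioning:
        if name not in known_sets:
            issues.append(f"unknown conditioning set name: {name!r}")
    for name in config.simulation.assoc_effects:
        if name not in known_sets:
            issues.append(f"unknown assoc_effects set name: {name!r}")
    stages = set(config.simulation.sc_celltypes)
    for a, b in config.stage_pairs:
        for stage in (a, b):
            if stage not in stages:
                issues.append(f"stage pair references unknown stage: {stage!r}")
    if config.gsea_min_genes < 2:
        issues.append(f"gsea_min_genes too small: {config.gsea_min_genes}")
    return issues


def _known_set_names(sim: SimulationConfig) -> set[str]:
    names = {"all", "lofi"}
    for program in sim.program_sizes:
        names |= {program, f"{program}^-/-", f"{program}^WTonly"}
    return names


def simulate_inputs(config: PipelineConfig, outdir: Path | None = None):
    """Run all generators; optionally write the input files + ground truth."""
    sim = config.simulation
    universe, truth = simulate_universe(sim)
    deg_tables = simulate_deg_tables(universe, truth, sim)
    stats = simulate_gene_stats(universe, truth, sim)
    denovo_data = simulate_denovo(universe, truth, sim)
    sc = simulate_sc(universe, truth, sim)
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        for contrast, table in deg_tables.items():
            table.table.to_csv(outdir / f"deg_{contrast}.tsv", sep="\t",
                               index=False)
        stats.table.to_csv(outdir / "gene_stats.tsv", sep="\t", index=False)
        pd.DataFrame(
            {"gene_id": universe.genes,
             "mu_lof": [truth.mu[g] for g in universe.genes]}
        ).to_csv(outdir / "rates.tsv", sep="\t", index=False)
        rows = [
            {"cohort": cname, "gene_id": g, "count": c}
            for cname, cohort in denovo_data.cohorts.items()
            for g, c in sorted(cohort.counts.items())
        ]
        pd.DataFrame(rows, columns=["cohort", "gene_id", "count"]).to_csv(
            outdir / "denovo_counts.tsv", sep="\t", index=False)
        pd.DataFrame(
            {"cohort": list(denovo_data.cohorts),
             "n_trios": [c.n_trios for c in denovo_data.cohorts.values()]}
        ).to_csv(outdir / "cohorts.tsv", sep="\t", index=False)
        write_cell_matrix(sc, outdir / "sc_matrix.tsv",
                          outdir / "sc_genes.tsv", outdir / "sc_cells.tsv",
                          outdir / "sc_labels.tsv")
        sets = GeneSetCollection()
        for name in sorted(truth.sets):
            sets.add(name, truth.sets[name], "ground-truth set")
        write_gmt(sets, outdir / "truth_sets.gmt")
        with open(outdir / "ground_truth.json", "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "labels": truth.labels,
                    "ko_down": sorted(truth.ko_down),
                    "lofi": sorted(truth.lofi),
                    "assoc_effects": truth.assoc_effects,
                    "stage_means": truth.stage_means,
                    "stage_order": truth.stage_order,
                },
                fh, indent=1, sort_keys=True,
            )
            fh.write("\n")
    return universe, truth, deg_tables, stats, denovo_data, sc


def _term_collection(
    universe: GeneUniverse,
    program_sets: Mapping[str, frozenset[str]],
    config: PipelineConfig,
) -> GeneSetCollection:
    """Terms for the over-representation stage: estimated program sets, the
    LoFi flag set, and deterministic decoy slices of the gene list."""
    terms = GeneSetCollection()
    for name in sorted(program_sets):
        if program_sets[name]:
            terms.add(f"program:{name}", program_sets[name])
    if universe.flags.get("lofi"):
        terms.add("lofi", universe.flags["lofi"])
    ordered = sorted(universe.genes)
    for i in range(config.n_decoy_terms):
        start = (i * config.decoy_term_size) % max(1, len(ordered))
        decoy = ordered[start:start + config.decoy_term_size]
        if decoy:
            terms.add(f"decoy:{i}", decoy)
    return terms


def run_all(config: PipelineConfig) -> ResultsBundle:
    """Execute all stages in dependency order and write every result table.

    Raises on the first failing stage (the stage name is in the message);
    re-running with the same config is byte-identical.
    """
    issues = validate_config(config)
    if issues:
        raise ValueError("invalid config: " + "; ".join(issues))
    outdir = Path(config.outdir)
    inputs_dir = outdir / "inputs"
    results_dir = outdir / "results"
    results_dir.mkdir(parents=True, exist_ok=True)

    bundle = ResultsBundle(metadata={
        "seed": config.seed,
        "config_hash": _config_hash(config),
    })

    stage = "simulate"
    try:
        log.info("stage=%s seed=%d", stage, config.seed)
        universe, truth, deg_tables, stats, denovo_data, sc = simulate_inputs(
            config, inputs_dir)

        stage = "programs"
        log.info("stage=%s", stage)
        deg_sets = {c: call_deg(deg_tables[c], alpha=config.alpha_deg)
                    for c in CONTRASTS}
        assignment = classify_programs(
            deg_sets["WT_20v30"].up, deg_sets["WT_30v60"].up,
            deg_sets["WT_20v60"].up, universe=universe.genes,
        )
        ko_down = deg_sets["KO_30"].down
        ko_partition = split_by_ko(assignment, ko_down,
                                   exempt=config.exempt_programs)
        early_ko_segments = {
            name: genes for name, genes in ko_partition.segments.items()
            if name.endswith("^-/-") and name.split("^")[0] in EARLY_LABELS
        }
        lofi_partition = partition_by_set(
            universe.flags["lofi"], ProgramPartition(early_ko_segments),
            universe, reference_name="lofi",
        )
        bundle.tables["program_assignment"] = assignment.to_frame()
        bundle.tables["program_partition"] = _partition_frame(ko_partition)
        bundle.tables["lofi_partition"] = _partition_frame(lofi_partition)

        stage = "overrep"
        log.info("stage=%s", stage)
        program_sets = {label: assignment.members(label)
                        for label in sorted(set(assignment.labels.values()))
                        if label != "none"}
        terms = _term_collection(universe, program_sets, config)
        refined = overrep.refine_terms(
            ko_down, terms, universe.genes, alpha=config.alpha_overrep)
        bundle.tables["refined_terms"] = overrep.results_to_frame(refined)

        stage = "gsea"
        log.info("stage=%s", stage)
        conditioning = [truth.sets[name] for name in config.gsea_conditioning]
        enrich = gsea.partition_enrichment(
            stats, ko_partition, conditioning=conditioning,
            sidedness=config.gsea_sidedness, min_genes=config.gsea_min_genes,
        )
        bundle.tables["gsea_enrichment"] = gsea.enrichment_frame(enrich)

        stage = "denovo"
        log.info("stage=%s", stage)
        scan_ko = dn.denovo_partition_scan(
            denovo_data, ko_partition, universe, truth.mu)
        scan_lofi = dn.denovo_partition_scan(
            denovo_data, lofi_partition, universe, truth.mu)
        bundle.tables["denovo_rate_ratios"] = dn.rate_ratio_frame(scan_ko)
        bundle.tables["denovo_lofi_rate_ratios"] = dn.rate_ratio_frame(scan_lofi)

        stage = "scprofile"
        log.info("stage=%s", stage)
        filtered = sc_profiles.filter_genes(
            sc_profiles.filter_cells(sc, config.sc_min_frac_genes),
            config.sc_min_frac_cells,
        )
        zscored = sc_profiles.zscore_genes(filtered)
        means = sc_profiles.celltype_gene_means(zscored)
        profile_rows, test_rows = [], []
        for label, members in sorted(program_sets.items()):
            present = members & set(means.gene_ids)
            if len(present) < 3:
                continue
            profile = sc_profiles.program_profile(means, members)
            for stage_name, mu, sem in zip(profile.stages, profile.mean,
                                           profile.sem):
                profile_rows.append({
                    "program": label, "stage": stage_name, "mean": mu,
                    "sem": sem, "n_genes": profile.n_genes,
                })
            for res in sc_profiles.successive_stage_tests(
                    means, members, pairs=list(config.stage_pairs)):
                test_rows.append({
                    "program": label, "stage_a": res.stage_a,
                    "stage_b": res.stage_b, "t": res.t, "p_raw": res.p_raw,
                    "p_corrected": res.p_corrected, "n_genes": res.n_genes,
                })
        bundle.tables["sc_profiles"] = pd.DataFrame(
            profile_rows,
            columns=["program", "stage", "mean", "sem", "n_genes"])
        bundle.tables["sc_stage_tests"] = pd.DataFrame(
            test_rows,
            columns=["program", "stage_a", "stage_b", "t", "p_raw",
                     "p_corrected", "n_genes"])
    except Exception as exc:
        (results_dir / "FAILED").write_text(f"stage={stage}: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    for name, table in bundle.tables.items():
        table.to_csv(results_dir / f"{name}.tsv", sep="\t", index=False)
    bundle.metadata["bundle_hash"] = bundle_hash(bundle)
    bundle.to_json(results_dir / "bundle.json")
    failed = results_dir / "FAILED"
    if failed.exists():
        failed.unlink()
    return bundle


def bundle_hash(bundle: ResultsBundle) -> str:
    """SHA-256 over all result tables (metadata timestamps excluded)."""
    digest = hashlib.sha256()
    for name in sorted(bundle.tables):
        digest.update(name.encode())
        digest.update(bundle.tables[name].to_csv(sep="\t", index=False).encode())
    return digest.hexdigest()


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(_jsonable(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def _jsonable(obj):
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _jsonable(getattr(obj, k))
                for k in obj.__dataclass_fields__}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def _partition_frame(partition: ProgramPartition) -> pd.DataFrame:
    rows = [
        {"gene_id": gene, "segment": name}
        for name in partition.segments
        for gene in sorted(partition.segments[name])
    ]
    return pd.DataFrame(rows, columns=["gene_id", "segment"])
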