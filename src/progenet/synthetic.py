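"""Linked synthetic inputs with known ground truth.

One integer seed drives independent named substreams (universe, deg, gwas,
denovo, sc) so each generator is a pure function of (config, seed). The
emitted DEG tables encode true program labels through their set algebra, the
gene-level Z-scores carry injected set effects, de novo counts follow
per-gene mutation rates with cohort-specific rate ratios, and the single-cell
matrix realizes configured per-stage program profiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.stats
import yaml

from .denovo import Cohort, DenovoDataset
from .gsea import GeneAssocStats
from .programs import EARLY_LABELS, DEGTable, GeneUniverse
from .sc_profiles import SCExpressionMatrix

__all__ = [
    "SimulationConfig",
    "CohortConfig",
    "GroundTruth",
    "simulate_universe",
    "simulate_deg_tables",
    "simulate_gene_stats",
    "simulate_denovo",
    "simulate_sc",
]

_STREAMS = {"universe": 0, "deg": 1, "gwas": 2, "denovo": 3, "sc": 4}

#: DEG contrast names emitted by :func:`simulate_deg_tables`
CONTRASTS = ("WT_20v30", "WT_30v60", "WT_20v60", "KO_30")

#: ordered fetal cortical stages used by the default single-cell config
DEFAULT_STAGES = ("RG-early", "RG", "IPC", "Transitioning", "Newborn",
                  "Developing")

#: the six stage comparisons tested by default on single-cell profiles
DEFAULT_STAGE_PAIRS = (
    ("RG-early", "RG"),
    ("RG", "IPC"),
    ("RG", "Transitioning"),
    ("IPC", "Transitioning"),
    ("Transitioning", "Newborn"),
    ("Newborn", "Developing"),
)


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[stream],))
    )


@dataclass
class CohortConfig:
    n_trios: int
    rate_ratio_by_segment: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for seg, rho in self.rate_ratio_by_segment.items():
            if rho <= 0:
                raise ValueError(f"rate ratio for {seg!r} must be > 0: {rho}")


def _default_program_sizes() -> dict[str, int]:
    return {"early-transient": 150, "early-stable": 150,
            "early-increasing": 150, "late": 150}


def _default_cohorts() -> dict[str, CohortConfig]:
    return {
        "NDD": CohortConfig(31058, {"early-stable^-/-": 5.0}),
        "ASD": CohortConfig(6430, {"early-stable^-/-": 3.0}),
        "SZ": CohortConfig(3444, {"early-stable^-/-": 1.5}),
        "SIB": CohortConfig(1995, {}),
    }


def _default_sc_celltypes() -> dict[str, int]:
    return {stage: 100 for stage in DEFAULT_STAGES}


def _default_sc_profile() -> dict[str, list[float]]:
    return {
        "early-increasing": [0.0, 0.4, 0.8, 1.2, 1.6, 2.0],
        "early-transient": [0.0, 1.0, 2.0, 1.0, 0.0, -0.5],
        "early-stable": [0.0, 1.0, 1.5, 1.5, 1.5, 1.5],
        "late": [-1.0, -1.0, -0.5, 0.0, 1.0, 2.0],
    }


@dataclass
class SimulationConfig:
    """Knobs for all five generators; see module docstring."""

    n_genes: int = 2000
    program_sizes: dict[str, int] = field(default_factory=_default_program_sizes)
    ko_down_fraction: float = 0.5
    deg_effect: float = 2.0          # |log2FC| driving program membership
    deg_noise_sd: float = 0.1        # log2FC noise
    deg_se: float = 0.2              # per-gene Wald standard error
    assoc_effects: dict[str, float] = field(
        default_factory=lambda: {"early-stable^-/-": 0.6})
    confound_effect: float = 0.0
    lofi_fraction: float = 0.15
    lofi_program_odds: float = 3.0
    cohorts: dict[str, CohortConfig] = field(default_factory=_default_cohorts)
    mu_logmean: float = math.log(2e-6)
    mu_logsd: float = 1.0
    sc_celltypes: dict[str, int] = field(default_factory=_default_sc_celltypes)
    sc_profile: dict[str, list[float]] = field(default_factory=_default_sc_profile)
    dropout: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.program_sizes.values()) > self.n_genes:
            raise ValueError(
                f"program sizes sum to {sum(self.program_sizes.values())} "
                f"> n_genes {self.n_genes}"
            )
        for name, value in (("ko_down_fraction", self.ko_down_fraction),
                            ("lofi_fraction", self.lofi_fraction),
                            ("dropout", self.dropout)):
            if not 0 <= value <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if not self.sc_celltypes:
            raise ValueError("sc_celltypes must list at least one stage")
        n_stages = len(self.sc_celltypes)
        for program, shifts in self.sc_profile.items():
            if len(shifts) != n_stages:
                raise ValueError(
                    f"sc_profile[{program!r}] has {len(shifts)} entries for "
                    f"{n_stages} stages"
                )

    @classmethod
    def from_dict(cls, raw: Mapping) -> "SimulationConfig":
        data = dict(raw)
        if "cohorts" in data:
            data["cohorts"] = {
                name: cfg if isinstance(cfg, CohortConfig) else CohortConfig(**cfg)
                for name, cfg in data["cohorts"].items()
            }
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class GroundTruth:
    """Everything the generators decided, for oracle-style checks."""

    labels: dict[str, str]                  # gene -> program label (or none)
    ko_down: frozenset[str]
    lofi: frozenset[str]
    sets: dict[str, frozenset[str]]         # named sets usable in configs
    assoc_effects: dict[str, float]
    mu: dict[str, float]                    # per-gene LoF mutation rate
    stage_means: dict[str, list[float]]     # program -> per-stage mean shift
    stage_order: list[str]


def simulate_universe(config: SimulationConfig) -> tuple[GeneUniverse, GroundTruth]:
    """Draw gene ids, program labels, KO-down flags, LoFi flags and mutation
    rates; returns the universe plus the full ground truth."""
    rng = _rng(config.seed, "universe")
    width = max(6, len(str(config.n_genes)))
    genes = [f"g{i:0{width}d}" for i in range(1, config.n_genes + 1)]

    order = rng.permutation(config.n_genes)
    labels = {g: "none" for g in genes}
    cursor = 0
    for program in sorted(config.program_sizes):
        size = config.program_sizes[program]
        for idx in order[cursor:cursor + size]:
            labels[genes[idx]] = program
        cursor += size

    ko_down = frozenset(
        g for g in genes
        if labels[g] != "none" and rng.random() < config.ko_down_fraction
    )

    base_odds = config.lofi_fraction / (1 - config.lofi_fraction) \
        if config.lofi_fraction < 1 else math.inf
    lofi: set[str] = set()
    for g in genes:
        odds = base_odds
        if labels[g] in EARLY_LABELS:
            odds *= config.lofi_program_odds
        if rng.random() < odds / (1 + odds):
            lofi.add(g)

    mu = dict(zip(genes, np.exp(
        rng.normal(config.mu_logmean, config.mu_logsd, size=config.n_genes)
    )))

    sets: dict[str, frozenset[str]] = {"all": frozenset(genes),
                                       "lofi": frozenset(lofi)}
    for program in config.program_sizes:
        members = frozenset(g for g in genes if labels[g] == program)
        sets[program] = members
        sets[f"{program}^-/-"] = members & ko_down
        sets[f"{program}^WTonly"] = members - ko_down

    truth = GroundTruth(
        labels=labels,
        ko_down=ko_down,
        lofi=frozenset(lofi),
        sets=sets,
        assoc_effects=dict(config.assoc_effects),
        mu=mu,
        stage_means={p: list(v) for p, v in config.sc_profile.items()},
        stage_order=list(config.sc_celltypes),
    )
    universe = GeneUniverse(
        genes=genes,
        flags={"lofi": frozenset(lofi), "ko_down": ko_down},
    )
    return universe, truth


# true log2FC sign pattern per program for the three WT contrasts
_PATTERN = {
    "early-increasing": {"WT_20v30": 1, "WT_30v60": 1, "WT_20v60": 1},
    "early-stable": {"WT_20v30": 1, "WT_30v60": 0, "WT_20v60": 1},
    "early-transient": {"WT_20v30": 1, "WT_30v60": -1, "WT_20v60": 0},
    "late": {"WT_20v30": 0, "WT_30v60": 1, "WT_20v60": 1},
    "none": {"WT_20v30": 0, "WT_30v60": 0, "WT_20v60": 0},
}


def simulate_deg_tables(
    universe: GeneUniverse,
    truth: GroundTruth,
    config: SimulationConfig,
) -> dict[str, DEGTable]:
    """DEG tables whose up-set algebra encodes the true program labels.

    True log2FC per contrast follows the program's sign pattern at magnitude
    ``deg_effect``; observed log2FC adds Normal(0, deg_noise_sd) noise and the
    p-value is the two-sided normal tail of log2fc / deg_se. The KO contrast
    assigns -deg_effect to true KO-down genes.
    """
    rng = _rng(config.seed, "deg")
    genes = universe.genes
    n = len(genes)
    tables: dict[str, DEGTable] = {}
    for contrast in CONTRASTS:
        if contrast == "KO_30":
            true_lfc = np.array(
                [-config.deg_effect if g in truth.ko_down else 0.0
                 for g in genes]
            )
        else:
            true_lfc = np.array(
                [_PATTERN[truth.labels[g]][contrast] * config.deg_effect
                 for g in genes]
            )
        noise = rng.normal(0.0, config.deg_noise_sd, size=n) \
            if config.deg_noise_sd > 0 else np.zeros(n)
        lfc = true_lfc + noise
        pvals = 2 * scipy.stats.norm.sf(np.abs(lfc) / config.deg_se)
        tables[contrast] = DEGTable(
            contrast=contrast,
            table=pd.DataFrame(
                {"gene_id": genes, "log2fc": lfc, "pvalue": pvals}
            ),
        )
    return tables


def simulate_gene_stats(
    universe: GeneUniverse,
    truth: GroundTruth,
    config: SimulationConfig,
) -> GeneAssocStats:
    """Gene-level Z-scores: sum of injected set effects, an optional stored
    confounder, and standard-normal noise."""
    unknown = set(config.assoc_effects) - set(truth.sets)
    if unknown:
        raise ValueError(
            f"assoc_effects references unknown set(s): {sorted(unknown)}; "
            f"known: {sorted(truth.sets)}"
        )
    rng = _rng(config.seed, "gwas")
    genes = universe.genes
    z = rng.normal(0.0, 1.0, size=len(genes))
    confound = rng.normal(0.0, 1.0, size=len(genes))
    z = z + config.confound_effect * confound
    for set_name, beta in config.assoc_effects.items():
        members = truth.sets[set_name]
        z += beta * np.fromiter((g in members for g in genes), dtype=float,
                                count=len(genes))
    return GeneAssocStats(
        table=pd.DataFrame(
            {"gene_id": genes, "z": z, "cov_confound": confound}
        )
    )


def simulate_denovo(
    universe: GeneUniverse,
    truth: GroundTruth,
    config: SimulationConfig,
) -> DenovoDataset:
    """Per-cohort de novo counts ~ Poisson(2 * n_trios * mu_g * rho(g)), with
    rho the product of the cohort's segment rate-ratio multipliers."""
    rng = _rng(config.seed, "denovo")
    genes = universe.genes
    mu = np.array([truth.mu[g] for g in genes])
    cohorts: dict[str, Cohort] = {}
    for cohort_name in sorted(config.cohorts):
        cc = config.cohorts[cohort_name]
        unknown = set(cc.rate_ratio_by_segment) - set(truth.sets)
        if unknown:
            raise ValueError(
                f"cohort {cohort_name!r} references unknown segment(s): "
                f"{sorted(unknown)}"
            )
        rho = np.ones(len(genes))
        for seg_name, mult in cc.rate_ratio_by_segment.items():
            members = truth.sets[seg_name]
            mask = np.fromiter((g in members for g in genes), dtype=bool,
                               count=len(genes))
            rho[mask] *= mult
        lam = 2.0 * cc.n_trios * mu * rho
        counts = rng.poisson(lam)
        cohorts[cohort_name] = Cohort(
            n_trios=cc.n_trios,
            counts={g: int(c) for g, c in zip(genes, counts) if c > 0},
        )
    return DenovoDataset(cohorts=cohorts)


def simulate_sc(
    universe: GeneUniverse,
    truth: GroundTruth,
    config: SimulationConfig,
) -> SCExpressionMatrix:
    """Stage-labeled TPM matrix with program-shaped per-stage mean shifts.

    log-TPM ~ Normal(shift(program, stage), 1), exponentiated, then zeroed
    with probability ``dropout``.
    """
    rng = _rng(config.seed, "sc")
    genes = universe.genes
    stages = list(config.sc_celltypes)
    for program in config.sc_profile:
        if program not in truth.sets and program != "none":
            raise ValueError(f"sc_profile references unknown program "
                             f"{program!r}")
    shift_by_label = {
        label: np.asarray(shifts, dtype=float)
        for label, shifts in config.sc_profile.items()
    }
    zero = np.zeros(len(stages))
    cell_ids: list[str] = []
    labels: dict[str, str] = {}
    blocks: list[np.ndarray] = []
    gene_shifts = np.stack(
        [shift_by_label.get(truth.labels[g], zero) for g in genes]
    )  # genes x stages
    for j, stage in enumerate(stages):
        n_cells = config.sc_celltypes[stage]
        log_tpm = rng.normal(
            loc=gene_shifts[:, [j]], scale=1.0, size=(len(genes), n_cells)
        )
        tpm = np.exp(log_tpm)
        if config.dropout > 0:
            tpm[rng.random(tpm.shape) < config.dropout] = 0.0
        blocks.append(tpm)
        for k in range(n_cells):
            cid = f"{stage}_c{k:04d}"
            cell_ids.append(cid)
            labels[cid] = stage
    return SCExpressionMatrix(
        values=np.concatenate(blocks, axis=1),
        gene_ids=list(genes),
        cell_ids=cell_ids,
        labels=labels,
        stage_order=stages,
    )
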