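"""Expressed-gene universe, DEG calling and transcriptional-program algebra.

Genes are classified into four programs from the intersections of three
timecourse up-regulation sets, optionally split by knockout down-regulation,
and reference sets (e.g. loss-of-function-intolerant genes) are partitioned
against the resulting segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "PROGRAM_LABELS",
    "GeneUniverse",
    "DEGTable",
    "DEGSets",
    "ProgramAssignment",
    "ProgramPartition",
    "filter_expressed",
    "call_deg",
    "classify_programs",
    "split_by_ko",
    "partition_by_set",
]

#: mutually exclusive trajectory labels; "none" marks unassigned genes
PROGRAM_LABELS = ("early-transient", "early-stable", "early-increasing",
                  "late", "none")

EARLY_LABELS = ("early-transient", "early-stable", "early-increasing")


@dataclass
class GeneUniverse:
    """Ordered, unique gene ids plus named boolean flags per gene."""

    genes: list[str]
    flags: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene ids in universe")
        for name, members in self.flags.items():
            stray = members - set(self.genes)
            if stray:
                raise ValueError(
                    f"flag {name!r} marks genes outside the universe: "
                    f"{sorted(stray)[:5]}"
                )

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.gene_set

    @property
    def gene_set(self) -> frozenset[str]:
        return frozenset(self.genes)

    def flagged(self, name: str) -> frozenset[str]:
        return self.flags[name]


@dataclass
class DEGTable:
    """Per-gene (log2fc, pvalue) records for one contrast."""

    contrast: str
    table: pd.DataFrame  # columns gene_id, log2fc, pvalue

    def __post_init__(self) -> None:
        required = {"gene_id", "log2fc", "pvalue"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"DEG table missing columns: {sorted(missing)}")
        if self.table["gene_id"].duplicated().any():
            dup = self.table["gene_id"][self.table["gene_id"].duplicated()]
            raise ValueError(f"duplicate gene ids: {list(dup.head())}")
        p = self.table["pvalue"].to_numpy(float)
        if ((p < 0) | (p > 1)).any():
            raise ValueError("p-values outside [0, 1]")

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class DEGSets:
    """Bonferroni-significant up/down gene sets for one contrast."""

    up: frozenset[str]
    down: frozenset[str]
    alpha: float
    n_tested: int

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValueError("up and down sets overlap")


@dataclass
class ProgramAssignment:
    """gene_id -> program label; every gene gets exactly one label."""

    labels: dict[str, str]

    def __post_init__(self) -> None:
        bad = {v for v in self.labels.values()} - set(PROGRAM_LABELS)
        if bad:
            raise ValueError(f"unknown program label(s): {sorted(bad)}")

    def members(self, label: str) -> frozenset[str]:
        return frozenset(g for g, l in self.labels.items() if l == label)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene_id": list(self.labels), "label": list(self.labels.values())}
        ).sort_values("gene_id", ignore_index=True)


@dataclass
class ProgramPartition:
    """Named, pairwise-disjoint gene-set segments."""

    segments: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        names = list(self.segments)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                overlap = self.segments[a] & self.segments[b]
                if overlap:
                    raise ValueError(
                        f"segments {a!r} and {b!r} overlap: "
                        f"{sorted(overlap)[:5]}"
                    )

    def union(self) -> frozenset[str]:
        out: frozenset[str] = frozenset()
        for genes in self.segments.values():
            out |= genes
        return out

    def __len__(self) -> int:
        return len(self.segments)


def filter_expressed(
    counts: pd.DataFrame,
    cpm_min: float = 1.0,
    sample_frac: float = 1 / 3,
) -> frozenset[str]:
    """Genes with counts-per-million >= ``cpm_min`` in at least
    ``ceil(sample_frac * n_samples)`` samples.

    ``counts`` is a genes x samples frame indexed by gene id. cpm is computed
    per sample against that sample's library size; a zero-total sample is an
    error. Ties at exactly the threshold are inclusive.
    """
    values = counts.to_numpy(float)
    if values.shape[1] < 1:
        raise ValueError("need at least one sample")
    if (values < 0).any():
        raise ValueError("negative counts")
    libsize = values.sum(axis=0)
    zero = np.flatnonzero(libsize == 0)
    if zero.size:
        raise ValueError(
            f"sample(s) with zero total counts: {list(counts.columns[zero])}"
        )
    cpm = values / libsize * 1e6
    need = int(np.ceil(sample_frac * values.shape[1]))
    keep = (cpm >= cpm_min).sum(axis=1) >= need
    return frozenset(np.asarray(counts.index)[keep])


def call_deg(table: DEGTable, alpha: float = 0.05) -> DEGSets:
    """Split a contrast into Bonferroni-significant up/down sets.

    A gene is significant when ``pvalue * n_tested < alpha`` with ``n_tested``
    the number of genes in the table; the direction is the strict sign of
    log2fc (log2fc == 0 lands in neither set).
    """
    if len(table) == 0:
        raise ValueError(f"empty DEG table for contrast {table.contrast!r}")
    n = len(table)
    df = table.table
    sig = df["pvalue"].to_numpy(float) * n < alpha
    lfc = df["log2fc"].to_numpy(float)
    genes = df["gene_id"].to_numpy()
    return DEGSets(
        up=frozenset(genes[sig & (lfc > 0)]),
        down=frozenset(genes[sig & (lfc < 0)]),
        alpha=alpha,
        n_tested=n,
    )


def classify_programs(
    up_20_30: Iterable[str],
    up_30_60: Iterable[str],
    up_20_60: Iterable[str],
    universe: Iterable[str] | None = None,
) -> ProgramAssignment:
    """Label genes by timecourse set algebra.

    early-increasing = up_20_30 & up_30_60;
    early-stable     = (up_20_30 & up_20_60) - up_30_60;
    early-transient  = up_20_30 - up_20_60 - up_30_60;
    late             = up_30_60 - up_20_30;
    everything else  = none.

    Precedence early-increasing > early-stable > early-transient makes the
    labels provably disjoint.
    """
    a, b, c = frozenset(up_20_30), frozenset(up_30_60), frozenset(up_20_60)
    labels: dict[str, str] = {}
    for g in a | b | c | (frozenset(universe) if universe is not None else frozenset()):
        if g in a and g in b:
            labels[g] = "early-increasing"
        elif g in a and g in c:
            labels[g] = "early-stable"
        elif g in a:
            labels[g] = "early-transient"
        elif g in b:
            labels[g] = "late"
        else:
            labels[g] = "none"
    return ProgramAssignment(labels)


def split_by_ko(
    assignment: ProgramAssignment,
    ko_down: Iterable[str],
    exempt: Iterable[str] = ("late",),
) -> ProgramPartition:
    """Split each program into knocked-down and WT-only segments.

    Non-exempt programs P yield ``P^-/- = P & ko_down`` and
    ``P^WTonly = P - ko_down``; exempt programs (default: late) pass through
    intact. The "none" label is never segmented.
    """
    exempt = set(exempt)
    unknown = exempt - set(PROGRAM_LABELS)
    if unknown:
        raise ValueError(f"unknown exempt label(s): {sorted(unknown)}")
    ko = frozenset(ko_down)
    segments: dict[str, frozenset[str]] = {}
    for label in PROGRAM_LABELS:
        if label == "none":
            continue
        members = assignment.members(label)
        if label in exempt:
            segments[label] = members
        else:
            segments[f"{label}^-/-"] = members & ko
            segments[f"{label}^WTonly"] = members - ko
    return ProgramPartition(segments)


def partition_by_set(
    reference: Iterable[str],
    partition: ProgramPartition | Mapping[str, frozenset[str]],
    universe: GeneUniverse | Iterable[str],
    reference_name: str = "ref",
    include_nonref: bool = True,
) -> ProgramPartition:
    """Partition a reference set against program segments.

    Emits ``<segment>^<ref>`` = reference & segment for every segment, plus
    ``other-<ref>`` = reference genes in no segment, plus (optionally)
    ``<segment>^non-<ref>`` = segment - reference. Segments stay pairwise
    disjoint and jointly cover reference | union(segments).
    """
    ref = frozenset(reference)
    uni = universe.gene_set if isinstance(universe, GeneUniverse) else frozenset(universe)
    stray = ref - uni
    if stray:
        raise ValueError(
            f"reference gene(s) outside the universe: {sorted(stray)[:10]}"
        )
    segs = partition.segments if isinstance(partition, ProgramPartition) else dict(partition)
    out: dict[str, frozenset[str]] = {}
    covered: frozenset[str] = frozenset()
    for name, genes in segs.items():
        out[f"{name}^{reference_name}"] = genes & ref
        if include_nonref:
            out[f"{name}^non-{reference_name}"] = genes - ref
        covered |= genes
    out[f"other-{reference_name}"] = ref - covered
    return ProgramPartition(out)
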