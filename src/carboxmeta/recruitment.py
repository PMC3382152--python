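"""Isolate-genome coverage by best-hit recruitment of metagenome proteins.

Each metagenome protein-coding gene is assigned to at most one isolate
genome — the genome of its highest-identity hit — and a genome's coverage is
the number of such recruited genes relative to the genome's own
protein-coding gene count, as a percentage.  Coverage above 100% indicates
over-recruitment, typically when a metagenome contains several strains of
the species a single reference genome represents.  Recruitment-plot point
data (subject position vs percent identity, colored by identity class) is
emitted for plotting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from ._util import round_half_up

HIT_COLUMNS = ["gene_id", "genome", "subject_gene", "identity_pct", "subject_pos"]


@dataclass(frozen=True)
class HitRecord:
    """Best-hit of one metagenome protein against one isolate genome gene."""

    gene_id: str
    genome: str
    subject_gene: str
    identity_pct: float
    subject_pos: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity_pct <= 100.0):
            raise ValueError("identity_pct must lie in [0, 100]")
        if self.subject_pos < 0:
            raise ValueError("subject_pos must be non-negative")


@dataclass(frozen=True)
class CoverageReport:
    genome: str
    homologs: int
    genome_genes: int
    coverage_pct: int


@dataclass(frozen=True)
class GroupCoverageReport:
    """Coverage range for a species group backed by several isolate genomes."""

    group: str
    homologs: int
    genome_genes_range: tuple[int, int]
    coverage_range: tuple[int, int]


@dataclass(frozen=True)
class RecruitmentPoint:
    subject_pos: int
    identity_pct: float
    identity_class: str  # "30-60" | "60-90" | ">90"


def coverage(homologs: int, genome_genes: int) -> int:
    """Genome coverage percent: round(100 * homologs / genome_genes).

    Rounded to the nearest integer (half up); may exceed 100 when the
    metagenome over-recruits (multiple strains hitting one reference).
    """
    if genome_genes <= 0:
        raise ValueError("genome_genes must be positive")
    if homologs < 0:
        raise ValueError("homologs must be non-negative")
    return int(round_half_up(100.0 * homologs / genome_genes))


def _best_hits(hits: pd.DataFrame) -> pd.DataFrame:
    """One row per metagenome gene: its highest-identity hit.

    Ties are broken deterministically by (identity desc, genome label asc,
    subject_gene asc).
    """
    ordered = hits.sort_values(
        ["gene_id", "identity_pct", "genome", "subject_gene"],
        ascending=[True, False, True, True],
        kind="mergesort",
    )
    return ordered.drop_duplicates(subset="gene_id", keep="first")


def recruit(
    hits: pd.DataFrame,
    genome_catalog: Mapping[str, int],
    min_identity: float = 30.0,
) -> list[CoverageReport]:
    """Coverage report per catalog genome from a best-hit table.

    ``genome_catalog`` maps genome label -> protein-coding gene count.  A
    gene is recruited to the genome of its single best hit, provided that
    hit's identity is >= ``min_identity``; every catalog genome is reported,
    with zero homologs where nothing recruited.
    """
    missing = [c for c in HIT_COLUMNS if c not in hits.columns]
    if missing:
        raise ValueError(f"hit table missing columns: {missing}")
    unknown = set(hits["genome"].unique()) - set(genome_catalog)
    if unknown:
        raise KeyError(f"hit table references unknown genome(s): {sorted(unknown)}")
    if hits.empty:
        counts: Mapping[str, int] = {}
    else:
        best = _best_hits(hits)
        best = best.loc[best["identity_pct"] >= min_identity]
        counts = best.groupby("genome").size().to_dict()
    return [
        CoverageReport(g, int(counts.get(g, 0)), int(n), coverage(int(counts.get(g, 0)), int(n)))
        for g, n in sorted(genome_catalog.items())
    ]


def recruit_groups(
    hits: pd.DataFrame,
    group_catalog: Mapping[str, Mapping[str, int]],
    min_identity: float = 30.0,
) -> list[GroupCoverageReport]:
    """Coverage ranges for species groups with several sequenced isolates.

    ``group_catalog`` maps group label -> {genome label -> gene count}.
    Homologs are deduplicated metagenome genes whose best hit falls on any
    member genome; the coverage range spans the member gene counts (largest
    genome gives the lower bound).
    """
    genome_to_group = {
        genome: grp for grp, members in group_catalog.items() for genome in members
    }
    unknown = set(hits["genome"].unique()) - set(genome_to_group)
    if unknown:
        raise KeyError(f"hit table references unknown genome(s): {sorted(unknown)}")
    reports = []
    if hits.empty:
        grouped: Mapping[str, int] = {}
    else:
        best = _best_hits(hits)
        best = best.loc[best["identity_pct"] >= min_identity]
        grouped = best.groupby(best["genome"].map(genome_to_group)).size().to_dict()
    for grp, members in sorted(group_catalog.items()):
        if not members:
            raise ValueError(f"group {grp!r} has no member genomes")
        h = int(grouped.get(grp, 0))
        lo_genes, hi_genes = min(members.values()), max(members.values())
        reports.append(
            GroupCoverageReport(
                grp, h, (int(lo_genes), int(hi_genes)),
                (coverage(h, hi_genes), coverage(h, lo_genes)),
            )
        )
    return reports


def classify_identity(identity_pct: float) -> str | None:
    """Identity class for recruitment plots; None when identity <= 30."""
    if identity_pct > 90.0:
        return ">90"
    if identity_pct > 60.0:
        return "60-90"
    if identity_pct > 30.0:
        return "30-60"
    return None


def plot_points(hits: pd.DataFrame) -> list[RecruitmentPoint]:
    """Recruitment-plot points for one genome's hits.

    Identity classes are lower-exclusive: (30,60], (60,90], (90,100]; hits
    at or below 30% identity are excluded.
    """
    bad = hits.loc[(hits["identity_pct"] < 0) | (hits["identity_pct"] > 100)]
    if not bad.empty:
        raise ValueError("identities must lie in [0, 100]")
    points = []
    for row in hits.itertuples(index=False):
        cls = classify_identity(row.identity_pct)
        if cls is not None:
            points.append(RecruitmentPoint(int(row.subject_pos), float(row.identity_pct), cls))
    return points


def coverage_frame(reports: Sequence[CoverageReport]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.genome, r.homologs, r.genome_genes, r.coverage_pct) for r in reports],
        columns=["genome", "homologs", "genome_genes", "coverage_pct"],
    )
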