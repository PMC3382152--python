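"""Reading, filtering and profiling of gene functional-annotation tables.

Metagenome annotation pipelines emit one row per (gene, database, category)
assignment with an alignment e-value.  This module applies per-database
e-value cutoffs, builds per-sample category count profiles (the input of the
enrichment test), and produces glycoside-hydrolase (GH) family proportion
tables in the style used to compare lignocellulose-degrading metagenomes.

The expected annotation table is a TSV with columns::

    gene_id  contig_id  db  category  e_value

where ``db`` is one of KEGG, COG, PFAM, EC, GH.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._util import round_half_up

RECOGNIZED_DBS = frozenset({"KEGG", "COG", "PFAM", "EC", "GH"})

#: Default per-database maximum e-values.  The KEGG (1e-5), COG (1e-2) and
#: GH (1e-6) cutoffs follow common practice for BLASTx / RPS-BLAST / CAZy
#: searches of assembled metagenomes; PFAM and EC default to 1e-5.
DEFAULT_EVALUE_CUTOFFS: Mapping[str, float] = {
    "KEGG": 1e-5,
    "COG": 1e-2,
    "GH": 1e-6,
    "PFAM": 1e-5,
    "EC": 1e-5,
}

ANNOTATION_COLUMNS = ["gene_id", "contig_id", "db", "category", "e_value"]


@dataclass(frozen=True)
class GeneAnnotation:
    """One functional assignment of a predicted protein-coding gene."""

    gene_id: str
    contig_id: str
    db: str
    category: str
    e_value: float

    def __post_init__(self) -> None:
        if self.db not in RECOGNIZED_DBS:
            raise ValueError(f"unrecognized annotation database: {self.db!r}")
        if self.e_value < 0:
            raise ValueError("e_value must be non-negative")


@dataclass
class CategoryCountProfile:
    """Per-sample gene counts by functional category for one database.

    ``total`` is the number of (gene, category) assignments, i.e. the
    library size N used as the denominator of the enrichment test.
    """

    sample_label: str
    db: str
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return int(sum(self.counts.values()))

    def __getitem__(self, category: str) -> int:
        return int(self.counts.get(category, 0))


@dataclass
class GhProportionTable:
    """GH family counts and percent-of-total-GH, with an aggregate remainder."""

    rows: pd.DataFrame  # columns: family, count, percent
    other_count: int
    other_percent: float
    total_gh: int

    def to_frame(self) -> pd.DataFrame:
        other = pd.DataFrame(
            [{"family": "All other GH", "count": self.other_count, "percent": self.other_percent}]
        )
        return pd.concat([self.rows, other], ignore_index=True)


def read_annotations(path) -> pd.DataFrame:
    """Read an annotation TSV and validate its columns and databases."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "contig_id": str, "db": str, "category": str})
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation table missing columns: {missing}")
    bad = set(df["db"].unique()) - RECOGNIZED_DBS
    if bad:
        raise ValueError(f"unrecognized annotation databases: {sorted(bad)}")
    return df[ANNOTATION_COLUMNS]


def write_annotations(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def filter_annotations(
    annotations: pd.DataFrame,
    cutoffs: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Keep annotations whose e-value passes the cutoff of their database.

    A row is retained iff ``e_value <= cutoffs[db]``; input order is
    preserved.  Every database present in the table must have a cutoff.
    """
    if cutoffs is None:
        cutoffs = DEFAULT_EVALUE_CUTOFFS
    for db, cut in cutoffs.items():
        if cut <= 0:
            raise ValueError(f"cutoff for {db} must be positive, got {cut}")
    present = set(annotations["db"].unique())
    unknown = present - set(cutoffs)
    if unknown:
        raise KeyError(f"no e-value cutoff defined for database(s): {sorted(unknown)}")
    if annotations.empty:
        return annotations.copy()
    limits = annotations["db"].map(cutoffs)
    return annotations.loc[annotations["e_value"] <= limits].copy()


def build_profile(
    annotations: pd.DataFrame,
    sample_label: str,
    db: str,
    depth: Mapping[str, float] | None = None,
) -> CategoryCountProfile:
    """Collapse annotations of one database into a category count profile.

    Each gene contributes one count per *distinct* category it carries
    (duplicate (gene, category) rows are collapsed).  With ``depth`` a
    contig_id -> read-depth map, counts are instead depth-weighted and
    rounded to integers; the default, and the counting unit used throughout,
    is one per gene copy.
    """
    if db not in RECOGNIZED_DBS:
        raise ValueError(f"unrecognized annotation database: {db!r}")
    sub = annotations.loc[annotations["db"] == db]
    dedup = sub.drop_duplicates(subset=["gene_id", "category"])
    if depth is None:
        counts = dedup.groupby("category").size()
    else:
        weights = dedup["contig_id"].map(depth).fillna(1.0)
        counts = weights.groupby(dedup["category"]).sum().round()
    return CategoryCountProfile(
        sample_label=sample_label,
        db=db,
        counts={str(k): int(v) for k, v in counts.items()},
    )


def default_gh_families() -> pd.DataFrame:
    """The shipped GH family set (family, function_group), editable on disk."""
    ref = importlib.resources.files("carboxmeta.resources").joinpath("gh_families.tsv")
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def gh_proportions(
    profile: CategoryCountProfile,
    listed_families: Sequence[str] | None = None,
) -> GhProportionTable:
    """Build a GH family proportion table from a GH count profile.

    Percentages are 100 * count / total_gh, reported half-up to two
    decimals.  Families in ``listed_families`` absent from the profile get
    0; counts of unlisted families are aggregated into "All other GH".
    """
    if profile.db != "GH":
        raise ValueError(f"profile database must be GH, got {profile.db}")
    total = profile.total
    if total == 0:
        raise ValueError("profile contains no GH assignments")
    if listed_families is None:
        listed_families = list(default_gh_families()["family"])
    listed = list(dict.fromkeys(listed_families))  # preserve order, dedupe
    rows = []
    listed_count = 0
    for fam in listed:
        c = profile[fam]
        listed_count += c
        rows.append({"family": fam, "count": c, "percent": round_half_up(100.0 * c / total, 2)})
    other = total - listed_count
    return GhProportionTable(
        rows=pd.DataFrame(rows, columns=["family", "count", "percent"]),
        other_count=other,
        other_percent=round_half_up(100.0 * other / total, 2),
        total_gh=total,
    )


def annotations_from_records(records: Iterable[GeneAnnotation]) -> pd.DataFrame:
    """Convenience: build an annotation table from GeneAnnotation records."""
    return pd.DataFrame(
        [(a.gene_id, a.contig_id, a.db, a.category, a.e_value) for a in records],
        columns=ANNOTATION_COLUMNS,
    )
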