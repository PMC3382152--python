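"""Bin quality control: pangenome completeness, over-binning, function flags.

A taxon bin's completeness is estimated as the fraction of the order-level
pangenome core genes (COGs found in every sequenced genome of the order)
that are detected in the bin.  Over-binning — several strains merged into
one bin — is indicated by conserved single-copy genes (CSCG) appearing in
multiple copies: the duplication score is the fraction of *detected* CSCGs
with multiplicity >= 2.  Fermentation-related capabilities are flagged by
marker-set presence: each function carries one or more alternative KEGG
orthology marker sets, and the flag is raised when any one set is fully
contained in the bin's KO terms (ANY-of across sets, ALL-of within a set).
"""

from __future__ import annotations

import json
import importlib.resources
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from ._util import round_half_up


@dataclass
class BinGeneContent:
    """Gene category content of one bin, with multiplicities."""

    bin_id: str
    gene_categories: Counter = field(default_factory=Counter)
    order_label: str = ""

    @classmethod
    def from_iterable(cls, bin_id: str, categories: Iterable[str], order_label: str = "") -> "BinGeneContent":
        return cls(bin_id, Counter(categories), order_label)


@dataclass(frozen=True)
class PangenomeReference:
    """Order-level core-gene and conserved-single-copy-gene inventories."""

    order_label: str
    core_genes: frozenset
    cscg: frozenset

    def __post_init__(self) -> None:
        if not self.core_genes:
            raise ValueError("core gene set must be non-empty")
        if not self.cscg:
            raise ValueError("CSCG set must be non-empty")


@dataclass(frozen=True)
class BinQcReport:
    bin_id: str
    completeness_pct: float
    duplicated_cscg_pct: float
    function_flags: frozenset


def completeness(bin_content: BinGeneContent, reference: PangenomeReference) -> float:
    """Percent of the order's core genes detected in the bin (2 decimals)."""
    present = sum(1 for g in reference.core_genes if bin_content.gene_categories.get(g, 0) >= 1)
    return round_half_up(100.0 * present / len(reference.core_genes), 2)


def duplicated_cscg(bin_content: BinGeneContent, reference: PangenomeReference) -> float:
    """Percent of detected CSCGs that are duplicated (2 decimals).

    Detected means multiplicity >= 1 in the bin; duplicated means >= 2.
    When no CSCG is detected the score is 0.00 by convention (with a
    warning), since there is no evidence of over-binning.
    """
    detected = [g for g in reference.cscg if bin_content.gene_categories.get(g, 0) >= 1]
    if not detected:
        warnings.warn(
            f"bin {bin_content.bin_id}: no CSCG detected; duplication reported as 0.00",
            stacklevel=2,
        )
        return 0.0
    duplicated = sum(1 for g in detected if bin_content.gene_categories[g] >= 2)
    return round_half_up(100.0 * duplicated / len(detected), 2)


def default_marker_map() -> dict[int, list[frozenset]]:
    """The shipped, illustrative function -> marker-set map (editable JSON)."""
    ref = importlib.resources.files("carboxmeta.resources").joinpath("function_markers.json")
    return parse_marker_map(json.loads(ref.read_text()))


def parse_marker_map(obj: Mapping) -> dict[int, list[frozenset]]:
    """Parse a marker-map JSON object into {function id: [alternative sets]}."""
    functions = obj.get("functions", obj)
    out: dict[int, list[frozenset]] = {}
    for key, val in functions.items():
        if isinstance(key, str) and key.startswith("_"):
            continue
        sets = val["marker_sets"] if isinstance(val, Mapping) else val
        out[int(key)] = [frozenset(s) for s in sets]
    return out


def function_flags(
    ko_terms: Iterable[str],
    marker_map: Mapping[int, Sequence[frozenset]] | None = None,
) -> frozenset:
    """Function ids whose marker requirement is satisfied by the KO terms."""
    if marker_map is None:
        marker_map = default_marker_map()
    if not marker_map:
        raise ValueError("marker map is empty")
    terms = set(ko_terms)
    flags = {
        fn
        for fn, alternatives in marker_map.items()
        if any(set(alt) <= terms for alt in alternatives)
    }
    return frozenset(flags)


def qc_report(
    bin_content: BinGeneContent,
    reference: PangenomeReference,
    ko_terms: Iterable[str] = (),
    marker_map: Mapping[int, Sequence[frozenset]] | None = None,
) -> BinQcReport:
    """Full QC report for one bin."""
    return BinQcReport(
        bin_id=bin_content.bin_id,
        completeness_pct=completeness(bin_content, reference),
        duplicated_cscg_pct=duplicated_cscg(bin_content, reference),
        function_flags=function_flags(ko_terms, marker_map) if marker_map or ko_terms else frozenset(),
    )
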