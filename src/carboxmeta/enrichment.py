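"""Z-normalized log-odds-ratio enrichment testing between two gene pools.

Given per-category gene counts from two communities (x1 of n1 vs x2 of n2),
each category is laid out as a 2x2 table and scored by the Wald log odds
ratio.  With a Haldane-Anscombe pseudocount c added to every cell,

    a = x1 + c,  b = n1 - x1 + c,  d = x2 + c,  e = n2 - x2 + c
    LOR = ln(a/b) - ln(d/e)
    SE  = sqrt(1/a + 1/b + 1/d + 1/e)
    Z   = LOR / SE

Two-sided p-values come from the standard normal, and false-discovery-rate
control across the categories of a database uses Benjamini-Hochberg.
"Z-normalized" is read as the Wald standardization Z = LOR/SE; an
alternative across-category standardization of the LOR vector is provided
as :func:`z_normalize_across_categories` for plotting on a common scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotations import CategoryCountProfile

__all__ = [
    "EnrichmentResult",
    "log_odds_ratio",
    "compare_profiles",
    "z_normalize_across_categories",
    "results_frame",
]


@dataclass
class EnrichmentResult:
    """Per-category outcome of the two-community enrichment test."""

    category: str
    x1: int
    n1: int
    x2: int
    n2: int
    lor: float
    se: float
    z: float
    p: float
    q: float
    direction: str  # enriched_in_1 | enriched_in_2 | none
    z_across: float | None = None


def log_odds_ratio(
    x1: int, n1: int, x2: int, n2: int, pseudocount: float = 0.5
) -> tuple[float, float, float]:
    """Wald log odds ratio, its standard error, and the Z statistic.

    The pseudocount is added unconditionally to all four cells, keeping the
    statistic finite and continuous at empty cells.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("totals n1 and n2 must be positive")
    if not (0 <= x1 <= n1) or not (0 <= x2 <= n2):
        raise ValueError("counts must satisfy 0 <= x <= n")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    c = pseudocount
    a, b = x1 + c, n1 - x1 + c
    d, e = x2 + c, n2 - x2 + c
    if min(a, b, d, e) <= 0:
        raise ValueError("degenerate table: zero cell with zero pseudocount")
    lor = math.log(a / b) - math.log(d / e)
    se = math.sqrt(1.0 / a + 1.0 / b + 1.0 / d + 1.0 / e)
    return lor, se, lor / se


def compare_profiles(
    profile1: CategoryCountProfile,
    profile2: CategoryCountProfile,
    alpha: float = 0.05,
    pseudocount: float = 0.5,
) -> list[EnrichmentResult]:
    """Test every category of two same-database profiles for enrichment.

    The union of categories is tested (a category absent from one profile
    counts 0 there).  q-values are Benjamini-Hochberg over all tested
    categories; ``direction`` is set by the sign of the LOR when q < alpha.
    Categories are processed in sorted label order so that p-value ties are
    broken deterministically.
    """
    if profile1.db != profile2.db:
        raise ValueError(f"profiles use different databases: {profile1.db} vs {profile2.db}")
    n1, n2 = profile1.total, profile2.total
    if n1 == 0 and n2 == 0:
        raise ValueError("both profiles are empty")
    if n1 == 0 or n2 == 0:
        raise ValueError("one profile is empty; totals must be positive")
    categories = sorted(set(profile1.counts) | set(profile2.counts))
    if not categories:
        raise ValueError("no categories to test")

    results: list[EnrichmentResult] = []
    pvals = np.empty(len(categories))
    for i, cat in enumerate(categories):
        x1, x2 = profile1[cat], profile2[cat]
        lor, se, z = log_odds_ratio(x1, n1, x2, n2, pseudocount)
        p = float(2.0 * stats.norm.sf(abs(z)))
        pvals[i] = p
        results.append(
            EnrichmentResult(cat, x1, n1, x2, n2, lor, se, z, p, q=math.nan, direction="none")
        )
    qvals = multipletests(pvals, method="fdr_bh")[1]
    for res, q in zip(results, qvals):
        res.q = float(q)
        if res.q < alpha and res.lor > 0:
            res.direction = "enriched_in_1"
        elif res.q < alpha and res.lor < 0:
            res.direction = "enriched_in_2"
        else:
            res.direction = "none"
    return results


def z_normalize_across_categories(
    results: Sequence[EnrichmentResult], ddof: int = 1
) -> list[EnrichmentResult]:
    """Standardize the LOR vector across categories (mean 0, sd 1).

    This is a presentation transform putting categories on a common scale
    for plotting; it does not alter the Wald p/q values.  ``ddof=1`` uses
    the sample standard deviation, ``ddof=0`` the population one.
    """
    if len(results) < 2:
        raise ValueError("need at least two categories to standardize")
    lors = np.array([r.lor for r in results], dtype=float)
    sd = float(lors.std(ddof=ddof))
    if sd == 0.0:
        raise ValueError("LOR vector is constant; standardization undefined")
    mean = float(lors.mean())
    out = []
    for r, lor in zip(results, lors):
        out.append(
            EnrichmentResult(
                r.category, r.x1, r.n1, r.x2, r.n2, r.lor, r.se, r.z, r.p, r.q,
                r.direction, z_across=float((lor - mean) / sd),
            )
        )
    return out


def results_frame(results: Sequence[EnrichmentResult]) -> "pd.DataFrame":
    """Tabulate results for TSV export."""
    import pandas as pd

    cols = ["category", "x1", "n1", "x2", "n2", "lor", "se", "z", "p", "q", "direction"]
    df = pd.DataFrame([{c: getattr(r, c) for c in cols} for r in results])
    if results and results[0].z_across is not None:
        df["z_across"] = [r.z_across for r in results]
    return df
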