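"""Carboxylate-platform fermentation performance and product-spectrum metrics.

Mixed-culture anaerobic fermentations of lignocellulose are scored on the
volatile-solids (VS) balance and the carboxylic acids produced:

* VS = oven-dry mass - ash mass (the digestible organic fraction)
* conversion   = VS digested / VS loaded
* selectivity  = total acids / VS digested
* yield        = total acids / VS loaded  (= conversion x selectivity)
* productivity = total acids / (liquid volume x duration), g acid L^-1 d^-1

The product spectrum is the relative abundance (%) of acids by carbon chain
length (C2 acetic ... C6 caproic; isomers summed), reported as mean +/- SE
over replicates, with Student's t-tests between treatments.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._util import round_half_up

#: canonical acid -> chain-length class; isomers collapse onto one class
ACID_CHAIN = {
    "acetic": "C2",
    "propionic": "C3",
    "butyric": "C4",
    "isobutyric": "C4",
    "valeric": "C5",
    "isovaleric": "C5",
    "caproic": "C6",
    "isocaproic": "C6",
}

CHAIN_ORDER = ["C2", "C3", "C4", "C5", "C6"]


def acid_chain_class(acid: str) -> str:
    """Chain-length class (C2..C6) for an acid name; isomer prefixes collapse."""
    key = acid.strip().lower().replace("n-", "").replace(" acid", "")
    if key.startswith("c") and key[1:] in {"2", "3", "4", "5", "6"}:
        return key.upper()
    try:
        return ACID_CHAIN[key]
    except KeyError:
        raise ValueError(f"unrecognized acid name: {acid!r}") from None


def volatile_solids(oven_dry_g: float, ashed_g: float) -> float:
    """VS mass: oven-dry weight minus ashed weight."""
    if oven_dry_g < 0 or ashed_g < 0:
        raise ValueError("masses must be non-negative")
    if ashed_g > oven_dry_g:
        raise ValueError("ashed mass cannot exceed oven-dry mass")
    return oven_dry_g - ashed_g


@dataclass
class FermentationBatch:
    """Terminal measurements of one fermentor replicate.

    ``oven_dry_g``/``ashed_g`` are the residual (undigested) solids; their
    difference is the VS remaining at harvest.
    """

    replicate_id: str
    oven_dry_g: float
    ashed_g: float
    vs_loaded_g: float
    acid_masses_g: dict = field(default_factory=dict)
    liquid_volume_L: float = 1.0
    duration_d: float = 1.0

    def __post_init__(self) -> None:
        volatile_solids(self.oven_dry_g, self.ashed_g)  # validates
        if self.vs_loaded_g <= 0:
            raise ValueError("vs_loaded_g must be positive")
        if self.duration_d <= 0 or self.liquid_volume_L <= 0:
            raise ValueError("duration and liquid volume must be positive")
        if any(m < 0 for m in self.acid_masses_g.values()):
            raise ValueError("acid masses must be non-negative")

    @property
    def vs_remaining_g(self) -> float:
        return volatile_solids(self.oven_dry_g, self.ashed_g)

    @property
    def total_acid_g(self) -> float:
        return float(sum(self.acid_masses_g.values()))


@dataclass(frozen=True)
class PerformanceMetrics:
    conversion: float
    selectivity: float | None  # None when VS digested is zero
    yield_: float
    productivity: float
    inconsistent: bool = False


def performance(batch: FermentationBatch) -> PerformanceMetrics:
    """Conversion, selectivity, yield, and productivity for one replicate.

    With zero VS digested, selectivity is undefined (None); acids measured
    despite zero digestion additionally set the inconsistency flag.
    Selectivity above 1 (acids exceeding VS digested) also flags the batch
    as inconsistent rather than raising, since measurement error can
    produce it.
    """
    digested = batch.vs_loaded_g - batch.vs_remaining_g
    if digested < 0:
        raise ValueError("VS remaining exceeds VS loaded")
    acids = batch.total_acid_g
    conversion = digested / batch.vs_loaded_g
    yield_ = acids / batch.vs_loaded_g
    productivity = acids / (batch.liquid_volume_L * batch.duration_d)
    if digested == 0:
        if acids > 0:
            warnings.warn(
                f"replicate {batch.replicate_id}: acids measured with zero VS digested",
                stacklevel=2,
            )
        return PerformanceMetrics(0.0, None, yield_, productivity, inconsistent=acids > 0)
    selectivity = acids / digested
    return PerformanceMetrics(
        conversion, selectivity, yield_, productivity, inconsistent=selectivity > 1.0
    )


@dataclass
class ProductSpectrum:
    """Per-chain-length relative abundances over replicates."""

    per_replicate: pd.DataFrame  # rows: replicate, columns: C2..C6, percent
    mean: pd.Series
    se: pd.Series
    not_detected: frozenset  # chain classes with zero mass in every replicate

    @property
    def n_replicates(self) -> int:
        return len(self.per_replicate)


def product_spectrum(acid_masses: pd.DataFrame) -> ProductSpectrum:
    """Relative product abundances (%) by chain length, mean +/- SE.

    ``acid_masses`` is a long table (replicate, acid, mass_g).  Isomers are
    summed into their chain class, each replicate's classes are divided by
    its total acid mass, and mean and standard error (sd/sqrt(n), sample
    sd) are taken over replicates.  Chain classes with no mass in any
    replicate are reported as not detected (ND).
    """
    required = {"replicate", "acid", "mass_g"}
    if not required <= set(acid_masses.columns):
        raise ValueError(f"acid mass table needs columns {sorted(required)}")
    if acid_masses.empty:
        raise ValueError("need at least one replicate")
    if (acid_masses["mass_g"] < 0).any():
        raise ValueError("acid masses must be non-negative")
    df = acid_masses.copy()
    df["chain"] = df["acid"].map(acid_chain_class)
    wide = (
        df.pivot_table(index="replicate", columns="chain", values="mass_g", aggfunc="sum")
        .reindex(columns=CHAIN_ORDER, fill_value=0.0)
        .fillna(0.0)
    )
    totals = wide.sum(axis=1)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"replicate(s) with zero total acid mass: {bad}")
    percents = wide.div(totals, axis=0) * 100.0
    n = len(percents)
    mean = percents.mean(axis=0)
    sd = percents.std(axis=0, ddof=1) if n > 1 else pd.Series(0.0, index=percents.columns)
    se = sd / math.sqrt(n)
    nd = frozenset(percents.columns[(wide == 0).all(axis=0)])
    return ProductSpectrum(percents, mean, se, nd)


def welch_from_summary(
    mean1: float, se1: float, n1: int, mean2: float, se2: float, n2: int
) -> float:
    """Two-sided Welch t-test p-value from printed means and standard errors."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 in each group")
    if se1 == 0 and se2 == 0:
        return 1.0 if mean1 == mean2 else 0.0
    res = stats.ttest_ind_from_stats(
        mean1, se1 * math.sqrt(n1), n1, mean2, se2 * math.sqrt(n2), n2, equal_var=False
    )
    return float(res.pvalue)


def _pair_p(a: np.ndarray, b: np.ndarray, mode: str) -> float:
    if np.array_equal(a, b):
        return 1.0
    if mode == "paired":
        diff = a - b
        if np.all(diff == diff[0]):  # zero-variance differences, unequal means
            return 0.0
        return float(stats.ttest_rel(a, b).pvalue)
    if mode == "welch_from_replicates":
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            return 1.0 if a.mean() == b.mean() else 0.0
        return float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    raise ValueError(f"unknown mode: {mode!r}")


def compare_spectra(
    spectrum_a: ProductSpectrum | Mapping[str, tuple[float, float, int]],
    spectrum_b: ProductSpectrum | Mapping[str, tuple[float, float, int]],
    mode: str = "welch_from_replicates",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-acid-class significance between two treatments' product spectra.

    Modes: ``paired`` (replicate-paired Student's t; equal n required),
    ``welch_from_replicates`` (unequal-variance t on per-replicate values),
    and ``welch_from_summary`` (inputs are {chain: (mean, SE, n)} summaries,
    for printed-table comparisons).  Treatments share a superscript letter
    for an acid iff p >= alpha.
    """
    rows = []
    if mode == "welch_from_summary":
        chains = [c for c in CHAIN_ORDER if c in spectrum_a and c in spectrum_b]
        if not chains:
            raise ValueError("no common chain classes in summaries")
        for chain in chains:
            m1, s1, k1 = spectrum_a[chain]
            m2, s2, k2 = spectrum_b[chain]
            rows.append((chain, welch_from_summary(m1, s1, k1, m2, s2, k2)))
    else:
        if not isinstance(spectrum_a, ProductSpectrum) or not isinstance(spectrum_b, ProductSpectrum):
            raise TypeError("replicate modes require ProductSpectrum inputs")
        if mode == "paired" and spectrum_a.n_replicates != spectrum_b.n_replicates:
            raise ValueError("paired mode requires equal replicate counts")
        for chain in CHAIN_ORDER:
            a = spectrum_a.per_replicate[chain].to_numpy(dtype=float)
            b = spectrum_b.per_replicate[chain].to_numpy(dtype=float)
            rows.append((chain, _pair_p(a, b, mode)))
    out = pd.DataFrame(rows, columns=["chain", "p"])
    out["significant"] = out["p"] < alpha
    out["letter_a"] = "a"
    out["letter_b"] = np.where(out["significant"], "b", "a")
    return out


def spectrum_table(spectrum: ProductSpectrum, ndigits: int = 2) -> pd.DataFrame:
    """Printable mean +/- SE table with ND markers."""
    rows = []
    for chain in CHAIN_ORDER:
        if chain in spectrum.not_detected:
            rows.append((chain, 0.0, 0.0, "ND"))
        else:
            rows.append(
                (
                    chain,
                    round_half_up(float(spectrum.mean[chain]), ndigits),
                    round_half_up(float(spectrum.se[chain]), ndigits),
                    f"{round_half_up(float(spectrum.mean[chain]), ndigits):.2f}"
                    f" +/- {round_half_up(float(spectrum.se[chain]), ndigits):.2f}",
                )
            )
    return pd.DataFrame(rows, columns=["chain", "mean_pct", "se_pct", "display"])
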