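"""Synthetic fermentor-metagenome data with planted ground truth.

Every input the analysis pipeline consumes can be generated here with a
known answer: paired annotation tables with planted per-category enrichment
factors, contigs with taxon-specific 3-mer composition / G+C / depth for the
binning stage, best-hit tables with planted genome-coverage fractions, bin
gene inventories with planted completeness and CSCG duplication, and
fermentation replicate measurements with planted product spectra.  The
noise models are deliberately the simplest consistent choices (multinomial
counts, truncated normals, first-order k-mer-consistent Markov sequences);
the generators exist to exercise and validate the analysis, not to simulate
biology.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from ._util import round_half_up
from .binning import KMERS3, RC_PERMUTATION
from .binqc import PangenomeReference
from .fermentation import FermentationBatch

_NT = "ACGT"
_GC_IDX = np.array([1, 2])  # C and G in ACGT order


# ---------------------------------------------------------------------------
# community / enrichment plants
# ---------------------------------------------------------------------------

@dataclass
class CommunitySpec:
    """Two gene pools sharing baseline category frequencies, with planted
    per-category enrichment multipliers applied to community B."""

    n_categories: int
    baseline_weights: np.ndarray
    enrichment_factors: np.ndarray
    n_genes_a: int
    n_genes_b: int
    seed: int
    db: str = "PFAM"

    def __post_init__(self) -> None:
        self.baseline_weights = np.asarray(self.baseline_weights, dtype=float)
        self.enrichment_factors = np.asarray(self.enrichment_factors, dtype=float)
        if self.n_categories <= 0 or self.n_genes_a <= 0 or self.n_genes_b <= 0:
            raise ValueError("counts must be positive")
        if self.baseline_weights.shape != (self.n_categories,):
            raise ValueError("baseline_weights length must equal n_categories")
        if self.enrichment_factors.shape != (self.n_categories,):
            raise ValueError("enrichment_factors length must equal n_categories")
        if (self.baseline_weights < 0).any():
            raise ValueError("baseline weights must be non-negative")
        if abs(self.baseline_weights.sum() - 1.0) > 1e-9:
            raise ValueError("baseline weights must sum to 1")
        if (self.enrichment_factors <= 0).any():
            raise ValueError("enrichment factors must be positive")

    @property
    def categories(self) -> list[str]:
        return [f"CAT{i:04d}" for i in range(self.n_categories)]


class CategoryTables(NamedTuple):
    table_a: pd.DataFrame
    table_b: pd.DataFrame
    truth: dict  # category -> planted factor, for factors != 1


def _annotation_table(
    rng: np.random.Generator, sample: str, counts: np.ndarray, categories: list[str], db: str
) -> pd.DataFrame:
    cats = np.repeat(np.array(categories, dtype=object), counts)
    cats = rng.permutation(cats)
    n = len(cats)
    gene_ids = np.array([f"{sample}_g{i:06d}" for i in range(n)], dtype=object)
    contig_ids = np.array([f"{sample}_c{i // 10:05d}" for i in range(n)], dtype=object)
    evals = 10.0 ** rng.uniform(-30.0, -6.0, size=n)
    return pd.DataFrame(
        {"gene_id": gene_ids, "contig_id": contig_ids, "db": db, "category": cats, "e_value": evals}
    )


def generate_category_tables(spec: CommunitySpec) -> CategoryTables:
    """Draw the two communities' annotation tables and the enrichment truth.

    Community A gene categories are multinomial(baseline); community B uses
    baseline * factors, renormalized.  The truth map lists the categories
    whose planted factor differs from 1.
    """
    rng = np.random.default_rng(spec.seed)
    p_a = spec.baseline_weights
    p_b = spec.baseline_weights * spec.enrichment_factors
    p_b = p_b / p_b.sum()
    counts_a = rng.multinomial(spec.n_genes_a, p_a)
    counts_b = rng.multinomial(spec.n_genes_b, p_b)
    cats = spec.categories
    table_a = _annotation_table(rng, "A", counts_a, cats, spec.db)
    table_b = _annotation_table(rng, "B", counts_b, cats, spec.db)
    truth = {c: float(f) for c, f in zip(cats, spec.enrichment_factors) if f != 1.0}
    return CategoryTables(table_a, table_b, truth)


def default_community_spec(
    seed: int,
    n_categories: int = 200,
    n_genes: int = 50_000,
    enriched: dict | None = None,
) -> CommunitySpec:
    """Study-condition community plant: Zipf-like baseline over 200
    categories, 50,000 genes per community, one factor-4 and one factor-1/4
    category planted by default."""
    ranks = np.arange(1, n_categories + 1, dtype=float)
    baseline = (1.0 / ranks) / (1.0 / ranks).sum()
    factors = np.ones(n_categories)
    if enriched is None:
        enriched = {10: 4.0, 20: 0.25}
    for idx, f in enriched.items():
        factors[idx] = f
    return CommunitySpec(n_categories, baseline, factors, n_genes, n_genes, seed)


# ---------------------------------------------------------------------------
# contigs for binning
# ---------------------------------------------------------------------------

def _stationary(matrix: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (power iteration)."""
    n = matrix.shape[0]
    pi = np.full(n, 1.0 / n)
    for _ in range(500):
        nxt = pi @ matrix
        if np.abs(nxt - pi).sum() < 1e-13:
            pi = nxt
            break
        pi = nxt
    return pi / pi.sum()


def _conditional_from_weights(w: np.ndarray) -> np.ndarray:
    """16x4 conditional P(next | bigram) implied by a 3-mer distribution."""
    w3 = w.reshape(16, 4)
    rows = w3.sum(axis=1, keepdims=True)
    cond = np.divide(w3, rows, out=np.full_like(w3, 0.25), where=rows > 0)
    return cond


def _bigram_transition(cond: np.ndarray) -> np.ndarray:
    """16x16 bigram-chain transition matrix from a 16x4 conditional."""
    t = np.zeros((16, 16))
    for ab in range(16):
        b = ab % 4
        for c in range(4):
            t[ab, 4 * b + c] = cond[ab, c]
    return t


def _chain_gc(cond: np.ndarray) -> float:
    pi = _stationary(_bigram_transition(cond))
    freq = pi @ cond  # stationary next-nucleotide frequency
    return float(freq[_GC_IDX].sum())


def _tilt_to_gc(cond: np.ndarray, gc_target: float) -> np.ndarray:
    """Exponentially tilt G/C emission probabilities to hit a target GC.

    Bisection on the log tilt factor; the target is clipped away from the
    degenerate 0/100% endpoints.
    """
    target = min(max(gc_target / 100.0, 0.01), 0.99)

    def tilted(log_t: float) -> np.ndarray:
        w = cond.copy()
        w[:, _GC_IDX] *= math.exp(log_t)
        return w / w.sum(axis=1, keepdims=True)

    lo, hi = -12.0, 12.0
    if _chain_gc(tilted(lo)) > target or _chain_gc(tilted(hi)) < target:
        return tilted(0.0)  # unreachable target; keep the untilted chain
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if _chain_gc(tilted(mid)) < target:
            lo = mid
        else:
            hi = mid
    return tilted(0.5 * (lo + hi))


def _sample_sequence(rng: np.random.Generator, cond: np.ndarray, length: int) -> str:
    pi = _stationary(_bigram_transition(cond))
    cum = np.cumsum(cond, axis=1)
    state = int(np.searchsorted(np.cumsum(pi), rng.random()))
    chars = [_NT[state // 4], _NT[state % 4]]
    draws = rng.random(length - 2)
    for u in draws:
        c = int(np.searchsorted(cum[state], u))
        c = min(c, 3)
        chars.append(_NT[c])
        state = 4 * (state % 4) + c
    return "".join(chars[:length])


@dataclass
class TaxonSignatureSpec:
    """Composition/G+C/depth model of one taxon's contigs.

    ``kmer_weights`` should be a self-consistent 3-mer distribution (one
    realizable as the stationary 3-mer law of a nucleotide Markov chain);
    the constructors below guarantee this.
    """

    label: str
    kmer_weights: np.ndarray
    gc_mean: float
    gc_sd: float
    depth_mean: float
    depth_sd: float
    n_contigs: int
    contig_length_range: tuple[int, int] = (5000, 8000)

    def __post_init__(self) -> None:
        self.kmer_weights = np.asarray(self.kmer_weights, dtype=float)
        if self.kmer_weights.shape != (64,):
            raise ValueError("kmer_weights must have 64 entries")
        if (self.kmer_weights < 0).any() or abs(self.kmer_weights.sum() - 1.0) > 1e-9:
            raise ValueError("kmer_weights must be a distribution over the 64 trinucleotides")
        if not (0.0 <= self.gc_mean <= 100.0):
            raise ValueError("gc_mean must lie in [0, 100]")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        if self.gc_sd < 0 or self.depth_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.n_contigs <= 0:
            raise ValueError("n_contigs must be positive")
        lo, hi = self.contig_length_range
        if lo < 1000 or hi < lo:
            raise ValueError("contig lengths must be >= 1 kb and ordered")

    @property
    def expected_signature(self) -> np.ndarray:
        """Strand-symmetrized 3-mer law the pooled signature converges to."""
        return 0.5 * (self.kmer_weights + self.kmer_weights[RC_PERMUTATION])

    @classmethod
    def from_nucleotide_freqs(
        cls, label: str, gc_pct: float, *, gc_sd: float = 1.5,
        depth_mean: float = 15.0, depth_sd: float = 2.0, n_contigs: int = 40,
        contig_length_range: tuple[int, int] = (5000, 8000),
    ) -> "TaxonSignatureSpec":
        """I.i.d. nucleotide model at a given G+C content (strand-symmetric
        and Markov-consistent by construction)."""
        g = gc_pct / 100.0
        p = np.array([(1 - g) / 2, g / 2, g / 2, (1 - g) / 2])
        w = np.einsum("i,j,k->ijk", p, p, p).reshape(64)
        return cls(label, w / w.sum(), gc_pct, gc_sd, depth_mean, depth_sd,
                   n_contigs, contig_length_range)

    @classmethod
    def from_transition_matrix(
        cls, label: str, transition: np.ndarray, **kwargs
    ) -> "TaxonSignatureSpec":
        """First-order nucleotide chain; the implied stationary 3-mer law is
        used as the k-mer weight vector."""
        t = np.asarray(transition, dtype=float)
        if t.shape != (4, 4) or (t < 0).any():
            raise ValueError("transition must be a non-negative 4x4 matrix")
        t = t / t.sum(axis=1, keepdims=True)
        pi = _stationary(t)
        w = np.einsum("a,ab,bc->abc", pi, t, t).reshape(64)
        w = w / w.sum()
        gc_mean = kwargs.pop("gc_mean", float(pi[_GC_IDX].sum()) * 100.0)
        return cls(label, w, gc_mean, kwargs.pop("gc_sd", 1.5),
                   kwargs.pop("depth_mean", 15.0), kwargs.pop("depth_sd", 2.0),
                   kwargs.pop("n_contigs", 40),
                   kwargs.pop("contig_length_range", (5000, 8000)))


class SyntheticContigs(NamedTuple):
    sequences: dict  # contig_id -> nucleotide string
    metadata: pd.DataFrame  # contig_id, taxon, length_bp, gc_pct, depth


def generate_contigs(specs: Sequence[TaxonSignatureSpec], seed: int) -> SyntheticContigs:
    """Sample contigs per taxon spec: Markov sequences whose 3-mer law
    matches the taxon signature, with per-contig planted G+C and depth drawn
    from the taxon's (truncated) normals.

    The planted G+C steers the sequence model via an exponential tilt of the
    G/C emission probabilities, so metadata and sequence composition agree.
    """
    if not specs:
        raise ValueError("need at least one taxon spec")
    rng = np.random.default_rng(seed)
    sequences: dict[str, str] = {}
    rows = []
    for spec in specs:
        base_cond = _conditional_from_weights(spec.kmer_weights)
        lo, hi = spec.contig_length_range
        for i in range(spec.n_contigs):
            cid = f"{spec.label}_c{i:04d}"
            length = int(rng.integers(lo, hi + 1))
            gc = spec.gc_mean if spec.gc_sd == 0 else float(
                np.clip(rng.normal(spec.gc_mean, spec.gc_sd), 0.0, 100.0)
            )
            depth = spec.depth_mean if spec.depth_sd == 0 else float(
                max(rng.normal(spec.depth_mean, spec.depth_sd), 1e-3)
            )
            cond = base_cond if gc == spec.gc_mean else _tilt_to_gc(base_cond, gc)
            if gc == spec.gc_mean and abs(_chain_gc(base_cond) * 100 - gc) > 0.5:
                cond = _tilt_to_gc(base_cond, gc)
            sequences[cid] = _sample_sequence(rng, cond, length)
            rows.append((cid, spec.label, length, gc, depth))
    metadata = pd.DataFrame(rows, columns=["contig_id", "taxon", "length_bp", "gc_pct", "depth"])
    return SyntheticContigs(sequences, metadata)


def default_taxon_specs() -> list[TaxonSignatureSpec]:
    """Three well-separated order-level taxa with G+C and depth in the range
    typical of fermentor bins (G+C 35-57%, depth ~9-35x)."""
    return [
        TaxonSignatureSpec.from_nucleotide_freqs(
            "Clostridiales", 32.0, gc_sd=1.5, depth_mean=20.8, depth_sd=2.0, n_contigs=40),
        TaxonSignatureSpec.from_nucleotide_freqs(
            "Bacteroidales", 50.0, gc_sd=1.5, depth_mean=11.2, depth_sd=1.5, n_contigs=40),
        TaxonSignatureSpec.from_nucleotide_freqs(
            "Actinomycetales", 68.0, gc_sd=1.5, depth_mean=35.3, depth_sd=3.0, n_contigs=40),
    ]


def write_fasta(sequences: dict, path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s), id=cid, description="") for cid, s in sequences.items()]
    seqio_write(records, str(path), "fasta")


def read_fasta(path) -> dict:
    from Bio.SeqIO import parse

    return {rec.id: str(rec.seq) for rec in parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# best-hit tables for genome recruitment
# ---------------------------------------------------------------------------

IDENTITY_RANGES = ((30.0, 60.0), (60.0, 90.0), (90.0, 100.0))


@dataclass
class CoveragePlantSpec:
    """Planted coverage of one isolate genome by a metagenome gene pool.

    ``planted_fraction`` may exceed 1 (up to 1.75) to emulate the
    over-recruitment seen when several strains hit a single reference.
    """

    genome_label: str
    n_genes: int
    planted_fraction: float
    identity_distribution: tuple[float, float, float] = (0.2, 0.4, 0.4)

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if not (0.0 <= self.planted_fraction <= 1.75):
            raise ValueError("planted_fraction must lie in [0, 1.75]")
        w = np.asarray(self.identity_distribution, dtype=float)
        if w.shape != (3,) or (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("identity_distribution must be 3 mixture weights summing to 1")


def generate_hit_table(
    spec: CoveragePlantSpec, n_metagenome_genes: int, seed: int
) -> pd.DataFrame:
    """Best-hit table planting round(fraction * n_genes) homologs.

    Exactly that many distinct metagenome genes receive a best hit to the
    genome, with identities drawn from the mixture over (30,60], (60,90],
    (90,100] and subject positions uniform over the genome's gene indices.
    """
    n_hits = int(round_half_up(spec.planted_fraction * spec.n_genes))
    if n_hits > n_metagenome_genes:
        raise ValueError(
            f"planted fraction requires {n_hits} homologs but only "
            f"{n_metagenome_genes} metagenome genes exist"
        )
    rng = np.random.default_rng(seed)
    if n_hits == 0:
        return pd.DataFrame(
            columns=["gene_id", "genome", "subject_gene", "identity_pct", "subject_pos"]
        )
    gene_idx = rng.choice(n_metagenome_genes, size=n_hits, replace=False)
    comp = rng.choice(3, size=n_hits, p=np.asarray(spec.identity_distribution))
    lows = np.array([r[0] for r in IDENTITY_RANGES])[comp]
    highs = np.array([r[1] for r in IDENTITY_RANGES])[comp]
    identity = highs - (highs - lows) * rng.random(n_hits)  # in (low, high]
    pos = rng.integers(0, spec.n_genes, size=n_hits)
    return pd.DataFrame(
        {
            "gene_id": [f"mg_g{i:06d}" for i in gene_idx],
            "genome": spec.genome_label,
            "subject_gene": [f"{spec.genome_label}_g{p:05d}" for p in pos],
            "identity_pct": identity,
            "subject_pos": pos,
        }
    )


# ---------------------------------------------------------------------------
# bin QC inventories
# ---------------------------------------------------------------------------

@dataclass
class QcPlantSpec:
    """Planted completeness and CSCG duplication for one synthetic bin."""

    n_core: int
    present_fraction: float
    n_cscg: int
    duplicated_fraction: float

    def __post_init__(self) -> None:
        if self.n_core <= 0 or self.n_cscg <= 0:
            raise ValueError("gene set sizes must be positive")
        if not (0.0 <= self.present_fraction <= 1.0):
            raise ValueError("present_fraction must lie in [0, 1]")
        if not (0.0 <= self.duplicated_fraction <= 1.0):
            raise ValueError("duplicated_fraction must lie in [0, 1]")


class QcInventory(NamedTuple):
    bin_content: pd.DataFrame  # columns: category, copies
    reference: PangenomeReference
    expected_completeness: float
    expected_duplication: float


def generate_qc_inventory(spec: QcPlantSpec, seed: int) -> QcInventory:
    """Bin gene inventory with planted completeness and duplication.

    round(present_fraction * n_core) distinct core genes are placed in the
    bin; all CSCGs are detected once and round(duplicated_fraction * n_cscg)
    of them get a second copy.
    """
    rng = np.random.default_rng(seed)
    core = [f"CORE{i:04d}" for i in range(spec.n_core)]
    cscg = [f"CSCG{i:04d}" for i in range(spec.n_cscg)]
    n_present = int(round_half_up(spec.present_fraction * spec.n_core))
    n_dup = int(round_half_up(spec.duplicated_fraction * spec.n_cscg))
    present = rng.choice(core, size=n_present, replace=False) if n_present else np.array([], dtype=object)
    dup = rng.choice(cscg, size=n_dup, replace=False) if n_dup else np.array([], dtype=object)
    rows = [(g, 1) for g in present]
    dup_set = set(dup)
    rows += [(g, 2 if g in dup_set else 1) for g in cscg]
    rows += [(f"OTHER{i:04d}", 1) for i in range(10)]  # non-core filler
    reference = PangenomeReference("synthetic", frozenset(core), frozenset(cscg))
    return QcInventory(
        pd.DataFrame(rows, columns=["category", "copies"]),
        reference,
        expected_completeness=round_half_up(100.0 * n_present / spec.n_core, 2),
        expected_duplication=round_half_up(100.0 * n_dup / spec.n_cscg, 2),
    )


# ---------------------------------------------------------------------------
# fermentation replicates
# ---------------------------------------------------------------------------

@dataclass
class FermentationPlantSpec:
    """Planted product spectrum and VS balance for replicate fermentors.

    ``acid_means``/``acid_sds`` are relative-abundance percentages per acid;
    means must sum to 100 within 0.5 (printed-table rounding slack).
    """

    acid_means: dict
    acid_sds: dict
    n_replicates: int = 3
    vs_loaded_g: float = 32.0
    vs_digested_g: float = 16.0
    acid_total_g: float = 8.0
    liquid_volume_L: float = 0.4
    duration_d: float = 16.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("need at least two replicates")
        total = sum(self.acid_means.values())
        if abs(total - 100.0) > 0.5:
            raise ValueError(f"acid means must sum to 100 +/- 0.5, got {total}")
        if set(self.acid_sds) != set(self.acid_means):
            raise ValueError("acid_sds must cover exactly the acids in acid_means")
        if any(s < 0 for s in self.acid_sds.values()):
            raise ValueError("SDs must be non-negative")
        for name, val in [
            ("vs_loaded_g", self.vs_loaded_g), ("acid_total_g", self.acid_total_g),
            ("liquid_volume_L", self.liquid_volume_L), ("duration_d", self.duration_d),
        ]:
            if val <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 <= self.vs_digested_g <= self.vs_loaded_g):
            raise ValueError("vs_digested_g must lie in [0, vs_loaded_g]")


class FermentationReplicates(NamedTuple):
    measurements: pd.DataFrame  # replicate, acid, pct, mass_g
    batches: list  # FermentationBatch per replicate


def generate_fermentation_replicates(spec: FermentationPlantSpec) -> FermentationReplicates:
    """Replicate acid spectra: normal draws per acid, floored at 0 and
    renormalized to 100, with mass columns consistent with the planted VS
    balance and total acid production."""
    rng = np.random.default_rng(spec.seed)
    acids = list(spec.acid_means)
    means = np.array([spec.acid_means[a] for a in acids])
    sds = np.array([spec.acid_sds[a] for a in acids])
    rows = []
    batches = []
    ash_g = 5.0
    vs_remaining = spec.vs_loaded_g - spec.vs_digested_g
    for r in range(spec.n_replicates):
        draw = np.maximum(rng.normal(means, sds), 0.0)
        if draw.sum() == 0:
            draw = means.copy()
        pct = 100.0 * draw / draw.sum()
        masses = pct / 100.0 * spec.acid_total_g
        rep = f"rep{r + 1}"
        rows += [(rep, a, float(p), float(m)) for a, p, m in zip(acids, pct, masses)]
        batches.append(
            FermentationBatch(
                replicate_id=rep,
                oven_dry_g=ash_g + vs_remaining,
                ashed_g=ash_g,
                vs_loaded_g=spec.vs_loaded_g,
                acid_masses_g={a: float(m) for a, m in zip(acids, masses)},
                liquid_volume_L=spec.liquid_volume_L,
                duration_d=spec.duration_d,
            )
        )
    measurements = pd.DataFrame(rows, columns=["replicate", "acid", "pct", "mass_g"])
    return FermentationReplicates(measurements, batches)


def thermophilic_spectrum_spec(seed: int = 0) -> FermentationPlantSpec:
    """Study-condition plant for a 55 degC product spectrum (n = 3).

    SDs are SE * sqrt(3) for the printed per-acid standard errors.
    """
    se = {"acetic": 2.84, "propionic": 0.69, "butyric": 2.54, "valeric": 0.42, "caproic": 0.0}
    return FermentationPlantSpec(
        acid_means={"acetic": 58.69, "propionic": 1.38, "butyric": 39.52, "valeric": 0.42, "caproic": 0.0},
        acid_sds={k: v * math.sqrt(3) for k, v in se.items()},
        seed=seed,
    )


def mesophilic_spectrum_spec(seed: int = 0) -> FermentationPlantSpec:
    """Study-condition plant for a 40 degC product spectrum (n = 3)."""
    se = {"acetic": 0.84, "propionic": 2.06, "butyric": 1.64, "valeric": 0.37, "caproic": 0.72}
    return FermentationPlantSpec(
        acid_means={"acetic": 51.63, "propionic": 12.81, "butyric": 28.39, "valeric": 2.60, "caproic": 4.56},
        acid_sds={k: v * math.sqrt(3) for k, v in se.items()},
        seed=seed,
    )
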