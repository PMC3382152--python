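"""Composition-based contig binning with G+C/depth outlier pruning.

Contigs are summarized by strand-symmetric 3-mer frequency vectors
(overlapping k-mers of the sequence and its reverse complement, pooled and
normalized) and assigned to the nearest trained taxon signature, subject to
a distance cutoff.  Assigned bins are then pruned in a single pass: contigs
whose G+C content or read depth deviates by more than one (population)
standard deviation from their bin's pre-pruning mean are marked as outliers
and unbinned.

The representation is a plain normalized k-mer vector; the default distance
is Euclidean with a 0.01 cutoff, and the cutoff can be recalibrated on
labeled training data (:func:`calibrate_cutoff`) since composition distances
scale with contig length.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

UNBINNED = "UNBINNED"

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _kmers(k: int) -> list[str]:
    return ["".join(t) for t in itertools.product("ACGT", repeat=k)]

KMERS3 = _kmers(3)
_KMER3_INDEX = {kmer: i for i, kmer in enumerate(KMERS3)}

#: permutation sending each 3-mer index to the index of its reverse complement
RC_PERMUTATION = np.array(
    [_KMER3_INDEX[kmer.translate(_COMPLEMENT)[::-1]] for kmer in KMERS3]
)


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


def gc_percent(sequence: str) -> float:
    """G+C content of a sequence in percent, ignoring ambiguity codes."""
    seq = sequence.upper()
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        raise ValueError("sequence contains no unambiguous nucleotides")
    return 100.0 * (seq.count("G") + seq.count("C")) / acgt


def kmer_signature(sequence: str, k: int = 3) -> np.ndarray:
    """Strand-symmetric k-mer frequency vector of a nucleotide sequence.

    Overlapping k-mers of the sequence and of its reverse complement are
    counted together and normalized to sum to 1.  K-mers containing
    ambiguity codes are skipped.  Only k = 3 (the 64 trinucleotides) is
    supported.
    """
    if k != 3:
        raise ValueError("only k = 3 is supported")
    seq = sequence.upper()
    if len(seq) < k:
        raise ValueError(f"sequence shorter than k = {k}")
    counts = np.zeros(64, dtype=float)
    for i in range(len(seq) - k + 1):
        idx = _KMER3_INDEX.get(seq[i : i + k])
        if idx is not None:
            counts[idx] += 1.0
    counts = counts + counts[RC_PERMUTATION]  # pool with reverse complement
    total = counts.sum()
    if total == 0:
        raise ValueError("no unambiguous k-mers in sequence")
    return counts / total


@dataclass
class ContigRecord:
    """A contig with the metadata the binning stage consumes."""

    contig_id: str
    sequence: str
    depth: float
    gc_pct: float | None = None
    kmer_vector: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.gc_pct is None:
            self.gc_pct = gc_percent(self.sequence)
        if self.kmer_vector is None:
            self.kmer_vector = kmer_signature(self.sequence)

    @property
    def length_bp(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class BinSignature:
    """Trained composition centroid of one taxon bin."""

    bin_id: str
    centroid: np.ndarray
    order_label: str = ""

    def __post_init__(self) -> None:
        total = float(np.asarray(self.centroid).sum())
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ValueError("centroid must be a distribution summing to 1")


@dataclass
class BinAssignment:
    contig_id: str
    bin_id: str  # bin label or UNBINNED
    distance: float
    outlier_flag: bool = False
    tie: bool = False
    pruned_from: str | None = None  # original bin of a pruned outlier


def train_signatures(
    contigs: Sequence[ContigRecord], labels: Mapping[str, str]
) -> list[BinSignature]:
    """Mean k-mer vector per label over labeled training contigs."""
    by_label: dict[str, list[np.ndarray]] = {}
    for contig in contigs:
        label = labels.get(contig.contig_id)
        if label is not None:
            by_label.setdefault(label, []).append(contig.kmer_vector)
    if not by_label:
        raise ValueError("no training contigs matched the provided labels")
    sigs = []
    for label in sorted(by_label):
        centroid = np.mean(by_label[label], axis=0)
        sigs.append(BinSignature(label, centroid / centroid.sum()))
    return sigs


def _distance(u: np.ndarray, v: np.ndarray, metric: str) -> float:
    if metric == "euclidean":
        return float(np.linalg.norm(u - v))
    if metric == "manhattan":
        return float(np.abs(u - v).sum())
    raise ValueError(f"unknown metric: {metric!r}")


def assign(
    contig: ContigRecord,
    signatures: Sequence[BinSignature],
    cutoff: float = 0.01,
    metric: str = "euclidean",
    tie_tol: float = 1e-12,
) -> BinAssignment:
    """Assign a contig to its nearest signature if within the cutoff.

    An exact tie between the two nearest bins (within ``tie_tol``) leaves
    the contig unbinned with the tie recorded.
    """
    if not signatures:
        raise ValueError("need at least one signature")
    dists = [_distance(contig.kmer_vector, s.centroid, metric) for s in signatures]
    order = np.argsort(dists, kind="stable")
    best = int(order[0])
    d = dists[best]
    if len(signatures) > 1 and abs(dists[int(order[1])] - d) <= tie_tol:
        return BinAssignment(contig.contig_id, UNBINNED, d, tie=True)
    if d > cutoff:
        return BinAssignment(contig.contig_id, UNBINNED, d)
    return BinAssignment(contig.contig_id, signatures[best].bin_id, d)


def assign_all(
    contigs: Sequence[ContigRecord],
    signatures: Sequence[BinSignature],
    cutoff: float = 0.01,
    metric: str = "euclidean",
) -> list[BinAssignment]:
    return [assign(c, signatures, cutoff, metric) for c in contigs]


def calibrate_cutoff(
    contigs: Sequence[ContigRecord],
    labels: Mapping[str, str],
    signatures: Sequence[BinSignature],
    quantile: float = 0.99,
    metric: str = "euclidean",
) -> float:
    """Distance cutoff from labeled data: a quantile of within-taxon distances.

    Composition distances shrink with contig length, so a fixed cutoff tuned
    for one length regime misclassifies another; this recalibrates it as the
    ``quantile`` of distances from labeled contigs to their own taxon's
    signature.
    """
    by_id = {s.bin_id: s for s in signatures}
    dists = [
        _distance(c.kmer_vector, by_id[labels[c.contig_id]].centroid, metric)
        for c in contigs
        if labels.get(c.contig_id) in by_id
    ]
    if not dists:
        raise ValueError("no labeled contigs with matching signatures")
    return float(np.quantile(dists, quantile))


def prune_outliers(
    assignments: Sequence[BinAssignment],
    metadata: pd.DataFrame,
) -> list[BinAssignment]:
    """Single-pass G+C/depth outlier removal within each bin.

    ``metadata`` must be indexed by contig_id with columns ``gc_pct`` and
    ``depth``.  Per bin with at least two members, the mean and population
    standard deviation of G+C and depth are computed over the *pre-pruning*
    membership; a contig is flagged (and unbinned) iff it deviates strictly
    more than one SD from the mean in either variable.  Re-running the pass
    on its own output changes nothing, because the statistics are frozen at
    the original membership.
    """
    def origin_bin(a: BinAssignment) -> str | None:
        if a.bin_id != UNBINNED:
            return a.bin_id
        return a.pruned_from if a.outlier_flag else None

    members: dict[str, list[BinAssignment]] = {}
    for a in assignments:
        origin = origin_bin(a)
        if origin is not None:
            members.setdefault(origin, []).append(a)

    flagged: set[str] = set()
    for bin_id, assigned in members.items():
        if len(assigned) < 2:
            continue
        ids = [a.contig_id for a in assigned]
        gc = metadata.loc[ids, "gc_pct"].to_numpy(dtype=float)
        depth = metadata.loc[ids, "depth"].to_numpy(dtype=float)
        gc_mean, gc_sd = gc.mean(), gc.std(ddof=0)
        d_mean, d_sd = depth.mean(), depth.std(ddof=0)
        for cid, g, d in zip(ids, gc, depth):
            if abs(g - gc_mean) > gc_sd or abs(d - d_mean) > d_sd:
                flagged.add(cid)

    out = []
    for a in assignments:
        origin = origin_bin(a)
        if origin is not None and a.contig_id in flagged:
            out.append(
                BinAssignment(a.contig_id, UNBINNED, a.distance,
                              outlier_flag=True, tie=a.tie, pruned_from=origin)
            )
        else:
            out.append(BinAssignment(a.contig_id, a.bin_id, a.distance, a.outlier_flag, a.tie, a.pruned_from))
    return out


def assignments_frame(assignments: Sequence[BinAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [(a.contig_id, a.bin_id, a.distance, a.outlier_flag) for a in assignments],
        columns=["contig_id", "bin_id", "distance", "outlier_flag"],
    )
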