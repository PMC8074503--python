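"""Length-stratified sub-datasets and balanced resampling replicates.

Protein length strongly shapes composition-derived features, so training is
stratified into four length-homogeneous sub-datasets Q1..Q4, with separate
length quartile bins for the positive (circadian) and negative classes.  The
negative class outnumbers the positive in every stratum; class balance is
restored by repeatedly drawing a fresh negative subset the size of the
positive set (undersampling without replacement), so that across replicates
the whole negative set participates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .features import DEFAULT_TABLES, DescriptorTables, encode
from .sequence_io import ProteinRecord

BIN_NAMES = ("Q1", "Q2", "Q3", "Q4")

#: Default positive-class length quartile bins (half-open; last bin closed).
POSITIVE_BINS: tuple[tuple[int, int], ...] = ((39, 221), (221, 363), (363, 538), (538, 1000))
#: Default negative-class length quartile bins.
NEGATIVE_BINS: tuple[tuple[int, int], ...] = ((43, 407), (407, 485), (485, 607), (607, 1000))


def _check_bins(bins: Sequence[tuple[int, int]]) -> None:
    if len(bins) != 4:
        raise ValueError("expected exactly 4 length bins")
    for (lo, hi), (lo2, _) in zip(bins, bins[1:]):
        if hi != lo2:
            raise ValueError("bins must be contiguous and ordered")
    if any(lo >= hi for lo, hi in bins):
        raise ValueError("each bin must have lo < hi")


@dataclass(frozen=True)
class LengthBins:
    """Per-class length intervals; half-open [lo, hi), last bin closed at cap."""

    positive_bins: tuple[tuple[int, int], ...] = POSITIVE_BINS
    negative_bins: tuple[tuple[int, int], ...] = NEGATIVE_BINS

    def __post_init__(self) -> None:
        _check_bins(self.positive_bins)
        _check_bins(self.negative_bins)

    def bin_of(self, length: int, positive: bool) -> str | None:
        """Bin name for a length, or None if outside the class's range."""
        bins = self.positive_bins if positive else self.negative_bins
        for name, (lo, hi) in zip(BIN_NAMES, bins):
            last = name == BIN_NAMES[-1]
            if lo <= length < hi or (last and length == hi):
                return name
        return None


DEFAULT_BINS = LengthBins()


def compute_quartile_bins(
    lengths: Sequence[int], cap: int = 1000
) -> tuple[tuple[int, int], ...]:
    """Quartile-based length bins from observed lengths.

    Boundaries are the linear-interpolation quartiles of the lengths; the last
    bin is capped at ``min(max(lengths), cap)``.  Raises on fewer than 4
    lengths or a degenerate (all-equal) distribution.
    """
    lengths = np.asarray(lengths)
    if lengths.size < 4:
        raise ValueError("need at least 4 lengths to compute quartile bins")
    q1, med, q3 = np.quantile(lengths, [0.25, 0.5, 0.75], method="linear")
    lo, hi = lengths.min(), min(int(lengths.max()), cap)
    edges = [lo, q1, med, q3, hi]
    if len({float(e) for e in edges}) < 5:
        raise ValueError("degenerate length distribution: coincident quartiles")
    return tuple((edges[i], edges[i + 1]) for i in range(4))


@dataclass
class SubDataset:
    """One length-homogeneous stratum: feature rows for both classes.

    Labels follow the convention +1 = circadian (CRG), -1 = non-circadian.
    """

    name: str
    X_pos: np.ndarray
    X_neg: np.ndarray
    pos_ids: list[str] = field(default_factory=list)
    neg_ids: list[str] = field(default_factory=list)

    @property
    def n_pos(self) -> int:
        return self.X_pos.shape[0]

    @property
    def n_neg(self) -> int:
        return self.X_neg.shape[0]


@dataclass(frozen=True)
class BalancedReplicate:
    """One balanced draw: all positives plus an equal-size negative subset."""

    replicate_index: int
    seed: int
    X: np.ndarray
    y: np.ndarray
    neg_indices: np.ndarray  # rows of the SubDataset's X_neg that were drawn


def assign_bins(
    records: Iterable[ProteinRecord],
    labels: Iterable[int],
    bins: LengthBins = DEFAULT_BINS,
) -> tuple[dict[str, tuple[list[ProteinRecord], list[ProteinRecord]]], list[ProteinRecord]]:
    """Route labelled records into Q1..Q4 by class-specific length bins.

    Returns ``(by_bin, rejected)`` where ``by_bin[name]`` is a
    ``(positives, negatives)`` pair and ``rejected`` holds records whose
    length falls outside their class's binned range.  Counts are conserved.
    """
    by_bin: dict[str, tuple[list[ProteinRecord], list[ProteinRecord]]] = {
        name: ([], []) for name in BIN_NAMES
    }
    rejected: list[ProteinRecord] = []
    for rec, label in zip(records, labels, strict=True):
        if label not in (-1, 1):
            raise ValueError(f"labels must be +/-1, got {label!r}")
        name = bins.bin_of(rec.length, positive=label == 1)
        if name is None:
            rejected.append(rec)
        else:
            by_bin[name][0 if label == 1 else 1].append(rec)
    return by_bin, rejected


def build_subdatasets(
    pos_records: Sequence[ProteinRecord],
    neg_records: Sequence[ProteinRecord],
    bins: LengthBins = DEFAULT_BINS,
    tables: DescriptorTables = DEFAULT_TABLES,
) -> tuple[dict[str, SubDataset], list[ProteinRecord]]:
    """Encode records and assemble the four SubDatasets."""
    records = list(pos_records) + list(neg_records)
    labels = [1] * len(pos_records) + [-1] * len(neg_records)
    by_bin, rejected = assign_bins(records, labels, bins)
    subs = {}
    for name, (pos, neg) in by_bin.items():
        subs[name] = SubDataset(
            name=name,
            X_pos=np.array([encode(r, tables).values for r in pos]).reshape(len(pos), -1),
            X_neg=np.array([encode(r, tables).values for r in neg]).reshape(len(neg), -1),
            pos_ids=[r.id for r in pos],
            neg_ids=[r.id for r in neg],
        )
    return subs, rejected


def make_balanced_replicates(
    sub: SubDataset, n_replicates: int = 10, master_seed: int = 0
) -> list[BalancedReplicate]:
    """Balanced undersampling replicates of one sub-dataset.

    Each replicate stacks all positives over ``n_pos`` negatives drawn without
    replacement with seed ``master_seed + replicate_index`` (1-based), so the
    protocol is reproducible and replicates differ.
    """
    if sub.n_neg < sub.n_pos:
        raise ValueError(
            f"{sub.name}: negatives ({sub.n_neg}) fewer than positives "
            f"({sub.n_pos}); balanced undersampling impossible"
        )
    if sub.n_pos == 0:
        raise ValueError(f"{sub.name}: no positive instances")
    replicates = []
    for idx in range(1, n_replicates + 1):
        seed = master_seed + idx
        rng = np.random.default_rng(seed)
        chosen = np.sort(rng.choice(sub.n_neg, size=sub.n_pos, replace=False))
        X = np.vstack([sub.X_pos, sub.X_neg[chosen]])
        y = np.concatenate([np.ones(sub.n_pos), -np.ones(sub.n_pos)]).astype(int)
        replicates.append(
            BalancedReplicate(replicate_index=idx, seed=seed, X=X, y=y, neg_indices=chosen)
        )
    return replicates
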