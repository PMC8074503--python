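"""Proteome-wide prediction with the 4-bin model ensemble.

A :class:`ModelBundle` carries one trained SVM per length stratum (Q1..Q4)
plus the routing intervals that send an unlabelled sequence to its model.
Routing uses the positive-class length bins — the entity being detected —
extended so the bins tile [39, 1000] without gaps; sequences outside that
range are rejected with a reason.  Predicted probability is P(circadian);
the label is CRG when the probability exceeds the threshold (default 0.8,
chosen to suppress false positives in whole-proteome scans).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import joblib
import numpy as np
import pandas as pd

from .classifier import SVMModel, fit
from .datasets import BIN_NAMES, DEFAULT_BINS, LengthBins, build_subdatasets, make_balanced_replicates
from .features import DEFAULT_TABLES, DescriptorTables, encode
from .kernels import KernelSpec
from .sequence_io import MIN_LENGTH, ProteinRecord

logger = logging.getLogger(__name__)

FORMAT_VERSION = 1


@dataclass
class ModelBundle:
    """Four per-stratum SVMs plus their length-routing intervals."""

    models: dict[str, SVMModel]
    routing_bins: tuple[tuple[int, int], ...]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.models) != set(BIN_NAMES):
            raise ValueError(f"bundle must hold exactly the models {BIN_NAMES}")
        if len(self.routing_bins) != len(BIN_NAMES):
            raise ValueError("one routing interval per model required")
        for (_, hi), (lo, _) in zip(self.routing_bins, self.routing_bins[1:]):
            if hi != lo:
                raise ValueError("routing intervals must tile the length range")
        self.metadata.setdefault("format_version", FORMAT_VERSION)

    def save(self, path: str | Path) -> None:
        joblib.dump(
            {"format_version": FORMAT_VERSION, "bundle": self}, path, compress=3
        )

    @classmethod
    def load(cls, path: str | Path) -> "ModelBundle":
        payload = joblib.load(path)
        version = payload.get("format_version")
        if version != FORMAT_VERSION:
            raise ValueError(
                f"model bundle format {version!r} unsupported "
                f"(expected {FORMAT_VERSION})"
            )
        return payload["bundle"]


def default_routing_bins(
    bins: LengthBins = DEFAULT_BINS, min_len: int = MIN_LENGTH
) -> tuple[tuple[int, int], ...]:
    """Positive-class bins, with the first extended down to the minimum length."""
    routed = list(bins.positive_bins)
    lo, hi = routed[0]
    routed[0] = (min(lo, min_len), hi)
    return tuple(routed)


def route(record: ProteinRecord, bundle: ModelBundle) -> tuple[str | None, str | None]:
    """``(bin_name, None)`` for a routable record, ``(None, reason)`` otherwise."""
    length = record.length
    first_lo = bundle.routing_bins[0][0]
    last_hi = bundle.routing_bins[-1][1]
    if length < first_lo:
        return None, f"length {length} < {first_lo}"
    if length > last_hi:
        return None, f"length {length} > {last_hi}"
    for name, (lo, hi) in zip(BIN_NAMES, bundle.routing_bins):
        last = name == BIN_NAMES[-1]
        if lo <= length < hi or (last and length == hi):
            return name, None
    return None, f"length {length} unroutable"  # pragma: no cover


def train_bundle(
    pos_records,
    neg_records,
    spec: KernelSpec,
    C: float = 1.0,
    seed: int = 0,
    bins: LengthBins = DEFAULT_BINS,
    tables: DescriptorTables = DEFAULT_TABLES,
) -> ModelBundle:
    """Train the 4-bin ensemble from labelled records.

    Each stratum's model is fit on one balanced draw (all positives plus an
    equal-size seeded negative subset).
    """
    subs, rejected = build_subdatasets(pos_records, neg_records, bins, tables)
    if rejected:
        logger.info("train_bundle: %d record(s) outside the binned range", len(rejected))
    models = {}
    for name in BIN_NAMES:
        sub = subs[name]
        replicate = make_balanced_replicates(sub, n_replicates=1, master_seed=seed)[0]
        models[name] = fit(replicate.X, replicate.y, spec, C)
    return ModelBundle(
        models=models,
        routing_bins=default_routing_bins(bins),
        metadata={"kernel": spec.name, "C": C, "seed": seed},
    )


def predict_records(
    records: Iterable[ProteinRecord],
    bundle: ModelBundle,
    threshold: float = 0.8,
    tables: DescriptorTables = DEFAULT_TABLES,
) -> pd.DataFrame:
    """Predict every record; one output row per input, in input order.

    Columns: id, length, bin, probability, label, note.  Rejected sequences
    keep their row with an empty bin, NaN probability, and the rejection
    reason in ``note``.
    """
    rows = []
    n_crg = n_rejected = 0
    for rec in records:
        bin_name, reason = route(rec, bundle)
        if bin_name is None:
            n_rejected += 1
            rows.append(
                {
                    "id": rec.id,
                    "length": rec.length,
                    "bin": "",
                    "probability": np.nan,
                    "label": "rejected",
                    "note": reason,
                }
            )
            continue
        model = bundle.models[bin_name]
        prob = float(model.predict(encode(rec, tables).values)[1][0])
        label = "CRG" if prob > threshold else "non-CRG"
        n_crg += label == "CRG"
        rows.append(
            {
                "id": rec.id,
                "length": rec.length,
                "bin": bin_name,
                "probability": prob,
                "label": label,
                "note": "",
            }
        )
    logger.info(
        "predicted %d sequence(s): %d CRG at threshold, %d rejected",
        len(rows),
        n_crg,
        n_rejected,
    )
    columns = ["id", "length", "bin", "probability", "label", "note"]
    return pd.DataFrame(rows, columns=columns)


def predict_proteome(
    fasta_path: str | Path,
    bundle: ModelBundle,
    threshold: float = 0.8,
    tables: DescriptorTables = DEFAULT_TABLES,
) -> pd.DataFrame:
    """Read a proteome FASTA (skipping invalid records) and predict it."""
    from .sequence_io import read_fasta

    records = read_fasta(fasta_path, policy="skip")
    return predict_records(records, bundle, threshold=threshold, tables=tables)
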