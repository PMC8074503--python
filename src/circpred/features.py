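"""The 62-dimensional numeric encoding of a protein sequence.

Layout (fixed order, 62 features):

====================  ==  =========================================
block                  k  contents
====================  ==  =========================================
``aac_*``             20  amino-acid composition (frequencies)
``protfp_*``           8  8-component residue-scale means
``fasgai_*``           6  6-component residue-scale means
``cruciani_*``         3  3-component residue-scale means
``trans_*``           21  CTD class-transition frequencies
physico-chemical       4  GRAVY, instability index, molecular
                          weight (Da), isoelectric point (pH)
====================  ==  =========================================

The 21 transition features decompose as 9 ordered hydrophobicity-class pairs
(3 classes, self-pairs included), 9 ordered secondary-structure-class pairs,
and 3 unordered solvent-accessibility-class pairs (2 classes).  Each block is
normalized by the number of adjacent residue pairs (L-1), so each of the
three sub-blocks sums to 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .descriptors import DEFAULT_TABLES, DescriptorTables
from .sequence_io import CANONICAL_RESIDUES, ProteinRecord

N_FEATURES = 62


def _scale_feature_names(tables: DescriptorTables) -> list[str]:
    names = [f"aac_{aa}" for aa in CANONICAL_RESIDUES]
    names += [f"protfp_{j + 1}" for j in range(8)]
    names += [f"fasgai_{j + 1}" for j in range(6)]
    names += [f"cruciani_{j + 1}" for j in range(3)]
    for prefix, grouping, ordered in (
        ("hyd", tables.ctd_hydrophobicity, True),
        ("ss", tables.ctd_secondary_structure, True),
        ("sa", tables.ctd_solvent_accessibility, False),
    ):
        for a, b in _class_pairs(list(grouping), ordered):
            names.append(f"trans_{prefix}_{a}_{b}")
    names += ["gravy", "instability_index", "molecular_weight", "isoelectric_point"]
    return names


def _class_pairs(classes: Sequence[str], ordered: bool) -> list[tuple[str, str]]:
    if ordered:
        return list(product(classes, classes))
    pairs = []
    for i, a in enumerate(classes):
        for b in classes[i:]:
            pairs.append((a, b))
    return pairs


#: Stable, documented feature-name order for the default tables.
FEATURE_NAMES: tuple[str, ...] = tuple(_scale_feature_names(DEFAULT_TABLES))
assert len(FEATURE_NAMES) == N_FEATURES


@dataclass(frozen=True)
class FeatureVector:
    """Ordered, named 62-dimensional descriptor vector for one sequence."""

    values: np.ndarray
    names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "values", np.asarray(self.values, dtype=float).reshape(-1)
        )
        if self.values.shape[0] != len(self.names):
            raise ValueError("values/names length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature vector contains non-finite values")

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.names))


def aac(record: ProteinRecord) -> np.ndarray:
    """Amino-acid composition: 20 residue frequencies, alphabetical order."""
    counts = np.zeros(20)
    index = {aa: i for i, aa in enumerate(CANONICAL_RESIDUES)}
    for ch in record.sequence:
        counts[index[ch]] += 1
    return counts / record.length


def scale_mean(
    record: ProteinRecord, table: Mapping[str, tuple[float, ...]]
) -> np.ndarray:
    """Arithmetic mean, over residues, of a multi-component residue scale."""
    rows = np.asarray([table[ch] for ch in record.sequence], dtype=float)
    return rows.mean(axis=0)


def _class_of(grouping: Mapping[str, str]) -> dict[str, str]:
    return {aa: cls for cls, members in grouping.items() for aa in members}


def transitional(
    record: ProteinRecord, tables: DescriptorTables = DEFAULT_TABLES
) -> np.ndarray:
    """The 21 CTD class-transition frequencies (9 + 9 + 3 layout).

    For each property grouping the sequence is mapped to its class string and
    adjacent-pair transitions are counted over the L-1 dipeptides, normalized
    by L-1.  Hydrophobicity and secondary structure use ordered pairs
    (self-pairs included); the two-class solvent-accessibility grouping uses
    unordered pairs, so each sub-block is a frequency simplex.
    """
    if record.length < 2:
        raise ValueError("transition features require length >= 2")
    blocks: list[np.ndarray] = []
    for grouping, ordered in (
        (tables.ctd_hydrophobicity, True),
        (tables.ctd_secondary_structure, True),
        (tables.ctd_solvent_accessibility, False),
    ):
        lookup = _class_of(grouping)
        classes = list(grouping)
        pairs = _class_pairs(classes, ordered)
        pair_index: dict[tuple[str, str], int] = {}
        for idx, (a, b) in enumerate(pairs):
            pair_index[(a, b)] = idx
            if not ordered:
                pair_index[(b, a)] = idx
        counts = np.zeros(len(pairs))
        seq = record.sequence
        for x, y in zip(seq, seq[1:]):
            counts[pair_index[(lookup[x], lookup[y])]] += 1
        blocks.append(counts / (record.length - 1))
    return np.concatenate(blocks)


def gravy(record: ProteinRecord, tables: DescriptorTables = DEFAULT_TABLES) -> float:
    """Grand average of hydropathy: mean Kyte–Doolittle value per residue."""
    scale = tables.hydrophobicity_scale
    return sum(scale[ch] for ch in record.sequence) / record.length


def molecular_weight(
    record: ProteinRecord, tables: DescriptorTables = DEFAULT_TABLES
) -> float:
    """Average molecular weight in Da: sum of residue masses plus one water."""
    masses = tables.residue_masses
    return sum(masses[ch] for ch in record.sequence) + tables.water_mass


def instability_index(
    record: ProteinRecord, tables: DescriptorTables = DEFAULT_TABLES
) -> float:
    """Guruprasad instability index: (10/L) * sum of DIWV over adjacent pairs."""
    if record.length < 2:
        raise ValueError("instability index requires length >= 2")
    seq = record.sequence
    total = sum(tables.diwv[x][y] for x, y in zip(seq, seq[1:]))
    return 10.0 * total / record.length


def net_charge(
    sequence: str, ph: float, tables: DescriptorTables = DEFAULT_TABLES
) -> float:
    """Henderson–Hasselbalch net charge of a sequence at a given pH."""
    pka = tables.pka_set
    charge = 1.0 / (1.0 + 10.0 ** (ph - pka["Nterm"]))
    charge -= 1.0 / (1.0 + 10.0 ** (pka["Cterm"] - ph))
    for aa, n in ((aa, sequence.count(aa)) for aa in "KRH"):
        charge += n / (1.0 + 10.0 ** (ph - pka[aa]))
    for aa, n in ((aa, sequence.count(aa)) for aa in "DECY"):
        charge -= n / (1.0 + 10.0 ** (pka[aa] - ph))
    return charge


def isoelectric_point(
    record: ProteinRecord,
    tables: DescriptorTables = DEFAULT_TABLES,
    tol: float = 1e-3,
) -> float:
    """pH at which the net charge crosses zero, by bisection on [0, 14]."""
    lo, hi = 0.0, 14.0
    if net_charge(record.sequence, lo, tables) < 0:
        return lo
    if net_charge(record.sequence, hi, tables) > 0:
        return hi
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(record.sequence, mid, tables) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def encode(
    record: ProteinRecord, tables: DescriptorTables = DEFAULT_TABLES
) -> FeatureVector:
    """Encode one record into the fixed 62-feature vector."""
    if record.length < 2:
        raise ValueError("encoding requires length >= 2")
    values = np.concatenate(
        [
            aac(record),
            scale_mean(record, tables.protfp),
            scale_mean(record, tables.fasgai),
            scale_mean(record, tables.cruciani),
            transitional(record, tables),
            [
                gravy(record, tables),
                instability_index(record, tables),
                molecular_weight(record, tables),
                isoelectric_point(record, tables),
            ],
        ]
    )
    return FeatureVector(values)


def encode_records(
    records: Iterable[ProteinRecord], tables: DescriptorTables = DEFAULT_TABLES
) -> pd.DataFrame:
    """Encode many records into a DataFrame (rows = sequences, 62 columns).

    The index holds record ids; a leading ``length`` column is included for
    downstream length-bin routing.
    """
    records = list(records)
    data = np.empty((len(records), N_FEATURES))
    for i, rec in enumerate(records):
        data[i] = encode(rec, tables).values
    df = pd.DataFrame(
        data, index=[r.id for r in records], columns=list(FEATURE_NAMES)
    )
    df.insert(0, "length", [r.length for r in records])
    return df
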