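"""Synthetic labelled protein sequences with controllable class separation.

Residues are drawn i.i.d. from a class-specific composition: the positive
class shifts probability mass +delta onto a designated residue subset (the
hydrophobic CTD class by default) and the negative class shifts -delta, both
renormalized.  With delta = 0 the classes are identically distributed, so
any downstream classifier should sit at chance; growing delta produces a
purely compositional signal that the 62-feature encoding captures.  An
optional two-state Markov switch adds adjacency structure for exercising the
transition features.  The i.i.d. model is sufficient for this package's
feature set, which is entirely composition- and adjacency-frequency-based;
it makes no attempt at biologically realistic circadian proteins.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .descriptors import CTD_HYDROPHOBICITY
from .sequence_io import CANONICAL_RESIDUES, ProteinRecord

#: Residues receiving the composition shift: the hydrophobic CTD class.
DEFAULT_EFFECT_RESIDUES: str = CTD_HYDROPHOBICITY["hydrophobic"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic dataset."""

    n_pos: int = 400
    n_neg: int = 400
    length_range: tuple[int, int] = (60, 400)
    base_composition: tuple[float, ...] = tuple([0.05] * 20)
    effect: float = 0.15  # per-class composition shift magnitude (delta)
    effect_residues: str = DEFAULT_EFFECT_RESIDUES
    seed: int = 0
    markov_self_bias: float = 0.0  # extra P(stay in the same CTD class)

    def __post_init__(self) -> None:
        base = np.asarray(self.base_composition, dtype=float)
        if base.shape != (20,) or np.any(base < 0) or abs(base.sum() - 1) > 1e-9:
            raise ValueError("base_composition must be a 20-point simplex")
        if self.effect < 0:
            raise ValueError("effect must be >= 0")
        if not set(self.effect_residues) <= set(CANONICAL_RESIDUES):
            raise ValueError("effect_residues must be canonical")
        lo, hi = self.length_range
        if lo < 2 or hi < lo:
            raise ValueError("invalid length_range")
        if not 0 <= self.markov_self_bias < 1:
            raise ValueError("markov_self_bias must be in [0, 1)")
        # the shifted compositions must stay on the simplex
        self.class_composition(-1)
        self.class_composition(+1)

    def class_composition(self, label: int) -> np.ndarray:
        """Residue distribution for one class (+1 positive, -1 negative)."""
        comp = np.asarray(self.base_composition, dtype=float).copy()
        subset = np.array([aa in self.effect_residues for aa in CANONICAL_RESIDUES])
        shift = label * self.effect / subset.sum()
        comp[subset] += shift
        if np.any(comp < 0):
            raise ValueError(
                f"effect {self.effect} pushes the class composition off the simplex"
            )
        return comp / comp.sum()


def _draw_sequence(
    rng: np.random.Generator, comp: np.ndarray, length: int, self_bias: float
) -> str:
    alphabet = np.frombuffer(CANONICAL_RESIDUES.encode(), dtype="S1")
    if self_bias == 0.0:
        idx = rng.choice(20, size=length, p=comp)
        return b"".join(alphabet[idx]).decode()
    # two-state Markov switch over CTD hydrophobicity classes: with probability
    # self_bias the next residue is redrawn from the current residue's class
    classes = {aa: cls for cls, members in CTD_HYDROPHOBICITY.items() for aa in members}
    members = {
        cls: np.array([i for i, aa in enumerate(CANONICAL_RESIDUES) if classes[aa] == cls])
        for cls in CTD_HYDROPHOBICITY
    }
    seq_idx = [int(rng.choice(20, p=comp))]
    for _ in range(length - 1):
        if rng.random() < self_bias:
            cls = classes[CANONICAL_RESIDUES[seq_idx[-1]]]
            pool = members[cls]
            p = comp[pool] / comp[pool].sum()
            seq_idx.append(int(rng.choice(pool, p=p)))
        else:
            seq_idx.append(int(rng.choice(20, p=comp)))
    return "".join(CANONICAL_RESIDUES[i] for i in seq_idx)


def generate(spec: SyntheticSpec) -> tuple[list[ProteinRecord], list[ProteinRecord]]:
    """Generate ``(positives, negatives)`` reproducibly from the spec seed."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.length_range
    out: list[list[ProteinRecord]] = []
    for label, n, prefix in ((1, spec.n_pos, "pos"), (-1, spec.n_neg, "neg")):
        comp = spec.class_composition(label)
        records = []
        for i in range(n):
            length = int(rng.integers(lo, hi + 1))
            seq = _draw_sequence(rng, comp, length, spec.markov_self_bias)
            records.append(ProteinRecord(id=f"{prefix}_{i + 1}", sequence=seq))
        out.append(records)
    return out[0], out[1]


def write_truth_table(
    pos: Sequence[ProteinRecord], neg: Sequence[ProteinRecord], path: str | Path
) -> None:
    """TSV of id, label (+1/-1), length for a generated dataset."""
    with open(path, "w") as fh:
        fh.write("id\tlabel\tlength\n")
        for rec in pos:
            fh.write(f"{rec.id}\t1\t{rec.length}\n")
        for rec in neg:
            fh.write(f"{rec.id}\t-1\t{rec.length}\n")
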