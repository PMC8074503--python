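"""Per-residue descriptor tables used by the feature encoder.

The numeric encoding needs five kinds of residue-level data:

* three multi-component descriptor scales (8-, 6- and 3-dimensional) filling
  the roles of the ProtFP, FASGAI and Cruciani scales — shipped as synthetic
  stand-ins (see :mod:`circpred._scales_synthetic`) and replaceable by the
  user;
* the Kyte–Doolittle hydropathy scale (GRAVY);
* the Guruprasad dipeptide instability weights (DIWV, 20x20);
* average residue masses and the mass of water (molecular weight);
* a pKa set (EMBOSS values) for the isoelectric point;
* three CTD property partitions of the residue alphabet (hydrophobicity,
  secondary-structure propensity, solvent accessibility) for the
  transition features.

Kyte–Doolittle, DIWV and masses come from Biopython's curated data modules.
All tables cover exactly the 20 canonical residues.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping

from Bio.Data.IUPACData import protein_weights
from Bio.SeqUtils import ProtParamData

from ._scales_synthetic import SYNTHETIC_PCP3, SYNTHETIC_PCP6, SYNTHETIC_PCP8
from .sequence_io import CANONICAL_RESIDUES

#: Average mass of one water molecule (Da), released per peptide bond.
WATER_MASS: float = 18.0153

#: Average residue (amino acid minus water) masses, Da.
RESIDUE_MASSES: Mapping[str, float] = MappingProxyType(
    {aa: protein_weights[aa] - WATER_MASS for aa in CANONICAL_RESIDUES}
)

#: Kyte–Doolittle hydropathy values.
KYTE_DOOLITTLE: Mapping[str, float] = MappingProxyType(dict(ProtParamData.kd))

#: Guruprasad dipeptide instability weights: DIWV[x][y] for dipeptide xy.
DIWV: Mapping[str, Mapping[str, float]] = MappingProxyType(
    {x: MappingProxyType(dict(row)) for x, row in ProtParamData.DIWV.items()}
)

#: EMBOSS pKa values for the termini and ionizable side chains.
EMBOSS_PKA: Mapping[str, float] = MappingProxyType(
    {
        "Nterm": 8.6,
        "Cterm": 3.6,
        "C": 8.5,
        "D": 3.9,
        "E": 4.1,
        "H": 6.5,
        "K": 10.8,
        "R": 12.5,
        "Y": 10.1,
    }
)

#: Side chains carrying positive charge below their pKa.
POSITIVE_RESIDUES = ("K", "R", "H")
#: Side chains carrying negative charge above their pKa.
NEGATIVE_RESIDUES = ("D", "E", "C", "Y")

# CTD property partitions.  Each grouping is a disjoint, exhaustive partition
# of the 20 residues; class order fixes the transition-feature layout.
CTD_HYDROPHOBICITY: Mapping[str, str] = MappingProxyType(
    {
        "polar": "RKEDQN",
        "neutral": "GASTPHY",
        "hydrophobic": "CLVIMFW",
    }
)
CTD_SECONDARY_STRUCTURE: Mapping[str, str] = MappingProxyType(
    {
        "helix": "EALMQKRH",
        "strand": "VIYCWFT",
        "coil": "GNPSD",
    }
)
CTD_SOLVENT_ACCESSIBILITY: Mapping[str, str] = MappingProxyType(
    {
        "buried": "ALFCGIVWMPSTHY",
        "exposed": "RKQEND",
    }
)


def _as_table(raw: Mapping[str, tuple]) -> Mapping[str, tuple[float, ...]]:
    return MappingProxyType({aa: tuple(raw[aa]) for aa in CANONICAL_RESIDUES})


def _check_partition(grouping: Mapping[str, str], name: str) -> None:
    joined = "".join(grouping.values())
    if sorted(joined) != sorted(CANONICAL_RESIDUES):
        raise ValueError(f"CTD grouping {name!r} is not a partition of the 20 residues")


@dataclass(frozen=True)
class DescriptorTables:
    """Bundle of the residue-level lookup tables behind one encoder version.

    The three multi-component scales default to the package's synthetic
    stand-ins; users holding the published ProtFP/FASGAI/Cruciani values can
    pass their own 20-row mappings of 8-, 6- and 3-tuples.
    """

    protfp: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: _as_table(SYNTHETIC_PCP8)
    )
    fasgai: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: _as_table(SYNTHETIC_PCP6)
    )
    cruciani: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: _as_table(SYNTHETIC_PCP3)
    )
    hydrophobicity_scale: Mapping[str, float] = field(default_factory=lambda: KYTE_DOOLITTLE)
    diwv: Mapping[str, Mapping[str, float]] = field(default_factory=lambda: DIWV)
    residue_masses: Mapping[str, float] = field(default_factory=lambda: RESIDUE_MASSES)
    water_mass: float = WATER_MASS
    pka_set: Mapping[str, float] = field(default_factory=lambda: EMBOSS_PKA)
    ctd_hydrophobicity: Mapping[str, str] = field(default_factory=lambda: CTD_HYDROPHOBICITY)
    ctd_secondary_structure: Mapping[str, str] = field(
        default_factory=lambda: CTD_SECONDARY_STRUCTURE
    )
    ctd_solvent_accessibility: Mapping[str, str] = field(
        default_factory=lambda: CTD_SOLVENT_ACCESSIBILITY
    )

    def __post_init__(self) -> None:
        for name, table, k in (
            ("protfp", self.protfp, 8),
            ("fasgai", self.fasgai, 6),
            ("cruciani", self.cruciani, 3),
        ):
            if set(table) != set(CANONICAL_RESIDUES):
                raise ValueError(f"{name} table must cover exactly the 20 residues")
            if any(len(v) != k for v in table.values()):
                raise ValueError(f"{name} table rows must have {k} components")
        for name, scale in (
            ("hydrophobicity_scale", self.hydrophobicity_scale),
            ("residue_masses", self.residue_masses),
        ):
            if set(scale) != set(CANONICAL_RESIDUES):
                raise ValueError(f"{name} must cover exactly the 20 residues")
        _check_partition(self.ctd_hydrophobicity, "hydrophobicity")
        _check_partition(self.ctd_secondary_structure, "secondary_structure")
        _check_partition(self.ctd_solvent_accessibility, "solvent_accessibility")


#: Default tables, shared across the package.
DEFAULT_TABLES = DescriptorTables()
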