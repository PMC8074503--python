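"""Regenerate the synthetic stand-in residue descriptor tables.

The encoder's ProtFP/FASGAI/Cruciani slots need per-residue numeric scales of
dimensionality 8, 6 and 3.  The published tables are embedded applications of
PCA to large physico-chemical property collections; the stand-ins shipped with
this package are built the same way, deterministically, from RDKit 2D
descriptors of the 20 free amino acids: standardize each descriptor across the
20 residues, run PCA, keep the leading components, and round to 4 decimals.

Run from the repository root; writes src/circpred/_scales_synthetic.py.
Requires rdkit (not a runtime dependency of the package itself).
"""

from __future__ import annotations

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors

AA_SMILES = {
    "A": "C[C@@H](C(=O)O)N",
    "R": "C(C[C@@H](C(=O)O)N)CN=C(N)N",
    "N": "C([C@@H](C(=O)O)N)C(=O)N",
    "D": "C([C@@H](C(=O)O)N)C(=O)O",
    "C": "C([C@@H](C(=O)O)N)S",
    "E": "C(CC(=O)O)[C@@H](C(=O)O)N",
    "Q": "C(CC(=O)N)[C@@H](C(=O)O)N",
    "G": "C(C(=O)O)N",
    "H": "C1=C(NC=N1)C[C@@H](C(=O)O)N",
    "I": "CC[C@H](C)[C@@H](C(=O)O)N",
    "L": "CC(C)C[C@@H](C(=O)O)N",
    "K": "C(CCN)C[C@@H](C(=O)O)N",
    "M": "CSCC[C@@H](C(=O)O)N",
    "F": "C1=CC=C(C=C1)C[C@@H](C(=O)O)N",
    "P": "C1C[C@H](NC1)C(=O)O",
    "S": "C([C@@H](C(=O)O)N)O",
    "T": "C[C@H]([C@@H](C(=O)O)N)O",
    "W": "C1=CC=C2C(=C1)C(=CN2)C[C@@H](C(=O)O)N",
    "Y": "C1=CC(=CC=C1C[C@@H](C(=O)O)N)O",
    "V": "CC(C)[C@@H](C(=O)O)N",
}

RESIDUES = sorted(AA_SMILES)


def descriptor_matrix() -> np.ndarray:
    rows = []
    for aa in RESIDUES:
        mol = Chem.MolFromSmiles(AA_SMILES[aa])
        rows.append([fn(mol) for _, fn in Descriptors.descList])
    X = np.asarray(rows, dtype=float)
    # drop constant / non-finite descriptor columns
    ok = np.all(np.isfinite(X), axis=0) & (np.std(X, axis=0) > 1e-12)
    X = X[:, ok]
    return (X - X.mean(axis=0)) / X.std(axis=0)


def pca_components(X: np.ndarray, k: int) -> np.ndarray:
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    scores = U[:, :k] * s[:k]
    # sign convention: largest-magnitude loading of each component positive
    for j in range(k):
        if scores[np.argmax(np.abs(scores[:, j])), j] < 0:
            scores[:, j] = -scores[:, j]
    return np.round(scores, 4)


def format_table(name: str, scores: np.ndarray) -> str:
    lines = [f"{name} = {{"]
    for i, aa in enumerate(RESIDUES):
        vals = ", ".join(f"{v: .4f}" for v in scores[i])
        lines.append(f'    "{aa}": ({vals}),')
    lines.append("}")
    return "\n".join(lines)


def main() -> None:
    X = descriptor_matrix()
    header = '''"""Synthetic stand-in residue descriptor scales.

These tables fill the 8-, 6- and 3-component descriptor slots of the feature
encoder (the roles played by the ProtFP, FASGAI and Cruciani scales).  They
are NOT the published values: they are synthetic stand-ins generated by
standardized PCA of RDKit 2D descriptors of the 20 free amino acids (see
scripts/derive_scales.py).  Users with access to the published tables can
substitute them via DescriptorTables.

Auto-generated; do not edit by hand.
"""

'''
    body = "\n\n".join(
        format_table(name, pca_components(X, k))
        for name, k in (
            ("SYNTHETIC_PCP8", 8),
            ("SYNTHETIC_PCP6", 6),
            ("SYNTHETIC_PCP3", 3),
        )
    )
    with open("src/circpred/_scales_synthetic.py", "w") as fh:
        fh.write(header + body + "\n")


if __name__ == "__main__":
    main()
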