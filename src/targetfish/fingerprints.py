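"""Circular fingerprints and Tanimoto similarity.

Molecules are represented by hashed circular substructures (Morgan
environments, ECFP-style).  Fingerprints are kept as sparse feature
*sets* rather than folded bit vectors, so Tanimoto similarity is exact:
no folding collisions.  A helper to fold into fixed-length bit vectors
is provided for interoperability with other toolkits.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .models import Fingerprint, Molecule, SimilarityMatrix

DEFAULT_RADIUS = 2  # ECFP4-equivalent neighbourhood


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return mol


def compute_fingerprint(molecule: Molecule, radius: int = DEFAULT_RADIUS) -> Fingerprint:
    """Hash the atom-centred environments of ``molecule`` up to ``radius``.

    The feature set is canonical: atom-order permutations of the same
    molecular graph yield identical sets.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    mol = _mol_from_smiles(molecule.smiles)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius)
    features = gen.GetSparseCountFingerprint(mol).GetNonzeroElements()
    return Fingerprint(
        compound_id=molecule.id,
        features=frozenset(features),
        radius=radius,
    )


def compute_fingerprints(
    molecules: Iterable[Molecule], radius: int = DEFAULT_RADIUS
) -> dict[str, Fingerprint]:
    """Fingerprint a collection; returns a compound_id -> Fingerprint map."""
    return {m.id: compute_fingerprint(m, radius) for m in molecules}


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Set Tanimoto |A∩B| / |A∪B| between two fingerprints.

    Both fingerprints must be computed at the same radius; two empty
    feature sets have no defined similarity.
    """
    if a.radius != b.radius:
        raise ValueError(f"fingerprint radius mismatch: {a.radius} vs {b.radius}")
    if not a.features and not b.features:
        raise ValueError("Tanimoto undefined for two empty feature sets")
    inter = len(a.features & b.features)
    union = len(a.features) + len(b.features) - inter
    return inter / union


def fold(fp: Fingerprint, n_bits: int = 2048) -> np.ndarray:
    """Fold a sparse fingerprint into a fixed-length 0/1 vector (modulo hash)."""
    if n_bits <= 0:
        raise ValueError("n_bits must be positive")
    bits = np.zeros(n_bits, dtype=np.uint8)
    for f in fp.features:
        bits[f % n_bits] = 1
    return bits


def tanimoto_folded(a: np.ndarray, b: np.ndarray) -> float:
    """Bit-vector Tanimoto on folded fingerprints."""
    inter = int(np.sum(a & b))
    union = int(np.sum(a | b))
    if union == 0:
        raise ValueError("Tanimoto undefined for two empty bit vectors")
    return inter / union


def similarity_matrix_from_fps(
    fps: Sequence[Fingerprint] | Mapping[str, Fingerprint],
) -> SimilarityMatrix:
    """All-against-all Tanimoto matrix from precomputed fingerprints."""
    if isinstance(fps, Mapping):
        fps = [fps[k] for k in fps]
    fps = list(fps)
    if not fps:
        raise ValueError("need at least one fingerprint")
    n = len(fps)
    values = np.ones((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            t = tanimoto(fps[i], fps[j])
            values[i, j] = values[j, i] = t
    return SimilarityMatrix(ids=[f.compound_id for f in fps], values=values)


def similarity_matrix(
    molecules: Sequence[Molecule], radius: int = DEFAULT_RADIUS
) -> SimilarityMatrix:
    """All-against-all Tanimoto matrix for a set of molecules."""
    molecules = list(molecules)
    if not molecules:
        raise ValueError("need at least one molecule")
    fps = [compute_fingerprint(m, radius) for m in molecules]
    return similarity_matrix_from_fps(fps)
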