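"""Molecular parsing, canonicalization, fingerprints, and similarity.

Thin, deterministic wrappers around RDKit that every other module consumes.
Molecules are exchanged as SMILES strings; atom indices are 0-based over
heavy atoms in parse order, hydrogens are implicit throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator, MACCSkeys

RDLogger.DisableLog("rdApp.*")  # parse errors are reported via exceptions

__all__ = [
    "Molecule",
    "Fingerprint",
    "FingerprintScheme",
    "InvalidSmilesError",
    "SchemeMismatchError",
    "parse_smiles",
    "canonicalize",
    "fingerprint",
    "tanimoto",
    "atom_environment",
]


class InvalidSmilesError(ValueError):
    """Raised when a SMILES string cannot be parsed; carries the string."""

    def __init__(self, smiles: str, reason: str = "invalid SMILES"):
        self.smiles = smiles
        super().__init__(f"{reason}: {smiles!r}")


class SchemeMismatchError(ValueError):
    """Raised when Tanimoto is requested across fingerprint schemes."""


class FingerprintScheme(str, Enum):
    """Supported fingerprint families.

    rdk_path: RDKit path-based fingerprint, max path length 7, 2048 bits.
    maccs:    166 MACCS structural keys.
    morgan:   circular fingerprint, radius 2, 2048 bits.
    """

    RDK_PATH = "rdk_path"
    MACCS = "maccs"
    MORGAN = "morgan"


# fingerprint parameters are fixed here so that results are reproducible
RDK_MAX_PATH = 7
RDK_N_BITS = 2048
MORGAN_RADIUS = 2
MORGAN_N_BITS = 2048
MACCS_N_BITS = 167  # RDKit reserves bit 0; keys are 1..166

BondOrder = str  # "single" | "double" | "triple" | "aromatic"

_BOND_ORDER = {
    Chem.BondType.SINGLE: "single",
    Chem.BondType.DOUBLE: "double",
    Chem.BondType.TRIPLE: "triple",
    Chem.BondType.AROMATIC: "aromatic",
}


@dataclass(frozen=True)
class Molecule:
    """A parsed molecule: SMILES plus its heavy-atom graph.

    Attributes
    ----------
    smiles : str
        The input SMILES string as given.
    canonical_smiles : str
        RDKit canonical SMILES; unique per molecular graph.
    atoms : tuple of (index, element, aromatic)
        Heavy atoms in RDKit parse order.
    bonds : tuple of (i, j, order)
        Bonds with i < j and order in {single, double, triple, aromatic}.
    rings : tuple of frozenset of atom indices
        Smallest set of smallest rings.
    """

    smiles: str
    canonical_smiles: str
    atoms: tuple
    bonds: tuple
    rings: tuple
    _rdmol: Chem.Mol = field(repr=False, compare=False, hash=False)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def rdkit_mol(self) -> Chem.Mol:
        """Underlying RDKit Mol (read-only use)."""
        return self._rdmol


@dataclass(frozen=True)
class Fingerprint:
    """A binary fingerprint as the set of on-bit indices."""

    scheme: FingerprintScheme
    bits: frozenset
    n_bits: int

    def __post_init__(self):
        if self.bits and max(self.bits) >= self.n_bits:
            raise ValueError("bit index exceeds n_bits")


def parse_smiles(smiles: str) -> Molecule:
    """Parse a SMILES string into a :class:`Molecule`.

    Raises
    ------
    InvalidSmilesError
        If the string is empty or fails RDKit sanitization.
    """
    if not isinstance(smiles, str) or not smiles:
        raise InvalidSmilesError(str(smiles), "empty SMILES")
    rdmol = Chem.MolFromSmiles(smiles)
    if rdmol is None:
        raise InvalidSmilesError(smiles)
    atoms = tuple(
        (a.GetIdx(), a.GetSymbol(), a.GetIsAromatic()) for a in rdmol.GetAtoms()
    )
    bonds = tuple(
        sorted(
            (
                min(b.GetBeginAtomIdx(), b.GetEndAtomIdx()),
                max(b.GetBeginAtomIdx(), b.GetEndAtomIdx()),
                _BOND_ORDER[b.GetBondType()],
            )
            for b in rdmol.GetBonds()
        )
    )
    rings = tuple(frozenset(r) for r in Chem.GetSymmSSSR(rdmol))
    return Molecule(
        smiles=smiles,
        canonical_smiles=Chem.MolToSmiles(rdmol),
        atoms=atoms,
        bonds=bonds,
        rings=rings,
        _rdmol=rdmol,
    )


def canonicalize(smiles: str) -> str:
    """Canonical SMILES for ``smiles``; graph-isomorphic inputs map to the
    same output and the map is idempotent."""
    return parse_smiles(smiles).canonical_smiles


def fingerprint(mol: Molecule, scheme: FingerprintScheme | str) -> Fingerprint:
    """Compute the fingerprint of ``mol`` under ``scheme``.

    Parameters are fixed (see module constants) so equal molecules always
    yield equal bit sets.
    """
    scheme = FingerprintScheme(scheme)
    rdmol = mol.rdkit_mol()
    if scheme is FingerprintScheme.RDK_PATH:
        gen = _rdk_generator()
        bv = gen.GetFingerprint(rdmol)
        n_bits = RDK_N_BITS
    elif scheme is FingerprintScheme.MORGAN:
        gen = _morgan_generator()
        bv = gen.GetFingerprint(rdmol)
        n_bits = MORGAN_N_BITS
    else:
        bv = MACCSkeys.GenMACCSKeys(rdmol)
        n_bits = MACCS_N_BITS
    return Fingerprint(scheme=scheme, bits=frozenset(bv.GetOnBits()), n_bits=n_bits)


_GENERATORS: dict = {}


def _rdk_generator():
    if "rdk" not in _GENERATORS:
        _GENERATORS["rdk"] = rdFingerprintGenerator.GetRDKitFPGenerator(
            maxPath=RDK_MAX_PATH, fpSize=RDK_N_BITS
        )
    return _GENERATORS["rdk"]


def _morgan_generator():
    if "morgan" not in _GENERATORS:
        _GENERATORS["morgan"] = rdFingerprintGenerator.GetMorganGenerator(
            radius=MORGAN_RADIUS, fpSize=MORGAN_N_BITS
        )
    return _GENERATORS["morgan"]


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto similarity |A∩B| / |A∪B| between two fingerprints.

    Both fingerprints must use the same scheme. If both bit sets are empty
    the similarity is defined as 0.0 (with a warning) to avoid 0/0.
    """
    if a.scheme != b.scheme:
        raise SchemeMismatchError(f"{a.scheme.value} vs {b.scheme.value}")
    union = len(a.bits | b.bits)
    if union == 0:
        warnings.warn("tanimoto of two empty fingerprints; returning 0.0")
        return 0.0
    return len(a.bits & b.bits) / union


def smiles_similarity(
    a: str, b: str, scheme: FingerprintScheme | str = FingerprintScheme.RDK_PATH
) -> float:
    """Convenience: Tanimoto similarity between two SMILES strings."""
    fa = fingerprint(parse_smiles(a), scheme)
    fb = fingerprint(parse_smiles(b), scheme)
    return tanimoto(fa, fb)


def atom_environment(mol: Molecule, atom_index: int):
    """Local environment of one atom.

    Returns
    -------
    (neighbors, aromatic, ring_sizes)
        ``neighbors`` is a list of (index, element) in ascending index order;
        ``aromatic`` is the atom's aromaticity flag; ``ring_sizes`` lists the
        sizes of SSSR rings containing the atom, ascending.
    """
    if not 0 <= atom_index < mol.n_atoms:
        raise IndexError(f"atom index {atom_index} out of range 0..{mol.n_atoms - 1}")
    neighbors = sorted(
        (j if i == atom_index else i, mol.atoms[j if i == atom_index else i][1])
        for i, j, _order in mol.bonds
        if atom_index in (i, j)
    )
    aromatic = mol.atoms[atom_index][2]
    ring_sizes = sorted(len(r) for r in mol.rings if atom_index in r)
    return neighbors, aromatic, ring_sizes
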