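"""Molecule handling, circular fingerprints, Tanimoto similarity, and descriptors.

All chemistry goes through RDKit. Molecules are represented by their canonical
SMILES; a molecule parsed from any SMILES spelling of the same structure maps
to the same :class:`Molecule` and hence the same fingerprint and descriptors.
Multi-fragment inputs (salts, solvates) are reduced to the largest fragment,
since catalogs list salt forms while descriptors are defined per parent.

Fingerprints are binary Morgan (ECFP-style) circular fingerprints folded to a
fixed width, computed with RDKit's ``MorganGenerator``; the default radius-3 /
2048-bit configuration is used everywhere in the pipeline unless overridden.
"""

from __future__ import annotations

import os
import sys
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional

import numpy as np
from rdkit import Chem, RDConfig, RDLogger
from rdkit.Chem import Descriptors, QED, rdFingerprintGenerator, rdMolDescriptors

from .errors import ConfigError, DimensionError, ParseError

RDLogger.DisableLog("rdApp.*")

# Ertl-Schuffenhauer synthetic-accessibility scorer shipped with RDKit Contrib.
sys.path.append(os.path.join(RDConfig.RDContribDir, "SA_Score"))
import sascorer  # noqa: E402

DEFAULT_RADIUS = 3
DEFAULT_N_BITS = 2048


@dataclass(frozen=True)
class Molecule:
    """A parsed molecule, keyed by its canonical SMILES.

    ``smiles_canonical`` is idempotent under :func:`canonicalize` and serves
    as the identity for deduplication throughout the pipeline.
    """

    smiles_canonical: str
    n_heavy_atoms: int
    source_id: Optional[str] = None

    def to_rdkit(self) -> Chem.Mol:
        return _mol_from_canonical(self.smiles_canonical)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.smiles_canonical


@dataclass(frozen=True)
class Fingerprint:
    """Binary circular fingerprint folded to ``n_bits``.

    Bits are stored packed (uint8, little-endian within each byte is
    irrelevant: packing is fixed by numpy's big-endian bitorder default),
    so Tanimoto reduces to vectorized popcounts.
    """

    packed: np.ndarray  # shape (n_bits // 8,), dtype uint8
    n_bits: int
    radius: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "packed", np.ascontiguousarray(self.packed, dtype=np.uint8))

    @property
    def popcount(self) -> int:
        return int(np.bitwise_count(self.packed).sum())

    @property
    def on_bits(self) -> np.ndarray:
        """Indices of set bits, ascending."""
        return np.flatnonzero(np.unpackbits(self.packed, count=self.n_bits))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Fingerprint):
            return NotImplemented
        return (
            self.n_bits == other.n_bits
            and self.radius == other.radius
            and bool(np.array_equal(self.packed, other.packed))
        )

    def __hash__(self) -> int:
        return hash((self.n_bits, self.radius, self.packed.tobytes()))


@dataclass(frozen=True)
class PropertyPanel:
    """The physicochemical/drug-likeness descriptors used in hit characterization.

    mw: molecular weight (g/mol, average atomic weights, implicit H included)
    heteroatom_count: heavy atoms that are neither carbon nor hydrogen
    rotatable_bonds: non-ring single bonds between non-terminal heavy atoms,
        amide C-N excluded
    qed: quantitative estimate of drug-likeness in [0, 1] (weighted-mean
        desirability parameterization)
    sa_score: synthetic accessibility in [1 easy, 10 hard]
    """

    mw: float
    heteroatom_count: int
    rotatable_bonds: int
    qed: float
    sa_score: float

    _FIELDS = ("mw", "heteroatom_count", "rotatable_bonds", "qed", "sa_score")

    def __getitem__(self, name: str) -> float:
        if name not in self._FIELDS:
            raise KeyError(name)
        return getattr(self, name)


@lru_cache(maxsize=200_000)
def _mol_from_canonical(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:  # canonical SMILES always reparse; defensive
        raise ParseError(f"cannot re-parse canonical SMILES: {smiles!r}")
    return mol


def canonicalize(smiles: str, source_id: Optional[str] = None) -> Molecule:
    """Parse a SMILES string into a :class:`Molecule`.

    Salts / multi-fragment inputs keep the largest fragment (by heavy-atom
    count, ties by canonical SMILES for determinism). Stereochemistry and
    formal charges are preserved.

    Raises
    ------
    ParseError
        If ``smiles`` is empty or not valid SMILES.
    """
    if not isinstance(smiles, str) or not smiles.strip():
        raise ParseError(f"empty or non-text SMILES input: {smiles!r}")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"unparsable SMILES: {smiles!r}")
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) > 1:
        mol = max(frags, key=lambda m: (m.GetNumHeavyAtoms(), Chem.MolToSmiles(m)))
    canonical = Chem.MolToSmiles(mol)
    return Molecule(
        smiles_canonical=canonical,
        n_heavy_atoms=mol.GetNumHeavyAtoms(),
        source_id=source_id,
    )


@lru_cache(maxsize=8)
def _morgan_generator(radius: int, n_bits: int):
    return rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)


def fingerprint(
    mol: Molecule, radius: int = DEFAULT_RADIUS, n_bits: int = DEFAULT_N_BITS
) -> Fingerprint:
    """Binary Morgan (ECFP-style) fingerprint of ``mol``, folded to ``n_bits``.

    Deterministic: the same molecule, from any SMILES spelling, yields
    identical bits for a given (radius, n_bits).
    """
    if radius < 0:
        raise ConfigError(f"radius must be >= 0, got {radius}")
    if n_bits < 8 or n_bits % 8 != 0:
        raise ConfigError(f"n_bits must be a multiple of 8 and >= 8, got {n_bits}")
    fp = _morgan_generator(radius, n_bits).GetFingerprintAsNumPy(mol.to_rdkit())
    return Fingerprint(packed=np.packbits(fp.astype(np.uint8)), n_bits=n_bits, radius=radius)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto similarity |a AND b| / |a OR b| in [0, 1]; two empty fingerprints -> 0."""
    if a.n_bits != b.n_bits:
        raise DimensionError(f"fingerprint widths differ: {a.n_bits} vs {b.n_bits}")
    inter = int(np.bitwise_count(a.packed & b.packed).sum())
    union = int(np.bitwise_count(a.packed | b.packed).sum())
    return inter / union if union else 0.0


def property_panel(mol: Molecule) -> PropertyPanel:
    """Compute the descriptor panel used for nomination characterization."""
    m = mol.to_rdkit()
    heteroatoms = sum(1 for a in m.GetAtoms() if a.GetAtomicNum() not in (1, 6))
    return PropertyPanel(
        mw=float(Descriptors.MolWt(m)),
        heteroatom_count=heteroatoms,
        rotatable_bonds=int(rdMolDescriptors.CalcNumRotatableBonds(m)),
        qed=float(QED.qed(m)),
        sa_score=float(sascorer.calculateScore(m)),
    )


def read_smi(path) -> list[tuple[str, str]]:
    """Read a ``.smi`` file: one ``SMILES<whitespace>ID`` record per line.

    Lines without an ID get a positional id ``row<N>``. Blank lines and
    ``#`` comments are skipped. Returns (id, smiles) pairs, unvalidated.
    """
    out: list[tuple[str, str]] = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smiles = parts[0]
            ident = parts[1].strip() if len(parts) > 1 else f"row{i}"
            out.append((ident, smiles))
    return out


def write_smi(path, records) -> None:
    """Write (id, smiles) pairs as ``SMILES ID`` lines."""
    with open(path, "w") as fh:
        for ident, smiles in records:
            fh.write(f"{smiles} {ident}\n")
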