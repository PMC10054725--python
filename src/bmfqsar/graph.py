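"""Molecular graphs: SMILES parsing, curation and canonicalization.

Structures are handled as hydrogen-suppressed graphs with explicit
attached-hydrogen counts, which is the representation all 2D descriptors
in this package operate on.  RDKit does the heavy lifting for SMILES
perception, aromaticity and canonical output; the :class:`MolecularGraph`
view exposes only the topology and atom attributes the descriptor engine
needs, so descriptor code never touches RDKit directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors as _RDDescriptors
from rdkit.Chem.MolStandardize import rdMolStandardize
from scipy.sparse.csgraph import shortest_path

RDLogger.DisableLog("rdApp.*")


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be interpreted as a molecule."""

    def __init__(self, smiles: str, detail: str = ""):
        self.smiles = smiles
        self.detail = detail
        msg = f"unparsable SMILES: {smiles!r}"
        if detail:
            msg += f" ({detail})"
        super().__init__(msg)


class CurationError(ValueError):
    """Raised when curation leaves no usable structure."""


@dataclass(frozen=True)
class Atom:
    element: str
    charge: int
    aromatic: bool
    n_h: int  # attached (implicit + explicit) hydrogens


@dataclass(frozen=True)
class Bond:
    i: int
    j: int
    order: int  # 1, 2 or 3 (aromatic bonds carry order 1 here, flag set)
    aromatic: bool

    @property
    def conventional_order(self) -> float:
        """Bond order with aromatic bonds counted as 1.5."""
        return 1.5 if self.aromatic else float(self.order)


@dataclass
class MolecularGraph:
    """Hydrogen-suppressed molecular graph with attached-H counts."""

    atoms: list[Atom]
    bonds: list[Bond]
    _mol: Chem.Mol = field(repr=False, compare=False, default=None)

    def __post_init__(self):
        n = len(self.atoms)
        seen = set()
        for b in self.bonds:
            if not (0 <= b.i < n and 0 <= b.j < n):
                raise ValueError(f"bond ({b.i},{b.j}) out of range for {n} atoms")
            if b.i == b.j:
                raise ValueError("self-bond not allowed")
            key = frozenset((b.i, b.j))
            if key in seen:
                raise ValueError(f"duplicate bond between {b.i} and {b.j}")
            seen.add(key)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def neighbors(self, i: int) -> list[int]:
        out = []
        for b in self.bonds:
            if b.i == i:
                out.append(b.j)
            elif b.j == i:
                out.append(b.i)
        return out

    def bond_between(self, i: int, j: int) -> Bond | None:
        for b in self.bonds:
            if {b.i, b.j} == {i, j}:
                return b
        return None

    def adjacency(self) -> np.ndarray:
        a = np.zeros((self.n_atoms, self.n_atoms))
        for b in self.bonds:
            a[b.i, b.j] = a[b.j, b.i] = 1.0
        return a

    def distance_matrix(self) -> np.ndarray:
        """Topological (shortest-path) distances between heavy atoms."""
        return shortest_path(self.adjacency(), method="BF", unweighted=True)

    def degrees(self) -> np.ndarray:
        a = self.adjacency()
        return a.sum(axis=1).astype(int)

    def is_connected(self) -> bool:
        if self.n_atoms <= 1:
            return True
        return np.all(np.isfinite(self.distance_matrix()))

    def to_rdkit(self) -> Chem.Mol:
        if self._mol is None:
            raise ValueError("graph has no attached RDKit molecule")
        return self._mol


def _graph_from_mol(mol: Chem.Mol) -> MolecularGraph:
    atoms = [
        Atom(
            element=a.GetSymbol(),
            charge=a.GetFormalCharge(),
            aromatic=a.GetIsAromatic(),
            n_h=a.GetTotalNumHs(),
        )
        for a in mol.GetAtoms()
    ]
    order_map = {
        Chem.BondType.SINGLE: 1,
        Chem.BondType.DOUBLE: 2,
        Chem.BondType.TRIPLE: 3,
        Chem.BondType.AROMATIC: 1,
    }
    bonds = []
    for b in mol.GetBonds():
        if b.GetBondType() not in order_map:
            raise SmilesParseError(Chem.MolToSmiles(mol), f"unsupported bond type {b.GetBondType()}")
        bonds.append(
            Bond(
                i=b.GetBeginAtomIdx(),
                j=b.GetEndAtomIdx(),
                order=order_map[b.GetBondType()],
                aromatic=b.GetIsAromatic(),
            )
        )
    return MolecularGraph(atoms=atoms, bonds=bonds, _mol=mol)


def parse_smiles(smiles: str) -> MolecularGraph:
    """Parse a SMILES string into a :class:`MolecularGraph`.

    Aromaticity is perceived and stereo descriptors are discarded (all
    descriptors used downstream are 2D and the endpoint data exclude
    stereoisomer-specific records).

    Raises
    ------
    SmilesParseError
        if the string is empty or cannot be interpreted.
    """
    if not isinstance(smiles, str) or not smiles.strip():
        raise SmilesParseError(str(smiles), "empty input")
    smiles = smiles.strip()
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        # second chance: defer sanitization so e.g. neutral-nitro forms load,
        # then let the standardizer repair them
        raw = Chem.MolFromSmiles(smiles, sanitize=False)
        if raw is None:
            raise SmilesParseError(smiles, "syntax error")
        try:
            mol = rdMolStandardize.Cleanup(raw)
        except Exception as exc:  # pragma: no cover - rdkit message varies
            raise SmilesParseError(smiles, str(exc)) from exc
        if mol is None:
            raise SmilesParseError(smiles, "sanitization failed")
    Chem.RemoveStereochemistry(mol)
    return _graph_from_mol(mol)


def _fragment_key(frag: Chem.Mol):
    """Sort key for salt stripping: most heavy atoms, then heaviest, then
    lexicographically smallest canonical SMILES."""
    return (
        -frag.GetNumHeavyAtoms(),
        -_RDDescriptors.MolWt(frag),
        Chem.MolToSmiles(frag),
    )


def curate(graph: MolecularGraph) -> MolecularGraph:
    """Curate a parsed structure the way the descriptor pipeline expects.

    Keeps the largest covalently connected component (salt removal),
    re-perceives aromaticity and rewrites nitro groups in the single
    charge-separated form ``[N+](=O)[O-]``.  Idempotent.
    """
    mol = graph.to_rdkit()
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if not frags:
        raise CurationError("no fragments after parsing")
    best = min(frags, key=_fragment_key)
    if best.GetNumHeavyAtoms() == 0:
        raise CurationError("empty structure after salt stripping")
    normalized = rdMolStandardize.Normalize(best)  # nitro & friends
    Chem.SanitizeMol(normalized)
    Chem.RemoveStereochemistry(normalized)
    Chem.SetAromaticity(normalized)
    return _graph_from_mol(normalized)


def canonicalize(graph: MolecularGraph) -> str:
    """Deterministic canonical SMILES of a (curated) graph."""
    return Chem.MolToSmiles(graph.to_rdkit())


def from_smiles(smiles: str) -> MolecularGraph:
    """Parse + curate in one step (the standard entry point)."""
    return curate(parse_smiles(smiles))


def canonical_smiles(smiles: str) -> str:
    """Canonical SMILES of the curated structure behind ``smiles``."""
    return canonicalize(from_smiles(smiles))
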