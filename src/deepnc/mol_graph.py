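"""SMILES to molecular graph featurization.

A compound is represented as its heavy-atom graph: nodes carry a
concatenation of five one-hot blocks (element symbol, degree, attached
hydrogens, implicit valence, aromaticity flag) and every covalent bond
is stored as two directed arcs.  For the hypergraph-convolution variant
the same molecule is additionally expressed as a node/hyperedge
incidence structure.

RDKit does all chemistry (parsing, ring perception, hydrogen counts);
this module fixes the feature schema and the deterministic ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.error")

__all__ = [
    "AtomFeatureSchema",
    "MolGraph",
    "HyperIncidence",
    "FeaturizationError",
    "atom_features",
    "smiles_to_graph",
    "build_hyperedges",
    "read_smiles_file",
]

#: 44-symbol organic/metal vocabulary; anything else hits the "other" slot.
DEFAULT_SYMBOLS = (
    "C", "N", "O", "S", "F", "Si", "P", "Cl", "Br", "Mg", "Na", "Ca", "Fe",
    "As", "Al", "I", "B", "V", "K", "Tl", "Yb", "Sb", "Sn", "Ag", "Pd", "Co",
    "Se", "Ti", "Zn", "H", "Li", "Ge", "Cu", "Au", "Ni", "Cd", "In", "Mn",
    "Zr", "Cr", "Pt", "Hg", "Pb",
)


class FeaturizationError(ValueError):
    """Raised when a SMILES string cannot be turned into a graph."""

    def __init__(self, smiles: str, reason: str = "unparseable SMILES"):
        self.smiles = smiles
        super().__init__(f"{reason}: {smiles!r}")


@dataclass(frozen=True)
class AtomFeatureSchema:
    """Defines the layout of the per-atom indicator vector.

    The vector is five concatenated blocks: one-hot element symbol with a
    trailing "other" slot, one-hot degree (0..degree_max, clamped), one-hot
    attached-hydrogen count, one-hot implicit valence, and one aromaticity
    bit.  A schema is frozen so a featurized dataset and a checkpoint can
    share it verbatim.
    """

    symbol_vocab: tuple = field(default=DEFAULT_SYMBOLS)
    degree_max: int = 10
    num_h_max: int = 10
    implicit_valence_max: int = 10

    @property
    def feature_length(self) -> int:
        return (len(self.symbol_vocab) + 1 + (self.degree_max + 1)
                + (self.num_h_max + 1) + (self.implicit_valence_max + 1) + 1)

    def to_dict(self) -> dict:
        return {
            "symbol_vocab": list(self.symbol_vocab),
            "degree_max": self.degree_max,
            "num_h_max": self.num_h_max,
            "implicit_valence_max": self.implicit_valence_max,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AtomFeatureSchema":
        return cls(symbol_vocab=tuple(d["symbol_vocab"]),
                   degree_max=int(d["degree_max"]),
                   num_h_max=int(d["num_h_max"]),
                   implicit_valence_max=int(d["implicit_valence_max"]))


@dataclass
class MolGraph:
    """Heavy-atom graph of one compound.

    ``edge_index`` stores each undirected bond as the two ordered arcs
    (i, j) and (j, i); atom order is RDKit's parse order, which is stable
    for a given SMILES string.
    """

    smiles: str
    num_atoms: int
    atom_features: np.ndarray  # [num_atoms, F] float 0/1
    edge_index: np.ndarray     # [num_edges, 2] int

    def adjacency(self) -> np.ndarray:
        a = np.zeros((self.num_atoms, self.num_atoms))
        for i, j in self.edge_index:
            a[i, j] = 1.0
        return a

    def permuted(self, perm: np.ndarray) -> "MolGraph":
        """Relabel atoms: new index of old atom i is perm[i]."""
        perm = np.asarray(perm, dtype=np.intp)
        inv = np.empty_like(perm)
        inv[perm] = np.arange(self.num_atoms)
        feats = self.atom_features[inv]
        edges = (perm[self.edge_index]
                 if len(self.edge_index) else self.edge_index.copy())
        return MolGraph(self.smiles, self.num_atoms, feats, edges)


@dataclass
class HyperIncidence:
    """Sparse incidence structure of a hypergraph.

    ``incidence`` lists (node, hyperedge) pairs of the binary matrix H;
    ``weights`` is the diagonal of the positive hyperedge weight matrix W.
    """

    num_nodes: int
    num_hyperedges: int
    incidence: np.ndarray  # [nnz, 2] int pairs (node, hyperedge)
    weights: np.ndarray    # [num_hyperedges] > 0

    def dense(self) -> np.ndarray:
        h = np.zeros((self.num_nodes, self.num_hyperedges))
        for i, e in self.incidence:
            h[i, e] = 1.0
        return h

    def validate(self) -> None:
        if len(self.weights) != self.num_hyperedges:
            raise ValueError("one weight per hyperedge required")
        if self.num_hyperedges and np.any(self.weights <= 0):
            raise ValueError("hyperedge weights must be positive")
        if self.num_hyperedges:
            sizes = np.bincount(self.incidence[:, 1],
                                minlength=self.num_hyperedges)
            if np.any(sizes < 2):
                raise ValueError("every hyperedge needs >= 2 incident nodes")


def atom_features(symbol: str, degree: int, num_h: int, implicit_valence: int,
                  is_aromatic: bool,
                  schema: AtomFeatureSchema) -> np.ndarray:
    """One atom's indicator vector; unknown symbols map to the "other"
    slot and counts above a block's maximum clamp to its last slot."""
    vocab = schema.symbol_vocab
    vec = np.zeros(schema.feature_length)
    try:
        vec[vocab.index(symbol)] = 1.0
    except ValueError:
        vec[len(vocab)] = 1.0
    off = len(vocab) + 1
    vec[off + min(degree, schema.degree_max)] = 1.0
    off += schema.degree_max + 1
    vec[off + min(num_h, schema.num_h_max)] = 1.0
    off += schema.num_h_max + 1
    vec[off + min(implicit_valence, schema.implicit_valence_max)] = 1.0
    off += schema.implicit_valence_max + 1
    vec[off] = 1.0 if is_aromatic else 0.0
    return vec


def smiles_to_graph(smiles: str,
                    schema: AtomFeatureSchema | None = None) -> MolGraph:
    """Parse a SMILES string into a :class:`MolGraph`.

    Hydrogens stay implicit (counted per heavy atom, never nodes) and the
    atom order is the parser's canonical order for that string.
    """
    if schema is None:
        schema = AtomFeatureSchema()
    if not smiles:
        raise FeaturizationError(smiles, "empty SMILES")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise FeaturizationError(smiles)
    n = mol.GetNumAtoms()
    feats = np.zeros((n, schema.feature_length))
    for atom in mol.GetAtoms():
        feats[atom.GetIdx()] = atom_features(
            atom.GetSymbol(), atom.GetDegree(), atom.GetTotalNumHs(),
            atom.GetImplicitValence(), atom.GetIsAromatic(), schema)
    arcs = []
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        arcs.append((i, j))
        arcs.append((j, i))
    edge_index = (np.array(arcs, dtype=np.intp) if arcs
                  else np.zeros((0, 2), dtype=np.intp))
    return MolGraph(smiles, n, feats, edge_index)


def build_hyperedges(g: MolGraph, mode: str = "bond") -> HyperIncidence:
    """Derive a hypergraph incidence from a molecular graph.

    mode "bond": one size-2 hyperedge per undirected bond (the molecular
    graph itself seen as a degenerate hypergraph).  mode "bond+ring":
    additionally one hyperedge per smallest ring joining that ring's
    atoms.  All weights are 1.  Hyperedges are ordered bonds-first, in
    bond order, then rings in perception order.
    """
    if mode not in ("bond", "bond+ring"):
        raise ValueError(f"unknown hyperedge mode: {mode!r}")
    pairs = []
    n_edges = 0
    seen = set()
    for i, j in g.edge_index:
        key = (min(i, j), max(i, j))
        if key in seen:
            continue
        seen.add(key)
        pairs.append((int(key[0]), n_edges))
        pairs.append((int(key[1]), n_edges))
        n_edges += 1
    if mode == "bond+ring":
        mol = Chem.MolFromSmiles(g.smiles)
        if mol is None:
            raise FeaturizationError(g.smiles)
        for ring in mol.GetRingInfo().AtomRings():
            for a in ring:
                pairs.append((int(a), n_edges))
            n_edges += 1
    incidence = (np.array(pairs, dtype=np.intp) if pairs
                 else np.zeros((0, 2), dtype=np.intp))
    inc = HyperIncidence(g.num_atoms, n_edges, incidence,
                         np.ones(n_edges))
    inc.validate()
    return inc


def read_smiles_file(path) -> list[str]:
    """Read SMILES strings, one per line; blank lines skipped."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]
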