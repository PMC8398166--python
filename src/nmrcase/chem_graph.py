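"""Heavy-atom molecular graphs with implicit hydrogens.

The central object is a labelled multigraph over heavy atoms only; hydrogens
are book-kept as a per-atom count (``n_h``) and never appear as nodes.  Each
atom additionally carries the number of pi bonds it participates in
(``n_pi``), so that the sigma-skeleton degree of every atom is fixed a priori:

    sigma_degree = valence - n_h - n_pi

This is what makes exhaustive constitution enumeration a degree-constrained
graph search.  Canonicalisation, SMILES and SDF output are delegated to RDKit;
shortest-path queries go through networkx.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
from rdkit import Chem
from rdkit.Chem import AllChem  # noqa: F401  (registers coordgen etc.)
from rdkit.Geometry import Point3D

__all__ = [
    "DEFAULT_VALENCES",
    "SUPPORTED_ELEMENTS",
    "AtomSpec",
    "MolecularGraph",
    "MolecularFormula",
    "parse_formula",
    "degrees_of_unsaturation",
    "topo_distance",
    "canonical_form",
    "read_smiles",
    "write_smiles",
    "to_rdkit",
    "write_sdf",
]

#: Default (neutral) total bond-order capacities.  Charged or hypervalent
#: atoms must be expressed through an explicit per-atom valence override.
DEFAULT_VALENCES: dict[str, int] = {
    "C": 4,
    "N": 3,
    "O": 2,
    "S": 2,
    "F": 1,
    "Cl": 1,
    "Br": 1,
    "I": 1,
}

SUPPORTED_ELEMENTS = frozenset(DEFAULT_VALENCES)

_HYBRIDIZATION_PI = {"sp3": 0, "sp2": 1, "sp": 2}


class GraphError(ValueError):
    """Raised for graphs or atoms that violate valence bookkeeping."""


@dataclass(frozen=True)
class AtomSpec:
    """A heavy atom with its hydrogen count and pi-bond budget.

    Parameters
    ----------
    label:
        Free-form user string ("C-7", "N1", ...).  Never reinterpreted.
    element:
        Element symbol; one of C, N, O, S and the halogens.
    n_h:
        Number of attached (implicit) hydrogens.
    n_pi:
        Number of pi bonds this atom participates in (0, 1 or 2).  A double
        bond contributes one pi at each end, a triple bond two.
    valence:
        Total bond-order capacity.  Defaults per element (C=4, N=3, O=2,
        S=2, halogens=1).
    allowed_neighbors:
        Optional restriction of the element symbols this atom may bond to.
    """

    label: str
    element: str
    n_h: int = 0
    n_pi: int = 0
    valence: Optional[int] = None
    allowed_neighbors: Optional[frozenset[str]] = None

    def __post_init__(self) -> None:
        if self.element not in SUPPORTED_ELEMENTS:
            raise GraphError(f"unsupported element {self.element!r}")
        if self.valence is None:
            object.__setattr__(self, "valence", DEFAULT_VALENCES[self.element])
        if self.allowed_neighbors is not None:
            object.__setattr__(
                self, "allowed_neighbors", frozenset(self.allowed_neighbors)
            )
            unknown = set(self.allowed_neighbors) - SUPPORTED_ELEMENTS
            if unknown:
                raise GraphError(f"unknown allowed_neighbors elements {sorted(unknown)}")
        if self.n_h < 0 or self.n_pi not in (0, 1, 2):
            raise GraphError(f"atom {self.label}: n_h must be >= 0 and n_pi in {{0,1,2}}")
        if self.n_h + self.n_pi > self.valence:
            raise GraphError(
                f"atom {self.label}: n_h + n_pi = {self.n_h + self.n_pi} "
                f"exceeds valence {self.valence}"
            )

    @property
    def sigma_degree(self) -> int:
        """Number of heavy-atom sigma bonds this atom must form."""
        return self.valence - self.n_h - self.n_pi

    @property
    def valence_is_default(self) -> bool:
        return self.valence == DEFAULT_VALENCES[self.element]

    @classmethod
    def from_dict(cls, d: Mapping) -> "AtomSpec":
        """Build from the native-dialect atom record (hybridization keyword
        or explicit n_pi; sp3 -> 0 pi, sp2 -> 1, sp -> 2)."""
        d = dict(d)
        label = d.pop("label")
        element = d.pop("element")
        n_h = int(d.pop("n_h", 0))
        if "n_pi" in d:
            n_pi = int(d.pop("n_pi"))
            d.pop("hybridization", None)
        elif "hybridization" in d:
            hyb = d.pop("hybridization")
            if hyb not in _HYBRIDIZATION_PI:
                raise GraphError(f"atom {label}: unknown hybridization {hyb!r}")
            n_pi = _HYBRIDIZATION_PI[hyb]
        else:
            n_pi = 0
        valence = d.pop("valence", None)
        allowed = d.pop("allowed_neighbors", None)
        if d:
            raise GraphError(f"atom {label}: unknown keys {sorted(d)}")
        return cls(
            label=label,
            element=element,
            n_h=n_h,
            n_pi=n_pi,
            valence=int(valence) if valence is not None else None,
            allowed_neighbors=frozenset(allowed) if allowed is not None else None,
        )


@dataclass
class MolecularGraph:
    """Heavy-atom graph: ordered atoms plus bonds with orders 1..3.

    ``bonds`` maps a frozenset pair of atom indices to a bond order.  A
    *complete* graph (``validate(complete=True)``) satisfies, per atom,
    sum of incident orders + n_h == valence and sum of (order-1) == n_pi.
    """

    atoms: list[AtomSpec]
    bonds: dict[frozenset, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = [a.label for a in self.atoms]
        if len(set(labels)) != len(labels):
            raise GraphError("duplicate atom labels")
        self.validate(complete=False)

    # -- bookkeeping ---------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def index_of(self, label: str) -> int:
        for i, a in enumerate(self.atoms):
            if a.label == label:
                return i
        raise KeyError(f"no atom labelled {label!r}")

    def add_bond(self, i: int, j: int, order: int = 1) -> None:
        if i == j:
            raise GraphError("self-loops are not allowed")
        key = frozenset((i, j))
        if key in self.bonds:
            raise GraphError(f"duplicate bond {i}-{j}")
        if order not in (1, 2, 3):
            raise GraphError(f"bond order {order} outside 1..3")
        self.bonds[key] = order

    def neighbors(self, i: int) -> list[int]:
        out = []
        for key in self.bonds:
            if i in key:
                (j,) = key - {i}
                out.append(j)
        return sorted(out)

    def sigma_edges(self) -> list[tuple[int, int]]:
        return sorted(tuple(sorted(k)) for k in self.bonds)

    def validate(self, complete: bool = True) -> None:
        n = self.n_atoms
        incident_order = [0] * n
        incident_pi = [0] * n
        for key, order in self.bonds.items():
            if len(key) != 2:
                raise GraphError("self-loop bond")
            i, j = sorted(key)
            if not (0 <= i < n and 0 <= j < n):
                raise GraphError(f"bond index out of range: {i}-{j}")
            if order not in (1, 2, 3):
                raise GraphError(f"bond order {order} outside 1..3")
            for v in (i, j):
                incident_order[v] += order
                incident_pi[v] += order - 1
        for v, atom in enumerate(self.atoms):
            if incident_order[v] + atom.n_h > atom.valence:
                raise GraphError(
                    f"atom {atom.label}: incident order {incident_order[v]} + "
                    f"{atom.n_h} H exceeds valence {atom.valence}"
                )
            if complete:
                if incident_order[v] + atom.n_h != atom.valence:
                    raise GraphError(
                        f"atom {atom.label}: valence not saturated "
                        f"({incident_order[v]} + {atom.n_h} != {atom.valence})"
                    )
                if incident_pi[v] != atom.n_pi:
                    raise GraphError(
                        f"atom {atom.label}: realised pi count {incident_pi[v]} "
                        f"!= declared {atom.n_pi}"
                    )

    def is_connected(self) -> bool:
        if self.n_atoms <= 1:
            return True
        return nx.is_connected(self.to_networkx())

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for i, a in enumerate(self.atoms):
            g.add_node(i, element=a.element, n_h=a.n_h, n_pi=a.n_pi, valence=a.valence)
        for key, order in self.bonds.items():
            i, j = sorted(key)
            g.add_edge(i, j, order=order)
        return g

    def formula(self) -> "MolecularFormula":
        counts: dict[str, int] = {}
        n_h = 0
        for a in self.atoms:
            counts[a.element] = counts.get(a.element, 0) + 1
            n_h += a.n_h
        if n_h:
            counts["H"] = n_h
        return MolecularFormula(counts)

    def relabelled(self, perm: Sequence[int]) -> "MolecularGraph":
        """Return the graph with atom i moved to position perm[i]."""
        n = self.n_atoms
        new_atoms: list[Optional[AtomSpec]] = [None] * n
        for i, a in enumerate(self.atoms):
            new_atoms[perm[i]] = a
        bonds = {
            frozenset((perm[i], perm[j])): order
            for (i, j), order in ((tuple(sorted(k)), o) for k, o in self.bonds.items())
        }
        return MolecularGraph(list(new_atoms), bonds)  # type: ignore[arg-type]


class MolecularFormula(dict):
    """Element -> count map, hydrogen included."""

    def __init__(self, counts: Mapping[str, int]):
        for el, c in counts.items():
            if c < 0:
                raise GraphError(f"negative count for {el}")
        super().__init__({el: int(c) for el, c in counts.items() if c})

    def consistent_with(self, atoms: Iterable[AtomSpec]) -> bool:
        return dict(self) == dict(MolecularGraph(list(atoms)).formula())


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> MolecularFormula:
    """Parse a Hill-notation-like molecular formula string.

    >>> dict(parse_formula("C8H10N4O2"))
    {'C': 8, 'H': 10, 'N': 4, 'O': 2}
    """
    counts: dict[str, int] = {}
    pos = 0
    pt = Chem.GetPeriodicTable()
    while pos < len(text):
        m = _FORMULA_TOKEN.match(text, pos)
        if not m or m.start() != pos or not m.group(1):
            raise GraphError(f"malformed formula at {text[pos:]!r}")
        symbol, digits = m.groups()
        try:
            known = pt.GetAtomicNumber(symbol) > 0
        except Exception:
            known = False
        if not known:
            raise GraphError(f"unknown element symbol {symbol!r}")
        counts[symbol] = counts.get(symbol, 0) + (int(digits) if digits else 1)
        pos = m.end()
    if not counts:
        raise GraphError("empty formula")
    return MolecularFormula(counts)


def degrees_of_unsaturation(f: Mapping[str, int]) -> float:
    """Double-bond equivalents: DBE = (2 nC + 2 + nN - nH - nHalogen) / 2.

    Divalent elements (O, S) do not enter.  May be negative for inconsistent
    input, which downstream feasibility checks flag.
    """
    n_c = f.get("C", 0)
    n_n = f.get("N", 0)
    n_h = f.get("H", 0)
    n_hal = sum(f.get(x, 0) for x in ("F", "Cl", "Br", "I"))
    return (2 * n_c + 2 + n_n - n_h - n_hal) / 2


def topo_distance(g: MolecularGraph, a: int, b: int) -> float:
    """Shortest heavy-atom bond path between atoms a and b.

    Bond orders are ignored; a heavy distance of d corresponds to a
    (d+1)-bond H->X coupling path once the H-X bond is counted.  Returns
    ``math.inf`` when the atoms sit in different components.
    """
    n = g.n_atoms
    if not (0 <= a < n and 0 <= b < n):
        raise IndexError(f"atom index out of range: {a}, {b}")
    if a == b:
        return 0
    try:
        return nx.shortest_path_length(g.to_networkx(), a, b)
    except nx.NetworkXNoPath:
        return math.inf


def _type_isotope(atom: AtomSpec) -> int:
    # Encode the atom type (H count, pi count, valence) into the isotope
    # field so that RDKit's canonical ranking sees it; the sigma-skeleton
    # SMILES then certifies (connectivity + atom types).
    return 1 + atom.n_pi + 10 * atom.n_h + 100 * atom.valence


def canonical_form(g: MolecularGraph) -> str:
    """Canonical certificate of the constitution.

    Computed on the sigma-skeleton plus atom types (element, n_h, n_pi,
    valence) so that alternative pi-bond matchings of one connectivity
    collapse to a single string.  Identical for all relabellings of
    isomorphic graphs.
    """
    g.validate(complete=True)
    mol = Chem.RWMol()
    for a in g.atoms:
        at = Chem.Atom(a.element)
        at.SetNoImplicit(True)
        at.SetIsotope(_type_isotope(a))
        mol.AddAtom(at)
    for key in g.bonds:
        i, j = sorted(key)
        mol.AddBond(i, j, Chem.BondType.SINGLE)
    m = mol.GetMol()
    m.UpdatePropertyCache(strict=False)
    return Chem.MolToSmiles(m, canonical=True)


_BOND_TYPES = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE, 3: Chem.BondType.TRIPLE}


def to_rdkit(g: MolecularGraph, sanitize: bool = True) -> Chem.Mol:
    """Convert to an RDKit molecule with explicit H counts and bond orders."""
    g.validate(complete=True)
    mol = Chem.RWMol()
    for a in g.atoms:
        at = Chem.Atom(a.element)
        at.SetNumExplicitHs(a.n_h)
        at.SetNoImplicit(True)
        mol.AddAtom(at)
    for key, order in g.bonds.items():
        i, j = sorted(key)
        mol.AddBond(i, j, _BOND_TYPES[order])
    m = mol.GetMol()
    if sanitize:
        Chem.SanitizeMol(m, catchErrors=True)
    else:
        m.UpdatePropertyCache(strict=False)
    return m


def write_smiles(g: MolecularGraph) -> str:
    """Canonical SMILES of the full (bond-order-resolved) graph."""
    return Chem.MolToSmiles(to_rdkit(g), canonical=True)


def read_smiles(s: str, label_prefix: str = "") -> MolecularGraph:
    """Parse a SMILES string into a heavy-atom graph.

    Aromatic systems are kekulized so that pi counts are well defined.
    Atoms receive labels "<element><index+1>" (1-based).  Charged species
    are rejected: the valence model is neutral.
    """
    mol = Chem.MolFromSmiles(s)
    if mol is None:
        raise GraphError(f"unparsable SMILES {s!r}")
    Chem.Kekulize(mol, clearAromaticFlags=True)
    orders: dict[frozenset, int] = {}
    pi = [0] * mol.GetNumAtoms()
    deg = [0] * mol.GetNumAtoms()
    for b in mol.GetBonds():
        o = int(b.GetBondTypeAsDouble())
        if o not in (1, 2, 3):
            raise GraphError(f"unsupported bond order {b.GetBondTypeAsDouble()}")
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        orders[frozenset((i, j))] = o
        for v in (i, j):
            pi[v] += o - 1
            deg[v] += o
    atoms = []
    for at in mol.GetAtoms():
        if at.GetFormalCharge() != 0:
            raise GraphError("charged atoms are not supported")
        sym = at.GetSymbol()
        if sym not in SUPPORTED_ELEMENTS:
            raise GraphError(f"unsupported element {sym!r} in SMILES")
        i = at.GetIdx()
        n_h = at.GetTotalNumHs()
        total = deg[i] + n_h
        atoms.append(
            AtomSpec(
                label=f"{label_prefix}{sym}{i + 1}",
                element=sym,
                n_h=n_h,
                n_pi=pi[i],
                valence=total if total != DEFAULT_VALENCES[sym] else None,
            )
        )
    g = MolecularGraph(atoms, orders)
    g.validate(complete=True)
    return g


def write_sdf(records: Iterable[tuple[Chem.Mol, Mapping[str, object]]]) -> str:
    """Serialise (molecule-with-conformer, properties) records to SDF V2000.

    Property fields are written as ``> <NAME>`` data items; the caller is
    responsible for supplying TOTAL_ENERGY / RESTRAINT_ENERGY / RANK keys
    where applicable.
    """
    chunks = []
    for mol, props in records:
        conf_id = 0 if mol.GetNumConformers() else -1
        if conf_id < 0:
            # graph only: give RDKit a zeroed conformer so V2000 is valid
            mol = Chem.Mol(mol)
            conf = Chem.Conformer(mol.GetNumAtoms())
            for i in range(mol.GetNumAtoms()):
                conf.SetAtomPosition(i, Point3D(0.0, 0.0, 0.0))
            mol.AddConformer(conf, assignId=True)
            conf_id = 0
        block = Chem.MolToMolBlock(mol, confId=conf_id, kekulize=True)
        lines = [block.rstrip("\n")]
        for key, value in props.items():
            lines.append(f">  <{key}>")
            lines.append(f"{value}")
            lines.append("")
        lines.append("$$$$")
        chunks.append("\n".join(lines))
    return "\n".join(chunks) + ("\n" if chunks else "")
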