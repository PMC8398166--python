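"""Stage-2 post-processing: deduplicate, embed in 3D, score, rank.

Assignments that share a canonical form are collapsed so only one
conformation search runs per constitution.  3D coordinates come from
distance geometry (RDKit): NOE-derived heavy-atom distance bounds are
written into the molecule's distance-bounds matrix *before* embedding, the
embedded structures are relaxed with MMFF94 plus flat-bottom harmonic
distance restraints, and each constitution keeps its lowest-total-energy
conformation.  The total energy is the force-field energy plus the
restraint penalty, so NOE violations directly worsen a proposal's rank;
constitutions that cannot be embedded at all are ranked strictly last.

Because protons are implicit, an NOE between two protons is projected onto
the carrier heavy atoms: the upper bound is padded by one C-H offset
(1.1 A) per side and the lower bound floored at 2.0 A heavy-heavy.
Force-field energies are only comparable within one run of one force
field; all ranking here is relative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, rdDistGeom

from .case_generator import Constitution, Solution
from .chem_graph import MolecularGraph, to_rdkit
from .nmr_data import NOERestraint

__all__ = [
    "PROTOCOLS",
    "DEFAULT_RESTRAINT_K",
    "Conformation",
    "RankedProposal",
    "deduplicate",
    "heavy_atom_bounds",
    "flat_bottom_penalty",
    "embed",
    "score",
    "rank",
    "rmsd_superpose",
]

#: Named ensemble sizes for the distance-geometry protocol.
PROTOCOLS = {"short": 90, "long": 499}

#: Flat-bottom harmonic force constant, kcal mol^-1 A^-2.
DEFAULT_RESTRAINT_K = 10.0

#: One C-H bond length, the per-side pad applied to proton-proton upper
#: bounds when projecting onto carrier heavy atoms.
_CH_PAD = 1.1

#: Heavy-heavy lower-bound floor (two bonded-to-H heavy atoms can hardly
#: approach closer).
_HEAVY_LOWER_FLOOR = 2.0


@dataclass
class Conformation:
    """One embedded 3D structure of a constitution.

    ``coordinates`` holds the heavy-atom positions (A) in the atom order of
    the representative graph; ``total_energy`` = force-field energy +
    restraint penalty (kcal/mol); ``per_restraint_violation`` gives, per
    NOE, the distance (A) by which the proxy distance falls outside its
    padded bounds (0 when satisfied).
    """

    coordinates: np.ndarray
    total_energy: float
    ff_energy: float
    restraint_energy: float
    per_restraint_violation: list[float]
    seed: int
    mol: Optional[Chem.Mol] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.restraint_energy < 0:
            raise ValueError("restraint energy must be non-negative")
        if not np.isfinite(self.total_energy):
            raise ValueError("total energy must be finite")


@dataclass
class RankedProposal:
    """A constitution with its best conformation (or a failure marker) and
    its 1-based rank; all failures rank after all successes."""

    constitution: Constitution
    conformation: Optional[Conformation]
    rank: int

    @property
    def failed(self) -> bool:
        return self.conformation is None


def deduplicate(solutions: Sequence[Solution]) -> list[Constitution]:
    """Group solutions by canonical form (one constitution per class).

    The representative graph is the first member in deterministic order;
    non-isomorphic graphs can never merge because the canonical form is a
    complete isomorphism certificate of (connectivity, atom types).
    """
    groups: dict[str, Constitution] = {}
    for s in sorted(solutions, key=lambda s: (s.canonical, s.sigma_edges())):
        c = groups.get(s.canonical)
        if c is None:
            groups[s.canonical] = Constitution(
                canonical=s.canonical, graph=s.graph, solutions=[s]
            )
        else:
            c.solutions.append(s)
    return [groups[k] for k in sorted(groups)]


def heavy_atom_bounds(noe: NOERestraint) -> tuple[float, float]:
    """Project proton-proton NOE bounds onto the carrier heavy atoms."""
    lower = max(_HEAVY_LOWER_FLOOR, noe.lower_bound)
    upper = noe.upper_bound + 2 * _CH_PAD
    return lower, upper


def flat_bottom_penalty(
    d: float, lower: float, upper: float, k: float = DEFAULT_RESTRAINT_K
) -> float:
    """Flat-bottom harmonic: 0 inside [lower, upper], k*(excess)^2 outside."""
    if d > upper:
        return k * (d - upper) ** 2
    if d < lower:
        return k * (lower - d) ** 2
    return 0.0


def _noe_index_bounds(
    graph: MolecularGraph, noes: Sequence[NOERestraint]
) -> list[tuple[int, int, float, float]]:
    out = []
    for r in noes:
        i = graph.index_of(r.label_a)
        j = graph.index_of(r.label_b)
        lb, ub = heavy_atom_bounds(r)
        out.append((i, j, lb, ub))
    return out


def _restraint_terms(
    coords: np.ndarray,
    idx_bounds: Sequence[tuple[int, int, float, float]],
    k: float,
) -> tuple[float, list[float]]:
    penalty = 0.0
    violations = []
    for i, j, lb, ub in idx_bounds:
        d = float(np.linalg.norm(coords[i] - coords[j]))
        penalty += flat_bottom_penalty(d, lb, ub, k)
        violations.append(max(0.0, d - ub, lb - d))
    return penalty, violations


def embed(
    constitution: Constitution | MolecularGraph,
    noes: Sequence[NOERestraint] = (),
    n_structures: int = PROTOCOLS["short"],
    seed: int = 0,
    k_restraint: float = DEFAULT_RESTRAINT_K,
) -> list[Conformation]:
    """Distance-geometry ensemble for one constitution.

    Runs ``n_structures`` independent embeddings with seeds ``seed``,
    ``seed+1``, ... (so a longer protocol's attempt set strictly contains a
    shorter one's for the same base seed), injecting NOE heavy-atom bounds
    into the distance-bounds matrix, then MMFF-minimising under flat-bottom
    restraints.  Failed attempts are recorded silently; an empty return
    marks an embedding failure for the whole constitution.
    """
    graph = constitution.graph if isinstance(constitution, Constitution) else constitution
    if n_structures < 1:
        raise ValueError("n_structures must be >= 1")
    try:
        mol = to_rdkit(graph)
        Chem.SanitizeMol(mol)
        molh = Chem.AddHs(mol)
    except Exception:
        return []
    n_heavy = graph.n_atoms
    idx_bounds = _noe_index_bounds(graph, noes)

    bm = rdDistGeom.GetMoleculeBoundsMatrix(molh)
    for i, j, lb, ub in idx_bounds:
        a, b = min(i, j), max(i, j)
        # upper triangle = upper bounds, lower triangle = lower bounds
        bm[a][b] = min(bm[a][b], ub)
        bm[b][a] = max(bm[b][a], lb)
        if bm[a][b] < bm[b][a]:  # NOE tighter than covalent geometry: defer to it
            bm[a][b] = bm[b][a] + 0.1
    from rdkit import DistanceGeometry

    DistanceGeometry.DoTriangleSmoothing(bm)

    mmff_props = AllChem.MMFFGetMoleculeProperties(molh)
    conformations: list[Conformation] = []
    for attempt in range(n_structures):
        params = rdDistGeom.EmbedParameters()
        params.randomSeed = int((seed + attempt) % (2**31 - 1))
        params.useRandomCoords = True
        params.SetBoundsMat(bm)
        params.clearConfs = True
        try:
            cid = rdDistGeom.EmbedMolecule(molh, params)
        except Exception:
            cid = -1
        if cid < 0:
            continue
        if mmff_props is not None:
            try:
                ff = AllChem.MMFFGetMoleculeForceField(molh, mmff_props, confId=cid)
                for i, j, lb, ub in idx_bounds:
                    ff.MMFFAddDistanceConstraint(i, j, False, lb, ub, k_restraint)
                ff.Minimize(maxIts=500)
                ff_plain = AllChem.MMFFGetMoleculeForceField(molh, mmff_props, confId=cid)
                ff_energy = float(ff_plain.CalcEnergy())
            except Exception:
                continue
        else:
            continue
        coords_all = molh.GetConformer(cid).GetPositions()
        coords = np.array(coords_all[:n_heavy], dtype=float)
        penalty, violations = _restraint_terms(coords, idx_bounds, k_restraint)
        keeper = Chem.Mol(molh)  # snapshot with this conformer only
        conformations.append(
            Conformation(
                coordinates=coords,
                total_energy=ff_energy + penalty,
                ff_energy=ff_energy,
                restraint_energy=penalty,
                per_restraint_violation=violations,
                seed=params.randomSeed,
                mol=keeper,
            )
        )
    conformations.sort(key=lambda c: c.total_energy)
    return conformations


def score(
    conformation: Conformation,
    noes: Sequence[NOERestraint],
    graph: Optional[MolecularGraph] = None,
    k: float = DEFAULT_RESTRAINT_K,
) -> tuple[float, float]:
    """(total_energy, restraint_energy) of a conformation under ``noes``.

    The restraint share is recomputed from the stored heavy-atom
    coordinates against the padded heavy-atom bounds; the force-field share
    is taken from the conformation.  Supplying ``graph`` allows scoring
    under a different NOE list than the one used at embedding time.
    """
    if graph is None:
        penalty = conformation.restraint_energy
    else:
        idx_bounds = _noe_index_bounds(graph, noes)
        penalty, _ = _restraint_terms(conformation.coordinates, idx_bounds, k)
    return conformation.ff_energy + penalty, penalty


def rank(
    items: Iterable[tuple[Constitution, Optional[Conformation]]]
) -> list[RankedProposal]:
    """Order proposals by ascending total energy, embedding failures last,
    ties broken by canonical form; ranks are 1..N."""
    successes = []
    failures = []
    for constitution, conf in items:
        (failures if conf is None else successes).append((constitution, conf))
    successes.sort(key=lambda t: (t[1].total_energy, t[0].canonical))
    failures.sort(key=lambda t: t[0].canonical)
    out = []
    for pos, (constitution, conf) in enumerate(successes + failures, start=1):
        out.append(RankedProposal(constitution=constitution, conformation=conf, rank=pos))
    return out


def rmsd_superpose(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    atom_map: Optional[Sequence[tuple[int, int]]] = None,
) -> float:
    """Least-squares rigid-body superposition RMSD (Kabsch, rotations only).

    ``atom_map`` pairs indices of a with indices of b (identity by
    default); at least 3 mapped atoms are required, and collinear point
    sets are flagged with a warning (the fit is then underdetermined).
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if atom_map is not None:
        ia, ib = zip(*atom_map)
        a = a[list(ia)]
        b = b[list(ib)]
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("coordinate arrays must be matching (n, 3)")
    n = a.shape[0]
    if n < 3:
        raise ValueError("need at least 3 mapped atoms")
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    if min(np.linalg.matrix_rank(a, tol=1e-8), np.linalg.matrix_rank(b, tol=1e-8)) < 2:
        warnings.warn("collinear coordinates: superposition is underdetermined")
    h = a.T @ b
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    diff = a @ rot.T - b
    return float(np.sqrt((diff**2).sum() / n))
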