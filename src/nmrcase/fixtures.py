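"""Reference structures and the synthetic experimental-data generator.

The caffeine constitution is fully specified here with its conventional
purine numbering; its complete theoretical correlation set is derivable
in-package and doubles as its experimental set.  The experimental
correlation lists of the two natural-product study systems (a
pyrrole-alkaloid with four observed 4J-HMBC correlations, and a
proton-rich diterpene with 15 NOEs) are not public, so this module ships
*synthetic stand-in* skeletons of the same flavour plus
:func:`make_fixture`, which emulates how such data sets arise: the
complete theoretical set of a known structure, thinned by random omission,
plus a chosen number of genuine four-bond HMBC entries.
"""

from __future__ import annotations

import random
from typing import Optional, Sequence

import networkx as nx

from .case_generator import GeneratorConfig
from .chem_graph import (
    DEFAULT_VALENCES,
    AtomSpec,
    MolecularGraph,
    read_smiles,
)
from .nmr_data import Correlation, CorrelationSet, write_input
from .theo_calc import backcalc

__all__ = [
    "caffeine",
    "CAFFEINE_SMILES",
    "oxo_alkaloid_like",
    "noe_terpenoid_like",
    "random_fixture_molecule",
    "make_fixture",
]

CAFFEINE_SMILES = "Cn1cnc2c1c(=O)n(C)c(=O)n2C"


def caffeine() -> MolecularGraph:
    """Caffeine with conventional purine numbering (N1/C2/N3/C4/C5/C6 ring,
    N7/C8/N9 imidazole, N-methyls C10/C11/C12, carbonyl oxygens O13/O14).

    The atom table carries the neighbour knowledge a spectroscopist reads
    off the 13C shifts before any structure generation: the three methyls
    (27.8/29.6/33.5 ppm) sit on nitrogen (C-CH3 would be < 25, O-CH3
    > 50 ppm), and C5 (107.4 ppm) cannot bear oxygen (an oxygenated sp2
    carbon resonates far downfield).  This per-atom typing is part of the
    input data, exactly as hybridisation and H counts are.
    """
    atoms = [
        AtomSpec("N1", "N", 0, 0),
        AtomSpec("C2", "C", 0, 1),
        AtomSpec("N3", "N", 0, 0),
        AtomSpec("C4", "C", 0, 1),
        AtomSpec("C5", "C", 0, 1, allowed_neighbors=frozenset({"C", "N"})),
        AtomSpec("C6", "C", 0, 1),
        AtomSpec("N7", "N", 0, 0),
        AtomSpec("C8", "C", 1, 1),
        AtomSpec("N9", "N", 0, 1),
        AtomSpec("C10", "C", 3, 0, allowed_neighbors=frozenset({"N"})),
        AtomSpec("C11", "C", 3, 0, allowed_neighbors=frozenset({"N"})),
        AtomSpec("C12", "C", 3, 0, allowed_neighbors=frozenset({"N"})),
        AtomSpec("O13", "O", 0, 1),
        AtomSpec("O14", "O", 0, 1),
    ]
    g = MolecularGraph(atoms)
    idx = {a.label: i for i, a in enumerate(atoms)}
    for a, b, order in [
        ("N1", "C2", 1),
        ("C2", "N3", 1),
        ("N3", "C4", 1),
        ("C4", "C5", 2),
        ("C5", "C6", 1),
        ("C6", "N1", 1),
        ("C5", "N7", 1),
        ("N7", "C8", 1),
        ("C8", "N9", 2),
        ("N9", "C4", 1),
        ("N1", "C10", 1),
        ("N3", "C11", 1),
        ("N7", "C12", 1),
        ("C2", "O13", 2),
        ("C6", "O14", 2),
    ]:
        g.add_bond(idx[a], idx[b], order)
    g.validate(complete=True)
    return g


def oxo_alkaloid_like() -> MolecularGraph:
    """Synthetic stand-in for an N-rich oxidised pyrrole-alkaloid skeleton
    (methylpyrrole carboxamide).  Not the published natural product; sized
    so that exhaustive generation from its own data stays desk-scale while
    offering several genuine four-bond H->C pairs for injection."""
    return read_smiles("CC1=CC(=CN1)C(N)=O")


def noe_terpenoid_like() -> MolecularGraph:
    """Synthetic stand-in for a proton-rich carbocyclic skeleton (acetyl
    trimethylcyclohexane): many COSY pairs and NOE-able proton-bearing
    centres, no heteroaromatics.  Not the published natural product."""
    return read_smiles("CC1CCC(C(C)=O)C(C)C1")


def random_fixture_molecule(
    seed: int,
    n_atoms: int = 6,
    elements: Sequence[str] = ("C", "C", "C", "N", "O"),
    p_extra_edge: float = 0.4,
    p_double: float = 0.3,
) -> MolecularGraph:
    """Random connected valence-consistent molecule for property tests.

    Draws a random spanning tree, sprinkles ring-closing edges and double
    bonds within valence capacity, and assigns all remaining valence to
    hydrogens.  Retries until at least one atom bears a proton.
    Deterministic in ``seed``.
    """
    rng = random.Random(seed)
    for _ in range(200):
        syms = [rng.choice(elements) for _ in range(n_atoms)]
        cap = [DEFAULT_VALENCES[s] for s in syms]
        edges: dict[tuple[int, int], int] = {}
        ok = True
        for i in range(1, n_atoms):
            partners = [j for j in range(i) if cap[j] > 0]
            if not partners or cap[i] == 0:
                ok = False
                break
            j = rng.choice(partners)
            edges[(j, i)] = 1
            cap[i] -= 1
            cap[j] -= 1
        if not ok:
            continue
        for _ in range(n_atoms):
            if rng.random() > p_extra_edge:
                continue
            candidates = [
                (i, j)
                for i in range(n_atoms)
                for j in range(i + 1, n_atoms)
                if (i, j) not in edges and cap[i] > 0 and cap[j] > 0
            ]
            if candidates:
                i, j = rng.choice(candidates)
                edges[(i, j)] = 1
                cap[i] -= 1
                cap[j] -= 1
        for e in sorted(edges):
            i, j = e
            if rng.random() < p_double and cap[i] > 0 and cap[j] > 0:
                edges[e] += 1
                cap[i] -= 1
                cap[j] -= 1
        if not any(cap):  # need at least one proton somewhere
            continue
        atoms = []
        pi = [0] * n_atoms
        for (i, j), order in edges.items():
            pi[i] += order - 1
            pi[j] += order - 1
        for i, s in enumerate(syms):
            atoms.append(AtomSpec(f"{s}{i + 1}", s, n_h=cap[i], n_pi=pi[i]))
        g = MolecularGraph(atoms, {frozenset(e): o for e, o in edges.items()})
        g.validate(complete=True)
        return g
    raise RuntimeError("could not draw a valid random molecule")


def _fourj_candidates(g: MolecularGraph) -> list[Correlation]:
    """Genuine heavy-distance-3 H->C pairs of the source constitution, as
    plain HMBC entries (one per unordered pair), deterministically ordered."""
    nxg = g.to_networkx()
    dists = dict(nx.all_pairs_shortest_path_length(nxg, cutoff=3))
    out = []
    seen = set()
    for i, a in enumerate(g.atoms):
        if a.n_h < 1:
            continue
        for j, d in dists[i].items():
            if d != 3 or g.atoms[j].element != "C":
                continue
            key = frozenset((a.label, g.atoms[j].label))
            if key in seen:
                continue
            seen.add(key)
            out.append(Correlation("HMBC", a.label, g.atoms[j].label))
    out.sort(key=lambda c: (c.from_label, c.to_label))
    return out


def make_fixture(
    known_structure: MolecularGraph,
    omission_rate: float = 0.0,
    n_injected_4j: int = 0,
    seed: int = 0,
    config: Optional[GeneratorConfig] = None,
) -> str:
    """Emulate an experimental data set from a known structure.

    Back-calculates the complete theoretical correlation set, removes a
    seeded random fraction ``omission_rate`` of it, injects
    ``n_injected_4j`` genuine four-bond HMBC entries (verified heavy
    distance 3 in the source), and emits the native JSON dialect.
    Reproducible by seed; raises when the structure offers fewer
    distance-3 H->C pairs than requested.
    """
    if not 0 <= omission_rate < 1:
        raise ValueError("omission_rate must be in [0, 1)")
    rng = random.Random(seed)
    cs = backcalc(known_structure)
    corrs = list(cs.correlations)
    n_remove = round(omission_rate * len(corrs))
    if n_remove:
        removed = set(rng.sample(range(len(corrs)), n_remove))
        corrs = [c for k, c in enumerate(corrs) if k not in removed]
    candidates = _fourj_candidates(known_structure)
    if n_injected_4j > len(candidates):
        raise ValueError(
            f"requested {n_injected_4j} four-bond injections but the structure "
            f"offers only {len(candidates)} distance-3 H->C pairs"
        )
    if n_injected_4j:
        corrs += rng.sample(candidates, n_injected_4j)
    out_cs = CorrelationSet(corrs, list(cs.noes), atoms=list(known_structure.atoms))
    return write_input(
        known_structure.atoms, out_cs, config if config is not None else GeneratorConfig()
    )
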