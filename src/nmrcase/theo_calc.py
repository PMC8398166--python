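"""Back-calculation of complete theoretical correlation sets.

Given a known constitution, derive every correlation the standard 2D
experiments could show: COSY between proton-bearing neighbours, HMBC from a
proton-bearing atom to carbons at heavy distance 1-2 (2J/3J), NHMBC likewise
to nitrogens, and 1,1-ADEQUATE between a protonated carbon and its directly
bonded carbons.  Feeding this theoretical set back into the generator
measures the intrinsic ambiguity of the molecule's NMR data: if more than
one constitution reproduces its own complete data set, no amount of
conventional correlation spectroscopy can tell them apart.

Correlations are emitted once per unordered heavy-atom pair: when both
partners bear protons the two directed cross peaks carry the same
topological information and collapse to a single entry (this is also how
the tabulated correlation counts of the study molecules are reached).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx

from .chem_graph import MolecularGraph, canonical_form
from .nmr_data import Correlation, CorrelationSet

__all__ = ["backcalc", "ReciprocityReport", "reciprocity_report"]


def _all_pairs_distances(g: MolecularGraph) -> dict[int, dict[int, int]]:
    return dict(nx.all_pairs_shortest_path_length(g.to_networkx(), cutoff=3))


def backcalc(
    g: MolecularGraph,
    kinds: Sequence[str] = ("COSY", "HMBC", "NHMBC", "ADEQ"),
    include_4j: bool = False,
) -> CorrelationSet:
    """Complete theoretical correlation set of a constitution.

    One entry per unordered atom pair and kind; deterministic order (kind,
    then labels).  With ``include_4j`` the heavy-distance-3 H->C pairs are
    appended as ordinary HMBC entries (the experiment cannot mark them).
    Raises on disconnected graphs.
    """
    g.validate(complete=True)
    if not g.is_connected():
        raise ValueError("back-calculation requires a connected graph")
    kinds = set(kinds)
    dists = _all_pairs_distances(g)
    atoms = g.atoms
    corrs: list[Correlation] = []
    seen: set[tuple] = set()

    _targets = {"HMBC": "C", "NHMBC": "N"}

    def emit(kind: str, i: int, j: int) -> None:
        la, lb = atoms[i].label, atoms[j].label
        pair_key = (kind, frozenset((la, lb)))
        if pair_key in seen:
            return
        seen.add(pair_key)
        # when either end could be the proton-bearing side, normalise the
        # stored direction by label so output is relabelling-invariant
        if kind in _targets:
            el = _targets[kind]
            if (
                atoms[j].n_h >= 1
                and atoms[i].element == el
                and atoms[j].element == el
                and lb < la
            ):
                la, lb = lb, la
        corrs.append(Correlation(kind=kind, from_label=la, to_label=lb))

    hmbc_span = (1, 2, 3) if include_4j else (1, 2)
    for i, a in enumerate(atoms):
        if a.n_h < 1:
            continue
        for j, d in dists[i].items():
            if j == i:
                continue
            b = atoms[j]
            if "COSY" in kinds and d == 1 and b.n_h >= 1:
                emit("COSY", i, j)
            if "ADEQ" in kinds and d == 1 and a.element == "C" and b.element == "C":
                emit("ADEQ", i, j)
            if "HMBC" in kinds and b.element == "C" and d in hmbc_span:
                emit("HMBC", i, j)
            if "NHMBC" in kinds and b.element == "N" and d in (1, 2):
                emit("NHMBC", i, j)

    corrs.sort(key=lambda c: (c.kind, c.from_label, c.to_label))
    return CorrelationSet(correlations=corrs, atoms=list(atoms))


@dataclass
class ReciprocityReport:
    """Ambiguity analysis of a constitution against its own theoretical
    data: how many solutions/constitutions the back-calculated set admits,
    and whether the input is among them (it always must be)."""

    n_solutions: int
    n_constitutions: int
    input_recovered: bool
    canonical_forms: list[str]


def reciprocity_report(g: MolecularGraph, config=None) -> ReciprocityReport:
    """Back-calculate, regenerate, and report the ambiguity of ``g``."""
    from .case_generator import GeneratorConfig, generate

    if config is None:
        config = GeneratorConfig()
    cs = backcalc(g)
    sols = generate(g.atoms, cs, config)
    forms = sorted({s.canonical for s in sols})
    own = canonical_form(g)
    return ReciprocityReport(
        n_solutions=len(sols),
        n_constitutions=len(forms),
        input_recovered=own in forms,
        canonical_forms=forms,
    )
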