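"""Exhaustive enumeration of molecular constitutions under NMR constraints.

Stage 1 of the two-stage workflow: given a heavy-atom list (with per-atom
hydrogen and pi counts fixing every sigma degree), a set of COSY / HMBC /
NHMBC / 1,1-ADEQUATE correlations, and a budget of HMBC correlations that
may be realised over four bonds (heavy distance 3), produce the COMPLETE
set of labelled graphs satisfying everything.

The search is a backtracking decision over candidate atom pairs in canonical
order with optimistic forward pruning: at every node a "possible graph"
(decided edges plus still-decidable pairs with residual sigma capacity on
both ends) is built, and a branch is abandoned when residual degrees cannot
be met, when the possible graph is disconnected, when a correlation cannot
reach its allowed distance even optimistically, or when more correlations
are forced to a four-bond interpretation than the budget allows.  Any edge
of the final graph is an edge of every ancestor's possible graph, so the
pruning is admissible and the enumeration complete; a brute-force oracle
(:func:`brute_force_enumerate`) referees this on small instances.

Four-bond accounting follows the *realised* minimal distance: an HMBC
correlation satisfiable at heavy distance <= 2 in a candidate never consumes
budget, even if the experimentalist suspected it of being long range.  This
is what lets a genuine 4J correlation be re-interpreted as 2J/3J while a
different correlation takes the 4J slot, enlarging the solution set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import pandas as pd

from .chem_graph import AtomSpec, GraphError, MolecularGraph, canonical_form
from .nmr_data import Correlation, CorrelationSet

__all__ = [
    "GeneratorConfig",
    "Solution",
    "Constitution",
    "generate",
    "verify",
    "brute_force_enumerate",
    "sweep_4j",
]

log = logging.getLogger(__name__)

_BRUTE_FORCE_MAX_ATOMS = 8


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the constitution generator.

    fourj_flag:
        Maximum number of HMBC correlations that may be realised at heavy
        distance 3 (four-bond coupling).  0 forbids any 4J interpretation,
        -1 removes the limit, k > 0 allows at most k.
    forbidden_bonds:
        Element pairs that may never bond (e.g. {frozenset({"N","N"}),
        frozenset({"N","O"})}).  Empty by default.
    """

    fourj_flag: int = 0
    forbidden_bonds: frozenset = frozenset()
    require_connected: bool = True
    strict_satisfaction: bool = True
    max_solutions: Optional[int] = None
    deterministic_order: bool = True

    def __post_init__(self) -> None:
        if self.fourj_flag < -1:
            raise ValueError("fourj_flag must be >= -1")
        if not self.strict_satisfaction:
            raise NotImplementedError(
                "only strict constraint satisfaction is implemented"
            )
        object.__setattr__(
            self,
            "forbidden_bonds",
            frozenset(frozenset(p) for p in self.forbidden_bonds),
        )

    def allows_4j(self) -> bool:
        return self.fourj_flag != 0


@dataclass
class Solution:
    """One labelled graph satisfying all constraints.

    Distinct solutions may be isomorphic: they then differ in which input
    label sits at which position (different *assignments* of one
    constitution).
    """

    graph: MolecularGraph
    assignment: dict[str, int]
    interpretation: dict[tuple, int]  # correlation key -> realised heavy distance
    fourj_used: int
    _canonical: Optional[str] = field(default=None, repr=False, compare=False)

    @property
    def canonical(self) -> str:
        if self._canonical is None:
            self._canonical = canonical_form(self.graph)
        return self._canonical

    def sigma_edges(self) -> tuple[tuple[int, int], ...]:
        return tuple(self.graph.sigma_edges())


@dataclass
class Constitution:
    """A connectivity class: all solutions sharing one canonical form."""

    canonical: str
    graph: MolecularGraph
    solutions: list[Solution] = field(default_factory=list)

    @property
    def n_assignments(self) -> int:
        return len(self.solutions)


# ---------------------------------------------------------------------------
# shared classification / verification


def _pi_matching(atoms: Sequence[AtomSpec], edges: Sequence[tuple[int, int]]):
    """Distribute pi bonds over sigma edges so every atom realises exactly
    its declared n_pi; returns {edge: extra_order} or None.

    Equivalent to a b-matching with per-atom demand n_pi and per-edge
    capacity 2 (bond order <= 3).  First solution in lexicographic edge
    order is returned, making the representative deterministic.
    """
    rem = [a.n_pi for a in atoms]
    edges = sorted(edges)
    n_e = len(edges)
    # remaining incident edges per atom, for pruning
    inc_after = [[0] * (n_e + 1) for _ in range(len(atoms))]
    for k in range(n_e - 1, -1, -1):
        i, j = edges[k]
        for v in range(len(atoms)):
            inc_after[v][k] = inc_after[v][k + 1] + (2 if v in (i, j) else 0)
    out: dict[tuple[int, int], int] = {}

    def bt(k: int) -> bool:
        if k == n_e:
            return all(r == 0 for r in rem)
        for v in range(len(rem)):
            if rem[v] > inc_after[v][k]:
                return False
        i, j = edges[k]
        for extra in range(0, min(rem[i], rem[j], 2) + 1):
            rem[i] -= extra
            rem[j] -= extra
            if bt(k + 1):
                if extra:
                    out[(i, j)] = extra
                return True
            rem[i] += extra
            rem[j] += extra
        return False

    return out if bt(0) else None


def _classify(graph: MolecularGraph, cs: CorrelationSet):
    """Realised minimal heavy distance per correlation (graph-exact BFS)."""
    n = graph.n_atoms
    adj: list[list[int]] = [[] for _ in range(n)]
    for key in graph.bonds:
        i, j = sorted(key)
        adj[i].append(j)
        adj[j].append(i)
    label_to_idx = {a.label: i for i, a in enumerate(graph.atoms)}
    sources = {label_to_idx[c.from_label] for c in cs.correlations}
    dist_from: dict[int, list[float]] = {}
    for s in sources:
        dist = [float("inf")] * n
        dist[s] = 0
        frontier = [s]
        d = 0
        while frontier:
            d += 1
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if dist[v] > d:
                        dist[v] = d
                        nxt.append(v)
            frontier = nxt
        dist_from[s] = dist
    out = {}
    for c in cs.correlations:
        a = label_to_idx[c.from_label]
        b = label_to_idx[c.to_label]
        out[c.key] = dist_from[a][b]
    return out


def solution_from_skeleton(
    atoms: Sequence[AtomSpec],
    edges: Iterable[tuple[int, int]],
    cs: CorrelationSet,
) -> Optional[Solution]:
    """Lift a sigma-skeleton to a full Solution (pi matching + correlation
    interpretation); None when no pi matching exists."""
    edges = [tuple(sorted(e)) for e in edges]
    match = _pi_matching(atoms, edges)
    if match is None:
        return None
    bonds = {frozenset(e): 1 + match.get(e, 0) for e in edges}
    graph = MolecularGraph(list(atoms), bonds)
    realized = _classify(graph, cs)
    interpretation = {}
    fourj = 0
    for c in cs.correlations:
        d = realized[c.key]
        interpretation[c.key] = d
        if c.kind == "HMBC" and d == 3 and d not in c.distances:
            fourj += 1
    return Solution(
        graph=graph,
        assignment={a.label: i for i, a in enumerate(atoms)},
        interpretation=interpretation,
        fourj_used=fourj,
    )


def verify(solution: Solution, cs: CorrelationSet, config: GeneratorConfig) -> list[str]:
    """Independent checker: every breach of valence, connectivity, forbidden
    bonds, neighbour restrictions, correlation distances or the 4J budget is
    listed; an empty list certifies the solution."""
    v: list[str] = []
    g = solution.graph
    try:
        g.validate(complete=True)
    except GraphError as e:
        v.append(f"valence: {e}")
    if config.require_connected and not g.is_connected():
        v.append("graph is disconnected")
    for key in g.bonds:
        i, j = sorted(key)
        ei, ej = g.atoms[i].element, g.atoms[j].element
        if frozenset((ei, ej)) in config.forbidden_bonds:
            v.append(f"forbidden bond {g.atoms[i].label}-{g.atoms[j].label} ({ei}-{ej})")
        for a, b in ((i, j), (j, i)):
            allowed = g.atoms[a].allowed_neighbors
            if allowed is not None and g.atoms[b].element not in allowed:
                v.append(
                    f"atom {g.atoms[a].label} bonded to disallowed element "
                    f"{g.atoms[b].element}"
                )
    realized = _classify(g, cs)
    fourj = 0
    for c in cs.correlations:
        d = realized[c.key]
        if d in c.distances:
            continue
        if c.kind == "HMBC" and d == 3 and config.allows_4j():
            fourj += 1
            continue
        v.append(
            f"{c.kind} {c.from_label}->{c.to_label}: realised distance {d} "
            f"not in allowed {sorted(c.distances)}"
        )
    if config.fourj_flag >= 0 and fourj > config.fourj_flag:
        v.append(f"4J budget exceeded: {fourj} > {config.fourj_flag}")
    return v


# ---------------------------------------------------------------------------
# the generator


def _pair_allowed(a: AtomSpec, b: AtomSpec, config: GeneratorConfig) -> bool:
    if frozenset((a.element, b.element)) in config.forbidden_bonds:
        return False
    if a.allowed_neighbors is not None and b.element not in a.allowed_neighbors:
        return False
    if b.allowed_neighbors is not None and a.element not in b.allowed_neighbors:
        return False
    return True


def generate(
    atoms: Sequence[AtomSpec],
    cs: CorrelationSet,
    config: GeneratorConfig = GeneratorConfig(),
) -> list[Solution]:
    """Enumerate every solution consistent with atoms, correlations and the
    4J budget.  Deterministically ordered (canonical form, then sigma edge
    list) unless ``config.deterministic_order`` is off."""
    atoms = list(atoms)
    cs = CorrelationSet(list(cs.correlations), list(cs.noes), atoms=atoms)
    n = len(atoms)
    sigma = [a.sigma_degree for a in atoms]
    if sum(sigma) % 2:
        log.warning("infeasible: sigma-degree sum %d is odd", sum(sigma))
        return []
    n_sigma_bonds = sum(sigma) // 2
    if config.require_connected and n > 1 and n_sigma_bonds < n - 1:
        log.warning(
            "infeasible: %d sigma bonds cannot connect %d atoms", n_sigma_bonds, n
        )
        return []

    label_to_idx = {a.label: i for i, a in enumerate(atoms)}

    # internal search order: most-constrained atoms first
    involvement = [0] * n
    for c in cs.correlations:
        involvement[label_to_idx[c.from_label]] += 1
        involvement[label_to_idx[c.to_label]] += 1
    order = sorted(range(n), key=lambda i: (-involvement[i], -sigma[i], atoms[i].label))
    int_atoms = [atoms[o] for o in order]
    int_sigma = [sigma[o] for o in order]
    to_internal = {o: k for k, o in enumerate(order)}

    allowed = [[False] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            ok = _pair_allowed(int_atoms[i], int_atoms[j], config)
            allowed[i][j] = allowed[j][i] = ok

    # correlations in internal indexing; distance-{1} constraints force edges
    forced: set[tuple[int, int]] = set()
    dist_corrs: list[tuple[int, int, frozenset, bool]] = []  # (a, b, dists, is_hmbc)
    for c in cs.correlations:
        a = to_internal[label_to_idx[c.from_label]]
        b = to_internal[label_to_idx[c.to_label]]
        if c.distances == frozenset({1}):
            forced.add((min(a, b), max(a, b)))
        else:
            dist_corrs.append((a, b, c.distances, c.kind == "HMBC"))

    res = list(int_sigma)
    adj = [0] * n
    for i, j in forced:
        if not allowed[i][j]:
            log.warning("infeasible: required bond between forbidden pair")
            return []
        adj[i] |= 1 << j
        adj[j] |= 1 << i
        res[i] -= 1
        res[j] -= 1
    if any(r < 0 for r in res):
        log.warning("infeasible: forced bonds exceed an atom's sigma capacity")
        return []

    pairs = [
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if allowed[i][j] and (i, j) not in forced
    ]
    n_pairs = len(pairs)
    full_mask = (1 << n) - 1
    budget = config.fourj_flag
    require_conn = config.require_connected
    results: list[Solution] = []
    cap = config.max_solutions

    def prune(k: int) -> bool:
        poss = list(adj)
        for idx in range(k, n_pairs):
            i, j = pairs[idx]
            if res[i] > 0 and res[j] > 0:
                poss[i] |= 1 << j
                poss[j] |= 1 << i
        for i in range(n):
            if res[i] > (poss[i] & ~adj[i]).bit_count():
                return False
        if require_conn and n > 1:
            seen = 1
            frontier = 1
            while frontier:
                nxt = 0
                m = frontier
                while m:
                    low = m & -m
                    nxt |= poss[low.bit_length() - 1]
                    m ^= low
                frontier = nxt & ~seen
                seen |= nxt
            if seen != full_mask:
                return False
        if dist_corrs:
            forced4 = 0
            reach_cache: dict[int, tuple[int, int, int]] = {}
            for a, b, dists, is_h in dist_corrs:
                r = reach_cache.get(a)
                if r is None:
                    r1 = poss[a]
                    r2 = r1
                    m = r1
                    while m:
                        low = m & -m
                        r2 |= poss[low.bit_length() - 1]
                        m ^= low
                    r3 = r2
                    m = r2
                    while m:
                        low = m & -m
                        r3 |= poss[low.bit_length() - 1]
                        m ^= low
                    r = (r1, r2, r3)
                    reach_cache[a] = r
                bbit = 1 << b
                if bbit & r[0]:
                    dmin = 1
                elif bbit & r[1]:
                    dmin = 2
                elif bbit & r[2]:
                    dmin = 3
                else:
                    dmin = 4
                if dmin in dists:
                    continue
                if is_h and dmin == 3 and budget != 0:
                    forced4 += 1
                    continue
                return False
            if budget > 0 and forced4 > budget:
                return False
        return True

    def finalize() -> None:
        edges_internal = list(forced)
        for i in range(n):
            m = adj[i]
            while m:
                low = m & -m
                j = low.bit_length() - 1
                m ^= low
                if j > i and (i, j) not in forced:
                    edges_internal.append((i, j))
        # map back to the caller's atom order
        edges = [tuple(sorted((order[i], order[j]))) for i, j in edges_internal]
        sol = solution_from_skeleton(atoms, edges, cs)
        if sol is None:
            return
        if verify(sol, cs, config):
            return
        results.append(sol)

    def rec(k: int) -> None:
        if cap is not None and len(results) >= cap:
            return
        # fast-forward over pairs that cannot be edges
        while k < n_pairs:
            i, j = pairs[k]
            if res[i] > 0 and res[j] > 0:
                break
            k += 1
        if not prune(k):
            return
        if k == n_pairs:
            if all(r == 0 for r in res):
                finalize()
            return
        i, j = pairs[k]
        # branch 1: place the edge
        adj[i] |= 1 << j
        adj[j] |= 1 << i
        res[i] -= 1
        res[j] -= 1
        rec(k + 1)
        adj[i] &= ~(1 << j)
        adj[j] &= ~(1 << i)
        res[i] += 1
        res[j] += 1
        # branch 2: leave it open
        rec(k + 1)

    rec(0)
    if config.deterministic_order:
        results.sort(key=lambda s: (s.canonical, s.sigma_edges()))
    return results


def brute_force_enumerate(
    atoms: Sequence[AtomSpec],
    cs: CorrelationSet,
    config: GeneratorConfig = GeneratorConfig(),
) -> list[Solution]:
    """Test oracle: enumerate ALL simple graphs meeting the sigma-degree
    sequence by unconstrained search, then keep those :func:`verify`
    accepts.  Capped at 8 heavy atoms."""
    atoms = list(atoms)
    if len(atoms) > _BRUTE_FORCE_MAX_ATOMS:
        raise ValueError(
            f"brute force capped at {_BRUTE_FORCE_MAX_ATOMS} atoms, got {len(atoms)}"
        )
    cs = CorrelationSet(list(cs.correlations), list(cs.noes), atoms=atoms)
    n = len(atoms)
    sigma = [a.sigma_degree for a in atoms]
    if sum(sigma) % 2:
        raise ValueError("infeasible sigma-degree sequence (odd sum)")
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    res = list(sigma)
    chosen: list[tuple[int, int]] = []
    results: list[Solution] = []
    # remaining incident pairs per atom from position k (degree feasibility)
    inc_after = [[0] * (len(pairs) + 1) for _ in range(n)]
    for k in range(len(pairs) - 1, -1, -1):
        i, j = pairs[k]
        for v in range(n):
            inc_after[v][k] = inc_after[v][k + 1] + (1 if v in (i, j) else 0)

    def rec(k: int) -> None:
        for v in range(n):
            if res[v] > inc_after[v][k]:
                return
        if k == len(pairs):
            if any(res):
                return
            sol = solution_from_skeleton(atoms, chosen, cs)
            if sol is not None and not verify(sol, cs, config):
                results.append(sol)
            return
        i, j = pairs[k]
        if res[i] > 0 and res[j] > 0:
            res[i] -= 1
            res[j] -= 1
            chosen.append((i, j))
            rec(k + 1)
            chosen.pop()
            res[i] += 1
            res[j] += 1
        rec(k + 1)

    rec(0)
    results.sort(key=lambda s: (s.canonical, s.sigma_edges()))
    return results


def sweep_4j(
    atoms: Sequence[AtomSpec],
    base_cs: CorrelationSet,
    named_4j_correlations: Sequence[Correlation],
    flags: Optional[Sequence[int]] = None,
    subsets: Optional[Sequence[Sequence[int]]] = None,
    config: GeneratorConfig = GeneratorConfig(),
) -> pd.DataFrame:
    """Solution counts over (injected-4J subset) x (4J budget) cells.

    ``named_4j_correlations`` are HMBC entries suspected of being four-bond;
    each subset of them is appended to the base data and :func:`generate`
    run at each flag value.  The default subsets mirror the study layout:
    the empty set, every single, then growing prefixes; data sets are
    lettered A, B, C, ... in that order.  Returns a tidy DataFrame with one
    row per cell (columns: data_set, fourj_flag, one indicator per named
    correlation, n_solutions, n_constitutions).
    """
    named = list(named_4j_correlations)
    if flags is None:
        flags = list(range(len(named) + 1)) + [-1]
    if subsets is None:
        subsets = [()]
        subsets += [(i,) for i in range(len(named))]
        subsets += [tuple(range(k)) for k in range(2, len(named) + 1)]
    rows = []
    for set_idx, subset in enumerate(subsets):
        letter = chr(ord("A") + set_idx)
        cs = CorrelationSet(
            list(base_cs.correlations) + [named[i] for i in subset],
            list(base_cs.noes),
            atoms=list(atoms),
        )
        for flag in flags:
            sols = generate(atoms, cs, replace(config, fourj_flag=flag))
            n_const = len({s.canonical for s in sols})
            row = {"data_set": letter, "fourj_flag": flag}
            for i, c in enumerate(named):
                row[f"{c.from_label}/{c.to_label}"] = "X" if i in subset else "-"
            row["n_solutions"] = len(sols)
            row["n_constitutions"] = n_const
            rows.append(row)
    return pd.DataFrame(rows)
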