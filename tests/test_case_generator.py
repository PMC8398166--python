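import random

import pytest

from nmrcase.case_generator import (
    GeneratorConfig,
    brute_force_enumerate,
    generate,
    sweep_4j,
    verify,
)
from nmrcase.chem_graph import AtomSpec
from nmrcase.fixtures import random_fixture_molecule
from nmrcase.nmr_data import Correlation, CorrelationSet
from nmrcase.theo_calc import backcalc


def chain_atoms():
    """Four sp3 carbons: CH3-CH2-CH2-CH3 degree sequence."""
    return [
        AtomSpec("C1", "C", n_h=3),
        AtomSpec("C2", "C", n_h=2),
        AtomSpec("C3", "C", n_h=2),
        AtomSpec("C4", "C", n_h=3),
    ]


def solution_set(solutions):
    return {(s.canonical, s.sigma_edges()) for s in solutions}


class TestGenerate:
    def test_single_atom(self):
        sols = generate([AtomSpec("C1", "C", n_h=4)], CorrelationSet())
        assert len(sols) == 1 and sols[0].graph.bonds == {}

    def test_fourj_budget_gates_long_range_hmbc(self):
        """An HMBC only satisfiable over four bonds blocks generation at
        budget 0 and opens the linear chain at budget 1."""
        atoms = chain_atoms()
        cs = CorrelationSet([Correlation("HMBC", "C1", "C4")])
        assert generate(atoms, cs, GeneratorConfig(fourj_flag=0)) == []
        sols = generate(atoms, cs, GeneratorConfig(fourj_flag=1))
        assert len(sols) >= 1
        for s in sols:
            assert s.fourj_used == 1
            assert s.interpretation[("HMBC", "C1", "C4")] == 3
        # oracle agreement at both budgets
        for flag in (0, 1):
            cfg = GeneratorConfig(fourj_flag=flag)
            assert solution_set(generate(atoms, cs, cfg)) == solution_set(
                brute_force_enumerate(atoms, cs, cfg)
            )

    def test_realized_distance_never_wastes_budget(self):
        """A nominally long-range correlation satisfied at distance <= 2
        in a candidate does not consume the 4J budget."""
        # ring closure: in cyclobutane C1..C4, C1-C4 are bonded (distance 1)
        atoms = [AtomSpec(f"C{i}", "C", n_h=2) for i in range(1, 5)]
        cs = CorrelationSet([Correlation("HMBC", "C1", "C4")])
        sols = generate(atoms, cs, GeneratorConfig(fourj_flag=0))
        assert sols and all(s.fourj_used == 0 for s in sols)

    def test_empty_on_infeasible_degrees(self):
        # three CH3: sigma-degree sum 3 is odd, no graph exists
        atoms = [AtomSpec(f"C{i}", "C", n_h=3) for i in range(1, 4)]
        assert generate(atoms, CorrelationSet()) == []

    def test_forbidden_bonds_respected(self):
        atoms = [AtomSpec("N1", "N", n_h=2), AtomSpec("N2", "N", n_h=2), AtomSpec("C1", "C", n_h=2)]
        cfg = GeneratorConfig(forbidden_bonds={frozenset({"N", "N"})})
        sols = generate(atoms, CorrelationSet(), cfg)
        assert sols  # N-C-N chain remains
        for s in sols:
            for key in s.graph.bonds:
                i, j = sorted(key)
                assert {s.graph.atoms[i].element, s.graph.atoms[j].element} != {"N"}

    def test_output_independent_of_atom_order(self):
        atoms = chain_atoms()
        cs = CorrelationSet([Correlation("COSY", "C1", "C2")])
        base = {s.canonical for s in generate(atoms, cs)}
        for seed in range(5):
            perm = atoms[:]
            random.Random(seed).shuffle(perm)
            shuffled = {s.canonical for s in generate(perm, cs)}
            assert shuffled == base

    def test_max_solutions_cap(self):
        atoms = chain_atoms()
        sols = generate(atoms, CorrelationSet(), GeneratorConfig(max_solutions=2))
        assert len(sols) == 2


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(8))
    @pytest.mark.parametrize("flag", [0, 1, -1])
    def test_generate_equals_brute_force(self, seed, flag):
        g = random_fixture_molecule(seed, n_atoms=5 + seed % 3)
        cs = backcalc(g)
        cfg = GeneratorConfig(fourj_flag=flag)
        assert solution_set(generate(g.atoms, cs, cfg)) == solution_set(
            brute_force_enumerate(g.atoms, cs, cfg)
        )

    def test_no_correlations_three_atoms_matches_oracle(self):
        atoms = [AtomSpec("C1", "C", n_h=2), AtomSpec("C2", "C", n_h=2), AtomSpec("O1", "O", n_h=0)]
        cs = CorrelationSet()
        assert solution_set(generate(atoms, cs)) == solution_set(
            brute_force_enumerate(atoms, cs)
        )

    def test_brute_force_atom_cap(self):
        atoms = [AtomSpec(f"C{i}", "C", n_h=3) for i in range(9)]
        with pytest.raises(ValueError):
            brute_force_enumerate(atoms, CorrelationSet())


class TestMonotonicity:
    def test_solution_sets_nested_in_budget(self):
        g = random_fixture_molecule(4, n_atoms=6)
        cs = backcalc(g, include_4j=True)  # contains genuine distance-3 entries
        prev = set()
        counts = []
        for flag in (0, 1, 2, 3):
            cur = solution_set(generate(g.atoms, cs, GeneratorConfig(fourj_flag=flag)))
            assert prev <= cur
            counts.append(len(cur))
            prev = cur
        unlimited = solution_set(generate(g.atoms, cs, GeneratorConfig(fourj_flag=-1)))
        assert prev <= unlimited
        assert counts == sorted(counts)

    def test_adding_correlation_never_enlarges_at_unlimited_budget(self):
        g = random_fixture_molecule(7, n_atoms=6)
        cs = backcalc(g)
        cfg = GeneratorConfig(fourj_flag=-1)
        full = solution_set(generate(g.atoms, cs, cfg))
        for drop in range(min(3, len(cs.correlations))):
            sub = CorrelationSet(
                [c for k, c in enumerate(cs.correlations) if k != drop], [], atoms=g.atoms
            )
            assert full <= solution_set(generate(g.atoms, sub, cfg))


class TestVerify:
    def test_generator_output_passes(self, caffeine_graph, caffeine_cs, caffeine_solutions):
        cfg = GeneratorConfig(
            fourj_flag=0,
            forbidden_bonds=frozenset({frozenset({"N", "N"}), frozenset({"N", "O"})}),
        )
        for s in caffeine_solutions:
            assert verify(s, caffeine_cs, cfg) == []

    def test_fabricated_long_range_correlation_listed(self, caffeine_graph):
        from nmrcase.case_generator import solution_from_skeleton

        # H10 -> C8 is five bonds away in caffeine (heavy distance 4)
        cs = CorrelationSet([Correlation("HMBC", "C10", "C8")], atoms=caffeine_graph.atoms)
        sol = solution_from_skeleton(
            caffeine_graph.atoms, [tuple(sorted(k)) for k in caffeine_graph.bonds], cs
        )
        violations = verify(sol, cs, GeneratorConfig(fourj_flag=-1))
        assert any("C10->C8" in v for v in violations)

    def test_forbidden_bond_listed(self):
        from nmrcase.case_generator import solution_from_skeleton

        atoms = [AtomSpec("N1", "N", n_h=2), AtomSpec("N2", "N", n_h=2)]
        sol = solution_from_skeleton(atoms, [(0, 1)], CorrelationSet(atoms=atoms))
        cfg = GeneratorConfig(forbidden_bonds={frozenset({"N", "N"})})
        assert any("forbidden" in v for v in verify(sol, CorrelationSet(atoms=atoms), cfg))

    def test_budget_overrun_listed(self):
        atoms = chain_atoms()
        cs = CorrelationSet([Correlation("HMBC", "C1", "C4")], atoms=atoms)
        from nmrcase.case_generator import solution_from_skeleton

        sol = solution_from_skeleton(atoms, [(0, 1), (1, 2), (2, 3)], cs)
        assert verify(sol, cs, GeneratorConfig(fourj_flag=1)) == []
        assert any("not in allowed" in v for v in verify(sol, cs, GeneratorConfig(fourj_flag=0)))


class TestSweep:
    def test_flag_minus_one_upper_bounds_every_flag(self):
        g = random_fixture_molecule(2, n_atoms=6)
        base = backcalc(g)
        df = sweep_4j(g.atoms, base, [], flags=[0, -1])
        by_flag = df.set_index("fourj_flag")["n_solutions"]
        assert by_flag[-1] >= by_flag[0]

    def test_empty_injection_at_flag_zero_equals_base_run(self):
        g = random_fixture_molecule(3, n_atoms=5)
        base = backcalc(g)
        df = sweep_4j(g.atoms, base, [], flags=[0])
        n_base = len(generate(g.atoms, base, GeneratorConfig(fourj_flag=0)))
        assert df.iloc[0]["n_solutions"] == n_base
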