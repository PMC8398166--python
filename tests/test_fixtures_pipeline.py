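import json

import pytest

from nmrcase.case_generator import GeneratorConfig, generate
from nmrcase.chem_graph import canonical_form, topo_distance
from nmrcase.fixtures import (
    make_fixture,
    noe_terpenoid_like,
    oxo_alkaloid_like,
    random_fixture_molecule,
)
from nmrcase.nmr_data import read_input
from nmrcase.pipeline import pipeline
from nmrcase.theo_calc import backcalc


class TestMakeFixture:
    def test_deterministic_in_seed(self):
        g = oxo_alkaloid_like()
        assert make_fixture(g, 0.3, 1, seed=42) == make_fixture(g, 0.3, 1, seed=42)
        assert make_fixture(g, 0.3, 1, seed=42) != make_fixture(g, 0.3, 1, seed=43)

    def test_zero_omission_zero_injection_is_theoretical_set(self, caffeine_graph):
        doc = make_fixture(caffeine_graph, 0.0, 0, seed=0)
        _, cs, _ = read_input(doc)
        theo = backcalc(caffeine_graph)
        assert {c.key for c in cs.correlations} == {c.key for c in theo.correlations}

    def test_injected_entries_are_distance_three_in_source(self):
        g = oxo_alkaloid_like()
        theo_keys = {c.key for c in backcalc(g).correlations}
        _, cs, _ = read_input(make_fixture(g, 0.0, 2, seed=1))
        injected = [c for c in cs.correlations if c.key not in theo_keys]
        assert len(injected) == 2
        idx = {a.label: i for i, a in enumerate(g.atoms)}
        for c in injected:
            assert topo_distance(g, idx[c.from_label], idx[c.to_label]) == 3

    def test_omission_removes_expected_fraction(self):
        g = oxo_alkaloid_like()
        n_theo = len(backcalc(g).correlations)
        _, cs, _ = read_input(make_fixture(g, 0.25, 0, seed=5))
        assert len(cs.correlations) == n_theo - round(0.25 * n_theo)

    def test_too_many_injections_rejected(self):
        with pytest.raises(ValueError, match="distance-3"):
            make_fixture(oxo_alkaloid_like(), 0.0, 99, seed=0)

    def test_round_trip_recovers_source(self):
        """Zero-omission fixture -> generate always finds the source."""
        for seed in (0, 1, 2):
            g = random_fixture_molecule(seed, n_atoms=6)
            doc = make_fixture(g, 0.0, 0, seed=seed)
            atoms, cs, config = read_input(doc)
            forms = {s.canonical for s in generate(atoms, cs, config)}
            assert canonical_form(g) in forms


class TestFourJBudgetPattern:
    def test_zero_below_injection_count_recovered_at_it(self):
        """n genuine 4J entries: generation fails for every budget < n and
        recovers the source constitution at budget n."""
        g = oxo_alkaloid_like()
        n_inject = 2
        atoms, cs, _ = read_input(make_fixture(g, 0.0, n_inject, seed=3))
        counts = {}
        for flag in range(n_inject + 1):
            sols = generate(atoms, cs, GeneratorConfig(fourj_flag=flag))
            counts[flag] = len(sols)
            if flag < n_inject:
                assert sols == []
            else:
                assert len(sols) >= 1
                assert canonical_form(g) in {s.canonical for s in sols}

    def test_table_experiment_zero_cells(self):
        g = oxo_alkaloid_like()
        base = backcalc(g)
        from nmrcase.fixtures import _fourj_candidates

        named = _fourj_candidates(g)[:2]
        doc_atoms = g.atoms
        from nmrcase.case_generator import sweep_4j

        df = sweep_4j(doc_atoms, base, named, flags=[0, 1, 2, -1])
        for _, row in df.iterrows():
            n_injected = sum(row[f"{c.from_label}/{c.to_label}"] == "X" for c in named)
            flag = row["fourj_flag"]
            if flag != -1 and flag < n_injected:
                assert row["n_solutions"] == 0
        # the unlimited column upper-bounds every finite flag per data set
        for ds, block in df.groupby("data_set"):
            unlimited = block[block.fourj_flag == -1]["n_solutions"].iloc[0]
            assert (block[block.fourj_flag != -1]["n_solutions"] <= unlimited).all()


class TestPipeline:
    def test_caffeine_end_to_end(self, caffeine_graph):
        cfg = GeneratorConfig(
            fourj_flag=0,
            forbidden_bonds=frozenset({frozenset({"N", "N"}), frozenset({"N", "O"})}),
        )
        doc = make_fixture(caffeine_graph, 0.0, 0, seed=0, config=cfg)
        res = pipeline(doc, n_structures=8, seed=7)
        assert res.report["n_constitutions"] == 3
        assert res.report["n_embedded"] == 3
        assert [p["rank"] for p in res.report["proposals"]] == [1, 2, 3]
        energies = [p["total_energy"] for p in res.report["proposals"]]
        assert energies == sorted(energies)
        assert res.sdf.count("$$$$") == 3
        assert ">  <TOTAL_ENERGY>" in res.sdf

    def test_infeasible_input_empty_with_diagnostic(self):
        doc = {
            "atoms": [
                {"label": "C1", "element": "C", "n_h": 3},
                {"label": "C2", "element": "C", "n_h": 3},
                {"label": "C3", "element": "C", "n_h": 3},
            ]
        }
        res = pipeline(json.dumps(doc), n_structures=1)
        assert res.report["n_solutions"] == 0
        assert "diagnostic" in res.report

    def test_empty_correlations_ranks_all_feasible_graphs(self):
        from nmrcase.case_generator import brute_force_enumerate
        from nmrcase.chem_graph import AtomSpec
        from nmrcase.nmr_data import CorrelationSet

        atoms = [
            AtomSpec("C1", "C", n_h=3),
            AtomSpec("C2", "C", n_h=2),
            AtomSpec("O1", "O", n_h=1),
        ]
        doc = {
            "atoms": [
                {"label": a.label, "element": a.element, "n_h": a.n_h} for a in atoms
            ]
        }
        res = pipeline(json.dumps(doc), n_structures=3, seed=1)
        oracle = brute_force_enumerate(atoms, CorrelationSet())
        assert res.report["n_solutions"] == len(oracle)
        assert res.report["n_constitutions"] == len({s.canonical for s in oracle})

    def test_noe_pipeline_embeds_all_assignments(self):
        """With NOEs present every assignment is embedded, and restraint
        energies appear in the report."""
        from nmrcase.nmr_data import NOERestraint, write_input

        g = noe_terpenoid_like()
        cs = backcalc(g)
        cs.noes = [NOERestraint("C1", "C9")]
        cs.resolve(g.atoms)
        doc = write_input(g.atoms, cs, GeneratorConfig())
        res = pipeline(doc, n_structures=3, seed=2)
        assert res.report["n_embedded"] >= 1
        top = res.report["proposals"][0]
        assert top["restraint_energy"] is not None


def test_cli_round_trip(tmp_path):
    from click.testing import CliRunner

    from nmrcase.cli import main

    runner = CliRunner()
    fix = tmp_path / "fix.json"
    r = runner.invoke(
        main,
        ["fixture", "--smiles", "CCO", "--seed", "1", "-o", str(fix)],
    )
    assert r.exit_code == 0, r.output
    sols = tmp_path / "sols.smi"
    r = runner.invoke(main, ["generate", "--input", str(fix), "-o", str(sols)])
    assert r.exit_code == 0, r.output
    assert len(sols.read_text().strip().splitlines()) == 1
    sdf = tmp_path / "ranked.sdf"
    r = runner.invoke(
        main,
        ["rank", "--solutions", str(sols), "--input", str(fix), "-o", str(sdf)],
    )
    assert r.exit_code == 0, r.output
    assert "$$$$" in sdf.read_text()
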