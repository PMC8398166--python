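# nmrcase

Computer-assisted structure elucidation (CASE) from 2D-NMR correlation
data, for natural-product and small-molecule NMR spectroscopists.

Determining a constitution from COSY, HMBC, ¹H,¹⁵N-HMBC and
1,1-ADEQUATE data is a constraint-satisfaction problem: every heavy atom
carries a fixed number of hydrogens and π bonds (so its σ-bond degree is
known a priori), and every correlation restricts the topological distance
between two labelled atoms.  The notorious complication is the HMBC
experiment: a cross peak usually means a two- or three-bond H→C coupling
(heavy-atom distance 1–2), but occasionally spans four bonds (distance 3),
and misreading a single ⁴J peak as ²J/³J makes every standard generator
fail.  `nmrcase` implements a two-stage workflow around this:

1. **Generation.**  Exhaustive backtracking enumeration of *all* labelled
   molecular graphs that meet every atom's σ-degree and π count, avoid
   forbidden element pairs, and satisfy every correlation — where at most
   `fourj_flag` HMBC correlations may be *realised* at heavy distance 3
   (`0` = no ⁴J interpretation, `-1` = unlimited, `k` = at most `k`).
   A correlation is charged against the budget only by its realised
   minimal distance in the candidate, so a genuinely long-range peak that
   a candidate satisfies at distance ≤ 2 costs nothing there, and a
   different peak may take the ⁴J slot instead.
2. **Ranking.**  Solutions (labelled graphs / assignments) are collapsed
   to unique constitutions via canonical SMILES, each constitution is
   embedded in 3D by distance geometry with NOE-derived distance bounds
   (default NOE window 1.8–4.0 Å between protons, projected onto the
   carrier heavy atoms because hydrogens are implicit), relaxed under
   MMFF94 plus flat-bottom harmonic restraints
   (`k·max(0, d−upper)² + k·max(0, lower−d)²`, `k` = 10 kcal mol⁻¹ Å⁻²),
   and ranked by total energy = force field + restraint penalty.
   Constitutions that cannot be embedded rank strictly last.

The package also back-calculates the *complete theoretical* correlation
set of a known structure and feeds it back through the generator
(`reciprocity_report`) — measuring how ambiguous a molecule's own NMR
data is.  Even textbook molecules are ambiguous: caffeine's complete
correlation data admits three constitutions (see below).

A brute-force oracle (`brute_force_enumerate`) enumerates all graphs for
≤ 8 heavy atoms and referees the pruned generator in the test suite.

## Worked example: how unique is caffeine?

```python
from nmrcase import GeneratorConfig, make_fixture, pipeline
from nmrcase.fixtures import caffeine

cfg = GeneratorConfig(
    fourj_flag=0,   # no four-bond HMBC interpretation
    forbidden_bonds={frozenset({"N", "N"}), frozenset({"N", "O"})},
)
doc = make_fixture(caffeine(), omission_rate=0.0, n_injected_4j=0,
                   seed=0, config=cfg)          # complete theoretical data
res = pipeline(doc, protocol="short", seed=7)
print("solutions:", res.report["n_solutions"])
print("constitutions:", res.report["n_constitutions"])
for p in res.report["proposals"]:
    print(f"rank {p['rank']}  E = {p['total_energy']:8.2f} kcal/mol  "
          f"{p['smiles']}")
```

prints

```
solutions: 6
constitutions: 3
rank 1  E =  -122.53 kcal/mol  Cn1c(=O)c2c(ncn2C)n(C)c1=O
rank 2  E =   -28.70 kcal/mol  Cn1cnc(=O)n(C)c2n(C)c(=O)c1=2
rank 3  E =     9.07 kcal/mol  CN1C(=O)c2nc(cn2C)N(C)C1=O
```

The complete theoretical data set of caffeine (8 HMBC + 5 NHMBC
correlations, N–N and N–O bonds forbidden, shift-derived neighbour typing
on the N-methyls and C5) still admits **three** constitutions — the data
alone cannot distinguish them; caffeine itself is the rank-1 proposal.
The six solutions collapse 2:1 onto the three constitutions because the
two carbonyl positions can swap assignments.

The same machinery drives the ⁴J study pattern: inject `n` genuine
four-bond HMBC entries with `make_fixture(..., n_injected_4j=n)` and
generation returns nothing for every budget below `n`, recovers the
source constitution at budget `n`, and the solution count grows
monotonically with the budget (`sweep_4j` / `table3_experiment` tabulate
the full subset × budget cross).

## Command line

```bash
nmrcase backcalc --smiles 'Cn1cnc2c1c(=O)n(C)c(=O)n2C'   # theoretical data
nmrcase generate --input data.json --fourj-flag 1 -o solutions.smi
nmrcase rank --solutions solutions.smi --input data.json --protocol short -o ranked.sdf
nmrcase pipeline --input data.json --seed 7 -o ranked.sdf --report report.json
nmrcase fixture --smiles 'CC1=CC(=CN1)C(N)=O' --inject-4j 2 --seed 1
nmrcase sweep --input data.json --fourj H7:C3 --flags 0,1,-1
```

Input is a small JSON dialect: an atom table (`label`, `element`, `n_h`,
`hybridization` or `n_pi`, optional `valence` / `allowed_neighbors`),
correlation and NOE lists, and generator options.  `nmrcase backcalc`
emits a complete document from a SMILES to start from.

## Layout

- `nmrcase.chem_graph` — heavy-atom graphs, valence bookkeeping,
  canonicalisation, SMILES/SDF I/O
- `nmrcase.nmr_data` — correlation/NOE types and the JSON dialect
- `nmrcase.theo_calc` — theoretical data back-calculation, reciprocity
- `nmrcase.case_generator` — the enumeration engine, verifier, oracle,
  ⁴J sweep
- `nmrcase.conf_rank` — deduplication, restrained distance geometry,
  scoring, ranking, RMSD superposition
- `nmrcase.pipeline` / `nmrcase.cli` / `nmrcase.fixtures` — end-to-end
  workflow, command line, and the synthetic-data generator

See `docs/methods.md` for the model, parameter choices and limitations.
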