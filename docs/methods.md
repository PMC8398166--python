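# Methods

## The constraint model

A molecule is modelled as a heavy-atom multigraph.  Each atom is typed by
element, attached-hydrogen count `n_h`, π-bond count `n_pi` (sp³ → 0,
sp² → 1, sp → 2), a total valence (defaults: C 4, N 3, O 2, S 2,
halogens 1; neutral species only — charges or hypervalency require an
explicit valence override), and optionally a set of allowed neighbour
elements.  Because hydrogens are implicit, the heavy-atom σ-degree of
every atom is fixed before any search:

    sigma_degree = valence − n_h − n_pi

Correlations restrict shortest-path distances in the σ-skeleton (bond
orders ignored; a heavy distance *d* corresponds to a (*d*+1)-bond H→X
coupling):

| kind   | experiment              | allowed heavy distances |
|--------|--------------------------|------------------------|
| COSY   | vicinal ¹H–¹H            | {1} (a required bond)  |
| HMBC   | ²J/³J ¹H–¹³C             | {1, 2}, extensible to 3 by the ⁴J budget |
| NHMBC  | ¹H–¹⁵N multiple bond     | {1, 2}                 |
| ADEQ   | 1,1-ADEQUATE (¹J C–C)    | {1} (a required bond)  |

Geminal COSY peaks (both protons on one carbon) have no heavy-atom
expression and are dropped with a warning.  Satisfaction is strict: one
unsatisfiable correlation empties the result set, which is exactly the
observed failure mode when genuine four-bond peaks are present but the
⁴J budget is zero.

### The ⁴J budget

`fourj_flag` bounds how many HMBC correlations may be *realised* at heavy
distance 3 (0 = none, −1 = unlimited).  Classification is by the realised
minimal distance in each candidate, with ties resolved toward the shorter
distance: a correlation that a candidate satisfies at distance ≤ 2 never
consumes budget, even if it is long-range in the true structure.  This
reproduces the characteristic re-interpretation effect — adding one
genuine ⁴J entry with budget 1 can *enlarge* the solution set, because
candidates may satisfy the new entry conventionally and spend the budget
on a different correlation.

## Enumeration

The generator backtracks over candidate atom pairs in a fixed order
(most-correlation-involved, then highest-σ-degree atoms first), deciding
edge / no-edge.  At every node it builds the *possible graph* — decided
edges plus all still-undecided pairs whose endpoints both retain σ
capacity — and prunes when (i) an atom's residual degree exceeds its
possible partners, (ii) the possible graph is disconnected, (iii) some
correlation cannot reach an allowed distance even in the possible graph,
or (iv) more correlations are forced to distance 3 than the budget
permits.  Every edge of any completed descendant lies in the current
possible graph, so pruning never removes a completable branch and the
enumeration is complete.  Completed σ-skeletons are lifted to full
molecules by distributing π bonds as a b-matching (demand `n_pi` per
atom, capacity 2 per edge, first solution in lexicographic edge order);
skeletons with no π matching are rejected.  Each accepted solution is
finally re-checked by the independent verifier, so generator and verifier
agree by construction; *completeness* is the property the brute-force
oracle (unconstrained degree-sequence enumeration + verifier filter,
≤ 8 atoms) referees in the tests.

Distinct labelled graphs that are isomorphic count as distinct
*solutions* (assignments); canonicalisation groups them into
*constitutions*.  The canonical form is RDKit's canonical SMILES of the
σ-skeleton with the atom type (element, `n_h`, `n_pi`, valence) encoded
into the isotope field — bond orders are excluded deliberately, since a
single connectivity may admit several π matchings and constitutions are
connectivity classes.  One representative π matching is kept for SMILES
and 3D output.

## Back-calculation and reciprocity

`backcalc` emits the complete theoretical correlation set of a known
structure: COSY between adjacent proton-bearing atoms, ADEQ between
adjacent carbons with at least one protonated, HMBC/NHMBC from
proton-bearing atoms to C/N at heavy distance 1–2.  Correlations are
emitted **once per unordered atom pair**: when both partners bear
protons, the two reciprocal cross peaks carry identical topological
information and collapse to one entry (this is also the counting that
matches the tabulated correlation totals of the reference molecules; for
caffeine it gives 8 HMBC and 5 NHMBC).  No distance-3 entries are
generated by default; `include_4j=True` appends them as ordinary HMBC
entries, which is how the fixture generator injects genuine ⁴J data.

`reciprocity_report` pipes a structure's own theoretical data back into
the generator.  For caffeine with N–N/N–O bonds forbidden this yields
three constitutions — the data cannot distinguish them.

### Atom typing as input data

A real CASE input encodes more than element/H-count/hybridisation: the
¹³C shift fixes obvious neighbour constraints before any generation.
The caffeine fixture therefore carries the standard shift reading as
`allowed_neighbors`: the three methyls (27.8/29.6/33.5 ppm) are N-CH₃
(C-CH₃ resonates below ~25 ppm, O-CH₃ above ~50 ppm), and C5 (107.4 ppm)
cannot bear oxygen (sp² C–O carbons appear far downfield).  Without this
typing the same run admits ten constitutions, several with three- and
four-membered ring fusions; with it, three.  The typing is part of the
fixture's input data, not of the algorithm.

## NOE-restrained distance geometry

NOEs are distance bounds between protons (default window 1.8–4.0 Å when
no quantification is available).  Hydrogens being implicit, a restraint
between protons is projected onto the carrier heavy atoms: the upper
bound is padded by one C–H offset (1.1 Å) per side and the lower bound
floored at 2.0 Å heavy–heavy — a deliberately conservative pseudo-atom
treatment that cannot distinguish diastereotopic protons and determines
no stereochemistry.

Embedding runs per constitution (per *assignment* when NOEs are present,
since the label→position mapping changes which atom pair a restraint
binds): the projected bounds are written into the RDKit distance-bounds
matrix before triangle smoothing, `n_structures` independent embeddings
are drawn with seeds `seed, seed+1, …` (named protocols: `short` = 90,
`long` = 499; a longer protocol's attempt set strictly contains a
shorter one's, so its best energy is never worse), and each structure is
relaxed with MMFF94 plus flat-bottom harmonic distance restraints with
`k` = 10 kcal mol⁻¹ Å⁻² (no functional form is canonical here; the
flat-bottom harmonic is the simplest penalty that is zero inside the
bounds and smooth outside).  The conformation's total energy is the
plain MMFF94 energy plus the restraint penalty recomputed from the final
coordinates, so NOE violations directly worsen a proposal's rank.
Force-field energies are comparable only within one run of one force
field; all ranking is relative, and absolute energies are not
reproducible across programs.  Constitutions for which embedding or
MMFF typing fails on every attempt are marked failed and ranked strictly
last, with ties broken by canonical form for reproducibility.

## Synthetic data

The experimental correlation lists of the two natural-product reference
systems are not public.  `fixtures` therefore ships synthetic stand-in
skeletons of the same character — `oxo_alkaloid_like` (an N-rich
methylpyrrole carboxamide, 9 heavy atoms) and `noe_terpenoid_like` (a
proton-rich acetyl trimethylcyclohexane, 11 heavy atoms) — sized so that
exhaustive generation from their own data completes in seconds, and
`make_fixture`, which emulates how experimental sets arise: the complete
theoretical set of a known structure, a seeded random fraction removed
(peaks missing from real spectra), plus a chosen number of genuine
heavy-distance-3 HMBC entries (verified in the source structure).  What
these fixtures do **not** emulate: overlapping/ambiguous chemical shifts
(every peak resolves to exactly one label), solvent-dependent peak
observability, intensity information, and the sheer size of real
natural-product data sets — so passing tests demonstrate correctness of
the constraint semantics at desk scale, not performance or robustness on
noisy assignments.

`random_fixture_molecule` draws small random valence-consistent
connected molecules (spanning tree + ring closures + double bonds within
capacity) for property testing against the brute-force oracle.

## Numerical and design choices

- Degree/feasibility rejects (odd σ sum, too few bonds to connect) return
  empty results with a logged diagnostic rather than raising: an
  infeasible data set is a scientific outcome, not a programming error.
- Solutions are ordered by (canonical form, σ-edge list); all stage
  counts and listings are reproducible, and embedding is reproducible
  given the seed and library version.
- The default forbidden-bond set is empty; N–N/N–O prohibitions are a
  per-run option (they are molecule-specific chemistry knowledge).
- `strict_satisfaction=False` is reserved and raises: tolerating
  unsatisfied correlations needs a principled scoring model we do not
  have.
- RMSD superposition is rotation-only Kabsch (proper rotations,
  reflection excluded); collinear point sets are flagged as
  underdetermined.
- The ⁴J sweep driver defaults to the study layout (empty set, singles,
  growing prefixes); `table3_experiment` runs the full subset cross.
  Runtime columns are deliberately not part of any result table.

## Known limitations

- Neutral molecules only; no tautomer handling; no stereochemistry; no
  aromaticity perception beyond what canonical SMILES output needs.
- No chemical-shift *prediction* — candidate filtering by predicted
  shifts is out of scope; `allowed_neighbors` is the only channel for
  shift knowledge.
- One label per correlation endpoint (no overlapped-shift ambiguity).
- Enumeration cost grows steeply with atom count and constraint
  looseness; the engine targets well-constrained data sets of up to
  roughly 15–20 heavy atoms, and `max_solutions` caps runaway searches
  at the price of completeness.
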