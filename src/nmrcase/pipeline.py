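"""End-to-end workflow: generate -> deduplicate -> embed -> rank.

When NOEs are present the conformational stage runs over *every
assignment* of every constitution, not just one representative: the NOE
endpoints are peak labels, so two assignments of one constitution can map
an NOE onto different atom pairs and satisfy it differently.  Without
NOEs one embedding per constitution suffices.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from .case_generator import (
    Constitution,
    GeneratorConfig,
    Solution,
    generate,
    sweep_4j,
)
from .chem_graph import write_sdf, write_smiles
from .conf_rank import (
    PROTOCOLS,
    Conformation,
    RankedProposal,
    deduplicate,
    embed,
    rank,
)
from .nmr_data import Correlation, read_input, summarize

__all__ = ["PipelineResult", "pipeline", "table3_experiment"]

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    solutions: list[Solution]
    constitutions: list[Constitution]
    proposals: list[RankedProposal]
    report: dict
    sdf: str


def pipeline(
    document: str | Mapping,
    config: Optional[GeneratorConfig] = None,
    protocol: str = "short",
    seed: int = 0,
    n_structures: Optional[int] = None,
) -> PipelineResult:
    """Run the full two-stage workflow on a native-dialect document.

    ``protocol`` selects the distance-geometry ensemble size ("short" = 90,
    "long" = 499) unless ``n_structures`` overrides it.  The report carries
    the stage counts (solutions, constitutions, embeddings, failures), the
    per-solution 4J usage, and the per-proposal energies.
    """
    atoms, cs, doc_config = read_input(document)
    cfg = config if config is not None else doc_config
    if n_structures is None:
        if protocol not in PROTOCOLS:
            raise ValueError(f"unknown protocol {protocol!r}; use {sorted(PROTOCOLS)}")
        n_structures = PROTOCOLS[protocol]

    log.info("stage 1: generating constitutions (4J budget %d)", cfg.fourj_flag)
    try:
        solutions = generate(atoms, cs, cfg)
    except Exception as e:
        raise RuntimeError(f"generation stage failed: {e}") from e
    constitutions = deduplicate(solutions)
    log.info(
        "stage 1: %d solutions in %d constitutions", len(solutions), len(constitutions)
    )

    items: list[tuple[Constitution, Optional[Conformation]]] = []
    n_embedded = 0
    try:
        for c in constitutions:
            if cs.noes:
                # NOEs bind to labels: every assignment may fulfil them
                # differently, so embed each member and keep the best.
                best: Optional[Conformation] = None
                for member in c.solutions:
                    confs = embed(member.graph, cs.noes, n_structures, seed)
                    if confs and (best is None or confs[0].total_energy < best.total_energy):
                        best = confs[0]
                items.append((c, best))
            else:
                confs = embed(c, (), n_structures, seed)
                items.append((c, confs[0] if confs else None))
            if items[-1][1] is not None:
                n_embedded += 1
    except Exception as e:
        raise RuntimeError(f"embedding stage failed: {e}") from e
    log.info(
        "stage 2: %d/%d constitutions embedded", n_embedded, len(constitutions)
    )
    proposals = rank(items)

    records = []
    for p in proposals:
        props = {
            "SMILES": write_smiles(p.constitution.graph),
            "RANK": p.rank,
            "N_ASSIGNMENTS": p.constitution.n_assignments,
        }
        if p.conformation is not None:
            props["TOTAL_ENERGY"] = f"{p.conformation.total_energy:.4f}"
            props["RESTRAINT_ENERGY"] = f"{p.conformation.restraint_energy:.4f}"
            props["MAX_NOE_VIOLATION"] = (
                f"{max(p.conformation.per_restraint_violation, default=0.0):.4f}"
            )
            mol = p.conformation.mol
        else:
            props["EMBEDDING_FAILED"] = 1
            from .chem_graph import to_rdkit

            mol = to_rdkit(p.constitution.graph)
        records.append((mol, props))
    sdf = write_sdf(records)

    report = {
        "input_counts": summarize(cs),
        "fourj_flag": cfg.fourj_flag,
        "n_solutions": len(solutions),
        "n_constitutions": len(constitutions),
        "n_embedded": n_embedded,
        "n_embedding_failures": len(constitutions) - n_embedded,
        "fourj_used_per_solution": [s.fourj_used for s in solutions],
        "proposals": [
            {
                "rank": p.rank,
                "smiles": write_smiles(p.constitution.graph),
                "n_assignments": p.constitution.n_assignments,
                "total_energy": None
                if p.conformation is None
                else p.conformation.total_energy,
                "restraint_energy": None
                if p.conformation is None
                else p.conformation.restraint_energy,
                "embedding_failed": p.failed,
            }
            for p in proposals
        ],
    }
    if not solutions:
        report["diagnostic"] = (
            "no constitution satisfies all constraints under the current 4J budget"
        )
    return PipelineResult(solutions, constitutions, proposals, report, sdf)


def table3_experiment(
    document: str | Mapping,
    named_4j_correlations: Sequence[Correlation],
    flags: Optional[Sequence[int]] = None,
) -> pd.DataFrame:
    """Full cross of injected-4J subsets x 4J budgets on one base data set.

    Subsets run the empty set, all singles, all pairs, ... up to the full
    list (lettered A, B, ... in that order); each cell records the solution
    and constitution counts from a fresh generation run.
    """
    atoms, cs, config = read_input(document)
    named = list(named_4j_correlations)
    subsets: list[tuple[int, ...]] = []
    for size in range(len(named) + 1):
        subsets.extend(itertools.combinations(range(len(named)), size))
    return sweep_4j(atoms, cs, named, flags=flags, subsets=subsets, config=config)
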