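"""Typed NMR correlation constraints, NOE restraints, and the native JSON
input dialect.

Correlation kinds and their default allowed heavy-atom distances:

==========  ============================  =========================
kind        experiment                    default heavy distances
==========  ============================  =========================
COSY        vicinal 1H-1H                 {1}
HMBC        1H-13C multiple bond (2J/3J)  {1, 2}
NHMBC       1H-15N multiple bond          {1, 2}
ADEQ        1,1-ADEQUATE (1J C-C)         {1}
==========  ============================  =========================

A heavy distance of d corresponds to a (d+1)-bond H->X coupling.  Four-bond
HMBC interpretation (heavy distance 3) is not encoded in the correlation
itself; it is granted at generation time by the 4J budget
(:class:`nmrcase.case_generator.GeneratorConfig.fourj_flag`).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional

import pandas as pd

from .chem_graph import AtomSpec

__all__ = [
    "KINDS",
    "DEFAULT_DISTANCES",
    "Correlation",
    "NOERestraint",
    "CorrelationSet",
    "read_input",
    "write_input",
    "summarize",
]

KINDS = ("COSY", "HMBC", "NHMBC", "ADEQ")

DEFAULT_DISTANCES: dict[str, frozenset[int]] = {
    "COSY": frozenset({1}),
    "HMBC": frozenset({1, 2}),
    "NHMBC": frozenset({1, 2}),
    "ADEQ": frozenset({1}),
}

#: Kinds whose endpoint pair is symmetric (stored with sorted labels).
SYMMETRIC_KINDS = frozenset({"COSY", "ADEQ"})

#: Allowed target elements per kind ("C-like" = carbon).
TARGET_ELEMENTS = {"COSY": None, "HMBC": {"C"}, "NHMBC": {"N"}, "ADEQ": {"C"}}


class NMRDataError(ValueError):
    pass


@dataclass(frozen=True)
class Correlation:
    """One 2D-NMR correlation between labelled heavy atoms.

    ``from_label`` is the proton-bearing side; for the symmetric kinds
    (COSY, ADEQ) the pair is stored sorted so duplicates collapse.
    """

    kind: str
    from_label: str
    to_label: str
    distances: frozenset[int] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise NMRDataError(f"unknown correlation kind {self.kind!r}")
        if self.distances is None:
            object.__setattr__(self, "distances", DEFAULT_DISTANCES[self.kind])
        else:
            object.__setattr__(self, "distances", frozenset(int(d) for d in self.distances))
        if self.kind == "HMBC":
            if not self.distances <= {1, 2, 3} or not {1, 2} <= self.distances:
                raise NMRDataError(
                    f"HMBC distances must satisfy {{1,2}} <= D <= {{1,2,3}}, got "
                    f"{sorted(self.distances)}"
                )
        if any(d < 1 for d in self.distances):
            raise NMRDataError("heavy distances must be >= 1")
        if self.kind in SYMMETRIC_KINDS and self.to_label < self.from_label:
            a, b = self.to_label, self.from_label
            object.__setattr__(self, "from_label", a)
            object.__setattr__(self, "to_label", b)

    @property
    def key(self) -> tuple:
        return (self.kind, self.from_label, self.to_label)


@dataclass(frozen=True)
class NOERestraint:
    """Through-space proximity bound between two proton-bearing heavy atoms.

    Bounds are inter-proton distances in Angstrom; the default range
    1.8-4.0 A is the generic qualitative-NOE window.  ``pseudo_mode``
    selects how implicit protons are projected onto their carrier heavy
    atoms (currently only ``"heavy_pad"``: pad the upper bound by one C-H
    offset per side and floor the lower bound; see
    :func:`nmrcase.conf_rank.heavy_atom_bounds`).
    """

    label_a: str
    label_b: str
    lower_bound: float = 1.8
    upper_bound: float = 4.0
    pseudo_mode: str = "heavy_pad"

    def __post_init__(self) -> None:
        if not (0 < self.lower_bound < self.upper_bound):
            raise NMRDataError(
                f"NOE bounds must satisfy 0 < lower < upper, got "
                f"[{self.lower_bound}, {self.upper_bound}]"
            )
        if self.pseudo_mode != "heavy_pad":
            raise NMRDataError(f"unknown pseudo_mode {self.pseudo_mode!r}")
        if self.label_b < self.label_a:
            a, b = self.label_b, self.label_a
            object.__setattr__(self, "label_a", a)
            object.__setattr__(self, "label_b", b)

    @property
    def key(self) -> tuple:
        return (self.label_a, self.label_b)


@dataclass
class CorrelationSet:
    """All constraints of one experiment: correlations plus NOEs, bound to
    an atom table."""

    correlations: list[Correlation] = field(default_factory=list)
    noes: list[NOERestraint] = field(default_factory=list)
    atoms: Optional[list[AtomSpec]] = None

    def __post_init__(self) -> None:
        if self.atoms is not None:
            self.resolve(self.atoms)

    def resolve(self, atoms: list[AtomSpec]) -> None:
        """Validate every constraint against the atom table; dedup."""
        by_label = {a.label: a for a in atoms}
        kept: list[Correlation] = []
        seen = set()
        for c in self.correlations:
            for lbl in (c.from_label, c.to_label):
                if lbl not in by_label:
                    raise NMRDataError(f"correlation refers to unknown atom {lbl!r}")
            if c.from_label == c.to_label:
                warnings.warn(
                    f"dropping zero-length {c.kind} {c.from_label}<->{c.to_label} "
                    "(geminal pairs are inexpressible on a heavy-atom graph)"
                )
                continue
            if c.kind == "COSY":
                # both partners carry the protons that couple
                for lbl in (c.from_label, c.to_label):
                    if by_label[lbl].n_h < 1:
                        raise NMRDataError(f"COSY atom {lbl} bears no proton")
            elif c.kind == "ADEQ":
                # undirected; at least one carbon must be protonated
                if max(by_label[c.from_label].n_h, by_label[c.to_label].n_h) < 1:
                    raise NMRDataError(
                        f"ADEQ {c.from_label}-{c.to_label}: neither carbon bears a proton"
                    )
                for lbl in (c.from_label, c.to_label):
                    if by_label[lbl].element != "C":
                        raise NMRDataError(f"ADEQ atom {lbl} is not carbon")
            else:
                if by_label[c.from_label].n_h < 1:
                    raise NMRDataError(
                        f"{c.kind} from {c.from_label}: atom bears no proton"
                    )
                targets = TARGET_ELEMENTS[c.kind]
                if by_label[c.to_label].element not in targets:
                    raise NMRDataError(
                        f"{c.kind} to {c.to_label}: target element "
                        f"{by_label[c.to_label].element} not in {sorted(targets)}"
                    )
            if c.key in seen:
                warnings.warn(f"duplicate correlation {c.key}; keeping first")
                continue
            seen.add(c.key)
            kept.append(c)
        self.correlations = kept
        noes_kept: list[NOERestraint] = []
        seen_noe = set()
        for r in self.noes:
            for lbl in (r.label_a, r.label_b):
                if lbl not in by_label:
                    raise NMRDataError(f"NOE refers to unknown atom {lbl!r}")
                if by_label[lbl].n_h < 1:
                    raise NMRDataError(f"NOE atom {lbl} bears no proton")
            if r.label_a == r.label_b:
                warnings.warn(f"dropping self-NOE on {r.label_a}")
                continue
            if r.key in seen_noe:
                warnings.warn(f"duplicate NOE {r.key}; keeping first")
                continue
            seen_noe.add(r.key)
            noes_kept.append(r)
        self.noes = noes_kept
        self.atoms = atoms

    def by_kind(self, kind: str) -> list[Correlation]:
        return [c for c in self.correlations if c.kind == kind]


# ---------------------------------------------------------------------------
# Native JSON dialect

_TOP_KEYS = {"formula", "atoms", "correlations", "noes", "options"}
_CORR_KEYS = {"kind", "from", "to", "distances"}
_NOE_KEYS = {"a", "b", "lower", "upper", "pseudo_mode"}


def read_input(document: str | Mapping):
    """Parse a native-dialect JSON document.

    Returns ``(atoms, correlation_set, generator_config)``.  Unknown keys
    are rejected; per-kind distance defaults and NOE default bounds
    (1.8-4.0 A) are applied.
    """
    from .case_generator import GeneratorConfig  # local: avoids import cycle

    doc = json.loads(document) if isinstance(document, str) else dict(document)
    unknown = set(doc) - _TOP_KEYS
    if unknown:
        raise NMRDataError(f"unknown top-level keys {sorted(unknown)}")
    if "atoms" not in doc:
        raise NMRDataError("document lacks 'atoms'")
    atoms = [AtomSpec.from_dict(a) for a in doc["atoms"]]

    corrs = []
    for rec in doc.get("correlations", []):
        rec = dict(rec)
        unknown = set(rec) - _CORR_KEYS
        if unknown:
            raise NMRDataError(f"unknown correlation keys {sorted(unknown)}")
        corrs.append(
            Correlation(
                kind=rec["kind"],
                from_label=rec["from"],
                to_label=rec["to"],
                distances=frozenset(rec["distances"]) if "distances" in rec else None,
            )
        )
    noes = []
    for rec in doc.get("noes", []):
        rec = dict(rec)
        unknown = set(rec) - _NOE_KEYS
        if unknown:
            raise NMRDataError(f"unknown NOE keys {sorted(unknown)}")
        noes.append(
            NOERestraint(
                label_a=rec["a"],
                label_b=rec["b"],
                lower_bound=float(rec.get("lower", 1.8)),
                upper_bound=float(rec.get("upper", 4.0)),
                pseudo_mode=rec.get("pseudo_mode", "heavy_pad"),
            )
        )
    cs = CorrelationSet(correlations=corrs, noes=noes, atoms=atoms)

    opts = dict(doc.get("options", {}))
    if "forbidden_bonds" in opts:
        opts["forbidden_bonds"] = frozenset(
            frozenset(pair) for pair in opts["forbidden_bonds"]
        )
    config = GeneratorConfig(**opts)

    if "formula" in doc and doc["formula"]:
        from .chem_graph import parse_formula

        formula = parse_formula(doc["formula"])
        implied = {}
        n_h = 0
        for a in atoms:
            implied[a.element] = implied.get(a.element, 0) + 1
            n_h += a.n_h
        if n_h:
            implied["H"] = n_h
        if dict(formula) != implied:
            raise NMRDataError(
                f"formula {dict(formula)} inconsistent with atom list {implied}"
            )
    return atoms, cs, config


def write_input(atoms, cs: CorrelationSet, config) -> str:
    """Serialise to the native dialect; ``read_input`` round-trips it."""
    doc = {
        "atoms": [
            {
                "label": a.label,
                "element": a.element,
                "n_h": a.n_h,
                "n_pi": a.n_pi,
                **({"valence": a.valence} if not a.valence_is_default else {}),
                **(
                    {"allowed_neighbors": sorted(a.allowed_neighbors)}
                    if a.allowed_neighbors is not None
                    else {}
                ),
            }
            for a in atoms
        ],
        "correlations": [
            {
                "kind": c.kind,
                "from": c.from_label,
                "to": c.to_label,
                **(
                    {"distances": sorted(c.distances)}
                    if c.distances != DEFAULT_DISTANCES[c.kind]
                    else {}
                ),
            }
            for c in cs.correlations
        ],
        "noes": [
            {"a": r.label_a, "b": r.label_b, "lower": r.lower_bound, "upper": r.upper_bound}
            for r in cs.noes
        ],
        "options": {
            "fourj_flag": config.fourj_flag,
            "forbidden_bonds": sorted(sorted(p) for p in config.forbidden_bonds),
            "require_connected": config.require_connected,
            "strict_satisfaction": config.strict_satisfaction,
            **({"max_solutions": config.max_solutions} if config.max_solutions else {}),
        },
    }
    return json.dumps(doc, indent=2)


def summarize(cs: CorrelationSet) -> dict[str, int]:
    """Per-kind correlation counts plus the NOE count."""
    counts = {k: 0 for k in KINDS}
    for c in cs.correlations:
        counts[c.kind] += 1
    counts["NOE"] = len(cs.noes)
    return counts


def summarize_csv(cs: CorrelationSet) -> str:
    """One-row CSV of :func:`summarize` (COSY,HMBC,NHMBC,ADEQ,NOE)."""
    return pd.DataFrame([summarize(cs)]).to_csv(index=False)
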