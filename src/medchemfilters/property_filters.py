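"""Threshold-rule (property) filters and their evaluation engine.

Each filter is a named set of descriptor bounds plus an allowed number of
rule breaks (the rule-of-five classically tolerates one).  Evaluation is a
pure function of the filter definition and the descriptor vector: every
breached bound is listed as a violation and the verdict passes when the
violation count does not exceed ``allowed_breaks``.

Bound strictness follows the published cutoffs exactly: almost all are
non-strict inequalities; the CNS-activity (Murcko) aromatic-ring cutoff and
the lead-like (Oprea) molecular-weight / upper-logP cutoffs are printed as
strict inequalities and are implemented as such.

logD-dependent rules (Fichert, the Oprea logD window) need an externally
supplied logD.  A record without one is "unevaluable": it fails closed but
is flagged separately from rule failures, unless logP substitution has been
explicitly enabled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import yaml

from .chem_io import Molecule
from .descriptors import DescriptorVector

__all__ = [
    "FilterRule",
    "FilterDefinition",
    "Verdict",
    "builtin_filter",
    "builtin_filter_names",
    "evaluate",
    "muegge_evaluate",
    "save_filter",
    "load_filter",
]


@dataclass(frozen=True)
class FilterRule:
    """One inequality on a descriptor; bounds inclusive unless marked strict."""

    descriptor: str
    lower: Optional[float] = None
    upper: Optional[float] = None
    lower_strict: bool = False
    upper_strict: bool = False

    def __post_init__(self) -> None:
        if self.lower is None and self.upper is None:
            raise ValueError(f"rule on {self.descriptor!r} has no bounds")
        if self.lower is not None and self.upper is not None and self.lower > self.upper:
            raise ValueError(f"rule on {self.descriptor!r}: lower > upper")

    @property
    def name(self) -> str:
        parts = []
        if self.lower is not None:
            parts.append(f"{self.lower:g}{'<' if self.lower_strict else '<='}")
        parts.append(self.descriptor)
        if self.upper is not None:
            parts.append(f"{'<' if self.upper_strict else '<='}{self.upper:g}")
        return "".join(parts)

    def satisfied_by(self, value: float) -> bool:
        if self.lower is not None:
            if value < self.lower or (self.lower_strict and value == self.lower):
                return False
        if self.upper is not None:
            if value > self.upper or (self.upper_strict and value == self.upper):
                return False
        return True


@dataclass(frozen=True)
class FilterDefinition:
    name: str
    rules: tuple[FilterRule, ...]
    allowed_breaks: int = 0
    description: str = ""

    def __post_init__(self) -> None:
        if self.allowed_breaks >= len(self.rules):
            raise ValueError(
                f"{self.name}: allowed_breaks must be < number of rules"
            )


@dataclass
class Verdict:
    """Per-molecule outcome of one filter or screen."""

    passed: bool
    violations: list[str] = field(default_factory=list)
    matches: list[str] = field(default_factory=list)
    tier: Optional[str] = None
    unevaluable: bool = False
    details: dict = field(default_factory=dict)


def _f(name, rules, allowed_breaks=0, description=""):
    return FilterDefinition(
        name=name, rules=tuple(rules), allowed_breaks=allowed_breaks,
        description=description,
    )


_BUILTINS: dict[str, FilterDefinition] = {}


def _register(defn: FilterDefinition) -> None:
    _BUILTINS[defn.name] = defn


_register(_f(
    "lipinski",
    [
        FilterRule("mw", upper=500),
        FilterRule("slogp", upper=5),
        FilterRule("hbd", upper=5),
        FilterRule("hba", upper=10),
    ],
    allowed_breaks=1,
    description="Rule-of-five oral drug-likeness; one rule break allowed.",
))

_register(_f(
    "ro3",
    [
        FilterRule("mw", upper=300),
        FilterRule("slogp", upper=3),
        FilterRule("hbd", upper=3),
        FilterRule("hba", upper=3),
        FilterRule("rot_bonds", upper=3),
    ],
    description="Rule-of-three for fragment libraries.",
))

_register(_f(
    "ro4",
    [
        FilterRule("mw", lower=400),
        FilterRule("slogp", lower=4),
        FilterRule("rings", lower=4),
        FilterRule("hba", lower=4),
    ],
    description="Rule-of-four for protein-protein interaction inhibitors.",
))

_register(_f(
    "veber",
    [
        FilterRule("rot_bonds", upper=10),
        FilterRule("tpsa", upper=140),
    ],
    description="Oral bioavailability (rotatable bonds, polar surface area).",
))

_register(_f(
    "egan",
    [
        FilterRule("slogp", upper=5.88),
        FilterRule("tpsa", upper=131.6),
    ],
    description="Membrane permeability / absorption (logP, PSA).",
))

_register(_f(
    "mozziconacci",
    [
        FilterRule("rot_bonds", upper=15),
        FilterRule("rings", upper=6),
        FilterRule("o_count", lower=1),
        FilterRule("n_count", lower=1),
        FilterRule("halogens", upper=7),
    ],
    description="Drug-likeness from 15 public chemical libraries.",
))

_register(_f(
    "vdwaterbeemd",
    [
        FilterRule("mw", upper=450),
        FilterRule("tpsa", upper=90),
    ],
    description="Blood-brain barrier permeation estimate.",
))

_register(_f(
    "murcko",
    [
        FilterRule("mw", lower=200, upper=540),
        FilterRule("slogp", lower=0, upper=5.2),
        FilterRule("hba", upper=4),
        FilterRule("hbd", upper=3),
        FilterRule("rot_bonds", upper=7),
        FilterRule("branch_points", lower=3.4, upper=12.2),
        FilterRule("aromatic_rings", upper=3, upper_strict=True),
    ],
    description=(
        "CNS activity; the branching window uses the pluggable branch-point "
        "count as a stand-in for the original unspecified branching index."
    ),
))

_register(_f(
    "oprea",
    [
        FilterRule("mw", upper=450, upper_strict=True),
        FilterRule("slogp", lower=-3.5, upper=4.5, upper_strict=True),
        FilterRule("logd", lower=-4, upper=4),
        FilterRule("rings", upper=4),
        FilterRule("nonterminal_single_bonds", upper=10),
        FilterRule("hbd", upper=5),
        FilterRule("hba", upper=8),
    ],
    description="Lead-likeness (complexity and rigidity on top of Ro5-style bounds).",
))

_register(_f(
    "ghose",
    [
        FilterRule("mw", lower=180, upper=480),
        FilterRule("smr", lower=40, upper=130),
        FilterRule("slogp", lower=-0.4, upper=5.6),
        FilterRule("total_atoms_incl_h", lower=20, upper=70),
    ],
    description="Drug-likeness from the Comprehensive Medicinal Chemistry set.",
))

_register(_f(
    "fichert",
    [
        FilterRule("mw", upper=500),
        FilterRule("logd", lower=0, upper=3),
    ],
    description="Caco-2 permeability; requires a supplied logD.",
))

_register(_f(
    "reos_properties",
    [
        FilterRule("hbd", upper=5),
        FilterRule("hba", upper=10),
        FilterRule("formal_charge", lower=-2, upper=2),
        FilterRule("rot_bonds", upper=8),
        FilterRule("mw", lower=200, upper=500),
        FilterRule("heavy_atoms", lower=20, upper=50),
        FilterRule("slogp", lower=-2, upper=5),
    ],
    description="The seven property rules of the REOS hybrid filter.",
))


def builtin_filter_names() -> list[str]:
    return sorted(_BUILTINS)


def builtin_filter(name: str) -> FilterDefinition:
    """Return a built-in filter definition by name."""
    try:
        return _BUILTINS[name]
    except KeyError:
        raise KeyError(
            f"unknown filter {name!r}; available: {', '.join(builtin_filter_names())}"
        ) from None


def evaluate(
    f: FilterDefinition,
    d: DescriptorVector,
    substitute_slogp_for_logd: bool = False,
) -> Verdict:
    """Evaluate a property filter on a descriptor vector.

    Each breached bound contributes one violation; the verdict passes when
    the number of violations is at most ``f.allowed_breaks``.  A rule that
    references an absent descriptor (logD not supplied, substitution off)
    makes the record unevaluable: it does not pass, and is flagged so
    reports can distinguish "rejected" from "not assessable".  For the
    lead-like filter specifically, a missing logD skips only the optional
    logD window rather than making the record unevaluable.
    """
    violations: list[str] = []
    for rule in f.rules:
        value = d.get(rule.descriptor)
        if value is None:
            if rule.descriptor == "logd":
                if substitute_slogp_for_logd:
                    value = d.slogp
                elif f.name == "oprea":
                    continue  # logD window is optional for lead-likeness
                else:
                    return Verdict(
                        passed=False, unevaluable=True,
                        violations=[f"{rule.name} (logD not supplied)"],
                    )
            else:
                return Verdict(
                    passed=False, unevaluable=True,
                    violations=[f"{rule.name} (descriptor missing)"],
                )
        if not rule.satisfied_by(value):
            violations.append(rule.name)
    return Verdict(passed=len(violations) <= f.allowed_breaks, violations=violations)


# --- pharmacophore-point (Muegge) filter -----------------------------------

from rdkit import Chem  # noqa: E402

# amine nitrogen: trivalent, only single bonds, non-aromatic, not an
# amide/sulfonamide/N-nitroso-type nitrogen.  Aromatic azole/diazine
# nitrogens are excluded by the non-aromatic requirement.
_AMINE = Chem.MolFromSmarts(
    "[NX3;!$([NX3][CX3]=[OX1]);!$([NX3][CX3]=[SX1]);"
    "!$([NX3][SX4](=O)=O);!$([NX3][NX2]=O);!n]"
)


def amine_pharmacophore_points(m: Molecule) -> int:
    """Count amine pharmacophore points.

    Primary, secondary and tertiary amines each contribute one point;
    aromatic azole/diazine nitrogens are excluded; intracyclic amines that
    share a ring fuse into a single point.
    """
    matches = [idx for (idx,) in m.structure.GetSubstructMatches(_AMINE)]
    if not matches:
        return 0
    rings = m.structure.GetRingInfo().AtomRings()
    # union-find over matched amines: fuse those sharing any ring
    parent = {i: i for i in matches}

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        parent[find(i)] = find(j)

    for ring in rings:
        in_ring = [i for i in matches if i in ring]
        for a, b in zip(in_ring, in_ring[1:]):
            union(a, b)
    return len({find(i) for i in matches})


def muegge_evaluate(
    m: Molecule,
    d: DescriptorVector,
    min_points: Optional[int] = None,
    max_points: Optional[int] = None,
) -> Verdict:
    """Pharmacophore-point drug-likeness filter.

    Dismisses compounds with more than one carboxylic acid or without any
    ring; always reports the amine pharmacophore-point count.  Optional
    min/max point thresholds are off by default because the original pass
    window for the point count is not published.
    """
    violations: list[str] = []
    if d.carboxylic_acids > 1:
        violations.append("carboxylic_acids>1")
    if d.rings == 0:
        violations.append("no_ring")
    points = amine_pharmacophore_points(m)
    if min_points is not None and points < min_points:
        violations.append(f"amine_points<{min_points}")
    if max_points is not None and points > max_points:
        violations.append(f"amine_points>{max_points}")
    return Verdict(
        passed=not violations,
        violations=violations,
        details={"amine_pharmacophore_points": points},
    )


# --- (de)serialization ------------------------------------------------------

def _rule_to_dict(r: FilterRule) -> dict:
    out: dict = {"descriptor": r.descriptor}
    if r.lower is not None:
        out["lower"] = r.lower
        if r.lower_strict:
            out["lower_strict"] = True
    if r.upper is not None:
        out["upper"] = r.upper
        if r.upper_strict:
            out["upper_strict"] = True
    return out


def filter_to_dict(f: FilterDefinition) -> dict:
    return {
        "name": f.name,
        "allowed_breaks": f.allowed_breaks,
        "description": f.description,
        "rules": [_rule_to_dict(r) for r in f.rules],
    }


def filter_from_dict(data: dict) -> FilterDefinition:
    rules = tuple(FilterRule(**r) for r in data["rules"])
    return FilterDefinition(
        name=data["name"],
        rules=rules,
        allowed_breaks=int(data.get("allowed_breaks", 0)),
        description=data.get("description", ""),
    )


def save_filter(f: FilterDefinition, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(filter_to_dict(f), fh, sort_keys=False)


def load_filter(path) -> FilterDefinition:
    with open(path) as fh:
        return filter_from_dict(yaml.safe_load(fh))
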