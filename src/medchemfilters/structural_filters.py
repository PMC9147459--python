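"""SMARTS-catalog screens: PAINS and the functional-group half of REOS.

A catalog is a list of named SMARTS patterns, each with a maximum allowed
number of distinct matches (``max_count``, default 0: any occurrence flags
the compound).  Raising a pattern's ``max_count`` tunes the screen to a
given campaign; it can only grow the pass set.

Two catalogs ship as editable package data:

``pains``
    Family-representative patterns for the classic pan-assay interference
    classes (rhodanines, phenolic Mannich bases, hydroxyphenylhydrazones,
    alkylidene barbiturates and other alkylidene heterocycles, N-aryl
    pyrroles, activated benzofurazans, 2-amino-3-carbonylthiophenes,
    catechols, quinones).  This is a curated reconstruction, not a byte
    copy of any specific published list; drop in your own file to use one.
``reos``
    Reactive/undesirable moieties: nitro, peroxide, triflate, aldehyde,
    acetal, Michael acceptor, acyl halide, epoxide, isocyanate, alkyl
    halide, thiol.

REOS itself is a hybrid: :func:`reos_full` combines the structural screen
with its seven property rules, and the property half can be omitted.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Optional

from rdkit import Chem

from .chem_io import Molecule
from .descriptors import DescriptorVector, count_substructure
from .property_filters import Verdict, builtin_filter, evaluate

__all__ = [
    "SmartsPattern",
    "Catalog",
    "load_catalog",
    "save_catalog",
    "screen",
    "reos_full",
]

_BUILTIN_CATALOGS = {"pains", "reos"}


@dataclass(frozen=True)
class SmartsPattern:
    """A named substructure pattern with its maximum allowed match count."""

    name: str
    smarts: str
    max_count: int = 0

    def __post_init__(self) -> None:
        if self.max_count < 0:
            raise ValueError(f"{self.name}: max_count must be >= 0")
        if self.query is None:
            raise ValueError(f"{self.name}: invalid SMARTS {self.smarts!r}")

    @property
    def query(self) -> Optional[Chem.Mol]:
        return Chem.MolFromSmarts(self.smarts)


@dataclass(frozen=True)
class Catalog:
    name: str
    patterns: tuple[SmartsPattern, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        names = [p.name for p in self.patterns]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"catalog {self.name}: duplicate pattern names {dupes}")

    def pattern(self, name: str) -> SmartsPattern:
        for p in self.patterns:
            if p.name == name:
                return p
        raise KeyError(f"catalog {self.name}: no pattern {name!r}")

    def with_max_count(self, pattern_name: str, max_count: int) -> "Catalog":
        """Return a copy with one pattern's max_count changed."""
        self.pattern(pattern_name)  # raises on unknown name
        patterns = tuple(
            replace(p, max_count=max_count) if p.name == pattern_name else p
            for p in self.patterns
        )
        return replace(self, patterns=patterns)


def _parse_catalog_lines(lines: Iterable[str], name: str, provenance: str) -> Catalog:
    patterns = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) not in (2, 3):
            raise ValueError(
                f"{provenance}:{lineno}: expected 'name SMARTS [max_count]', got {line!r}"
            )
        max_count = int(parts[2]) if len(parts) == 3 else 0
        if Chem.MolFromSmarts(parts[1]) is None:
            raise ValueError(f"{provenance}:{lineno}: invalid SMARTS {parts[1]!r}")
        patterns.append(SmartsPattern(parts[0], parts[1], max_count))
    return Catalog(name=name, patterns=tuple(patterns), provenance=provenance)


def load_catalog(source: str | Path) -> Catalog:
    """Load a catalog by builtin name ('pains', 'reos') or from a file.

    Files are UTF-8, '#'-commented, whitespace-separated
    ``name SMARTS [max_count]`` lines.  Every SMARTS is validated at load;
    an invalid pattern aborts with the offending line.
    """
    if isinstance(source, str) and source in _BUILTIN_CATALOGS:
        ref = importlib.resources.files("medchemfilters.data") / f"{source}.smarts"
        text = ref.read_text(encoding="utf-8")
        return _parse_catalog_lines(
            text.splitlines(), name=source, provenance=f"builtin:{source}"
        )
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(
            f"no builtin catalog or file named {source!r} "
            f"(builtins: {sorted(_BUILTIN_CATALOGS)})"
        )
    with open(path, encoding="utf-8") as fh:
        return _parse_catalog_lines(fh, name=path.stem, provenance=str(path))


def save_catalog(catalog: Catalog, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# catalog {catalog.name}\n")
        for p in catalog.patterns:
            fh.write(f"{p.name}\t{p.smarts}\t{p.max_count}\n")


def screen(m: Molecule, catalog: Catalog) -> Verdict:
    """Screen one molecule against a catalog.

    ``matches`` lists every pattern whose distinct-match count exceeds its
    max_count; the verdict passes iff that list is empty.  The full list is
    always carried so flag-mode runs can report what fired.
    """
    matches = [
        p.name
        for p in catalog.patterns
        if count_substructure(m, p.query) > p.max_count
    ]
    return Verdict(passed=not matches, matches=matches)


def reos_full(
    m: Molecule,
    d: DescriptorVector,
    mode: str = "hybrid",
    catalog: Optional[Catalog] = None,
) -> Verdict:
    """The hybrid REOS filter: functional-group screen + 7 property rules.

    ``mode='hybrid'`` requires both halves to pass; ``mode='structural_only'``
    omits the property half.
    """
    if mode not in {"hybrid", "structural_only"}:
        raise ValueError(f"mode must be 'hybrid' or 'structural_only', got {mode!r}")
    structural = screen(m, catalog if catalog is not None else load_catalog("reos"))
    if mode == "structural_only":
        return structural
    props = evaluate(builtin_filter("reos_properties"), d)
    return Verdict(
        passed=structural.passed and props.passed,
        violations=props.violations,
        matches=structural.matches,
        unevaluable=props.unevaluable,
    )
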