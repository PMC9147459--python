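"""Reading, writing and standardizing compound libraries.

Compound libraries arrive as SMILES files (one record per line, optional
whitespace-separated identifier) or SDF (V2000).  Every input record yields
exactly one :class:`LibraryRecord`; records that fail to parse are retained
with a ``parse_error`` instead of being silently dropped, so a run report can
always account for the whole input.

All downstream logic keys on RDKit canonical SMILES, which makes duplicate
detection and verdict tables stable across input spellings of the same
molecule.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

from rdkit import Chem
from rdkit import RDLogger

# RDKit logs every sanitization complaint to stderr; parse failures are
# reported through LibraryRecord.parse_error instead.
RDLogger.DisableLog("rdApp.error")
RDLogger.DisableLog("rdApp.warning")

__all__ = [
    "Molecule",
    "LibraryRecord",
    "StandardizeOptions",
    "parse_smiles",
    "canonicalize",
    "standardize",
    "read_library",
    "write_library",
]


@dataclass(frozen=True)
class Molecule:
    """A parsed, sanitized structure together with its canonical SMILES."""

    structure: Chem.Mol
    canonical_smiles: str

    def __eq__(self, other) -> bool:  # structural identity via canonical form
        if not isinstance(other, Molecule):
            return NotImplemented
        return self.canonical_smiles == other.canonical_smiles

    def __hash__(self) -> int:
        return hash(self.canonical_smiles)


@dataclass
class LibraryRecord:
    """One input record: either a molecule or a recorded parse failure."""

    record_id: str
    source_text: str
    molecule: Optional[Molecule] = None
    parse_error: Optional[str] = None
    properties: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.molecule is None) == (self.parse_error is None):
            raise ValueError(
                "exactly one of molecule / parse_error must be set "
                f"(record {self.record_id!r})"
            )

    @property
    def ok(self) -> bool:
        return self.molecule is not None


@dataclass(frozen=True)
class StandardizeOptions:
    """Standardization switches applied after parsing.

    keep_largest_fragment
        Reduce multi-fragment inputs (salts, mixtures) to the fragment with
        the most heavy atoms.  Ties are broken by lexicographic canonical-
        SMILES order, which makes the choice deterministic.
    """

    keep_largest_fragment: bool = True


DEFAULT_STANDARDIZE = StandardizeOptions()


class ParseFailure(ValueError):
    """Raised when a SMILES string cannot be parsed/sanitized."""


def parse_smiles(text: str) -> Molecule:
    """Parse a SMILES string into a sanitized :class:`Molecule`.

    Raises :class:`ParseFailure` with a reason on malformed input; batch
    readers catch this and record it per-record rather than aborting.
    """
    if not text or not text.strip():
        raise ParseFailure("empty SMILES string")
    mol = Chem.MolFromSmiles(text)
    if mol is None:
        raise ParseFailure(f"unparsable SMILES: {text!r}")
    return Molecule(structure=mol, canonical_smiles=Chem.MolToSmiles(mol))


def canonicalize(m: Molecule) -> str:
    """Return the canonical SMILES of ``m`` (idempotent)."""
    return m.canonical_smiles


def standardize(
    m: Molecule, opts: StandardizeOptions = DEFAULT_STANDARDIZE
) -> Molecule:
    """Apply standardization (largest-fragment keeping) to a molecule."""
    if not opts.keep_largest_fragment:
        return m
    frags = Chem.GetMolFrags(m.structure, asMols=True, sanitizeFrags=False)
    if len(frags) <= 1:
        return m
    # largest by heavy atoms; ties broken by canonical-SMILES sort order
    keyed = sorted(
        ((-f.GetNumHeavyAtoms(), Chem.MolToSmiles(f)) for f in frags)
    )
    return parse_smiles(keyed[0][1])


def _records_from_smiles_lines(
    lines: Iterable[str], opts: StandardizeOptions
) -> Iterator[LibraryRecord]:
    n = 0
    for raw in lines:
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        n += 1
        parts = line.split()
        smiles = parts[0]
        rec_id = parts[1] if len(parts) > 1 else f"rec{n}"
        try:
            mol = standardize(parse_smiles(smiles), opts)
            yield LibraryRecord(rec_id, line, molecule=mol)
        except ParseFailure as exc:
            yield LibraryRecord(rec_id, line, parse_error=str(exc))


def _records_from_sdf(
    path: Path, opts: StandardizeOptions
) -> Iterator[LibraryRecord]:
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    for i, mol in enumerate(supplier, start=1):
        if mol is None:
            yield LibraryRecord(
                f"rec{i}", f"<sdf record {i}>", parse_error="unparsable SDF record"
            )
            continue
        rec_id = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"rec{i}"
        smiles = Chem.MolToSmiles(mol)
        try:
            m = standardize(parse_smiles(smiles), opts)
            yield LibraryRecord(rec_id, smiles, molecule=m)
        except ParseFailure as exc:
            yield LibraryRecord(rec_id, smiles, parse_error=str(exc))


def _infer_format(path: Path, fmt: Optional[str]) -> str:
    if fmt is not None:
        return fmt.lower()
    suffix = path.suffix.lower().lstrip(".")
    if suffix in {"smi", "smiles", "txt", "ism"}:
        return "smi"
    if suffix in {"sdf", "sd", "mol"}:
        return "sdf"
    if suffix == "csv":
        return "csv"
    raise ValueError(f"cannot infer library format from {path.name!r}")


def read_library(
    path: str | Path,
    fmt: Optional[str] = None,
    opts: StandardizeOptions = DEFAULT_STANDARDIZE,
) -> list[LibraryRecord]:
    """Read a compound library (.smi, .sdf or .csv) into LibraryRecords.

    A CSV input must have a ``smiles`` column; ``id`` and ``logD`` columns
    are picked up when present (logD becomes a per-record property, since it
    cannot be computed from the structure alone).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, fmt)
    if fmt == "smi":
        with open(path) as fh:
            return list(_records_from_smiles_lines(fh, opts))
    if fmt == "sdf":
        return list(_records_from_sdf(path, opts))
    if fmt == "csv":
        return _read_csv(path, opts)
    raise ValueError(f"unsupported library format: {fmt!r}")


def _read_csv(path: Path, opts: StandardizeOptions) -> list[LibraryRecord]:
    records: list[LibraryRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not any(
            f.lower() == "smiles" for f in reader.fieldnames
        ):
            raise ValueError(f"{path}: CSV library needs a 'smiles' column")
        cols = {f.lower(): f for f in reader.fieldnames}
        for i, row in enumerate(reader, start=1):
            smiles = (row.get(cols["smiles"]) or "").strip()
            rec_id = (row.get(cols.get("id", ""), "") or "").strip() or f"rec{i}"
            props = {}
            if "logd" in cols:
                raw = (row.get(cols["logd"]) or "").strip()
                if raw:
                    props["logd"] = float(raw)
            try:
                mol = standardize(parse_smiles(smiles), opts)
                rec = LibraryRecord(rec_id, smiles, molecule=mol)
            except ParseFailure as exc:
                rec = LibraryRecord(rec_id, smiles, parse_error=str(exc))
            rec.properties.update(props)
            records.append(rec)
    return records


def write_library(
    records: Iterable[LibraryRecord],
    path: str | Path,
    fmt: Optional[str] = None,
) -> None:
    """Write records carrying molecules to .smi, .sdf or .csv.

    The written file re-reads to the same canonical-SMILES sequence.
    Records with parse errors are skipped (they carry no structure).
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    mols = [r for r in records if r.ok]
    if fmt == "smi":
        with open(path, "w") as fh:
            for r in mols:
                fh.write(f"{r.molecule.canonical_smiles} {r.record_id}\n")
    elif fmt == "sdf":
        writer = Chem.SDWriter(str(path))
        try:
            for r in mols:
                mol = Chem.Mol(r.molecule.structure)
                mol.SetProp("_Name", r.record_id)
                writer.write(mol)
        finally:
            writer.close()
    elif fmt == "csv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["id", "smiles"])
            for r in mols:
                w.writerow([r.record_id, r.molecule.canonical_smiles])
    else:
        raise ValueError(f"unsupported output format: {fmt!r}")
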