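"""Deterministic fixtures: curated molecules that exercise every filter.

Three generators back the test suite and double as quick-start data:

* :func:`alkane_series` -- linear alkanes, whose descriptors are known in
  closed form (monotone MW, rotatable bonds = max(0, n-3), no rings, no
  H-bonding), used as monotonicity probes.
* :func:`functional_group_probes` -- one molecule per screened moiety
  class, each carrying exactly one instance of its target group on an
  otherwise inert scaffold, plus inert controls.
* :func:`drug_like_panel` -- a bundled 56-molecule panel spanning
  fragment-size to PPI-inhibitor-size chemistry (MW ~ 46-706, SlogP ~ -1..9)
  so every built-in filter has both passers and failers.

The aggregator-reference fixture (20 lipophilic, polycyclic structures) is
synthetic: it stands in for the external known-aggregator collection and
claims no fidelity to it.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

from .chem_io import LibraryRecord, parse_smiles, standardize

__all__ = [
    "CuratedRecord",
    "alkane_series",
    "functional_group_probes",
    "drug_like_panel",
    "panel_records",
    "aggregator_reference_path",
    "materialize",
]


@dataclass(frozen=True)
class CuratedRecord:
    """A curated test molecule with its construction rationale."""

    smiles: str
    note: str
    expected: dict = field(default_factory=dict)  # catalog/filter -> pattern/verdict


def alkane_series(n_max: int) -> list[str]:
    """Linear alkanes C1..Cn_max as SMILES."""
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    return ["C" * n for n in range(1, n_max + 1)]


def functional_group_probes() -> list[CuratedRecord]:
    """One probe per screened moiety class, each built to fire exactly its
    intended pattern within its catalog, plus inert controls.

    ``expected`` maps catalog name ('pains' / 'reos') to the single pattern
    name expected to fire, or to None for a clean pass.
    """
    return [
        # REOS moieties
        CuratedRecord("O=[N+]([O-])c1ccccc1", "nitrobenzene: one nitro group",
                      {"reos": "nitro"}),
        CuratedRecord("CCOOCC", "diethyl peroxide: one O-O bond",
                      {"reos": "peroxide"}),
        CuratedRecord("O=S(=O)(Oc1ccccc1)C(F)(F)F", "phenyl triflate",
                      {"reos": "triflate"}),
        CuratedRecord("O=Cc1ccccc1", "benzaldehyde: one aldehyde",
                      {"reos": "aldehyde"}),
        CuratedRecord("COC(OC)c1ccccc1", "benzaldehyde dimethyl acetal",
                      {"reos": "acetal"}),
        CuratedRecord("CC(=O)C=C", "methyl vinyl ketone: Michael acceptor",
                      {"reos": "michael_acceptor"}),
        CuratedRecord("O=C(Cl)c1ccccc1", "benzoyl chloride: acyl halide",
                      {"reos": "acyl_halide"}),
        CuratedRecord("c1ccccc1C1CO1", "styrene oxide: one epoxide",
                      {"reos": "epoxide"}),
        CuratedRecord("O=C=Nc1ccccc1", "phenyl isocyanate",
                      {"reos": "isocyanate"}),
        CuratedRecord("BrCc1ccccc1", "benzyl bromide: alkyl halide",
                      {"reos": "alkyl_halide"}),
        CuratedRecord("SCc1ccccc1", "benzyl thiol",
                      {"reos": "thiol"}),
        # PAINS families
        CuratedRecord("Oc1ccccc1O", "catechol", {"pains": "catechol"}),
        CuratedRecord("O=C1C=CC(=O)C=C1", "p-benzoquinone",
                      {"pains": "quinone_para"}),
        CuratedRecord("O=C1C(=O)C=CC=C1", "o-benzoquinone",
                      {"pains": "quinone_ortho"}),
        CuratedRecord("O=C1CSC(=S)N1", "rhodanine core (no ene)",
                      {"pains": "rhodanine"}),
        CuratedRecord("CN(C)Cc1ccccc1O", "phenolic Mannich base",
                      {"pains": "phenolic_mannich_base"}),
        CuratedRecord("NN=Cc1ccc(O)cc1", "4-hydroxyphenyl hydrazone",
                      {"pains": "hydroxyphenyl_hydrazone"}),
        CuratedRecord("O=C1NC(=O)NC(=O)C1=CC", "ethylidene barbiturate",
                      {"pains": "alkylidene_barbiturate"}),
        CuratedRecord("CC1=NN(c2ccccc2)C(=O)C1=Cc1ccccc1",
                      "benzylidene pyrazolone: alkylidene 5-ring heterocycle",
                      {"pains": "alkylidene_five_ring_het"}),
        CuratedRecord("Cc1ccc(C)n1-c1ccccc1", "2,5-dimethyl-N-phenylpyrrole",
                      {"pains": "aralkyl_pyrrole"}),
        CuratedRecord("O=[N+]([O-])c1ccc2nonc2c1", "nitrobenzofurazan",
                      {"pains": "activated_benzofurazan"}),
        CuratedRecord("Nc1sccc1C(C)=O", "2-amino-3-acetylthiophene",
                      {"pains": "amino_thiophene_carbonyl"}),
        # inert controls: no flagged group in either catalog
        CuratedRecord("CCOCC", "diethyl ether: inert control",
                      {"reos": None, "pains": None}),
        CuratedRecord("Cc1ccccc1", "toluene: inert control",
                      {"reos": None, "pains": None}),
    ]


def drug_like_panel() -> list[tuple[str, str]]:
    """The bundled (smiles, id) panel; see the module docstring."""
    ref = importlib.resources.files("medchemfilters.data") / "drug_like_panel.smi"
    out = []
    for line in ref.read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        smiles, rec_id = line.split()
        out.append((smiles, rec_id))
    return out


def panel_records() -> list[LibraryRecord]:
    """The drug-like panel as parsed, standardized LibraryRecords."""
    return [
        LibraryRecord(rec_id, smiles, molecule=standardize(parse_smiles(smiles)))
        for smiles, rec_id in drug_like_panel()
    ]


def aggregator_reference_path() -> Path:
    """Path to the bundled synthetic 20-molecule aggregator reference."""
    ref = importlib.resources.files("medchemfilters.data") / "aggregator_reference.smi"
    return Path(str(ref))


def materialize(out_dir: str | Path) -> list[Path]:
    """Write all bundled fixture files into a directory; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    data = importlib.resources.files("medchemfilters.data")
    for name in ("drug_like_panel.smi", "aggregator_reference.smi",
                 "pains.smarts", "reos.smarts"):
        target = out_dir / name
        target.write_text((data / name).read_text(encoding="utf-8"), encoding="utf-8")
        written.append(target)
    probes = out_dir / "functional_group_probes.smi"
    with open(probes, "w") as fh:
        for i, rec in enumerate(functional_group_probes(), start=1):
            fh.write(f"{rec.smiles} probe{i}\n")
    written.append(probes)
    return written
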