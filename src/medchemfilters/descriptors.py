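"""Molecular descriptors, fingerprints and substructure counting.

Every numeric quantity any implemented filter consumes is computed here, in
one pass per molecule, and returned as a :class:`DescriptorVector`.

Descriptor conventions
----------------------
* ``slogp`` / ``smr`` are the Crippen atom-contribution estimates of logP
  and molar refractivity (the descriptors the RDKit calculator names SlogP
  and SMR).  All filters that print a logP-type cutoff (logP, AlogP, ClogP)
  are evaluated against ``slogp``; the single-estimator choice is a
  documented approximation, not a claim that the original authors used
  Crippen values.
* ``hbd`` / ``hba`` are the Lipinski-style counts: HBD = number of N-H and
  O-H hydrogens, HBA = number of N and O atoms.  Filter verdicts are
  sensitive to this definition; it matches the provenance of the rules.
* ``rings`` is the SSSR ring count; ``aromatic_rings`` counts aromatic SSSR
  rings.
* ``total_atoms_incl_h`` counts every atom including implicit hydrogens
  (the Ghose "number of atoms" convention).
* ``logd`` is never estimated internally: it is a pH-dependent measured or
  externally predicted quantity.  It stays ``None`` unless supplied per
  record, and rules that need it either use the supplied value or -- via an
  explicit opt-in -- substitute ``slogp``.
* ``branch_points`` (heavy atoms with heavy-atom degree >= 3) is a simple
  stand-in for the continuous "branching" index used by the CNS-activity
  filter, whose exact formula is not public; it is pluggable via
  ``branching_index``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors
from rdkit.Chem import rdFingerprintGenerator

from .chem_io import Molecule

__all__ = [
    "DescriptorVector",
    "FingerprintConfig",
    "Fingerprint",
    "compute_descriptors",
    "count_substructure",
    "fingerprint",
    "tanimoto",
    "branching_index",
    "nonterminal_single_bond_count",
]

_HALOGENS = {9, 17, 35, 53, 85}

# matches protonated and deprotonated carboxylic acids
_CARBOXYLIC_ACID = Chem.MolFromSmarts("[CX3](=O)[OX2H1,OX1-]")


@dataclass(frozen=True)
class DescriptorVector:
    """All per-molecule numeric descriptors the filters consume."""

    slogp: float
    smr: float
    tpsa: float
    mw: float
    rot_bonds: int
    hba: int
    hbd: int
    heavy_atoms: int
    rings: int
    aromatic_rings: int
    total_atoms_incl_h: int
    formal_charge: int
    halogens: int
    n_count: int
    o_count: int
    c_count: int
    carboxylic_acids: int
    nonterminal_single_bonds: int
    branch_points: int
    logd: Optional[float] = None

    def get(self, name: str) -> Optional[float]:
        return getattr(self, name)

    def with_logd(self, logd: float) -> "DescriptorVector":
        return replace(self, logd=logd)


def branching_index(m: Molecule) -> int:
    """Number of heavy atoms with heavy-atom degree >= 3.

    Default branching measure; a continuous index can be substituted by
    passing ``branching_fn`` to :func:`compute_descriptors`.
    """
    return sum(1 for a in m.structure.GetAtoms() if a.GetDegree() >= 3)


def nonterminal_single_bond_count(m: Molecule) -> int:
    """Single non-aromatic bonds between heavy atoms, neither end terminal."""
    n = 0
    for bond in m.structure.GetBonds():
        if bond.GetBondType() != Chem.BondType.SINGLE or bond.GetIsAromatic():
            continue
        if bond.GetBeginAtom().GetDegree() > 1 and bond.GetEndAtom().GetDegree() > 1:
            n += 1
    return n


def compute_descriptors(m: Molecule, branching_fn=branching_index) -> DescriptorVector:
    """Compute the full descriptor vector for a molecule.

    Deterministic for a given canonical structure.  ``logd`` is left unset;
    see the module docstring.
    """
    # re-parse from the canonical string so float-summation order (Crippen
    # atom contributions) cannot depend on the input atom order
    mol = Chem.MolFromSmiles(m.canonical_smiles)
    atoms = list(mol.GetAtoms())
    halogens = sum(1 for a in atoms if a.GetAtomicNum() in _HALOGENS)
    return DescriptorVector(
        slogp=Crippen.MolLogP(mol),
        smr=Crippen.MolMR(mol),
        tpsa=Descriptors.TPSA(mol),
        mw=Descriptors.MolWt(mol),
        rot_bonds=Lipinski.NumRotatableBonds(mol),
        hba=Lipinski.NOCount(mol),
        hbd=Lipinski.NHOHCount(mol),
        heavy_atoms=mol.GetNumHeavyAtoms(),
        rings=rdMolDescriptors.CalcNumRings(mol),
        aromatic_rings=rdMolDescriptors.CalcNumAromaticRings(mol),
        total_atoms_incl_h=mol.GetNumAtoms() + sum(a.GetTotalNumHs() for a in atoms),
        formal_charge=Chem.GetFormalCharge(mol),
        halogens=halogens,
        n_count=sum(1 for a in atoms if a.GetAtomicNum() == 7),
        o_count=sum(1 for a in atoms if a.GetAtomicNum() == 8),
        c_count=sum(1 for a in atoms if a.GetAtomicNum() == 6),
        carboxylic_acids=count_substructure(m, _CARBOXYLIC_ACID),
        nonterminal_single_bonds=nonterminal_single_bond_count(m),
        branch_points=branching_fn(m),
    )


def count_substructure(m: Molecule, pattern) -> int:
    """Number of distinct (symmetry-deduplicated) matches of a SMARTS pattern.

    ``pattern`` is a pre-parsed RDKit query molecule (invalid SMARTS is a
    configuration error caught at catalog load, not here).  Matches are
    uniquified so a symmetric group is counted once per chemical group.
    """
    return len(m.structure.GetSubstructMatches(pattern, uniquify=True))


@dataclass(frozen=True)
class FingerprintConfig:
    """Fingerprint family + size; fingerprints compare only within a config."""

    family: str = "morgan"
    radius: int = 2
    n_bits: int = 2048


DEFAULT_FP_CONFIG = FingerprintConfig()

_GENERATORS: dict[FingerprintConfig, object] = {}


@dataclass(frozen=True)
class Fingerprint:
    bits: frozenset[int]
    config: FingerprintConfig


def _generator(cfg: FingerprintConfig):
    gen = _GENERATORS.get(cfg)
    if gen is None:
        if cfg.family != "morgan":
            raise ValueError(f"unsupported fingerprint family: {cfg.family!r}")
        gen = rdFingerprintGenerator.GetMorganGenerator(
            radius=cfg.radius, fpSize=cfg.n_bits
        )
        _GENERATORS[cfg] = gen
    return gen


def fingerprint(m: Molecule, cfg: FingerprintConfig = DEFAULT_FP_CONFIG) -> Fingerprint:
    """Circular (Morgan) fingerprint as a set of on-bit indices."""
    bv = _generator(cfg).GetFingerprint(m.structure)
    return Fingerprint(bits=frozenset(bv.GetOnBits()), config=cfg)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto coefficient |A n B| / |A u B|; 0.0 when both sets are empty."""
    if a.config != b.config:
        raise ValueError("fingerprints computed with different configurations")
    union = len(a.bits | b.bits)
    if union == 0:
        return 0.0
    return len(a.bits & b.bits) / union
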