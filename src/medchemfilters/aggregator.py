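"""Aggregation-propensity classification by similarity to known aggregators.

Colloidal aggregators cause false-positive inhibition in biochemical
assays.  Propensity is estimated from two signals: the maximum Tanimoto
similarity T of a compound to a reference set of known aggregators, and its
lipophilicity (SlogP).  The printed tier bands are::

    high   : T >= 0.85  or  SlogP > 5
    medium : T >= 0.5   and SlogP > 3
    low    : T < 0.85   and SlogP <= 3

The three bands are not an exact partition of the (T, SlogP) plane (e.g.
T = 0.6, SlogP = 2 satisfies the printed "low" band while also failing
"medium"), so classification is an ordered cascade -- high, else medium,
else low -- which reproduces every printed band assignment and leaves no
gaps.

The reference set is user-supplied; the canonical ~12,600-compound
collection of known aggregators is an external download and is not
redistributed.  A small synthetic fixture reference ships for testing.
Similarity search is an exact linear scan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from .chem_io import Molecule, read_library
from .descriptors import (
    DEFAULT_FP_CONFIG,
    Fingerprint,
    FingerprintConfig,
    fingerprint,
    tanimoto,
)
from .property_filters import Verdict

__all__ = [
    "AggregatorReference",
    "PropensityTiers",
    "DEFAULT_TIERS",
    "load_reference",
    "max_similarity",
    "classify_propensity",
    "aggregator_verdict",
    "STRINGENCIES",
]

logger = logging.getLogger(__name__)

STRINGENCIES = ("keep_only_low", "remove_high_only", "keep_all_flag")


@dataclass(frozen=True)
class PropensityTiers:
    """Configurable tier thresholds; defaults are the published bands."""

    high_tanimoto_min: float = 0.85
    high_slogp_min: float = 5.0
    medium_tanimoto_min: float = 0.5
    medium_slogp_min: float = 3.0

    def __post_init__(self) -> None:
        if self.high_tanimoto_min < self.medium_tanimoto_min:
            raise ValueError("high tier Tanimoto threshold below medium tier's")


DEFAULT_TIERS = PropensityTiers()


@dataclass(frozen=True)
class AggregatorReference:
    fingerprints: tuple[tuple[str, Fingerprint], ...]  # (record_id, fp)
    fp_config: FingerprintConfig = DEFAULT_FP_CONFIG
    n_parse_failures: int = 0

    def __len__(self) -> int:
        return len(self.fingerprints)


def load_reference(
    path: str | Path, fp_config: FingerprintConfig = DEFAULT_FP_CONFIG
) -> AggregatorReference:
    """Load a known-aggregator SMILES file into a fingerprint reference.

    Parse failures are logged and counted, never fatal.  An empty reference
    is legal but degenerate (everything scores T = 0), so it warns loudly.
    """
    records = read_library(path, fmt="smi")
    fps = tuple(
        (r.record_id, fingerprint(r.molecule, fp_config)) for r in records if r.ok
    )
    failures = sum(1 for r in records if not r.ok)
    if failures:
        logger.warning("aggregator reference %s: %d unparsable record(s)", path, failures)
    if not fps:
        logger.warning(
            "aggregator reference %s is EMPTY: every compound will score "
            "Tanimoto 0 and tiering will rest on SlogP alone", path,
        )
    return AggregatorReference(
        fingerprints=fps, fp_config=fp_config, n_parse_failures=failures
    )


def max_similarity(
    m: Molecule, ref: AggregatorReference
) -> tuple[float, Optional[str]]:
    """Maximum Tanimoto of ``m`` over the reference and the nearest member.

    Returns ``(0.0, None)`` for an empty reference.
    """
    fp = fingerprint(m, ref.fp_config)
    best, nearest = 0.0, None
    for rec_id, ref_fp in ref.fingerprints:
        t = tanimoto(fp, ref_fp)
        if t > best or nearest is None:
            best, nearest = t, rec_id
    return best, nearest


def classify_propensity(
    t: float, slogp: float, tiers: PropensityTiers = DEFAULT_TIERS
) -> str:
    """Ordered cascade over the tier bands; exactly one tier per input."""
    if not 0.0 <= t <= 1.0:
        raise ValueError(f"Tanimoto similarity must be in [0, 1], got {t}")
    if t >= tiers.high_tanimoto_min or slogp > tiers.high_slogp_min:
        return "high"
    if t >= tiers.medium_tanimoto_min and slogp > tiers.medium_slogp_min:
        return "medium"
    return "low"


def aggregator_verdict(tier: str, stringency: str = "keep_only_low") -> Verdict:
    """Turn a propensity tier into a pass/fail verdict at a given stringency.

    keep_only_low
        Only low-propensity compounds pass (the most stringent setting).
    remove_high_only
        Low and medium pass.
    keep_all_flag
        Everything passes; the tier is recorded for later assessment.
    """
    if tier not in {"low", "medium", "high"}:
        raise ValueError(f"unknown tier {tier!r}")
    if stringency not in STRINGENCIES:
        raise ValueError(f"stringency must be one of {STRINGENCIES}, got {stringency!r}")
    if stringency == "keep_only_low":
        passed = tier == "low"
    elif stringency == "remove_high_only":
        passed = tier != "high"
    else:
        passed = True
    return Verdict(passed=passed, tier=tier)
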