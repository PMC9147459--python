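"""Filter chains, library sampling, and before/after descriptor statistics.

A chain is an ordered list of steps, each naming a filter and a mode:
``remove`` steps shrink the working set, ``flag`` steps only annotate.
Every property and structural filter is a pure per-record predicate, so the
final surviving set of a remove-mode chain is order-invariant; ordering
still matters for speed (put the most aggressive filter first) and for the
per-step counts in the report.

Chemical-space shift is characterized the way screening-library curation
papers do it: mean and sample standard deviation of a basic descriptor set
(SlogP, SMR, TPSA, MW, rotatable bonds, HBA, HBD, heavy atoms, rings, and
C/N/O atom counts) before and after filtering, optionally on a seeded
uniform sample of the library.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .aggregator import (
    DEFAULT_TIERS,
    AggregatorReference,
    aggregator_verdict,
    classify_propensity,
    max_similarity,
)
from .chem_io import LibraryRecord
from .descriptors import DescriptorVector, compute_descriptors
from .property_filters import (
    Verdict,
    builtin_filter,
    builtin_filter_names,
    evaluate,
    muegge_evaluate,
)
from .structural_filters import Catalog, load_catalog, reos_full, screen

__all__ = [
    "ChainStep",
    "FilterChainSpec",
    "LibraryStats",
    "StatsDelta",
    "RunReport",
    "STATS_DESCRIPTORS",
    "sample_library",
    "run_chain",
    "compute_stats",
    "compare_stats",
    "available_steps",
]

STATS_DESCRIPTORS = (
    "slogp", "smr", "tpsa", "mw", "rot_bonds", "hba", "hbd",
    "heavy_atoms", "rings", "c_count", "n_count", "o_count",
)

# step-name aliases accepted in chain specs and on the command line
_ALIASES = {"ro5": "lipinski", "vdw": "vdwaterbeemd", "reos_hybrid": "reos"}


def available_steps() -> list[str]:
    names = set(builtin_filter_names()) - {"reos_properties"}
    names |= {"muegge", "pains", "reos", "reos_structural", "reos_properties",
              "aggregator"}
    return sorted(names)


@dataclass(frozen=True)
class ChainStep:
    filter: str
    mode: str = "remove"
    options: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in {"remove", "flag"}:
            raise ValueError(f"step {self.filter}: mode must be remove|flag")


@dataclass(frozen=True)
class FilterChainSpec:
    steps: tuple[ChainStep, ...]
    sample_fraction: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.steps:
            raise ValueError("chain must have at least one step")
        if self.sample_fraction is not None and not 0 < self.sample_fraction <= 1:
            raise ValueError("sample_fraction must be in (0, 1]")

    @classmethod
    def from_names(
        cls,
        names: Sequence[str],
        mode: str = "remove",
        sample_fraction: Optional[float] = None,
        seed: int = 0,
        options: Optional[dict] = None,
    ) -> "FilterChainSpec":
        options = options or {}
        steps = tuple(
            ChainStep(n, mode=mode, options=options.get(n, {})) for n in names
        )
        return cls(steps=steps, sample_fraction=sample_fraction, seed=seed)


@dataclass
class LibraryStats:
    n: int
    mean: dict[str, float] = field(default_factory=dict)
    sd: dict[str, Optional[float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"n": self.n, "mean": self.mean, "sd": self.sd}


@dataclass
class StatsDelta:
    mean_delta: dict[str, float]
    pass_fraction: float


@dataclass
class StepReport:
    name: str
    mode: str
    entering: int
    passing: int
    stats_after: LibraryStats

    @property
    def pass_fraction(self) -> float:
        return self.passing / self.entering if self.entering else float("nan")


@dataclass
class RunReport:
    input_count: int
    parsed_count: int
    failed_parse_count: int
    stats_before: LibraryStats
    steps: list[StepReport]
    verdicts: pd.DataFrame  # one row per (record, step)

    def to_dict(self) -> dict:
        return {
            "input_count": self.input_count,
            "parsed_count": self.parsed_count,
            "failed_parse_count": self.failed_parse_count,
            "stats_before": self.stats_before.to_dict(),
            "steps": [
                {
                    "name": s.name,
                    "mode": s.mode,
                    "entering": s.entering,
                    "passing": s.passing,
                    "pass_fraction": s.pass_fraction,
                    "stats_after": s.stats_after.to_dict(),
                }
                for s in self.steps
            ],
        }

    def save_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def save_verdicts_csv(self, path: str | Path) -> None:
        self.verdicts.to_csv(path, index=False)


def sample_library(
    records: Sequence[LibraryRecord], fraction: float, seed: int
) -> list[LibraryRecord]:
    """Seeded uniform sample without replacement of floor(n * fraction) records.

    ``fraction=1.0`` returns all records in the original order; smaller
    fractions preserve the relative input order of the drawn records.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if fraction == 1.0:
        return list(records)
    k = math.floor(len(records) * fraction)
    rng = np.random.default_rng(seed)
    idx = sorted(rng.choice(len(records), size=k, replace=False))
    return [records[i] for i in idx]


def compute_stats(
    records: Sequence[LibraryRecord],
    descriptors: Optional[dict[str, DescriptorVector]] = None,
) -> LibraryStats:
    """Mean and sample SD (n-1 denominator) of the standard descriptor set.

    SD is reported as absent (None) when fewer than two records; an empty
    library yields n = 0 and no moments.
    """
    ok = [r for r in records if r.ok]
    if not ok:
        return LibraryStats(n=0)
    if descriptors is None:
        descriptors = {r.record_id: compute_descriptors(r.molecule) for r in ok}
    frame = pd.DataFrame(
        [
            {name: getattr(descriptors[r.record_id], name) for name in STATS_DESCRIPTORS}
            for r in ok
        ]
    )
    mean = {k: float(v) for k, v in frame.mean().items()}
    if len(ok) < 2:
        sd: dict[str, Optional[float]] = {k: None for k in STATS_DESCRIPTORS}
    else:
        sd = {k: float(v) for k, v in frame.std(ddof=1).items()}
    return LibraryStats(n=len(ok), mean=mean, sd=sd)


def compare_stats(before: LibraryStats, after: LibraryStats) -> StatsDelta:
    """Per-descriptor mean shift (after - before) and the pass fraction."""
    deltas = {
        k: after.mean[k] - before.mean[k]
        for k in before.mean
        if k in after.mean
    }
    frac = after.n / before.n if before.n else float("nan")
    return StatsDelta(mean_delta=deltas, pass_fraction=frac)


def _resolve_step(
    step: ChainStep,
    aggregator_reference: Optional[AggregatorReference],
    catalogs: dict[str, Catalog],
    substitute_slogp_for_logd: bool,
) -> Callable[[LibraryRecord, DescriptorVector], Verdict]:
    """Build the per-record evaluator for one step; fails fast on missing
    resources so a chain never dies halfway through a library."""
    name = _ALIASES.get(step.filter, step.filter)
    opts = step.options

    if name == "aggregator":
        if aggregator_reference is None:
            raise ValueError(
                "chain contains an aggregator step but no aggregator "
                "reference was provided"
            )
        tiers = opts.get("tiers", DEFAULT_TIERS)
        stringency = opts.get("stringency", "keep_only_low")
        ref = aggregator_reference

        def eval_aggregator(rec: LibraryRecord, d: DescriptorVector) -> Verdict:
            t, nearest = max_similarity(rec.molecule, ref)
            tier = classify_propensity(t, d.slogp, tiers)
            v = aggregator_verdict(tier, stringency)
            v.details.update({"tanimoto": t, "nearest_aggregator": nearest})
            return v

        return eval_aggregator

    if name in {"pains", "reos_structural"}:
        catalog = catalogs[name if name == "pains" else "reos"]
        return lambda rec, d: screen(rec.molecule, catalog)

    if name == "reos":
        catalog = catalogs["reos"]
        return lambda rec, d: reos_full(rec.molecule, d, mode="hybrid", catalog=catalog)

    if name == "muegge":
        min_points = opts.get("min_points")
        max_points = opts.get("max_points")
        return lambda rec, d: muegge_evaluate(
            rec.molecule, d, min_points=min_points, max_points=max_points
        )

    defn = opts.get("definition") or builtin_filter(name)
    return lambda rec, d: evaluate(
        defn, d, substitute_slogp_for_logd=substitute_slogp_for_logd
    )


def run_chain(
    records: Sequence[LibraryRecord],
    spec: FilterChainSpec,
    aggregator_reference: Optional[AggregatorReference] = None,
    substitute_slogp_for_logd: bool = False,
) -> tuple[list[LibraryRecord], RunReport]:
    """Run a filter chain over a library.

    Returns the surviving records and a :class:`RunReport` with per-step
    counts, before/after descriptor statistics, and the full per-record
    verdict table (kept even for removed records, so flag-style review is
    always possible after the fact).
    """
    # resolve all evaluators up front: missing resources are fatal before
    # any record is processed
    catalogs = {"pains": load_catalog("pains"), "reos": load_catalog("reos")}
    evaluators = [
        (
            step,
            _resolve_step(step, aggregator_reference, catalogs,
                          substitute_slogp_for_logd),
        )
        for step in spec.steps
    ]

    records = list(records)
    if spec.sample_fraction is not None:
        records = sample_library(records, spec.sample_fraction, spec.seed)

    parsed = [r for r in records if r.ok]
    failed = [r for r in records if not r.ok]

    # one descriptor pass per record, shared by every step
    descriptors: dict[str, DescriptorVector] = {}
    for r in parsed:
        d = compute_descriptors(r.molecule)
        if "logd" in r.properties:
            d = d.with_logd(float(r.properties["logd"]))
        descriptors[r.record_id] = d

    stats_before = compute_stats(parsed, descriptors)
    working = parsed
    verdict_rows: list[dict] = []
    step_reports: list[StepReport] = []

    for step, evaluator in evaluators:
        entering = len(working)
        survivors: list[LibraryRecord] = []
        for rec in working:
            v = evaluator(rec, descriptors[rec.record_id])
            verdict_rows.append(
                {
                    "record_id": rec.record_id,
                    "smiles": rec.molecule.canonical_smiles,
                    "step": step.filter,
                    "mode": step.mode,
                    "passed": v.passed,
                    "unevaluable": v.unevaluable,
                    "violations": ";".join(v.violations),
                    "matches": ";".join(v.matches),
                    "tier": v.tier or "",
                }
            )
            if v.passed or step.mode == "flag":
                survivors.append(rec)
        passing = sum(
            1 for row in verdict_rows[-entering:] if row["passed"]
        ) if entering else 0
        working = survivors
        step_reports.append(
            StepReport(
                name=step.filter,
                mode=step.mode,
                entering=entering,
                passing=passing,
                stats_after=compute_stats(working, descriptors),
            )
        )

    report = RunReport(
        input_count=len(records),
        parsed_count=len(parsed),
        failed_parse_count=len(failed),
        stats_before=stats_before,
        steps=step_reports,
        verdicts=pd.DataFrame(
            verdict_rows,
            columns=["record_id", "smiles", "step", "mode", "passed",
                     "unevaluable", "violations", "matches", "tier"],
        ),
    )
    return working, report


def chain_spec_from_yaml(path: str | Path) -> FilterChainSpec:
    """Load a chain specification from a YAML config file.

    Schema::

        steps:
          - filter: lipinski
            mode: remove          # or flag
            options: {}
        sample_fraction: 0.01     # optional
        seed: 42
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    steps = tuple(
        ChainStep(
            filter=s["filter"],
            mode=s.get("mode", "remove"),
            options=s.get("options", {}),
        )
        for s in data["steps"]
    )
    return FilterChainSpec(
        steps=steps,
        sample_fraction=data.get("sample_fraction"),
        seed=int(data.get("seed", 0)),
    )
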