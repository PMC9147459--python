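#!/usr/bin/env python
"""OPTIONAL, network-dependent demonstration: regenerate a pass-percentage
table on a current ZINC sample plus the public known-aggregator set.

Never run by the test suite.  ZINC tranche contents and the aggregator
collection change over time, so agreement with any historical survey is
expected only approximately and is not asserted anywhere.

Usage:
    python scripts/fetch_zinc_demo.py --zinc-smi TRANCHE.smi \
        --aggregators aggregators.smi --sample 0.01 --seed 42

Download the inputs yourself first (both require accepting the providers'
terms):
  * a 2D "in-stock" SMILES tranche from https://zinc.docking.org/tranches/
  * the known-aggregator SMILES from http://advisor.bkslab.org/rawdata/
"""

from __future__ import annotations

import argparse


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--zinc-smi", required=True)
    parser.add_argument("--aggregators", required=True)
    parser.add_argument("--sample", type=float, default=0.01)
    parser.add_argument("--seed", type=int, default=42)
    args = parser.parse_args()

    from medchemfilters.aggregator import load_reference
    from medchemfilters.chem_io import read_library
    from medchemfilters.pipeline import FilterChainSpec, run_chain, sample_library

    records = sample_library(read_library(args.zinc_smi), args.sample, args.seed)
    reference = load_reference(args.aggregators)

    print(f"sampled {len(records)} records")
    print(f"{'filter':16s} {'pass %':>8s}")
    for name in ["reos", "pains", "aggregator", "ro3", "ro4", "veber", "egan",
                 "lipinski", "mozziconacci", "vdwaterbeemd", "murcko"]:
        spec = FilterChainSpec.from_names(
            [name], options={"aggregator": {"stringency": "keep_only_low"}}
        )
        _, report = run_chain(records, spec, aggregator_reference=reference)
        step = report.steps[0]
        print(f"{name:16s} {100 * step.pass_fraction:7.1f}%")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
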