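# medchemfilters

Compound-library curation for virtual screening: a single library + CLI
that applies the common medicinal-chemistry filters to SMILES/SDF compound
collections, either removing or merely flagging compounds, and reports how
each filter shifts the library's chemical space.

It is aimed at computational and medicinal chemists preparing screening
libraries: the first step of a high-throughput virtual-screening campaign,
where millions of raw vendor structures must be reduced to a tractable,
drug-like (or deliberately *non*-drug-like, e.g. fragment or PPI-inhibitor)
subset before docking or similarity searching.

## What it implements

**Property filters** — each a set of inclusive descriptor bounds with an
allowed number of rule breaks, evaluated as
pass ⇔ #{violated rules} ≤ allowed breaks:

| filter | cutoffs |
|---|---|
| Lipinski (Ro5) | MW ≤ 500, SlogP ≤ 5, HBD ≤ 5, HBA ≤ 10 — **one break allowed** |
| Rule-of-3 | MW ≤ 300, SlogP ≤ 3, HBD ≤ 3, HBA ≤ 3, RotB ≤ 3 |
| Rule-of-4 | MW ≥ 400, SlogP ≥ 4, rings ≥ 4, HBA ≥ 4 |
| Veber | RotB ≤ 10, TPSA ≤ 140 Å² |
| Egan | SlogP ≤ 5.88, TPSA ≤ 131.6 Å² |
| Ghose | 180 ≤ MW ≤ 480, 40 ≤ SMR ≤ 130, −0.4 ≤ SlogP ≤ 5.6, 20 ≤ atoms ≤ 70 |
| Mozziconacci | RotB ≤ 15, rings ≤ 6, O ≥ 1, N ≥ 1, halogens ≤ 7 |
| van de Waterbeemd | MW ≤ 450, TPSA ≤ 90 Å² |
| Murcko (CNS) | 200 ≤ MW ≤ 540, 0 ≤ SlogP ≤ 5.2, HBA ≤ 4, HBD ≤ 3, RotB ≤ 7, branching 3.4–12.2, aromatic rings < 3 |
| Oprea lead-like | MW < 450, −3.5 ≤ SlogP < 4.5, −4 ≤ logD ≤ 4, rings ≤ 4, nonterminal single bonds ≤ 10, HBD ≤ 5, HBA ≤ 8 |
| Fichert | MW ≤ 500, 0 ≤ logD ≤ 3 (logD must be supplied) |
| Muegge | dismisses >1 carboxylic acid or ring-free compounds; reports amine pharmacophore points |

**Substructure screens** — editable SMARTS catalogs with a per-pattern
maximum allowed match count: `pains` (promiscuous assay-interference
families: rhodanines, catechols, quinones, …) and `reos` (reactive groups:
nitro, peroxide, triflate, aldehyde, acetal, Michael acceptors, …).  REOS
is hybrid: its seven property rules (HBD ≤ 5, HBA ≤ 10, |charge| ≤ 2,
RotB ≤ 8, 200 ≤ MW ≤ 500, 20 ≤ heavy atoms ≤ 50, −2 ≤ SlogP ≤ 5) can be
applied together with the functional-group screen or omitted.

**Aggregator filter** — classifies aggregation propensity from the maximum
Tanimoto similarity *T* to a user-supplied set of known aggregators plus
lipophilicity: high if *T* ≥ 0.85 or SlogP > 5; else medium if *T* ≥ 0.5
and SlogP > 3; else low.  Stringency settings keep only low, remove high
only, or flag everything.

## Worked example

Run the classic sequential curation chain — rule-of-five, PAINS, hybrid
REOS, then the aggregator filter at its most stringent setting — on the
bundled 56-molecule drug-like panel:

```bash
medchemfilters run \
  --input src/medchemfilters/data/drug_like_panel.smi \
  --chain ro5,pains,reos,aggregator \
  --aggregator-reference src/medchemfilters/data/aggregator_reference.smi \
  --output survivors.smi --report report.json --verdicts verdicts.csv
```

prints

```
read 56 records (56 parsed, 0 failed)
  ro5              [remove] entering=    56 passing=    47 ( 83.9%)
  pains            [remove] entering=    47 passing=    47 (100.0%)
  reos             [remove] entering=    47 passing=    15 ( 31.9%)
  aggregator       [remove] entering=    15 passing=    15 (100.0%)
surviving: 15
```

Reading the numbers: 9 of 56 panel members break two or more rule-of-five
bounds (one break is tolerated) and are removed; the curated panel carries
no assay-interference substructures, so PAINS removes nothing; hybrid REOS
is the aggressive step here because its property floors (MW ≥ 200, heavy
atoms ≥ 20) reject every fragment-sized member; and the 15 survivors are
already low-lipophilicity, so none resembles the aggregator reference at
high similarity.  `report.json` holds per-step counts and mean ± SD of the
descriptor set (SlogP, SMR, TPSA, MW, RotB, HBA, HBD, heavy atoms, rings,
C/N/O counts) before and after each step; `verdicts.csv` lists every
molecule's violated rules, matched patterns and aggregator tier — including
removed molecules, so a remove-mode run can still be reviewed like a
flag-mode one.

The same machinery is available as a library:

```python
from medchemfilters import parse_smiles, compute_descriptors, builtin_filter, evaluate
d = compute_descriptors(parse_smiles("CC(=O)Oc1ccccc1C(=O)O"))  # aspirin
evaluate(builtin_filter("lipinski"), d).passed                   # True
```

`medchemfilters list-filters` prints every builtin with its cutoffs;
`medchemfilters fixtures --out DIR` materializes the bundled panel,
probes, catalogs and the synthetic aggregator reference.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the full curation chain above from scratch on the bundled panel and
aggregator reference (the seed drives the sampling machinery) and writes
the machine-readable results object to `--out`, printing the per-step
survival table as it goes.

`scripts/fetch_zinc_demo.py` is an optional, network-dependent script that
reproduces a pass-percentage survey on a current ZINC tranche sample plus
the public known-aggregator set; tranche contents drift over time, so its
output is illustrative and never asserted by the test suite.

See `docs/methods.md` for the scientific conventions (descriptor
definitions, bound semantics, tier cascade, catalog provenance) and known
limitations.
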