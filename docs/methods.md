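# Methods

## Problem and scope

Screening-library curation discriminates compounds on a pass/fail basis
against knowledge-based rules: property windows typical of known drugs (or
of fragments, leads, CNS drugs, PPI inhibitors), substructure screens for
reactive or assay-interfering chemotypes, and similarity to known colloidal
aggregators.  This package implements those three families behind one chain
runner.  Everything is 2D: no conformers, tautomer enumeration, pKa or
stereochemistry expansion.

## Standardization and canonical forms

Inputs are sanitized with RDKit; multi-fragment records (salts, mixtures)
are reduced to the largest fragment by heavy-atom count, with ties broken
by lexicographic canonical-SMILES order so the choice is reproducible.
All identity logic keys on RDKit canonical SMILES.  No specific canonical
algorithm is scientifically privileged — any consistent canonicalizer
satisfies the round-trip contracts — but descriptor computation re-parses
from the canonical string so that floating-point summation order cannot
make two spellings of one molecule differ in the last bits of SlogP.
Unparsable records are retained with their error and counted, never
silently dropped.

## Descriptor conventions

The verdict of every filter is only as defined as its descriptors:

* **SlogP / SMR** — Crippen atom-contribution logP and molar refractivity.
  All printed logP-type cutoffs (logP, AlogP, ClogP) are evaluated against
  SlogP.  This is a deliberate single-estimator simplification: the
  original filter authors used various estimators, and absolute pass rates
  shift by a few percent across estimators.
* **HBD / HBA** — Lipinski-style counts (HBD = N–H plus O–H hydrogens,
  HBA = N plus O atoms), matching the provenance of the rules that use
  them.  Stricter pharmacophore-based donor/acceptor definitions would
  give systematically lower counts.
* **TPSA** — Ertl topological polar surface area, Å².
* **rings** — SSSR count; **aromatic rings** counts aromatic SSSR rings.
* **number of atoms** (Ghose) — all atoms including implicit hydrogens.
* **nonterminal single bonds** — non-aromatic order-1 bonds between heavy
  atoms where neither endpoint has heavy-atom degree 1.
* **branching** — the CNS-activity filter prints a continuous branching
  window (3.4–12.2) whose defining formula is not public; the default
  stand-in is the integer count of heavy atoms with degree ≥ 3, and the
  measure is pluggable (`compute_descriptors(..., branching_fn=...)`).
  Verdicts from this rule should be read with that substitution in mind.
* **logD** — pH-dependent and not derivable from the graph; never
  estimated internally.  It is accepted as a per-record CSV column.  Rules
  that need it (Fichert; the optional Oprea logD window) mark records
  without it *unevaluable* — they fail closed but are counted separately
  from rule failures — unless SlogP substitution is explicitly enabled.
  The Oprea logP window always applies; its logD window only when a value
  exists.

## Rule engine

A filter is a list of descriptor bounds plus an allowed break count; each
breached bound contributes one violation and the compound passes when
violations ≤ allowed breaks (rule-of-five: 1; all others: 0, configurable).
Bounds are inclusive exactly as printed; the three printed strict
inequalities (Murcko aromatic rings < 3, Oprea MW < 450 and SlogP < 4.5)
are strict.  Evaluation is a pure function of (definition, descriptor
vector); definitions serialize to YAML so users can modify cutoffs or
define new filters without touching code.

The pharmacophore-point (Muegge) filter enforces its three published
dismissal rules (more than one carboxylic acid; no ring) and reports the
amine pharmacophore-point count.  Amines are trivalent, single-bonded,
non-aromatic nitrogens excluding amide/thioamide/sulfonamide/N-nitroso
environments; aromatic azole and diazine nitrogens are excluded by the
non-aromatic requirement, matching the published exclusion list; amines
sharing a ring fuse into one point.  The original pass window for the
point count is not published, so min/max thresholds exist but default off.

## Substructure screens

Catalogs are plain-text `name SMARTS [max_count]` files validated entirely
at load time.  A compound fails when any pattern's number of *distinct*
matches (symmetry-deduplicated, so a symmetric group counts once per
chemical group) exceeds its `max_count`; the default 0 means any
occurrence flags.  Raising a `max_count` can only grow the pass set —
tuning is monotone by construction.

The bundled PAINS catalog is a curated, family-representative
reconstruction (11 patterns covering rhodanines, phenolic Mannich bases,
hydroxyphenylhydrazones, alkylidene barbiturates and other alkylidene
five-ring heterocycles, 2,5-disubstituted N-aryl pyrroles, activated
benzofurazans, 2-amino-3-carbonylthiophenes, catechols, ortho- and
para-quinones), not the full ~480-pattern published list; the test suite
cross-checks it against RDKit's compiled full PAINS catalog on probe
structures, and any published SMARTS list can be dropped in as a file.
The REOS catalog covers the classically named reactive moieties (nitro,
peroxide, triflate, aldehyde, acetal, Michael acceptor, acyl halide,
epoxide, isocyanate, alkyl halide, thiol).  Neither catalog claims
byte-level parity with any specific historical implementation.  Both
screens were designed for non-covalent campaigns; for covalent-drug work,
flag rather than remove.

## Aggregator propensity

Propensity combines the maximum Tanimoto similarity *T* over a reference
set of known aggregators (default fingerprint: 2048-bit Morgan, radius 2;
configurable, and both sides of a comparison must share the
configuration) with SlogP:

    high   : T ≥ 0.85  or  SlogP > 5
    medium : T ≥ 0.5   and SlogP > 3
    low    : otherwise

The three published bands do not partition the (T, SlogP) plane — e.g.
T = 0.6, SlogP = 2 satisfies the printed "low" band while also failing
"medium" — so classification is an ordered cascade (high, else medium,
else low), which reproduces every printed band assignment and leaves no
gap.  Tanimoto of two empty bit sets is defined as 0.  Similarity search
is an exact linear scan; at library scale this is O(|library| × |reference|)
and deliberately favors correctness over speed.

The canonical ~12,600-compound aggregator collection is an external
download and is not redistributed.  The bundled 20-molecule reference is
*synthetic*: lipophilic, polycyclic chemotypes of the kind enriched among
aggregators (flavonoids, polyphenols, azoles, dyes, steroids).  It makes
the machinery testable offline; a green test against it establishes the
tiering and stringency logic, **not** recall against the real collection.

## Chains, sampling and statistics

Chain steps are pure per-record predicates, so the final surviving set of
remove-mode chains is invariant under step permutation; ordering matters
only for speed and per-step accounting.  Flag-mode steps annotate without
removing.  Descriptors are computed once per record and shared across
steps (plumbing, no semantic effect).  Per-record verdicts are always
emitted, including for removed records.

Sampling is a seeded uniform draw without replacement of ⌊n·fraction⌋
records, preserving input order; the historical 1%-sample surveys quote no
seed, so determinism-under-seed is the contract, not bitwise
reproduction.  Library statistics are mean and *sample* standard deviation
(n−1 denominator; the source surveys do not state theirs) of the
12-descriptor set; SD is reported absent for n < 2.

## Test fixtures

The 56-molecule drug-like panel spans MW ≈ 46–706 and SlogP ≈ −1–9 so
every filter has passers and failers at panel scale; expected verdicts are
re-derived in the tests by an independent literal-bounds oracle rather
than frozen from any external service.  Functional-group probes carry
exactly one target moiety on an inert scaffold, so each is expected to
fire exactly one pattern within its catalog.  The panel is a breadth
fixture, not a statistical sample of any vendor library: pass *rates* on
it say nothing about pass rates on real libraries, and the directional
chemical-space checks (fragment-rule survivors lighter, PPI-rule survivors
ring-richer, BBB-rule survivors lower-TPSA) are the intended qualitative
assertions.

## Known limitations

* Pass rates depend on the descriptor estimators above; this is inherent
  to all property-filter reimplementations, not a defect of the rules.
* The PAINS/REOS catalogs are representative, editable reconstructions —
  recall against the full published lists requires dropping those lists in.
* The branching descriptor is a stand-in (see above).
* The Lee natural-product filter is not implementable as pass/fail (only
  distribution means were ever published) and is omitted; the Eli Lilly
  275-rule set is likewise out of scope.
* No attempt is made to model covalent-chemistry campaigns.
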