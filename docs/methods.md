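# Methods

## Model

`hazmix` screens co-exposure to airborne chemicals under the additivity
assumption: substances whose toxic effects fall in the same toxicological
class (same target organ or mode of action) are assumed to contribute
summed risk. For each class activated by at least one mixture component,
the engine computes a Hazard Index

HI = Σᵢ 100 · Cᵢ / OELᵢ   (percent),

summing over the scenario substances that activate the class; a class is
*risky* iff HI > 100% **strictly** (HI = 100.0 exactly is not flagged — the
threshold is "greater than", and the boundary is verified by test sweep).
The sum uses `math.fsum` so contribution ordering cannot perturb the index.
Additivity implies three structural facts the test suite checks directly:
homogeneity (scaling all concentrations by k scales every HI by k),
monotonicity (adding an activating substance never lowers an HI), and
decomposition (the HI of a scenario equals the per-class sum of HIs over
any partition of its records).

The same OEL is used for a substance in every class it activates. This is a
known conservative simplification: an OEL is derived from the critical
effect only, so classes corresponding to less sensitive endpoints are
over-weighted. For a first-level alert tool this bias is acceptable and is
documented rather than corrected.

### Alert classes

Six of the 24 classes are non-additive *alert classes*: endocrine
disruption, male and female reproductive system damage, developmental
damage, carcinogenicity and/or mutagenicity, and sensitization. Summing
ratios is not a defensible model for these mechanisms, and for carcinogens
regulation requires minimizing exposure even below the limit. Activating an
alert class therefore produces a warning finding (keyed by a stable
`message_key`, the extension point for display text) and a class row with a
not-applicable index; no non-additive class ever carries a numeric HI in
any report. Ototoxicity is additive and keeps its HI, but its activation
additionally emits an *informational* finding, because noise co-exposure is
known to aggravate solvent ototoxicity and the combined "CMR and/or
ototoxic" warning is part of the expected report surface.

### Qualitative mode

When no measurements exist, the analysis degrades gracefully: every
activated class is reported with the number and identity of activating
substances, classes shared by ≥ 2 substances are flagged (more substances
attacking one organ ⇒ more concern), and per-substance ratios are rendered
as ">0%" / "N.A." markers, never numbers. The set of activated classes is
identical between the two modes for the same substance list — an invariant
under test.

### Ranking

Reports are totally ordered: alert classes first, then additive classes by
decreasing HI (quantitative) or decreasing substance count (qualitative);
alert classes rank among themselves by activating-substance count; all ties
break alphabetically by `class_id`, making rendering byte-deterministic.
Classes activated by no scenario substance are omitted, not shown as 0%
rows.

## Tunable parameters

| Parameter | Default | Units | Rationale |
|---|---|---|---|
| Risk threshold | 100 | % of summed OEL fraction | definitional for the Hazard Index |
| Molar volume | 24.45 | L/mol | ideal gas at 25 °C, 101.325 kPa; industrial-hygiene convention for ppm ↔ mg/m³ |
| OEL precedence | 8 h → ceiling → short-term | — | the full-shift limit is always used when present; fallbacks are conservative screens and always warned |
| `allow_missing` | off | — | quantitative records without concentrations are a hard error unless set; then they are dropped with a warning and every HI is a lower bound |

Unit reconciliation: when a measurement and an OEL disagree between ppm and
mg/m³, the measurement is converted via mg/m³ = ppm × MW / 24.45; a missing
molecular weight is a hard error naming the substance (a silently wrong
ratio is the worst failure mode). Fibre counts (f/cm³) convert to nothing.

## Data model and formats

The canonical database format is a single JSON document:

```json
{"jurisdiction": "...", "oel_name": "...",
 "substances": [{"cas": "...", "name": "...", "molecular_weight": 92.14,
                 "synthetic": false,
                 "oels": {"eight_hour": {"value": 20.0, "unit": "ppm"}},
                 "class_ids": ["central_nervous_system_damage"],
                 "evidence_notes": "..."}]}
```

Validation is structural and record-level (no external schema engine):
unknown fields, unknown OEL kinds or units, non-positive values, unknown
class links, duplicate CAS and bad CAS check digits are all rejected with
diagnostics naming the record. CAS numbers follow the registry convention
(2–7/2/1 digits, modulo-10 weighted check digit); entries flagged
`synthetic` are exempt from the check so generated fixtures cannot collide
with real registry numbers while still exercising the validator.

Because substance↔class is many-to-many, the flat dialect is two CSV files
in one directory: `substances.csv` (one row per OEL; descriptive fields
repeated and required to agree) and `classes.csv` (cas, class_id link
table). Two `#key=value` header lines carry the jurisdiction and OEL display
name, and `synthetic`/`evidence_notes` columns are included so that
parse∘write is an identity in both formats — a property tested on generated
databases. JSON writing sorts all keys; two writes of the same database are
byte-identical.

`evidence_notes` is free-text provenance metadata (e.g. the human ≤5×OEL /
animal ≤100×OEL literature criteria under which a class link was
established). It is stored and round-tripped but never interpreted: this
package does not do literature curation.

## Synthetic data

The real 700+-substance regulatory corpus behind tools of this kind is not
redistributable, so `generate_substance_db` fabricates one with the same
shape: CAS-shaped identifiers with valid check digits drawn from a high
(2,000,000+) range unlikely to be assigned, 8 h OELs uniform over
1–500 ppm or 0.1–100 mg/m³, occasional short-term (2–4× the 8 h value) and
ceiling (3–6×) companions, a 5% chance of carrying no full-shift limit
(half of those keep a ceiling or short-term value, exercising the fallback
path, half have no OEL at all, exercising exclusion), a 10% chance of a
missing molecular weight, and independent per-class Bernoulli memberships
(default 0.15 per additive class ≈ 2–3 classes per substance, 0.05 per
alert class). Scenario generation selects substances without replacement
and draws target C/OEL ratios uniformly from [0, 1.5] — spanning safe and
risky situations — expressed in the unit of the substance's selected OEL.
All generation is `random.Random(seed)`-driven and byte-reproducible.

What this emulates: the combinatorial structure the engine cares about
(shared classes, alert hits, OEL gaps, unit variety). What it does not:
real co-occurrence correlations between substances (solvent and metal
clusters in real workplaces), realistic OEL magnitudes per substance
family, or curated class assignments. Passing tests therefore demonstrate
the algorithmic contract, not the toxicological accuracy of any particular
database fed to the tool.

The packaged case study (`case_study_fixture`) is a *reconstruction* of a
printing-workshop co-exposure to MEK, MIBK, toluene and trichloroethylene:
real CAS numbers and qualitatively correct class memberships, but
illustrative OELs and concentrations chosen so that each substance sits at
40% of its own limit — the configuration in which single-substance
screening is blind while the four shared additive classes each reach
HI = 160%, and the two alert classes (developmental damage: MEK + toluene;
carcinogenicity/mutagenicity: MIBK + trichloroethylene) fire. Its
`evidence_notes` say so.

## Numerical and design choices

- HI is reported uncapped at full precision in JSON; text rendering rounds
  to one decimal. Risky rows are marked; alert rows print "N.A.".
- Any scenario CAS absent from the database is an error listing the unknown
  numbers, rather than a silent drop — a typo must not shrink an index.
- A substance with no usable OEL is excluded from every HI sum with a
  prominent warning but still counts for class activation and alert
  findings: the qualitative information remains valid, and this keeps the
  activated-class sets of the two modes identical.
- Exit codes of the `analyze` CLI: 0 ran/no signal, 2 ran/risk signal (any
  HI > 100% or any alert finding), 1 error — distinct so shell pipelines
  can separate "found something" from "failed". Reports go to stdout,
  logging to stderr.
- Test and acceptance problem sizes (databases of 40–60 substances, 1,000
  random scenarios of ≤ 10 substances for the brute-force cross-check) are
  chosen as the smallest sizes at which every code path and invariant is
  exercised many times over; the whole suite runs in a few seconds.

## Known limitations

- No interaction modelling: supra-additivity (synergy, potentialization)
  and infra-additivity are real but rarely quantifiable pairwise; this tool
  deliberately stops at the additive default plus alert handling.
- No short-term (15 min) exposure assessment: ceiling/short-term values are
  used only as warned fallbacks for a missing 8 h OEL.
- The single-OEL-per-substance convention over-weights non-critical
  endpoints (see above).
- Highest-value selection among repeated measurements, sampling strategy,
  and biological/physical co-stressors (noise aside from the informational
  ototoxicity note) are out of scope.
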