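# hazmix

Additive Hazard Index screening for workers co-exposed to several airborne
chemicals.

## The problem

Occupational risk is usually screened one substance at a time: compare each
measured atmospheric concentration *C* with the substance's occupational
exposure limit (OEL) and flag exceedances. That misses mixtures. Several
solvents, each comfortably below its own limit, can attack the same target
organ — and a central-nervous-system depressant at 40% of its OEL next to
three others at 40% of theirs is not a safe workplace.

The screening convention recommended by ACGIH and the EPA is **additivity**:
for every *toxicological class* (a target organ or mode of action) shared by
the mixture components, sum the exposure ratios into a Hazard Index

```
HI = (C1/OEL1 + C2/OEL2 + ... + Cn/OELn) × 100
```

and call the class risky when HI strictly exceeds 100%. `hazmix` implements
this over a built-in taxonomy of 24 toxicological classes. Six classes —
carcinogenicity/mutagenicity, sensitization, endocrine disruption, male and
female reproductive toxicity, and developmental toxicity — are **alert
classes**: additivity is not a meaningful model there, so any exposure at
all raises a warning instead of an index (exposure to carcinogens is to be
minimized regardless of the limit). A **qualitative mode** covers the common
case where no measurements exist yet: it reports which classes are activated
and which are shared by two or more substances.

The package is aimed at industrial hygienists, occupational physicians and
prevention engineers who have an exposure inventory (with or without
measurements) and a substance/OEL database, and want a ranked, auditable
first-level diagnosis of mixture risk.

## Worked example

The packaged case study reconstructs a printing-workshop maintenance task
where methyl ethyl ketone (MEK), methyl isobutyl ketone (MIBK), toluene and
trichloroethylene occur together, each measured at 40% of its own OEL (the
OELs and concentrations are illustrative, not regulatory values):

```python
import hazmix as hx

db, scenario = hx.case_study_fixture()
report = hx.analyze_quantitative(scenario, db)
print(hx.render_report(report, "text"))
```

prints

```
Mixture analysis (quantitative mode, 4 substances)
==================================================

Alerts:
  [cmr_present] Carcinogenic and/or mutagenic substance(s) present. Additivity is not applicable: minimize exposure regardless of measured levels.
      substances: 108-10-1, 79-01-6
  [developmental_toxicant_present] Substance(s) presenting a risk to the development of the foetus, embryo and/or child present. Additivity is not applicable.
      substances: 78-93-3, 108-88-3
  [ototoxicant_present] Ototoxic substance(s) present: combined exposure with noise may aggravate hearing damage (informational).
      substances: 78-93-3, 108-10-1, 108-88-3, 79-01-6

Toxicological class                            HI %  Substances
Carcinogenicity and/or mutagenicity            N.A.  108-10-1, 79-01-6
Developmental damage                           N.A.  78-93-3, 108-88-3
Central nervous system damage                 160.0  108-10-1, 108-88-3, 78-93-3, 79-01-6  ** >100%
Ocular damage                                 160.0  108-10-1, 108-88-3, 78-93-3, 79-01-6  ** >100%
Ototoxicity                                   160.0  108-10-1, 108-88-3, 78-93-3, 79-01-6  ** >100%
Skin damage                                   160.0  108-10-1, 108-88-3, 78-93-3, 79-01-6  ** >100%

Multiple-exposure risk (any HI > 100%): YES
```

Reading it: no substance exceeds its own limit (every individual ratio is
40%), so single-substance screening sees nothing — yet the four classes all
four solvents share each sum to HI = 4 × 40 = 160%, a genuine
multiple-exposure risk. Alert classes head the table with "N.A." in place of
an index, and the two alert messages name the carcinogenic pair (MIBK,
trichloroethylene) and the developmental-toxicity pair (MEK, toluene).

The same analysis is available from the shell:

```sh
hazmix fixtures case-study --out cs/
hazmix analyze --db cs/database.json --scenario cs/scenario.json
```

`analyze` exits 0 when nothing is flagged, 2 when a risk signal is present
(some HI > 100% and/or alert classes activated), 1 on errors — so it can be
scripted over an inventory. `hazmix validate-db`, `hazmix taxonomy` and
`hazmix fixtures generate-db` round out the CLI.

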