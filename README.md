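# thyrostage

Anatomic-checklist notation, AJCC staging rule engine and understaging
audit for grossly invasive thyroid cancer.

## Why

When thyroid cancer grossly invades surrounding structures, accurate AJCC
(8th edition) staging depends on what the surgeon saw and did: cancer
dissected cleanly off the recurrent laryngeal nerve, the trachea or the
esophageal muscularis leaves no histologic trace, so a pathologist staging
from the specimen and a free-text operative note will systematically
understage the disease.  A surgeon-completed anatomic checklist fixes the
information handoff.  This package is the checklist as software, for
surgeons, pathologists and clinical-informatics teams:

- a **shorthand classification grammar** (`pT4a N1b Mx PE-E^0 Vas-V_IJ^1
  LT-T_2^0 N-RLN^1`) with a strict parser and a canonical formatter;
- a **staging rule engine** mapping recorded anatomy to AJCC T-category
  floors (muscle → T3b; laryngotracheal complex, pharyngoesophagus, RLN,
  bone → T4a; arterial encasement → T4b), with recurrent-disease handling
  (`Rec` prefix, no TNM) and an ATA risk-of-recurrence tier;
- a **cohort audit**: per-case accuracy verdicts, structure-omission
  tallies, and a first-principles two-tailed Fisher exact test, plus the
  35-case study cohort packaged as structured fixtures and a seeded
  synthetic-cohort generator.

In the notation, each token is `CATEGORY-SUBSITE^degree`: degree `0` means
the structure was involved but preserved in a tissue-sparing plane
(subepineural / subperichondrial / subperiosteal / subadventitial /
muscularis-only), degree `1` means it was resected.  Muscle involvement is
binary (no degree); `LT-T_2^0` means the perichondrium of two tracheal
rings.  `R1`/`R2` record microscopic/gross residual disease.  The
recommended T is `max(size-based T, anatomic floor)` under
`T0 < T1a < T1b < T2 < T3a < T3b < T4a < T4b`.

See `docs/methods.md` for the full rule table and the modeling decisions.

## Worked example

Parse, stage and report one case (the RLN-sacrifice + sternocleidomastoid
case of the packaged cohort):

```python
import thyrostage as ts

cohort = ts.load_paper_cohort()          # 35 cases: 29 primary, 6 recurrent
case = {c.record.case_id: c for c in cohort}["25"]

staged = ts.derive_stage(case.record)
print(staged.classification)             # -> pT4a N1b Mx N-RLN^1 M-SCM
print(staged.ror)                        # -> high
print([(rid, inv.token()) for rid, inv in staged.rule_trace])
#                                        -> [('R1', 'M-SCM'), ('R2', 'N-RLN^1')]

report = ts.audit_cohort(cohort)
print(report.arm_counts)
# {'checklist':    {'n': 15, 'accurate': 15, 'discrepant': 0},
#  'no_checklist': {'n': 14, 'accurate': 1,  'discrepant': 13}}
print(f"{report.fisher_p:.2e}")          # -> 2.06e-07
```

The staged classification reads: gross invasion floors the T category at
T4a (RLN sacrifice), nodal category N1b and unassessed distant metastasis
pass through, and the anatomic suffix records the sacrificed nerve and the
resected sternocleidomastoid.  The audit shows every checklist-accompanied
case accurately staged, 13 of 14 no-checklist reports understaged, and a
Fisher exact p far below 0.01 for the association.

The same is available from the shell:

```sh
thyrostage parse "R2 pT2 N1b Mx VAS-V_IJ/INN^1"
# R2 pT2 N1b Mx Vas-V_IJ^1 Vas-V_INN^1
thyrostage fixtures export cohort.csv
thyrostage audit cohort.csv --format text
# no checklist: 13/14 discrepant
# checklist: 15/15 accurate
# fisher_p: 2.0629520121260516e-07
thyrostage simulate --n 200 --seed 7 synthetic.csv
thyrostage schema                # JSON record schema
thyrostage rules                 # default floor-rule table (YAML, editable)
```

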