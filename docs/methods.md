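# Methods

## The problem being modeled

Grossly invasive thyroid cancer (visible extrathyroidal extension, ETE, or
extranodal extension, ENE, at surgery) is staged from intraoperative
findings as much as from specimen histology: cancer dissected cleanly off a
nerve or the trachea leaves no histologic trace, so a pathologist working
from the specimen alone will understage the disease.  The anatomic
checklist closes this gap.  `thyrostage` implements the checklist as
machine-readable data: a shorthand classification grammar, a rule engine
that derives the recommended AJCC category from the recorded anatomy, and a
cohort audit that quantifies understaging when the checklist is absent.

## The classification shorthand

A classification string is

```
["Rec"] [R1|R2] [pT<cat> [N<cat>] [M<cat>]] token ...
```

where each token is `CATEGORY-SUBSITE` with an optional `_` subscript and
`^` superscript.  Categories and subsites (fixed vocabulary):

| category | label                   | subsites                |
|----------|-------------------------|-------------------------|
| `LT`     | laryngotracheal complex | `Th`, `Cr`, `T`         |
| `B`      | bone                    | `Clav`, `St`            |
| `N`      | nerves                  | `RLN`, `SLN`, `Vag`     |
| `PE`     | pharyngoesophagus       | `Ph`, `E`               |
| `Vas`    | arteries and veins      | `A_CC`, `A_INN`, `V_IJ`, `V_INN` |
| `M`      | muscle                  | `SM`, `SCM`, `CT`       |

The superscript is the degree of invasion as resolved by surgery: `^0`
means the structure was preserved by dissection in a tissue-sparing plane
(subepineural, subperichondrial, subperiosteal, subadventitial, or
muscularis-only for the pharyngoesophagus); `^1` means the structure was
resected, producing a transmural/through defect.  Muscle involvement is
binary and never carries a superscript.  The subscript on `LT-T` counts
involved tracheal rings; the vessel "subscripts" (`_CC`, `_INN`, `_IJ`) are
part of the vessel name.

Design decisions in the grammar, made where source material is typeset
rather than machine-readable:

- **ASCII dialect.** `^`/`_` stand in for typographic super/subscripts so
  strings survive plain-text interchange (EHR paste, CSV columns).
- **Liberal input, single canonical output.** The parser accepts
  case-insensitive category/subsite codes (`VAS-`/`Vas-`), chained groups
  that inherit the category (`B-St^1 Clav^1`), concatenated groups inside a
  token (`LT-T_2^0Cr^0`), `/`-compression that distributes the category,
  the vessel letter and a shared trailing degree (`M-SM/CT`,
  `VAS-V_IJ/INN^1`), either order of `^`/`_` suffixes (`LT-T^0_2`), a TNM
  with missing N/M tokens (defaulting to `Nx`/`Mx`), and parenthesized
  English glosses (ignored).  The formatter emits exactly one spelling:
  `Rec`, then the residual code, then `pT.. N.. M..`, then one full token
  per subsite with categories in the order LT, B, N, PE, Vas, M and
  subsites in vocabulary order.  `format(parse(s)) == s` for canonical
  strings, and `parse(format(p)) == p` for every valid parsed value (tested
  on 10,000 random classifications).
- **No implicit degrees.** A degree-taking subsite without a superscript is
  a parse error, not an implicit `^0` — silence must not be readable as
  "structure preserved".
- **`Rec` excludes TNM.** AJCC categories are not defined for recurrent or
  persistent surgical disease; a `Rec` string carrying a `pT` token is a
  parse error, and the formatter refuses the combination.

Parse errors carry a stable code and the character offset of the offending
text.

## The staging rule engine

Gross invasion imposes a *floor* on the T category; the recommended T is
the maximum, under the strict order `T0 < T1a < T1b < T2 < T3a < T3b < T4a
< T4b` (TX incomparable), of the size/extent-based pathology T and the
highest floor fired by any involvement:

| rule | trigger                                        | effect |
|------|------------------------------------------------|--------|
| R1   | any muscle subsite (SM, SCM, CT)               | floor T3b |
| R2   | any LT, PE or bone subsite, or N-RLN (any degree) | floor T4a |
| R3   | carotid/innominate artery, degree 1 (encasement/transection) | floor T4b |
| R4   | carotid/innominate artery, degree 0 (subadventitial) | no floor; warning `arterial_involvement_review` |
| R5   | jugular/innominate vein, any degree            | no floor |
| R6   | SLN or vagus, any degree                       | no floor; warning `nerve_outside_rule_table` |

Decisions where the rule set was genuinely open:

- **Veins never modify T** (R5): the one cohort case with isolated
  jugular/innominate vein resection is recommended `pT2` — size-based — so a
  mediastinal-vessel T4b reading is rejected.
- **Subadventitial arterial dissection does not auto-floor T4b** (R4):
  AJCC T4b requires encasement, and no primary case arbitrates the degree-0
  situation; the engine warns and leaves the decision to a human.  The rule
  table is exportable/importable as YAML (`thyrostage rules`), so an
  institution that disagrees can override the floor without touching code.
- **Cricothyroid muscle floors T3b with the other neck muscles**, not T4a
  with the larynx (a combined strap/cricothyroid case is recommended T3b).
- **Epineural RLN dissection (degree 0) floors T4a** like sacrifice: the
  cohort's epineurium-only case is recommended pT4a.
- **SLN/vagus carry no floor** — no staging text or primary cohort case
  assigns one — but fire a review warning so they cannot pass silently.

N passes through from the record; M passes through except that known
distant metastasis forces M1.  If no size-based T is supplied the floor
alone is used; with neither, the result is TX plus a warning.  Recurrent or
persistent records produce no TNM: the output is `Rec` + suffix.

**Risk of recurrence** is implemented to the resolution the checklist can
feed: any recorded gross invasion, an R1/R2 residual code, or known distant
metastasis ⇒ *high*.  The checklist alone cannot separate low from
intermediate (that requires histologic vascular invasion, nodal burden and
mutational interpretation), so a case firing no high rule is reported as
*low* with an explicit `ror_incomplete_inputs` warning rather than a
guessed tier; recurrent disease is *not applicable*.

## The audit

A reported classification is **discrepant** with the recommendation iff it
understages T (strictly below under the T order), omits a recommended
R1/R2 residual code, or lacks a recommended involvement (subsite-level
match; a degree mismatch also counts).  A reported T *above* the
recommendation is not, by itself, a discrepancy — the failure mode under
audit is understaging — but such cases are caught through missing
residual/vessel tokens.  An explicit per-case *accuracy override* exists
for the situation where a correctly worded operative report conveyed the
finding without a checklist; the override case still counts in its arm's
denominator.  N0a/N0b are accepted as distinct categories but no accuracy
judgment distinguishes them from N0 (the audit never compares N).

Recurrent cases get no AJCC accuracy verdict; they are summarized by the
recommended items absent from their reports.

**Packaged cohort.** The 35 consecutive study cases (29 primary, 6
recurrent) ship as a checksummed JSON fixture holding, per case, the
surgeon, checklist flag, the printed reported stage and the recommended
classification string.  Two reconstruction choices were required because
the source tables print outcomes, not inputs:

1. *Size-based pathology T* is not printed anywhere; it is reconstructed as
   min(reported T, recommended T).  The recommended classification proves
   the size T cannot exceed it, and where no anatomic floor bound the stage
   the reported T *is* the size T (e.g. the vein-only case recommended
   pT2).  The golden suite then checks that the engine rebuilds every
   recommended T from these inputs — i.e. that the floors, not the answer,
   do the work.
2. For checklist-submitted cases the transmitted checklist is part of the
   final report, so the *effective* reported classification equals the
   recommended one; the bare printed TNM is retained as an annotation.
   Without this reading, a checklist case whose printed column shows only
   `pT4a N1a M1` would be scored as "missing involvements" — contradicting
   the study's own accuracy count.

**Structure tallies** count, per structure class (strap, cricothyroid,
SCM, RLN sacrifice vs epineurium, pharyngoesophagus, laryngotracheal, bone,
vessels, SLN/vagus), the cases whose recommended classification contains
the class but whose report does not.  The pharyngoesophageal count is
reported under both defensible conventions — case-level (7 on the packaged
cohort) and token-level (9) — because they genuinely differ; neither is
privileged.  The "Items not reported on" annotations are carried verbatim
but are non-authoritative (one case's annotation names a structure its own
recommended classification lacks).

**Fisher exact test** (two-tailed) is computed from first principles: with
all margins fixed, the p-value is the sum of hypergeometric probabilities
of every table no more probable than the observed one.  Numerical choices:
log-factorials (`lgamma`) for overflow safety; a relative tie tolerance of
1e-7 when comparing masses to the observed mass; exact 1.0 when every
admissible table qualifies; p = 1 by convention for degenerate margins.
The implementation is verified exhaustively against an exact
integer-arithmetic enumeration oracle on every 2×2 table with grand total
≤ 40, and against an independent statistics library on random tables.

## The synthetic cohort generator

The generator emulates the study's omission mechanism, not its biology.
Each case draws involvements independently per subsite, derives its true
recommended stage through the rule engine, then constructs the reported
classification: identical to the recommendation when a checklist is used
(probability `p_checklist`), otherwise each involvement is independently
dropped with probability `p_omit` — whole structures, matching the observed
missed items — and the reported T is re-derived from the survivors, which
is exactly how understaging arises.  Per-case substreams are derived from
the seed by counter, so cohorts are reproducible and order-independent.

Defaults are the study conditions: subsite prevalences are the cohort
frequencies over the 29 primary cases (e.g. RLN 13/29, strap 11/29,
esophagus 11/29), `p_checklist = 15/29`, and `p_omit = 0.9` (essentially no
involved structure reached a no-checklist final report; 0.9 leaves room for
the occasional operative-report rescue).  The degree-1 probability per
category and the size-based T distribution (`T1a` 0.1, `T1b` 0.2, `T2`
0.4, `T3a` 0.3) are rounded cohort frequencies.  Rare-in-cohort subsites
get a nominal prevalence of 0.01 rather than 0 so they remain reachable.

The no-checklist discrepancy rate has the closed form
`1 − Π_s (1 − prevalence_s · p_omit_s)`; the generator is checked against
it at n = 10,000 within three standard errors.

What the generator does **not** model — hence what passing tests do not
show about real data: correlated involvement patterns (RLN + esophagus
co-occur in real invasive disease), residual-disease and distant-metastasis
prevalence, recurrent cases, surgeon effects, and any pathologist behavior
beyond independent whole-structure omission.

## Problem sizes and determinism

All headline quantities are deterministic recomputations from the 35-case
packaged cohort and run in well under a second.  The property suites use
10,000 random classifications for the round-trip law, 300 random insertion
orders for floor monotonicity, exhaustive enumeration to grand total 40 for
the Fisher oracle, and a 10,000-case synthetic cohort for the convergence
check; the full suite runs in a few seconds on one CPU.

## Known limitations

- The minimum data set covers the textually specified fields (molecular
  testing, per-side vocal cord function, distant metastasis, residual code,
  disease status); form-only fields of the printed checklist are not
  guessed.
- AJCC prognostic stage *groups* (I–IV) are out of scope: they depend on
  age and histology, and the audit concerns T/N/M categories only.
  Likewise out of scope: nodal-burden sub-rules, histology-specific staging
  tables, and the full ATA low/intermediate rule set.
- Whether epineural RLN dissection should always imply T4a is an open
  clinical question; the engine follows the cohort's precedent, and the
  YAML rule override exists precisely so institutions can disagree.
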