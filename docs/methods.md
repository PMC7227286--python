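# Methods

This note documents the models, conventions and numerical choices behind
`burdenalign`, and what the synthetic-data tests do and do not demonstrate
about real bibliographic data.

## Disease typology

Diseases are classified by the ratio of burden per capita in low- and
middle-income countries to burden per capita in high-income countries,
using DALYs as the burden measure. Two choices deserve note:

- **LMIC pooling.** "Burden per capita in LMICs" is computed as a single
  pooled rate — summed DALYs of the UMIC, LoMIC and LIC groups divided by
  their summed population — not as an average of the three group rates.
  The pooled rate is population-weighted and is the natural reading of a
  per-capita rate over a merged population; the choice is recorded in each
  run's metadata (`lmic_pooling`).
- **Boundary convention.** Bins are closed below and open above: a ratio
  of exactly 0.75 is type 1b, 3.00 is type 2, 35.0 is type 3. A disease
  with zero HIC burden but positive LMIC burden has ratio +inf and is type
  3; a disease with zero burden everywhere has an undefined ratio and is
  excluded from typing with a warning rather than silently assigned.

The four cut-points (0.75, 1.25, 3.00, 35.0) are configurable
(`TypeThresholds`) for sensitivity analysis but default to the canonical
values.

## Counting conventions

- **Fractional country counting** is per author-affiliation instance: with
  n instances each carries 1/n, aggregated by country and then by income
  group. Per-author versus per-address counting is indistinguishable when
  only an address list is available; the per-instance rule degrades
  gracefully and conserves exactly one unit of credit per publication.
- **Disease counting** defaults to `fractional` (a record matching k
  diseases gives each 1/k), so type shares are additive and sum to 100%.
  The `full` policy (each matched disease gets 1) is available for
  whole-count analyses; totals must then be normalised by assignments, not
  records.
- **Unknown countries** either raise (default) or are routed to an
  excluded, logged "unclassified" bucket; in the latter case a record can
  contribute less than one unit to income-group aggregates, and group
  conservation holds only over classified weight.
- **Pharma matching** normalises case and strips punctuation, then tests
  alias substrings; there is no fuzzy matching, so results are
  deterministic and auditable. A consequence of plain substring matching
  is that place names containing a company alias (e.g. "La Roche-sur-Yon")
  match; curated alias lists should avoid over-general aliases. Pre-set
  boolean flags bypass matching entirely.

## Journal quartiles

Within each subject category and year, journals are ranked by descending
impact factor; a journal whose best rank r among N satisfies r/N ≤ 0.25 is
Q1, ≤ 0.5 Q2, ≤ 0.75 Q3, else Q4. Tied impact factors all take the best
quartile of their tied block, and a single-journal category is Q1 (the
journal is the top of its own category). A journal indexed in several
categories takes its best quartile across them. Records published in a
year missing from the journal table fall back to the journal's nearest
available edition (logged); records whose journal is absent altogether are
excluded from Q1 denominators but retained for share analyses.

## Citation normalisation

Citation indicators are normalised by subject category (field) and
publication year against a reference corpus — by default the full analysed
corpus itself, supplied explicitly so a broader reference set can be used.
Subset analyses never recompute baselines; domestic, international and
pharma subsets are always scored against the full-corpus baselines.

- **MNCS**: per record, citations divided by the field-year mean, averaged
  with equal weight over the journal's categories; the aggregate value is
  the weighted mean of record scores. Over a reference corpus whose
  journals have a single category the corpus-wide MNCS is identically 1.
  Degenerate case: a field-year whose mean is zero scores an uncited
  record 1.0 (it sits exactly at the field mean); a cited record in such a
  field-year is an error, since the reference set cannot contain it.
- **PPtop10%**: the field-year threshold t is the smallest observed
  citation value with #(citations > t) ≤ 0.1·n; records above t count 1,
  records at t count the tie fraction (0.1·n − #above)/#tied, others 0.
  Tie-fractionalisation makes the worldwide value exactly 10% regardless
  of the citation distribution's discreteness.

## Synthetic worlds

The generator produces the full input suite — countries with income
groups and populations, a 134-disease registry with synthetic MeSH
descriptors, a DALY table, a journal table, and a publication corpus —
from two seeded configurations.

**World.** Each disease samples a target burden ratio log-uniformly inside
its intended type's bin (bounds are validated to nest inside the bin, so
classification recovers the intended type by construction) and a total
world burden log-uniformly over 10^6–10^8 DALYs, independent of type, so
type-level DALY shares track the type sizes (34/28/26/22/24 diseases).
The HIC/LMIC split is then solved exactly from the target ratio, and the
LMIC pool is divided among UMIC/LoMIC/LIC proportionally to population
with random perturbation (which cannot move the pooled ratio). Default
populations put ~16.5% of people in HICs.

**Corpus.** Each record draws a lead income group (defaults: HIC 79%,
UMIC 17%, LoMIC 3.4%, LIC 0.6%), a disease type from the lead group's
specialisation row (HIC row skewed to type 1a), a disease uniformly within
type, and a year uniformly in 2010–2014. With the lead group's
collaboration rate (defaults 0.20 for HIC/UMIC/LoMIC, 0.75 for LIC) the
record is international: one lead-country and one partner-country
affiliation (equal split), the partner group drawn from the output mix of
the remaining groups; otherwise 1–3 domestic instances. Citations are
negative binomial with mean `base_mean[year] × type_effect × group_effect`
(type effects 1.2 → 0.8 from 1a to 3, dispersion 1.2) — an overdispersed
integer model with realistic zero inflation. Journals are drawn Q1-or-not
by a per-type propensity (nearly flat, 0.25–0.30); pharma authorship and
funding are independent Bernoulli flags declining from type 1a to type 3.
A small fraction (5%) of records are non-article/review documents to
exercise the corpus filter.

**Ground truth.** Because collaboration redistributes fractional weight
across groups, the recorded ground truth carries the *analytical
expectations* of the pipeline's estimators — expected type×group cell
shares, expected per-group international weight fractions, and expected
per-type normalised citation scores (the lead cell's effect relative to
the corpus-mean effect; exact because type, field and year are sampled
independently and base means cancel in the normalisation). Recovery tests
compare estimates to these expectations within three standard errors at
20,000 publications.

**What the synthetic tests do not show.** The generator has no MeSH
semantics (descriptors are opaque, disjoint by default), no skew of
particular countries within a group (real HIC output is dominated by the
US, UMIC by China), no journal-field citation differences unless
configured, no citation dependence on collaboration or journal quartile,
and no text realism in affiliations beyond alias-matchable tokens.
Passing recovery tests therefore demonstrates the correctness of the
counting and normalisation machinery, not the empirical magnitudes of any
real corpus.

## Problem sizes and numerics

The test suite runs worlds of 134 diseases and corpora of 2,000–20,000
records; 20,000 is ample for three-standard-error recovery of shares down
to ~0.5% and keeps the full suite in a few seconds. Shares are compared
to 1 within 1e-9; per-record weight conservation within 1e-12; the MNCS
and PPtop10% worldwide identities within 1e-9. Quartile ties are broken
by journal id only for output ordering, never for quartile assignment
(tied blocks share a quartile). All randomness flows through
`numpy.random.default_rng` seeded from the configuration, making every
world, corpus and pipeline run bit-reproducible.

## Known limitations

- The ICD-10↔MeSH concordance is consumed as data, never constructed;
  descriptor matching is by identifier, with no MeSH-tree explosion.
- Citation counts are taken as given (a fixed collection-time snapshot);
  no citation-window modelling is attempted.
- Multi-category journals average normalised scores with equal category
  weights; fractional field assignment by publication volume is not
  implemented.
- The `full` disease-counting policy is provided but all shipped tables
  use the fractional default.
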