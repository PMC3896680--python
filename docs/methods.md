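# Methods

## The DCV model

A discriminant content validity (DCV) exercise asks `n` judges to allocate
each questionnaire item to up to three domains of a behavioral-determinant
framework, rating each allocation's confidence `c ∈ [0, 1]` (collected as
0–100% and normalized on read). For a target domain `d`, each allocation is
scored `+c` if it names `d` and `−c` otherwise; a judge's score for an
(item, `d`) pair is the sum over their allocations of that item, and a
judge with no allocation scores 0. Since the up-to-three domains must be
distinct, at most one allocation can match the target, bounding per-judge
scores in `[−3, +1]` (and in `[−1, +1]` when judges make single
allocations).

For every item the tested domains are its intended domain(s) plus every
*co-allocated* domain — a non-intended domain named by at least
`min_coalloc_judges` distinct judges (default 2, i.e. "more than one
judge", counting any of the three ranks). Each (item, domain) pair gets an
upper-tailed one-sample t-test of mean score > 0 over all enrolled judges
(sample sd, `df = n − 1`); `n` is constant across tests because missing
allocations score 0. p-values are corrected by the Benjamini–Hochberg
step-up across all tests of the run (configurable to per-item families, or
off). Zero-variance samples use the conventions p = 0 / 1 / 0.5 for
positive / negative / zero mean; they occur in perfect-agreement data.

The inclusion taxonomy is then:

- **pure_intended** — some intended-domain test rejected with positive
  mean, no co-allocated domains, no other test rejected; only these items
  enter the final questionnaire;
- **misclassified** — some non-intended test rejected with positive mean;
- **mixed** — co-allocated domains exist (and the item is not
  misclassified);
- **unclassified** — none of the above.

Only positive means classify: the hypothesis is directional, so a strongly
negative mean on a domain is evidence of *non*-membership and carries no
inclusion weight of its own; the misclassification signal lives in the
positive test on the other domain.

## Agreement

Cohen's kappa `κ = (p_o − p_e)/(1 − p_e)` uses pairwise-complete deletion
and empirical marginal products for `p_e`; the degenerate case `p_e = 1`
(both raters constant) returns 1 for perfect observed agreement and 0
otherwise, so perfect-agreement fixtures do not fault. Light's kappa is the
unweighted mean of Cohen's kappa over all rater pairs; overall agreement
uses judges' first-choice labels (judges treat the first-named domain as
their preferred one), per-domain agreement uses binary
selected/not-selected matrices over any rank (configurable to first-choice
only). Judges who never selected a domain can be excluded from that
domain's coefficient — their all-zero columns say nothing about how the
domain is used — and are reported. Confidence intervals are percentile
bootstrap over items (default 1000 resamples, seeded); items, not judges,
are the sampling units of a DCV study, and the CI method is recorded in
the result metadata because no canonical method exists for Light's kappa.

## Synthetic data generator

Each synthetic item carries a *semantic profile*: a distribution over
domains describing where judges perceive its meaning. A judge's first
allocation is drawn from the profile composed with a row-stochastic
domain-confusion matrix (identity by default, separating item ambiguity
from judge fallibility). With probability `p_second` (then `p_third`) the
judge draws again from the same distribution; under the default
`extra_policy="skip"` a duplicate draw adds nothing — a judge writes a
second domain only when a distinct one comes to mind — so extra
allocations are naturally rare for pure items and frequent for mixed ones,
as in real data. Under `extra_policy="resample"` a distinct domain is
forced and the expected allocations per judge×item equal
`1 + p2 + p2·p3` exactly; under "skip" that value is an upper bound.
Confidences are Beta-distributed with a given mean and concentration
(defaults 0.7 and 10 — confident-but-fallible experts), optionally decaying
by rank, and rescaled so a judge's confidences for one item sum to at most
1 (switchable, to probe the unconstrained reading). A single integer seed
drives one root generator.

The reference scenario mirrors the dimensions of the published study the
packaged item bank comes from: 19 judges, 79 items, 14 domains — 60 pure
items (profile mass 0.9 on the intended domain, remainder spread evenly),
15 two-domain mixed items (0.45/0.45), 4 misdesigned items (mass 0.9 on a
non-intended domain), `p_second = 0.5`, `p_third = 0.15`. A uniform-profile
null scenario provides a type-I-style control.

What the generator does *not* emulate: semantic adjacency (real
misallocations concentrate on related domains rather than spreading
evenly), per-judge bias and expertise heterogeneity, and correlation of
confidence with correctness. Passing recovery tests therefore shows the
pipeline recovers designed structure under exchangeable, symmetric noise —
not that it is robust to structured rater bias.

### A known ceiling on pure-item recovery

With 19 judges, purity 0.9 and `p_second = 0.5`, a designed-pure item
accrues on average ~1.9 first-choice misallocations plus ~0.9 kept extra
allocations, spread over the 13 non-intended domains. The chance that no
single domain is named by two or more judges — the co-allocation trigger —
is then only ≈ 0.77 (a multinomial collision bound), so roughly a fifth to
a quarter of designed-pure items are demoted to *mixed* by scattered noise
alone; across seeds the recovered-pure fraction averages ≈ 75%. This is a
property of the study conditions, not an estimator defect: lowering
`p_second`, raising purity, or raising the co-allocation threshold all
lift the ceiling.

## Item bank and TACT templating

The packaged bank holds the 79 screened items (unique ids; the four Action
planning items are single items intended for both Goals and Behavioral
regulation), with English text throughout and Dutch text for the 32 final
items — no Dutch text is fabricated for screened-out items. Placeholders
form a small grammar: a bracketed group of comma-separated tokens, each
resolving to one of `A` (action), `C` (context), `T` (time), `Ta`
(target), `innovation`, `profession`; composite groups like `[C, T]`
render comma-joined, Dutch surface forms (`[innovatie/richtlijn]`,
`[beroep]`) alias the same keys, and a sentence-initial capitalized token
re-capitalizes its replacement. Rendering is idempotent on
placeholder-free text and never leaves a grammar-conforming token behind.

## Numerical and design choices

- Confidence is stored as a fraction; file values above 1 are percent.
  Whether judges' per-item confidences were constrained to sum to 1 is not
  knowable from the study design, so the reader accepts any value and the
  generator's rescaling is switchable.
- BH ties break by stable sort on original index. The statsmodels step-up
  implementation is used, verified in the tests against an exhaustive
  search over rejection counts.
- The FDR family defaults to all tests of a run; the published analysis
  only states that multiple tests were corrected, and the global family is
  the conservative, reproducible choice.
- The packaged study-results fixture transcribes printed per-item outcomes
  (means, t values, significance and co-allocation markers). The raw judge
  data were never deposited, so the printed means, t values and kappas are
  not recomputable; the fixture supports exact replay of the inclusion
  partition, and internal consistency is checked by back-solving the sd
  implied by a printed mean/t pair (mean .88, t 17.58, n 19 ⇒ sd ≈ .218)
  and reproducing the t exactly from any vector with those moments.
- Report writing is deterministic: identical inputs and seed give
  byte-identical files (no timestamps; a config hash records the run).

## Problem sizes used in the test suite

Kernel oracles run on 1000 random score vectors (t-test), all p-vectors of
length ≤ 4 over a 5-value grid plus 200 random vectors (BH), and 200
simulated 79×19 null matrices (agreement). Recovery tests use one seeded
run of the 19×79 reference scenario and 20 seeded uniform-null runs —
sizes chosen to match the study design the package models.

## Limitations

- Light's kappa inherits Cohen's prevalence sensitivity; near-empty
  domains yield unstable per-domain coefficients even with rater
  exclusion.
- The bootstrap CI treats items as exchangeable; clustered item families
  (e.g. rephrasings of one construct) violate that and narrow the CI
  optimistically.
- The inclusion rule is binary and threshold-based; items just under the
  co-allocation threshold are labeled pure with no strength-of-evidence
  shading beyond the reported test table.
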