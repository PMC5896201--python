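# Methods

## Overview

`clonalhsc` analyses single-cell transplantation assays of the mouse
phenotypic HSC compartment. Each datum is one clone: a single CD34⁻KSL
cell (sorted fraction F1/F2/F3, young or aged donor) transplanted with
competitor marrow into an irradiated recipient, with donor chimerism of
five peripheral-blood lineages (nm, E, P, B, T) measured at weeks 2, 3, 4,
8, (12), 16, (20), 24, and optionally 1–5 secondary recipients bled at
weeks 4, 12, 16, 20, (21–22). The pipeline has three stages — chimerism,
classification, compartment estimation — plus a synthetic-cohort generator
that makes all three testable without animal data.

## Chimerism and detection limits

Chimerism is `100 · donor_events / total_events` within a lineage gate.
Gates are finite (leukocyte lineages 30,000–50,000 events, platelets
20,000–50,000, erythrocytes 500,000), so the smallest representable signal
depends on gate size: at the 0.005% reconstitution threshold a
30,000-event gate corresponds to 1.5 events. `detection_floor` exposes
this arithmetic; the classifier can therefore require a minimum donor
event count (default 2) behind any positive call, applied only when raw
counts accompany the percentages. Missing (week, lineage) cells are
treated as unobserved, never as zero — weeks 12 and 20 are optional in the
primary schedule and no rule requires them.

## Classification

With threshold τ (percent chimerism; default 0.005, alternative 0.1):

* **Lineage positivity.** A lineage is reconstituted if it has at least
  `min_positive_timepoints` (default 1) observed weeks at ≥ τ, each backed
  by ≥ `min_donor_events` donor events when counts exist.
* **Duration.** `none` if no lineage is positive. `ST` if no lineage is
  ≥ τ at the terminal primary week (24). Otherwise `LT` if any linked
  secondary recipient shows any lineage ≥ τ at a week ≥ 16, else `IT`.
  Clones positive at week 24 but lacking any secondary assay cannot be
  resolved between LT and IT; they are reported IT with an
  `LT/IT-unresolved` flag rather than dropped, since secondary
  transplantation is not feasible for every primary recipient. A clone
  whose terminal week is unobserved (and is not death-censored) is treated
  as not positive there, i.e. ST.
* **Cell type.** Empty set → non-reconstituting. The myeloid-restricted
  chain is strictly nested — {P} → Mk, {P,E} → ME, {P,E,nm} → CM — with
  suffix RP (ST) or SC (IT/LT). HSC requires nm+E+P plus at least one of
  B/T; a strict all-five switch (`hsc_requires_all_five`) is provided
  because the literature is not explicit on whether one lymphoid lineage
  suffices, and B-or-T acquisition is elsewhere treated as multipotency
  evidence — that is the default's rationale. Anything else ({nm} alone,
  {E} alone, {P,nm} without E, any lymphoid-containing non-HSC set) is
  "other": only the Mk ⊂ ME ⊂ CM chain has named classes.
* **Latent-HSC.** A clone whose primary lineage set is a non-empty subset
  of {nm,E,P}, persists at the terminal week (duration IT/LT), and whose
  union of secondary lineage sets contains B or T is relabelled
  latent-HSC. The latent call takes precedence over the MySC label, so no
  clone is counted twice.
* **Censoring.** Recipients flagged dead (non-null `censored_week`) are
  excluded before classification and never appear in downstream counts.

Classification is order-invariant and deterministic; output rows are
sorted by clone id. A vectorised cohort path and a readable per-series
path coexist and are pinned to each other (and to an independent
brute-force enumeration) by tests.

## Compartment estimation

For age group g with compartment size `N` (pHSC per 10⁶ BM cells) and
fraction shares `s_f`:

* per-fraction composition `p_{t|f} = n_{t,f} / n_f` over the full
  15-label taxonomy (zero counts kept);
* absolute frequency `F_t = N · Σ_f s_f · p_{t|f}`, within-compartment
  share `π_t = F_t / (N · Σ_f s_f)`;
* conservation `Σ_t F_t = N · Σ_f s_f` holds exactly, and `F_t` equals the
  per-clone weight sum in which each clone contributes `N · s_f / n_f`.

Unfractionated transplants carry no `s_f` and are excluded from frequency
estimation (kept for composition-only summaries). Fractions with share
zero are ignored; a weighted fraction with zero assayed clones is an
error, not a silent zero.

**Bootstrap.** Clones are exchangeable within a fraction, so resampling
clones with replacement is a multinomial draw of the count vector;
per replicate `F_t` is recomputed and the central 95% percentile interval
reported (default B = 1000, seeded). Fractions with fewer than two clones
flag the interval unreliable. **Fold changes** are aged/young rounded
half-away-from-zero to one decimal, `n/a` when the young frequency is
zero; this rounding convention is what reproduces the published per-row
folds. Four published IT-row folds (IT-HSC 9.0, IT-CMSC 19.7, IT-MESC
27.8, IT-MkSC 17.1) are not reproducible from their own printed frequency
pairs (they presumably derive from unrounded values); the package computes
8.9, 20.1, 30.3 and 17.0 for them and they are not used as checks.
**Composition test.** A single pre-specified Pearson chi-square on the
young-vs-aged count vectors (categories empty in both groups dropped,
df = k − 1, no continuity correction, no multiplicity adjustment).

## Synthetic cohorts

What the generator emulates: the sampling design above. Each archetype
(one per taxonomy label) specifies per-lineage kinetics — zero before an
onset week, saturating rise `plateau · (1 − e^{−r(w−onset)})`, optional
exponential decay past a start week — a secondary-engraftment probability
and a secondary lineage profile. Onsets follow hematopoietic recovery
order (P, nm week 2; E week 3; B week 4; T week 8). Short-term archetypes
decay below 0.005% well before week 24; the latent archetype has myeloid
primary plateaus and five-lineage secondary plateaus. A single per-clone
log-normal factor (σ = 0.5 on the log scale) jitters all plateaus,
reproducing wide clone-to-clone spread while keeping lineages coherent;
the value is a calibration choice, as per-clone variance is not published.
Observed counts are `Binomial(gate, true/100)` with gate sizes uniform in
the stated ranges (erythrocytes fixed at 500,000). Recipients die with
probability 30/451 at a week uniform over the non-terminal schedule;
observations after the death week are dropped and the clone censored.
1–5 secondaries are drawn uniformly for engrafting archetypes.

The `paper_scenarios()` presets set `N` to the published compartment
totals (young 67.3, aged 725.1 per 10⁶ BM cells; a 10.8-fold expansion)
and use the published marginal composition as the archetype mixture,
identically in all three fractions, so expected per-10⁶-BM frequencies
equal the published values by construction. Fraction shares (young
F1/F2/F3 = 0.45/0.03/0.52; aged 0.25/0.60/0.15) reflect the described
~20-fold rise of the F2 share with age and sum to 1 (the small
CD150⁻CD41⁺ quadrant is neglected).

Deliberate simplifications — hence what passing tests do *not* show about
real data:

* no per-fraction enrichment (real latent-HSCs were found only in aged F2;
  real HSCs concentrate in F1) — estimates are exercised under
  fraction-homogeneous truth;
* IT archetypes always receive a secondary assay with sub-threshold
  output, and LT/latent archetypes engraft secondaries with probability 1,
  so duration is recoverable by design; real assays leave many clones
  LT/IT-unresolved;
* archetype plateaus are well-separated from the threshold (≥ 10× τ), so
  the ≥ 95% label-recovery result measures pipeline correctness under the
  stated design, not classifier performance on marginal clones;
* no mechanistic model of HSC division, aging or the myeloid-bypass route;
  no bone-marrow progenitor-compartment chimerism.

## Numerical choices and degenerate inputs

Fold rounding is decimal (half away from zero), not binary, to avoid
0.5-ulp artifacts. Bootstrap and cohort generation draw from a single
seeded `numpy` Generator (bit-reproducible per seed). Degenerate
compositions (one type with p = 1) give zero-width intervals at
`N · Σ s_f`. Gate percentages are validated into [0, 100]; counts must
satisfy 0 ≤ donor ≤ total, total ≥ 1. When counts and a percent column
disagree beyond 1e-6, counts win with a warning (counts carry the
information the minimum-event rule needs). Duplicate
(recipient, week, lineage) keys, unknown lineage codes, secondary series
without a linked primary, and unflagged clones with zero observations are
hard errors.

## Problem sizes

Default validation runs use 2,000 clones per age preset for label recovery
and parameter recovery, 200 cohorts of 300 clones (B = 200) for bootstrap
coverage — evaluated for cell types holding ≥ 5% of the compartment, since
rarer types yield degenerate zero-count intervals that measure
discreteness rather than calibration — and 100 random small instances for
estimator–oracle equivalence. The acceptance recomputation
(`scripts/acceptance.py`) simulates 20,000 clones per age so that
Monte-Carlo error on the rarer per-million frequencies is a few percent.
The full suite runs in about a minute on one CPU.

## Known limitations

The estimator treats fraction shares and compartment size as fixed inputs
(their flow-cytometry measurement error is not propagated). The bootstrap
is percentile-based and within-fraction only. The ST/IT/LT boundary
follows the standard criteria (terminal-week positivity; secondary
engraftment at ≥ week 16) but is configurable, because published
descriptions of the exact boundary vary; all thresholds in
`ClassificationCriteria` can be overridden via config or CLI flags.
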