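# Methods

## Data model

A `Microdata` table is an ordered list of records under an
`AttributeSchema` that assigns each attribute a disclosure role —
`identifier`, `quasi_identifier`, `sensitive`, `other` — and a value kind
(`text`, `date`, `integer`, `category`). Tables round-trip through
RFC 4180 CSV (UTF-8, empty field = missing, dates as ISO-8601 text).
Record ids come from a declared id column or, failing that, the zero-based
row index as `r{n}`, so parsing is deterministic and file-order stable.

## k-l-anonymity

For a dataset `D`, a string field, and a threshold `l`, each record's
anonymity level is

    k(r) = 1 + |{ x ≠ r : dist(value(r), value(x)) ≤ l }|

with `dist` the Levenshtein distance on Unicode code points. Conventions
that matter:

* `k` counts the record itself, so `k = 1` means "uniquely identifiable";
  two records with identical values are each other's neighbors at any `l`.
  This is the only reading under which `l = 0` reduces exactly to classic
  k-anonymity (per-record `k` equals the exact-match equivalence-class
  size), and that reduction is asserted in the tests.
* The dataset-level predicate `satisfies_kl(D, field, k, l)` quantifies
  universally: it holds iff every record has at least `k − 1` neighbors
  within `l`. Per-record risk is exposed separately through the profile
  and its histogram (`unique_fraction`, `frac_at_most(m)`).
* `k(r)` is non-decreasing in `l` and the unique fraction non-increasing;
  histogram counts always sum to `n`.

Strings are normalized before comparison (case-fold, strip
apostrophes/hyphens/periods, collapse whitespace) by default; the policy
is configurable, including "none", because distance-on-raw vs
distance-on-cleaned names is a genuinely open choice and punctuation
variation is rarely the error process of interest.

Identifier granularity is the caller's choice: reports can profile a
concatenated `full_name` or a single name field (`first`). Both modes are
first-class, since which one a given directory analysis wants is
scenario-dependent.

### Computation

Distances are computed by `edlib` (Myers bit-vector, banded by the
threshold) over *unique* field values with their multiplicities; candidate
pairs are pruned by the length lower bound `|len(a) − len(b)| ≤ l`. A risk
sweep over several thresholds evaluates each unique pair once at the
largest threshold and accumulates per-distance neighbor counts, so
`risk_sweep(md, f, [0..4])` costs one pass. Correctness is defined
extensionally — equality with an O(n²) full dynamic-programming scan —
and the test suite checks it against an independently written
Wagner–Fischer oracle on 500-record phonebooks for `l = 0..4`, plus
randomized metric-axiom checks (symmetry, identity, triangle inequality,
length lower bound).

## Approximate-knowledge adversary

The simulator models an attacker who knows a target's identifying string
up to `e` edit errors and retrieves every record within radius `l`.
`perturb` applies `e` uniform random edits (operation uniform over
insert/delete/substitute, position uniform, characters uniform over
`a–z`) and rejection-resamples until the full distance computation
confirms the result is at distance *exactly* `e`; this exact-distance
semantics makes the guarantee `e ≤ l ⇒ target ∈ candidates` a theorem
(triangle inequality) rather than a tendency, and the tests assert
recovery rate exactly 1.0 there. A substitution-only error model is
available as a flag. Bounded rejection (10,000 draws) turns the
pathological cases — e.g. positive `e` from an empty string under
substitutions only — into errors.

`recovery_experiment` samples targets uniformly with replacement (simplest
unbiased estimator), derives one sub-seed per trial from the experiment
seed, and aggregates hit rate and the candidate-set-size distribution.
Candidate lists are ordered by distance to the corrupted string, then
record id, for deterministic reports. On small fixtures the Monte-Carlo
estimates are checked against exhaustive enumeration of the single-edit
outcome distribution.

## Profile linkage

Attribution → inference → aggregation:

* **Inference** is rule-based only: configurable free-text substring rules
  (defaults: "my husband" ⇒ gender female, "my wife" ⇒ gender male) plus
  birthdate → age at a reference date. Derived values never overwrite
  explicitly present ones.
* **Strong evidence** is an exact match, after normalization (emails and
  usernames case-folded, phones reduced to digits), on an
  identifier-class attribute group: email, phone, username. Phone-like
  columns (`phone`, `cell_phone`, `home_phone`) are pooled, since sources
  disagree about which number they store.
* **Weak evidence** is quasi-identifier consistency: equal gender, equal
  normalized location (case-fold, strip punctuation; no gazetteer), and
  age/birthdate agreement within a slack (default ±1 year — profile ages
  are self-reported at unknown dates). Missing attributes contribute
  nothing; disagreements contribute nothing at link time and resurface as
  conflicts at merge time.
* **Confidence** is noisy-or, `1 − Π(1 − wᵢ)`: evidences act as
  independent imperfect witnesses. Default weights — email 0.95, phone
  0.95, username 0.70, weak 0.30, threshold 0.50 — encode the ranking
  "email/phone ≈ unique, username relatively unique, consistency checks
  corroborative". They are configuration, not estimates.
* **Aggregation** takes connected components of the link graph at the
  threshold (transitive closure: dossiers chain through pairwise
  identifiers). Components partition the profiles at every threshold, and
  raising the threshold only refines the partition. Merged attributes
  carry per-source provenance; email and username are treated as
  multi-valued, other attributes take the highest-priority source's value
  with differing values recorded as conflicts.

### Small-town weighting

Weak evidence optionally sharpens against a reference population: the
weight of a weak-evidence set is divided by the number of residents
matching the *conjunction of whatever matched* (for ages, counted over
the inclusive span of the two compared ages, which is symmetric in the
pair and covers both candidates of any cross-person match). Agreement on
a combination unique in town keeps full weight; agreement every tenth
resident satisfies decays tenfold. This is what makes "same gender, same
small town, consistent age" meaningful corroboration in a 15k-person town
and noise in a metropolis. With it enabled, clean multi-source profiles
are linked at pairwise precision = recall = 1.0 against ground truth, and
under username typos weak evidence strictly lifts recall over
strong-evidence-only matching — both asserted in the tests. Without a
reference population, weak-only pairs that clear the threshold (e.g.
three coincidental agreements: `1 − 0.7³ ≈ 0.66`) will over-merge in
populations with few locations; measured precision is then a property of
the configuration, which is the point of exposing it.

## Synthetic data

The generator emulates the material a real adversary collects, not any
real population:

* **Names** are drawn from bundled lexicons (~220 first names, ~250
  surnames, plus a street list) with rank-frequency weights
  `P(rank r) ∝ 1/r^s`, default `s = 1` — a heavy head of very common
  names and a tail of rarer ones. Users may supply their own lexicons.
* **Demographics**: gender balanced; birthdates uniform over 1931–1993
  (adults at the 2011-11-24 default reference date); locations assigned
  proportionally to configured sizes (default: a college town of ~38k
  plus four satellite localities); phone numbers and addresses synthetic
  but well-formed.
* **Phonebook**: a uniform subsample of round(coverage · n) records,
  round-half-to-even, default coverage 0.64.
* **Profiles**: per-source attribute subsets with independent per-attribute
  disclosure probabilities; typos are single edits (distance exactly 1,
  composable with the adversary's exact-distance semantics) applied per
  disclosed field at the configured rate; usernames derive from the
  person's name plus a two-digit tag, are globally unique (registration
  systems enforce that), and are reused across sources with the configured
  probability. Every generated profile is entered in the returned identity
  map.
* Everything is deterministic given (config, seed).

### What the generator does not emulate

Real name distributions have a vastly larger support: a real 24k-entry
directory contains thousands of distinct first names, many of them
near-unique. With a few-hundred-entry lexicon, *no* first name is unique
at that scale, so the first-name unique fraction is 0 in the
phonebook-scale demonstration and the risk sweep's content there is
conservation and monotonicity, not the level. Full names (≈10⁴ distinct
combinations) do show graded uniqueness and carry the level signal at
that scale. Likewise the generator has no household structure beyond a
spouse field, no name–gender or name–age correlation, and no demographic
fidelity; passing tests show the metrics and pipelines behave correctly
under the stated model, not that any particular real population is safe
or at risk.

## Problem sizes and numerical choices

The test suite and the acceptance script size their experiments to keep
full runs fast while leaving no code path unexercised: oracle-equivalence
on twenty 500-record phonebooks; 10,000-triple metric-axiom checks;
10,000 adversary trials across (e, l) settings and a 4,000-trial
comparison against exhaustive enumeration on a 20-name fixture; linkage
ground truth on a 200-person, two-source world (profile scoring is
all-pairs O(P²), so linkage experiments stay in the hundreds of profiles);
and one phonebook-scale (25,000-entry) risk sweep. The acceptance script
additionally emulates the full study shape: population 38,123, coverage
0.64, phonebook 24,399.

Ties and degenerate inputs: empty strings are valid values (distance =
length of the other string); missing values index as empty strings;
duplicate `l` values in a sweep are deduplicated; `satisfies_kl` with
`k = 1` is vacuously true; histograms of empty profiles, uniqueness of
empty datasets, and attacks on empty datasets are errors, not silent
zeros. Seeds are plain integers; every derived sub-seed stays below 2³¹.
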