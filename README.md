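# privrisk

Re-identification risk assessment for person-level microdata.

De-identified health records are routinely published for secondary use, and
the standard worry is an adversary who joins them with external sources —
phonebooks, voter rolls, online social-network profiles. `privrisk` measures
how exposed a population is to two attack families that classic k-anonymity
does not cover:

1. **Adversaries with approximate knowledge.** An attacker who overhears or
   misreads a patient's name knows it only up to a few spelling errors, yet
   can often correct those errors against a public directory. The toolkit
   measures this with *k-l-anonymity*: a dataset `D` with distance function
   `dist` satisfies k-l-anonymity when for every record `r` there exist
   `k − 1` other records `r_x` with `dist(r, r_x) ≤ l`. With Levenshtein
   (edit) distance and `l = 0` this is exactly classic k-anonymity; for
   `l > 0` it asks how many people are confusable with you under `l`
   spelling errors. Per-record `k` values, their histogram, and the
   "uniquely identifiable" fraction (records with `k = 1`) are the core
   outputs, alongside a Monte-Carlo attack simulator that corrupts a
   target's name by exactly `e` edits and searches the dataset within
   radius `l`.

2. **Cross-source profile aggregation.** Profiles of the same person
   scattered over several sites can be chained into one dossier via three
   steps: *attribution* (extract attributes per source), *inference*
   (logical rules, e.g. a "my husband" mention implies the owner is female;
   a birthdate plus a reference date yields an age) and *aggregation*
   (score profile pairs on strong evidence — exact email/phone/username
   matches — and weak evidence — gender/location/age consistency — combine
   weights by noisy-or `1 − Π(1 − wᵢ)`, link pairs above a confidence
   threshold, and merge connected components of the link graph).

Since real phonebooks and patient profiles cannot ship with a software
package, a synthetic-data module generates reproducible populations
(Zipf-weighted name lexicons, gender, birthdate, location), phonebook
subsamples at configurable coverage, and multi-source profile sets with
configurable disclosure, typo and username-reuse rates — together with the
ground-truth identity map, so linkage quality is scored exactly.

## Worked example

```python
from privrisk import (AttributeSchema, Microdata, Record, kl_profile,
                      k_histogram, satisfies_kl, recovery_experiment)

schema = AttributeSchema.build([("name", "identifier", "text")])
md = Microdata(schema=schema, records=[
    Record(f"r{i}", {"name": n})
    for i, n in enumerate(["ann", "anne", "anna", "bob"])])

prof = kl_profile(md, "name", l=1)
print("k values:", dict(prof.k_values))
print("unique fraction:", k_histogram(prof).unique_fraction)
print("satisfies 2-1-anonymity:", satisfies_kl(md, "name", k=2, l=1))

stats = recovery_experiment(md, "name", e=1, l=1, n_trials=1000, seed=0)
print("recovery rate (e=1, l=1):", stats.recovery_rate)
print("candidate set sizes:", dict(sorted(stats.candidate_size_dist.items())))
```

prints

```
k values: {'r0': 3, 'r1': 3, 'r2': 3, 'r3': 1}
unique fraction: 0.25
satisfies 2-1-anonymity: False
recovery rate (e=1, l=1): 1.0
candidate set sizes: {1: 775, 2: 96, 3: 129}
```

`ann`, `anne` and `anna` are each within one edit of the other two, so each
has `k = 3`; `bob` has no neighbor and is uniquely identifiable (`k = 1`),
which is also why the dataset fails 2-1-anonymity. The attack simulator
corrupts a uniformly drawn target's name by exactly one edit and searches
within one edit: because the corruption distance never exceeds the search
radius, the true target is always recovered (rate 1.0), and the candidate
sets stay small.

The same analyses run from the shell:

```sh
privrisk simulate --n 2000 --coverage 0.64 --seed 42 --out-dir demo
privrisk risk-report --input demo/phonebook.csv --schema demo/schema.yaml \
    --field full_name --l 0,1,2 --out demo/report.json
```

which on this seed yields a 1,280-entry phonebook whose full-name unique
fractions fall from 0.640 (`l = 0`) to 0.628 (`l = 1`) to 0.548 (`l = 2`) —
tolerating more spelling error can only make people harder to single out.
`attack-sim` and `link` cover the adversary simulation and the profile
linkage pipeline; every report embeds its config, seed and toolkit version.

## Documentation

`docs/methods.md` describes the metrics, the evidence model, the
synthetic-data generator and its limitations, and the numerical choices.
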