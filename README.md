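# rarebio

Genome-resolved rare-biosphere analysis for time-series metagenomes:
delineate rare vs. abundant populations from coverage patterns, account
for their transitions across disturbance events, and classify habitat
generalists vs. specialists with the proportional similarity index.

## Who this is for

Microbial ecologists working with metagenome-assembled genomes (MAGs)
mapped against time-series metagenomes — e.g. a coastal observatory
sampled across seasons and years — who want reproducible, quantitative
answers to two questions that are usually settled by arbitrary cutoffs:

* *which populations are rare in a given sample*, and
* *which populations are niche generalists vs. specialists*,

and who then want to test whether rare populations buffer the community
against disturbance (the insurance hypothesis) and whether disturbance
favors generalists (the disturbance-specialization hypothesis).

## The model

**Abundance.** A MAG's abundance in a sample is its TAD80 — the truncated
average depth over the middle 80% of genome positions, robust to conserved
regions and recent gene loss — divided by the sample's *genome
equivalents* (total bp / average community genome size):

```
rel_abund = TAD80 / genome_equivalents
```

**Rare vs. abundant.** Detected populations are ranked per sample and the
species abundance curve is fitted on a log scale (default: ln abundance on
ln rank). An exhaustive search for a continuous two-segment fit locates
the knee where the slope drops sharply; if the two-segment model beats the
single line by BIC, the fitted abundance at the knee — clamped to the
0.08–0.2% field range — becomes the per-sample threshold (default 0.1%
otherwise). A population is **abundant** when relative abundance ≥
threshold *and* breadth of coverage ≥ 90%, **undetected** below 10%
breadth (the reliable-detection floor; under Poisson coverage the limit of
detection is `-ln(0.9)/genome_equivalents`), and **rare** otherwise.

**Transitions.** For each disturbance event (pre/during[/post] samples),
every MAG detected in pre or during is assigned `Abun_Abun`, `Rare_Abun`,
`Abun_Rare` or `Rare_Rare` from its labels (undetected collapses into
rare), with cumulative relative abundances per category and a recovery
flag (return to the pre-disturbance label in the post sample).

**Niche breadth.** The proportional similarity index compares a MAG's
distribution over habitat categories `p_i` with category availability
`q_i`:

```
PS = 1 - 0.5 * Σ_i |p_i - q_i|        (1 = broadest niche)
```

computed at two levels — season (main type) and season×year (sub-type).
MAGs in the top tercile of PS ranks at both levels are **generalists**;
bottom tercile at both are **specialists** (regular if rank_sub ≥
rank_main, strict otherwise); MAGs detected in ≤1 sample are excluded.
Levins' B = 1/Σp² is reported for comparison, and a permutation null
(`ps_null_test`) calibrates specialism p-values.

**Diversity.** Chao1 richness (bias-corrected by default), the Chao-Shen
coverage-corrected Shannon entropy (nats), and its Hill transform
`^1D = exp(H)`.

A synthetic coastal community generator (`rarebio.generate`) produces
coverage tables with planted ground truth — log-normal abundances,
Dirichlet seasonal preferences, planted disturbance responders, Poisson
coverage observation — so every stage is testable without sequencing data.

## Worked example

```python
import rarebio as rb

matrix, samples, events, truth = rb.generate(seed=1)   # synthetic coastal series
norm = rb.normalize_matrix(matrix, samples)            # TAD80 -> relative abundance

clf = rb.RarityClassifier().fit(norm)                  # per-sample thresholds
print(f"{clf.thresholds_['s01']:.4%}")                 # -> 0.0800%
calls = clf.predict(norm)
print(calls["label"].value_counts().to_dict())
# -> {'undetected': 1977, 'rare': 1604, 'abundant': 219}

records = rb.assess_recovery(rb.classify_transitions(calls, events))
print(rb.recovery_summary(records).head(3).to_string(index=False))
# event_id  category  n_mags  cumulative_pre  cumulative_during  n_recovered  recovery_fraction
#       E1 Abun_Abun       1        0.094586           0.038432            1           1.000000
#       E1 Abun_Rare       9        0.023642           0.003202            7           0.777778
#       E1 Rare_Abun       8        0.002727           0.072452            8           1.000000

profiles = rb.classify_niche(norm, samples)
print(profiles["label"].value_counts().to_dict())
# -> {'excluded': 73, 'intermediate': 47, 'generalist': 40,
#     'regular_specialist': 30, 'strict_specialist': 10}
```

Reading the transition summary: eight formerly-rare MAGs surged from
0.27% to 7.2% of the community during event E1 and every one returned to
rarity afterwards — the insurance-hypothesis signature the transition
accounting is built to expose. `rb.truth_metrics(truth, ...)` scores any
of these outputs against the planted ground truth.

The same pipeline runs from the shell on TSV inputs:

```
rarebio simulate --seed 1 --out sim/
rarebio run-all --coverage sim/coverage.tsv --samples sim/samples.tsv \
                --events sim/events.tsv --out results/
```

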