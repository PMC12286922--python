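# Methods

This note documents the models and procedures implemented in `rarebio`,
the parameters that matter, what the synthetic generator does and does not
emulate, and the design choices made where the design was genuinely open.

## Coverage metrics

**TAD80.** Genome positions are sorted by mapped depth and
`floor(((1 - central_fraction)/2) · L)` positions are discarded from each
tail (`central_fraction` defaults to 0.8, i.e. 10% per tail; a small
epsilon guards the floor against binary-float artifacts such as
`(1-0.8)/2 < 0.1`). The mean of the retained middle is the abundance
proxy. The fixed floor rule makes results bit-reproducible and matches
common truncated-average-depth implementations. Consequences worth
knowing: TAD80 is exactly the mean when `central_fraction = 1`, is
invariant to spiking fewer than 10% of positions to arbitrary depth, and
collapses to 0 once ≥ 90% of positions are uncovered — which is precisely
the 10% breadth detection floor, so "TAD80 > 0" and "breadth above the
detection limit" fail together.

**Breadth** is the fraction of positions with depth ≥ 1.
**Normalization** divides TAD80 by the sample's genome equivalents
(MicrobeCensus-style; total bp / average community genome size), giving
relative abundance as a community fraction. Fractions are used internally
everywhere; percent appears only in rendered output.

**Limit of detection.** Under Poisson coverage, expected breadth at mean
depth c is `1 − e^(−c)`; requiring 10% breadth gives minimum depth
`−ln(0.9) ≈ 0.105` and minimum relative abundance `−ln(0.9)/GE`. At the
default GE of 2302.6 this is 4.6·10⁻⁵ — comfortably below the 0.1% rare
threshold, so rarity calls are not artifacts of sequencing effort for any
realistic effort (GE ≥ 106).

**Quality filtering** uses `completeness − 5·contamination +
0.5·strain_heterogeneity` on the fractional scale with defaults
completeness ≥ 0.70, contamination ≤ 0.10 and score strictly > 0.5.
CheckM-style tables report percentages while the 0.5 score cutoff implies
fractions; inputs with completeness > 1.5 are therefore auto-rescaled by
1/100 with a logged notice. Strain heterogeneity defaults to 0 when a
table omits it.

## Rare/abundant delineation

Per sample, detected populations (rel_abund > 0) are ranked descending
with ties broken by MAG id. The default model regresses ln(abundance) on
ln(rank) ("loglog"); "semilog" (raw abundance on ln rank) is available by
configuration because a "log scale model" is ambiguous. R² is reported on
the regression's own response scale.

The per-sample threshold formalizes what is otherwise a visual judgment:
an exhaustive search over candidate knees (ranks 4 … n−4, at least four
points per segment) fits a continuous two-segment line — design matrix
`[1, x, max(0, x − x_k)]` — and the minimum-SSE knee is accepted only if
its BIC (`n·ln(SSE/n) + p·ln n`, p = 4 vs. 2) beats the single line. The
threshold is the fitted abundance at the knee, clamped to the 0.08–0.2%
field range; curves with fewer than 8 points, exactly-linear curves
(single-line SSE at machine precision), or rejected knees fall back to
the 0.1% default. Knee ties resolve to the smaller rank; both outcomes
are logged.

Labels: *undetected* when breadth < 0.10; *abundant* when rel_abund ≥
threshold AND breadth ≥ 0.90; otherwise *rare*. Abundance and breadth are
required jointly because the two criteria fail together at the knee; a
mixed case (high abundance, low breadth — e.g. a relative of the
reference genome rather than the population itself) is conservatively
called rare. The three labels partition all cells.

## Transitions

Events are supplied explicitly (pre/during[/post] sample ids): event
detection from community composition is a separate amplicon-based problem
and out of scope. Undetected collapses into rare for categorization — the
rare biosphere includes populations below detection — but undetected
flags are kept per record for audit. MAGs undetected in both pre and
during are omitted, so category counts per event sum to the number of
MAGs detected in either sample. Cumulative abundance per category is
reported in both the pre and during samples, since both are needed for
headline statements of the form "initially X% but Y% after". Recovery is
`post label == pre label` on the rare/abundant binary; without a post
sample it is left undefined rather than imputed.

## Niche classification

PS = 1 − 0.5·Σ|p_i − q_i| with p the MAG's per-category abundance shares.
Two availability bases are implemented: `cells` (default) weights
categories by their share of summed community relative abundance,
matching the formula's "cells" reading; `samples` weights by sample
counts, matching the sampling-effort reading. Both appear in the
literature; the choice is a config switch. PS is 1 exactly when p ≡ q and
approaches 0 only as the occupied category's availability vanishes; it is
invariant to uniform rescaling of the MAG's abundances. Note the
direction: high PS = broad niche = generalist.

Classification ranks PS ascending (average ties) over all classifiable
MAGs at both category levels; "upper/lower third percentile" is read as
terciles of the ranked distribution (bottom: rank ≤ floor(N/3); top:
rank > N − floor(N/3)) — a literal 3rd percentile would leave almost no
generalists. Generalist requires the top tercile at both levels;
specialist the bottom at both, subdivided by comparing sub-type vs
main-type ranks (tie → regular, logged). Ranks are computed over all
classifiable MAGs, not within the specialist subset. MAGs detected
(breadth ≥ 0.10) in ≤ 1 sample are excluded — no reliable niche breadth
exists for them. Levins' B = 1/Σp² over main types, standardized to
(B−1)/(N−1), is reported for comparison with the equal-availability
tradition.

`ps_null_test` permutes sample-to-category labels and reports
`p = (1 + #{PS_perm ≤ PS_obs}) / (n_perm + 1)` for specialism; at least
99 permutations are required.

## Diversity estimators

Chao1 defaults to the bias-corrected form `S_obs + F1(F1−1)/(2(F2+1))`
to avoid the classic form's F2 = 0 singularity (the classic `F1²/(2F2)`
is available; with F2 = 0 it uses its standard `F1(F1−1)/2` limit). The
Chao-Shen entropy applies Good-Turing coverage `C = 1 − F1/n` and a
Horvitz-Thompson inclusion correction; it is undefined when every count
is a singleton, and errs with guidance. Entropy is in nats so that
`^1D = exp(H)` is the Hill number in effective categories.

## Synthetic community generator

The generator emulates the coastal study conditions at desk scale:

| parameter | default | rationale |
|---|---|---|
| n_mags | 200 | dereplicated MAG catalogue size |
| n_samples | 19 | 3 seasons × 3 years, uneven replication |
| sad_meanlog, sad_sdlog | 0, 2.0 | log-normal SAD; top MAG near 3% of reads |
| total_mapped_fraction | 0.12 | MAGs jointly map 12% of reads (field range 5–18%) |
| frac generalists/specialists | 1/3, 1/3 | planted class balance |
| Dirichlet concentrations | 20 / 3 / 0.8 | generalist / intermediate / specialist seasonal preference |
| genome_equivalents | 2302.6 | makes expected breadth at 0.1% abundance exactly 0.90 |
| genome_length | 20 000 | exposure for the count model (positions) |
| dispersion | 0.05 | gamma CV² of depth noise beyond Poisson |
| events | 2 | 8 rare→abundant (×30), 5 abundant→rare (÷50) responders each |

Observation model: expected depth `c = rel_abund · GE`; mapped counts are
Poisson with exposure `genome_length` (gamma-mixed when dispersion > 0,
i.e. negative binomial); breadth follows the Lander–Waterman identity
`1 − e^(−depth)`. This makes the detection-limit formula internally
consistent and testable. The log-log R² of a rank-abundance fit is
invariant to `sad_sdlog` (the response is affine in it), so the SAD width
was set by the top-MAG target while the R² band is governed by the
seasonal-preference mixture and observation noise; at defaults the
per-sample R² lands in ≈ 0.77–0.88 (median ≈ 0.83).

Seasonal structure: per sample, base abundances are multiplied by the
MAG's preference weight for the sample's season and renormalized to the
mapped fraction. Disturbance responders are drawn from pools chosen so
the planted fold is unambiguous (rare pool: < 0.05% in pre and during,
high enough that ×30 exceeds 0.25%; abundant pool: ≥ 0.2% — the clamp
ceiling, so the pre label is abundant under any admissible threshold —
and low enough that ÷50 lands below 0.064%). Responders keep their exact
folded values; the rest of the community absorbs the compositional shift,
and post samples restore responders to pre levels the same way. A
configuration whose responder counts exceed the eligible pools raises an
error rather than silently planting less; at extreme seeds the abundant
fringe of a 12%-mapped community can hold fewer than the default five
abundant-to-rare responders, which surfaces as exactly this error.

Ground truth: the per-MAG `niche_label` is the label a noise-free
observer would assign (the tercile rule applied to true abundances); the
drawn Dirichlet class is kept separately as `niche_class`, because
overlapping Dirichlet draws make the drawn class an unattainable target
even without observation noise. Similarly, `truth_metrics` scores
transition categories against the noise-free reference computed from true
abundances with the *inferred* per-sample thresholds, isolating
observation noise: with zero noise the score is exactly 1. Planted
responders are scored as precision/recall against the planted flags —
note that compositional displacement creates genuine unplanted
abundant-to-rare transitions, so Abun_Rare precision against planted
flags is expectedly below 1 even noise-free, while Rare_Abun
precision/recall stay at 1 (natural upward crossings cannot occur when
pre and during share a season and the community only shrinks around
boosted responders).

What the generator does **not** emulate: read-level errors and mapping
ambiguity, strain-level variation within a population, conserved-region
depth inflation (TAD80's reason for existing), uneven sequencing effort
across samples, environmental covariates, and autocorrelated
within-season dynamics. Passing recovery tests therefore demonstrate the
*inference machinery* is correct under the stated statistical
assumptions, not that those assumptions hold for any particular real
dataset.

## Problem sizes and numerics

Tests and the acceptance script run the full pipeline on 200 MAGs × 19
samples over ten seeds — the catalogue scale of the motivating field
study — which keeps the whole suite under a minute while exercising every
stage. Threshold detection is exact enumeration (no numerical search);
OLS uses `numpy.linalg.lstsq`. Degenerate inputs (all-zero samples,
constant curves, single categories, all-singleton counts) raise typed
errors with messages naming the offending entity; fallback paths
(too-short curves) log rather than raise, as specified per operation.

## Known limitations

* The breakpoint detector fits one knee; multi-regime curves will place
  the knee at the dominant slope change.
* The per-sample threshold is clamped into 0.08–0.2% by construction; a
  community whose true delineation sits outside that range requires
  changing `threshold_clamp`.
* PS categories must all have nonzero availability under the `cells`
  basis; empty categories are an error, not a silent drop.
* `transition_balanced_accuracy` depends on the noise-free reference and
  is therefore only defined for synthetic data with truth attached.
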