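"""Synthetic coastal community generator with ground truth.

The generator emulates the statistical structure the analysis assumes:

1. base abundances drawn from a log-normal species abundance distribution
   and renormalized so the ~200 MAGs jointly map a fixed fraction of the
   reads (default 12%, field range 5--18%);
2. planted niche structure — each MAG gets a seasonal preference vector
   from a symmetric Dirichlet whose concentration depends on its class
   (near-uniform for generalists, concentrated for specialists);
3. per-sample true abundances: base x seasonal preference, renormalized;
4. planted disturbances: responder MAGs drawn from the correct abundance
   pool are folded up (rare-to-abundant) or down (abundant-to-rare) in the
   during sample and restored to pre-disturbance levels in the post
   sample, with per-sample renormalization so fold changes perturb rather
   than violate compositionality;
5. observation: expected depth = rel_abund x genome equivalents; mapped
   counts are Poisson over a genome-length exposure (gamma-mixed, i.e.
   negative binomial, when ``dispersion`` > 0) and breadth follows the
   Lander-Waterman identity ``1 - exp(-depth)``.

All randomness flows from one seed through independent substreams per
stage, so changing one stage's draw does not cascade into the others.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import EventSpec, GeneratorConfig
from .containers import CoverageMatrix, DisturbanceEvent, SampleInfo

__all__ = ["SyntheticTruth", "generate", "truth_metrics"]

# planted delineation used for truth labels (mirrors RunConfig defaults)
TRUE_THRESHOLD = 0.001
TRUE_BREADTH_CUTOFF = 0.90
TRUE_DETECTION_BREADTH = 0.10

_SEASON_DATES = {"winter": (2, 1), "spring": (5, 1), "summer": (8, 1)}


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a synthetic dataset.

    ``true_rel_abund`` is the MAG x sample matrix of true community
    fractions. ``mags`` records each MAG's drawn niche class, its seasonal
    preference vector and ``niche_label``: the label a noise-free observer
    applying the tercile rule to the true abundances would assign (the
    drawn class is kept separately as ``niche_class``). ``responders``
    lists planted event responders; ``true_calls`` gives the noise-free
    rarity label of every cell under the planted 0.1%/90% delineation.
    """

    true_rel_abund: pd.DataFrame
    mags: pd.DataFrame
    responders: pd.DataFrame
    true_calls: pd.DataFrame
    config: GeneratorConfig = field(repr=False, default=None)


def _build_samples(config: GeneratorConfig) -> list[SampleInfo]:
    slots = [(y, s) for y in config.years for s in config.seasons]
    counts = [config.n_samples // len(slots)] * len(slots)
    for i in range(config.n_samples % len(slots)):
        counts[i] += 1
    samples = []
    idx = 0
    for (year, season), n_reps in zip(slots, counts):
        month, day = _SEASON_DATES.get(season, (6, 1))
        for rep in range(n_reps):
            idx += 1
            samples.append(
                SampleInfo(
                    sample_id=f"s{idx:02d}",
                    date=datetime.date(year, month, min(day + 14 * rep, 28)),
                    main_type=season,
                    sub_type=f"{season}_{year}",
                    genome_equivalents=config.genome_equivalents,
                )
            )
    return samples


def _season_index(samples: Sequence[SampleInfo], seasons: Sequence[str]) -> np.ndarray:
    lookup = {s: i for i, s in enumerate(seasons)}
    return np.array([lookup[s.main_type] for s in samples])


def _rarity_label(ab: np.ndarray, br: np.ndarray) -> np.ndarray:
    return np.where(
        br < TRUE_DETECTION_BREADTH,
        "undetected",
        np.where((ab >= TRUE_THRESHOLD) & (br >= TRUE_BREADTH_CUTOFF), "abundant", "rare"),
    )


def generate(
    config: Optional[GeneratorConfig] = None, seed: Optional[int] = None
) -> tuple[CoverageMatrix, list[SampleInfo], list[DisturbanceEvent], SyntheticTruth]:
    """Generate a synthetic coverage table, metadata, events and truth."""
    config = config or GeneratorConfig()
    if seed is None:
        seed = config.rng_seed
    ss = np.random.SeedSequence(seed)
    rng_sad, rng_niche, rng_events, rng_obs = (
        np.random.default_rng(child) for child in ss.spawn(4)
    )

    n, m = config.n_mags, config.n_samples
    mag_ids = [f"MAG{i + 1:04d}" for i in range(n)]
    samples = _build_samples(config)
    sample_ids = [s.sample_id for s in samples]
    season_of = _season_index(samples, config.seasons)

    # (1) log-normal species abundance distribution
    base = rng_sad.lognormal(config.sad_meanlog, config.sad_sdlog, n)

    # (2) planted niche classes and seasonal preferences
    n_gen = int(np.floor(config.frac_generalists * n))
    n_spec = int(np.floor(config.frac_specialists * n))
    classes = np.array(
        ["generalist"] * n_gen
        + ["specialist"] * n_spec
        + ["intermediate"] * (n - n_gen - n_spec)
    )
    rng_niche.shuffle(classes)
    conc = {
        "generalist": config.generalist_concentration,
        "specialist": config.specialist_concentration,
        "intermediate": config.intermediate_concentration,
    }
    n_seasons = len(config.seasons)
    prefs = np.vstack(
        [rng_niche.dirichlet(np.full(n_seasons, conc[c])) for c in classes]
    )

    # (3) per-sample true abundances
    true = np.empty((n, m))
    for j in range(m):
        w = base * prefs[:, season_of[j]]
        true[:, j] = w / w.sum() * config.total_mapped_fraction

    # (4) planted disturbances
    events: list[DisturbanceEvent] = []
    responder_rows = []
    for spec in config.default_events():
        d = spec.during_index
        if not 1 <= d < m:
            raise ValueError(f"event {spec.event_id}: during_index {d} out of range")
        pre, post = d - 1, (d + 1 if d + 1 < m else None)
        # rare pool: clearly rare pre and during, yet high enough that the
        # planted fold lands them clearly abundant
        floor_up = 2.5 * TRUE_THRESHOLD / spec.fold_up
        rare_pool = np.flatnonzero(
            (true[:, d] < 0.5 * TRUE_THRESHOLD)
            & (true[:, d] >= floor_up)
            & (true[:, pre] < 0.5 * TRUE_THRESHOLD)
        )
        # abundant pool floor sits at the clamp ceiling so the pre label is
        # abundant under any admissible per-sample threshold; the ceiling
        # guarantees the planted fold lands clearly rare
        ceil_down = 0.8 * 0.0008 * spec.fold_down
        abun_pool = np.flatnonzero(
            (true[:, d] >= 2.0 * TRUE_THRESHOLD)
            & (true[:, d] <= ceil_down)
            & (true[:, pre] >= 2.0 * TRUE_THRESHOLD)
        )
        if len(rare_pool) < spec.n_rare_to_abun:
            raise ValueError(
                f"event {spec.event_id}: rare pool has {len(rare_pool)} MAGs "
                f"< requested {spec.n_rare_to_abun}"
            )
        if len(abun_pool) < spec.n_abun_to_rare:
            raise ValueError(
                f"event {spec.event_id}: abundant pool has {len(abun_pool)} MAGs "
                f"< requested {spec.n_abun_to_rare}"
            )
        up = rng_events.choice(rare_pool, spec.n_rare_to_abun, replace=False)
        down = rng_events.choice(abun_pool, spec.n_abun_to_rare, replace=False)
        resp = np.r_[up, down]
        pre_levels = true[resp, pre].copy()
        # responders keep their exact folded values; the rest of the
        # community absorbs the compositional shift
        resp_vals = np.r_[true[up, d] * spec.fold_up, true[down, d] / spec.fold_down]
        resp_sum = resp_vals.sum()
        if resp_sum > 0.75 * config.total_mapped_fraction:
            raise ValueError(
                f"event {spec.event_id}: planted responders would claim "
                f"{resp_sum:.3f} of the community; reduce counts or folds"
            )
        others = np.setdiff1d(np.arange(n), resp)
        true[others, d] *= (
            config.total_mapped_fraction - resp_sum
        ) / true[others, d].sum()
        true[resp, d] = resp_vals
        if post is not None:
            others_sum = true[np.setdiff1d(np.arange(n), resp), post].sum()
            true[resp, post] = pre_levels
            true[np.setdiff1d(np.arange(n), resp), post] *= (
                config.total_mapped_fraction - pre_levels.sum()
            ) / others_sum
        events.append(
            DisturbanceEvent(
                event_id=spec.event_id,
                pre_sample=sample_ids[pre],
                during_sample=sample_ids[d],
                post_sample=sample_ids[post] if post is not None else None,
                description="planted synthetic disturbance",
            )
        )
        for i in up:
            responder_rows.append(
                {"event_id": spec.event_id, "mag_id": mag_ids[i], "planted_category": "Rare_Abun"}
            )
        for i in down:
            responder_rows.append(
                {"event_id": spec.event_id, "mag_id": mag_ids[i], "planted_category": "Abun_Rare"}
            )

    # (5) observation model
    expected_depth = true * config.genome_equivalents
    rate = expected_depth.copy()
    if config.dispersion > 0:
        shape = 1.0 / config.dispersion
        rate *= rng_obs.gamma(shape, 1.0 / shape, size=rate.shape)
    counts = rng_obs.poisson(rate * config.genome_length)
    depth = counts / config.genome_length
    brd = 1.0 - np.exp(-depth)

    depth_df = pd.DataFrame(depth, index=mag_ids, columns=sample_ids)
    brd_df = pd.DataFrame(brd, index=mag_ids, columns=sample_ids)
    matrix = CoverageMatrix(depth_df, brd_df)

    true_df = pd.DataFrame(true, index=mag_ids, columns=sample_ids)
    true_breadth = 1.0 - np.exp(-expected_depth)
    true_calls = pd.DataFrame(
        {
            "mag_id": np.repeat(mag_ids, m),
            "sample_id": np.tile(sample_ids, n),
            "label": _rarity_label(true, true_breadth).ravel(),
            "rel_abund": true.ravel(),
        }
    )

    mags = pd.DataFrame(
        {
            "mag_id": mag_ids,
            "niche_class": classes,
            **{
                f"pref_{s}": prefs[:, i] for i, s in enumerate(config.seasons)
            },
        }
    )
    mags["niche_label"] = _noise_free_niche_labels(
        true_df, pd.DataFrame(true_breadth, index=mag_ids, columns=sample_ids), samples
    )

    truth = SyntheticTruth(
        true_rel_abund=true_df,
        mags=mags,
        responders=pd.DataFrame(
            responder_rows, columns=["event_id", "mag_id", "planted_category"]
        ),
        true_calls=true_calls,
        config=config,
    )
    return matrix, samples, events, truth


def _noise_free_niche_labels(
    true_rel: pd.DataFrame, true_breadth: pd.DataFrame, samples: Sequence[SampleInfo]
) -> np.ndarray:
    """Niche labels a noise-free observer would assign from true abundances."""
    from .niche import NicheClassifier

    matrix = CoverageMatrix(
        depth=true_rel * 1.0 + 0.0,  # placeholder depth; only breadth/rel used
        breadth=true_breadth.where(true_rel > 0, 0.0),
        rel_abund=true_rel,
    )
    clf = NicheClassifier().fit(matrix, samples)
    return clf.labels_.to_numpy()


def _binary_balanced_accuracy(truth: pd.Series, positive_ok: pd.Series) -> float:
    pos = truth.to_numpy()
    ok = positive_ok.to_numpy()
    recalls = [ok[pos == grp].mean() for grp in np.unique(pos)]
    return float(np.mean(recalls))


def truth_metrics(
    truth: SyntheticTruth,
    calls: Optional[pd.DataFrame] = None,
    records: Optional[pd.DataFrame] = None,
    profiles: Optional[pd.DataFrame] = None,
    thresholds: Optional[pd.Series] = None,
    events: Optional[Sequence[DisturbanceEvent]] = None,
) -> dict:
    """Score pipeline outputs against the planted truth.

    Computes (whatever inputs allow): balanced accuracy of the binary
    abundant/not-abundant calls against the planted 0.1%/90% delineation;
    transition-category balanced accuracy against the noise-free reference
    (true abundances classified with the *inferred* per-sample thresholds,
    so the score isolates observation noise); precision and recall of the
    planted Rare_Abun and Abun_Rare responders; and balanced accuracy of
    the niche labels (three-class, plus the binary
    generalist-vs-specialist restriction).
    """
    report: dict = {}

    if calls is not None:
        merged = calls.merge(
            truth.true_calls[["mag_id", "sample_id", "label"]],
            on=["mag_id", "sample_id"],
            suffixes=("", "_true"),
            validate="one_to_one",
        )
        if len(merged) != len(truth.true_calls):
            raise ValueError("mag/sample ids of calls do not match the truth")
        t_ab = merged["label_true"] == "abundant"
        p_ab = merged["label"] == "abundant"
        report["rarity_balanced_accuracy"] = _binary_balanced_accuracy(t_ab, p_ab == t_ab)

    if records is not None:
        if thresholds is None or events is None:
            raise ValueError("transition scoring needs thresholds and events")
        from .transitions import classify_transitions

        ref_calls = truth.true_calls.copy()
        thr = ref_calls["sample_id"].map(thresholds)
        true_breadth = 1.0 - np.exp(
            -ref_calls["rel_abund"] * truth.config.genome_equivalents
        )
        ref_calls["label"] = np.where(
            true_breadth < TRUE_DETECTION_BREADTH,
            "undetected",
            np.where(
                (ref_calls["rel_abund"] >= thr) & (true_breadth >= TRUE_BREADTH_CUTOFF),
                "abundant",
                "rare",
            ),
        )
        ref_records = classify_transitions(ref_calls, events)
        merged = records.merge(
            ref_records[["mag_id", "event_id", "category"]],
            on=["mag_id", "event_id"],
            how="outer",
            suffixes=("", "_ref"),
            indicator=True,
        )
        # cells detected on one side only count as mismatches
        both = merged["_merge"] == "both"
        cats = merged.loc[both, "category_ref"]
        correct = merged.loc[both, "category"] == cats
        recalls = []
        for cat in cats.unique():
            recalls.append(float(correct[cats == cat].mean()))
        # one-sided records are misses for their category
        if (~both).any():
            recalls.append(0.0)
        report["transition_balanced_accuracy"] = float(np.mean(recalls))

        for cat in ("Rare_Abun", "Abun_Rare"):
            planted = truth.responders[truth.responders["planted_category"] == cat]
            planted_keys = set(zip(planted["event_id"], planted["mag_id"]))
            predicted = records[records["category"] == cat]
            pred_keys = set(zip(predicted["event_id"], predicted["mag_id"]))
            tp = len(planted_keys & pred_keys)
            prefix = cat.lower()
            report[f"{prefix}_precision"] = tp / len(pred_keys) if pred_keys else float("nan")
            report[f"{prefix}_recall"] = tp / len(planted_keys) if planted_keys else float("nan")

    if profiles is not None:
        merged = truth.mags.merge(profiles[["mag_id", "label"]], on="mag_id")
        if len(merged) != len(truth.mags):
            raise ValueError("mag ids of niche profiles do not match the truth")

        def collapse(s: pd.Series) -> pd.Series:
            return s.replace({"regular_specialist": "specialist", "strict_specialist": "specialist"})

        t_lab = collapse(merged["niche_label"])
        p_lab = collapse(merged["label"])
        usable = t_lab != "excluded"
        recalls = [
            float((p_lab[usable & (t_lab == grp)] == grp).mean())
            for grp in t_lab[usable].unique()
        ]
        report["niche_balanced_accuracy"] = float(np.mean(recalls))
        binary = usable & t_lab.isin(["generalist", "specialist"])
        report["generalist_specialist_balanced_accuracy"] = _binary_balanced_accuracy(
            t_lab[binary], (p_lab[binary] == t_lab[binary])
        )
    return report
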