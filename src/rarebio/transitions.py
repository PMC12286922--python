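"""Disturbance transition accounting.

For each disturbance event (a pre/during[/post] sample triple) every MAG
detected in pre or during is assigned one of four categories from its
rarity labels — Abun_Abun, Rare_Abun, Abun_Rare, Rare_Rare — with
*undetected* collapsed into *rare* (the rare biosphere includes
populations below detection). Cumulative relative abundances per category
reproduce the paper-style headline sums, and recovery (return to the
pre-disturbance label in the post sample) is assessed when a post sample
exists.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd

from .containers import DisturbanceEvent

__all__ = [
    "CATEGORIES",
    "classify_transitions",
    "cumulative_abundance",
    "assess_recovery",
    "recovery_summary",
]

CATEGORIES = ("Abun_Abun", "Rare_Abun", "Abun_Rare", "Rare_Rare")


def _pivot(calls: pd.DataFrame, column: str) -> pd.DataFrame:
    return calls.pivot(index="mag_id", columns="sample_id", values=column)


def _binary(label: pd.Series) -> pd.Series:
    # undetected collapses into rare for transition bookkeeping
    return label.map(lambda v: "Abun" if v == "abundant" else "Rare")


def classify_transitions(
    calls: pd.DataFrame, events: Iterable[DisturbanceEvent]
) -> pd.DataFrame:
    """Per-MAG per-event transition records.

    ``calls`` is the output of :meth:`RarityClassifier.predict`. MAGs
    undetected in both the pre and during samples are omitted; the
    undetected status of the remaining records is retained in the
    ``pre_undetected`` / ``during_undetected`` columns for auditability.
    """
    labels = _pivot(calls, "label")
    abund = _pivot(calls, "rel_abund")
    records = []
    for event in events:
        for sid in (event.pre_sample, event.during_sample, event.post_sample):
            if sid is not None and sid not in labels.columns:
                raise ValueError(
                    f"event {event.event_id}: no rarity calls for sample {sid!r}"
                )
        pre, during = labels[event.pre_sample], labels[event.during_sample]
        keep = ~((pre == "undetected") & (during == "undetected"))
        category = _binary(pre) + "_" + _binary(during)
        frame = pd.DataFrame(
            {
                "mag_id": labels.index,
                "event_id": event.event_id,
                "category": category,
                "pre_abund": abund[event.pre_sample],
                "during_abund": abund[event.during_sample],
                "pre_undetected": (pre == "undetected"),
                "during_undetected": (during == "undetected"),
            }
        )[keep.to_numpy()]
        if event.post_sample is not None:
            frame["post_abund"] = abund.loc[frame["mag_id"], event.post_sample].to_numpy()
            frame["post_label"] = labels.loc[frame["mag_id"], event.post_sample].to_numpy()
        else:
            frame["post_abund"] = float("nan")
            frame["post_label"] = None
        records.append(frame)
    if not records:
        return pd.DataFrame(
            columns=[
                "mag_id", "event_id", "category", "pre_abund", "during_abund",
                "pre_undetected", "during_undetected", "post_abund", "post_label",
            ]
        )
    return pd.concat(records, ignore_index=True)


def cumulative_abundance(records: pd.DataFrame, category: str, when: str = "during") -> float:
    """Summed relative abundance of a category's members in the pre or
    during sample (for records of a single event)."""
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}; expected one of {CATEGORIES}")
    if when not in ("pre", "during"):
        raise ValueError("when must be 'pre' or 'during'")
    members = records[records["category"] == category]
    return float(members[f"{when}_abund"].sum())


def assess_recovery(records: pd.DataFrame) -> pd.DataFrame:
    """Add a ``recovered`` flag: the post-disturbance label equals the
    pre-disturbance label (undetected collapsed into rare). Records of
    events without a post sample keep ``recovered`` undefined (NA)."""
    records = records.copy()
    has_post = records["post_label"].notna()
    pre_bin = records["category"].str.split("_").str[0]
    post_bin = records["post_label"].map(
        lambda v: None if v is None or (isinstance(v, float) and pd.isna(v))
        else ("Abun" if v == "abundant" else "Rare")
    )
    records["recovered"] = pd.array(
        [
            (pb == prb) if hp else None
            for hp, pb, prb in zip(has_post, post_bin, pre_bin)
        ],
        dtype="boolean",
    )
    return records


def recovery_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Per-event per-category counts and recovery fractions."""
    if "recovered" not in records.columns:
        records = assess_recovery(records)
    rows = []
    for (event_id, category), grp in records.groupby(["event_id", "category"]):
        n = len(grp)
        assessed = grp["recovered"].dropna()
        rows.append(
            {
                "event_id": event_id,
                "category": category,
                "n_mags": n,
                "cumulative_pre": float(grp["pre_abund"].sum()),
                "cumulative_during": float(grp["during_abund"].sum()),
                "n_recovered": int(assessed.sum()) if len(assessed) else pd.NA,
                "recovery_fraction": (
                    float(assessed.mean()) if len(assessed) else float("nan")
                ),
            }
        )
    return pd.DataFrame(rows)
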