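"""Blank suppression, mode merging, control correction, presence/absence.

The qualitative dataset used throughout the intersection analyses is a
:class:`PresenceMatrix` built with the study's detection rule: an ion is
present in a group (one fruit, or the flies reared on one fruit) iff its
peak area is strictly greater than 1000 in at least three replicates of
that group.  The 1000-area cut approximates the practical quantification
threshold of the mass spectrometer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import FeatureTable

__all__ = [
    "PresenceMatrix",
    "ContaminationReport",
    "remove_blank_ions",
    "merge_modes",
    "control_correct",
    "to_presence",
    "sample_groups",
    "contamination_tau",
]

AREA_THRESHOLD = 1000.0
MIN_REPLICATES = 3


@dataclass
class PresenceMatrix:
    """Boolean ions x groups matrix (the qualitative dataset).

    ``groups`` are ordered canonically: fruits alphabetically, then fly
    diets alphabetically; labels are ``fruit:<diet>`` / ``fly:<diet>``.
    """

    present: pd.DataFrame  # bool, ions x groups

    def __post_init__(self) -> None:
        self.present = self.present.astype(bool)

    @property
    def ions(self) -> list[str]:
        return list(self.present.index)

    @property
    def groups(self) -> list[str]:
        return list(self.present.columns)


@dataclass
class ContaminationReport:
    """Per-diet Kendall tau-b between fruit and fly mean ion areas."""

    table: pd.DataFrame  # index diet; columns tau, p_value, n_ions

    @property
    def max_abs_tau(self) -> float:
        return float(self.table["tau"].abs().max())


def remove_blank_ions(table: FeatureTable, blank_ids: list[str] | None = None) -> FeatureTable:
    """Suppress ions present in blank injections.

    An ion is dropped when its maximum area across the blank injections
    is greater than or equal to its maximum area across all non-blank
    samples; blank columns are removed from the output.  Ions with zero
    blank area are never dropped.
    """
    if blank_ids is None:
        blank_ids = table.sample_ids(kind="blank")
    if not blank_ids:
        raise ValueError("table has no blank samples")
    blank_ids = list(blank_ids)
    other_ids = [s for s in table.areas.columns if s not in set(blank_ids)]
    blank_max = table.areas[blank_ids].max(axis=1)
    sample_max = table.areas[other_ids].max(axis=1)
    suppressed = (blank_max > 0) & (blank_max >= sample_max)
    keep = table.areas.index[~suppressed]
    if len(keep) == 0:
        warnings.warn("blank suppression removed every ion", stacklevel=2)
    return FeatureTable(
        areas=table.areas.loc[keep, other_ids],
        samples=table.samples.loc[other_ids].reset_index(drop=True),
        modes=table.modes,
    )


def merge_modes(pos: FeatureTable, neg: FeatureTable) -> FeatureTable:
    """Merge positive- and negative-mode tables by row concatenation.

    Ion ids are suffixed ``_pos`` / ``_neg`` (unless already suffixed),
    so identifiers colliding across modes stay distinct.  Both tables
    must cover the same samples.
    """
    if set(pos.areas.columns) != set(neg.areas.columns):
        diff = sorted(set(pos.areas.columns) ^ set(neg.areas.columns))
        raise ValueError(f"sample sets differ between modes: {diff}")

    def _suffixed(t: FeatureTable, mode: str) -> pd.DataFrame:
        idx = [i if i.endswith(f"_{mode}") else f"{i}_{mode}" for i in t.areas.index]
        out = t.areas.copy()
        out.index = idx
        return out

    pos_a = _suffixed(pos, "pos")
    neg_a = _suffixed(neg, "neg")[pos_a.columns]
    merged = pd.concat([pos_a, neg_a], axis=0)
    modes = pd.Series(
        ["pos"] * len(pos_a) + ["neg"] * len(neg_a), index=merged.index
    )
    return FeatureTable(areas=merged, samples=pos.samples.reset_index(drop=True), modes=modes)


def control_correct(
    fly_table: FeatureTable,
    control_table: FeatureTable,
    min_area: float = AREA_THRESHOLD,
) -> FeatureTable:
    """Center fly areas on the control-fly median, per ion and generation.

    For each ion and fly sample, the median area of the control flies of
    the same generation is subtracted; negative values are clamped to 0
    (a peak area cannot be negative), and any corrected value below
    ``min_area`` is set to 0.  This removes signal contributed by the
    artificial component of the rearing media.
    """
    ctrl = control_table.samples
    ctrl_ids = list(ctrl.index[ctrl["kind"] == "control_fly"])
    if not ctrl_ids:
        raise ValueError("control table has no control_fly samples")
    ctrl_gens = control_table.samples.loc[ctrl_ids, "generation"]
    fly_gens = fly_table.samples["generation"]
    missing = sorted(set(fly_gens.dropna()) - set(ctrl_gens.dropna()))
    if missing:
        raise ValueError(f"no control flies for generations: {missing}")

    medians = {}
    for g in sorted(set(ctrl_gens.dropna())):
        ids = [s for s in ctrl_ids if ctrl_gens[s] == g]
        medians[g] = control_table.areas.reindex(fly_table.areas.index)[ids].fillna(0.0).median(axis=1)

    corrected = fly_table.areas.copy()
    for s in corrected.columns:
        g = fly_gens[s]
        corrected[s] = (corrected[s] - medians[g]).clip(lower=0.0)
    corrected[corrected < min_area] = 0.0
    return FeatureTable(areas=corrected, samples=fly_table.samples.reset_index(drop=True),
                        modes=fly_table.modes)


def sample_groups(samples: pd.DataFrame) -> pd.Series:
    """Map each fruit/fly sample to its canonical group label.

    Control flies and blanks carry no group (NaN): the qualitative
    analyses run on the eight fruit/fly groups only.
    """
    labels = pd.Series(index=samples.index, dtype=object)
    fruit = samples["kind"] == "fruit"
    fly = samples["kind"] == "fly"
    labels[fruit] = "fruit:" + samples.loc[fruit, "diet"].astype(str)
    labels[fly] = "fly:" + samples.loc[fly, "diet"].astype(str)
    return labels


def to_presence(
    table: FeatureTable,
    area_threshold: float = AREA_THRESHOLD,
    min_replicates: int = MIN_REPLICATES,
    strict: bool = True,
) -> PresenceMatrix:
    """Binarize a feature table into the per-group presence matrix.

    An ion is present in a group iff its area is strictly above
    ``area_threshold`` in at least ``min_replicates`` of the group's
    samples.  Replicates are pooled across generations, so fly groups
    typically hold 6 samples (3 for a single-generation diet).  Groups
    with fewer samples than ``min_replicates`` raise unless
    ``strict=False`` (downgraded to a warning).
    """
    labels = sample_groups(table.samples)
    if labels.isna().all():
        raise ValueError("table has no fruit or fly samples to group")
    groups = sorted(labels.dropna().unique(), key=lambda g: (g.split(":")[0] != "fruit", g))
    cols = {}
    for g in groups:
        ids = list(labels.index[labels == g])
        if len(ids) < min_replicates:
            msg = f"group {g} has {len(ids)} samples < min_replicates={min_replicates}"
            if strict:
                raise ValueError(msg)
            warnings.warn(msg, stacklevel=2)
        cols[g] = (table.areas[ids] > area_threshold).sum(axis=1) >= min_replicates
    return PresenceMatrix(present=pd.DataFrame(cols)[groups])


def contamination_tau(fruit_table: FeatureTable, fly_table: FeatureTable) -> ContaminationReport:
    """Rank correlation between fruit and fly mean ion areas, per diet.

    A strong positive Kendall tau-b would indicate that fly samples are
    directly contaminated by their diet medium rather than reflecting
    metabolism; the reference analysis treats |tau| < 0.2 as absence of
    contamination.  Computed per diet over the union of ions detected on
    either side, on the shared ion universe of the two tables.
    """
    shared = fruit_table.areas.index.intersection(fly_table.areas.index)
    if len(shared) < 2:
        raise ValueError("need at least 2 shared ions")
    diets = sorted(set(fruit_table.samples["diet"].dropna()) & set(fly_table.samples["diet"].dropna()))
    rows = {}
    for diet in diets:
        fruit_mean = fruit_table.areas.loc[shared, fruit_table.sample_ids(diet=diet)].mean(axis=1)
        fly_mean = fly_table.areas.loc[shared, fly_table.sample_ids(diet=diet)].mean(axis=1)
        either = (fruit_mean > 0) | (fly_mean > 0)
        if either.sum() < 2:
            raise ValueError(f"fewer than 2 detected ions for diet {diet}")
        tau, p = stats.kendalltau(fruit_mean[either], fly_mean[either])
        rows[diet] = {"tau": float(tau), "p_value": float(p), "n_ions": int(either.sum())}
    return ContaminationReport(table=pd.DataFrame(rows).T)
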