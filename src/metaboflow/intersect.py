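"""Qualitative set algebra over the presence matrix.

Each ion's membership across the eight groups (4 fruits, then 4 fly
diets, canonical order) is encoded as an 8-bit mask; the partition of
ions by mask gives upset-style intersection sizes, per-domain
intersection degrees (0-4), and the 5x5 fruit-degree x fly-degree flow
matrix that links dietary compounds to their fate in consumers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import PresenceMatrix

__all__ = [
    "MembershipProfiles",
    "IntersectionSummary",
    "DegreeFlow",
    "membership_profiles",
    "intersection_sizes",
    "degrees",
    "flow_matrix",
    "mask_label",
]

N_DOMAIN = 4  # groups per domain (fruits / fly diets)


@dataclass
class MembershipProfiles:
    """Per-ion 8-bit masks over the canonically ordered groups.

    Bit ``i`` of a mask is set iff the ion is present in group ``i``;
    bits 0-3 are the fruits, bits 4-7 the fly diets.
    """

    ions: list[str]
    groups: list[str]
    masks: np.ndarray  # uint16, one per ion

    def __post_init__(self) -> None:
        self.masks = np.asarray(self.masks, dtype=np.uint16)
        if len(self.ions) != len(self.masks):
            raise ValueError("one mask per ion required")


@dataclass
class IntersectionSummary:
    """Exact partition of ions by membership mask."""

    counts: dict[int, int]  # mask -> ion count (empty mask retained)
    total: int
    groups: list[str]

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.total:
            raise ValueError("intersection counts must partition the ions")

    def top(self, k: int) -> list[tuple[int, int]]:
        """The k largest intersections, ties broken by ascending mask."""
        return sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))[:k]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for mask, count in sorted(self.counts.items()):
            row = {g: bool(mask >> i & 1) for i, g in enumerate(self.groups)}
            row["mask"] = mask
            row["count"] = count
            rows.append(row)
        return pd.DataFrame(rows).set_index("mask")


@dataclass
class DegreeFlow:
    """Ion counts by (fruit intersection degree, fly intersection degree)."""

    counts: np.ndarray  # (5, 5) ints; row = fruit degree, column = fly degree

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (N_DOMAIN + 1, N_DOMAIN + 1):
            raise ValueError(f"flow matrix must be {N_DOMAIN + 1}x{N_DOMAIN + 1}")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def fruit_marginal(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def fly_marginal(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        idx = [f"fruit_degree_{i}" for i in range(N_DOMAIN + 1)]
        cols = [f"fly_degree_{j}" for j in range(N_DOMAIN + 1)]
        return pd.DataFrame(self.counts, index=idx, columns=cols)


def mask_label(mask: int, groups: list[str]) -> str:
    """Human-readable name of an intersection mask."""
    members = [g for i, g in enumerate(groups) if mask >> i & 1]
    return " & ".join(members) if members else "(none)"


def membership_profiles(presence: PresenceMatrix) -> MembershipProfiles:
    """Encode the presence matrix as one membership mask per ion."""
    mat = presence.present.to_numpy(dtype=bool)
    weights = (1 << np.arange(mat.shape[1], dtype=np.uint16)).astype(np.uint16)
    masks = mat @ weights
    return MembershipProfiles(
        ions=list(presence.present.index),
        groups=list(presence.present.columns),
        masks=masks.astype(np.uint16),
    )


def intersection_sizes(profiles: MembershipProfiles) -> IntersectionSummary:
    """Count ions per intersection mask (an exact partition)."""
    values, counts = np.unique(profiles.masks, return_counts=True)
    return IntersectionSummary(
        counts={int(v): int(c) for v, c in zip(values, counts)},
        total=len(profiles.masks),
        groups=profiles.groups,
    )


def degrees(profiles: MembershipProfiles, domain: str) -> np.ndarray:
    """Per-ion intersection degree (0-4) within ``fruits`` or ``flies``."""
    if domain == "fruits":
        bits = profiles.masks & 0xF
    elif domain == "flies":
        bits = (profiles.masks >> N_DOMAIN) & 0xF
    else:
        raise ValueError(f"domain must be 'fruits' or 'flies', got {domain!r}")
    return np.bitwise_count(bits.astype(np.uint16)).astype(int)


def flow_matrix(fruit_degrees: np.ndarray, fly_degrees: np.ndarray) -> DegreeFlow:
    """Joint ion counts over (fruit degree, fly degree)."""
    fruit_degrees = np.asarray(fruit_degrees, dtype=int)
    fly_degrees = np.asarray(fly_degrees, dtype=int)
    if fruit_degrees.shape != fly_degrees.shape:
        raise ValueError("degree vectors must share the ion universe")
    counts = np.zeros((N_DOMAIN + 1, N_DOMAIN + 1), dtype=int)
    np.add.at(counts, (fruit_degrees, fly_degrees), 1)
    return DegreeFlow(counts=counts)
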