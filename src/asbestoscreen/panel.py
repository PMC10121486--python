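"""Three-rater panel aggregation and inter-rater agreement statistics.

Each application is assessed by a panel of three pulmonologists casting
binary votes; the majority sets the verdict.  This module aggregates votes
into verdicts, decomposes unanimity, and computes Krippendorff's alpha for
nominal data — the chance-corrected agreement coefficient (1 = perfect
agreement, 0 = agreement expected by chance).

Because all units share the same two categories, alpha for full three-rater
panels depends only on the per-case count of positive votes, so a
:class:`VoteTable` (cases counted by number of positive votes k = 0..3) is a
sufficient statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "PanelVotes",
    "VoteTable",
    "majority_verdict",
    "make_soft_label",
    "agreement_summary",
    "krippendorff_alpha",
    "krippendorff_alpha_from_counts",
]


def _check_votes(votes: Sequence[int]) -> tuple[int, int, int]:
    if len(votes) != 3:
        raise ValueError(f"a full panel has exactly 3 votes, got {len(votes)}")
    out = []
    for v in votes:
        if v is None:
            raise ValueError("missing vote; verdicts require a full panel")
        iv = int(v)
        if iv not in (0, 1):
            raise ValueError(f"votes must be binary, got {v}")
        out.append(iv)
    return tuple(out)


def majority_verdict(votes: Sequence[int]) -> bool:
    """Majority rule over three binary votes: positive iff >= 2 votes positive."""
    return sum(_check_votes(votes)) >= 2


def make_soft_label(votes: Sequence[int]) -> float:
    """Soft training target: the fraction of panel members voting positive."""
    return sum(_check_votes(votes)) / 3.0


@dataclass(frozen=True)
class PanelVotes:
    """Three binary assessments of one application."""

    votes: tuple[int, int, int]

    def __post_init__(self):
        object.__setattr__(self, "votes", _check_votes(self.votes))

    @property
    def n_positive(self) -> int:
        return sum(self.votes)

    @property
    def verdict(self) -> bool:
        return self.n_positive >= 2

    @property
    def unanimous(self) -> bool:
        return self.n_positive in (0, 3)

    @property
    def soft_label(self) -> float:
        return self.n_positive / 3.0


@dataclass(frozen=True)
class VoteTable:
    """Counts of cases by number of positive votes k = 0, 1, 2, 3."""

    counts: tuple[int, int, int, int]

    def __post_init__(self):
        c = tuple(int(x) for x in self.counts)
        if len(c) != 4 or any(x < 0 for x in c):
            raise ValueError("counts must be four nonnegative integers (k = 0..3)")
        object.__setattr__(self, "counts", c)

    @classmethod
    def from_votes(cls, votes: Iterable[Sequence[int]]) -> "VoteTable":
        counts = [0, 0, 0, 0]
        for v in votes:
            counts[sum(_check_votes(v))] += 1
        return cls(tuple(counts))

    @property
    def n_cases(self) -> int:
        return sum(self.counts)


def agreement_summary(table: VoteTable) -> dict:
    """Cohort-level vote decomposition with percentages to one decimal.

    Returns the case count, percent positive verdicts (k >= 2), percent
    unanimous overall (k in {0, 3}), and percent unanimous within the
    positive and negative verdict groups.
    """
    c0, c1, c2, c3 = table.counts
    n = table.n_cases
    if n == 0:
        raise ValueError("empty vote table")
    n_pos = c2 + c3
    n_neg = c0 + c1
    n_unan = c0 + c3
    summary = {
        "n": n,
        "pct_positive": round(100.0 * n_pos / n, 1),
        "pct_unanimous": round(100.0 * n_unan / n, 1),
        "pct_unanimous_positive": round(100.0 * c3 / n_pos, 1) if n_pos else float("nan"),
        "pct_unanimous_negative": round(100.0 * c0 / n_neg, 1) if n_neg else float("nan"),
    }
    return summary


def krippendorff_alpha_from_counts(unit_counts: Iterable[tuple[int, int]]) -> float:
    """Nominal Krippendorff's alpha from per-unit (positives, total ratings).

    Uses the coincidence form for two categories: observed disagreement
    ``Do = (1/N) * sum_u 2 * k_u * (m_u - k_u) / (m_u - 1)`` and expected
    disagreement ``De = 2 * N1 * N0 / (N * (N - 1))`` with ``N`` the total
    number of ratings and ``N1``/``N0`` the category marginals.  Units with
    fewer than two ratings carry no pairable information and are dropped.
    """
    n_ratings = 0
    n_pos = 0
    do_num = 0.0
    for k, m in unit_counts:
        k, m = int(k), int(m)
        if not 0 <= k <= m:
            raise ValueError(f"invalid unit counts ({k}, {m})")
        if m < 2:
            continue
        n_ratings += m
        n_pos += k
        do_num += 2.0 * k * (m - k) / (m - 1)
    if n_ratings < 2:
        raise ValueError("alpha needs at least one unit with >= 2 ratings")
    n_neg = n_ratings - n_pos
    de = 2.0 * n_pos * n_neg / (n_ratings * (n_ratings - 1))
    if de == 0.0:
        warnings.warn("all ratings identical; expected disagreement is zero, alpha defined as 1.0", stacklevel=2)
        return 1.0
    return 1.0 - (do_num / n_ratings) / de


def krippendorff_alpha(table: VoteTable) -> float:
    """Nominal Krippendorff's alpha for a cohort of full three-rater panels."""
    units = []
    for k, count in enumerate(table.counts):
        units.extend([(k, 3)] * count)
    return krippendorff_alpha_from_counts(units)
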