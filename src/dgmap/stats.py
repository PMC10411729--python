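"""Episode summaries and exact small-sample group comparison.

Episodes are labelled self-terminating (ST, < 10 s) or non-terminating
(NT, >= 10 s — the animal is defibrillated once the arrhythmia reaches
that duration, so longer episodes are non-terminating by protocol).
Groups of per-episode statistics (e.g. the average number of simultaneous
reentry loops) are compared with a Mann–Whitney U test computed exactly:
with group sizes this small (a handful of episodes per group), the full
distribution of U over all C(n1+n2, n1) assignments of the pooled values
to groups is enumerable, and ties receive the conventional half credit.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np

from .focal import FocalSource
from .reentry import ReentryTrack, SimultaneousProfile, simultaneous_profile

__all__ = [
    "NT_THRESHOLD_S",
    "EpisodeSummary",
    "GroupComparison",
    "summarize",
    "group_mean",
    "mann_whitney_exact",
]

NT_THRESHOLD_S = 10.0  # episodes at least this long are non-terminating

#: beyond this pooled size the exact enumeration is replaced by the
#: normal approximation with tie correction
_EXACT_LIMIT = 25


@dataclass
class EpisodeSummary:
    """Headline numbers for one arrhythmia episode."""

    episode_id: str
    label: str  # ST | NT
    duration_s: float
    mean_loops: float
    max_loops: int
    n_tracks: int
    holo_fraction_pct: float | None
    n_focal_beats: int
    profile: SimultaneousProfile | None = None


def summarize(
    tracks: list[ReentryTrack],
    focal_sources: list[FocalSource],
    episode_id: str = "episode",
    duration_s: float | None = None,
    episode_span: tuple[float, float] | None = None,
) -> EpisodeSummary:
    """Aggregate one episode's tracks and verified focal sources.

    The loop statistics are computed over reentry-present time (the
    simultaneous-loop profile); focal beats are counted over the whole
    episode.  The ST/NT label follows the 10 s rule.
    """
    prof = simultaneous_profile(tracks, episode_span)
    if duration_s is None:
        stops = [tr.end for tr in tracks] + [s.time for s in focal_sources]
        starts = [tr.start for tr in tracks] + [s.time for s in focal_sources]
        duration_s = ((max(stops) - min(starts)) / 1000.0) if stops else 0.0
    label = "NT" if duration_s >= NT_THRESHOLD_S else "ST"
    return EpisodeSummary(
        episode_id=episode_id,
        label=label,
        duration_s=duration_s,
        mean_loops=prof.mean_loops,
        max_loops=prof.max_loops,
        n_tracks=prof.n_tracks,
        holo_fraction_pct=prof.holo_fraction_pct,
        n_focal_beats=len(focal_sources),
        profile=prof,
    )


def group_mean(values) -> float:
    """Arithmetic mean of a non-empty group of per-episode statistics."""
    values = np.asarray(values, float)
    if values.size == 0:
        raise ValueError("empty group")
    return float(values.mean())


@dataclass
class GroupComparison:
    """Exact Mann–Whitney comparison of two small groups."""

    u: float  # min(U1, U2), ties given half credit
    u1: float
    u2: float
    p_one_sided: float
    p_two_sided: float
    n1: int
    n2: int
    method: str  # exact | normal


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for group a: #(a > b) pairs + half credit for ties."""
    gt = (a[:, None] > b[None, :]).sum()
    eq = (a[:, None] == b[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def mann_whitney_exact(a, b) -> GroupComparison:
    """Mann–Whitney U with the exact permutation distribution.

    U = min(U1, U2).  The one-sided p is the probability, over all
    C(n1+n2, n1) equally likely assignments of the pooled values to the
    two groups, that a group's U is at most the observed minimum; the
    two-sided p counts both tails, P(min(U1, U2) <= u_obs).  For pooled
    sizes beyond 25 the normal approximation with tie correction is used.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n1, n2 = len(a), len(b)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")

    u1 = _u_statistic(a, b)
    u2 = _u_statistic(b, a)
    u = min(u1, u2)

    if n1 + n2 <= _EXACT_LIMIT:
        pooled = np.concatenate([a, b])
        idx = range(n1 + n2)
        total = comb(n1 + n2, n1)
        lower_one = 0  # assignments with U_a <= u
        lower_min = 0  # assignments with min(U) <= u
        for picks in combinations(idx, n1):
            mask = np.zeros(n1 + n2, bool)
            mask[list(picks)] = True
            ua = _u_statistic(pooled[mask], pooled[~mask])
            if ua <= u + 1e-12:
                lower_one += 1
                lower_min += 1
            elif n1 * n2 - ua <= u + 1e-12:  # U_b = n1*n2 - U_a (with ties, still)
                lower_min += 1
        p_one = lower_one / total
        p_two = lower_min / total
        method = "exact"
    else:
        from scipy.stats import tiecorrect, rankdata

        pooled = np.concatenate([a, b])
        t = tiecorrect(rankdata(pooled))
        mu = n1 * n2 / 2.0
        sd = np.sqrt(t * n1 * n2 * (n1 + n2 + 1) / 12.0)
        from scipy.stats import norm

        z = (u - mu + 0.5) / sd  # continuity corrected, lower tail
        p_one = float(norm.cdf(z))
        p_two = min(1.0, 2.0 * p_one)
        method = "normal"

    return GroupComparison(
        u=u, u1=u1, u2=u2,
        p_one_sided=p_one, p_two_sided=min(1.0, p_two),
        n1=n1, n2=n2, method=method,
    )
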