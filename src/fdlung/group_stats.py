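"""Nonparametric comparison of fitted parameters across exposure groups.

The study design this mirrors compares small cohorts (e.g. n = 5/5/6) of
subjects per exposure group on each fitted curve parameter and each A/B
ratio: a Kruskal-Wallis (KW) test across all groups, then pairwise
Mann-Whitney post hoc (MWph) tests for every group pair. Post hoc p-values
are reported raw alongside the KW p — no multiple-testing correction by
default, matching the original reporting style — with an optional Holm
adjustment for users who want a stricter rule. All tests are two-sided.

Statistic computation (H, U, asymptotic p with tie correction) is delegated
to scipy.stats; exact small-sample p-values — the KW permutation null for
total n <= 12 and the tie-aware MW enumeration — are computed here by
explicit enumeration, which at these sample sizes is cheap and removes any
reliance on asymptotics exactly where they are weakest.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ParameterError, ValidationError

__all__ = [
    "TestResult",
    "PairResult",
    "ParameterComparison",
    "CohortComparison",
    "kruskal_wallis",
    "mann_whitney",
    "compare_groups",
]

#: Largest pooled sample size for which the KW permutation null is enumerated.
KW_EXACT_MAX_N = 12
#: Largest per-side size for which the MW null is enumerated in auto mode.
MW_EXACT_MAX_N = 8


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    n_per_group: tuple[int, ...]


@dataclass
class PairResult:
    group_a: str
    group_b: str
    test: TestResult
    significant: bool  # raw post hoc decision at alpha
    significant_gated: bool  # post hoc decision gated on KW significance


@dataclass
class ParameterComparison:
    parameter: str
    kw: TestResult
    pairs: list[PairResult]


@dataclass
class CohortComparison:
    alpha: float
    comparisons: dict[str, ParameterComparison] = field(default_factory=dict)

    def flagged(self, parameter: str, group_a: str, group_b: str, gated: bool = True) -> bool:
        """Whether the (group_a, group_b) contrast of ``parameter`` is significant."""
        comp = self.comparisons[parameter]
        key = {group_a, group_b}
        for pair in comp.pairs:
            if {pair.group_a, pair.group_b} == key:
                return pair.significant_gated if gated else pair.significant
        raise KeyError(f"no pair ({group_a}, {group_b}) for parameter {parameter}")

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "parameters": {
                name: {
                    "kw": {
                        "H": comp.kw.statistic,
                        "p": comp.kw.p_value,
                        "method": comp.kw.method,
                    },
                    "pairs": [
                        {
                            "a": p.group_a,
                            "b": p.group_b,
                            "U": p.test.statistic,
                            "p": p.test.p_value,
                            "method": p.test.method,
                            "significant": p.significant,
                            "significant_gated": p.significant_gated,
                        }
                        for p in comp.pairs
                    ],
                }
                for name, comp in self.comparisons.items()
            },
        }


def _h_from_ranks(ranks: np.ndarray, sizes: Sequence[int], tie_term: float) -> float:
    """KW H from pooled mid-ranks split into consecutive groups."""
    n = len(ranks)
    h = 0.0
    start = 0
    for m in sizes:
        rsum = float(ranks[start : start + m].sum())
        h += rsum * rsum / m
        start += m
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    return h / tie_term if tie_term > 0 else 0.0


def _tie_term(pooled: np.ndarray) -> float:
    n = len(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    return 1.0 - float(np.sum(counts**3 - counts)) / (n**3 - n)


def kruskal_wallis(groups: Sequence[Sequence[float]], method: str = "auto") -> TestResult:
    """Kruskal-Wallis H test across two or more groups.

    H uses mid-ranks with the standard tie correction. The p-value comes
    from the chi-square reference (df = k - 1), or — when ``method`` is
    ``"exact"``, or ``"auto"`` with pooled n <= 12 — from full enumeration
    of the permutation null of group assignments.

    All-identical data (every rank tied) gives H = 0, p = 1.
    """
    arrays = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(arrays) < 2:
        raise ParameterError("Kruskal-Wallis needs at least 2 groups")
    if any(len(a) < 2 for a in arrays):
        raise ParameterError("every group needs at least 2 values")
    sizes = tuple(len(a) for a in arrays)
    pooled = np.concatenate(arrays)
    n = len(pooled)

    if np.unique(pooled).size == 1:
        return TestResult(0.0, 1.0, "kw", sizes)

    ranks = sps.rankdata(pooled)
    tie = _tie_term(pooled)
    h_obs = _h_from_ranks(ranks, sizes, tie)

    exact = method == "exact" or (method == "auto" and n <= KW_EXACT_MAX_N)
    if not exact:
        p = float(sps.chi2.sf(h_obs, len(sizes) - 1))
        return TestResult(h_obs, p, "kw", sizes)

    # Enumerate every split of the pooled ranks into groups of the given sizes.
    count = 0
    total = 0
    indices = np.arange(n)

    def _splits(avail: np.ndarray, remaining: tuple[int, ...]):
        if len(remaining) == 1:
            yield (avail,)
            return
        m = remaining[0]
        # fix the smallest available index in the first group is NOT valid for
        # unequal sizes; enumerate plainly
        for combo in itertools.combinations(range(len(avail)), m):
            chosen = avail[list(combo)]
            rest = np.delete(avail, list(combo))
            for tail in _splits(rest, remaining[1:]):
                yield (chosen, *tail)

    for split in _splits(indices, sizes):
        perm_ranks = np.concatenate([ranks[part] for part in split])
        h = _h_from_ranks(perm_ranks, sizes, tie)
        total += 1
        if h >= h_obs - 1e-12:
            count += 1
    return TestResult(h_obs, count / total, "kw_exact", sizes)


def _mw_u(ranks_a: np.ndarray, n_a: int) -> float:
    return float(ranks_a.sum() - n_a * (n_a + 1) / 2.0)


def mann_whitney(
    a: Sequence[float], b: Sequence[float], mode: str = "auto"
) -> TestResult:
    """Two-sided Mann-Whitney U test.

    ``exact`` enumerates all C(n_a + n_b, n_a) label assignments on pooled
    mid-ranks (ties handled naturally); the two-sided p is
    ``min(1, 2 * min(P(U <= u), P(U >= u)))``. ``normal`` uses the
    tie-corrected normal approximation with continuity correction (scipy).
    ``auto`` picks exact when both sides have <= 8 values and there are no
    ties, else normal.
    """
    xa = np.asarray(a, dtype=float).ravel()
    xb = np.asarray(b, dtype=float).ravel()
    if len(xa) == 0 or len(xb) == 0:
        raise ParameterError("both sides of a Mann-Whitney test must be non-empty")
    n_a, n_b = len(xa), len(xb)
    pooled = np.concatenate([xa, xb])
    has_ties = np.unique(pooled).size < len(pooled)

    if mode == "auto":
        mode = "exact" if (max(n_a, n_b) <= MW_EXACT_MAX_N and not has_ties) else "normal"
    if mode == "normal":
        u, p = sps.mannwhitneyu(
            xa, xb, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        return TestResult(float(u), float(p), "mw_normal", (n_a, n_b))
    if mode != "exact":
        raise ParameterError(f"mode must be exact, normal or auto, got {mode!r}")

    ranks = sps.rankdata(pooled)
    u_obs = _mw_u(ranks[:n_a], n_a)
    total = comb(n_a + n_b, n_a)
    le = 0
    ge = 0
    for combo in itertools.combinations(range(n_a + n_b), n_a):
        u = _mw_u(ranks[list(combo)], n_a)
        if u <= u_obs + 1e-12:
            le += 1
        if u >= u_obs - 1e-12:
            ge += 1
    p = min(1.0, 2.0 * min(le, ge) / total)
    return TestResult(u_obs, p, "mw_exact", (n_a, n_b))


def compare_groups(
    table: pd.DataFrame,
    parameters: Sequence[str],
    group_col: str = "group",
    alpha: float = 0.05,
    correction: str | None = None,
) -> CohortComparison:
    """KW across groups plus pairwise MW post hoc tests, per parameter.

    ``table`` holds one row per subject with a group label column and one
    column per parameter. Post hoc p-values are raw by default
    (``correction=None``); ``correction="holm"`` applies a Holm step-down
    adjustment across the pairs of each parameter. Each pair carries two
    decisions: ``significant`` (raw MW p < alpha) and ``significant_gated``
    (additionally requires KW p < alpha).
    """
    if not 0 < alpha < 1:
        raise ParameterError(f"alpha must be in (0, 1), got {alpha}")
    if correction not in (None, "holm"):
        raise ParameterError(f"correction must be None or 'holm', got {correction!r}")
    if group_col not in table.columns:
        raise ValidationError(f"table has no group column {group_col!r}")
    group_names = list(dict.fromkeys(table[group_col]))
    if len(group_names) < 2:
        raise ValidationError("need at least 2 groups")

    result = CohortComparison(alpha=alpha)
    for name in parameters:
        if name not in table.columns:
            raise ParameterError(f"parameter {name!r} missing from the table")
        by_group = {g: table.loc[table[group_col] == g, name].to_numpy(float) for g in group_names}
        kw = kruskal_wallis(list(by_group.values()))
        pair_tests = [
            (ga, gb, mann_whitney(by_group[ga], by_group[gb]))
            for ga, gb in itertools.combinations(group_names, 2)
        ]
        p_vals = np.array([t.p_value for _, _, t in pair_tests])
        if correction == "holm":
            order = np.argsort(p_vals)
            adj = np.empty_like(p_vals)
            running = 0.0
            for rank, idx in enumerate(order):
                running = max(running, (len(p_vals) - rank) * p_vals[idx])
                adj[idx] = min(1.0, running)
            p_vals = adj
        pairs = []
        for (ga, gb, test), p_adj in zip(pair_tests, p_vals):
            sig = bool(p_adj < alpha)
            pairs.append(
                PairResult(ga, gb, test, sig, sig and kw.p_value < alpha)
            )
        result.comparisons[name] = ParameterComparison(name, kw, pairs)
    return result
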