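"""Nonparametric statistics: Kruskal-Wallis, Dunn's test, bootstrap CIs.

All tests use mid-ranks with the standard tie-correction factor.  Dunn's
pairwise z statistics are computed from pooled ranks:

    z_ij = (R̄_i − R̄_j) / sqrt( (N(N+1)/12 − ΣT/(12(N−1))) (1/n_i + 1/n_j) )

with ΣT = Σ(t³ − t) over tie groups, two-sided normal p values, and
optional Holm or Bonferroni correction (the default is no correction,
reporting raw p values).

Note on usage: the convention followed here — Dunn's test for two-group
comparisons and Kruskal-Wallis for three or more — treats Dunn's z as a
standalone two-sample statistic rather than strictly as a post-hoc
procedure.  That usage is unconventional but implemented as stated; with
two groups the Dunn z and the Kruskal-Wallis H are monotonically related
(H = z²).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .errors import ConfigurationError, DataError


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    groups: tuple[str, ...]
    correction: str = "none"
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value outside [0, 1]")

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def _as_groups(groups) -> tuple[list[np.ndarray], list[str]]:
    if isinstance(groups, Mapping):
        names = list(groups.keys())
        arrs = [np.asarray(groups[k], dtype=float) for k in names]
    else:
        arrs = [np.asarray(g, dtype=float) for g in groups]
        names = [f"g{i}" for i in range(len(arrs))]
    if any(len(a) == 0 for a in arrs):
        raise DataError("all groups must be nonempty")
    return arrs, names


def kruskal_wallis(groups, alpha: float = 0.05) -> TestResult:
    """Kruskal-Wallis H with tie correction; p from chi-square (k−1 df)."""
    arrs, names = _as_groups(groups)
    if len(arrs) < 2:
        raise DataError("need at least two groups")
    if sum(len(a) for a in arrs) < 3:
        raise DataError("need at least 3 observations in total")
    pooled = np.concatenate(arrs)
    if np.all(pooled == pooled[0]):
        return TestResult(statistic=0.0, p_value=1.0, groups=tuple(names), alpha=alpha)
    h, p = sps.kruskal(*arrs)
    return TestResult(statistic=float(h), p_value=float(p), groups=tuple(names),
                      alpha=alpha)


def _tie_term(pooled: np.ndarray) -> float:
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts ** 3 - counts))


def dunn_test(groups, correction: str = "none",
              alpha: float = 0.05) -> list[TestResult]:
    """Pairwise Dunn z tests on pooled mid-ranks with tie correction."""
    if correction not in ("none", "holm", "bonferroni"):
        raise ConfigurationError(f"unknown correction {correction!r}")
    arrs, names = _as_groups(groups)
    k = len(arrs)
    if k < 2:
        raise DataError("need at least two groups")
    pooled = np.concatenate(arrs)
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)
    sizes = [len(a) for a in arrs]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [ranks[bounds[i]:bounds[i + 1]].mean() for i in range(k)]
    var = (n_total * (n_total + 1) / 12.0
           - _tie_term(pooled) / (12.0 * (n_total - 1)))

    pairs, zs, ps = [], [], []
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(var * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
            p = 1.0 if se == 0 else 2.0 * sps.norm.sf(abs(z))
            pairs.append((names[i], names[j]))
            zs.append(float(z))
            ps.append(float(min(p, 1.0)))

    m = len(ps)
    if correction == "bonferroni":
        adj = [min(p * m, 1.0) for p in ps]
    elif correction == "holm":
        order = np.argsort(ps)
        adj = [0.0] * m
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * ps[idx])
            adj[idx] = min(running, 1.0)
    else:
        adj = ps
    return [
        TestResult(statistic=z, p_value=p, groups=pair, correction=correction,
                   alpha=alpha)
        for z, p, pair in zip(zs, adj, pairs)
    ]


def bootstrap_ci(values: np.ndarray, statistic: Callable[[np.ndarray], float],
                 n_boot: int = 2000, ci_level: float = 0.95,
                 seed: int = 0) -> tuple[float, float, float]:
    """Percentile bootstrap (mean of resampled statistics, low, high)."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise DataError("need at least 2 observations")
    if n_boot < 100:
        raise ConfigurationError("n_boot must be >= 100")
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 37]))
    n = len(values)
    boots = np.array([
        statistic(values[rng.integers(0, n, size=n)]) for _ in range(n_boot)
    ])
    alpha = (1.0 - ci_level) / 2.0
    lo = float(np.quantile(boots, alpha))
    hi = float(np.quantile(boots, 1.0 - alpha))
    point = float(boots.mean())
    return point, min(lo, point), max(hi, point)


@dataclass
class AreaAnalysis:
    areas: dict[str, np.ndarray]
    omnibus: TestResult
    pairwise: list[TestResult]
    flagged: list[str]  # annotators significantly below the rest (never excluded)


def annotation_area_analysis(masks_by_annotator: Mapping[str, Sequence[np.ndarray]],
                             alpha: float = 0.05,
                             correction: str = "none") -> AreaAnalysis:
    """Interobserver variability via per-image annotated areas.

    Uses the area of each annotation map as the variability index, runs a
    Kruskal-Wallis omnibus test across annotators and Dunn pairwise tests,
    and flags annotators whose areas are significantly below every other
    annotator's.  Flagged annotators are reported, never excluded.
    """
    if len(masks_by_annotator) < 2:
        raise DataError("need at least two annotators")
    areas = {
        a: np.array([float(np.asarray(m, dtype=bool).sum()) for m in masks],
                    dtype=float)
        for a, masks in masks_by_annotator.items()
    }
    omnibus = kruskal_wallis(areas, alpha=alpha)
    pairwise = dunn_test(areas, correction=correction, alpha=alpha)
    medians = {a: float(np.median(v)) for a, v in areas.items()}
    flagged = []
    for a in areas:
        others = [r for r in pairwise if a in r.groups]
        below = all(medians[a] < medians[b] for b in areas if b != a)
        if below and all(r.p_value < alpha for r in others):
            flagged.append(a)
    return AreaAnalysis(areas=areas, omnibus=omnibus, pairwise=pairwise,
                        flagged=flagged)
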