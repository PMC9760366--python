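"""Statistical layer: one-way ANOVA, Dunnett many-to-one comparisons
against the vehicle control, and a dose-response trend test.

Dunnett's procedure controls the familywise error rate over the set of
treatment-vs-control comparisons; adjusted p-values come from the
multivariate-t distribution of the comparison statistics (evaluated by
seeded quasi-Monte-Carlo in scipy), while raw p-values use the same
pooled-variance t statistics uncorrected. The dose-response test is a
Jonckheere-Terpstra ordered-alternative statistic with a label-permutation
p-value; a compound is flagged dose-dependently monotone when the
permutation p is at or below alpha and the trend runs downward.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateDataError

ALPHA = 0.05


@dataclass
class ComparisonResult:
    """One treatment-vs-control comparison."""

    condition: str
    mean: float
    control_mean: float
    statistic: float
    raw_p: float
    adjusted_p: float
    significant: bool
    direction: str  # "above" | "below"


@dataclass
class TrendResult:
    """Ordered-alternative dose-response test for one compound."""

    compound: str
    doses: tuple[float, ...]
    statistic: float
    expected: float
    permutation_p: float
    direction: str  # "decreasing" | "increasing" | "flat"
    monotone: bool  # significant *decreasing* trend


def _as_groups(groups) -> tuple[list[str], list[np.ndarray]]:
    if isinstance(groups, dict):
        labels = list(groups)
        arrays = [np.asarray(groups[k], dtype=float) for k in labels]
    else:
        arrays = [np.asarray(g, dtype=float) for g in groups]
        labels = [f"group{i + 1}" for i in range(len(arrays))]
    return labels, arrays


def dunnett_many_to_one(
    groups,
    control,
    alpha: float = ALPHA,
    seed: int | None = 0,
) -> list[ComparisonResult]:
    """Two-sided Dunnett comparisons of each group against the control.

    ``groups`` is a mapping ``label -> values`` (or a sequence of value
    arrays). Each group and the control need n >= 2. The adjusted p-values
    are reproducible for a fixed ``seed`` (the multivariate-t tail is
    integrated by quasi-Monte-Carlo). All-zero within-group variance is
    degenerate and rejected.
    """
    labels, arrays = _as_groups(groups)
    control = np.asarray(control, dtype=float)
    if control.size < 2 or any(a.size < 2 for a in arrays):
        raise DegenerateDataError("each group (and the control) needs n >= 2")
    if not arrays:
        return []

    all_groups = arrays + [control]
    pooled_ss = sum(((a - a.mean()) ** 2).sum() for a in all_groups)
    df = sum(a.size for a in all_groups) - len(all_groups)
    if pooled_ss <= 0:
        raise DegenerateDataError("zero within-group variance everywhere")
    s2 = pooled_ss / df

    res = stats.dunnett(*arrays, control=control, alternative="two-sided",
                        rng=np.random.default_rng(seed))

    out = []
    cmean = float(control.mean())
    for label, a, t, p_adj in zip(labels, arrays, res.statistic, res.pvalue):
        se = np.sqrt(s2 * (1.0 / a.size + 1.0 / control.size))
        t_raw = (a.mean() - cmean) / se
        raw_p = 2.0 * stats.t.sf(abs(t_raw), df)
        p_adj = float(min(max(p_adj, raw_p), 1.0))  # adjusted never below raw
        out.append(ComparisonResult(
            condition=label,
            mean=float(a.mean()),
            control_mean=cmean,
            statistic=float(t),
            raw_p=float(raw_p),
            adjusted_p=p_adj,
            significant=p_adj <= alpha,
            direction="above" if a.mean() > cmean else "below",
        ))
    return out


def anova_oneway(groups) -> tuple[float, float]:
    """One-way ANOVA F statistic and p-value across >= 2 groups."""
    _, arrays = _as_groups(groups)
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise DegenerateDataError("ANOVA needs >= 2 groups with n >= 2 each")
    if all(a.std() == 0 for a in arrays):
        raise DegenerateDataError("zero within-group variance everywhere")
    f, p = stats.f_oneway(*arrays)
    return float(f), float(p)


def _jt_statistic(values: np.ndarray, group_sizes: np.ndarray) -> float:
    """Jonckheere-Terpstra statistic for groups laid out consecutively in
    ``values`` in increasing dose order (ties count half)."""
    bounds = np.concatenate([[0], np.cumsum(group_sizes)])
    t = 0.0
    for i in range(len(group_sizes) - 1):
        x = values[bounds[i]:bounds[i + 1]]
        for j in range(i + 1, len(group_sizes)):
            y = values[bounds[j]:bounds[j + 1]]
            diff = y[:, None] - x[None, :]
            t += (diff > 0).sum() + 0.5 * (diff == 0).sum()
    return float(t)


def trend_test(
    doses: Sequence[float],
    values_per_dose: Sequence[Sequence[float]],
    compound: str = "",
    n_permutations: int = 10_000,
    alpha: float = ALPHA,
    seed: int | None = 0,
) -> TrendResult:
    """Dose-ordered trend test with a permutation p-value.

    ``values_per_dose[i]`` holds the replicate percent-of-control signals
    at ``doses[i]``. The Jonckheere-Terpstra statistic counts concordant
    pairs across increasing doses; its two-sided permutation p-value is
    ``(1 + #{|T* - E| >= |T - E|}) / (B + 1)``. ``monotone`` is True for a
    significant decreasing trend (dose-dependent inhibition).
    """
    if len(doses) < 3:
        raise ValueError("trend test needs >= 3 dose levels")
    if len(doses) != len(values_per_dose):
        raise ValueError("doses and values_per_dose lengths differ")
    order = np.argsort(doses)
    arrays = [np.asarray(values_per_dose[i], dtype=float) for i in order]
    if any(a.size < 2 for a in arrays):
        raise ValueError("each dose level needs >= 2 replicates")
    sizes = np.array([a.size for a in arrays])
    pooled = np.concatenate(arrays)

    # E[T] under exchangeability
    expected = float(sum(sizes[i] * sizes[j]
                         for i in range(len(sizes))
                         for j in range(i + 1, len(sizes))) / 2.0)
    t_obs = _jt_statistic(pooled, sizes)

    rng = np.random.default_rng(seed)
    dev = abs(t_obs - expected)
    hits = 0
    work = pooled.copy()
    for _ in range(n_permutations):
        rng.shuffle(work)
        if abs(_jt_statistic(work, sizes) - expected) >= dev - 1e-12:
            hits += 1
    p = (1 + hits) / (n_permutations + 1)

    if t_obs < expected:
        direction = "decreasing"
    elif t_obs > expected:
        direction = "increasing"
    else:
        direction = "flat"
    return TrendResult(
        compound=compound,
        doses=tuple(float(doses[i]) for i in order),
        statistic=t_obs,
        expected=expected,
        permutation_p=float(p),
        direction=direction,
        monotone=(p <= alpha and direction == "decreasing"),
    )


def significance_stars(p: float) -> str:
    """Star notation: * p<0.05, ** p<0.01, *** p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""
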