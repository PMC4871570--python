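"""Pre-analysis predictor reduction by within-group pairwise correlation.

Predictors are tagged with a "property group" (temperature-related,
precipitation-related, ...).  When two predictors of the same group are
correlated more strongly than the threshold (|r| > 0.90 by default,
strictly greater), the lower-priority member of the pair is removed;
cross-group pairs are never removed, however collinear.  Removal is
iterated until no same-group pair exceeds the threshold, which makes
screening idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import ScreeningError

__all__ = ["ScreeningReport", "screen_predictors"]


@dataclass
class ScreeningReport:
    retained: list[str]
    removed: list[tuple[str, str, float]] = field(default_factory=list)
    # removed entries: (dropped predictor, retained partner, r at removal)
    correlations: pd.DataFrame | None = None


def screen_predictors(
    env: pd.DataFrame,
    groups: dict[str, str],
    r_max: float = 0.90,
    priority: list[str] | None = None,
) -> tuple[pd.DataFrame, ScreeningReport]:
    """Drop same-group predictors correlated at |r| strictly above ``r_max``.

    ``priority`` lists predictors from most to least worth keeping; of a
    flagged pair the member further down the list (or unlisted) is
    removed.  Ties among unlisted predictors break by column order, the
    later column being removed.  Returns the reduced table and a report
    with the full correlation matrix and the removal log.
    """
    missing = [c for c in env.columns if c not in groups]
    if missing:
        raise ScreeningError(f"predictors missing from the group map: {missing}")

    corr = env.corr(method="pearson")
    priority = priority or []

    def keep_rank(name: str) -> tuple[int, int]:
        if name in priority:
            return (0, priority.index(name))
        return (1, list(env.columns).index(name))

    retained = list(env.columns)
    removed: list[tuple[str, str, float]] = []
    while True:
        worst = None
        for i, a in enumerate(retained):
            for b in retained[i + 1:]:
                if groups[a] != groups[b]:
                    continue
                r = abs(corr.loc[a, b])
                if r > r_max and (worst is None or r > worst[0]):
                    worst = (r, a, b)
        if worst is None:
            break
        r, a, b = worst
        drop, keep = (b, a) if keep_rank(a) <= keep_rank(b) else (a, b)
        retained.remove(drop)
        removed.append((drop, keep, float(corr.loc[drop, keep])))

    report = ScreeningReport(
        retained=retained, removed=removed, correlations=corr
    )
    return env[retained], report
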