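"""Mean-variance (Taylor's law) diagnostics.

Across biological groups, variance typically rises with the mean — often a
power law, so log SD is nearly linear in log mean with correlations above
0.9.  This module computes per-group moments and the log-log mean-SD
correlation and regression slope, the standard way to screen grouped data
for that coupling (and for its inversion near ceilings/floors).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["GroupMoments", "TaylorFit", "group_moments", "taylor_fit"]


@dataclass(frozen=True)
class GroupMoments:
    """Sample moments of one group.

    ``sd`` uses the n-1 denominator.  ``cv`` (= sd/mean) is ``None`` when the
    mean is not positive, where a coefficient of variation has no meaning.
    """

    group: object
    n: int
    mean: float
    sd: float
    stratum: object = None

    @property
    def cv(self) -> float | None:
        if self.mean <= 0:
            return None
        return self.sd / self.mean


@dataclass(frozen=True)
class TaylorFit:
    """Log-scale mean-SD association across groups.

    ``r`` is the Pearson correlation of log(mean) and log(SD); ``slope`` and
    ``intercept`` are the least-squares line log(SD) ~ log(mean).  The slope
    is the Taylor-exponent analogue on the SD scale (b/2 if variance scales
    as mean^b).  ``excluded`` lists the groups dropped before fitting, with
    reasons; they are reported, never silently discarded.
    """

    r: float
    slope: float
    intercept: float
    n_groups: int
    excluded: tuple[tuple[object, str], ...]
    log_base: float
    weighted: bool
    stratum: object = None


def group_moments(
    data: Mapping[object, Sequence[float]] | pd.DataFrame | Sequence[Sequence[float]],
    group_col: str = "group",
    value_col: str = "response",
    stratum_col: str | None = None,
) -> list[GroupMoments]:
    """Exact sample moments per group.

    ``data`` may be a mapping of group label to responses, a sequence of
    per-group arrays (labelled 0, 1, ...), or a long-format DataFrame with
    ``group_col``/``value_col`` columns (plus an optional stratum column,
    e.g. sex).  Every group needs at least two observations.
    """
    items: list[tuple[object, object, np.ndarray]] = []
    if isinstance(data, pd.DataFrame):
        keys = [group_col] + ([stratum_col] if stratum_col else [])
        for key, sub in data.groupby(keys, sort=True, observed=True):
            if stratum_col:
                items.append((key[0], key[1], sub[value_col].to_numpy(float)))
            else:
                key = key[0] if isinstance(key, tuple) else key
                items.append((key, None, sub[value_col].to_numpy(float)))
    elif isinstance(data, Mapping):
        items = [(g, None, np.asarray(v, float)) for g, v in data.items()]
    else:
        items = [(i, None, np.asarray(v, float)) for i, v in enumerate(data)]

    out = []
    for group, stratum, values in items:
        if values.size < 2:
            raise ValueError(
                f"group {group!r} has {values.size} observation(s); need >= 2"
            )
        out.append(
            GroupMoments(
                group=group,
                n=int(values.size),
                mean=float(values.mean()),
                sd=float(values.std(ddof=1)),
                stratum=stratum,
            )
        )
    return out


def _fit_one(
    moments: Sequence[GroupMoments],
    log_base: float,
    weighted: bool,
    stratum: object,
) -> TaylorFit:
    usable, excluded = [], []
    for m in moments:
        if m.mean <= 0:
            excluded.append((m.group, "non-positive mean"))
        elif m.sd <= 0:
            excluded.append((m.group, "zero SD"))
        else:
            usable.append(m)
    if len(usable) < 3:
        raise ValueError(
            f"need >= 3 usable groups for a mean-SD fit, have {len(usable)} "
            f"(excluded: {excluded})"
        )
    scale = math.log(log_base)
    x = np.array([math.log(m.mean) / scale for m in usable])
    y = np.array([math.log(m.sd) / scale for m in usable])
    w = np.array([m.n for m in usable], dtype=float) if weighted else None
    if weighted:
        # weighted Pearson correlation and weighted least squares
        def wmean(v):
            return np.average(v, weights=w)

        xc, yc = x - wmean(x), y - wmean(y)
        r = float(
            np.average(xc * yc, weights=w)
            / math.sqrt(np.average(xc * xc, weights=w) * np.average(yc * yc, weights=w))
        )
        slope = float(np.average(xc * yc, weights=w) / np.average(xc * xc, weights=w))
        intercept = float(wmean(y) - slope * wmean(x))
    else:
        lr = stats.linregress(x, y)
        r, slope, intercept = float(lr.rvalue), float(lr.slope), float(lr.intercept)
    return TaylorFit(
        r=r,
        slope=slope,
        intercept=intercept,
        n_groups=len(usable),
        excluded=tuple(excluded),
        log_base=log_base,
        weighted=weighted,
        stratum=stratum,
    )


def taylor_fit(
    moments: Sequence[GroupMoments],
    log_base: float = 10.0,
    weighted: bool = False,
    stratify: bool = False,
) -> TaylorFit | dict[object, TaylorFit]:
    """Correlation and regression of log(SD) on log(mean) across groups.

    Groups with non-positive mean or zero SD are excluded (and reported).
    The correlation does not depend on the log base; the slope and intercept
    do, and base 10 is the plotting convention.  ``weighted=True`` weights
    groups by their sample size.  With ``stratify=True`` the fit is done
    separately per ``stratum`` label (e.g. one fit per sex) and a dict of
    fits is returned.
    """
    if log_base <= 0 or log_base == 1:
        raise ValueError(f"log_base must be positive and != 1, got {log_base}")
    if not stratify:
        return _fit_one(moments, log_base, weighted, stratum=None)
    strata: dict[object, list[GroupMoments]] = {}
    for m in moments:
        strata.setdefault(m.stratum, []).append(m)
    return {
        s: _fit_one(ms, log_base, weighted, stratum=s) for s, ms in strata.items()
    }
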