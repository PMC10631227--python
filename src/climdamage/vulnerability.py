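"""Distribution of physical impacts across demographic groups.

Physical impacts are allocated to groups through exposure shares: for
each region the share of a sector's impact incident on each group,
together with the group's share of the regional population.  Shares are
held constant over time (no demographic projection).  The module reports
impact rates per 100 000 group members and differential-risk metrics
(rate ratio and absolute rate difference) against a reference population,
which defaults to the complement of the group ("all others").

The tract-level arithmetic this emulates is linear aggregation, so the
region x group coarsening is exact given correct shares.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError
from .scenarios import REGIONS

__all__ = ["GroupShares", "GroupImpactResult", "allocate_group_impacts",
           "differential_risk", "default_group_shares"]


@dataclass(frozen=True)
class GroupShares:
    """Exposure-share matrices for one categorisation axis.

    ``population_share[g][r]`` is the fraction of region ``r``'s
    population in group ``g``; ``impact_share[g][r]`` the fraction of the
    region's impact incident on the group.  When the axis is exhaustive
    (``exhaustive=True``) both must sum to 1 over groups per region.
    """

    axis: str
    groups: tuple
    population_share: pd.DataFrame   # groups x regions
    impact_share: pd.DataFrame       # groups x regions
    exhaustive: bool = True

    def __post_init__(self):
        for name, df in (("population_share", self.population_share),
                         ("impact_share", self.impact_share)):
            missing = set(REGIONS) - set(df.columns)
            if missing:
                raise InvalidArgumentError(
                    f"{name} missing regions {sorted(missing)}")
            if list(df.index) != list(self.groups):
                raise InvalidArgumentError(f"{name} rows must match groups")
            if (df.to_numpy() < 0).any() or (df.to_numpy() > 1).any():
                raise InvalidArgumentError(f"{name} must lie in [0, 1]")
        if self.exhaustive:
            for name, df in (("population_share", self.population_share),
                             ("impact_share", self.impact_share)):
                col = df[list(REGIONS)].sum(axis=0)
                if np.any(np.abs(col.to_numpy() - 1.0) > 1e-9):
                    raise InvalidArgumentError(
                        f"{name} must sum to 1 per region for an "
                        f"exhaustive axis {self.axis!r}")


@dataclass(frozen=True)
class GroupImpactResult:
    """Allocated impact for one group (one sector-year slice)."""

    axis: str
    group: str
    impact: float            # physical units/yr
    population: float        # persons in the group
    rate: float              # impact per 100 000 group members
    risk_ratio: float        # vs reference population
    rate_difference: float   # per 100 000


def differential_risk(group_rate: float, reference_rate: float,
                      ) -> tuple[float, float]:
    """Rate ratio and absolute rate difference vs the reference rate."""
    if reference_rate == 0:
        raise InvalidArgumentError(
            "risk ratio undefined for zero reference rate")
    return group_rate / reference_rate, group_rate - reference_rate


def allocate_group_impacts(
    impacts_by_region: Mapping[str, float],
    shares: GroupShares,
    regional_population: Mapping[str, float],
    reference: str = "complement",
) -> list[GroupImpactResult]:
    """Allocate regional physical impacts to groups and compute rates.

    ``group impact = sum_r impact(r) * impact_share(g, r)``;
    ``rate = impact / group population * 100 000``.  The reference rate
    is either the complement of the group (default) or the total
    population rate (``reference="total"``).
    """
    missing = set(REGIONS) - set(impacts_by_region)
    if missing:
        raise InvalidArgumentError(
            f"impact map missing regions {sorted(missing)}")
    missing = set(REGIONS) - set(regional_population)
    if missing:
        raise InvalidArgumentError(
            f"population map missing regions {sorted(missing)}")
    if reference not in ("complement", "total"):
        raise InvalidArgumentError(f"unknown reference {reference!r}")

    imp = np.array([impacts_by_region[r] for r in REGIONS])
    pop = np.array([regional_population[r] for r in REGIONS])
    total_impact = imp.sum()
    total_pop = pop.sum()

    results = []
    for g in shares.groups:
        w_imp = shares.impact_share.loc[g, list(REGIONS)].to_numpy()
        w_pop = shares.population_share.loc[g, list(REGIONS)].to_numpy()
        g_imp = float(imp @ w_imp)
        g_pop = float(pop @ w_pop)
        if g_pop <= 0:
            raise InvalidArgumentError(f"group {g!r} has zero population")
        rate = g_imp / g_pop * 1e5
        if reference == "total":
            ref_rate = total_impact / total_pop * 1e5
        else:
            c_pop = total_pop - g_pop
            c_imp = total_impact - g_imp
            ref_rate = (c_imp / c_pop * 1e5) if c_pop > 0 else np.nan
        if ref_rate and not np.isnan(ref_rate):
            ratio, diff = differential_risk(rate, ref_rate)
        else:
            # zero/undefined reference: ratio undefined, difference kept
            ratio, diff = np.nan, rate
        results.append(GroupImpactResult(
            axis=shares.axis, group=g, impact=g_imp, population=g_pop,
            rate=rate, risk_ratio=ratio, rate_difference=diff))
    return results


# Default synthetic exposure fixture: four axes with mild, documented
# differentials (higher exposure shares than population shares for the
# named vulnerable groups, strongest in the Southeast/Southwest).
_AXES = {
    "race/ethnicity": (
        ("Black or African American", 0.13, 1.25),
        ("Hispanic or Latino", 0.18, 1.20),
        ("all other race/ethnicity", None, None),
    ),
    "income": (
        ("low income", 0.25, 1.18),
        ("not low income", None, None),
    ),
    "age": (
        ("65 and older", 0.17, 1.12),
        ("under 65", None, None),
    ),
    "education": (
        ("no high-school diploma", 0.11, 1.22),
        ("high-school diploma or higher", None, None),
    ),
}


def default_group_shares() -> dict[str, GroupShares]:
    """Synthetic exposure-share fixture for the four vulnerability axes.

    Each axis is exhaustive; the named vulnerable group's impact share is
    its population share times a relative-exposure factor, with the
    remainder assigned to the complement group.
    """
    out = {}
    for axis, rows in _AXES.items():
        named = [r for r in rows if r[1] is not None]
        groups = tuple(r[0] for r in rows)
        pop = {}
        imp = {}
        for g, p_share, exposure in named:
            pop[g] = np.full(len(REGIONS), p_share)
            imp[g] = np.minimum(np.full(len(REGIONS), p_share * exposure), 1.0)
        rest = rows[-1][0]
        pop[rest] = 1.0 - sum(pop[g] for g, _, _ in named)
        imp[rest] = 1.0 - sum(imp[g] for g, _, _ in named)
        mk = lambda d: pd.DataFrame(
            {r: [d[g][i] for g in groups] for i, r in enumerate(REGIONS)},
            index=list(groups))
        out[axis] = GroupShares(axis=axis, groups=groups,
                                population_share=mk(pop),
                                impact_share=mk(imp))
    return out
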