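"""Grid search over the (alpha, beta) segment angles and optimum selection.

The design space is searched on a rectangular grid (the reference sweep is
0-180 degrees in 10-degree steps for both angles, 361 geometries).  Each
geometry is scored by the mean (sensitivity) and standard deviation
(homogeneity) of its B1 proxy over the ROI.  Because "best with respect to
both" is a two-objective statement, the default selection rule first
restricts to the Pareto front in (std down, mean up) and then picks the
front member with the smallest coefficient of variation; the rule
identifier is recorded with every result.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .geometry import InvalidSpecError, SolenoidSpec, build_variable_pitch_solenoid
from .metrics import MetricsResult, RoiSpec, homogeneity_sensitivity, sample_roi
from .solver import biot_savart_field

__all__ = [
    "GridSearchResult",
    "grid_search",
    "select_optimum",
    "pareto_front_mask",
    "DEFAULT_RULE",
    "paper_grid",
]

DEFAULT_RULE = "min-cv-on-pareto"


def paper_grid() -> np.ndarray:
    """The reference sweep values: 0 to 180 degrees in 10-degree steps."""
    return np.arange(0.0, 181.0, 10.0)


@dataclass(frozen=True)
class GridSearchResult:
    """Metric surface over an (alpha, beta) grid plus the selected optimum."""

    entries: tuple[MetricsResult, ...]
    selected: tuple[float, float]
    selection_rule: str

    def entry_at(self, alpha_deg: float, beta_deg: float) -> MetricsResult:
        for e in self.entries:
            if e.alpha_deg == alpha_deg and e.beta_deg == beta_deg:
                return e
        raise KeyError(f"no entry at ({alpha_deg}, {beta_deg})")


def pareto_front_mask(entries: Sequence[MetricsResult]) -> np.ndarray:
    """Boolean mask of non-dominated entries in (std_b1 minimised, mean_b1
    maximised).

    An entry is dominated when some other entry has strictly lower std
    AND strictly higher mean.
    """
    std = np.array([e.std_b1 for e in entries])
    mean = np.array([e.mean_b1 for e in entries])
    dominated = np.zeros(len(entries), dtype=bool)
    for i in range(len(entries)):
        dominated[i] = bool(np.any((std < std[i]) & (mean > mean[i])))
    return ~dominated


def _rank_key(e: MetricsResult) -> tuple[float, float, float]:
    # deterministic tie-break: smaller alpha, then smaller beta
    return (e.cv, e.alpha_deg, e.beta_deg)


def select_optimum(
    grid: GridSearchResult | Sequence[MetricsResult], rule: str = DEFAULT_RULE
) -> tuple[float, float]:
    """Apply a selection rule to a metric surface; return (alpha, beta).

    Rules
    -----
    ``min-cv-on-pareto`` (default)
        Restrict to the Pareto front of (std_b1 down, mean_b1 up), then
        take the front member with minimal CV.
    ``min-cv``
        Global minimum of the coefficient of variation.
    ``min-std-with-sensitivity-floor:<f>``
        Minimum std among entries whose mean_b1 is at least the fraction
        ``<f>`` of the best mean_b1 on the grid.

    Ties are always broken toward smaller alpha, then smaller beta.
    """
    entries = grid.entries if isinstance(grid, GridSearchResult) else tuple(grid)
    if not entries:
        raise ValueError("empty grid")
    if rule == "min-cv-on-pareto":
        front = [e for e, keep in zip(entries, pareto_front_mask(entries)) if keep]
        best = min(front, key=_rank_key)
    elif rule == "min-cv":
        best = min(entries, key=_rank_key)
    elif rule.startswith("min-std-with-sensitivity-floor:"):
        try:
            floor = float(rule.split(":", 1)[1])
        except ValueError:
            raise ValueError(f"malformed selection rule {rule!r}") from None
        thresh = floor * max(e.mean_b1 for e in entries)
        eligible = [e for e in entries if e.mean_b1 >= thresh]
        if not eligible:
            raise ValueError(f"no entry meets the sensitivity floor {floor}")
        best = min(eligible, key=lambda e: (e.std_b1, e.alpha_deg, e.beta_deg))
    else:
        raise ValueError(f"unknown selection rule {rule!r}")
    return (best.alpha_deg, best.beta_deg)


def grid_search(
    base_spec: SolenoidSpec,
    alpha_values: Sequence[float] | None = None,
    beta_values: Sequence[float] | None = None,
    roi: RoiSpec | None = None,
    rule: str = DEFAULT_RULE,
    b1_proxy: str = "magnitude",
) -> GridSearchResult:
    """Score every (alpha, beta) combination on the ROI and select the optimum.

    All combinations are validated up front; an invalid combination aborts
    the whole search with a message listing the offending pairs.  Entries
    are computed independently in (alpha-major, beta-minor) order.
    """
    alphas = paper_grid() if alpha_values is None else np.asarray(alpha_values, float)
    betas = paper_grid() if beta_values is None else np.asarray(beta_values, float)
    roi = roi or RoiSpec()

    bad: list[tuple[float, float]] = []
    specs = {}
    for a in alphas:
        for b in betas:
            try:
                specs[(float(a), float(b))] = base_spec.with_angles(float(a), float(b))
            except InvalidSpecError:
                bad.append((float(a), float(b)))
    if bad:
        raise InvalidSpecError(f"invalid (alpha, beta) combinations: {bad}")

    points = sample_roi(roi)
    entries = []
    for (a, b), spec in specs.items():
        path = build_variable_pitch_solenoid(spec)
        fm = biot_savart_field(path, points, b1_proxy=b1_proxy)
        entries.append(homogeneity_sensitivity(fm, (a, b)))
    result = GridSearchResult(
        entries=tuple(entries), selected=(np.nan, np.nan), selection_rule=rule
    )
    selected = select_optimum(result, rule)
    return GridSearchResult(
        entries=result.entries, selected=selected, selection_rule=rule
    )
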