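"""Variance-inflation-factor feature reduction.

VIF_j = 1 / (1 − R_j²), where R_j² is the coefficient of determination of an
ordinary least-squares regression (with intercept) of attribute j on all
other numeric conditional attributes.  Attributes are banded by two
thresholds (default 10 and 15): below the low threshold collinearity is
negligible, between them moderate, and at or above the high threshold the
attribute is removed.  Removal is stepwise — the worst offender goes first
and the remaining VIFs are recomputed — because deleting one column changes
every other column's R².

Rank-deficient designs (more predictors than observations, or exactly
collinear columns) are solved by minimum-norm least squares and flagged in
the report; with fewer observations than predictors the fit interpolates,
R² → 1 and the VIF is reported as infinite rather than raising.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .infosys import InformationSystem

__all__ = ["VifRecord", "VifReport", "compute_vif", "reduce_by_vif",
           "DegenerateAttributeError", "ReductionError"]


class DegenerateAttributeError(ValueError):
    """Attribute has zero variance; R² is undefined."""


class ReductionError(ValueError):
    """The system cannot support a VIF reduction."""


@dataclass(frozen=True)
class VifRecord:
    attribute: str
    r_squared: float
    vif: float  # inf when R² is numerically 1
    band: str   # low | moderate | high
    rank_deficient: bool = False
    removed_rank: int | None = None  # 1-based order of removal, None if kept


@dataclass
class VifReport:
    records: list[VifRecord]
    threshold_low: float = 10.0
    threshold_high: float = 15.0
    removed: list[str] = field(default_factory=list)

    def as_rows(self) -> list[dict]:
        return [
            {
                "attribute": r.attribute,
                "r_squared": r.r_squared,
                "vif": r.vif,
                "band": r.band,
                "rank_deficient": r.rank_deficient,
                "removed_rank": r.removed_rank,
            }
            for r in self.records
        ]


def _band(vif: float, lo: float, hi: float) -> str:
    if vif < lo:
        return "low"
    if vif < hi:
        return "moderate"
    return "high"


_R2_ONE_TOL = 1e-12


def vif_from_r_squared(r_squared: float) -> float:
    """1/(1 − R²); infinite when R² is numerically 1."""
    if r_squared >= 1.0 - _R2_ONE_TOL:
        return float("inf")
    return 1.0 / (1.0 - r_squared)


def _ols_r_squared(y: np.ndarray, X: np.ndarray) -> tuple[float, bool]:
    """R² of y ~ X + intercept by minimum-norm least squares.

    Returns (R², rank_deficient).  R² is clipped to [0, 1].
    """
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst <= 0.0:
        raise DegenerateAttributeError("response attribute has zero variance")
    design = np.column_stack([np.ones(len(y)), X])
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    ssr = float(resid @ resid)
    r2 = 1.0 - ssr / sst
    return float(np.clip(r2, 0.0, 1.0)), rank < design.shape[1]


def compute_vif(
    is_: InformationSystem,
    attribute: str,
    *,
    include_decision: bool = False,
    among: list[str] | None = None,
) -> tuple[float, float]:
    """R² and VIF of one attribute against the other numeric conditionals.

    Parameters
    ----------
    is_ : InformationSystem
    attribute : str
        Must be numeric (or the decision attribute when ``include_decision``).
    include_decision : bool
        Treat the decision attribute as a regular column, reproducing the
        worked small-table calculation that regresses the decision on the
        conditionals.  Never used in the real pipeline.
    among : list of str, optional
        Restrict the candidate predictor set (used internally by the
        stepwise reduction).

    Raises
    ------
    DegenerateAttributeError
        Zero-variance attribute.
    ValueError
        Fewer than 2 other numeric predictors.
    """
    pool = among if among is not None else _vif_pool(is_, include_decision)
    if attribute not in pool:
        raise ValueError(f"attribute {attribute!r} is not a numeric candidate")
    others = [a for a in pool if a != attribute]
    if len(others) < 2:
        raise ValueError("need at least 2 other numeric attributes for VIF")
    y = is_.column(attribute)
    X = np.column_stack([is_.column(a) for a in others])
    r2, _ = _ols_r_squared(y, X)
    return r2, vif_from_r_squared(r2)


def _vif_pool(is_: InformationSystem, include_decision: bool) -> list[str]:
    pool = is_.conditional_attributes(numeric_only=True)
    if include_decision and is_.decision_attribute is not None:
        pool = pool + [is_.decision_attribute]
    return pool


def reduce_by_vif(
    is_: InformationSystem,
    threshold_low: float = 10.0,
    threshold_high: float = 15.0,
    *,
    include_decision: bool = False,
) -> tuple[InformationSystem, VifReport]:
    """Stepwise-remove high-band attributes until none remain.

    At each step every candidate's VIF is recomputed on the surviving
    columns; the highest VIF at or above ``threshold_high`` is removed.
    The decision, time and event attributes are never candidates (the
    ``include_decision`` escape hatch exists only to reproduce the worked
    small-table example and still removes at most the decision's VIF row,
    not the column itself from the returned system's designated role).

    Returns the reduced system and a :class:`VifReport` whose records carry
    the final surviving VIFs plus one record per removed attribute with its
    removal-time VIF and 1-based ``removed_rank``.
    """
    pool = _vif_pool(is_, include_decision)
    if len(pool) < 3:
        raise ReductionError("need at least 3 numeric attributes to reduce")

    removed: list[VifRecord] = []
    current = list(pool)
    max_steps = len(pool)
    for _ in range(max_steps):
        stats: dict[str, tuple[float, float, bool]] = {}
        degenerate = 0
        for a in current:
            try:
                y = is_.column(a)
                X = np.column_stack(
                    [is_.column(b) for b in current if b != a]
                )
                r2, rank_def = _ols_r_squared(y, X)
            except DegenerateAttributeError:
                degenerate += 1
                continue
            stats[a] = (r2, vif_from_r_squared(r2), rank_def)
        if not stats:
            raise ReductionError("all attributes degenerate")
        if degenerate == 0 and len(stats) < 3:
            break
        worst = max(stats, key=lambda a: stats[a][1])
        r2, vif, rank_def = stats[worst]
        if vif < threshold_high or len(current) <= 3:
            break
        removed.append(
            VifRecord(
                worst, r2, vif, "high", rank_def, removed_rank=len(removed) + 1
            )
        )
        current.remove(worst)

    records = list(removed)
    for a in current:
        try:
            r2, vif = compute_vif(
                is_, a, include_decision=include_decision, among=current
            )
            y = is_.column(a)
            X = np.column_stack([is_.column(b) for b in current if b != a])
            _, rank_def = _ols_r_squared(y, X)
        except (DegenerateAttributeError, ValueError):
            continue
        records.append(
            VifRecord(a, r2, vif, _band(vif, threshold_low, threshold_high),
                      rank_def)
        )

    drop = [r.attribute for r in removed
            if r.attribute != is_.decision_attribute]
    reduced = is_.drop_attributes(drop)
    report = VifReport(
        records=records,
        threshold_low=threshold_low,
        threshold_high=threshold_high,
        removed=[r.attribute for r in removed],
    )
    return reduced, report
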