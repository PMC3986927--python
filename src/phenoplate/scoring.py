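"""Stress-tolerance scoring: %RSI, strain ranking, extreme-class labels,
log-ratio matrices against a reference strain, and condition correlations.

The central statistic is the percentage redox signal intensity of
control (%RSI): the redox signal under stress divided by the signal
under the matched unstressed condition, ×100, both taken at a fixed
endpoint (50 h as standard; 24 h for 40 °C thermal stress).  Values can
exceed 100 — mild heat, for example, can stimulate metabolic output.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .kinetics import endpoint_signal
from .plate_io import ConditionSpec

logger = logging.getLogger(__name__)

#: control signals below this (arbitrary units) are treated as no-growth
DEFAULT_EPS = 1.0

DEFAULT_REFERENCE = "S288C"
DEFAULT_CLIP = 3.0

TOLERANT = "tolerant"
INTERMEDIATE = "intermediate"
SENSITIVE = "sensitive"


@dataclass(frozen=True)
class ToleranceScore:
    """%RSI of one strain under one stress condition versus its control."""

    strain_id: str
    condition_id: str
    rsi_stress: float
    rsi_control: float
    percent_rsi: float
    low_control: bool = False

    def __post_init__(self) -> None:
        if self.rsi_stress < 0 or self.rsi_control < 0:
            raise ValidationError(
                f"score ({self.strain_id}, {self.condition_id}): negative RSI"
            )


def percent_rsi(
    rsi_stress: float, rsi_control: float, eps: float = DEFAULT_EPS
) -> tuple[float, bool]:
    """Percentage redox signal intensity of control.

    Returns ``(percent, low_control)``.  When the control signal falls
    below ``eps`` — a well that never grew — the ratio is meaningless
    and is reported as 0 with the ``low_control`` flag set, rather than
    propagating a near-infinite value.
    """
    if rsi_stress < 0 or rsi_control < 0:
        raise ValidationError(
            f"percent_rsi: inputs must be non-negative, got "
            f"stress={rsi_stress}, control={rsi_control}"
        )
    if rsi_control < eps:
        return 0.0, True
    return 100.0 * rsi_stress / rsi_control, False


def score_study(
    curves: Mapping[tuple[str, str], object],
    conditions: Sequence[ConditionSpec],
    eps: float = DEFAULT_EPS,
) -> list[ToleranceScore]:
    """Score every strain under every stress condition.

    Parameters
    ----------
    curves
        Mapping ``(strain_id, condition_id) -> curve`` where each curve
        exposes ``times``/``signals`` (replicate-mean smoothed curves in
        the standard pipeline).
    conditions
        All condition specs, controls included.  Each stress condition's
        ``endpoint_hours`` is applied to **both** the stress and the
        control curve (e.g. both at 24 h for the 40 °C assay).

    Strains missing either curve are skipped with a log message; a
    stress condition whose control curve is missing for every scored
    strain raises, listing the strains involved.
    """
    by_id = {c.condition_id: c for c in conditions}
    strains = sorted({k[0] for k in curves})
    scores: list[ToleranceScore] = []
    for cond in conditions:
        if cond.is_control:
            continue
        if cond.control_id not in by_id:
            raise ValidationError(
                f"condition {cond.condition_id!r}: unknown control {cond.control_id!r}"
            )
        cond_strains = [s for s in strains if (s, cond.condition_id) in curves]
        with_control = [s for s in cond_strains if (s, cond.control_id) in curves]
        if cond_strains and not with_control:
            raise ValidationError(
                f"condition {cond.condition_id!r}: no control curve "
                f"({cond.control_id!r}) for any strain; strains affected: "
                + ", ".join(cond_strains)
            )
        for strain in strains:
            stress_curve = curves.get((strain, cond.condition_id))
            control_curve = curves.get((strain, cond.control_id))
            if stress_curve is None or control_curve is None:
                logger.info(
                    "skipping (%s, %s): missing %s curve",
                    strain,
                    cond.condition_id,
                    "stress" if stress_curve is None else "control",
                )
                continue
            rsi_s = endpoint_signal(stress_curve, cond.endpoint_hours)
            rsi_c = endpoint_signal(control_curve, cond.endpoint_hours)
            pct, low = percent_rsi(rsi_s, rsi_c, eps=eps)
            scores.append(
                ToleranceScore(
                    strain_id=strain,
                    condition_id=cond.condition_id,
                    rsi_stress=rsi_s,
                    rsi_control=rsi_c,
                    percent_rsi=pct,
                    low_control=low,
                )
            )
    return scores


@dataclass
class RankTable:
    """Strains of one condition ordered from tolerant (top) to sensitive."""

    condition_id: str
    entries: list[tuple[str, float]]
    low_control: set = field(default_factory=set)
    labels: list[str] = field(default_factory=list)

    def strain_order(self) -> list[str]:
        return [s for s, _ in self.entries]


def rank_strains(scores: Iterable[ToleranceScore]) -> RankTable:
    """Rank strains of one condition by descending %RSI.

    Ties break alphabetically by strain id; strains whose control well
    never grew (``low_control``) cannot be ranked on the ratio and sit
    at the bottom, flagged.
    """
    scores = list(scores)
    if not scores:
        raise ValidationError("rank_strains: no scores")
    cond_ids = {s.condition_id for s in scores}
    if len(cond_ids) != 1:
        raise ValidationError(f"rank_strains: mixed condition ids {sorted(cond_ids)}")
    valid = sorted(
        (s for s in scores if not s.low_control),
        key=lambda s: (-s.percent_rsi, s.strain_id),
    )
    flagged = sorted((s for s in scores if s.low_control), key=lambda s: s.strain_id)
    entries = [(s.strain_id, s.percent_rsi) for s in valid + flagged]
    return RankTable(
        condition_id=cond_ids.pop(),
        entries=entries,
        low_control={s.strain_id for s in flagged},
    )


def classify_extremes(
    rank: RankTable, k_sensitive: int = 5, k_tolerant: int = 10
) -> list[str]:
    """Label the top ``k_tolerant`` strains tolerant and the bottom
    ``k_sensitive`` sensitive; everything between is intermediate.

    The defaults mirror the conventional reporting of five sensitive and
    ten tolerant extremes per condition.  Labels are also stored on the
    rank table.
    """
    n = len(rank.entries)
    if k_sensitive < 0 or k_tolerant < 0 or k_sensitive + k_tolerant > n:
        raise ValidationError(
            f"classify_extremes: k_sensitive={k_sensitive} + k_tolerant="
            f"{k_tolerant} exceeds {n} strains"
        )
    labels = [INTERMEDIATE] * n
    for i in range(k_tolerant):
        labels[i] = TOLERANT
    for i in range(n - k_sensitive, n):
        labels[i] = SENSITIVE
    rank.labels = labels
    return labels


@dataclass
class LogRatioMatrix:
    """Strains × conditions log₂ ratios versus a reference strain.

    Values are ``log2(strain / reference)`` clipped to ±``clip`` (the
    conventional heat-map colour range is ±3).  The reference row is
    identically zero.  Cells whose ratio is undefined (low-control
    strain or reference) are missing: NaN in ``values``, True in
    ``missing``.
    """

    values: pd.DataFrame
    missing: pd.DataFrame
    reference_id: str
    clip: float

    @property
    def strain_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def condition_ids(self) -> list[str]:
        return list(self.values.columns)


def log_ratio_matrix(
    scores: Iterable[ToleranceScore],
    reference_id: str = DEFAULT_REFERENCE,
    clip: float = DEFAULT_CLIP,
) -> LogRatioMatrix:
    """Build the clipped log₂-ratio matrix of %RSI against a reference strain."""
    scores = list(scores)
    df = pd.DataFrame(
        {
            "strain_id": [s.strain_id for s in scores],
            "condition_id": [s.condition_id for s in scores],
            "percent_rsi": [s.percent_rsi for s in scores],
            "low_control": [s.low_control for s in scores],
        }
    )
    if df.empty:
        raise ValidationError("log_ratio_matrix: no scores")
    if reference_id not in set(df["strain_id"]):
        raise ValidationError(
            f"log_ratio_matrix: reference strain {reference_id!r} has no scores"
        )
    pct = df.pivot(index="strain_id", columns="condition_id", values="percent_rsi")
    low = (
        df.pivot(index="strain_id", columns="condition_id", values="low_control")
        .fillna(True)
        .astype(bool)
    )
    pct = pct.sort_index()
    low = low.reindex(index=pct.index, columns=pct.columns)

    ref_pct = pct.loc[reference_id]
    ref_low = low.loc[reference_id]
    usable = ~low & ~pct.isna()
    usable &= ~ref_low  # a low-control reference invalidates the whole column
    usable &= (pct > 0) & (ref_pct > 0)

    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.log2(pct.to_numpy() / ref_pct.to_numpy()[None, :])
    values = pd.DataFrame(
        np.clip(ratios, -clip, clip), index=pct.index, columns=pct.columns
    )
    values = values.where(usable.to_numpy())
    # log2(x/x) = 0 exactly, but enforce against float wobble
    values.loc[reference_id] = np.where(usable.loc[reference_id], 0.0, np.nan)
    return LogRatioMatrix(
        values=values, missing=~usable, reference_id=reference_id, clip=clip
    )


def condition_correlation(
    endpoint_matrix: pd.DataFrame, cond_a: str, cond_b: str
) -> float:
    """Sample Pearson correlation of two condition columns across strains.

    Works on whichever per-strain value the columns carry (endpoint
    signals for sugar-utilisation comparisons, %RSI for stress
    comparisons).  Pairwise-complete; needs at least 3 strains with both
    values.  Zero variance in either column makes the correlation
    undefined: NaN is returned.
    """
    for c in (cond_a, cond_b):
        if c not in endpoint_matrix.columns:
            raise ValidationError(f"condition_correlation: unknown condition {c!r}")
    sub = endpoint_matrix[[cond_a, cond_b]].dropna()
    if len(sub) < 3:
        raise ValidationError(
            f"condition_correlation: only {len(sub)} strains with values in both "
            f"{cond_a!r} and {cond_b!r} (need >= 3)"
        )
    x = sub[cond_a].to_numpy()
    y = sub[cond_b].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning(
            "condition_correlation(%s, %s): zero variance, correlation undefined",
            cond_a,
            cond_b,
        )
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def mean_rank_aggregate(rank_tables: Sequence[RankTable]) -> RankTable:
    """Cross-condition aggregate ranking by unweighted mean rank position.

    No canonical multi-stress aggregation rule exists for this assay;
    this simple mean-rank summary is provided for convenience and
    labelled as such.  The returned table's scores are mean ranks
    (lower = more tolerant), re-expressed so the most tolerant strain
    sorts first.
    """
    if not rank_tables:
        raise ValidationError("mean_rank_aggregate: no rank tables")
    positions: dict[str, list[int]] = {}
    for table in rank_tables:
        for pos, (strain, _) in enumerate(table.entries, start=1):
            positions.setdefault(strain, []).append(pos)
    mean_pos = {s: float(np.mean(p)) for s, p in positions.items()}
    entries = sorted(mean_pos.items(), key=lambda kv: (kv[1], kv[0]))
    # report negative mean rank so "descending score" still means "tolerant first"
    return RankTable(
        condition_id="all_stress_mean_rank",
        entries=[(s, -m) for s, m in entries],
    )
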