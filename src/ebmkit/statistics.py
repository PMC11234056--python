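"""Effect statistics from 2x2 counts, and their Statistic representation.

Point estimates and intervals:

* proportion -- events/total with a Wilson score interval
  (``statsmodels.stats.proportion.proportion_confint``);
* odds ratio -- ``(a*d)/(b*c)`` with a Woolf (log-scale normal) interval,
  ``se = sqrt(1/a + 1/b + 1/c + 1/d)``;
* risk ratio -- ``(a/n1)/(c/n2)`` with the log-scale interval,
  ``se = sqrt(1/a - 1/n1 + 1/c - 1/n2)``;
* risk difference -- plain-scale normal interval.

A 0.5 continuity correction is applied to all four cells only when some
cell is zero (disable with ``continuity=False``).  Ratio measures live on
the log scale for interval construction and pooling; the risk difference
and proportion live on the plain scale.

:func:`to_statistic` / :func:`statistic_to_estimate` map between these
estimates and the resource model's Statistic structure, so effect sizes
survive a round trip through FHIR-JSON.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional

from scipy.stats import norm
from statsmodels.stats.proportion import proportion_confint

from . import model as m
from .errors import EstimateError, UndefinedMeasureError
from .terminology import SYSTEM_URI

__all__ = [
    "TwoByTwoCounts",
    "EffectEstimate",
    "compute_proportion",
    "compute_odds_ratio",
    "compute_risk_ratio",
    "compute_risk_difference",
    "to_statistic",
    "statistic_to_estimate",
    "render_percent",
    "LOG_SCALE_MEASURES",
]

#: Measures whose intervals and pooling live on the log scale.
LOG_SCALE_MEASURES = frozenset({"odds-ratio", "risk-ratio"})

#: measure -> (statistic-type code, display) in the packaged system.
_MEASURE_CODES = {
    "odds-ratio": ("odds-ratio", "odds ratio"),
    "risk-ratio": ("relative-risk", "relative risk"),
    "risk-difference": ("risk-difference", "risk difference"),
    "proportion": ("proportion", "proportion"),
}
_CODE_TO_MEASURE = {code: measure for measure, (code, _) in _MEASURE_CODES.items()}


@dataclass(frozen=True)
class TwoByTwoCounts:
    """A 2x2 table: (events, non-events) x (exposed, reference)."""

    events_exposed: int
    nonevents_exposed: int
    events_reference: int
    nonevents_reference: int

    def __post_init__(self) -> None:
        for name in (
            "events_exposed",
            "nonevents_exposed",
            "events_reference",
            "nonevents_reference",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_exposed == 0 or self.n_reference == 0:
            raise ValueError("each arm total must be > 0")

    @property
    def n_exposed(self) -> int:
        return self.events_exposed + self.nonevents_exposed

    @property
    def n_reference(self) -> int:
        return self.events_reference + self.nonevents_reference

    def swapped(self) -> "TwoByTwoCounts":
        """The table with exposed and reference arms exchanged."""
        return TwoByTwoCounts(
            self.events_reference,
            self.nonevents_reference,
            self.events_exposed,
            self.nonevents_exposed,
        )


@dataclass
class EffectEstimate:
    """A point estimate with its dispersion and interval.

    ``se`` is on the analysis scale: log for ratio measures, plain
    otherwise.
    """

    measure: str
    point: float
    se: Optional[float]
    ci_low: float
    ci_high: float
    ci_level: float = 0.95
    events: Optional[int] = None
    total: Optional[int] = None

    @property
    def log_scale(self) -> bool:
        return self.measure in LOG_SCALE_MEASURES

    @property
    def analysis_point(self) -> float:
        """The point estimate on the analysis (pooling) scale."""
        return math.log(self.point) if self.log_scale else self.point


def _z(ci_level: float) -> float:
    if not (0.0 < ci_level < 1.0):
        raise ValueError(f"ci_level must lie in (0, 1), got {ci_level}")
    return float(norm.ppf((1.0 + ci_level) / 2.0))


def render_percent(value: float) -> str:
    """Render a proportion as a percentage, half-up to one decimal.

    >>> render_percent(939 / 1171)
    '80.2%'
    """
    pct = Decimal(repr(value * 100)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    return f"{pct}%"


def compute_proportion(
    events: int, total: int, ci_level: float = 0.95
) -> EffectEstimate:
    """Proportion of events with a Wilson score interval."""
    if total <= 0:
        raise UndefinedMeasureError("proportion undefined for total <= 0")
    if not (0 <= events <= total):
        raise ValueError(f"events must lie in [0, total], got {events}/{total}")
    point = events / total
    low, high = proportion_confint(events, total, alpha=1 - ci_level, method="wilson")
    se = math.sqrt(point * (1 - point) / total) if 0 < point < 1 else None
    return EffectEstimate(
        measure="proportion",
        point=point,
        se=se,
        ci_low=float(low),
        ci_high=float(high),
        ci_level=ci_level,
        events=events,
        total=total,
    )


def _corrected_cells(
    c: TwoByTwoCounts, continuity: bool
) -> tuple[float, float, float, float]:
    a, b, cc, d = (
        c.events_exposed,
        c.nonevents_exposed,
        c.events_reference,
        c.nonevents_reference,
    )
    if continuity and 0 in (a, b, cc, d):
        return a + 0.5, b + 0.5, cc + 0.5, d + 0.5
    return float(a), float(b), float(cc), float(d)


def compute_odds_ratio(
    c: TwoByTwoCounts, ci_level: float = 0.95, continuity: bool = True
) -> EffectEstimate:
    """Unadjusted odds ratio with a Woolf log-scale interval."""
    if (c.events_exposed == 0 and c.events_reference == 0) or (
        c.nonevents_exposed == 0 and c.nonevents_reference == 0
    ):
        raise UndefinedMeasureError(
            "odds ratio undefined: both cells of one outcome are zero"
        )
    a, b, cc, d = _corrected_cells(c, continuity)
    if 0.0 in (a, b, cc, d):
        raise UndefinedMeasureError(
            "odds ratio undefined for a zero cell without continuity correction"
        )
    point = (a * d) / (b * cc)
    se = math.sqrt(1 / a + 1 / b + 1 / cc + 1 / d)
    z = _z(ci_level)
    return EffectEstimate(
        measure="odds-ratio",
        point=point,
        se=se,
        ci_low=math.exp(math.log(point) - z * se),
        ci_high=math.exp(math.log(point) + z * se),
        ci_level=ci_level,
        events=c.events_exposed + c.events_reference,
        total=c.n_exposed + c.n_reference,
    )


def compute_risk_ratio(
    c: TwoByTwoCounts, ci_level: float = 0.95, continuity: bool = True
) -> EffectEstimate:
    """Risk (rate) ratio with a log-scale normal interval."""
    if c.events_exposed == 0 and c.events_reference == 0:
        raise UndefinedMeasureError("risk ratio undefined: no events in either arm")
    a, b, cc, d = _corrected_cells(c, continuity)
    n1, n2 = a + b, cc + d
    if a == 0.0 or cc == 0.0:
        raise UndefinedMeasureError(
            "risk ratio undefined: zero events in one arm without correction"
        )
    point = (a / n1) / (cc / n2)
    se = math.sqrt(1 / a - 1 / n1 + 1 / cc - 1 / n2)
    z = _z(ci_level)
    return EffectEstimate(
        measure="risk-ratio",
        point=point,
        se=se,
        ci_low=math.exp(math.log(point) - z * se),
        ci_high=math.exp(math.log(point) + z * se),
        ci_level=ci_level,
        events=c.events_exposed + c.events_reference,
        total=c.n_exposed + c.n_reference,
    )


def compute_risk_difference(
    c: TwoByTwoCounts, ci_level: float = 0.95
) -> EffectEstimate:
    """Risk difference (exposed minus reference) with a plain-scale interval."""
    p1 = c.events_exposed / c.n_exposed
    p2 = c.events_reference / c.n_reference
    point = p1 - p2
    se = math.sqrt(
        p1 * (1 - p1) / c.n_exposed + p2 * (1 - p2) / c.n_reference
    )
    z = _z(ci_level)
    return EffectEstimate(
        measure="risk-difference",
        point=point,
        se=se,
        ci_low=point - z * se,
        ci_high=point + z * se,
        ci_level=ci_level,
        events=c.events_exposed + c.events_reference,
        total=c.n_exposed + c.n_reference,
    )


# ---------------------------------------------------------------------------
# Statistic <-> estimate mapping
# ---------------------------------------------------------------------------

_AE_SYSTEM = SYSTEM_URI["attribute-estimate-type"]
_ST_SYSTEM = SYSTEM_URI["statistic-type"]


def _ae_type(code: str, display: str) -> m.CodeableConcept:
    return m.CodeableConcept(
        coding=[m.Coding(system=_AE_SYSTEM, code=code, display=display)]
    )


def to_statistic(
    e: EffectEstimate,
    sample: Optional[m.SampleSize] = None,
    description: Optional[str] = None,
    interval_type: str = "confidence-interval",
) -> m.Statistic:
    """Express an effect estimate as a Statistic structure.

    The interval becomes an AttributeEstimate with ``level`` and a range;
    the standard error is carried as a second AttributeEstimate so the
    estimate is exactly recoverable.  ``interval_type`` selects the interval
    coding (``confidence-interval`` or ``credible-interval``).
    """
    try:
        code, display = _MEASURE_CODES[e.measure]
    except KeyError:
        raise EstimateError(f"unknown measure {e.measure!r}") from None
    attrs = [
        m.AttributeEstimate(
            type=_ae_type(
                interval_type, interval_type.replace("-", " ")
            ),
            level=e.ci_level,
            range_low=m.Quantity(value=e.ci_low),
            range_high=m.Quantity(value=e.ci_high),
        )
    ]
    if e.se is not None:
        attrs.append(
            m.AttributeEstimate(
                type=_ae_type("standard-error", "standard error"),
                quantity=m.Quantity(
                    value=e.se, unit="log scale" if e.log_scale else None
                ),
            )
        )
    if sample is None and e.total is not None:
        sample = m.SampleSize(total_participants=e.total, known_data_count=e.total)
    return m.Statistic(
        description=description,
        statistic_type=m.CodeableConcept(
            coding=[m.Coding(system=_ST_SYSTEM, code=code, display=display)]
        ),
        quantity=m.Quantity(value=e.point),
        number_of_events=e.events,
        sample_size=sample,
        attribute_estimate=attrs,
    )


_INTERVAL_CODES = {"confidence-interval", "credible-interval"}


def _find_interval(
    attrs: list[m.AttributeEstimate],
) -> Optional[m.AttributeEstimate]:
    for ae in attrs:
        for coding in ae.type.coding:
            if coding.code in _INTERVAL_CODES and ae.range_low and ae.range_high:
                return ae
    for ae in attrs:  # text-typed interval fallback
        text = (ae.type.text or "").lower()
        if "interval" in text and ae.range_low and ae.range_high:
            return ae
    return None


def _find_se(attrs: list[m.AttributeEstimate]) -> Optional[float]:
    for ae in attrs:
        for coding in ae.type.coding:
            if coding.code == "standard-error" and ae.quantity is not None:
                return ae.quantity.value
    return None


def statistic_to_estimate(s: m.Statistic, strict: bool = True) -> EffectEstimate:
    """Recover an effect estimate from a Statistic.

    The standard error is taken from an explicit standard-error attribute
    when present, else recovered from the interval width on the analysis
    scale.  Raises :class:`EstimateError` when the statistic type is
    unrecognized (strict mode) or no dispersion is recoverable.
    """
    measure = None
    for coding in s.statistic_type.coding:
        if coding.code in _CODE_TO_MEASURE:
            measure = _CODE_TO_MEASURE[coding.code]
            break
    if measure is None:
        if strict:
            raise EstimateError(
                "statistic has no recognized statisticType coding"
            )
        text = (s.statistic_type.text or "").lower().replace(" ", "-")
        measure = _CODE_TO_MEASURE.get(text, text or None)
        if measure is None:
            raise EstimateError("statistic carries neither coding nor text type")
    if s.quantity is None:
        raise EstimateError("statistic has no point quantity")
    point = s.quantity.value
    interval = _find_interval(s.attribute_estimate)
    se = _find_se(s.attribute_estimate)
    if interval is None and se is None:
        raise EstimateError("statistic has no interval and no standard error")
    log_scale = measure in LOG_SCALE_MEASURES
    if interval is not None:
        level = interval.level if interval.level is not None else 0.95
        lo, hi = interval.range_low.value, interval.range_high.value
        if se is None:
            z = _z(level)
            if log_scale:
                se = (math.log(hi) - math.log(lo)) / (2 * z)
            else:
                se = (hi - lo) / (2 * z)
    else:
        level = 0.95
        z = _z(level)
        if log_scale:
            lo = math.exp(math.log(point) - z * se)
            hi = math.exp(math.log(point) + z * se)
        else:
            lo, hi = point - z * se, point + z * se
    events = s.number_of_events
    total = s.sample_size.total_participants if s.sample_size else None
    return EffectEstimate(
        measure=measure,
        point=point,
        se=se,
        ci_low=lo,
        ci_high=hi,
        ci_level=level,
        events=events,
        total=total,
    )
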