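"""Median-split stratification, Kaplan-Meier curves, and the Mantel-Cox
log-rank screen.

Samples are dichotomized at the median of a stratifier (gene expression,
exon ratio, probe beta, or miRNA level); ties go to the low group. The
log-rank statistic accumulates, at each distinct event time, the observed
versus hypergeometric-expected events in the high group:

    chi2 = (sum O - sum E)**2 / sum V,   chi2 ~ chi2(1) under the null

and the favorable/unfavorable call is the sign of ``sum O - sum E`` for the
high group — more events than expected among high-stratifier samples means
the stratifier is unfavorable. The O/E/V accumulation is implemented here
directly because the direction call needs the signed excess, not just the
chi-square.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

from .data import Endpoint, SurvivalRecord
from .exceptions import DegenerateDataError, InsufficientDataError, ValidationError

ALPHA = 0.05


def median_split(values: dict[str, float] | pd.Series) -> tuple[set[str], set[str]]:
    """Split samples at the median: low = {v <= median}, high = {v > median}.

    Missing values are dropped first; >= 4 valid samples are required and
    an all-identical vector cannot be split.
    """
    series = pd.Series(values).dropna().astype(float)
    if len(series) < 4:
        raise InsufficientDataError(f"median split needs >= 4 samples, got {len(series)}")
    med = float(series.median())
    if series.nunique() == 1:
        raise DegenerateDataError("all stratifier values identical; cannot split")
    low = set(series.index[series <= med])
    high = set(series.index[series > med])
    if not high:
        # median ties with the maximum: fall back to a strict split so both
        # groups stay non-empty (values below the median exist here)
        low = set(series.index[series < med])
        high = set(series.index[series >= med])
    return low, high


def mean_split(values: dict[str, float] | pd.Series) -> tuple[set[str], set[str]]:
    """Mean-based variant of :func:`median_split` (same tie rule)."""
    series = pd.Series(values).dropna().astype(float)
    if len(series) < 4:
        raise InsufficientDataError(f"mean split needs >= 4 samples, got {len(series)}")
    if series.nunique() == 1:
        raise DegenerateDataError("all stratifier values identical; cannot split")
    center = float(series.mean())
    return set(series.index[series <= center]), set(series.index[series > center])


class KaplanMeierCurve:
    """Product-limit survival estimate: right-continuous step function, S(0)=1."""

    def __init__(self, times, events):
        times = np.asarray(times, dtype=float)
        events = np.asarray(events, dtype=int)
        if times.size == 0:
            raise InsufficientDataError("Kaplan-Meier needs >= 1 record")
        if (times <= 0).any():
            raise ValidationError("survival times must be > 0")
        kmf = KaplanMeierFitter()
        kmf.fit(times, event_observed=events)
        self._kmf = kmf
        sf = kmf.survival_function_
        self.step_times = sf.index.to_numpy(dtype=float)
        self.step_values = sf.iloc[:, 0].to_numpy(dtype=float)

    def survival(self, t: float) -> float:
        """S(t); S(0) = 1 and the curve is evaluated right-continuously."""
        if t < 0:
            raise ValidationError("time must be >= 0")
        return float(self._kmf.predict(t))

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.step_times, "survival": self.step_values})


def km_estimate(times, events) -> KaplanMeierCurve:
    """Kaplan-Meier product-limit estimator over (time, event) records."""
    return KaplanMeierCurve(times, events)


def logrank_test(
    group_low: list[SurvivalRecord] | pd.DataFrame,
    group_high: list[SurvivalRecord] | pd.DataFrame,
) -> tuple[float, float, str]:
    """Mantel-Cox log-rank test between low and high stratifier groups.

    Returns ``(chi_square, p_value, direction)`` where direction is
    ``"unfavorable"`` iff the high group saw more events than expected.
    """
    low = _as_frame(group_low)
    high = _as_frame(group_high)
    if low.empty or high.empty:
        raise InsufficientDataError("both groups must be non-empty")
    n_events = int(low["event"].sum() + high["event"].sum())
    if n_events == 0:
        raise DegenerateDataError("no events in either group; log-rank undefined")

    times = np.concatenate([low["time"], high["time"]])
    events = np.concatenate([low["event"], high["event"]])
    in_high = np.concatenate([np.zeros(len(low), bool), np.ones(len(high), bool)])

    total_o = 0.0
    total_e = 0.0
    variance = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & in_high).sum()
        d = int(((times == t) & (events == 1)).sum())
        d1 = int(((times == t) & (events == 1) & in_high).sum())
        e1 = d * n1 / n
        total_o += d1
        total_e += e1
        if n > 1:
            variance += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    o_minus_e = total_o - total_e
    if variance == 0:
        chi2 = 0.0
        p = 1.0
    else:
        chi2 = o_minus_e**2 / variance
        p = float(stats.chi2.sf(chi2, df=1))
    direction = "unfavorable" if o_minus_e > 0 else "favorable"
    return float(chi2), p, direction


@dataclass(frozen=True)
class SurvivalResult:
    stratifier_id: str
    cohort: str
    endpoint: str
    chi_square: float
    p_value: float
    direction: str
    n_high: int
    n_low: int
    significant: bool


def survival_screen(
    stratifier_values: dict[str, float] | pd.Series,
    survival_records: list[SurvivalRecord],
    endpoint: Endpoint | str = Endpoint.OS,
    alpha: float = ALPHA,
    stratifier_id: str = "stratifier",
    cohort: str = "",
    split: str = "median",
) -> SurvivalResult:
    """Median-split (or mean-split) log-rank screen for one stratifier.

    Only samples present in both the stratifier vector and the endpoint's
    survival table enter the split; >= 4 overlapping samples are required.
    """
    endpoint = Endpoint(endpoint)
    table = _as_frame([r for r in survival_records if r.endpoint is endpoint])
    values = pd.Series(stratifier_values).dropna()
    overlap = values.index.intersection(table.index)
    if len(overlap) < 4:
        raise InsufficientDataError(
            f"only {len(overlap)} samples shared between stratifier and survival table"
        )
    splitter = {"median": median_split, "mean": mean_split}.get(split)
    if splitter is None:
        raise ValidationError(f"unknown split rule {split!r}; use 'median' or 'mean'")
    low_ids, high_ids = splitter(values[overlap])
    chi2, p, direction = logrank_test(table.loc[sorted(low_ids)], table.loc[sorted(high_ids)])
    return SurvivalResult(
        stratifier_id=stratifier_id,
        cohort=cohort,
        endpoint=endpoint.value,
        chi_square=chi2,
        p_value=p,
        direction=direction,
        n_high=len(high_ids),
        n_low=len(low_ids),
        significant=p <= alpha,
    )


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return pd.DataFrame(
        {
            "time": [r.time for r in records],
            "event": [r.event for r in records],
        },
        index=[r.sample_id for r in records],
    )
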