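"""Feeding-event detection from capacitive food-interaction traces.

A FLIC (fly liquid-food interaction counter) arena reports a capacitance
signal every 200 ms; proboscis contact with the food produces sustained
supra-threshold deflections, while brief leg or wing touches produce short
artifacts. A feeding event is a maximal run of at least ``min_run`` (5)
consecutive background-subtracted samples at or above ``threshold``
(25 AU). Events are binned into 1-hour windows over a 24-hour recording
and feeding counts are analysed with factorial ANOVA against mating
status, time bin and VL2a-innervation factors.
"""
from __future__ import annotations

import itertools
import warnings
from collections.abc import Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .dimorphism import bonferroni_adjust
from .errors import ConfigError

#: Detection defaults: 25 AU over >=5 consecutive 200 ms samples.
DEFAULT_THRESHOLD = 25.0
DEFAULT_MIN_RUN = 5
SAMPLING_INTERVAL_S = 0.2
#: Default rolling-median window: one minute of samples (odd).
DEFAULT_WINDOW = 301


@dataclass
class FlicTrace:
    """One fly's capacitance signal sampled at a fixed interval."""

    fly_id: str
    samples: np.ndarray
    sampling_interval_s: float = SAMPLING_INTERVAL_S
    condition: str = "L-D"  # L-D (light-dark) or L-L (constant light)
    mating_status: str = "unknown"
    vl2a_innervated: bool | None = None
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.isfinite(self.samples).all():
            raise ValueError("trace samples must be finite")
        if self.sampling_interval_s <= 0:
            raise ValueError("sampling interval must be positive")


@dataclass
class FeedingEvent:
    """A detected supra-threshold run in a background-subtracted trace."""

    start_index: int
    length: int
    peak: float
    mean_intensity: float

    @property
    def stop_index(self) -> int:  # exclusive
        return self.start_index + self.length


def subtract_background(trace: FlicTrace | np.ndarray,
                        window: int = DEFAULT_WINDOW) -> np.ndarray:
    """Remove baseline drift: each sample minus the centered rolling median.

    The window (odd, >= 3 samples; default one minute at 200 ms) shrinks
    near the trace edges. The median baseline tracks slow drift while
    ignoring short feeding bouts.
    """
    samples = trace.samples if isinstance(trace, FlicTrace) \
        else np.asarray(trace, dtype=float)
    if window < 3 or window % 2 == 0:
        raise ConfigError("window must be odd and >= 3")
    if window >= samples.size:
        raise ConfigError(
            f"window {window} >= trace length {samples.size}")
    baseline = pd.Series(samples).rolling(
        window, center=True, min_periods=1).median().to_numpy()
    return samples - baseline


def detect_feeding_events(corrected: np.ndarray,
                          threshold: float = DEFAULT_THRESHOLD,
                          min_run: int = DEFAULT_MIN_RUN
                          ) -> list[FeedingEvent]:
    """Maximal runs of consecutive samples >= threshold, kept iff their
    length is >= min_run. Non-overlapping, ordered by start; a long run is
    one event (runs are never split)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    corrected = np.asarray(corrected, dtype=float)
    above = corrected >= threshold
    events: list[FeedingEvent] = []
    if not above.any():
        return events
    padded = np.diff(np.concatenate(([0], above.view(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    stops = np.flatnonzero(padded == -1)
    for start, stop in zip(starts, stops):
        length = int(stop - start)
        if length >= min_run:
            seg = corrected[start:stop]
            events.append(FeedingEvent(
                start_index=int(start), length=length,
                peak=float(seg.max()), mean_intensity=float(seg.mean())))
    return events


def bin_events(events: Sequence[FeedingEvent], trace: FlicTrace,
               bin_width_s: float = 3600.0,
               duration_s: float = 86400.0) -> pd.DataFrame:
    """Assign events to fixed time bins by their start sample.

    Emits every bin (zero-filled) over ``duration_s``; events starting
    beyond the duration are dropped with a warning. Total counts are
    conserved when all events fall within the duration.
    """
    n_bins = int(round(duration_s / bin_width_s))
    counts = np.zeros(n_bins, dtype=int)
    dropped = 0
    for ev in events:
        t = ev.start_index * trace.sampling_interval_s
        b = int(t // bin_width_s)
        if b >= n_bins:
            dropped += 1
            continue
        counts[b] += 1
    if dropped:
        warnings.warn(f"{dropped} event(s) beyond {duration_s} s dropped",
                      stacklevel=2)
    return pd.DataFrame({
        "fly_id": trace.fly_id, "bin_index": np.arange(n_bins),
        "event_count": counts, "condition": trace.condition,
        "mating_status": trace.mating_status,
        "vl2a_innervated": trace.vl2a_innervated,
    })


def detect_trace(trace: FlicTrace, threshold: float = DEFAULT_THRESHOLD,
                 min_run: int = DEFAULT_MIN_RUN,
                 window: int = DEFAULT_WINDOW) -> list[FeedingEvent]:
    """Background subtraction followed by event detection."""
    return detect_feeding_events(subtract_background(trace, window),
                                 threshold, min_run)


@dataclass
class AnovaReport:
    """Factorial ANOVA table plus Bonferroni-corrected pairwise post hocs.

    When ``hc_adjust`` was used, F-tests rest on an HC3
    heteroscedasticity-consistent covariance and the sum-of-squares
    column is omitted (it is not defined under the robust covariance).
    """

    table: pd.DataFrame
    posthoc: pd.DataFrame
    hc_adjust: bool
    formula: str

    def effect_p(self, term: str) -> float:
        key = f"C({term})"
        if key not in self.table.index:
            raise KeyError(f"no term {term!r} in ANOVA table")
        return float(self.table.loc[key, "PR(>F)"])


def factorial_anova(binned: pd.DataFrame, factors: Sequence[str],
                    response: str = "event_count",
                    hc_adjust: bool = False) -> AnovaReport:
    """Two- or three-way ANOVA with all interactions, type-II sums of
    squares, optional HC3 heteroscedasticity correction, and Bonferroni
    pairwise post hocs per factor (Welch t-tests on marginal level means).

    Every cell of the full factorial must contain at least one
    observation; otherwise the offending cell is named in the error.
    """
    factors = list(factors)
    if len(factors) not in (2, 3):
        raise ValueError("factors must name 2 or 3 columns")
    data = binned.copy()
    levels = {}
    for f in factors:
        lv = sorted(data[f].astype(str).unique())
        if len(lv) < 2:
            raise ValueError(f"factor {f!r} has <2 levels")
        levels[f] = lv
        data[f] = data[f].astype(str)
    for cell in itertools.product(*(levels[f] for f in factors)):
        mask = np.ones(len(data), dtype=bool)
        for f, lv in zip(factors, cell):
            mask &= data[f].to_numpy() == lv
        if not mask.any():
            raise ValueError(
                "empty cell in full factorial: "
                + ", ".join(f"{f}={lv}" for f, lv in zip(factors, cell)))
    formula = f"{response} ~ " + "*".join(f"C({f})" for f in factors)
    model = smf.ols(formula, data=data).fit()
    table = sm.stats.anova_lm(model, typ=2,
                              robust="hc3" if hc_adjust else None)
    if hc_adjust and "sum_sq" in table.columns:
        table = table.drop(columns=["sum_sq"])
    rows = []
    for f in factors:
        for a, b in itertools.combinations(levels[f], 2):
            xa = data.loc[data[f] == a, response].to_numpy(float)
            xb = data.loc[data[f] == b, response].to_numpy(float)
            t, p = stats.ttest_ind(xa, xb, equal_var=False)
            rows.append({"factor": f, "level_a": a, "level_b": b,
                         "mean_a": xa.mean(), "mean_b": xb.mean(),
                         "t": float(t), "raw_p": float(p)})
    posthoc = pd.DataFrame(rows)
    if len(posthoc):
        posthoc["adjusted_p"] = bonferroni_adjust(
            posthoc["raw_p"].tolist(), len(posthoc))
    return AnovaReport(table=table, posthoc=posthoc, hc_adjust=hc_adjust,
                       formula=formula)


def read_traces(path: str) -> list[FlicTrace]:
    """Read FLIC traces from CSV: columns ``signal_au`` plus ``time_s`` or
    ``sample_index``; an optional ``fly_id`` column allows a long-format
    multi-fly file."""
    df = pd.read_csv(path)
    if "signal_au" not in df.columns:
        raise ConfigError("trace CSV needs a 'signal_au' column")
    traces = []
    groups = df.groupby("fly_id") if "fly_id" in df.columns \
        else [("fly0", df)]
    for fly_id, sub in groups:
        if "time_s" in sub.columns:
            t = sub["time_s"].to_numpy(float)
            interval = float(np.median(np.diff(t))) if len(t) > 1 \
                else SAMPLING_INTERVAL_S
        else:
            interval = SAMPLING_INTERVAL_S
        traces.append(FlicTrace(fly_id=str(fly_id),
                                samples=sub["signal_au"].to_numpy(float),
                                sampling_interval_s=interval))
    return traces
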