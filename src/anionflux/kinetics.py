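"""Residence-event detection, survival curves and double-exponential fits.

For each compartment, a residence event is a maximal uninterrupted run of
frames an anion spends inside it.  Events are aligned at their start times;
the survival probability C(t) = N(t)/N0 is the fraction of events still
unbroken after elapsed time t.  C(t) is fitted with

    C(t) = A1 exp(-t/lambda1) + A2 exp(-t/lambda2)

and the amplitude-weighted mean residence time is

    tau = (A1 lambda1 + A2 lambda2) / (A1 + A2),

a convex combination of the two time constants that quantifies the overall
confinement strength.  Events still running at the final frame are censored:
they count as "surviving" up to their censoring time and leave the risk set
beyond it (removed from numerator and denominator), which keeps C(t)
non-increasing without biasing it upward.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from anionflux.compartments import LABEL_NAMES, LabelSeries


class InsufficientStatisticsError(ValueError):
    """Too few residence events to build a survival curve."""


class FitFailureError(RuntimeError):
    """Nonlinear fit failed from every start; carries the single-exp fallback."""

    def __init__(self, message, fallback=None):
        super().__init__(message)
        self.fallback = fallback


class DegenerateFitError(ValueError):
    """Fit amplitudes sum to zero."""


@dataclass(frozen=True)
class ResidenceEvent:
    anion_id: int
    compartment: int
    start_frame: int
    duration: float  # frames * frame spacing
    censored: bool

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")


@dataclass
class SurvivalCurve:
    """C(t) on the frame grid with the raw counts behind it."""

    times: np.ndarray
    N_t: np.ndarray  # events still resident at t (numerator)
    n_at_risk: np.ndarray  # events of known status at t (denominator)
    N0: int
    C: np.ndarray

    def __post_init__(self) -> None:
        if not np.isclose(self.C[0], 1.0):
            raise ValueError("C(0) must be 1")


@dataclass
class DoubleExpFit:
    A1: float
    lambda1: float
    A2: float
    lambda2: float
    tau: float
    rss: float
    selected_model: str  # "single" | "double"
    single_exp: tuple[float, float] | None = None  # (A, lambda) comparison fit


def find_events(
    labels: LabelSeries, compartment: int, gap_tolerance: int = 0
) -> list[ResidenceEvent]:
    """Maximal runs of ``compartment`` per anion.

    ``gap_tolerance`` frames outside the compartment are bridged (default 0:
    a single frame outside ends the event).  Runs touching the final frame
    are censored.  A single-frame run has duration one frame spacing.
    """
    arr = labels.labels
    dt = labels.frame_dt
    n_frames = labels.n_frames
    events: list[ResidenceEvent] = []
    for aid in range(labels.n_anions):
        inside = arr[aid] == compartment
        if gap_tolerance > 0:
            inside = _bridge_gaps(inside, gap_tolerance)
        if not inside.any():
            continue
        padded = np.concatenate([[False], inside, [False]])
        d = np.diff(padded.astype(int))
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1)  # exclusive
        for s, e in zip(starts, ends):
            censored = e == n_frames
            events.append(
                ResidenceEvent(
                    anion_id=aid,
                    compartment=compartment,
                    start_frame=int(s),
                    duration=float((e - s) * dt),
                    censored=bool(censored),
                )
            )
    return events


def _bridge_gaps(inside: np.ndarray, tol: int) -> np.ndarray:
    """Fill runs of at most ``tol`` False frames that separate True runs."""
    out = inside.copy()
    padded = np.concatenate([[True], inside, [True]])
    d = np.diff(padded.astype(int))
    gap_starts = np.flatnonzero(d == -1)
    gap_ends = np.flatnonzero(d == 1)
    for s, e in zip(gap_starts, gap_ends):
        # interior gaps only: must be flanked by True on both sides
        if s > 0 and e < len(inside) and (e - s) <= tol:
            out[s:e] = True
    return out


def survival_curve(
    events: list[ResidenceEvent], frame_dt: float | None = None, min_events: int = 20
) -> SurvivalCurve:
    """Align events at t = 0 and build C(t) = N(t)/N0 on the frame grid.

    Censored events stay in the risk set until their censoring time and are
    dropped from numerator and denominator beyond it.
    """
    if not events:
        raise InsufficientStatisticsError("no residence events")
    uncensored = [ev for ev in events if not ev.censored]
    if not uncensored:
        raise InsufficientStatisticsError(
            f"all events in compartment "
            f"{LABEL_NAMES.get(events[0].compartment, events[0].compartment)} are censored"
        )
    n0 = len(events)
    if n0 < min_events:
        comp = LABEL_NAMES.get(events[0].compartment, events[0].compartment)
        raise InsufficientStatisticsError(
            f"only {n0} events in compartment {comp}; need at least {min_events}"
        )
    durations = np.array([ev.duration for ev in events])
    censored = np.array([ev.censored for ev in events])
    if frame_dt is None:
        pos = durations[durations > 0]
        frame_dt = float(np.min(pos))
    t_max = float(durations.max())
    times = np.arange(0.0, t_max + 0.5 * frame_dt, frame_dt)
    # numerator: events known to still be resident at t
    num = np.array([np.sum(durations > t) for t in times])
    # denominator: events whose status at t is known (censored ones leave)
    den = np.array([n0 - np.sum(censored & (durations <= t)) for t in times])
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.where(den > 0, num / np.maximum(den, 1), 0.0)
    return SurvivalCurve(times=times, N_t=num, n_at_risk=den, N0=n0, C=C)


def _aicc(rss: float, n: int, k: int) -> float:
    rss = max(rss, 1e-300)
    aic = n * np.log(rss / n) + 2 * k
    if n - k - 1 > 0:
        aic += 2 * k * (k + 1) / (n - k - 1)
    return aic


def _double(t, a1, l1, a2, l2):
    return a1 * np.exp(-t / l1) + a2 * np.exp(-t / l2)


def _single(t, a, l):
    return a * np.exp(-t / l)


def fit_double_exp(curve: SurvivalCurve, min_tail_events: int = 5) -> DoubleExpFit:
    """Bounded nonlinear least-squares fit of the double exponential.

    The fit grid is truncated to points where the numerator still holds at
    least ``min_tail_events`` events (tail noise control).  Initialization is
    multi-start from a log-linear single-exponential fit whose time constant
    is split into lambda/3 and 3*lambda.  A single-exponential alternative is
    always fitted; the better model by small-sample AICc is reported, with
    A2 = 0 marking an effective single exponential.  Deterministic.
    """
    keep = (curve.C > 0) & (curve.N_t >= min_tail_events)
    keep[0] = True
    t = curve.times[keep]
    y = curve.C[keep]
    if len(t) < 6:
        raise InsufficientStatisticsError(
            f"only {len(t)} usable points on the survival curve; need >= 6"
        )
    # log-linear single-exp initialization
    pos = y > 0
    slope, intercept = np.polyfit(t[pos], np.log(y[pos]), 1)
    lam0 = -1.0 / slope if slope < 0 else float(t[-1])
    lam0 = float(np.clip(lam0, 1e-8, 1e8))
    a0 = float(np.clip(np.exp(intercept), 1e-8, 10.0))

    try:
        p_single, _ = curve_fit(
            _single, t, y, p0=[a0, lam0], bounds=([0, 1e-12], [np.inf, np.inf]), maxfev=10000
        )
        rss_single = float(np.sum((_single(t, *p_single) - y) ** 2))
    except RuntimeError:
        p_single, rss_single = (a0, lam0), float(np.sum((_single(t, a0, lam0) - y) ** 2))

    starts = [
        [a0 / 2, lam0 / 3.0, a0 / 2, lam0 * 3.0],
        [0.7 * a0, lam0, 0.3 * a0, lam0 * 10.0],
        [0.3 * a0, lam0 / 10.0, 0.7 * a0, lam0],
    ]
    best = None
    for p0 in starts:
        try:
            popt, _ = curve_fit(
                _double,
                t,
                y,
                p0=p0,
                bounds=([0, 1e-12, 0, 1e-12], [np.inf, np.inf, np.inf, np.inf]),
                maxfev=20000,
            )
        except RuntimeError:
            continue
        rss = float(np.sum((_double(t, *popt) - y) ** 2))
        if best is None or rss < best[1]:
            best = (popt, rss)
    if best is None:
        fallback = DoubleExpFit(
            A1=float(p_single[0]),
            lambda1=float(p_single[1]),
            A2=0.0,
            lambda2=float(p_single[1]),
            tau=float(p_single[1]),
            rss=rss_single,
            selected_model="single",
            single_exp=(float(p_single[0]), float(p_single[1])),
        )
        raise FitFailureError(
            "double-exponential fit failed from every start", fallback=fallback
        )
    popt, rss_double = best
    n = len(t)
    use_single = _aicc(rss_single, n, 2) < _aicc(rss_double, n, 4)
    if use_single:
        a, lam = float(p_single[0]), float(p_single[1])
        return DoubleExpFit(
            A1=a,
            lambda1=lam,
            A2=0.0,
            lambda2=lam,
            tau=lam,
            rss=rss_single,
            selected_model="single",
            single_exp=(a, lam),
        )
    a1, l1, a2, l2 = (float(v) for v in popt)
    if l1 > l2:
        a1, l1, a2, l2 = a2, l2, a1, l1
    if a1 + a2 <= 0:
        raise DegenerateFitError("fitted amplitudes sum to zero")
    tau = (a1 * l1 + a2 * l2) / (a1 + a2)
    return DoubleExpFit(
        A1=a1,
        lambda1=l1,
        A2=a2,
        lambda2=l2,
        tau=tau,
        rss=rss_double,
        selected_model="double",
        single_exp=(float(p_single[0]), float(p_single[1])),
    )


def mean_residence_time(fit: DoubleExpFit) -> float:
    """Amplitude-weighted mean lifetime (A1 l1 + A2 l2)/(A1 + A2)."""
    if fit.A1 + fit.A2 <= 0:
        raise DegenerateFitError("A1 + A2 must be positive")
    return (fit.A1 * fit.lambda1 + fit.A2 * fit.lambda2) / (fit.A1 + fit.A2)


def compartment_tau(
    labels: LabelSeries,
    compartment: int,
    min_events: int = 20,
    gap_tolerance: int = 0,
    drop_censored: bool = False,
) -> dict:
    """events -> survival curve -> fit -> tau for one compartment.

    Returns a flat dict suitable for tabular reports.  ``drop_censored``
    switches to the strict mode that discards censored events entirely.
    """
    events = find_events(labels, compartment, gap_tolerance=gap_tolerance)
    if drop_censored:
        events = [ev for ev in events if not ev.censored]
    curve = survival_curve(events, frame_dt=labels.frame_dt, min_events=min_events)
    fit = fit_double_exp(curve)
    return {
        "compartment": LABEL_NAMES[compartment],
        "A1": fit.A1,
        "lambda1": fit.lambda1,
        "A2": fit.A2,
        "lambda2": fit.lambda2,
        "tau": fit.tau,
        "rss": fit.rss,
        "model": fit.selected_model,
        "n_events": len(events),
        "n_censored": int(sum(ev.censored for ev in events)),
    }
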