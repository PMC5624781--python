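"""One-phase exponential fits of MANT-nucleotide exchange fluorescence traces.

GDP release is monitored as a fluorescence decay after adding excess unlabeled
nucleotide, F(t) = (F0 - P) exp(-k t) + P; GEF-facilitated GTP loading as an
association, F(t) = F0 + (Fmax - F0)(1 - exp(-k t)). Rates are stored in s^-1
and reported in 1e-4 s^-1. Traces that cannot be described by the one-phase
model (wrong monotonicity, unidentifiable amplitude, post-maximum signal loss)
are flagged rather than force-fitted, and any unfittable replicate marks the
whole condition "not determined".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "KineticTrace",
    "RateFit",
    "RateSummary",
    "fit_decay",
    "fit_association",
    "summarize_replicates",
    "read_traces",
]

RATE_REPORT_UNIT = 1e-4  # rates are printed in units of 1e-4 s^-1


@dataclass
class KineticTrace:
    """A fluorescence time course.

    ``condition`` is ``"dissociation"`` (decay) or ``"association"``;
    ``event_time`` marks a mid-course reagent addition (association fits use
    only t >= event_time).
    """

    t: np.ndarray
    F: np.ndarray
    condition: str
    gef: bool = False
    replicate: int = 0
    event_time: float | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.t.shape != self.F.shape:
            raise ValueError("t/F length mismatch")
        if len(self.t) < 10:
            raise ValueError("trace needs at least 10 points")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")
        if self.condition not in ("dissociation", "association"):
            raise ValueError(f"unknown condition {self.condition!r}")


@dataclass
class RateFit:
    """Result of a one-phase exponential fit."""

    model: str  # "decay" | "association"
    k: float  # s^-1
    k_se: float
    amplitude: float
    plateau: float
    r_squared: float
    fitted: bool
    leaky: bool = False
    message: str = ""

    @property
    def k_report(self) -> float:
        """Rate in the reporting unit (1e-4 s^-1)."""
        return self.k / RATE_REPORT_UNIT


@dataclass
class RateSummary:
    """Replicate mean ± SD (in 1e-4 s^-1), or a not-determined flag."""

    mean_k: float | None
    sd_k: float | None
    n: int
    nd: bool
    reason: str = ""


def _edge_mean(F: np.ndarray, frac: float = 0.1) -> tuple[float, float]:
    m = max(int(len(F) * frac), 3)
    return float(F[:m].mean()), float(F[-m:].mean())


def _r_squared(y: np.ndarray, fit: np.ndarray) -> float:
    ss_res = float(((y - fit) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0


def _fit_exponential(t, F, model: str, r2_min: float) -> RateFit:
    t = t - t[0]  # the model is invariant under time translation
    head, tail = _edge_mean(F)
    amp0 = F.max() - F.min()
    if amp0 <= 0 or not np.isfinite(amp0):
        return RateFit(model, np.nan, np.nan, 0.0, float(F.mean()), 0.0, False,
                       message="zero amplitude")

    # log-linear pre-fit for the initial rate guess
    if model == "decay":
        resid0 = F - F.min() + 0.05 * amp0
    else:
        resid0 = F.max() + 0.05 * amp0 - F
    with np.errstate(invalid="ignore", divide="ignore"):
        ylog = np.log(resid0)
    good = np.isfinite(ylog)
    k0 = 1.0 / max(t[-1] / 3.0, 1e-9)
    if good.sum() >= 3:
        slope = np.polyfit(t[good], ylog[good], 1)[0]
        if slope < 0:
            k0 = -slope

    if model == "decay":
        def f(t, k, F0, P):
            return (F0 - P) * np.exp(-k * t) + P
        p0_base = (F[0], tail)
    else:
        def f(t, k, F0, Fmax):
            return F0 + (Fmax - F0) * (1.0 - np.exp(-k * t))
        p0_base = (F[0], tail)

    best = None
    for factor in (1.0, 0.2, 0.5, 2.0, 5.0):
        try:
            popt, pcov = curve_fit(
                f, t, F, p0=(k0 * factor, *p0_base),
                bounds=([0.0, -np.inf, -np.inf], [np.inf, np.inf, np.inf]),
                maxfev=10000,
            )
        except (RuntimeError, ValueError):
            continue
        r2 = _r_squared(F, f(t, *popt))
        if best is None or r2 > best[2]:
            best = (popt, pcov, r2)
    if best is None:
        return RateFit(model, np.nan, np.nan, np.nan, np.nan, 0.0, False,
                       message="optimizer failed")
    popt, pcov, r2 = best
    k = float(popt[0])
    k_se = float(np.sqrt(pcov[0, 0])) if np.all(np.isfinite(pcov)) else np.inf
    if model == "decay":
        amplitude, plateau = float(popt[1] - popt[2]), float(popt[2])
    else:
        amplitude, plateau = float(popt[2] - popt[1]), float(popt[2])
    fitted = (r2 >= r2_min) and (k_se < k) and k > 0
    msg = "" if fitted else f"rejected: R2={r2:.3f}, k={k:.3g}, SE={k_se:.3g}"
    return RateFit(model, k, k_se, amplitude, plateau, float(r2), fitted, message=msg)


def fit_decay(trace: KineticTrace, r2_min: float = 0.90) -> RateFit:
    """Fit a one-phase exponential decay to a dissociation trace.

    The fit is rejected (``fitted=False``) if the trace is not net-decreasing,
    the amplitude is degenerate, R^2 < ``r2_min`` or the rate's standard error
    reaches the rate itself.
    """
    if trace.condition != "dissociation":
        raise ValueError("fit_decay expects a dissociation trace")
    head, tail = _edge_mean(trace.F)
    spread = trace.F.max() - trace.F.min()
    if spread == 0 or head - tail < 0.02 * spread:
        return RateFit("decay", np.nan, np.nan, 0.0, float(trace.F.mean()), 0.0, False,
                       message="trace is not net-decreasing")
    return _fit_exponential(trace.t, trace.F, "decay", r2_min)


def fit_association(
    trace: KineticTrace, r2_min: float = 0.90, leak_fraction: float = 0.10
) -> RateFit:
    """Fit a one-phase exponential association, flagging post-maximum signal loss.

    If the trace carries an ``event_time`` (mid-course GEF addition) only
    t >= event_time is fitted. A trace whose fluorescence falls after its
    maximum by more than ``leak_fraction`` of the amplitude is flagged
    ``leaky`` and left unfitted: such signal loss indicates nucleotide release
    competing with loading, which the one-phase model cannot describe.
    """
    if trace.condition != "association":
        raise ValueError("fit_association expects an association trace")
    t, F = trace.t, trace.F
    if trace.event_time is not None:
        mask = t >= trace.event_time
        if mask.sum() < 10:
            raise ValueError("fewer than 10 points after the addition event")
        t, F = t[mask], F[mask]
    head, tail = _edge_mean(F)
    spread = F.max() - F.min()
    if spread == 0 or tail - head < 0.02 * spread:
        return RateFit("association", np.nan, np.nan, 0.0, float(F.mean()), 0.0, False,
                       message="trace is not net-increasing")
    # leak check: smoothed signal loss after the maximum
    win = max(len(F) // 20, 1)
    smooth = np.convolve(F, np.ones(win) / win, mode="valid")
    imax = int(np.argmax(smooth))
    drop = smooth[imax] - smooth[imax:].min()
    amplitude = smooth[imax] - smooth[0]
    if amplitude > 0 and drop > leak_fraction * amplitude:
        return RateFit("association", np.nan, np.nan, float(amplitude), np.nan, 0.0,
                       False, leaky=True,
                       message="signal decreases after its maximum (leaky)")
    return _fit_exponential(t, F, "association", r2_min)


def summarize_replicates(fits: list[RateFit]) -> RateSummary:
    """Replicate mean ± SD in 1e-4 s^-1, or 'not determined' if any replicate failed.

    Mirrors the reporting convention of exchange-rate tables: a condition
    whose curves cannot all be described by the one-phase model is ND rather
    than summarized from the fittable subset.
    """
    if not fits:
        raise ValueError("no fits to summarize")
    bad = [f for f in fits if not f.fitted]
    if bad:
        reasons = "; ".join(f.message or ("leaky" if f.leaky else "unfitted") for f in bad)
        return RateSummary(None, None, len(fits), True, reason=reasons)
    ks = np.array([f.k_report for f in fits])
    return RateSummary(float(ks.mean()), float(ks.std(ddof=0)), len(fits), False)


def read_traces(source) -> list[KineticTrace]:
    """Read long-format kinetics data (t, F, condition, replicate, gef[, event_time]).

    Accepts a path or file-like object with a CSV/TSV table; one
    :class:`KineticTrace` is returned per (condition, gef, replicate) group.
    """
    import pandas as pd

    df = pd.read_csv(source, sep=None, engine="python")
    required = {"t", "F", "condition", "replicate", "gef"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    traces = []
    for (cond, gef, rep), grp in df.groupby(["condition", "gef", "replicate"]):
        grp = grp.sort_values("t")
        event = None
        if "event_time" in grp.columns and grp["event_time"].notna().any():
            event = float(grp["event_time"].dropna().iloc[0])
        traces.append(
            KineticTrace(grp["t"].to_numpy(), grp["F"].to_numpy(), str(cond),
                         gef=bool(gef), replicate=int(rep), event_time=event)
        )
    return traces
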