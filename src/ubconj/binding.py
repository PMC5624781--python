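"""1:1 biolayer-interferometry binding kinetics.

A ligand-coated sensor is dipped into analyte at concentration C
(association) and then into buffer (dissociation). Under the 1:1 Langmuir
model the response follows

    association:   R(t) = Req (1 - exp(-(kon C + koff) t)),
                   Req  = Rmax C / (C + Kd),  Kd = koff / kon
    dissociation:  R(t) = R0 exp(-koff (t - t_d))

with R0 the response at the end of association (continuity). kon and koff
are shared across a concentration series in a global fit with one Rmax per
concentration; the affinity is Kd = koff / kon with its standard error
propagated as dKd = Kd sqrt((dkon/kon)^2 + (dkoff/koff)^2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "Sensorgram",
    "OneToOneFit",
    "AffinityResult",
    "kd_from_rates",
    "propagate_kd_sem",
    "fit_sensorgram_global",
    "EFFECTOR_KINETICS_TABLE",
    "consistency_report",
    "read_sensorgrams",
]


@dataclass
class Sensorgram:
    """One BLI trace at a single analyte concentration.

    ``assoc_start``/``assoc_end`` bound the association phase in seconds;
    points before ``assoc_start`` are baseline, points after ``assoc_end``
    are the dissociation phase.
    """

    t: np.ndarray
    response: np.ndarray
    conc: float  # analyte concentration, M
    assoc_start: float
    assoc_end: float
    replicate: int = 0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.t.shape != self.response.shape:
            raise ValueError("t/response length mismatch")
        if self.conc <= 0:
            raise ValueError("concentration must be positive")
        if not self.assoc_start < self.assoc_end:
            raise ValueError("phases must be ordered: assoc_start < assoc_end")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")


@dataclass
class OneToOneFit:
    """Globally fitted 1:1 kinetics across a concentration series."""

    kon: float  # M^-1 s^-1
    kon_se: float
    koff: float  # s^-1
    koff_se: float
    rmax: dict[float, float]  # per-concentration Rmax
    residual_rms: float
    success: bool
    message: str = ""

    @property
    def kd(self) -> float:
        return kd_from_rates(self.kon, self.koff)

    @property
    def kd_se(self) -> float:
        return propagate_kd_sem(self.kon, self.kon_se, self.koff, self.koff_se)


@dataclass
class AffinityResult:
    kd: float  # M
    kd_se: float

    @property
    def kd_uM(self) -> float:
        return self.kd * 1e6

    @property
    def kd_se_uM(self) -> float:
        return self.kd_se * 1e6


def kd_from_rates(kon: float, koff: float) -> float:
    """Equilibrium dissociation constant Kd = koff / kon (M)."""
    if kon <= 0 or koff <= 0:
        raise ValueError("rate constants must be positive")
    return koff / kon


def propagate_kd_sem(kon: float, dkon: float, koff: float, dkoff: float) -> float:
    """SEM of Kd by first-order propagation of the rate-constant SEMs.

    dKd = (koff/kon) sqrt((dkon/kon)^2 + (dkoff/koff)^2); homogeneous of
    degree 1 in (dkon, dkoff) at fixed rates.
    """
    if kon <= 0 or koff <= 0:
        raise ValueError("rate constants must be positive")
    if dkon < 0 or dkoff < 0:
        raise ValueError("SEMs must be non-negative")
    kd = koff / kon
    return kd * np.sqrt((dkon / kon) ** 2 + (dkoff / koff) ** 2)


def _model_response(sg: Sensorgram, kon: float, koff: float, rmax: float) -> np.ndarray:
    """Piecewise 1:1 response over a sensorgram's time grid (baseline = 0)."""
    t = sg.t
    out = np.zeros_like(t)
    kobs = kon * sg.conc + koff
    req = rmax * kon * sg.conc / kobs  # = Rmax C / (C + Kd)
    assoc = (t >= sg.assoc_start) & (t <= sg.assoc_end)
    out[assoc] = req * (1.0 - np.exp(-kobs * (t[assoc] - sg.assoc_start)))
    r0 = req * (1.0 - np.exp(-kobs * (sg.assoc_end - sg.assoc_start)))
    dissoc = t > sg.assoc_end
    out[dissoc] = r0 * np.exp(-koff * (t[dissoc] - sg.assoc_end))
    return out


def fit_sensorgram_global(sensorgrams: list[Sensorgram]) -> OneToOneFit:
    """Global nonlinear least squares: shared kon/koff, one Rmax per concentration.

    Replicates at the same concentration share an Rmax. Standard errors come
    from the Gauss-Newton covariance at the optimum. A single-concentration
    series is fitted with a warning (kon and Rmax are then weakly
    identifiable); a singular covariance yields ``success=False``.
    """
    if not sensorgrams:
        raise ValueError("no sensorgrams")
    concs = sorted({sg.conc for sg in sensorgrams})
    if len(concs) < 2:
        warnings.warn("single analyte concentration: kon/Rmax weakly identifiable",
                      stacklevel=2)
    conc_index = {c: i for i, c in enumerate(concs)}

    rmax0 = max(sg.response.max() for sg in sensorgrams)
    tspan = max(sg.assoc_end - sg.assoc_start for sg in sensorgrams)
    # log-parameterization keeps rates positive
    x0 = np.concatenate([[np.log(1.0 / (tspan * np.mean(concs))), np.log(1.0 / tspan)],
                         np.log(np.full(len(concs), max(rmax0, 1e-12)))])

    def unpack(x):
        kon, koff = np.exp(x[0]), np.exp(x[1])
        rmax = np.exp(x[2:])
        return kon, koff, rmax

    def residuals(x):
        kon, koff, rmax = unpack(x)
        res = [
            sg.response - _model_response(sg, kon, koff, rmax[conc_index[sg.conc]])
            for sg in sensorgrams
        ]
        return np.concatenate(res)

    sol = least_squares(residuals, x0, method="trf", max_nfev=20000)
    kon, koff, rmax = unpack(sol.x)

    # covariance in the original (kon, koff) scale via the chain rule
    m = len(sol.fun)
    ndof = max(m - len(sol.x), 1)
    s2 = float(sol.fun @ sol.fun) / ndof
    JTJ = sol.jac.T @ sol.jac
    try:
        cov_log = np.linalg.inv(JTJ) * s2
        singular = False
    except np.linalg.LinAlgError:
        cov_log = np.full((len(sol.x), len(sol.x)), np.nan)
        singular = True
    kon_se = kon * float(np.sqrt(cov_log[0, 0])) if not singular else np.nan
    koff_se = koff * float(np.sqrt(cov_log[1, 1])) if not singular else np.nan
    return OneToOneFit(
        kon=float(kon),
        kon_se=kon_se,
        koff=float(koff),
        koff_se=koff_se,
        rmax={c: float(rmax[conc_index[c]]) for c in concs},
        residual_rms=float(np.sqrt(np.mean(sol.fun ** 2))),
        success=sol.success and not singular,
        message="singular covariance" if singular else sol.message,
    )


# ---------------------------------------------------------------------------
# printed effector-binding kinetics (input data) and consistency checking

#: Published effector-binding kinetics used as pipeline inputs:
#: (kon, kon_sem) in 1e2 M^-1 s^-1, (koff, koff_sem) in 1e-3 s^-1,
#: (kd, kd_sem) in µM, keyed by (GTPase variant, effector).
EFFECTOR_KINETICS_TABLE: dict[tuple[str, str], dict[str, float]] = {
    ("Rab5", "Rabaptin5"): dict(kon=6.6, kon_sem=2.8, koff=2.2, koff_sem=0.2, kd=8.0, kd_sem=3.4),
    ("mUbRab5_K116", "Rabaptin5"): dict(kon=2.4, kon_sem=0.1, koff=1.9, koff_sem=0.1, kd=8.0, kd_sem=0.6),
    ("mUbRab5_K140", "Rabaptin5"): dict(kon=13.9, kon_sem=1.8, koff=52.3, koff_sem=1.4, kd=37.7, kd_sem=4.9),
    ("mUbRab5_K165", "Rabaptin5"): dict(kon=3.2, kon_sem=0.1, koff=1.4, koff_sem=0.1, kd=4.4, kd_sem=0.2),
    ("Rab5", "EEA1"): dict(kon=4.5, kon_sem=0.2, koff=2.6, koff_sem=0.1, kd=5.8, kd_sem=0.3),
    ("mUbRab5_K116", "EEA1"): dict(kon=1.9, kon_sem=0.2, koff=5.0, koff_sem=0.2, kd=18.4, kd_sem=0.8),
    ("mUbRab5_K140", "EEA1"): dict(kon=1.8, kon_sem=0.4, koff=19.7, koff_sem=0.8, kd=108.0, kd_sem=22.0),
    ("mUbRab5_K165", "EEA1"): dict(kon=1.9, kon_sem=0.8, koff=0.9, koff_sem=0.1, kd=4.7, kd_sem=0.5),
}

KON_UNIT = 1e2  # table kon values are in 1e2 M^-1 s^-1
KOFF_UNIT = 1e-3  # table koff values are in 1e-3 s^-1


def affinity_from_table_row(row: dict[str, float]) -> AffinityResult:
    """Kd ± SEM recomputed from a table row's printed rate constants."""
    kon = row["kon"] * KON_UNIT
    koff = row["koff"] * KOFF_UNIT
    kd = kd_from_rates(kon, koff)
    kd_se = propagate_kd_sem(kon, row["kon_sem"] * KON_UNIT, koff, row["koff_sem"] * KOFF_UNIT)
    return AffinityResult(kd=kd, kd_se=kd_se)


def consistency_report(
    table: dict[tuple[str, str], dict[str, float]] | None = None,
    rel_tolerance: float = 0.0125,
) -> dict[tuple[str, str], dict[str, float]]:
    """Check each table row's printed Kd against koff/kon from its printed rates.

    Rows whose recomputed Kd deviates from the printed Kd by more than
    ``rel_tolerance`` (relative) are flagged ``inconsistent``; such rows are
    surfaced, never silently corrected.
    """
    table = table if table is not None else EFFECTOR_KINETICS_TABLE
    report = {}
    for key, row in table.items():
        derived = affinity_from_table_row(row)
        rel_dev = abs(derived.kd_uM - row["kd"]) / row["kd"]
        report[key] = {
            "printed_kd_uM": row["kd"],
            "derived_kd_uM": derived.kd_uM,
            "derived_kd_sem_uM": derived.kd_se_uM,
            "relative_deviation": rel_dev,
            "inconsistent": rel_dev > rel_tolerance,
        }
    return report


def read_sensorgrams(source) -> list[Sensorgram]:
    """Read long-format BLI data (t, response, conc_M, phase, replicate).

    ``phase`` must be one of baseline/association/dissociation; phase
    boundaries are inferred per (conc_M, replicate) group from the phase
    labels.
    """
    import pandas as pd

    df = pd.read_csv(source, sep=None, engine="python")
    required = {"t", "response", "conc_M", "phase", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    out = []
    for (conc, rep), grp in df.groupby(["conc_M", "replicate"]):
        grp = grp.sort_values("t")
        assoc_t = grp.loc[grp["phase"] == "association", "t"]
        if assoc_t.empty:
            raise ValueError(f"no association phase for conc={conc}, replicate={rep}")
        out.append(
            Sensorgram(
                grp["t"].to_numpy(), grp["response"].to_numpy(), float(conc),
                assoc_start=float(assoc_t.min()), assoc_end=float(assoc_t.max()),
                replicate=int(rep),
            )
        )
    return out
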