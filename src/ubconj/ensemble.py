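"""Genetic-algorithm selection of a sub-ensemble that fits an experimental curve.

A chromosome is a fixed-size multiset of pool indices (repeats allowed); its
fitness is the negative reduced chi-square of the multiset-averaged theoretical
curve against the experimental curve after analytic scaling. The GA uses
tournament selection, uniform crossover, per-gene mutation to a random pool
index and elitism; the initial population is seeded with the best single
conformer repeated, which makes the final chi-square provably no worse than
any single-conformer fit. Many independent runs are performed and the
lowest-chi-square solution kept, mirroring the repeat-and-select protocol of
ensemble-optimization practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ubconj.saxs import ScatteringCurve, _chi2_scale_arrays

__all__ = [
    "GAConfig",
    "EnsembleSolution",
    "EnsembleSummary",
    "run_ga",
    "select_best",
    "summarize_ensemble",
    "pool_curve_matrix",
]


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm hyperparameters.

    ensemble_size : number of (repeatable) members per chromosome.
    population : chromosomes per generation.
    generations : maximum generations per run.
    mutation_rate : per-gene probability of resetting to a random pool index.
    crossover_rate : per-pair probability of uniform crossover.
    elitism : number of best chromosomes copied unchanged each generation.
    runs : independent GA repetitions in :func:`select_best`.
    patience : stop a run early after this many generations without
        improvement of the best chi-square (None disables early stopping).
    """

    ensemble_size: int = 20
    population: int = 50
    generations: int = 1000
    mutation_rate: float = 0.1
    crossover_rate: float = 0.5
    elitism: int = 1
    runs: int = 100
    seed: int = 0
    patience: int | None = 200

    def __post_init__(self) -> None:
        if min(self.ensemble_size, self.population, self.generations, self.elitism, self.runs) < 1:
            raise ValueError("all counts must be >= 1")
        for rate in (self.mutation_rate, self.crossover_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")


@dataclass
class EnsembleSolution:
    """Best multiset found by one (or the best of many) GA run(s)."""

    members: np.ndarray  # pool indices, length ensemble_size, sorted
    scale: float
    chi2: float
    run_id: int
    trace: np.ndarray  # best chi2 per generation
    per_run_chi2: np.ndarray | None = None

    @property
    def weights(self) -> dict[int, float]:
        """Implied weights: multiplicity / ensemble size, keyed by pool index."""
        idx, counts = np.unique(self.members, return_counts=True)
        ne = len(self.members)
        return {int(i): float(c) / ne for i, c in zip(idx, counts)}


def pool_curve_matrix(pool_curves: list[ScatteringCurve], exp: ScatteringCurve) -> np.ndarray:
    """Stack pool curves interpolated onto the experimental q grid, shape (n_pool, K)."""
    if not pool_curves:
        raise ValueError("empty pool")
    rows = []
    for c in pool_curves:
        if exp.q[0] < c.q[0] - 1e-12 or exp.q[-1] > c.q[-1] + 1e-12:
            raise ValueError("experimental q outside a pool curve's grid")
        rows.append(np.interp(exp.q, c.q, c.I))
    return np.vstack(rows)


def _population_chi2(pop: np.ndarray, pool_I: np.ndarray, Ie: np.ndarray,
                     sig: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Chi-square and analytic scale of every chromosome's averaged curve."""
    avg = pool_I[pop].mean(axis=1)  # (pop, K)
    w = 1.0 / sig ** 2
    s = (avg * (w * Ie)).sum(axis=1) / (avg ** 2 * w).sum(axis=1)
    resid = s[:, None] * avg - Ie
    chi2 = (w * resid ** 2).sum(axis=1) / max(len(Ie) - 1, 1)
    return chi2, s


def run_ga(
    pool_curves: list[ScatteringCurve] | np.ndarray,
    exp: ScatteringCurve,
    config: GAConfig | None = None,
    rng: np.random.Generator | None = None,
    run_id: int = 0,
) -> EnsembleSolution:
    """One GA run over multisets of pool members against an experimental curve."""
    config = config or GAConfig()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    pool_I = pool_curves if isinstance(pool_curves, np.ndarray) else pool_curve_matrix(pool_curves, exp)
    if pool_I.ndim != 2 or pool_I.shape[0] == 0:
        raise ValueError("empty pool")
    n_pool = pool_I.shape[0]
    ne, npop = config.ensemble_size, config.population
    if exp.sigma is None:
        raise ValueError("experimental curve needs uncertainties")
    Ie, sig = exp.I, exp.sigma

    pop = rng.integers(0, n_pool, size=(npop, ne))
    # seed with the best single conformer repeated: guarantees the final
    # solution is at least as good as any single-conformer fit
    single_chi2, _ = _population_chi2(np.arange(n_pool)[:, None], pool_I, Ie, sig)
    pop[0, :] = int(np.argmin(single_chi2))

    trace = []
    best_members = None
    best_chi2 = np.inf
    best_scale = np.nan
    stall = 0
    for _gen in range(config.generations):
        chi2, scale = _population_chi2(pop, pool_I, Ie, sig)
        order = np.argsort(chi2)
        if chi2[order[0]] < best_chi2 - 1e-15:
            best_chi2 = float(chi2[order[0]])
            best_members = pop[order[0]].copy()
            best_scale = float(scale[order[0]])
            stall = 0
        else:
            stall += 1
        trace.append(best_chi2)
        if config.patience is not None and stall >= config.patience:
            break

        elite = pop[order[: config.elitism]]
        # tournament selection (size 2)
        a = rng.integers(0, npop, size=npop - config.elitism)
        b = rng.integers(0, npop, size=npop - config.elitism)
        winners = np.where(chi2[a] <= chi2[b], a, b)
        children = pop[winners].copy()
        # uniform crossover between consecutive pairs
        for i in range(0, len(children) - 1, 2):
            if rng.random() < config.crossover_rate:
                swap = rng.random(ne) < 0.5
                tmp = children[i, swap].copy()
                children[i, swap] = children[i + 1, swap]
                children[i + 1, swap] = tmp
        # per-gene mutation
        mut = rng.random(children.shape) < config.mutation_rate
        children[mut] = rng.integers(0, n_pool, size=int(mut.sum()))
        pop = np.vstack([elite, children])

    return EnsembleSolution(
        members=np.sort(best_members),
        scale=best_scale,
        chi2=best_chi2,
        run_id=run_id,
        trace=np.array(trace),
    )


def select_best(
    pool_curves: list[ScatteringCurve] | np.ndarray,
    exp: ScatteringCurve,
    config: GAConfig | None = None,
) -> EnsembleSolution:
    """Run ``config.runs`` independent GA repetitions and keep the lowest chi-square.

    Run ``r`` uses the derived substream ``default_rng([config.seed, r])``, so
    the result is reproducible and ties break toward the lower run id.
    """
    config = config or GAConfig()
    pool_I = pool_curves if isinstance(pool_curves, np.ndarray) else pool_curve_matrix(pool_curves, exp)
    solutions = [
        run_ga(pool_I, exp, config, rng=np.random.default_rng([config.seed, r]), run_id=r)
        for r in range(config.runs)
    ]
    per_run = np.array([s.chi2 for s in solutions])
    best = solutions[int(np.argmin(per_run))]
    best.per_run_chi2 = per_run
    return best


# ---------------------------------------------------------------------------
# population analysis

@dataclass
class EnsembleSummary:
    """Weighted Rg/Dmax distributions of pool vs selected ensemble, with modes."""

    rg_grid: np.ndarray
    rg_pool_density: np.ndarray
    rg_ensemble_density: np.ndarray
    dmax_grid: np.ndarray
    dmax_pool_density: np.ndarray
    dmax_ensemble_density: np.ndarray
    rg_modes: list[tuple[float, float]]  # (location Å, mass fraction)
    dmax_modes: list[tuple[float, float]]


def _smoothed_histogram(values: np.ndarray, weights: np.ndarray,
                        bin_width: float) -> tuple[np.ndarray, np.ndarray]:
    """Weighted histogram at ``bin_width`` resolution, binomially smoothed.

    Returns (bin centers, smoothed mass per bin). The light [1/4, 1/2, 1/4]
    filter suppresses single-bin jitter while keeping the resolution at the
    bin scale, so populations separated by a few bins stay resolved.
    """
    lo = np.floor(values.min() / bin_width) * bin_width - 2 * bin_width
    nb = int(np.ceil((values.max() + 2 * bin_width - lo) / bin_width)) + 1
    edges = lo + np.arange(nb + 1) * bin_width
    h, _ = np.histogram(values, bins=edges, weights=weights)
    smooth = np.convolve(h, [0.25, 0.5, 0.25], mode="same")
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, smooth


def _find_modes(centers: np.ndarray, mass: np.ndarray,
                depth_fraction: float) -> list[tuple[float, float]]:
    """Modes of a smoothed histogram, merged unless separated by a deep minimum.

    Two adjacent peaks count as distinct modes only if the minimum between
    them falls below ``depth_fraction`` of the smaller peak; otherwise the
    smaller peak is absorbed into the larger one. Each mode is reported as
    (mass centroid of its region, mass fraction), the regions being delimited
    by the separating minima.
    """
    nb = len(mass)
    peaks = [
        i for i in range(1, nb - 1)
        if mass[i] >= mass[i - 1] and mass[i] > mass[i + 1] and mass[i] > 0
    ]
    if not peaks:
        peaks = [int(np.argmax(mass))]
    changed = True
    while changed and len(peaks) > 1:
        changed = False
        for i in range(len(peaks) - 1):
            lo, hi = peaks[i], peaks[i + 1]
            valley = mass[lo:hi + 1].min()
            smaller = min(mass[lo], mass[hi])
            if valley >= depth_fraction * smaller:
                peaks.pop(i if mass[lo] < mass[hi] else i + 1)
                changed = True
                break
    # region boundaries at the separating minima (exclusive of the next region)
    bounds = [0]
    for i in range(len(peaks) - 1):
        lo, hi = peaks[i], peaks[i + 1]
        bounds.append(lo + int(np.argmin(mass[lo:hi + 1])))
    bounds.append(nb)
    total = mass.sum()
    modes = []
    for i, pk in enumerate(peaks):
        seg = slice(bounds[i], bounds[i + 1])
        seg_mass = mass[seg].sum()
        loc = (mass[seg] * centers[seg]).sum() / seg_mass if seg_mass > 0 else centers[pk]
        modes.append((float(loc), float(seg_mass / total)))
    return modes


def summarize_ensemble(
    pool,
    solution: EnsembleSolution,
    bandwidth: float = 1.0,
    depth_fraction: float = 0.5,
) -> EnsembleSummary:
    """Weighted Rg/Dmax population analysis of a selected ensemble vs its pool.

    ``pool`` is a :class:`~ubconj.pool.ConformerPool` (or any object with
    ``rg``/``dmax`` arrays). Distributions are weighted histograms at
    ``bandwidth`` (Å) resolution with light binomial smoothing; modes are
    reported as (mass-centroid location, mass fraction) and two peaks are
    distinct only when separated by a minimum below ``depth_fraction`` of
    the smaller peak.
    """
    rg_all = np.asarray(pool.rg, dtype=float)
    dmax_all = np.asarray(pool.dmax, dtype=float)
    members = solution.members
    wsel = np.full(len(members), 1.0 / len(members))

    out = {}
    for name, values in (("rg", rg_all), ("dmax", dmax_all)):
        grid, pool_dens = _smoothed_histogram(values, np.full(len(values), 1.0 / len(values)),
                                              bandwidth)
        egrid, ens_dens = _smoothed_histogram(values[members], wsel, bandwidth)
        out[name] = (egrid, np.interp(egrid, grid, pool_dens, left=0, right=0), ens_dens,
                     _find_modes(egrid, ens_dens, depth_fraction))

    return EnsembleSummary(
        rg_grid=out["rg"][0],
        rg_pool_density=out["rg"][1],
        rg_ensemble_density=out["rg"][2],
        dmax_grid=out["dmax"][0],
        dmax_pool_density=out["dmax"][1],
        dmax_ensemble_density=out["dmax"][2],
        rg_modes=out["rg"][3],
        dmax_modes=out["dmax"][3],
    )
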