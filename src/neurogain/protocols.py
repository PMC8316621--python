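"""Experiment orchestration: uniform gain/coupling sweeps, incremental
node-by-node neuromodulation, and fixed-size subset neuromodulation with
AUC summaries and statistical comparison."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from neurogain.connectome import Connectome, node_metrics, normalize_connectome
from neurogain.functional import fc_threshold, global_efficiency, modularity_consensus, phase_synchrony
from neurogain.hemodynamics import HemoParameters, bandpass_bold, bold_forward
from neurogain.neural_mass import (
    GainMap,
    JRParameters,
    NoiseSpec,
    SimulationConfig,
    make_gain_map,
    simulate,
)

__all__ = [
    "PipelineSettings",
    "SweepResult",
    "IncrementalResult",
    "SubsetRule",
    "SubsetResult",
    "evaluate_condition",
    "uniform_sweep",
    "incremental_neuromod",
    "subset_neuromod",
    "compare_auc",
]


@dataclass
class PipelineSettings:
    """Simulation/analysis knobs shared by every protocol.

    Defaults reproduce the full-scale protocol (660 s runs, 500 FC
    surrogates, 200 Louvain runs); tests and desk runs pass reduced values.
    ``measures`` controls whether the BOLD/FC branch ("graph") is computed in
    addition to phase synchrony ("sync").
    """

    duration: float = 660.0
    discard: float = 60.0
    dt: float = 0.001
    params: JRParameters = field(default_factory=JRParameters)
    noise_mu: float = 2.0
    noise_sigma: float = 2.0
    fc_surrogates: int = 500
    louvain_runs: int = 200
    band: tuple[float, float] = (0.01, 0.1)
    tr: float = 2.0
    measures: tuple[str, ...] = ("sync", "graph")


@dataclass
class SweepResult:
    alpha_grid: np.ndarray
    r0_grid: np.ndarray
    R_bar: np.ndarray  # alpha x r0, seed means
    E_w: np.ndarray
    Q_w: np.ndarray
    n_realizations: int


@dataclass
class IncrementalResult:
    metric_name: str
    direction: str
    n_modulated: np.ndarray
    target_r0_grid: np.ndarray
    R_bar: np.ndarray  # r0 x count x seed
    E_w: np.ndarray
    Q_w: np.ndarray
    auc: dict[str, np.ndarray]  # measure -> r0 x seed, trapezoid over counts


@dataclass
class SubsetRule:
    """Fixed members (possibly empty) completed to the subset size by random
    draws from ``pool`` (members excluded automatically)."""

    members: np.ndarray
    pool: np.ndarray

    def draw(self, size: int, rng: np.random.Generator) -> np.ndarray:
        members = np.asarray(self.members, dtype=int)
        if members.size > size:
            raise ValueError(
                f"category of {members.size} nodes cannot be reduced to {size}"
            )
        pool = np.setdiff1d(np.asarray(self.pool, dtype=int), members)
        extra = size - members.size
        if extra > pool.size:
            raise ValueError("complement pool too small")
        picked = rng.choice(pool, size=extra, replace=False) if extra else np.empty(0, int)
        return np.sort(np.concatenate([members, picked]).astype(int))


@dataclass
class SubsetResult:
    category: str
    subset_size: int
    r0_grid: np.ndarray
    delta_R_bar: np.ndarray  # r0 x realization, minus the null subset
    delta_E_w: np.ndarray
    delta_Q_w: np.ndarray
    auc: dict[str, np.ndarray]  # measure -> per-realization AUC over r0


def evaluate_condition(
    Mn,
    r0: np.ndarray | float,
    alpha: float,
    seed: int,
    settings: PipelineSettings,
) -> dict[str, float]:
    """One simulation -> {R_bar, E_w, Q_w} (graph measures NaN if disabled)."""
    n = Mn.n
    r0_vec = np.full(n, float(r0)) if np.isscalar(r0) else np.asarray(r0, dtype=float)
    config = SimulationConfig(
        gain=GainMap(r0_vec, alpha),
        params=settings.params,
        noise=NoiseSpec(settings.noise_mu, settings.noise_sigma, seed),
        dt=settings.dt,
        duration=settings.duration,
        discard=settings.discard,
    )
    trace = simulate(Mn, config)
    out = {"R_bar": np.nan, "E_w": np.nan, "Q_w": np.nan}
    if "sync" in settings.measures:
        out["R_bar"], _ = phase_synchrony(trace.nu, trace.rate)
    if "graph" in settings.measures:
        raw = bold_forward(trace.zeta, HemoParameters(), dt=settings.dt)
        bt = bandpass_bold(raw, rate=trace.rate, low=settings.band[0],
                           high=settings.band[1], tr=settings.tr)
        fc = fc_threshold(bt, n_surrogates=settings.fc_surrogates, seed=seed)
        out["E_w"] = global_efficiency(fc)
        if (fc.thresholded > 0).any():
            Q, _ = modularity_consensus(fc, runs=settings.louvain_runs, seed=seed)
            out["Q_w"] = Q
        else:
            out["Q_w"] = 0.0
    return out


def uniform_sweep(
    M: Connectome,
    alpha_grid,
    r0_grid,
    seeds,
    settings: PipelineSettings | None = None,
) -> SweepResult:
    """Seed-averaged synchrony/integration/segregation over a uniform
    (alpha, r0) grid; the connectome is mean-strength normalized first."""
    settings = settings or PipelineSettings()
    alpha_grid = np.asarray(alpha_grid, dtype=float)
    r0_grid = np.asarray(r0_grid, dtype=float)
    Mn = normalize_connectome(M)
    shape = (alpha_grid.size, r0_grid.size, len(seeds))
    R = np.full(shape, np.nan)
    E = np.full(shape, np.nan)
    Q = np.full(shape, np.nan)
    for ia, alpha in enumerate(alpha_grid):
        for ir, r0 in enumerate(r0_grid):
            for isd, seed in enumerate(seeds):
                try:
                    res = evaluate_condition(Mn, r0, alpha, int(seed), settings)
                except Exception as exc:  # annotate grid context
                    raise RuntimeError(
                        f"sweep failed at alpha={alpha}, r0={r0}, seed={seed}"
                    ) from exc
                R[ia, ir, isd] = res["R_bar"]
                E[ia, ir, isd] = res["E_w"]
                Q[ia, ir, isd] = res["Q_w"]
    return SweepResult(alpha_grid, r0_grid, R.mean(axis=2), E.mean(axis=2),
                       Q.mean(axis=2), len(seeds))


_METRICS = ("strength", "nodal_efficiency", "clustering")


def incremental_neuromod(
    M: Connectome,
    metric_name: str,
    direction: str,
    base_r0: float = 0.33,
    target_r0_grid=(0.67,),
    alpha: float = 0.65,
    seeds=(0,),
    step: int = 3,
    counts=None,
    settings: PipelineSettings | None = None,
) -> IncrementalResult:
    """Neuromodulate the top-k nodes of a structural-metric ranking for
    increasing k, and summarize each curve by its trapezoidal AUC over k."""
    settings = settings or PipelineSettings()
    if metric_name not in _METRICS:
        raise ValueError(f"unknown metric {metric_name!r}; choose from {_METRICS}")
    if direction not in ("low_to_high", "high_to_low", "random"):
        raise ValueError(f"unknown direction {direction!r}")
    nm = node_metrics(M)
    values = getattr(nm, metric_name)
    n = M.n
    if counts is None:
        counts = np.arange(0, n + 1, step)
        if counts[-1] != n:
            counts = np.append(counts, n)
    counts = np.asarray(counts, dtype=int)
    target_r0_grid = np.asarray(target_r0_grid, dtype=float)
    Mn = normalize_connectome(M)
    shape = (target_r0_grid.size, counts.size, len(seeds))
    R = np.full(shape, np.nan)
    E = np.full(shape, np.nan)
    Q = np.full(shape, np.nan)
    base_order = np.lexsort((np.arange(n), values))  # ascending, ties by index
    for isd, seed in enumerate(seeds):
        if direction == "random":
            order = np.random.default_rng(int(seed)).permutation(n)
        elif direction == "high_to_low":
            order = base_order[::-1]
        else:
            order = base_order
        for ir, tr0 in enumerate(target_r0_grid):
            for ic, k in enumerate(counts):
                gain = make_gain_map(n, alpha, base_r0, order[:k], tr0)
                res = evaluate_condition(Mn, gain.r0, alpha, int(seed), settings)
                R[ir, ic, isd] = res["R_bar"]
                E[ir, ic, isd] = res["E_w"]
                Q[ir, ic, isd] = res["Q_w"]
    auc = {
        name: np.trapezoid(arr, counts, axis=1)
        for name, arr in (("R_bar", R), ("E_w", E), ("Q_w", Q))
    }
    return IncrementalResult(metric_name, direction, counts, target_r0_grid,
                             R, E, Q, auc)


def subset_neuromod(
    M: Connectome,
    rules: dict[str, SubsetRule],
    seeds=(0,),
    base_r0: float = 0.33,
    alpha: float = 0.65,
    r0_grid=(0.5, 0.67, 0.85, 1.0),
    subset_size: int = 24,
    settings: PipelineSettings | None = None,
    null_pool=None,
) -> dict[str, SubsetResult]:
    """Neuromodulate fixed-size subsets built per category rule; every curve
    is reported relative to a random null subset drawn with the same seed."""
    settings = settings or PipelineSettings()
    r0_grid = np.asarray(r0_grid, dtype=float)
    Mn = normalize_connectome(M)
    n = M.n
    if null_pool is None:
        null_pool = np.arange(n)
    null_rule = SubsetRule(np.empty(0, int), np.asarray(null_pool, int))

    def _curves(rule: SubsetRule) -> dict[str, np.ndarray]:
        shape = (r0_grid.size, len(seeds))
        curves = {k: np.full(shape, np.nan) for k in ("R_bar", "E_w", "Q_w")}
        for isd, seed in enumerate(seeds):
            rng = np.random.default_rng(int(seed))
            subset = rule.draw(subset_size, rng)
            for ir, tr0 in enumerate(r0_grid):
                gain = make_gain_map(n, alpha, base_r0, subset, tr0)
                res = evaluate_condition(Mn, gain.r0, alpha, int(seed), settings)
                for k in curves:
                    curves[k][ir, isd] = res[k]
        return curves

    null_curves = _curves(null_rule)
    results: dict[str, SubsetResult] = {}
    for name, rule in rules.items():
        curves = _curves(rule)
        delta = {k: curves[k] - null_curves[k] for k in curves}
        auc = {k: np.trapezoid(delta[k], r0_grid, axis=0) for k in delta}
        results[name] = SubsetResult(
            name, subset_size, r0_grid,
            delta["R_bar"], delta["E_w"], delta["Q_w"], auc,
        )
    return results


def compare_auc(a, b) -> tuple[float, float]:
    """Mean difference and two-sided independent-samples t-test p-value."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 samples per group")
    diff = float(a.mean() - b.mean())
    if a.std() == 0 and b.std() == 0:
        if diff == 0:
            return 0.0, 1.0
        raise ValueError("zero variance in both groups with unequal means")
    t = stats.ttest_ind(a, b)
    return diff, float(t.pvalue)
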