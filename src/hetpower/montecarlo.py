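"""Monte Carlo power, Type I error and sample-size search.

The central quantity is the rejection rate of a term test over repeated
simulated experiments: with a true effect it estimates power, under a null
it estimates the Type I error rate.  A closed-form noncentral-t oracle is
available for balanced designs with known variances; it seeds and
cross-checks the simulation.

The sample-size search evaluates every candidate ``n_total`` with the same
underlying random streams (common random numbers): because each design cell
draws from its own substream, a smaller experiment's responses are a prefix
of a larger one's, which makes the empirical power curve smooth enough in
``n`` for integer bisection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datagen import _seed_sequence
from .inference import (
    HC_FLAVORS,
    SE_SOURCES,
    FitResult,
    design_matrix,
    fit_fgls_arrays,
    _hc_weights,
)
from .scenarios import Scenario, ScenarioError, cell_counts

__all__ = [
    "ModelSpec",
    "PowerEstimate",
    "SampleSizeResult",
    "SampleSizeError",
    "rejection_rate",
    "analytic_power",
    "required_n",
    "power_grid",
]


@dataclass(frozen=True)
class ModelSpec:
    """Which model is fitted and which standard errors are used."""

    include_interaction: bool = False
    se_source: str = "classical"

    def __post_init__(self) -> None:
        if self.se_source not in SE_SOURCES:
            raise ValueError(
                f"unknown se_source {self.se_source!r}; choose from {SE_SOURCES}"
            )

    @property
    def label(self) -> str:
        kind = "interaction" if self.include_interaction else "main-effects"
        return f"{kind}/{self.se_source}"


@dataclass(frozen=True)
class PowerEstimate:
    """Monte Carlo rejection proportion for one term with its MC uncertainty.

    When the term's true effect is zero this estimates the Type I error rate,
    otherwise power.  ``mc_se`` is the binomial standard error
    ``sqrt(p (1-p) / reps)``.
    """

    scenario: str
    term: str
    model: ModelSpec
    alpha: float
    n_total: int
    reps: int
    rejections: int
    seed: int | None
    dropped: int = 0

    @property
    def power(self) -> float:
        return self.rejections / self.reps

    @property
    def mc_se(self) -> float:
        p = self.power
        return float(np.sqrt(p * (1.0 - p) / self.reps))


@dataclass(frozen=True)
class SampleSizeResult:
    """Outcome of the sample-size search for a target power."""

    n_total: int
    target_power: float
    achieved: PowerEstimate
    trace: tuple[tuple[int, float], ...]
    scenario: str
    term: str
    model: ModelSpec
    alpha: float
    reps: int
    seed: int | None


class SampleSizeError(RuntimeError):
    """Target power unreachable below the cap; carries the search trace."""

    def __init__(self, message: str, trace: tuple[tuple[int, float], ...]) -> None:
        super().__init__(message)
        self.trace = trace


# ----------------------------------------------------------------------

def _design_for(scenario: Scenario, n_total: int, include_interaction: bool):
    counts = cell_counts(scenario.allocation, n_total)
    if (counts < 2).any():
        raise ScenarioError(
            f"n_total={n_total} leaves a design cell with fewer than 2 "
            f"observations (counts={counts.tolist()})"
        )
    sex_var = np.repeat([False, False, True, True], counts)
    treated = np.repeat([False, True, False, True], counts)
    X, terms = design_matrix(sex_var, treated, include_interaction)
    return counts, sex_var, X, terms


def rejection_rate(
    scenario: Scenario,
    n_total: int,
    model_spec: ModelSpec,
    term: str = "treatment",
    alpha: float = 0.05,
    reps: int = 2000,
    seed: int | np.random.SeedSequence = 0,
    on_error: str = "fail",
) -> PowerEstimate:
    """Estimate the rejection rate of one term by simulation.

    Simulates ``reps`` datasets from the scenario, fits the model, and counts
    two-sided rejections at level ``alpha``.  ``on_error`` controls what
    happens if a single replicate's fit fails (e.g. FGLS non-convergence):
    ``"fail"`` propagates the exception, ``"drop"`` discards the replicate
    and counts it in ``dropped`` (the rate's denominator shrinks).
    """
    if reps < 1:
        raise ValueError(f"reps must be >= 1, got {reps}")
    if on_error not in ("fail", "drop"):
        raise ValueError("on_error must be 'fail' or 'drop'")
    counts, sex_var, X, terms = _design_for(
        scenario, n_total, model_spec.include_interaction
    )
    if term not in terms:
        raise KeyError(f"term {term!r} not in model ({terms})")
    idx = terms.index(term)
    n, k = X.shape
    df = n - k
    tcrit = float(stats.t.isf(alpha / 2.0, df))
    means = scenario.cell_means
    sds = scenario.cell_sds

    use_fgls = model_spec.se_source == "fgls"
    if not use_fgls:
        xtx_inv = np.linalg.inv(X.T @ X)
        proj = xtx_inv @ X.T  # params = proj @ y
        proj_t = proj[idx]
        leverage = np.einsum("ij,jk,ik->i", X, xtx_inv, X)
        var_factor = xtx_inv[idx, idx]

    children = _seed_sequence(seed).spawn(reps)
    rejections = 0
    dropped = 0
    for child in children:
        cells = child.spawn(4)
        y = np.concatenate(
            [
                means[j]
                + sds[j]
                * np.random.default_rng(cells[j]).standard_normal(int(counts[j]))
                for j in range(4)
            ]
        )
        try:
            if use_fgls:
                fit = fit_fgls_arrays(X, y, terms, sex_var)
                est = fit.params[idx]
                var = fit.cov_classical[idx, idx]
            else:
                params = proj @ y
                est = params[idx]
                resid = y - X @ params
                if model_spec.se_source == "classical":
                    var = (resid @ resid) / df * var_factor
                else:
                    w = _hc_weights(model_spec.se_source, resid, leverage, n, k)
                    var = float((proj_t * w) @ proj_t)
        except Exception:
            if on_error == "fail":
                raise
            dropped += 1
            continue
        if abs(est) > tcrit * np.sqrt(var):
            rejections += 1
    return PowerEstimate(
        scenario=scenario.name,
        term=term,
        model=model_spec,
        alpha=alpha,
        n_total=n_total,
        reps=reps - dropped,
        rejections=rejections,
        seed=seed if isinstance(seed, int) else None,
        dropped=dropped,
    )


# ----------------------------------------------------------------------

def analytic_power(
    scenario: Scenario,
    n_total: float,
    term: str = "treatment",
    alpha: float = 0.05,
) -> float:
    """Closed-form power for balanced designs via the noncentral t.

    For a balanced 2x2 design without interaction, the main-effect estimate
    for ``term`` is a difference of two half-sample means, with variance
    ``(sigma_ref^2 + sigma_var^2) / (2 n_cell)`` where ``n_cell = n_total/4``.
    Power is the two-sided tail probability of a noncentral t with
    ``df = n_total - 3`` and noncentrality ``beta * sigma_ref / SE``.  Exact
    when the variances are known; a close approximation to the simulated
    (estimated-variance) test otherwise.  ``n_total`` may be non-integer —
    the search uses the continuous curve.
    """
    if not scenario.is_balanced:
        raise ScenarioError("analytic_power requires balanced allocation")
    if scenario.beta_int != 0:
        raise ScenarioError("analytic_power requires a scenario without interaction")
    if term == "treatment":
        beta = scenario.beta_trt
    elif term == "sex":
        beta = scenario.beta_sex
    else:
        raise ScenarioError("analytic_power handles the treatment or sex term only")
    if n_total <= 4:
        raise ScenarioError("n_total must exceed the 4 model parameters")
    s_ref, s_var = scenario.sigma_by_sex
    n_cell = n_total / 4.0
    se = np.sqrt((s_ref**2 + s_var**2) / (2.0 * n_cell))
    ncp = beta * scenario.sigma_ref / se
    df = n_total - 3
    tcrit = stats.t.isf(alpha / 2.0, df)
    return float(stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp))


def _analytic_crossing(
    scenario: Scenario, term: str, target_power: float, alpha: float, n_max: int
) -> float | None:
    """Continuous n at which the analytic power curve crosses the target."""
    try:
        lo, hi = 8.0, 16.0
        if analytic_power(scenario, lo, term, alpha) >= target_power:
            return lo
        while analytic_power(scenario, hi, term, alpha) < target_power:
            hi *= 2.0
            if hi > 4 * n_max:
                return None
        return float(
            optimize.brentq(
                lambda n: analytic_power(scenario, n, term, alpha) - target_power,
                lo,
                hi,
            )
        )
    except (ScenarioError, ValueError):
        return None


# ----------------------------------------------------------------------

def _min_feasible_n(scenario: Scenario) -> int:
    n = 8
    while True:
        if (cell_counts(scenario.allocation, n) >= 2).all():
            return n
        n += 1


def required_n(
    scenario: Scenario,
    model_spec: ModelSpec,
    term: str = "treatment",
    target_power: float = 0.80,
    alpha: float = 0.05,
    reps: int = 2000,
    seed: int = 0,
    n_max: int = 100_000,
) -> SampleSizeResult:
    """Smallest ``n_total`` whose Monte Carlo power reaches the target.

    Strategy: start from the analytic noncentral-t crossing point when it
    applies (balanced, no interaction, treatment/sex term), otherwise from a
    small default; bracket the target power geometrically; then bisect over
    integers.  Every candidate is evaluated with the same seed (common random
    numbers), so the power estimates at nearby ``n`` are strongly positively
    correlated and the empirical curve behaves monotonically.  Validate the
    returned size with an independent seed before using it.
    """
    if not (alpha < target_power < 1.0):
        raise ValueError(f"target_power must be in (alpha, 1), got {target_power}")
    n_min = _min_feasible_n(scenario)
    trace: dict[int, float] = {}

    def power_at(n: int) -> float:
        if n not in trace:
            trace[n] = rejection_rate(
                scenario, n, model_spec, term, alpha, reps, seed
            ).power
        return trace[n]

    def sorted_trace() -> tuple[tuple[int, float], ...]:
        return tuple(sorted(trace.items()))

    guess = _analytic_crossing(scenario, term, target_power, alpha, n_max)
    n0 = int(np.clip(round(guess) if guess is not None else 32, n_min, n_max))

    # geometric bracketing: lo fails, hi passes
    if power_at(n0) >= target_power:
        hi = n0
        lo = n0
        while lo > n_min:
            lo = max(n_min, int(lo / 1.5))
            if power_at(lo) < target_power:
                break
            hi = lo
        else:
            lo = n_min
        if power_at(lo) >= target_power:  # even the minimum passes
            lo = hi - 1
    else:
        lo = n0
        hi = n0
        while True:
            hi = min(n_max, hi * 2)
            if power_at(hi) >= target_power:
                break
            if hi >= n_max:
                raise SampleSizeError(
                    f"target power {target_power} unreachable below "
                    f"n_max={n_max} (best {max(trace.values()):.3f})",
                    sorted_trace(),
                )

    while hi - lo > 1:
        mid = (hi + lo) // 2
        if power_at(mid) >= target_power:
            hi = mid
        else:
            lo = mid

    achieved = rejection_rate(scenario, hi, model_spec, term, alpha, reps, seed)
    return SampleSizeResult(
        n_total=hi,
        target_power=target_power,
        achieved=achieved,
        trace=sorted_trace(),
        scenario=scenario.name,
        term=term,
        model=model_spec,
        alpha=alpha,
        reps=reps,
        seed=seed,
    )


# ----------------------------------------------------------------------

def power_grid(
    scenarios: Mapping[str, Scenario] | Sequence[Scenario],
    d_values: Sequence[float],
    model_specs: Sequence[ModelSpec],
    term: str = "treatment",
    mode: str = "power",
    n_totals: Sequence[int] | None = None,
    target_power: float = 0.80,
    alpha: float = 0.05,
    reps: int = 2000,
    seed: int = 0,
    out_csv=None,
) -> pd.DataFrame:
    """Evaluate power or required sample size over a factorial grid.

    ``mode="power"`` estimates the rejection rate at each ``n_totals`` entry;
    ``mode="samplesize"`` runs :func:`required_n` per grid cell.  Each cell
    gets its own deterministic seed derived from ``seed``, so a rerun of the
    same grid reproduces every row and partially completed runs can simply be
    rerun.  Rows are appended to ``out_csv`` as they complete; on error the
    rows finished so far are preserved before the exception propagates.
    """
    if mode not in ("power", "samplesize"):
        raise ValueError("mode must be 'power' or 'samplesize'")
    if mode == "power" and not n_totals:
        raise ValueError("mode='power' requires n_totals")
    if isinstance(scenarios, Mapping):
        scen_items = list(scenarios.items())
    else:
        scen_items = [(s.name, s) for s in scenarios]
    if not scen_items or not d_values or not model_specs:
        raise ValueError("grid must be non-empty")

    cells = [
        (name, scen, d, spec, n)
        for name, scen in scen_items
        for d in d_values
        for spec in model_specs
        for n in (n_totals if mode == "power" else [None])
    ]
    children = _seed_sequence(seed).spawn(len(cells))
    rows: list[dict] = []
    header_written = False

    def emit(row: dict) -> None:
        rows.append(row)
        nonlocal header_written
        if out_csv is not None:
            pd.DataFrame([row]).to_csv(
                out_csv, mode="a" if header_written else "w",
                header=not header_written, index=False,
            )
            header_written = True

    for (name, scen, d, spec, n), child in zip(cells, children):
        cell_seed = int(child.generate_state(1)[0] % 2**31)
        scen_d = scen.with_effect(d)
        if mode == "power":
            pe = rejection_rate(scen_d, n, spec, term, alpha, reps, cell_seed)
            emit(
                {
                    "scenario": name, "d": d, "model": spec.label,
                    "term": term, "n_total": n, "power": pe.power,
                    "mc_se": pe.mc_se, "seed": cell_seed,
                }
            )
        else:
            res = required_n(
                scen_d, spec, term, target_power, alpha, reps, cell_seed
            )
            emit(
                {
                    "scenario": name, "d": d, "model": spec.label,
                    "term": term, "n_total": res.n_total,
                    "power": res.achieved.power,
                    "mc_se": res.achieved.mc_se, "seed": cell_seed,
                }
            )
    return pd.DataFrame(rows)
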