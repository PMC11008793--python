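"""Synthetic data generators.

Three generators cover the study's simulated conditions:

* :func:`simulate_dataset` — Gaussian responses on the 2x2 sex-by-treatment
  grid with sex-specific SDs (the core power-simulation generator).
* :func:`simulate_lognormal_groups` — groups with a constant coefficient of
  variation, the canonical mechanism producing a mean-variance (Taylor's law)
  coupling: SD proportional to mean, hence log-log correlation 1 in the
  population.
* :func:`simulate_logistic_mapping` — a latent Gaussian trait pushed through
  a logistic response function, producing ceiling/floor compression: groups
  near the bounds have *smaller* SDs, the opposite of Taylor's law.

All generators are deterministic given an integer seed.  The 2x2 generator
draws each design cell from its own child random stream (spawned from the
seed), so datasets of different sizes generated from the same seed share
their leading draws cell by cell — the property that makes common random
numbers work in the sample-size search.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .scenarios import CELLS, Scenario, ScenarioError, cell_counts

__all__ = [
    "Dataset",
    "simulate_dataset",
    "simulate_lognormal_groups",
    "simulate_logistic_mapping",
    "dataset_to_csv",
    "dataset_from_csv",
]

SexSeed = int | np.random.SeedSequence


def _seed_sequence(seed: SexSeed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(int(seed))


@dataclass(frozen=True)
class Dataset:
    """Long-format observations from one 2x2 simulation (or imported data).

    ``frame`` has columns ``sex`` (``reference``/``variable``), ``treatment``
    (``control``/``treated``) and ``response`` (float).  Provenance fields
    record how the data were produced; they are ``None`` for imported data.
    """

    frame: pd.DataFrame
    scenario_name: str | None = None
    seed: int | None = None
    cell_n: tuple[int, int, int, int] | None = None

    def __post_init__(self) -> None:
        required = {"sex", "treatment", "response"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"Dataset frame missing column(s): {sorted(missing)}")
        bad_sex = set(self.frame["sex"].unique()) - {"reference", "variable"}
        bad_trt = set(self.frame["treatment"].unique()) - {"control", "treated"}
        if bad_sex or bad_trt:
            raise ValueError(
                f"unrecognised factor levels: sex={sorted(bad_sex)}, "
                f"treatment={sorted(bad_trt)}"
            )

    @property
    def n_total(self) -> int:
        return len(self.frame)

    def responses_by_cell(self) -> dict[tuple[str, str], np.ndarray]:
        out = {}
        for sex, trt in CELLS:
            mask = (self.frame["sex"] == sex) & (self.frame["treatment"] == trt)
            out[(sex, trt)] = self.frame.loc[mask, "response"].to_numpy()
        return out


def simulate_cell_responses(
    scenario: Scenario, counts: np.ndarray, seed: SexSeed
) -> list[np.ndarray]:
    """Draw the four cells' responses as arrays (internal fast path).

    One child stream per cell, in :data:`CELLS` order, so the draws for a
    given cell do not depend on the other cells' sizes.
    """
    children = _seed_sequence(seed).spawn(4)
    means = scenario.cell_means
    sds = scenario.cell_sds
    return [
        means[j] + sds[j] * np.random.default_rng(children[j]).standard_normal(int(counts[j]))
        for j in range(4)
    ]


def simulate_dataset(scenario: Scenario, n_total: int, seed: SexSeed) -> Dataset:
    """Simulate a long-format 2x2 dataset from a scenario.

    Per-cell counts are the largest-remainder rounding of
    ``allocation * n_total``.  Every resolved cell must hold at least two
    observations so per-cell and per-sex variances are estimable.
    """
    if n_total < 8:
        raise ScenarioError(f"n_total must be >= 8, got {n_total}")
    counts = cell_counts(scenario.allocation, n_total)
    if (counts < 2).any():
        raise ScenarioError(
            f"allocation {scenario.allocation} at n_total={n_total} yields a "
            f"cell with fewer than 2 observations (counts={counts.tolist()})"
        )
    cells = simulate_cell_responses(scenario, counts, seed)
    frame = pd.DataFrame(
        {
            "sex": np.repeat([c[0] for c in CELLS], counts),
            "treatment": np.repeat([c[1] for c in CELLS], counts),
            "response": np.concatenate(cells),
        }
    )
    seed_int = seed if isinstance(seed, int) else None
    return Dataset(
        frame=frame,
        scenario_name=scenario.name,
        seed=seed_int,
        cell_n=tuple(int(c) for c in counts),
    )


def simulate_lognormal_groups(
    group_means: Sequence[float],
    cv: float,
    n_per_group: int,
    seed: SexSeed,
) -> list[np.ndarray]:
    """Constant-CV log-normal groups with exact moment matching.

    For a target mean ``m`` and coefficient of variation ``cv`` the log-scale
    parameters are chosen so the *distribution's* mean is exactly ``m`` and
    its SD exactly ``cv * m``::

        sigma_log^2 = ln(1 + cv^2)
        mu_log      = ln(m) - sigma_log^2 / 2

    ``sigma_log`` is identical across groups, which is what makes the
    population SD exactly proportional to the mean (log-log correlation 1).
    """
    means = np.asarray(group_means, dtype=float)
    if means.size == 0:
        raise ValueError("group_means must be non-empty")
    if (means <= 0).any():
        raise ValueError(f"all group means must be > 0, got {means.tolist()}")
    if not cv > 0:
        raise ValueError(f"cv must be > 0, got {cv}")
    if n_per_group < 1:
        raise ValueError(f"n_per_group must be >= 1, got {n_per_group}")
    sigma_log = np.sqrt(np.log1p(cv * cv))
    children = _seed_sequence(seed).spawn(means.size)
    out = []
    for m, child in zip(means, children):
        mu_log = np.log(m) - 0.5 * sigma_log * sigma_log
        rng = np.random.default_rng(child)
        out.append(rng.lognormal(mean=mu_log, sigma=sigma_log, size=n_per_group))
    return out


def simulate_logistic_mapping(
    latent_mean: float,
    latent_sd: float,
    ceiling: float,
    slope: float,
    midpoint: float,
    n: int,
    seed: SexSeed,
) -> np.ndarray:
    """Responses from a logistic mapping of a latent Gaussian trait.

    ``y = L / (1 + exp(-k (x - x0)))`` with ``x ~ Normal(latent_mean,
    latent_sd)``, ``L = ceiling``, ``k = slope``, ``x0 = midpoint``.  All
    responses lie strictly inside ``(0, L)``.  Groups whose latent mean sits
    far above (or below) the midpoint are compressed against the ceiling
    (floor) and show reduced variability for the same latent SD.
    """
    if not ceiling > 0:
        raise ValueError(f"ceiling must be > 0, got {ceiling}")
    if not slope > 0:
        raise ValueError(f"slope must be > 0, got {slope}")
    if latent_sd < 0:
        raise ValueError(f"latent_sd must be >= 0, got {latent_sd}")
    rng = np.random.default_rng(_seed_sequence(seed))
    x = latent_mean + latent_sd * rng.standard_normal(n)
    from scipy.special import expit

    y = ceiling * expit(slope * (x - midpoint))
    # expit underflows to exactly 0/1 beyond ~|37|; keep the open interval.
    tiny = np.finfo(float).tiny
    return np.clip(y, tiny, ceiling * (1.0 - np.finfo(float).epsneg))


# ----------------------------------------------------------------------
# CSV interchange: external files use F/M sex labels; the scenario's
# ``variable_sex`` field says which of the two is the more-variable sex.

def _label_maps(variable_sex: str) -> tuple[dict[str, str], dict[str, str]]:
    reference_sex = "F" if variable_sex == "M" else "M"
    to_ext = {"reference": reference_sex, "variable": variable_sex}
    to_int = {v: k for k, v in to_ext.items()}
    return to_ext, to_int


def dataset_to_csv(dataset: Dataset, path: str | Path, variable_sex: str = "M") -> None:
    """Write ``sex,treatment,response`` CSV with F/M sex labels."""
    to_ext, _ = _label_maps(variable_sex)
    out = dataset.frame.copy()
    out["sex"] = out["sex"].map(to_ext)
    out.to_csv(path, index=False, lineterminator="\n")


def dataset_from_csv(path: str | Path, variable_sex: str = "M") -> Dataset:
    """Read a ``sex,treatment,response`` CSV (F/M labels) into a Dataset."""
    frame = pd.read_csv(path)
    required = {"sex", "treatment", "response"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    _, to_int = _label_maps(variable_sex)
    bad = set(frame["sex"].unique()) - set(to_int)
    if bad:
        raise ValueError(f"{path}: unrecognised sex label(s) {sorted(bad)}")
    frame = frame.copy()
    frame["sex"] = frame["sex"].map(to_int)
    return Dataset(frame=frame[["sex", "treatment", "response"]])
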