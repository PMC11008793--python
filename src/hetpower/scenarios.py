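"""Simulation scenarios for the 2x2 sex-by-treatment design.

A :class:`Scenario` fully specifies a Gaussian data-generating process on a
four-cell factorial layout (sex x treatment).  Effects are expressed as
standardised mean differences against the reference sex's standard deviation,
so the same effect size keeps its meaning when the heteroscedasticity level
changes.  The more-variable sex is the one carrying the sex main effect.
"""

from __future__ import annotations

import enum
import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "ConstraintMode",
    "Scenario",
    "ScenarioError",
    "CELLS",
    "build_scenario",
    "scenario_from_variance_ratio",
    "cell_means",
    "cell_counts",
    "load_scenario",
]

#: Fixed design-cell order: (sex, treatment).  The reference sex comes first,
#: control before treated; allocation vectors follow this order.
CELLS: tuple[tuple[str, str], ...] = (
    ("reference", "control"),
    ("reference", "treated"),
    ("variable", "control"),
    ("variable", "treated"),
)


class ScenarioError(ValueError):
    """Raised when scenario parameters are inconsistent or invalid."""


class ConstraintMode(str, enum.Enum):
    """How the two sex-specific SDs are resolved from ``(sigma_ref, sd_ratio)``.

    REFERENCE_FIXED
        The reference sex keeps ``sigma_ref``; the variable sex gets
        ``sd_ratio * sigma_ref``.  Raising ``sd_ratio`` raises the average
        variance of the design.
    MEAN_VARIANCE_FIXED
        The SDs are rescaled so their ratio is ``sd_ratio`` while the average
        of the two variances stays exactly ``sigma_ref**2``.  This isolates
        the effect of variance *imbalance* from that of overall noise level.
    """

    REFERENCE_FIXED = "REFERENCE_FIXED"
    MEAN_VARIANCE_FIXED = "MEAN_VARIANCE_FIXED"


@dataclass(frozen=True)
class Scenario:
    """Data-generating process for one simulation condition.

    Parameters
    ----------
    mu0:
        Baseline mean of the reference sex under control, in response units.
    beta_trt, beta_sex, beta_int:
        Treatment main effect, sex main effect and sex-by-treatment
        interaction, all in units of the reference-sex SD (standardised mean
        differences, the usual Cohen-style *d* scale).
    sigma_ref:
        Reference-sex SD in response units; must be positive.
    sd_ratio:
        Ratio of the more-variable sex's SD to the reference SD (>= 1).
        Canonical values: 1.00 (homoscedastic), 1.44 ("small"
        heteroscedasticity) and 1.73 ("large").
    constraint_mode:
        See :class:`ConstraintMode`.
    allocation:
        Per-cell sampling fractions in :data:`CELLS` order; positive, sum 1.
    variable_sex:
        Which external sex label ("F" or "M") plays the more-variable role;
        only used when mapping datasets to/from F/M-labelled CSV files.
    name:
        Free-form identifier carried into provenance records.
    """

    mu0: float = 0.0
    beta_trt: float = 0.0
    beta_sex: float = 0.0
    beta_int: float = 0.0
    sigma_ref: float = 1.0
    sd_ratio: float = 1.0
    constraint_mode: ConstraintMode = ConstraintMode.REFERENCE_FIXED
    allocation: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    variable_sex: str = "M"
    name: str = "scenario"

    def __post_init__(self) -> None:
        if not self.sigma_ref > 0:
            raise ScenarioError(f"sigma_ref must be > 0, got {self.sigma_ref}")
        if self.sd_ratio < 1:
            raise ScenarioError(
                f"sd_ratio must be >= 1 (the variable sex is the more "
                f"variable one), got {self.sd_ratio}"
            )
        mode = ConstraintMode(self.constraint_mode)
        object.__setattr__(self, "constraint_mode", mode)
        alloc = tuple(float(a) for a in self.allocation)
        if len(alloc) != 4:
            raise ScenarioError("allocation must have exactly 4 entries")
        if any(a <= 0 for a in alloc):
            raise ScenarioError(f"allocation entries must be > 0, got {alloc}")
        if abs(sum(alloc) - 1.0) > 1e-9:
            raise ScenarioError(
                f"allocation must sum to 1 within 1e-9, got sum={sum(alloc)!r}"
            )
        object.__setattr__(self, "allocation", alloc)
        if self.variable_sex not in ("F", "M"):
            raise ScenarioError("variable_sex must be 'F' or 'M'")
        if self.beta_sex != 0 and math.copysign(
            1.0, self.beta_sex + self.beta_int
        ) != math.copysign(1.0, self.beta_sex):
            warnings.warn(
                "beta_int reverses the direction of the sex effect in the "
                "treated group; the canonical interaction modifies its "
                "magnitude only",
                stacklevel=3,
            )

    # ------------------------------------------------------------------
    @property
    def sigma_by_sex(self) -> tuple[float, float]:
        """Resolved (reference-sex SD, variable-sex SD)."""
        if self.constraint_mode is ConstraintMode.REFERENCE_FIXED:
            return (self.sigma_ref, self.sd_ratio * self.sigma_ref)
        # MEAN_VARIANCE_FIXED: sigma_hi/sigma_lo = r and
        # (sigma_lo^2 + sigma_hi^2)/2 = sigma_ref^2 exactly.
        lo = self.sigma_ref * math.sqrt(2.0 / (1.0 + self.sd_ratio**2))
        return (lo, self.sd_ratio * lo)

    @property
    def cell_means(self) -> np.ndarray:
        """Population means of the four design cells in :data:`CELLS` order."""
        s = self.sigma_ref
        return np.array(
            [
                self.mu0,
                self.mu0 + self.beta_trt * s,
                self.mu0 + self.beta_sex * s,
                self.mu0 + (self.beta_sex + self.beta_trt + self.beta_int) * s,
            ]
        )

    @property
    def cell_sds(self) -> np.ndarray:
        """Population SDs of the four design cells in :data:`CELLS` order."""
        lo, hi = self.sigma_by_sex
        return np.array([lo, lo, hi, hi])

    @property
    def is_balanced(self) -> bool:
        return all(abs(a - 0.25) < 1e-12 for a in self.allocation)

    @property
    def is_null(self) -> bool:
        """True when all standardised effects are zero."""
        return self.beta_trt == self.beta_sex == self.beta_int == 0

    def with_effect(self, beta_trt: float) -> "Scenario":
        """Copy of this scenario with a different treatment effect size."""
        return replace(self, beta_trt=beta_trt)

    def to_dict(self) -> dict[str, Any]:
        d = {
            "mu0": self.mu0,
            "beta_trt": self.beta_trt,
            "beta_sex": self.beta_sex,
            "beta_int": self.beta_int,
            "sigma_ref": self.sigma_ref,
            "sd_ratio": self.sd_ratio,
            "constraint_mode": self.constraint_mode.value,
            "allocation": list(self.allocation),
            "variable_sex": self.variable_sex,
            "name": self.name,
        }
        return d


def build_scenario(params: Mapping[str, Any] | None = None, /, **kwargs: Any) -> Scenario:
    """Validate raw parameters and return a :class:`Scenario`.

    Accepts either a mapping (e.g. parsed from a YAML/JSON scenario file) or
    keyword arguments.  Unknown keys raise :class:`ScenarioError` so that
    typos in configuration files fail loudly instead of silently falling back
    to defaults.
    """
    raw: dict[str, Any] = dict(params or {})
    raw.update(kwargs)
    known = set(Scenario.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ScenarioError(f"unknown scenario field(s): {sorted(unknown)}")
    if "allocation" in raw:
        raw["allocation"] = tuple(raw["allocation"])
    try:
        return Scenario(**raw)
    except TypeError as exc:  # non-mapping junk etc.
        raise ScenarioError(str(exc)) from exc


def scenario_from_variance_ratio(
    variance_ratio: float, params: Mapping[str, Any] | None = None, /, **kwargs: Any
) -> Scenario:
    """Build a scenario from a *variance* ratio instead of an SD ratio.

    ``variance_ratio`` is var(variable sex) / var(reference sex); the SD ratio
    is its square root.  Provided because heteroscedasticity is quoted
    sometimes on the variance scale and sometimes on the SD scale, and the
    two conventions differ materially (a 100% variance increase is only a
    41% SD increase).
    """
    if variance_ratio < 1:
        raise ScenarioError(f"variance_ratio must be >= 1, got {variance_ratio}")
    return build_scenario(params, sd_ratio=math.sqrt(variance_ratio), **kwargs)


def cell_means(scenario: Scenario) -> np.ndarray:
    """Population cell means in :data:`CELLS` order (functional alias)."""
    return scenario.cell_means


def cell_counts(allocation: Sequence[float], n_total: int) -> np.ndarray:
    """Integer per-cell counts via largest-remainder (Hamilton) rounding.

    Each cell first receives ``floor(allocation * n_total)``; the leftover
    units go to the cells with the largest fractional remainders, ties broken
    by cell order.  The counts always sum exactly to ``n_total``.
    """
    if n_total < 1:
        raise ScenarioError(f"n_total must be positive, got {n_total}")
    raw = np.asarray(allocation, dtype=float) * n_total
    counts = np.floor(raw).astype(int)
    short = int(n_total - counts.sum())
    if short:
        order = np.argsort(-(raw - counts), kind="stable")
        counts[order[:short]] += 1
    return counts


def load_scenario(path: str | Path) -> Scenario:
    """Load a scenario from a YAML or JSON file (strict about field names)."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if not isinstance(raw, Mapping):
        raise ScenarioError(f"{path} does not contain a scenario mapping")
    return build_scenario(raw)
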