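"""Built-in scenario presets.

The canonical heteroscedasticity levels: the more-variable sex's SD exceeds
the reference sex's by 0%, 44% or 73%.  ``large-het-constmean`` holds the
average of the two sex-specific variances fixed while imposing the large SD
ratio, separating variance imbalance from overall noise level.  Presets are
plain data; build one with :func:`get_preset`.
"""

from __future__ import annotations

from typing import Any

from .scenarios import Scenario, build_scenario

PRESETS: dict[str, dict[str, Any]] = {
    "homoscedastic": {
        "name": "homoscedastic",
        "sd_ratio": 1.00,
        "constraint_mode": "REFERENCE_FIXED",
    },
    "small-het": {
        "name": "small-het",
        "sd_ratio": 1.44,
        "constraint_mode": "REFERENCE_FIXED",
    },
    "large-het": {
        "name": "large-het",
        "sd_ratio": 1.73,
        "constraint_mode": "REFERENCE_FIXED",
    },
    "large-het-constmean": {
        "name": "large-het-constmean",
        "sd_ratio": 1.73,
        "constraint_mode": "MEAN_VARIANCE_FIXED",
    },
}


def get_preset(name: str, /, **overrides: Any) -> Scenario:
    """Build a preset scenario, optionally overriding fields (e.g. beta_trt)."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    params = dict(PRESETS[name])
    params.update(overrides)
    return build_scenario(params)
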