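"""Packaged published cut-points, selectable by configuration.

The recommended typical-use configuration is acceleration, both legs,
PAP method: 1.00 m/s (sedentary/active) and 2.60 m/s (light/MV).
"""

from __future__ import annotations

import json
from importlib import resources

from .types import ThresholdSet

_DATA_FILE = "published_thresholds.json"


def _load() -> dict:
    with resources.files(__package__).joinpath("data", _DATA_FILE).open() as fh:
        return json.load(fh)


def published_thresholds(
    quantity: str = "acceleration",
    placement: str = "both",
    method: str = "PAP",
) -> ThresholdSet:
    """Look up the published cut-point pair for a configuration."""
    payload = _load()
    for entry in payload["thresholds"]:
        if (
            entry["quantity"] == quantity
            and entry["placement"] == placement
            and entry["method"] == method
        ):
            return ThresholdSet(
                quantity=quantity,
                placement=placement,
                method=method,
                t_sed_active=float(entry["t_sed_active"]),
                t_light_mv=float(entry["t_light_mv"]),
            )
    raise KeyError(
        f"no published thresholds for ({quantity}, {placement}, {method})"
    )


def published_version() -> str:
    return _load()["version"]
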