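"""Run configuration and tabular I/O.

Configuration is a flat YAML mapping whose keys mirror :class:`GridSpec`
plus ``output_dir``, ``mode`` and ``log_level``; absent keys fall back to
the default study design.  ``mode: scaled_down`` drops ``n_replicates`` to
100 (unless the key is given explicitly), intended for quick runs and CI.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .analytic import contour_surface
from .errors import ParameterError
from .experiment import GridSpec

__all__ = [
    "RunConfig",
    "ConfigError",
    "load_config",
    "write_summary_csv",
    "export_contour_data",
    "SUMMARY_COLUMNS",
]

logger = logging.getLogger(__name__)

SCALED_DOWN_REPLICATES = 100

#: documented column order of the summary CSV
SUMMARY_COLUMNS = [
    "prevalence",
    "incidence",
    "true_rr",
    "exposure_prevalence",
    "n_subjects",
    "n_replicates",
    "se",
    "sp",
    "variant",
    "inc_median",
    "inc_q1",
    "inc_q3",
    "inc_mean",
    "inc_sem",
    "rr_median",
    "rr_q1",
    "rr_q3",
    "n_missing_rr",
    "expected_incidence",
    "expected_rr",
]


class ConfigError(ParameterError):
    """Configuration file is missing, malformed, or violates a constraint."""


_GRID_KEYS = {f.name for f in dataclasses.fields(GridSpec)}
_EXTRA_KEYS = {"output_dir", "mode", "log_level"}
VALID_KEYS = sorted(_GRID_KEYS | _EXTRA_KEYS)
_MODES = ("full", "scaled_down")


@dataclass(frozen=True)
class RunConfig:
    """A validated grid specification plus run-level settings."""

    grid: GridSpec
    output_dir: Path = Path(".")
    mode: str = "full"
    log_level: str = "INFO"


def build_config(overrides: dict | None = None) -> RunConfig:
    """Build a :class:`RunConfig` from a flat mapping of overrides.

    Unknown keys and constraint violations raise :class:`ConfigError`.
    """
    overrides = dict(overrides or {})
    unknown = sorted(set(overrides) - set(VALID_KEYS))
    if unknown:
        raise ConfigError(
            f"unknown configuration key(s) {unknown}; valid keys: {VALID_KEYS}"
        )
    mode = overrides.pop("mode", "full")
    if mode not in _MODES:
        raise ConfigError(f"mode must be one of {_MODES}, got {mode!r}")
    output_dir = Path(overrides.pop("output_dir", "."))
    log_level = str(overrides.pop("log_level", "INFO"))
    if mode == "scaled_down":
        overrides.setdefault("n_replicates", SCALED_DOWN_REPLICATES)
    grid_kwargs = {}
    for key, value in overrides.items():
        if key in ("prevalences", "incidences", "se_values", "sp_values"):
            value = tuple(value) if isinstance(value, (list, tuple)) else (value,)
        grid_kwargs[key] = value
    try:
        grid = GridSpec(**grid_kwargs)
    except ParameterError as exc:
        raise ConfigError(str(exc)) from exc
    return RunConfig(grid=grid, output_dir=output_dir, mode=mode, log_level=log_level)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    An empty file yields the full default study design.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"configuration file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"configuration root must be a mapping, got {type(raw).__name__}")
    return build_config(raw)


def write_summary_csv(summary: pd.DataFrame, path: str | Path) -> Path:
    """Write a grid summary table as CSV with the documented column order.

    Floats are written at full precision so a round-trip read reproduces
    the table exactly.
    """
    if summary.empty:
        raise ParameterError("refusing to write an empty summary table")
    missing = [col for col in SUMMARY_COLUMNS if col not in summary.columns]
    if missing:
        raise ParameterError(f"summary table lacks required column(s): {missing}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    summary[SUMMARY_COLUMNS].to_csv(path, index=False)
    return path


def read_summary_csv(path: str | Path) -> pd.DataFrame:
    """Read a summary CSV written by :func:`write_summary_csv`."""
    return pd.read_csv(path)


def export_contour_data(
    variant: str,
    estimand: str,
    p: float,
    incidence: float,
    resolution: int = 50,
    true_rr: float = 3.0,
    exposure_prevalence: float = 0.5,
    se_range: tuple[float, float] = (0.7, 1.0),
    sp_range: tuple[float, float] = (0.8, 1.0),
    path: str | Path | None = None,
) -> pd.DataFrame:
    """Dense analytic surface for contour plotting.

    Returns a ``resolution x resolution`` DataFrame indexed by sensitivity
    (rows) with specificity values as columns; any contour plotter can
    consume the matrix together with its axis vectors.  If ``path`` is
    given the matrix is also written as CSV.
    """
    if resolution < 2:
        raise ParameterError(f"resolution must be >= 2, got {resolution}")
    se_grid = np.linspace(se_range[0], se_range[1], resolution)
    sp_grid = np.linspace(sp_range[0], sp_range[1], resolution)
    surface = contour_surface(
        variant, p, incidence, se_grid, sp_grid, estimand, true_rr, exposure_prevalence
    )
    frame = pd.DataFrame(surface, index=se_grid, columns=sp_grid)
    frame.index.name = "se"
    frame.columns.name = "sp"
    if path is not None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        frame.to_csv(path)
        logger.info("wrote %s contour surface to %s", estimand, path)
    return frame
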