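"""File formats, run configuration and the end-to-end pipeline.

Formulation tables are comma-separated text (UTF-8, ``.`` decimal) with
header ``name, concentration_mg_ml, mw_mda, crosslinked, g_prime_pa,
eta_pa_s, tan_delta``, or an equivalent JSON list of objects.  Cohort
tables use the column schema of :mod:`viscowin.cohort` and round-trip
losslessly.  A run configuration (YAML or JSON) wires the stages
together: simulate -> classify -> (optional) cohort -> validate.
"""

from __future__ import annotations

import dataclasses
import hashlib
import importlib.metadata
import importlib.resources
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, List, Optional

import pandas as pd
import yaml

from .exceptions import ConfigError, FormulationParseError, ViscowinError
from .rheology import FormulationRheology

FORMULATION_COLUMNS = [
    "name",
    "concentration_mg_ml",
    "mw_mda",
    "crosslinked",
    "g_prime_pa",
    "eta_pa_s",
    "tan_delta",
]

_TRUE = {"true", "1", "yes", "y", "si", "sí"}
_FALSE = {"false", "0", "no", "n"}


def _parse_bool(value: Any, where: str) -> bool:
    """Parse a boolean cell; Spanish Sí/No is normalised at ingest."""
    if isinstance(value, (bool,)):
        return value
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise FormulationParseError(f"{where}: cannot parse boolean value {value!r}")


def _record_from_mapping(row: dict, where: str) -> FormulationRheology:
    missing = [c for c in FORMULATION_COLUMNS if c not in row]
    if missing:
        raise FormulationParseError(f"{where}: missing column(s) {missing}")
    numeric = {}
    for col in ("concentration_mg_ml", "mw_mda", "g_prime_pa", "eta_pa_s", "tan_delta"):
        try:
            numeric[col] = float(row[col])
        except (TypeError, ValueError):
            raise FormulationParseError(
                f"{where}: non-numeric value {row[col]!r} in column {col!r}"
            ) from None
        if math.isnan(numeric[col]):
            raise FormulationParseError(f"{where}: missing value in column {col!r}")
    try:
        return FormulationRheology(
            name=str(row["name"]),
            concentration=numeric["concentration_mg_ml"],
            mol_weight=numeric["mw_mda"],
            crosslinked=_parse_bool(row["crosslinked"], where),
            g_prime=numeric["g_prime_pa"],
            eta_ref=numeric["eta_pa_s"],
            tan_delta=numeric["tan_delta"],
        )
    except ViscowinError as exc:
        raise FormulationParseError(f"{where}: {exc}") from exc


def read_formulations(path) -> List[FormulationRheology]:
    """Read a formulation table (CSV by default, JSON for ``.json`` paths).

    Errors name the offending row (1-based data rows for CSV, list
    indices for JSON).  An empty table yields an empty list with a
    warning.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text(encoding="utf-8"))
        if not isinstance(data, list):
            raise FormulationParseError(f"{path}: JSON formulation table must be a list")
        records = [_record_from_mapping(row, f"{path} entry {i}") for i, row in enumerate(data)]
    else:
        try:
            frame = pd.read_csv(path, dtype=str, comment="#", skip_blank_lines=True)
        except pd.errors.EmptyDataError:
            frame = pd.DataFrame(columns=FORMULATION_COLUMNS)
        missing = [c for c in FORMULATION_COLUMNS if c not in frame.columns]
        if missing and len(frame.columns) > 0 and len(frame) > 0:
            raise FormulationParseError(f"{path}: missing column(s) {missing}")
        records = [
            _record_from_mapping(dict(row), f"{path} row {i + 1}")
            for i, (_, row) in enumerate(frame.iterrows())
        ]
    if not records:
        warnings.warn(f"{path}: empty formulation table", RuntimeWarning, stacklevel=2)
    return records


def write_formulations(records: List[FormulationRheology], path) -> None:
    """Write a formulation table as CSV or JSON (by file suffix)."""
    path = Path(path)
    rows = [
        {
            "name": f.name,
            "concentration_mg_ml": f.concentration,
            "mw_mda": f.mol_weight,
            "crosslinked": f.crosslinked,
            "g_prime_pa": f.g_prime,
            "eta_pa_s": f.eta_ref,
            "tan_delta": f.tan_delta,
        }
        for f in records
    ]
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(rows, indent=2), encoding="utf-8")
    else:
        pd.DataFrame(rows, columns=FORMULATION_COLUMNS).to_csv(path, index=False)


def load_reference_formulations() -> List[FormulationRheology]:
    """Load the packaged reference table of four HA products (HA-A…HA-D)."""
    resource = importlib.resources.files("viscowin.data") / "reference_formulations.csv"
    with importlib.resources.as_file(resource) as p:
        return read_formulations(p)


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort table written by :func:`write_cohort`."""
    from .cohort import COHORT_COLUMNS

    frame = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise ConfigError(f"{path}: cohort table missing column(s) {missing}")
    frame["aligned"] = frame["aligned"].astype(bool)
    frame["responder"] = frame["responder"].astype(bool)
    return frame[COHORT_COLUMNS]


def write_cohort(frame: pd.DataFrame, path) -> None:
    """Write a cohort table as CSV (lossless float round-trip)."""
    frame.to_csv(path, index=False)


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    formulations: Optional[str] = None  # path; packaged reference table when None
    joint: dict = field(
        default_factory=lambda: {
            "joint_type": "knee",
            "synovial_volume": 6.0,
            "injected_volume": 3.0,
        }
    )
    loading: dict = field(default_factory=lambda: {"frequency": 1.0})
    kl_grade: str = "II"
    window: dict = field(default_factory=dict)
    cohort: Optional[dict] = None  # CohortConfig overrides; triggers validation
    adjustment: tuple = ("age", "sex")
    n_components: int = 2
    seed: Optional[int] = None
    out: Optional[str] = None
    log_level: str = "INFO"


def load_run_config(path) -> RunConfig:
    """Load a YAML or JSON run configuration."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text(encoding="utf-8")) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"{path}: unknown config key(s) {sorted(unknown)}")
    cfg = RunConfig(**raw)
    if isinstance(cfg.adjustment, list):
        cfg.adjustment = tuple(cfg.adjustment)
    return cfg


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _package_version() -> str:
    try:
        return importlib.metadata.version("viscowin")
    except importlib.metadata.PackageNotFoundError:  # pragma: no cover
        return "unknown"


def run_pipeline(config: RunConfig) -> dict:
    """Run simulate -> classify -> (optional) cohort -> validate.

    Returns a single JSON-serialisable report with one simulation result
    and one classification per input formulation; byte-identical across
    reruns with the same configuration and seed.
    """
    from .cohort import CohortConfig, generate_cohort_frame
    from .hasim import KLGrade, simulate_cyclic_response
    from .loading import GaitLoading, JointSpec, steps_to_frequency
    from .validation import validate_cohort
    from .window import DEFAULT_BOUNDS, WindowBounds, alignment_label, in_window

    if config.formulations is None:
        formulations = load_reference_formulations()
    else:
        formulations = read_formulations(config.formulations)

    joint = JointSpec(**config.joint)
    loading_kwargs = dict(config.loading)
    if "steps_per_min" in loading_kwargs:
        loading_kwargs["frequency"] = steps_to_frequency(loading_kwargs.pop("steps_per_min"))
    loading = GaitLoading(**loading_kwargs)
    kl = KLGrade.parse(config.kl_grade)
    bounds = WindowBounds(**config.window) if config.window else DEFAULT_BOUNDS

    report: dict = {
        "package_version": _package_version(),
        "config_sha256": _config_hash(config),
        "simulations": [],
        "classification": [],
    }
    for f in formulations:
        result = simulate_cyclic_response(f, joint, loading, kl_grade=kl)
        report["simulations"].append(result.to_dict())
        report["classification"].append(
            {
                "formulation": f.name,
                "in_window": in_window(f, bounds),
                "aligned": alignment_label(f, kl, joint, bounds),
            }
        )

    if config.cohort is not None:
        cohort_kwargs = dict(config.cohort)
        if "seed" not in cohort_kwargs:
            if config.seed is None:
                raise ConfigError("cohort generation requires a seed")
            cohort_kwargs["seed"] = config.seed
        frame = generate_cohort_frame(CohortConfig(**cohort_kwargs))
        validation = validate_cohort(
            frame, n_components=config.n_components, adjustment=config.adjustment
        )
        report["cohort"] = {
            "n": len(frame),
            "responder_pct": 100.0 * float(frame["responder"].mean()),
        }
        report["validation"] = validation.to_dict()
    return report
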