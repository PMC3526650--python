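"""File formats, run configuration and provenance.

CSV schemas
-----------
* bomb curve: ``year[,month],delta_c14_permil`` -- differential per mil
  relative to 1955; pre-1955 rows must be 0 (strict mode) or are zero-filled
  with a warning (lenient mode).
* subjects: ``id,sex,birth_year,lifespan[,end_c14,lambda_c14]``.
* stem-cell parameter tables: ``age,sex,n_csc,cyc_frac,mitosis_hours,
  expansion_exponent,apoptotic_frac,apoptosis_hours,halflife_years``.

Ledgers are written as TSV (``formation_offset\tsurviving_count``) with an
optional JSON summary carrying the trajectory, the per-year tallies and
provenance metadata (package version, seed, config hash) sufficient to
re-run the producing command.
"""

from __future__ import annotations

import csv
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version as _pkg_version
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from .carbon14 import (
    PRE_BOMB_YEAR,
    BombCurve,
    IncorporationPolicy,
    PloidyModel,
    synthetic_bomb_curve,
)
from .population import DEFAULT_N0, CohortLedger, HierarchicalParams, SubjectProfile

__all__ = [
    "load_bomb_curve",
    "write_bomb_curve",
    "load_subjects",
    "write_subjects",
    "load_param_table",
    "write_ledger",
    "provenance",
    "RunConfig",
]


def _package_version() -> str:
    try:
        return _pkg_version("myoturn")
    except PackageNotFoundError:  # running from a source tree
        return "unknown"


def provenance(seed: int | None = None, config_text: str | None = None, **extra: Any) -> dict:
    """Provenance block embedded in every output file."""
    block: dict[str, Any] = {"producer": "myoturn", "version": _package_version()}
    if seed is not None:
        block["seed"] = int(seed)
    if config_text is not None:
        block["config_sha256"] = hashlib.sha256(config_text.encode()).hexdigest()
    block.update(extra)
    return block


# ---------------------------------------------------------------------------
# Bomb curve CSV
# ---------------------------------------------------------------------------


def load_bomb_curve(path: str | Path, strict: bool = True) -> BombCurve:
    """Load an atmospheric Δ14C series from CSV.

    Malformed rows, non-numeric values and duplicate timestamps raise
    errors naming the offending line number.  Pre-1955 values must be 0:
    in strict mode a violation raises, in lenient mode it is zero-filled
    with a warning.
    """
    path = Path(path)
    times: list[float] = []
    values: list[float] = []
    monthly: bool | None = None
    seen: set[float] = set()
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader, start=1):
            if not row or all(not cell.strip() for cell in row):
                continue
            if lineno == 1 and not row[0].strip().lstrip("-").replace(".", "").isdigit():
                continue  # header
            if len(row) not in (2, 3):
                raise ValueError(f"{path}:{lineno}: expected 2 or 3 columns, got {len(row)}")
            row_monthly = len(row) == 3
            if monthly is None:
                monthly = row_monthly
            elif monthly != row_monthly:
                raise ValueError(f"{path}:{lineno}: inconsistent column count")
            try:
                year = int(row[0])
                if row_monthly:
                    month = int(row[1])
                    value = float(row[2])
                else:
                    month = None
                    value = float(row[1])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric value in {row!r}") from None
            if month is not None and not 1 <= month <= 12:
                raise ValueError(f"{path}:{lineno}: month must be in 1..12, got {month}")
            t = float(year) if month is None else year + (month - 0.5) / 12.0
            if t in seen:
                raise ValueError(f"{path}:{lineno}: duplicate timestamp {row[0]}" + (f"-{month}" if month else ""))
            seen.add(t)
            if t < PRE_BOMB_YEAR and value != 0.0:
                if strict:
                    raise ValueError(
                        f"{path}:{lineno}: value {value} before {PRE_BOMB_YEAR} must be 0 "
                        "(pass strict=False to zero-fill)"
                    )
                warnings.warn(f"{path}:{lineno}: pre-{PRE_BOMB_YEAR} value {value} zero-filled")
                value = 0.0
            times.append(t)
            values.append(value)
    if not times:
        raise ValueError(f"{path}: no data rows")
    order = np.argsort(times)
    return BombCurve(
        np.asarray(times)[order],
        np.asarray(values)[order],
        resolution="monthly" if monthly else "yearly",
    )


def write_bomb_curve(curve: BombCurve, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        if curve.resolution == "yearly":
            writer.writerow(["year", "delta_c14_permil"])
            for t, v in zip(curve.times, curve.values):
                writer.writerow([int(t), repr(float(v))])
        else:
            writer.writerow(["year", "month", "delta_c14_permil"])
            for t, v in zip(curve.times, curve.values):
                year = int(np.floor(t))
                month = int(round((t - year) * 12 + 0.5))
                writer.writerow([year, month, repr(float(v))])


# ---------------------------------------------------------------------------
# Subjects and parameter tables
# ---------------------------------------------------------------------------


def load_subjects(path: str | Path) -> list[SubjectProfile]:
    frame = pd.read_csv(path)
    required = {"id", "sex", "birth_year", "lifespan"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: subject table missing columns {sorted(missing)}")
    subjects = []
    for _, row in frame.iterrows():
        subjects.append(
            SubjectProfile(
                id=str(row["id"]),
                sex=str(row["sex"]),
                birth_year=int(row["birth_year"]),
                lifespan=int(row["lifespan"]),
                end_c14=None if pd.isna(row.get("end_c14", np.nan)) else float(row["end_c14"]),
                lambda_c14=None if pd.isna(row.get("lambda_c14", np.nan)) else float(row["lambda_c14"]),
            )
        )
    return subjects


def write_subjects(subjects: list[SubjectProfile] | pd.DataFrame, path: str | Path) -> None:
    if isinstance(subjects, pd.DataFrame):
        frame = subjects
    else:
        frame = pd.DataFrame(
            {
                "id": [s.id for s in subjects],
                "sex": [s.sex for s in subjects],
                "birth_year": [s.birth_year for s in subjects],
                "lifespan": [s.lifespan for s in subjects],
                "end_c14": [s.end_c14 for s in subjects],
                "lambda_c14": [s.lambda_c14 for s in subjects],
            }
        )
    frame.to_csv(path, index=False)


def load_param_table(path: str | Path, n0: float = DEFAULT_N0) -> HierarchicalParams:
    table = pd.read_csv(path)
    return HierarchicalParams(table, n0=n0)


# ---------------------------------------------------------------------------
# Ledger output
# ---------------------------------------------------------------------------


def write_ledger(
    ledger: CohortLedger,
    tsv_path: str | Path,
    summary_path: str | Path | None = None,
    prov: Mapping[str, Any] | None = None,
) -> None:
    """Write cohort counts as TSV and, optionally, a JSON summary."""
    tsv_path = Path(tsv_path)
    with tsv_path.open("w") as fh:
        fh.write("formation_offset\tsurviving_count\n")
        for k, count in enumerate(ledger.counts):
            fh.write(f"{k}\t{float(count)!r}\n")
    if summary_path is not None:
        summary = {
            "subject": {
                "id": ledger.subject.id,
                "sex": ledger.subject.sex,
                "birth_year": ledger.subject.birth_year,
                "lifespan": ledger.subject.lifespan,
            },
            "trajectory": ledger.trajectory.tolist(),
            "formed_per_year": ledger.formed_per_year.tolist(),
            "destroyed_per_year": ledger.destroyed_per_year.tolist(),
            "provenance": dict(prov) if prov else provenance(),
        }
        Path(summary_path).write_text(json.dumps(summary, indent=2))


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

_TOP_KEYS = {"scenario", "subject", "curve", "ploidy", "policy", "n0", "seed", "out", "log_level"}


@dataclass
class RunConfig:
    """Validated simulation run configuration (YAML).

    Top-level keys: ``scenario`` (family + params), ``subject``, ``curve``
    (``path`` or ``synthetic`` spec), ``ploidy`` (sigmoid parameters,
    ``table`` or ``none``), ``policy``, ``n0``, ``seed``, ``out``,
    ``log_level``.  Unknown keys are rejected.  All units are explicit:
    rates are fractions/year, C14 in per mil, ages/durations in years.
    """

    scenario_family: str
    scenario_params: dict[str, float]
    subject: SubjectProfile | None = None
    curve_path: str | None = None
    curve_synthetic: dict[str, float] | None = None
    ploidy_spec: dict[str, Any] = field(default_factory=dict)
    policy: IncorporationPolicy = field(default_factory=IncorporationPolicy)
    n0: float = DEFAULT_N0
    seed: int = 0
    out: str | None = None
    log_level: str = "INFO"
    raw_text: str = ""

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        doc = yaml.safe_load(text)
        if not isinstance(doc, dict):
            raise ValueError(f"{path}: config must be a mapping")
        unknown = set(doc) - _TOP_KEYS
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        scenario = doc.get("scenario")
        if not isinstance(scenario, dict) or "family" not in scenario:
            raise ValueError(f"{path}: config requires scenario.family")
        extra = set(scenario) - {"family", "params"}
        if extra:
            raise ValueError(f"{path}: unknown scenario keys {sorted(extra)}")
        subject = None
        if "subject" in doc:
            s = doc["subject"]
            subject = SubjectProfile(
                id=str(s.get("id", "subject")),
                sex=s["sex"],
                birth_year=int(s["birth_year"]),
                lifespan=int(s["lifespan"]),
            )
        curve = doc.get("curve", {}) or {}
        if set(curve) - {"path", "synthetic"}:
            raise ValueError(f"{path}: unknown curve keys")
        policy_doc = doc.get("policy", {}) or {}
        if set(policy_doc) - {"delay_years", "initial_mode"}:
            raise ValueError(f"{path}: unknown policy keys")
        return cls(
            scenario_family=str(scenario["family"]),
            scenario_params={k: float(v) for k, v in (scenario.get("params") or {}).items()},
            subject=subject,
            curve_path=curve.get("path"),
            curve_synthetic=curve.get("synthetic"),
            ploidy_spec=doc.get("ploidy", {}) or {},
            policy=IncorporationPolicy(
                delay_years=int(policy_doc.get("delay_years", 0)),
                initial_mode=policy_doc.get("initial_mode", "smoothed"),
            ),
            n0=float(doc.get("n0", DEFAULT_N0)),
            seed=int(doc.get("seed", 0)),
            out=doc.get("out"),
            log_level=str(doc.get("log_level", "INFO")),
            raw_text=text,
        )

    def curve(self) -> BombCurve:
        if self.curve_path:
            return load_bomb_curve(self.curve_path)
        return synthetic_bomb_curve(**(self.curve_synthetic or {}))

    def ploidy(self) -> PloidyModel:
        spec = self.ploidy_spec
        if not spec or spec.get("none"):
            return PloidyModel.none()
        if "table" in spec:
            table = pd.read_csv(spec["table"])
            return PloidyModel.from_table(
                table["age"], table["cumulative_fraction"], scale=float(spec.get("scale", 1.0))
            )
        allowed = {"midpoint", "steepness", "plateau", "scale"}
        unknown = set(spec) - allowed
        if unknown:
            raise ValueError(f"unknown ploidy keys {sorted(unknown)}")
        return PloidyModel.sigmoid(**{k: float(v) for k, v in spec.items()})
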