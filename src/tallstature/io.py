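"""Tabular I/O, run configuration and report rendering.

Patient tables are delimited text (default tab-separated), one row per child,
with the documented column names below; earlier height measurements travel in
an optional long-format companion table (columns ``id, age, height_cm``).
Empty cells mean "not recorded".  Serialization is deterministic: the same
cohort always produces byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional, Sequence, Union

import yaml

from . import __version__
from .auxology import AuxologyProfile, ClinicalFlags, PatientRecord
from .classify import (ClassificationResult, FlowchartOutcome, Thresholds)
from .errors import ParseError
from .references import Sex

__all__ = [
    "RECORD_COLUMNS",
    "FLAG_COLUMNS",
    "read_records",
    "write_records",
    "load_thresholds",
    "render_report",
    "report_to_json",
]

FLAG_COLUMNS = tuple(ClinicalFlags.model_fields)

RECORD_COLUMNS = (
    "id", "sex", "ca", "height_cm", "weight_kg", "sitting_height_cm",
    "head_circumference_cm", "bone_age_years", "father_height_cm",
    "mother_height_cm", "tanner_breast_or_genital", "tanner_pubic",
    "reported_puberty_onset_age",
) + tuple(f"flag_{f}" for f in FLAG_COLUMNS)

_FLOAT_FIELDS = {
    "ca", "height_cm", "weight_kg", "sitting_height_cm", "head_circumference_cm",
    "bone_age_years", "father_height_cm", "mother_height_cm",
    "reported_puberty_onset_age",
}
_INT_FIELDS = {"tanner_breast_or_genital", "tanner_pubic"}


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, Sex):
        return value.value
    if isinstance(value, float):
        return format(value, "g")
    return str(value)


def write_records(
    records: Sequence[PatientRecord],
    path: Union[str, Path],
    priors_path: Optional[Union[str, Path]] = None,
    *,
    sep: str = "\t",
    header_comment: Optional[str] = None,
) -> None:
    """Write a patient table (and, if requested, the priors companion table)."""
    lines = []
    if header_comment:
        lines.extend(f"# {ln}" for ln in header_comment.splitlines())
    lines.append(sep.join(RECORD_COLUMNS))
    for r in records:
        row = []
        for col in RECORD_COLUMNS:
            if col.startswith("flag_"):
                row.append(_fmt(getattr(r.flags, col[5:])))
            else:
                row.append(_fmt(getattr(r, col)))
        lines.append(sep.join(row))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
    if priors_path is not None:
        plines = [sep.join(("id", "age", "height_cm"))]
        for r in records:
            for age, h in r.prior_measurements:
                plines.append(sep.join((r.id, _fmt(float(age)), _fmt(float(h)))))
        Path(priors_path).write_text("\n".join(plines) + "\n", encoding="utf-8")


def read_records(
    path: Union[str, Path],
    priors_path: Optional[Union[str, Path]] = None,
    *,
    sep: str = "\t",
    row_errors: Optional[list[str]] = None,
) -> list[PatientRecord]:
    """Read a patient table; raises :class:`ParseError` with the row number.

    When ``row_errors`` is a list, malformed data rows are skipped and
    described there instead of aborting, so a run can continue past bad rows.
    """
    lines = [
        ln for ln in Path(path).read_text(encoding="utf-8").splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    if not lines:
        return []
    header = lines[0].split(sep)
    missing = [c for c in ("id", "sex", "ca", "height_cm") if c not in header]
    if missing:
        raise ParseError(f"patient table missing required columns {missing}")
    priors: dict[str, list[tuple[float, float]]] = {}
    if priors_path is not None and Path(priors_path).exists():
        plines = [
            ln for ln in Path(priors_path).read_text(encoding="utf-8").splitlines()
            if ln.strip() and not ln.startswith("#")
        ]
        for i, ln in enumerate(plines[1:], start=2):
            parts = ln.split(sep)
            if len(parts) != 3:
                raise ParseError(f"priors row {i}: expected 3 fields")
            try:
                priors.setdefault(parts[0], []).append((float(parts[1]), float(parts[2])))
            except ValueError as exc:
                raise ParseError(f"priors row {i}: {exc}") from None

    records = []
    for i, ln in enumerate(lines[1:], start=2):
        parts = ln.split(sep)
        if len(parts) != len(header):
            raise ParseError(f"row {i}: expected {len(header)} fields, got {len(parts)}")
        cell = dict(zip(header, parts))
        kwargs: dict = {}
        flags: dict = {}
        try:
            for col, raw in cell.items():
                raw = raw.strip()
                if col.startswith("flag_"):
                    if raw:
                        flags[col[5:]] = raw not in ("0", "false", "False", "")
                    continue
                if col not in RECORD_COLUMNS:
                    continue
                if raw == "":
                    continue
                if col in _FLOAT_FIELDS:
                    kwargs[col] = float(raw)
                elif col in _INT_FIELDS:
                    kwargs[col] = int(raw)
                elif col == "sex":
                    kwargs[col] = Sex(raw)
                else:
                    kwargs[col] = raw
            kwargs["flags"] = ClinicalFlags(**flags)
            kwargs["prior_measurements"] = priors.get(kwargs.get("id", ""), [])
            records.append(PatientRecord(**kwargs))
        except (ValueError, TypeError) as exc:
            if row_errors is not None:
                row_errors.append(f"row {i}: {exc}")
                continue
            raise ParseError(f"row {i}: {exc}") from None
    return records


def load_thresholds(path: Union[str, Path]) -> Thresholds:
    """Build a :class:`Thresholds` from a YAML mapping of overrides.

    Sex-keyed thresholds (epiphysiodesis, second referral) accept nested
    ``male``/``female`` mappings.  Unknown keys raise.
    """
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(data, dict):
        raise ParseError("threshold config must be a mapping")
    kwargs: dict = {}
    for key, value in data.items():
        if key not in Thresholds.__dataclass_fields__:
            raise ParseError(f"unknown threshold key {key!r}")
        if isinstance(value, dict):
            value = {Sex(k): float(v) for k, v in value.items()}
        kwargs[key] = value
    return Thresholds(**kwargs)


def _round_floats(obj, ndigits=4):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def report_to_json(
    profiles: Sequence[AuxologyProfile],
    results: Sequence[ClassificationResult],
    outcomes: Sequence[FlowchartOutcome],
    *,
    seed: Optional[int] = None,
    config_text: Optional[str] = None,
) -> str:
    """Machine-readable per-child report with provenance metadata."""
    meta = {"version": __version__}
    if seed is not None:
        meta["seed"] = seed
    if config_text is not None:
        meta["config_sha256"] = hashlib.sha256(config_text.encode()).hexdigest()
    children = []
    for p, r, o in zip(profiles, results, outcomes):
        d = {
            "id": r.record_id,
            "profile": _round_floats({k: v for k, v in asdict(p).items() if k != "record_id"}),
            "classification": {
                "is_tall": r.is_tall,
                "fts_by_th": r.fts_by_th,
                "fts_by_cth": r.fts_by_cth,
                "fts_by_tallest_parent": r.fts_by_tallest_parent,
                "its_subclass": r.its_subclass.value,
                "pathology_suspected": r.pathology_suspected,
                "epiphysiodesis_flag": r.epiphysiodesis_flag,
                "second_referral": list(r.second_referral) if r.second_referral else None,
            },
            "flowchart": {
                "terminal": o.terminal.value,
                "triggered_flags": o.triggered_flags,
                "rationale": o.rationale,
            },
        }
        children.append(d)
    return json.dumps({"meta": meta, "children": children}, indent=2, sort_keys=True)


def render_report(
    results: Sequence[ClassificationResult],
    outcomes: Sequence[FlowchartOutcome],
) -> str:
    """Aligned key-value text report, one block per child plus a count footer."""
    lines = []
    for r, o in zip(results, outcomes):
        lines.append(f"child {r.record_id}")
        lines.append(f"  tall:            {'yes' if r.is_tall else 'no'}")
        lines.append(f"  its_subclass:    {r.its_subclass.value}")
        lines.append(f"  terminal:        {o.terminal.value}")
        if o.triggered_flags:
            lines.append(f"  triggered_flags: {', '.join(o.triggered_flags)}")
        if r.second_referral:
            h, a = r.second_referral
            lines.append(f"  second_referral: at {h:g} cm before age {a:g} y")
    counts: dict[str, int] = {}
    for o in outcomes:
        counts[o.terminal.value] = counts.get(o.terminal.value, 0) + 1
    lines.append("")
    lines.append("terminal counts:")
    for term in sorted(counts):
        lines.append(f"  {term}: {counts[term]}")
    return "\n".join(lines) + "\n"
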