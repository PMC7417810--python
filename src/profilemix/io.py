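"""CSV readers/writers and run manifests.

The cohort CSV carries one row per patient (indicators, year, baseline and
final scores, session count, end status); the episode CSV one row per
session.  Empty cells denote missing values.  All files are comma-separated
UTF-8 with a header row and dot decimals.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Sequence

import math
import pandas as pd

from .mixture import IndicatorVector, default_schema
from .outcomes import EndStatus, EpisodeScores, ScorePair
from .simulate import PatientRecord
from .treatment import EpisodeTreatment

__all__ = [
    "SchemaError",
    "RowError",
    "RunManifest",
    "write_cohort",
    "read_cohort",
    "write_episodes",
    "read_episodes",
]

COHORT_COLUMNS = [
    "id",
    "year",
    "phq",
    "gad",
    "wsas",
    "age",
    "phobia",
    "gender",
    "medication",
    "welfare",
    "ethnicity",
    "baseline_phq",
    "baseline_gad",
    "final_phq",
    "final_gad",
    "n_sessions",
    "end_status",
    "true_profile",
]

EPISODE_COLUMNS = ["patient_id", "session_index", "modality", "intensity"]


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class RowError(ValueError):
    """A row holds an unparsable value; carries the row number."""


@dataclass
class RunManifest:
    """Reproducibility record for one pipeline invocation."""

    command: str
    seed: int
    config_hash: str = ""
    inputs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )

    def add_count(self, stage: str, n: int) -> None:
        self.counts[stage] = int(n)

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.__dict__, fh, indent=1, default=str)

    @staticmethod
    def hash_file(path) -> str:
        h = hashlib.sha256()
        with open(path, "rb") as fh:
            h.update(fh.read())
        return h.hexdigest()


def _fmt(v) -> str:
    if v is None:
        return ""
    if isinstance(v, float):
        if math.isnan(v):
            return ""
        if v == int(v):
            return str(int(v))
        return repr(v)
    return str(v)


def write_cohort(records: Sequence[PatientRecord], path) -> None:
    """Write one row per patient; missing values become empty cells."""
    rows = []
    for rec in records:
        row = {"id": rec.id, "year": rec.year}
        for name, val, obs in zip(
            default_schema().names, rec.indicators.values, rec.indicators.observed
        ):
            row[name] = val if obs else None
        sc = rec.scores
        row["baseline_phq"] = sc.baseline.phq if sc else None
        row["baseline_gad"] = sc.baseline.gad if sc else None
        row["final_phq"] = sc.final.phq if sc and sc.final else None
        row["final_gad"] = sc.final.gad if sc and sc.final else None
        row["n_sessions"] = sc.n_sessions if sc else None
        row["end_status"] = sc.end_status.value if sc else None
        row["true_profile"] = rec.true_profile
        rows.append(row)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(",".join(COHORT_COLUMNS) + "\n")
        for row in rows:
            fh.write(",".join(_fmt(row.get(c)) for c in COHORT_COLUMNS) + "\n")


def read_cohort(path) -> list[PatientRecord]:
    """Read a cohort CSV back into records (inverse of :func:`write_cohort`)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = [c for c in COHORT_COLUMNS if c not in ("true_profile",)]
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"cohort CSV is missing required column {col!r}")
    schema = default_schema()
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        row = row._asdict()

        def num(col, kind=float, row=row, line=i):
            cell = row[col].strip()
            if cell == "":
                return None
            try:
                return kind(float(cell))
            except ValueError as exc:
                raise RowError(f"line {line}: column {col!r} is not numeric: {cell!r}") from exc

        values = [num(name) for name in schema.names]
        indicators = IndicatorVector.from_values(values)
        b_phq, b_gad = num("baseline_phq", int), num("baseline_gad", int)
        scores = None
        if b_phq is not None and b_gad is not None:
            f_phq, f_gad = num("final_phq", int), num("final_gad", int)
            final = (
                ScorePair(phq=f_phq, gad=f_gad)
                if f_phq is not None and f_gad is not None
                else None
            )
            status = row["end_status"].strip() or "other"
            scores = EpisodeScores(
                baseline=ScorePair(phq=b_phq, gad=b_gad),
                final=final,
                n_sessions=num("n_sessions", int) or 0,
                end_status=EndStatus(status),
            )
        tp = row.get("true_profile", "").strip()
        records.append(
            PatientRecord(
                id=int(num("id", int)),
                indicators=indicators,
                year=row["year"],
                true_profile=int(tp) if tp else None,
                scores=scores,
            )
        )
    return records


def write_episodes(records: Sequence[PatientRecord], path) -> None:
    """Write one row per treatment session."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(",".join(EPISODE_COLUMNS) + "\n")
        for rec in records:
            if rec.episode is None:
                continue
            for s, (mod, inten) in enumerate(
                zip(rec.episode.session_modalities, rec.episode.session_intensities)
            ):
                fh.write(f"{rec.id},{s},{mod},{inten}\n")


def read_episodes(path) -> dict[int, EpisodeTreatment]:
    """Read a per-session CSV into per-patient episodes."""
    df = pd.read_csv(path, dtype={"patient_id": int, "session_index": int})
    for col in EPISODE_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"episode CSV is missing required column {col!r}")
    episodes: dict[int, EpisodeTreatment] = {}
    for pid, grp in df.sort_values("session_index").groupby("patient_id"):
        episodes[int(pid)] = EpisodeTreatment(
            session_modalities=tuple(grp["modality"]),
            session_intensities=tuple(grp["intensity"]),
        )
    return episodes


def attach_episodes(
    records: Sequence[PatientRecord], episodes: dict[int, EpisodeTreatment]
) -> list[PatientRecord]:
    """Return records with episodes joined on patient id."""
    from dataclasses import replace

    return [replace(r, episode=episodes.get(r.id)) for r in records]
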