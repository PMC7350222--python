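"""CSV interchange schemas, configuration files and the run manifest.

Two delimited-text schemas carry all trial data:

stage CSV
    ``animal_id, breed, antigen_group, tick_species, larvae_applied,
    larvae_engorged, larvae_molted, nymphs_applied, nymphs_engorged,
    nymphs_molted, females_applied, females_engorged, egg_mass_g,
    larval_mass_per_g_eggs_g`` — one row per (animal, tick species);
    one-host species leave the larval/nymphal columns empty.

serology CSV
    ``animal_id, antigen_group, coated_antigen, day, od450`` — one row per
    reading.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings as _warnings
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

import pandas as pd

from .records import AnimalStageRecord
from .serology import AntibodySeries

__all__ = [
    "STAGE_COLUMNS",
    "SEROLOGY_COLUMNS",
    "read_stage_records",
    "write_stage_records",
    "stage_records_to_frame",
    "read_serology",
    "write_serology",
    "serology_to_frame",
    "RunManifest",
]

STAGE_COLUMNS = [
    "animal_id",
    "breed",
    "antigen_group",
    "tick_species",
    "larvae_applied",
    "larvae_engorged",
    "larvae_molted",
    "nymphs_applied",
    "nymphs_engorged",
    "nymphs_molted",
    "females_applied",
    "females_engorged",
    "egg_mass_g",
    "larval_mass_per_g_eggs_g",
]

SEROLOGY_COLUMNS = ["animal_id", "antigen_group", "coated_antigen", "day", "od450"]

_INT_STAGE_FIELDS = [
    "larvae_applied",
    "larvae_engorged",
    "larvae_molted",
    "nymphs_applied",
    "nymphs_engorged",
    "nymphs_molted",
]


def stage_records_to_frame(records: Sequence[AnimalStageRecord]) -> pd.DataFrame:
    rows = [dataclasses.asdict(r) for r in records]
    df = pd.DataFrame(rows, columns=STAGE_COLUMNS)
    for col in _INT_STAGE_FIELDS:
        df[col] = df[col].astype("Int64")
    return df


def write_stage_records(records: Sequence[AnimalStageRecord], path: str | Path) -> None:
    # %.17g keeps the masses bit-exact across a write/read cycle
    stage_records_to_frame(records).to_csv(path, index=False, float_format="%.17g")


def read_stage_records(path: str | Path) -> list[AnimalStageRecord]:
    """Read and validate a stage CSV.

    Raises ``ValueError`` naming the offending row for missing columns,
    non-numeric fields or chain-consistency violations; an empty file returns
    an empty list with a warning.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        _warnings.warn(f"{path}: empty stage record file", stacklevel=2)
        return []
    missing = [c for c in STAGE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    records = []
    for idx, row in df.iterrows():
        kwargs = {}
        for col in STAGE_COLUMNS:
            val = row[col]
            if col in ("animal_id", "breed", "antigen_group", "tick_species"):
                kwargs[col] = str(val)
            elif pd.isna(val):
                kwargs[col] = None
            else:
                try:
                    kwargs[col] = int(val) if col not in ("egg_mass_g", "larval_mass_per_g_eggs_g") else float(val)
                except (TypeError, ValueError) as exc:
                    raise ValueError(f"{path}: row {idx + 2}: non-numeric {col}={val!r}") from exc
        for col in ("females_applied", "females_engorged", "egg_mass_g", "larval_mass_per_g_eggs_g"):
            if kwargs[col] is None:
                raise ValueError(f"{path}: row {idx + 2}: missing required field {col}")
        try:
            records.append(AnimalStageRecord(**kwargs))
        except ValueError as exc:
            raise ValueError(f"{path}: row {idx + 2}: {exc}") from exc
    return records


def serology_to_frame(series: Sequence[AntibodySeries]) -> pd.DataFrame:
    rows = [
        {
            "animal_id": s.animal_id,
            "antigen_group": s.antigen_group,
            "coated_antigen": s.coated_antigen,
            "day": day,
            "od450": od,
        }
        for s in series
        for day, od in sorted(s.readings.items())
    ]
    return pd.DataFrame(rows, columns=SEROLOGY_COLUMNS)


def write_serology(series: Sequence[AntibodySeries], path: str | Path) -> None:
    serology_to_frame(series).to_csv(path, index=False, float_format="%.17g")


def read_serology(path: str | Path) -> list[AntibodySeries]:
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        _warnings.warn(f"{path}: empty serology file", stacklevel=2)
        return []
    missing = [c for c in SEROLOGY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    out: dict[tuple[str, str, str], AntibodySeries] = {}
    for idx, row in df.iterrows():
        key = (str(row.animal_id), str(row.antigen_group), str(row.coated_antigen))
        if key not in out:
            out[key] = AntibodySeries(*key, readings={})
        try:
            day, od = int(row.day), float(row.od450)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: row {idx + 2}: non-numeric day/od450") from exc
        if od < 0:
            raise ValueError(f"{path}: row {idx + 2}: negative OD450")
        out[key].readings[day] = od
    return list(out.values())


def _jsonable(o):
    if dataclasses.is_dataclass(o) and not isinstance(o, type):
        return {f.name: _jsonable(getattr(o, f.name)) for f in dataclasses.fields(o)}
    if isinstance(o, dict):
        return {str(k): _jsonable(v) for k, v in o.items()}
    if isinstance(o, (list, tuple, set)):
        return [_jsonable(v) for v in o]
    if isinstance(o, (str, int, float, bool)) or o is None:
        return o
    return str(o)


def _canonical_json(obj) -> str:
    return json.dumps(_jsonable(obj), sort_keys=True)


@dataclass
class RunManifest:
    """Provenance of one pipeline run: config hash, seed, inputs, gate settings."""

    config_hash: str
    seed: int
    alpha: float
    gate_method: str
    created_utc: str
    input_digests: dict[str, str] = dataclasses.field(default_factory=dict)

    @classmethod
    def create(
        cls,
        config,
        seed: int,
        alpha: float,
        gate_method: str,
        input_paths: Sequence[str | Path] = (),
    ) -> "RunManifest":
        digests = {}
        for p in input_paths:
            p = Path(p)
            digests[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
        return cls(
            config_hash=hashlib.sha256(_canonical_json(config).encode()).hexdigest(),
            seed=seed,
            alpha=alpha,
            gate_method=gate_method,
            created_utc=datetime.now(timezone.utc).isoformat(timespec="seconds"),
            input_digests=digests,
        )

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")
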