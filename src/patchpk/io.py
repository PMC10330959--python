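"""Dataset file format, run configuration and results serialization.

Datasets are comma-delimited text with NONMEM-flavored columns:

    ID, TIME, DV, BLQ, AMT, EVID, AGE, WT, HT, BMI, SEX, STUDY

EVID = 0 marks an observation row (DV blank when BLQ = 1), EVID = 1 the
single patch-application row (AMT in ng), and EVID = 2 the patch-removal
marker.  Time is in hours from patch application.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import Dataset, DoseEvent, Observation, Subject

__all__ = ["read_dataset", "write_dataset", "RunConfig", "DatasetFormatError"]

COLUMNS = ["ID", "TIME", "DV", "BLQ", "AMT", "EVID", "AGE", "WT", "HT", "BMI", "SEX", "STUDY"]
_COVARIATE_COLS = ["AGE", "WT", "HT", "BMI", "SEX"]


class DatasetFormatError(ValueError):
    pass


def write_dataset(dataset: Dataset, path: str | Path) -> None:
    """Serialize a Dataset to the delimited text dialect."""
    rows = []
    for s in dataset:
        covs = {c: s.covariates.get(c, "") for c in _COVARIATE_COLS}
        base = {"ID": s.id, "STUDY": s.study, **covs}
        rows.append(
            base | {"TIME": s.dose.t_apply, "DV": "", "BLQ": 0, "AMT": s.dose.amount, "EVID": 1}
        )
        for o in s.observations:
            rows.append(
                base
                | {
                    "TIME": o.time,
                    "DV": "" if o.blq else o.conc,
                    "BLQ": int(o.blq),
                    "AMT": "",
                    "EVID": 0,
                }
            )
        rows.append(
            base | {"TIME": s.dose.t_remove, "DV": "", "BLQ": 0, "AMT": "", "EVID": 2}
        )
    frame = pd.DataFrame(rows, columns=COLUMNS)
    frame.to_csv(path, index=False)


def read_dataset(path: str | Path) -> Dataset:
    """Parse and validate a dataset file; raises DatasetFormatError with the
    offending file row number on invariant violations."""
    frame = pd.read_csv(path, dtype={"ID": str, "STUDY": str})
    missing = [c for c in COLUMNS if c not in frame.columns]
    if missing:
        raise DatasetFormatError(f"missing columns: {missing}")
    frame["_row"] = frame.index + 2  # header is line 1
    subjects = []
    seen_ids = set()
    for sid, g in frame.groupby("ID", sort=False):
        if sid in seen_ids:
            raise DatasetFormatError(f"duplicate subject id {sid!r}")
        seen_ids.add(sid)
        doses = g[g["EVID"] == 1]
        removals = g[g["EVID"] == 2]
        if len(doses) != 1 or len(removals) != 1:
            raise DatasetFormatError(
                f"subject {sid!r} must have exactly one EVID=1 and one EVID=2 row "
                f"(rows {g['_row'].tolist()})"
            )
        dose_row = doses.iloc[0]
        removal_row = removals.iloc[0]
        if not pd.isna(dose_row["DV"]):
            raise DatasetFormatError(
                f"row {dose_row['_row']}: DV must be blank on an EVID=1 dose row"
            )
        if pd.isna(dose_row["AMT"]):
            raise DatasetFormatError(f"row {dose_row['_row']}: dose row requires AMT")
        if not removal_row["TIME"] > dose_row["TIME"]:
            raise DatasetFormatError(
                f"row {removal_row['_row']}: removal time must exceed application time"
            )
        obs_rows = g[g["EVID"] == 0]
        times = obs_rows["TIME"].to_numpy(dtype=float)
        if np.any(np.diff(times) < 0):
            bad = obs_rows["_row"].iloc[int(np.flatnonzero(np.diff(times) < 0)[0]) + 1]
            raise DatasetFormatError(f"row {bad}: observation times not sorted for {sid!r}")
        observations = []
        for _, r in obs_rows.iterrows():
            blq = bool(int(r["BLQ"])) if not pd.isna(r["BLQ"]) else pd.isna(r["DV"])
            if blq and not pd.isna(r["DV"]):
                raise DatasetFormatError(
                    f"row {r['_row']}: BLQ row must not carry a DV value"
                )
            if not blq and pd.isna(r["DV"]):
                raise DatasetFormatError(f"row {r['_row']}: missing DV on a non-BLQ row")
            observations.append(
                Observation(
                    time=float(r["TIME"]),
                    conc=None if blq else float(r["DV"]),
                    blq=blq,
                )
            )
        covs = {}
        for c in _COVARIATE_COLS:
            v = dose_row[c]
            if not pd.isna(v) and v != "":
                covs[c] = float(v)
        subjects.append(
            Subject(
                id=str(sid),
                dose=DoseEvent(
                    amount=float(dose_row["AMT"]),
                    t_apply=float(dose_row["TIME"]),
                    t_remove=float(removal_row["TIME"]),
                ),
                observations=observations,
                covariates=covs,
                study=str(dose_row["STUDY"]),
            )
        )
    return Dataset(subjects)


@dataclass
class RunConfig:
    """Analysis configuration shared across the pipeline commands."""

    seed: int = 20230626
    lloq: float = 0.1
    forward_threshold: float = 3.84
    backward_threshold: float = 6.64
    n_boot: int = 1000
    n_vpc: int = 1000
    n_trials: int = 1000
    truncate_at_removal: bool = True
    cavg_mode: str = "tlast"
    stratified_bootstrap: bool = True
    residual_in_simulation: bool = True
    verdict_threshold: float = 0.85
    ofv_rtol: float = 1e-4
    param_rtol: float = 1e-3

    def __post_init__(self) -> None:
        for name in ("n_boot", "n_vpc", "n_trials"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.forward_threshold <= 0 or self.backward_threshold <= 0:
            raise ValueError("thresholds must be > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def write_table(frame: pd.DataFrame, path: str | Path, config: RunConfig | None = None,
                seed: int | None = None, **meta) -> None:
    """Write a tab-separated result table with a provenance header (the
    config and seed that produced it, as commented JSON)."""
    payload = {"seed": seed if seed is not None else (config.seed if config else None)}
    if config is not None:
        payload["config"] = config.as_dict()
    payload.update(meta)
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(payload, sort_keys=True) + "\n")
        frame.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path) -> tuple[pd.DataFrame, dict]:
    """Read a table written by write_table; returns (frame, provenance)."""
    with open(path) as fh:
        first = fh.readline()
        meta = json.loads(first[1:].strip()) if first.startswith("#") else {}
        frame = pd.read_csv(fh, sep="\t")
    return frame, meta
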