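"""Plain-text readers/writers, run manifests, and seed derivation.

All formats are text-first: angle files are one angle per line (or a named
CSV/TSV column), trial matrices are one delimited file per channel (rows =
trials, columns = samples) with a JSON sidecar carrying the sampling rate,
and results serialize to JSON or TSV.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .circstats import AngleSample
from .evaluate import ROCResult
from .exceptions import InvalidInputError
from .ranktest import TestResult
from .spectral import TrialArray

__all__ = [
    "read_angles",
    "write_angles",
    "read_trials",
    "write_trials",
    "write_result",
    "RunManifest",
    "derive_seed",
]


def derive_seed(master_seed: Optional[int], stage: str) -> int:
    """Deterministic per-stage seed: a hash of the master seed and stage name.

    Keeps independently named stages statistically independent while making
    every stage reproducible from one top-level seed. Result is < 2**31.
    """
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def read_angles(path, column: Optional[str] = None, units: str = "radians") -> AngleSample:
    """Read an AngleSample from a text file.

    Without ``column``: one angle per line; blank lines and ``#`` comments
    are skipped (a leading comment may carry the population label).
    With ``column``: a delimited table (separator sniffed) with that column.
    ``units="degrees"`` converts on read.
    """
    if units not in ("radians", "degrees"):
        raise InvalidInputError(f"units must be 'radians' or 'degrees', got {units!r}")
    path = Path(path)
    label = path.stem
    if column is not None:
        df = pd.read_csv(path, sep=None, engine="python")
        if column not in df.columns:
            raise InvalidInputError(f"column {column!r} not found in {path} (have {list(df.columns)})")
        values = pd.to_numeric(df[column], errors="coerce").to_numpy(dtype=float)
        if np.isnan(values).any():
            row = int(np.flatnonzero(np.isnan(values))[0])
            raise InvalidInputError(f"non-numeric entry in column {column!r} of {path} at row {row + 1}")
        label = column
    else:
        values = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                text = line.strip()
                if not text:
                    continue
                if text.startswith("#"):
                    stripped = text.lstrip("#").strip()
                    if stripped and lineno == 1:
                        label = stripped
                    continue
                try:
                    values.append(float(text))
                except ValueError:
                    raise InvalidInputError(f"non-numeric entry {text!r} in {path} at line {lineno}") from None
        if not values:
            raise InvalidInputError(f"no angles found in {path}")
        values = np.asarray(values, dtype=float)
    if units == "degrees":
        values = np.deg2rad(values)
    return AngleSample(values, label=label)


def write_angles(sample: AngleSample, path) -> None:
    """Write an AngleSample as one radian value per line, label in a header comment."""
    path = Path(path)
    lines = [f"# {sample.label}"] if sample.label else []
    lines += [f"{a:.17g}" for a in sample.angles]
    path.write_text("\n".join(lines) + "\n")


def read_trials(matrix_paths: Sequence, sidecar_path) -> TrialArray:
    """Assemble a TrialArray from per-channel delimited matrices and a JSON sidecar.

    Each matrix file holds one channel, rows = trials and columns = samples;
    all must share a shape. The sidecar must provide ``fs`` (Hz) and may
    provide ``t0`` (seconds) and ``channel_names`` (defining channel order).
    """
    sidecar = json.loads(Path(sidecar_path).read_text())
    if "fs" not in sidecar:
        raise InvalidInputError(f"sidecar {sidecar_path} is missing the required 'fs' field")
    fs = float(sidecar["fs"])
    if fs <= 0:
        raise InvalidInputError(f"sampling rate must be positive, got fs={fs}")
    mats = []
    shapes = []
    for p in matrix_paths:
        m = pd.read_csv(p, sep=None, engine="python", header=None).to_numpy(dtype=float)
        mats.append(m)
        shapes.append(m.shape)
    if len(set(shapes)) > 1:
        raise InvalidInputError(f"channel matrices disagree in shape: {shapes}")
    data = np.stack(mats, axis=1)  # (trial, channel, sample)
    return TrialArray(
        data=data,
        fs=fs,
        t0=float(sidecar.get("t0", 0.0)),
        channel_names=sidecar.get("channel_names"),
    )


def write_trials(trials: TrialArray, out_dir, stem: str = "channel") -> dict:
    """Write a TrialArray as per-channel CSV matrices plus a JSON sidecar; returns the sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    names = trials.channel_names or tuple(f"{stem}{c:02d}" for c in range(trials.n_channels))
    paths = []
    for c, name in enumerate(names):
        p = out_dir / f"{name}.csv"
        np.savetxt(p, trials.data[:, c, :], delimiter=",")
        paths.append(p.name)
    sidecar = {"fs": trials.fs, "t0": trials.t0, "channel_names": list(names), "files": paths}
    (out_dir / "trials.json").write_text(json.dumps(sidecar, indent=2) + "\n")
    return sidecar


def _roc_to_frame(result: ROCResult) -> pd.DataFrame:
    return pd.DataFrame(result.points, columns=["fpr", "tpr"])


def write_result(result, path, format: str = "json") -> None:
    """Serialize a TestResult, ROCResult, or benchmark DataFrame to JSON or TSV."""
    path = Path(path)
    if format not in ("json", "tsv"):
        raise InvalidInputError(f"format must be 'json' or 'tsv', got {format!r}")
    if isinstance(result, TestResult):
        if format == "tsv":
            pd.DataFrame([result.to_dict()]).drop(columns=["extra"]).to_csv(path, sep="\t", index=False)
        else:
            path.write_text(json.dumps(result.to_dict(), indent=2) + "\n")
    elif isinstance(result, ROCResult):
        if format == "tsv":
            _roc_to_frame(result).to_csv(path, sep="\t", index=False)
        else:
            payload = {
                "auc": result.auc,
                "auc_sd": result.auc_sd,
                "n_pos": result.n_pos,
                "n_neg": result.n_neg,
                "points": result.points.tolist(),
            }
            path.write_text(json.dumps(payload, indent=2) + "\n")
    elif isinstance(result, pd.DataFrame):
        if format == "tsv":
            result.to_csv(path, sep="\t", index=False)
        else:
            path.write_text(result.to_json(orient="records", indent=2) + "\n")
    else:
        raise InvalidInputError(f"cannot serialize object of type {type(result).__name__}")


@dataclasses.dataclass
class RunManifest:
    """Provenance record written by every CLI run."""

    tool_version: str
    subcommand: str
    resolved_config: dict
    seeds: dict
    timestamp: str = dataclasses.field(
        default_factory=lambda: datetime.datetime.now(datetime.timezone.utc).isoformat()
    )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, default=str) + "\n")
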