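"""File I/O, run configuration and seed management.

Streams travel as two-column CSV (time_s, amplitude_mV) with an optional
JSON sidecar (sampling rate, subject label, ground-truth R-peaks, lead-on
mask run-lengths) written by :func:`wheelbeat.synthetic.write_stream_csv`.
Reports are plain JSON.

One global seed fans out deterministically to per-stage seeds by hashing
the stage name (CRC-32) against the global seed, so stages can be re-run
in isolation without replaying the whole pipeline.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from wheelbeat.stream_prep import EcgStream

__all__ = ["RunConfig", "ParseError", "read_stream", "write_report",
           "read_report", "stage_seed"]


class ParseError(ValueError):
    """A malformed input file, with the offending line where known."""


def stage_seed(name: str, global_seed: int) -> int:
    """Deterministic per-stage sub-seed in [0, 2**31)."""
    return (zlib.crc32(name.encode()) ^ (int(global_seed) * 0x9E3779B1)) % (2**31)


@dataclass
class RunConfig:
    """All tunables of a pipeline run, serialisable to JSON/YAML."""

    fs: float = 1000.0
    seed: int = 0
    sg_window_s: float = 0.051
    sg_order: int = 3
    maf_window_s: float = 1.0
    nccc_n: int = 3
    nccc_eps0: float = 0.1
    scheme: str = "DCT"            # "DCT" | "HAAR2"
    model: str = "svm"             # svm | knn | mlp | gmmubm
    protocol: str = "70-30"        # "70-30" | "30s"
    folds: int = 1
    weighting_n: int = 4
    weighting_sigma_s: float = 2.0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ParseError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def dump(self, path: str | Path) -> Path:
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            import yaml

            path.write_text(yaml.safe_dump(self.to_dict()))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        if not isinstance(data, dict):
            raise ParseError(f"{path}: config must be a mapping")
        return cls.from_dict(data)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return f"{zlib.crc32(blob):08x}"

    def stage_seed(self, stage: str) -> int:
        return stage_seed(stage, self.seed)


def _expand_mask(runs: list, n: int) -> np.ndarray:
    mask = np.ones(n, dtype=bool)
    i = 0
    for value, length in runs:
        mask[i:i + length] = bool(value)
        i += length
    return mask


def read_stream(path: str | Path, fs: float | None = None) -> EcgStream:
    """Read a (time_s, amplitude_mV) CSV — or one bare amplitude column.

    The sampling rate is taken from ``fs``, else the JSON sidecar, else the
    median time step.  A sidecar lead-on mask is applied when present.
    Malformed lines raise :class:`ParseError` with the line number.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ParseError(f"{path}: file is empty")
    lines = text.splitlines()
    start = 0
    header = lines[0].replace(",", " ").split()
    if header and not _is_number(header[0]):
        start = 1
    rows = []
    for lineno, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        parts = line.replace(",", " ").split()
        try:
            rows.append([float(p) for p in parts])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: cannot parse {line!r}") from exc
    if not rows:
        warnings.warn(f"{path}: header-only file, returning an empty stream")
        return EcgStream(samples=np.empty(0), fs=fs or 1.0)
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        bad = next(i for i, r in enumerate(rows) if len(r) != width)
        raise ParseError(f"{path}:{start + bad + 1}: inconsistent column count")
    arr = np.asarray(rows, dtype=float)
    if width == 1:
        t, x = None, arr[:, 0]
    else:
        t, x = arr[:, 0], arr[:, 1]

    sidecar = path.with_suffix(path.suffix + ".json")
    mask = None
    if sidecar.exists():
        side = json.loads(sidecar.read_text())
        fs = fs or side.get("fs")
        if "mask_runs" in side:
            mask = _expand_mask(side["mask_runs"], x.size)
    if fs is None:
        if t is None or t.size < 2:
            raise ParseError(f"{path}: sampling rate unknown (no time column)")
        fs = 1.0 / float(np.median(np.diff(t)))
    return EcgStream(samples=x, fs=float(fs), mask=mask)


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def write_report(report: dict, path: str | Path) -> Path:
    """Write a JSON report (numpy types coerced to plain Python)."""
    path = Path(path)

    def coerce(obj):
        if isinstance(obj, np.generic):
            return obj.item()
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        raise TypeError(f"not JSON-serialisable: {type(obj)}")

    path.write_text(json.dumps(report, indent=2, default=coerce))
    return path


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


_MODEL_FORMAT = "wheelbeat-model-v1"


def save_model(model, path: str | Path) -> Path:
    """Persist a trained enrolment model (versioned joblib archive)."""
    import joblib

    path = Path(path)
    joblib.dump({"format": _MODEL_FORMAT, "model": model}, path)
    return path


def load_model(path: str | Path):
    import joblib

    blob = joblib.load(path)
    if not isinstance(blob, dict) or blob.get("format") != _MODEL_FORMAT:
        raise ParseError(f"{path}: not a {_MODEL_FORMAT} archive")
    return blob["model"]
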