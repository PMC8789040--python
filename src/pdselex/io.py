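"""Format readers/writers and reproducibility plumbing.

FASTQ is read through pysam (gzip-transparent) and written as plain 4-line
records; count tables travel as TSV, sensorgrams as tidy CSV, fit reports as
JSON.  A single master seed fans out to per-stage seeds through a
deterministic derivation so individual stages can be rerun in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FastqRecord",
    "FormatError",
    "read_counts_tsv",
    "read_fastq",
    "read_sensorgram_csv",
    "stage_rng",
    "stage_seed",
    "write_counts_tsv",
    "write_fastq",
    "write_fit_json",
    "write_manifest",
    "write_sensorgram_csv",
]


class FormatError(ValueError):
    """A file did not conform to the expected on-disk format."""


@dataclass(frozen=True)
class FastqRecord:
    id: str
    sequence: str
    quality: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise FormatError(
                f"record {self.id!r}: sequence and quality lengths differ"
            )


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------


def read_fastq(path) -> list[FastqRecord]:
    """Read a (possibly gzipped) FASTQ file into records."""
    import pysam

    records: list[FastqRecord] = []
    try:
        with pysam.FastxFile(str(path)) as fh:
            for entry in fh:
                records.append(
                    FastqRecord(entry.name, entry.sequence, entry.quality or "")
                )
    except OSError as exc:
        raise FormatError(f"cannot read FASTQ {path}: {exc}") from exc
    return records


def write_fastq(records, path) -> None:
    """Write 4-line FASTQ records (gzip if the path ends in .gz)."""
    import gzip

    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for rec in records:
            fh.write(f"@{rec.id}\n{rec.sequence}\n+\n{rec.quality}\n")


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

_COUNT_COLUMNS = ["sequence", "count"]


def write_counts_tsv(counts: pd.Series, path) -> None:
    """Write a sequence -> count series as a two-column TSV."""
    df = counts.rename("count").rename_axis("sequence").reset_index()
    df.to_csv(path, sep="\t", index=False)


def read_counts_tsv(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    for col in _COUNT_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    return pd.Series(df["count"].to_numpy(), index=df["sequence"], name="count")


def write_sensorgram_csv(sensorgrams, path) -> None:
    """Tidy CSV: one row per sample (time, response, concentration, phase)."""
    frames = []
    for sg in sensorgrams:
        frames.append(
            pd.DataFrame(
                {
                    "time": sg.time,
                    "response": sg.response,
                    "concentration": sg.concentration,
                    "phase": sg.phases(),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_sensorgram_csv(path):
    """Read a tidy sensorgram CSV into a list of Sensorgram objects."""
    from .kinetics import Sensorgram

    df = pd.read_csv(path)
    required = {"time", "response", "concentration"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing required column(s) {sorted(missing)}")
    out = []
    for conc, group in df.groupby("concentration", sort=True):
        group = group.sort_values("time")
        t = group["time"].to_numpy(float)
        r = group["response"].to_numpy(float)
        if "phase" in group.columns:
            assoc = group["phase"].to_numpy() == "association"
            t_assoc_end = float(t[assoc].max()) if assoc.any() else float(t.max())
        else:
            t_assoc_end = float(t.max())
        out.append(
            Sensorgram(
                concentration=float(conc), time=t, response=r,
                t_assoc_end=t_assoc_end,
            )
        )
    return out


def write_fit_json(results, path) -> None:
    with open(path, "w") as fh:
        json.dump(results.to_dict(), fh, indent=2)


# ---------------------------------------------------------------------------
# seeds & manifests
# ---------------------------------------------------------------------------


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 derived from a master seed."""
    return (int(master_seed) * 2_654_435_761 + zlib.crc32(stage.encode())) % (2**31)


def stage_rng(master_seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(stage_seed(master_seed, stage))


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir, *, stage: str, seed: int, inputs=None, parameters=None):
    """Record inputs, parameters, seed and output checksums for a run."""
    from . import __version__

    out_dir = Path(out_dir)
    outputs = {
        p.name: _checksum(p)
        for p in sorted(out_dir.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = {
        "stage": stage,
        "seed": int(seed),
        "version": __version__,
        "inputs": {str(k): str(v) for k, v in (inputs or {}).items()},
        "parameters": _jsonable(parameters or {}),
        "outputs": outputs,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
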