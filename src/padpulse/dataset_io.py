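"""HDF5 persistence for simulated waveform datasets.

Layout::

    /waveforms   float64, (n_samples, 2 sites, 2 quantities, N)
                 sites: [brachial, ankle]; quantities: [BP mmHg, BF cm^3/s]
    /labels      float64, (n_samples,)  severity (fractional area occlusion)
    /patient_idx int64,   (n_samples,)  index into /patient_ids
    /replicate   int64,   (n_samples,)
    /patient_ids variable-length str, unique patient ids
    attrs        manifest_hash, seed, period, label_hash, solver config JSON

Datasets are chunked and append-capable; an embedded SHA-256 of the label
array lets loads detect tampering or truncation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import h5py
import numpy as np

from .tl_solver import WaveformRecord

__all__ = ["DatasetWriter", "Dataset", "write_dataset", "read_dataset"]


def _label_hash(labels: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(labels, dtype=np.float64).tobytes()).hexdigest()


class DatasetWriter:
    """Chunked, append-capable writer for waveform records."""

    def __init__(self, path, n_samples_per_period: int, period: float,
                 manifest_hash: str = "", seed: int = 0, solver_config: dict | None = None,
                 mode: str = "w"):
        self._fh = h5py.File(path, mode)
        n = n_samples_per_period
        if "waveforms" not in self._fh:
            self._fh.create_dataset(
                "waveforms", shape=(0, 2, 2, n), maxshape=(None, 2, 2, n),
                chunks=(64, 2, 2, n), dtype="f8",
            )
            self._fh.create_dataset("labels", shape=(0,), maxshape=(None,), dtype="f8")
            self._fh.create_dataset("patient_idx", shape=(0,), maxshape=(None,), dtype="i8")
            self._fh.create_dataset("replicate", shape=(0,), maxshape=(None,), dtype="i8")
            self._fh.create_dataset(
                "patient_ids", shape=(0,), maxshape=(None,),
                dtype=h5py.string_dtype(),
            )
            self._fh.attrs["period"] = period
            self._fh.attrs["manifest_hash"] = manifest_hash
            self._fh.attrs["seed"] = seed
            self._fh.attrs["solver_config"] = json.dumps(solver_config or {})
        self._pid_index: dict[str, int] = {
            pid.decode() if isinstance(pid, bytes) else str(pid): i
            for i, pid in enumerate(self._fh["patient_ids"][:])
        }

    def append(self, record: WaveformRecord) -> None:
        arr = record.stacked()[None, ...]
        pid = str(record.meta.get("patient_id", ""))
        rep = int(record.meta.get("replicate", 0))
        if pid not in self._pid_index:
            ds = self._fh["patient_ids"]
            ds.resize((ds.shape[0] + 1,))
            ds[-1] = pid
            self._pid_index[pid] = ds.shape[0] - 1
        for name, value in (
            ("waveforms", arr),
            ("labels", np.array([record.severity])),
            ("patient_idx", np.array([self._pid_index[pid]])),
            ("replicate", np.array([rep])),
        ):
            ds = self._fh[name]
            ds.resize((ds.shape[0] + 1,) + ds.shape[1:])
            ds[-1] = value[0] if name == "waveforms" else value[0]

    def close(self) -> None:
        self._fh.attrs["label_hash"] = _label_hash(self._fh["labels"][:])
        self._fh.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()


@dataclass
class Dataset:
    """In-memory view of a verified waveform dataset."""

    waveforms: np.ndarray  # (n, 2, 2, N)
    labels: np.ndarray
    patient_ids: np.ndarray  # (n,) str
    replicate: np.ndarray
    period: float
    manifest_hash: str
    seed: int

    def __len__(self) -> int:
        return self.labels.size

    def brachial_bp(self) -> np.ndarray:
        return self.waveforms[:, 0, 0, :]

    def ankle_bp(self) -> np.ndarray:
        return self.waveforms[:, 1, 0, :]

    def select(self, mask: np.ndarray) -> "Dataset":
        return Dataset(
            self.waveforms[mask], self.labels[mask], self.patient_ids[mask],
            self.replicate[mask], self.period, self.manifest_hash, self.seed,
        )

    def for_patients(self, patient_ids) -> "Dataset":
        wanted = set(patient_ids)
        return self.select(np.array([p in wanted for p in self.patient_ids]))


def write_dataset(records, path, period: float | None = None,
                  manifest_hash: str = "", seed: int = 0,
                  solver_config: dict | None = None) -> int:
    """Write an iterable of WaveformRecords; returns the number written."""
    n_written = 0
    writer = None
    try:
        for rec in records:
            if writer is None:
                writer = DatasetWriter(
                    path, rec.brachial_bp.size, period if period is not None else rec.period,
                    manifest_hash, seed, solver_config,
                )
            writer.append(rec)
            n_written += 1
    finally:
        if writer is not None:
            writer.close()
    if n_written == 0:
        raise ValueError("no records to write")
    return n_written


def read_dataset(path, severity_range: tuple[float, float] | None = None,
                 verify: bool = True) -> Dataset:
    """Load a dataset, verify its integrity hash, optionally filter by severity."""
    with h5py.File(path, "r") as fh:
        labels = fh["labels"][:]
        if verify:
            stored = fh.attrs.get("label_hash", "")
            if stored and stored != _label_hash(labels):
                raise IOError(f"integrity check failed for {path}: label hash mismatch")
        pid_table = np.array(
            [p.decode() if isinstance(p, bytes) else str(p) for p in fh["patient_ids"][:]]
        )
        ds = Dataset(
            waveforms=fh["waveforms"][:],
            labels=labels,
            patient_ids=pid_table[fh["patient_idx"][:]] if labels.size else np.array([]),
            replicate=fh["replicate"][:],
            period=float(fh.attrs["period"]),
            manifest_hash=str(fh.attrs.get("manifest_hash", "")),
            seed=int(fh.attrs.get("seed", 0)),
        )
    if severity_range is not None:
        lo, hi = severity_range
        ds = ds.select((ds.labels >= lo) & (ds.labels <= hi))
    return ds


def iter_dataset(path, batch_size: int = 256):
    """Stream (waveforms, labels) batches without loading the full file."""
    with h5py.File(path, "r") as fh:
        n = fh["labels"].shape[0]
        for start in range(0, n, batch_size):
            sl = slice(start, min(start + batch_size, n))
            yield fh["waveforms"][sl], fh["labels"][sl]
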