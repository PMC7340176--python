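"""Virtual-patient cohort enumeration and replicate sampling.

Three layers of variability define a cohort:

* inter-individual — five anatomical/physiological parameters (segment
  length, diameter, wall thickness, elasticity, peripheral resistance)
  varied +/-20% around nominal in 10% steps: a 5^5 = 3125-point grid;
* disease severity — fractional area occlusion of the abdominal aorta,
  0-80% in 10% steps for the train/validation bases and 1% steps for the
  test basis;
* intra-individual — per-sample log-normal perturbation of the five
  parameters around the patient-specific values with CV = 0.01.

Patients are enumerated deterministically; replicate draws use independent
counter-keyed RNG streams so any sample can be regenerated in isolation.
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .arterial_tree import (
    ArterialTree,
    PatientScale,
    apply_stenosis,
    check_severity,
    scale_tree,
)
from . import tl_solver

__all__ = [
    "GRID_LEVELS",
    "VirtualPatient",
    "CohortManifest",
    "ReplicateSample",
    "enumerate_inter_individual_grid",
    "build_basis",
    "sample_replicates",
    "manifest_counts",
    "generate_dataset",
    "train_severities",
    "test_severities",
    "mini_manifests",
    "full_manifests",
]

#: the five inter-individual levels: +/-20% in 10% increments
GRID_LEVELS = (0.8, 0.9, 1.0, 1.1, 1.2)

#: intra-individual coefficient of variation
DEFAULT_CV = 0.01


@dataclass(frozen=True)
class VirtualPatient:
    patient_id: str
    scale: PatientScale
    severity: float


@dataclass
class CohortManifest:
    """Deterministic description of one dataset split."""

    patients: list[VirtualPatient]
    replicates_per_patient: int
    cv: float = DEFAULT_CV
    seed: int = 0
    role: str = "train"

    def __post_init__(self):
        if self.replicates_per_patient < 1:
            raise ValueError("replicates_per_patient must be >= 1")
        if self.cv < 0:
            raise ValueError("cv must be non-negative")
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            raise ValueError("patient ids must be unique within a manifest")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.patients:
            row = {"patient_id": p.patient_id, "severity": p.severity, "role": self.role}
            row.update({f"scale_{k}": v for k, v in p.scale.as_dict().items()})
            rows.append(row)
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, replicates_per_patient: int, cv: float = DEFAULT_CV, seed: int = 0
    ) -> "CohortManifest":
        patients = [
            VirtualPatient(
                patient_id=str(r.patient_id),
                scale=PatientScale(
                    **{k: getattr(r, f"scale_{k}") for k in PatientScale.PARAMS}
                ),
                severity=float(r.severity),
            )
            for r in df.itertuples(index=False)
        ]
        role = str(df["role"].iloc[0]) if len(df) else "train"
        return cls(patients, replicates_per_patient, cv, seed, role)

    def content_hash(self) -> str:
        h = hashlib.sha256()
        for p in self.patients:
            h.update(p.patient_id.encode())
            h.update(np.asarray(list(p.scale.as_dict().values()) + [p.severity]).tobytes())
        h.update(str((self.replicates_per_patient, self.cv, self.seed, self.role)).encode())
        return h.hexdigest()[:16]


@dataclass(frozen=True)
class ReplicateSample:
    patient_id: str
    replicate: int
    severity: float
    factors: PatientScale  # log-normally perturbed five-parameter vector


def enumerate_inter_individual_grid(
    levels=GRID_LEVELS, params=PatientScale.PARAMS
) -> list[PatientScale]:
    """Full Cartesian product of the grid levels over the varied parameters.

    Order is fixed: parameters lexicographic, levels ascending, last
    parameter fastest (itertools.product order).
    """
    out = []
    for combo in itertools.product(*([sorted(levels)] * len(params))):
        out.append(PatientScale(**dict(zip(params, combo))))
    return out


def train_severities() -> np.ndarray:
    """0-80% area occlusion in 10% steps (train/validation basis)."""
    return np.round(np.arange(0.0, 0.81, 0.1), 10)


def test_severities() -> np.ndarray:
    """0-80% area occlusion in 1% steps (test basis)."""
    return np.round(np.arange(0.0, 0.801, 0.01), 10)


def build_basis(
    grid: list[PatientScale], severities
) -> list[VirtualPatient]:
    """Cross product of anatomical grid and severity grid with stable ids."""
    severities = [check_severity(float(s)) for s in severities]
    for s in severities:
        if s > 0.8 + 1e-12:
            raise ValueError(f"severity {s} above the 0.8 study maximum")
    out = []
    for gi, scale in enumerate(grid):
        for s in severities:
            out.append(
                VirtualPatient(
                    patient_id=f"g{gi:05d}_s{round(s * 100):03d}",
                    scale=scale,
                    severity=s,
                )
            )
    return out


def _replicate_rng(seed: int, patient_id: str, replicate: int) -> np.random.Generator:
    """Counter-based stream: independent, reproducible per (patient, replicate)."""
    key = hashlib.sha256(f"{seed}|{patient_id}|{replicate}".encode()).digest()
    return np.random.default_rng(int.from_bytes(key[:8], "little"))


def _lognormal_factors(
    rng: np.random.Generator, means: np.ndarray, cv: float
) -> np.ndarray:
    """Log-normal draws with the given means and coefficient of variation.

    sigma^2 = ln(1 + cv^2), mu = ln(mean) - sigma^2 / 2, so E[X] = mean and
    sd[X]/E[X] = cv exactly.
    """
    if cv == 0:
        return means.copy()
    sigma2 = np.log1p(cv * cv)
    mu = np.log(means) - sigma2 / 2.0
    return np.exp(rng.normal(mu, np.sqrt(sigma2)))


def sample_replicates(manifest: CohortManifest):
    """Yield every ReplicateSample of the manifest in deterministic order."""
    for patient in manifest.patients:
        means = np.array([getattr(patient.scale, p) for p in PatientScale.PARAMS])
        for rep in range(manifest.replicates_per_patient):
            rng = _replicate_rng(manifest.seed, patient.patient_id, rep)
            draws = _lognormal_factors(rng, means, manifest.cv)
            yield ReplicateSample(
                patient_id=patient.patient_id,
                replicate=rep,
                severity=patient.severity,
                factors=PatientScale(**dict(zip(PatientScale.PARAMS, draws))),
            )


def manifest_counts(manifest: CohortManifest) -> dict[str, int]:
    """Patient and waveform-sample counts, without simulating anything."""
    n_patients = len(manifest.patients)
    return {
        "n_patients": n_patients,
        "n_samples": n_patients * manifest.replicates_per_patient,
    }


def generate_dataset(
    manifest: CohortManifest,
    tree: ArterialTree,
    stenosis_site: str = "abdominal_aorta",
    solver_config: dict | None = None,
    limit: int | None = None,
    max_failure_fraction: float = 0.01,
):
    """Simulate every replicate sample of a manifest.

    Yields (ReplicateSample, WaveformRecord) pairs in manifest order so
    callers can stream records to disk.  Individual solver failures are
    recorded and skipped; more than ``max_failure_fraction`` of failures
    aborts the run.
    """
    cfg = dict(solver_config or {})
    n_total = manifest_counts(manifest)["n_samples"] if limit is None else limit
    failures: list[tuple[str, int, str]] = []
    produced = 0
    for sample in sample_replicates(manifest):
        if limit is not None and produced >= limit:
            return
        try:
            patient_tree = scale_tree(tree, sample.factors)
            patient_tree = apply_stenosis(patient_tree, stenosis_site, sample.severity)
            rec = tl_solver.simulate_patient(
                patient_tree,
                severity=sample.severity,
                meta={"patient_id": sample.patient_id, "replicate": sample.replicate},
                **cfg,
            )
        except Exception as exc:  # noqa: BLE001 - per-sample failures are data
            failures.append((sample.patient_id, sample.replicate, str(exc)))
            if len(failures) > max_failure_fraction * max(n_total, 1):
                raise RuntimeError(
                    f"{len(failures)} solver failures out of {produced + len(failures)} "
                    f"samples (> {max_failure_fraction:.0%}); first: {failures[0]}"
                ) from exc
            continue
        produced += 1
        yield sample, rec


# ---------------------------------------------------------------------------
# presets

def full_manifests(seed: int = 0) -> dict[str, CohortManifest]:
    """The full-scale study design: 3125-patient grid, 100/10/10 replicates."""
    grid = enumerate_inter_individual_grid()
    train_basis = build_basis(grid, train_severities())
    test_basis = build_basis(grid, test_severities())
    return {
        "train": CohortManifest(train_basis, 100, DEFAULT_CV, seed * 3 + 0, "train"),
        "validation": CohortManifest(train_basis, 10, DEFAULT_CV, seed * 3 + 1, "validation"),
        "test": CohortManifest(test_basis, 10, DEFAULT_CV, seed * 3 + 2, "test"),
    }


def mini_manifests(seed: int = 0) -> dict[str, CohortManifest]:
    """Desk-scale preset: 3^3 grid over diameter/elasticity/peripheral
    resistance, the same severity grids, 3 train / 1 validation / 3 test
    replicates per patient."""
    levels = (0.8, 1.0, 1.2)
    grid = []
    for combo in itertools.product(levels, levels, levels):
        grid.append(
            PatientScale(
                diameter=combo[0], elasticity=combo[1], peripheral_resistance=combo[2]
            )
        )
    train_basis = build_basis(grid, train_severities())
    test_basis = build_basis(grid, test_severities())
    return {
        "train": CohortManifest(train_basis, 3, DEFAULT_CV, seed * 3 + 0, "train"),
        "validation": CohortManifest(train_basis, 1, DEFAULT_CV, seed * 3 + 1, "validation"),
        "test": CohortManifest(test_basis, 3, DEFAULT_CV, seed * 3 + 2, "test"),
    }
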