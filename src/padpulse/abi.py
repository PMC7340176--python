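"""Ankle-brachial index (ABI) and its polynomial calibration to severity.

ABI is the ratio of ankle to brachial systolic blood pressure; values near
1.1 are healthy and values below ~0.9 indicate peripheral obstruction.  To
use ABI as a severity *estimator* it is pre-calibrated on the nominal
virtual patient: the nominal tree is swept over a severity grid, ABI is
computed at each severity, and severity is least-squares fitted as a
polynomial in ABI.  Because ABI stays flat until roughly half-occlusion and
only then falls, the raw polynomial can wiggle; the prediction is therefore
projected onto the nearest non-increasing function of ABI before use.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.isotonic import IsotonicRegression

from .arterial_tree import ArterialTree, apply_stenosis
from .morphology import systolic_peak
from . import tl_solver

__all__ = ["AbiCalibration", "compute_abi", "calibrate", "abi_predict_severity"]

SEVERITY_MAX = 0.8


def compute_abi(brachial_bp: np.ndarray, ankle_bp: np.ndarray) -> float:
    """Systolic ankle / systolic brachial pressure ratio.

    Systolic values are the global maxima of the single-period series (the
    simulation is periodic, so no beat detection is involved).
    """
    brachial_bp = np.asarray(brachial_bp, dtype=float)
    ankle_bp = np.asarray(ankle_bp, dtype=float)
    for name, x in (("brachial", brachial_bp), ("ankle", ankle_bp)):
        if np.ptp(x) == 0:
            raise ValueError(f"{name} waveform is constant")
    sys_b = systolic_peak(brachial_bp)
    if sys_b <= 0:
        raise ValueError(f"non-positive brachial systolic pressure {sys_b}")
    return systolic_peak(ankle_bp) / sys_b


@dataclass
class AbiCalibration:
    """Polynomial map from ABI to severity, with a monotone projection.

    ``coefficients`` are highest-degree-first (numpy.polyval order) for the
    fit severity = P(abi).  Predictions are evaluated on a dense grid over
    the fit domain, projected to be non-increasing in ABI, clipped to
    [0, SEVERITY_MAX], and interpolated.
    """

    coefficients: np.ndarray
    degree: int
    abi_min: float
    abi_max: float
    provenance: dict = field(default_factory=dict)
    _grid_abi: np.ndarray = field(default=None, repr=False)
    _grid_sev: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.degree < 1:
            raise ValueError("polynomial degree must be >= 1")
        grid = np.linspace(self.abi_min, self.abi_max, 512)
        raw = np.polyval(self.coefficients, grid)
        iso = IsotonicRegression(increasing=False)
        mono = iso.fit_transform(grid, raw)
        self._grid_abi = grid
        self._grid_sev = np.clip(mono, 0.0, SEVERITY_MAX)

    def predict(self, abi) -> np.ndarray:
        """Severity estimate, non-increasing in ABI, clipped to [0, 0.8].

        Out-of-domain ABI values are clipped to the fit domain edge.
        """
        abi = np.clip(np.asarray(abi, dtype=float), self.abi_min, self.abi_max)
        return np.interp(abi, self._grid_abi, self._grid_sev)

    def to_json(self) -> str:
        return json.dumps(
            dict(
                coefficients=self.coefficients.tolist(),
                degree=self.degree,
                abi_min=self.abi_min,
                abi_max=self.abi_max,
                provenance=self.provenance,
            )
        )

    @classmethod
    def from_json(cls, text: str) -> "AbiCalibration":
        d = json.loads(text)
        return cls(
            np.asarray(d["coefficients"]), d["degree"], d["abi_min"], d["abi_max"],
            d.get("provenance", {}),
        )


def calibrate(
    tree: ArterialTree,
    severities=None,
    degree: int = 3,
    solver_config: dict | None = None,
    stenosis_site: str = "abdominal_aorta",
) -> AbiCalibration:
    """Fit severity = P(ABI) on the nominal patient (no intra-individual noise).

    The nominal tree is swept over the severity grid, ABI computed per
    severity, and the polynomial fitted by least squares.
    """
    if severities is None:
        severities = np.round(np.arange(0.0, 0.801, 0.05), 10)
    severities = np.asarray(severities, dtype=float)
    if severities.size < degree + 1:
        raise ValueError(
            f"degree-{degree} fit needs at least {degree + 1} severities, "
            f"got {severities.size}"
        )
    cfg = dict(solver_config or {})
    abis = []
    for s in severities:
        rec = tl_solver.simulate_patient(
            apply_stenosis(tree, stenosis_site, float(s)), severity=float(s), **cfg
        )
        abis.append(compute_abi(rec.brachial_bp, rec.ankle_bp))
    abis = np.asarray(abis)
    if np.ptp(abis) < 1e-12:
        raise ValueError("ABI is constant over the severity grid; fit is degenerate")
    coeffs = np.polyfit(abis, severities, degree)
    return AbiCalibration(
        coefficients=coeffs,
        degree=degree,
        abi_min=float(abis.min()),
        abi_max=float(abis.max()),
        provenance=dict(
            severities=severities.tolist(),
            abi=abis.tolist(),
            solver_config=cfg,
            stenosis_site=stenosis_site,
        ),
    )


def abi_predict_severity(cal: AbiCalibration, abi) -> np.ndarray:
    """Map ABI value(s) to severity through the fitted monotone calibration."""
    return cal.predict(abi)
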