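"""Pulse-waveform morphology features.

All series are one uniformly sampled cardiac period, treated as cyclic.
The features here are the ones whose severity trends characterise a
stenosis distal waveform: pulse amplitude, crest time (diastolic trough to
systolic peak) and pulse width at half amplitude.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "pulse_amplitude",
    "systolic_peak",
    "diastolic_trough",
    "crest_time",
    "half_amplitude_width",
]


def systolic_peak(x: np.ndarray) -> float:
    """Systolic value: the global maximum of the single-period series."""
    return float(np.max(x))


def diastolic_trough(x: np.ndarray) -> float:
    """Diastolic value: the global minimum of the single-period series."""
    return float(np.min(x))


def pulse_amplitude(x: np.ndarray) -> float:
    """Systolic minus diastolic value (pulse pressure for a BP series)."""
    return float(np.max(x) - np.min(x))


def _foot_index(x: np.ndarray, i_peak: int) -> int:
    """Index of the diastolic trough preceding the systolic upstroke.

    Walks backwards (cyclically) from the systolic peak until the series
    stops decreasing, i.e. the first local minimum before the upstroke.
    This is robust against secondary oscillations elsewhere in the cycle.
    """
    n = x.size
    i = i_peak
    for _ in range(n):
        j = (i - 1) % n
        if x[j] >= x[i]:
            break
        i = j
    return i


def crest_time(x: np.ndarray, period: float) -> float:
    """Interval from the diastolic trough to the systolic peak (seconds).

    The trough is the local minimum found walking back from the global
    maximum, so the measure tracks the upstroke duration even when the
    cycle contains secondary minima.
    """
    n = x.size
    i_peak = int(np.argmax(x))
    i_foot = _foot_index(x, i_peak)
    return ((i_peak - i_foot) % n) * period / n


def half_amplitude_width(x: np.ndarray, period: float) -> float:
    """Total time the series spends at or above half amplitude (seconds)."""
    half = 0.5 * (np.max(x) + np.min(x))
    return int(np.count_nonzero(x >= half)) * period / x.size
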