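"""Simulate brachial and ankle pulse waveforms across PAD severities.

Loads the built-in 55-segment arterial tree, inserts a graded abdominal
aortic stenosis, runs the transmission-line solver, and prints the
morphology features that change with disease severity.
"""

import numpy as np

from padpulse import apply_stenosis, load_default_tree, simulate_patient
from padpulse.morphology import crest_time, half_amplitude_width, pulse_amplitude

tree = load_default_tree()
print(f"arterial tree: {len(tree.segments)} segments, "
      f"{len(tree.terminal_load)} terminal loads")
print(f"{'severity':>8} {'brachial':>12} {'ankle':>12} {'ABI':>6} "
      f"{'crest(s)':>9} {'width(s)':>9}")

for s in np.arange(0.0, 0.81, 0.2):
    rec = simulate_patient(apply_stenosis(tree, "abdominal_aorta", s))
    abi = rec.ankle_bp.max() / rec.brachial_bp.max()
    print(
        f"{s:8.1f} "
        f"{rec.brachial_bp.max():5.1f}/{rec.brachial_bp.min():5.1f} "
        f"{rec.ankle_bp.max():5.1f}/{rec.ankle_bp.min():5.1f} "
        f"{abi:6.3f} {crest_time(rec.ankle_bp, rec.period):9.3f} "
        f"{half_amplitude_width(rec.ankle_bp, rec.period):9.3f}"
    )

print(
    "\nAs the abdominal aortic lumen closes, the ankle pulse flattens and"
    "\nbroadens (amplitude falls, crest time and half-amplitude width grow)"
    "\nwhile the brachial pulse grows from the reflected wave; their"
    "\nsystolic ratio (the ankle-brachial index) falls below the ~0.9"
    "\nclinical PAD cutoff only once the occlusion is severe."
)
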