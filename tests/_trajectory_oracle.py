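"""Rule-based call-class oracle, independent of the generator internals.

Classifies a trajectory purely from its shape: component count and ratio,
silent gaps, voiced duration, discontinuity count, monotonicity and
direction changes — mirroring how the call taxonomy is defined.
"""

from __future__ import annotations

import numpy as np

FLAT_TOL = 3_000.0
SHORT_MAX_S = 0.005
STEP_MIN_JUMP = 10_000.0
SWEEP_MIN_RANGE = 12_500.0


def classify_trajectory(traj, duration_s: float) -> str:
    """Return the call-class name implied by a noiseless trajectory."""
    freqs = np.asarray(traj.frequencies, dtype=float)
    voiced = np.asarray(traj.voiced, dtype=bool)
    n_frames = freqs.shape[1]

    if freqs.shape[0] == 2:
        ratio = freqs[1] / freqs[0]
        if np.allclose(ratio, 2.0, rtol=0.01):
            return "harmonics"
        return "composite"

    # voiced runs
    edges = np.flatnonzero(np.diff(np.r_[0, voiced.view(np.int8), 0]))
    runs = list(zip(edges[::2], edges[1::2]))
    if len(runs) == 2:
        return "two_syllable"

    voiced_s = duration_s * voiced.sum() / n_frames
    if voiced_s <= SHORT_MAX_S:
        return "short"

    f = freqs[0][voiced]
    d = np.diff(f)
    if np.any(np.abs(d) >= STEP_MIN_JUMP):
        return "frequency_steps"
    if f.max() - f.min() <= FLAT_TOL:
        return "flat"

    net = f[-1] - f[0]
    if np.all(d >= 0) and net >= SWEEP_MIN_RANGE:
        return "upward"
    if np.all(d <= 0) and -net >= SWEEP_MIN_RANGE:
        return "downward"

    signs = np.sign(d[np.abs(d) > 1e-9])
    changes = int(np.sum(signs[1:] != signs[:-1]))
    if changes == 1 and signs[0] > 0:
        return "chevron"
    if changes >= 2:
        return "complex"
    raise ValueError("trajectory matches no class rule")
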