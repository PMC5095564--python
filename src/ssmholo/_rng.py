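"""Counter-based substream seeding.

A single user-facing seed is expanded into independent per-stage random
streams through ``numpy.random.SeedSequence`` spawn keys, so that e.g. the
transmission-matrix draw and the detector-noise draw of one experiment are
reproducible in isolation: re-running only one stage with the same seed
gives the same numbers regardless of what other stages consumed.
"""

from __future__ import annotations

import numpy as np

# stage identifiers (arbitrary but fixed small integers)
STAGE_TM = 1
STAGE_INCIDENT = 2
STAGE_INTENSITY_NOISE = 3
STAGE_TM_NOISE = 4
STAGE_MOMENT = 5
STAGE_CALIBRATION_NOISE = 6
STAGE_SWEEP = 7
STAGE_PHANTOM = 8
STAGE_COMPOUND = 9


def substream(seed: int | None, *key: int) -> np.random.Generator:
    """Return an independent Generator for ``(seed, key...)``.

    ``seed=None`` delegates to OS entropy (non-reproducible).
    """
    if seed is None:
        return np.random.default_rng()
    ss = np.random.SeedSequence(int(seed), spawn_key=tuple(int(k) for k in key))
    return np.random.default_rng(ss)
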