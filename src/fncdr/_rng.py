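"""Named random substreams.

Every stochastic component of the pipeline draws from its own substream of a
single user seed, so that e.g. recalibrating outcome intercepts does not
perturb the covariate draws of the same cohort (common random numbers).
"""

from __future__ import annotations

import numpy as np

# Fixed registry: a stream's index must never change, or seeded runs would
# silently lose reproducibility across versions.
_STREAMS = {
    "covariates": 0,
    "random_effects": 1,
    "outcome_uniforms": 2,
    "episode_counts": 3,
    "calibration": 4,
    "cv_folds": 5,
    "forward_guard": 6,
    "replication": 7,
}


def substream(seed: int, name: str, index: int = 0) -> np.random.Generator:
    """Return a Generator for the named substream of ``seed``.

    ``index`` distinguishes repeated uses of the same stream (e.g. one per
    Monte-Carlo replication).
    """
    try:
        key = _STREAMS[name]
    except KeyError:
        raise KeyError(f"unknown substream {name!r}; known: {sorted(_STREAMS)}")
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(key, int(index)))
    return np.random.Generator(np.random.PCG64(ss))
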