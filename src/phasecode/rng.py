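"""Named, reproducible random-number streams.

A single master seed deterministically spawns one independent child stream
per stochastic component (LFP noise, stimulus profile, spike thinning,
background noise, bin shuffles, epoch sampling, codebook jitter, classifier
regularization).  Any component can therefore be re-drawn in isolation
without touching the others, and a whole experiment is bit-reproducible
from ``(config, seed)``.
"""

from __future__ import annotations

import numpy as np

#: Fixed registry of stream names; the index of a name is its spawn key, so
#: adding new names at the end never perturbs existing streams.
STREAM_NAMES = (
    "lfp",
    "profile",
    "spikes",
    "noise",
    "shuffles",
    "epochs",
    "jitter",
    "classifier",
)


def stream(seed: int, name: str) -> np.random.Generator:
    """Return the named child generator of ``seed``."""
    try:
        key = STREAM_NAMES.index(name)
    except ValueError:
        raise ValueError(f"unknown stream name {name!r}; expected one of {STREAM_NAMES}")
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(key,))
    return np.random.default_rng(ss)


def streams(seed: int) -> dict[str, np.random.Generator]:
    """All named child generators of ``seed`` as a dict."""
    return {name: stream(seed, name) for name in STREAM_NAMES}
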