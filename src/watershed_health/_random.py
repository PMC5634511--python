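"""Named random substreams derived from one root seed.

Every stage of the pipeline draws from its own independent stream so that,
e.g., regenerating the survey with a new root seed leaves the landscape
stream unchanged in structure, and each stage is reproducible in isolation.
"""

from __future__ import annotations

import numpy as np

# Stable stream identifiers; never renumber.
_STREAMS = {
    "landscape": 11,
    "clusters": 23,
    "displacement": 37,
    "climate": 41,
    "survey": 53,
}


def substream(seed: int, name: str) -> np.random.Generator:
    """Return the generator for the named stage under the given root seed."""
    if name not in _STREAMS:
        raise KeyError(f"unknown stream {name!r}; known: {sorted(_STREAMS)}")
    ss = np.random.SeedSequence([int(seed) % (2**31), _STREAMS[name]])
    return np.random.default_rng(ss)
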