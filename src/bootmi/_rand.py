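"""Random-stream plumbing shared across the package."""

from __future__ import annotations

import numpy as np

RandomState = "np.random.Generator | np.random.SeedSequence | int | None"


def as_generator(rng) -> np.random.Generator:
    """Coerce ``rng`` (Generator, SeedSequence, int seed or None) to a Generator.

    A Generator is passed through unchanged so that sequential calls share one
    stream; anything else seeds a fresh PCG64 stream.
    """
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)
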