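"""Named, independent random substreams derived from one master seed.

Each stochastic component of the automaton draws from its own generator so
that changing how one component consumes randomness does not shift the draws
seen by the others (which would silently change every regression trajectory).
"""

from __future__ import annotations

import numpy as np

STREAM_NAMES = ("ecm", "neighbourhood", "order", "movement", "tiebreak")


class RngStreams:
    """Independent named generators spawned from a single integer seed."""

    __slots__ = STREAM_NAMES + ("seed",)

    def __init__(self, seed: int):
        self.seed = int(seed)
        children = np.random.SeedSequence(self.seed).spawn(len(STREAM_NAMES))
        for name, child in zip(STREAM_NAMES, children):
            setattr(self, name, np.random.default_rng(child))

    def __repr__(self) -> str:  # pragma: no cover
        return f"RngStreams(seed={self.seed})"


def child_seeds(base_seed: int, n: int) -> np.ndarray:
    """Deterministic per-run integer seeds (< 2**31) for ensemble members."""
    state = np.random.SeedSequence(int(base_seed)).generate_state(n, dtype=np.uint32)
    return (state % np.uint32(2**31)).astype(np.int64)
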