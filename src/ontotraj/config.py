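"""Run configuration and deterministic random-stream management.

Every stochastic routine in the package draws from a child generator
derived from a single master seed and a routine-specific name, so results
are reproducible and independent of the order in which analyses run.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

DEFAULT_PERMUTATIONS = 10_000
DEFAULT_ALPHA = 0.05


@dataclass
class RunConfig:
    """Global settings shared by all analyses.

    Parameters
    ----------
    seed : int
        Master seed for all random streams.
    n_permutations : int
        Number of permutations for randomization tests (default 10,000).
    alpha : float
        Significance level, in (0, 1).
    size_transform : str
        Label for the size transform; natural log everywhere.
    output_dir : Path
        Where analysis drivers write their tables.
    """

    seed: int = 0
    n_permutations: int = DEFAULT_PERMUTATIONS
    alpha: float = DEFAULT_ALPHA
    size_transform: str = "ln"
    output_dir: Path = field(default_factory=lambda: Path("results"))

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        self.output_dir = Path(self.output_dir)

    def rng(self, name: str) -> np.random.Generator:
        """Child generator keyed by ``name``; order-independent."""
        return child_rng(self.seed, name)


def child_rng(seed: int, name: str) -> np.random.Generator:
    """Deterministic child stream derived from (seed, name).

    Uses a CRC32 of the name as a spawn key so streams for different
    routines are independent and do not depend on call order.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))
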