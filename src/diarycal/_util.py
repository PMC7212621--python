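"""Small shared helpers: seeding, link functions, validation errors."""

from __future__ import annotations

import zlib

import numpy as np

__all__ = [
    "ConfigurationError",
    "ValidationError",
    "EstimationError",
    "stage_seed",
    "sigmoid",
]


class ConfigurationError(ValueError):
    """A configuration field is missing or out of its legal range."""


class ValidationError(ValueError):
    """Input data violate a documented precondition."""


class EstimationError(RuntimeError):
    """A model fit cannot proceed (degenerate design, too few rows, ...)."""


def stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage seed from one pipeline seed.

    Stages get independent, reproducible streams: the stage name is hashed
    (CRC-32) and folded into the master seed. Result is always in
    [0, 2**31) so it is accepted by every RNG API we use.
    """
    return (int(seed) * 1_000_003 + zlib.crc32(stage.encode("utf-8"))) % (2**31)


def sigmoid(x):
    """Numerically safe logistic function."""
    x = np.clip(np.asarray(x, dtype=float), -500.0, 500.0)
    return 1.0 / (1.0 + np.exp(-x))
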