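"""Shared helpers: rounding, error hierarchy."""

from __future__ import annotations

import math


class MCDAError(Exception):
    """Base class for all package errors."""


class ValidationError(MCDAError, ValueError):
    """Input data violates a structural or range invariant."""


class ConfigurationError(MCDAError, ValueError):
    """A parameter is outside the supported configuration range."""


class NonConvergenceError(MCDAError, ArithmeticError):
    """An iterative numeric routine failed to converge."""


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, as printed tables conventionally do.

    Python's built-in ``round`` uses banker's rounding (7.705 -> 7.7 vs 7.71),
    which does not match how the reported tables are displayed.
    """
    if not math.isfinite(x):
        return x
    factor = 10.0**ndigits
    if x >= 0:
        return math.floor(x * factor + 0.5) / factor
    return -math.floor(-x * factor + 0.5) / factor


def fmt2(x: float) -> str:
    """Format a number at two decimals with half-up rounding."""
    return f"{round_half_up(x, 2):.2f}"
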