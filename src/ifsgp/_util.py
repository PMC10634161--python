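"""Shared helpers: error types and deterministic seed derivation."""

from __future__ import annotations

import numpy as np


class IfsgpError(Exception):
    """Base class for all package errors."""


class FormatError(IfsgpError, ValueError):
    """A file does not conform to the expected on-disk format."""


class ConsistencyError(IfsgpError, ValueError):
    """Companion files (or aligned containers) disagree about dimensions."""


class EmptyDataError(IfsgpError, ValueError):
    """A filtering or subsetting step removed all usable data."""


class UndefinedMetricError(IfsgpError, ValueError):
    """A requested metric is undefined for the given inputs (e.g. zero variance)."""


def derive_seed(*parts: int) -> int:
    """Derive a child seed from a master seed plus named-stage counters.

    Every randomized stage of the pipeline draws its seed from the master
    seed through this function, so the whole run is reproducible from a
    single integer while stages remain statistically independent.
    """
    entropy = [int(p) & 0xFFFFFFFF for p in parts]
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] % (2**31))
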