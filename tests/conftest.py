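"""Shared fixtures and brute-force oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest


def coverage_set(intervals, grid: int = 1) -> set[int]:
    """Integer-grid coverage oracle: the set of grid seconds inside any interval.

    Second ``t`` is covered iff some interval [s, e) contains it.  Used as an
    independent check of the sweep-based interval algebra.
    """
    out: set[int] = set()
    for iv in intervals:
        s, e = (iv.start_s, iv.end_s) if hasattr(iv, "start_s") else iv
        out.update(range(int(np.ceil(s)), int(np.ceil(e)), grid))
    return out


def random_interval_set(rng: np.random.Generator, span_s: float = 7200.0, max_n: int = 8):
    """Random disjoint-able integer interval list (may overlap before normalization)."""
    n = int(rng.integers(0, max_n + 1))
    out = []
    for _ in range(n):
        s = int(rng.integers(0, int(span_s) - 20))
        d = int(rng.integers(10, 400))
        out.append((float(s), float(min(s + d, span_s))))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
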