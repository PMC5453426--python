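"""Shared fixtures and independent reference implementations."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from histopatch.labels import CLASSES, PRIORITY


# ---------------------------------------------------------------------------
# brute-force fusion reference (kept deliberately independent of the package
# implementation: plain python, explicit priority scans)

_PRIO = list(PRIORITY)


def ref_argmax(vec):
    best = max(vec)
    candidates = [CLASSES[i] for i, v in enumerate(vec) if v == best]
    for cls in _PRIO:
        if cls in candidates:
            return cls
    raise AssertionError


def ref_majority(vectors):
    votes = [ref_argmax(v) for v in vectors]
    counts = {c: votes.count(c) for c in CLASSES}
    best = max(counts.values())
    for cls in _PRIO:
        if counts[cls] == best:
            return cls
    raise AssertionError


def ref_max(vectors):
    peak = max(max(v) for v in vectors)
    winners = set()
    for v in vectors:
        for i, x in enumerate(v):
            if x == peak:
                winners.add(CLASSES[i])
    for cls in _PRIO:
        if cls in winners:
            return cls
    raise AssertionError


def ref_sum(vectors):
    total = [sum(v[i] for v in vectors) for i in range(4)]
    return ref_argmax(total)


def probability_grid(step: float = 0.25):
    """All length-4 probability vectors on the given grid step."""
    n = round(1 / step)
    vectors = []
    for parts in itertools.product(range(n + 1), repeat=3):
        if sum(parts) <= n:
            rest = n - sum(parts)
            vectors.append(tuple(p * step for p in (*parts, rest)))
    return vectors


@pytest.fixture(scope="session")
def fusion_reference():
    return {"majority": ref_majority, "max": ref_max, "sum": ref_sum}


# ---------------------------------------------------------------------------


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def he_like_image():
    """A small two-stain synthetic image for stain-normalization tests."""
    from histopatch.synthetic_fixtures import default_class_suite, render_tissue_image

    spec = default_class_suite()["benign"]
    return render_tissue_image(spec, (192, 160), seed=5).pixels
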