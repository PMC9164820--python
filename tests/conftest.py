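"""Shared fixtures and small builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from mdrowse.io import ConditionAnnotation, Recording
from mdrowse.preprocess import EpochArray


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_recording(
    data: np.ndarray,
    rate: float = 250.0,
    labels: list[str] | None = None,
    annotations: list[tuple[str, float, float]] | None = None,
) -> Recording:
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if labels is None:
        labels = [f"C{i}" for i in range(data.shape[0])]
    anns = [ConditionAnnotation(lbl, s, e) for lbl, s, e in (annotations or [])]
    return Recording(data, rate, labels, anns)


def make_epochs(
    epochs: np.ndarray,
    rate: float = 250.0,
    labels: list[str] | None = None,
    condition: list[str] | None = None,
    flags: list[frozenset] | None = None,
) -> EpochArray:
    epochs = np.asarray(epochs, dtype=float)
    n_ep, n_ch, n_samp = epochs.shape
    if labels is None:
        labels = [f"C{i}" for i in range(n_ch)]
    return EpochArray(
        epochs,
        rate,
        n_samp / rate,
        np.arange(n_ep) * (n_samp / rate),
        condition or ["unassigned"] * n_ep,
        labels,
        flags or [],
    )
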