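"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from prorich import config as cfg

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

# blocks 3/4 carry rich+good, 6/7 poor+good unless stated otherwise
DEFAULT_PAIRING = {1: "single_task", 2: "single_task", 3: "rich_good",
                   4: "rich_good", 5: "single_task", 6: "poor_good",
                   7: "poor_good"}


def make_trials(
    latencies: dict[int, list[float]],
    errors: dict[int, list[int]] | None = None,
    pairing: dict[int, str] | None = None,
    participant_id: str = "p1",
) -> pd.DataFrame:
    """Build a one-participant trials table from per-block latency lists."""
    errors = errors or {}
    pairing = {**DEFAULT_PAIRING, **(pairing or {})}
    rows = []
    for block, lats in latencies.items():
        errs = errors.get(block, [0] * len(lats))
        assert len(errs) == len(lats)
        for idx, (lat, err) in enumerate(zip(lats, errs)):
            rows.append(
                {
                    "participant_id": participant_id,
                    "block": block,
                    "trial_index": idx,
                    "latency_ms": float(lat),
                    "error": int(err),
                    "pairing": pairing[block],
                    "order_condition": "congruent_first",
                    "attribute_set": 1,
                }
            )
    return pd.DataFrame(rows)


def full_block_trials(
    participant_id: str = "p1",
    base_latency: float = 800.0,
    fast: dict[int, int] | None = None,
    errors: dict[int, int] | None = None,
    slow: dict[int, int] | None = None,
) -> pd.DataFrame:
    """A complete 7-block trial set with per-block counts of fast (<300 ms),
    error, and slow (>10 s) trials injected from the start of each block."""
    fast, errors, slow = fast or {}, errors or {}, slow or {}
    lat_by_block = {}
    err_by_block = {}
    for block, n in cfg.BLOCK_SIZES.items():
        lats = [base_latency + 5 * i for i in range(n)]
        errs = [0] * n
        for i in range(fast.get(block, 0)):
            lats[i] = 250.0
        for i in range(slow.get(block, 0)):
            lats[n - 1 - i] = 12_000.0
        for i in range(errors.get(block, 0)):
            errs[i] = 1
        lat_by_block[block] = lats
        err_by_block[block] = errs
    return make_trials(lat_by_block, err_by_block, participant_id=participant_id)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def pilot_coefs():
    return dict(cfg.PILOT_COEFS)
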