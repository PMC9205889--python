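import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

import badgenet as bn


@pytest.fixture(scope="session")
def small_study():
    """One small simulated deployment with full movement coverage."""
    cfg = bn.SimConfig(
        n_orgs=3,
        org_sizes=(24, 24, 24),
        communities_per_org=3,
        n_days=5,
        seed=11,
        movement_mode="full",
    )
    return bn.simulate_study(cfg)


@pytest.fixture(scope="session")
def medium_features():
    """Feature table at moderate scale (no movement, faster)."""
    cfg = bn.SimConfig(
        n_orgs=4,
        org_sizes=(30, 30, 30, 30),
        n_days=5,
        seed=7,
        movement_mode="none",
    )
    return bn.simulate_study(cfg).features


def detections_from_minutes(minutes, u="A", v="B", org="O01"):
    """Build a symmetric detection frame from a set of dyad minutes."""
    rows = []
    for m in minutes:
        rows.append((org, u, v, m))
        rows.append((org, v, u, m))
    return pd.DataFrame(
        rows, columns=["org_id", "person_id", "counterpart_id", "minute"]
    )
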