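"""Shared fixtures: a hand-built rule-fidelity scene and a small simulation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from plaquemap import ExpressionMatrix, Plaque, RegionPolygon, SimulationConfig, simulate_dataset

GENES = [f"g{i:02d}" for i in range(1, 16)]

# count rows used by the hand-built scene
ROW_PASS = [10, 3, 3, 3, 3, 3, 3, 3, 3, 3, 3, 0, 0, 0, 0]  # total 40, 11 unique genes
ROW_39 = [9, 3, 3, 3, 3, 3, 3, 3, 3, 3, 3, 0, 0, 0, 0]  # total 39 -> fails transcripts
ROW_10_GENES = [31, 1, 1, 1, 1, 1, 1, 1, 1, 1, 0, 0, 0, 0, 0]  # total 40, 10 unique -> fails genes


@pytest.fixture(scope="session")
def rule_scene():
    """Twelve hand-placed cells and two square plaques with known outcomes.

    Plaque 1 spans (0..20)^2, plaque 2 spans x 60..80, y 0..20; the traced
    region is the rectangle (-10,-10)..(200,100).  Every proximity label,
    nearest-plaque id and QC-filter outcome below is hand-computed.
    """
    plaques = [
        Plaque.from_points(1, [(0, 0), (20, 0), (20, 20), (0, 20)]),
        Plaque.from_points(2, [(60, 0), (80, 0), (80, 20), (60, 20)]),
    ]
    region = RegionPolygon("cortex", np.array([(-10, -10), (200, -10), (200, 100), (-10, 100)]))
    rows = [
        # cell_id, x, y, volume, counts row
        ("c01", 10.0, 10.0, 150.0, ROW_PASS),   # inside plaque 1 -> d=0, associated
        ("c02", 35.0, 10.0, 150.0, ROW_PASS),   # d=15.0 exactly -> associated (inclusive)
        ("c03", 35.01, 10.0, 150.0, ROW_PASS),  # d=15.01 -> distal
        ("c04", 40.0, 10.0, 150.0, ROW_PASS),   # tie d=20 to both plaques -> plaque 1, distal
        ("c05", 25.0, 25.0, 150.0, ROW_PASS),   # nearest corner (20,20), d=sqrt(50), associated
        ("c06", 85.0, 10.0, 150.0, ROW_PASS),   # d=5 to plaque 2 -> associated
        ("c07", 300.0, 10.0, 150.0, ROW_PASS),  # outside region -> excluded from labels
        ("c08", 100.0, 50.0, 150.0, ROW_39),    # 39 transcripts -> removed
        ("c09", 100.0, 60.0, 150.0, ROW_PASS),  # 40 transcripts -> retained, distal
        ("c10", 100.0, 70.0, 99.99, ROW_PASS),  # volume 99.99 -> removed
        ("c11", 100.0, 80.0, 100.0, ROW_PASS),  # volume 100.0 -> retained, distal
        ("c12", 120.0, 50.0, 150.0, ROW_10_GENES),  # 10 unique genes -> removed
    ]
    cells = pd.DataFrame(
        {
            "cell_id": [r[0] for r in rows],
            "x_um": [r[1] for r in rows],
            "y_um": [r[2] for r in rows],
            "volume_um3": [r[3] for r in rows],
            "sample_id": "s1",
        }
    )
    counts = ExpressionMatrix(
        pd.DataFrame([r[4] for r in rows], index=pd.Index(cells["cell_id"]), columns=GENES)
    )
    expected = {
        "survivors": ["c01", "c02", "c03", "c04", "c05", "c06", "c07", "c09", "c11"],
        "fail_transcripts": ["c08"],
        "fail_volume": ["c10"],
        "fail_genes": ["c12"],
        "labels": {
            "c01": "plaque_associated",
            "c02": "plaque_associated",
            "c03": "distal",
            "c04": "distal",
            "c05": "plaque_associated",
            "c06": "plaque_associated",
            "c09": "distal",
            "c11": "distal",
        },
        "nearest": {"c01": 1, "c02": 1, "c03": 1, "c04": 1, "c05": 1, "c06": 2},
        "distances": {"c01": 0.0, "c02": 15.0, "c03": 15.01, "c04": 20.0, "c05": np.sqrt(50.0), "c06": 5.0},
        "out_of_region": ["c07"],
        "per_plaque_counts": {1: 3, 2: 1},
        "n_distal": 4,
        "region_area": 210.0 * 110.0,
        "plaque_area_total": 800.0,
    }
    return {"plaques": plaques, "region": region, "cells": cells, "counts": counts, "expected": expected}


@pytest.fixture(scope="session")
def small_dataset():
    """A modest simulated dataset shared across read-only unit tests."""
    cfg = SimulationConfig(seed=0, n_cells=600, n_genes=100, n_plaques=10, region=(0, 0, 600, 600))
    return simulate_dataset(cfg)
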