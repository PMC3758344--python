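"""Shared fixtures: hand-built toy experiments and one default synthetic run."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from kinarray import ArrayExperiment, SimulationConfig, generate
from kinarray.array_io import ANNOTATION_COLUMNS, MEASUREMENT_COLUMNS


def make_annotations(sample_ids, braf=None, tissue=None) -> pd.DataFrame:
    rows = []
    for i, sid in enumerate(sample_ids):
        rows.append(
            dict(
                sample_id=sid,
                tissue=(tissue or {}).get(sid, "melanoma"),
                braf=(braf or {}).get(sid, "wild_type"),
                nras="wild_type",
                cdkn2a="unknown",
                tp53="unknown",
                dtic_response="unknown",
                age=str(60 + i),
                sex="",
                stage="IV",
                site="",
            )
        )
    return pd.DataFrame(rows)[ANNOTATION_COLUMNS]


def make_experiment(records, panel=None) -> ArrayExperiment:
    """Build an experiment from (sample, peptide, chip, array, series,
    replicate, inhibitor, signal, background) tuples."""
    meas = pd.DataFrame(records, columns=MEASUREMENT_COLUMNS)
    ann = make_annotations(sorted(set(meas["sample_id"])))
    return ArrayExperiment(meas, ann, panel or [])


@pytest.fixture
def toy_experiment() -> ArrayExperiment:
    """2 samples x 3 peptides x 2 replicates x 2 conditions, one chip per
    sample; linear signals are exact powers of two for easy hand checks."""
    records = []
    for s in ("A", "B"):
        for j, pep in enumerate(("P1", "P2", "P3")):
            for r in (1, 2):
                base = 2.0 ** (4 + j)
                records.append((s, pep, f"chip{s}", 1, "S1", r, "none", base + 10.0, 10.0))
                records.append(
                    (s, pep, f"chip{s}", 2, "S1", r, "vemurafenib", base / 2 + 10.0, 10.0)
                )
    return make_experiment(records, panel=["P1", "P2", "P3"])


@pytest.fixture(scope="session")
def default_run():
    """One default-config synthetic experiment (seed 1) with its truth."""
    return generate(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20130830)
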