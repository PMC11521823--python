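"""Shared fixtures: small synthetic cohorts and hand-built toy objects."""

import logging

import numpy as np
import pandas as pd
import pytest

import pairedomics as po

logging.disable(logging.INFO)


def make_sheet(n=12, sample_type="plasma", batches=None, dropouts=0):
    """Sample sheet with n paired participants (plus optional BT-only
    dropouts) of one sample type."""
    rows = []
    for i in range(n):
        pid = f"P{i + 1:02d}"
        for tp in ("BT", "AT"):
            rows.append({"sample_id": f"{pid}_{tp}", "participant_id": pid,
                         "timepoint": tp, "sample_type": sample_type,
                         "batch": "1"})
    for i in range(dropouts):
        pid = f"D{i + 1:02d}"
        rows.append({"sample_id": f"{pid}_BT", "participant_id": pid,
                     "timepoint": "BT", "sample_type": sample_type,
                     "batch": "1"})
    df = pd.DataFrame(rows)
    if batches is not None:
        df["batch"] = list(batches)
    return po.SampleSheet(df)


def make_block(values, feature_ids=None, sample_ids=None, meta=None):
    values = np.asarray(values, dtype=float)
    feature_ids = feature_ids or [f"f{i}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"s{i}" for i in range(values.shape[1])]
    vdf = pd.DataFrame(values, index=feature_ids, columns=sample_ids)
    mdf = meta if meta is not None else pd.DataFrame(index=vdf.index)
    return po.OmicsBlock(vdf, mdf)


def paired_block(bt, at, feature_ids=None, sample_type="plasma", meta=None):
    """Block + sheet + design from BT and AT matrices (features x
    participants, same participant order)."""
    bt = np.asarray(bt, float)
    at = np.asarray(at, float)
    n = bt.shape[1]
    sheet = make_sheet(n, sample_type)
    cols = [f"P{i + 1:02d}_BT" for i in range(n)] + \
           [f"P{i + 1:02d}_AT" for i in range(n)]
    block = make_block(np.concatenate([bt, at], axis=1),
                       feature_ids=feature_ids, sample_ids=cols, meta=meta)
    design = po.build_paired_design(sheet)
    return block, sheet, design


@pytest.fixture(scope="session")
def default_cohort():
    """One default-condition synthetic cohort, reused read-only."""
    cfg = po.SynthConfig(seed=11)
    blocks, sheet, participants, truth = po.generate_cohort(cfg)
    return {"config": cfg, "blocks": blocks, "sheet": sheet,
            "participants": participants, "truth": truth,
            "design": po.build_paired_design(sheet)}


@pytest.fixture(scope="session")
def clean_cohort():
    """Small cohort without batch effects or missingness, for stages that
    need complete data."""
    cfg = po.SynthConfig(seed=5,
                         n_features={"buccal": 30, "pbmc": 30, "plasma": 80},
                         n_planted={"buccal": 5, "pbmc": 5, "plasma": 10},
                         batch_shift=0.0, batch_scale=1.0,
                         mnar_censor_quantile=0.0, mcar_rate=0.0)
    blocks, sheet, participants, truth = po.generate_cohort(cfg)
    return {"config": cfg, "blocks": blocks, "sheet": sheet,
            "participants": participants, "truth": truth,
            "design": po.build_paired_design(sheet)}
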