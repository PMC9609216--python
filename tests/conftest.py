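"""Shared fixtures.

``world`` is the default synthetic study (40 sequences per group, all
planted signals at their default strengths) carried through featurization,
cleansing, weighting, dataset selection and the full organism-task model
sweep.  It is expensive (a few minutes) and session-scoped; acceptance
tests share it.
"""

from __future__ import annotations

from types import SimpleNamespace

import pytest

from nkaminer import (
    SimConfig,
    cleanse,
    featurize_all,
    make_all_datasets,
    run_sweep,
    simulate_dataset,
    weight_all,
)

WORLD_SEED = 1


@pytest.fixture(scope="session")
def world():
    cfg = SimConfig(seed=WORLD_SEED)
    records, reference, truth = simulate_dataset(cfg)
    table = featurize_all(records)
    fcd_org = cleanse(table).table
    vert = table.rows(table.labels["group"] == "vertebrate")
    fcd_iso = cleanse(vert).table
    weights_org = weight_all(fcd_org, "group")
    weights_iso = weight_all(fcd_iso, "isoform")
    datasets_org = make_all_datasets(fcd_org, "group", "organism_groups", weights_org)
    datasets_iso = make_all_datasets(fcd_iso, "isoform", "isoforms", weights_iso)
    sweep_org = run_sweep(datasets_org, "group", folds=10, seed=WORLD_SEED)
    return SimpleNamespace(
        sim_config=cfg,
        records=records,
        reference=reference,
        truth=truth,
        table=table,
        fcd_org=fcd_org,
        fcd_iso=fcd_iso,
        weights_org=weights_org,
        weights_iso=weights_iso,
        datasets_org=datasets_org,
        datasets_iso=datasets_iso,
        sweep_org=sweep_org,
    )
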