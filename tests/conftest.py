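"""Shared fixtures: simulated studies at two scales.

``small_study`` is a fast panel for unit-level checks; ``reference_run``
executes the full training workflow once per session on the reference
simulation (2,000 genes, 30 correlated drivers, 200 cell lines, a 10x100
split ensemble) and is shared by the end-to-end recovery tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import drugresp as dr


@pytest.fixture(scope="session")
def small_study():
    cfg = dr.SimulationConfig(
        n_genes=300, n_driver_genes=10, n_cell_lines=80, seed=7
    )
    expr, panel, truth = dr.simulate_panel(cfg)
    return {"cfg": cfg, "expr": expr, "panel": panel, "truth": truth}


@pytest.fixture(scope="session")
def reference_run():
    cfg = dr.SimulationConfig(seed=11)  # 2000 genes, 30 drivers, n=200
    expr, panel, truth = dr.simulate_panel(cfg)
    pathways = dr.PathwayCollection(dr.make_pathways(truth, seed=cfg.seed))
    pipe_cfg = dr.PipelineConfig(n_outer=10, n_inner=100, seed=cfg.seed)
    result = dr.run_train(expr, panel, pathways, pipe_cfg)
    return {
        "cfg": cfg,
        "pipe_cfg": pipe_cfg,
        "expr": expr,
        "panel": panel,
        "truth": truth,
        "pathways": pathways,
        "result": result,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
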