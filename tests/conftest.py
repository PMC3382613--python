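"""Shared fixtures: synthetic receptors, ligand templates, pipeline runs.

Heavy objects are session-scoped so the probe-coating and docking tests
share one receptor and the pipeline tests share one finished run.
"""

from __future__ import annotations

import numpy as np
import pytest

from vasite.pipeline import PipelineConfig, run_pipeline
from vasite.structure_io import Conformation, read_ligand_template
from vasite.synthetic import CavitySpec, make_toy_receptor


@pytest.fixture(scope="session")
def halothane():
    return read_ligand_template()


@pytest.fixture(scope="session")
def cavity_receptor():
    """One halothane-sized hydrophobic chamber at the origin."""
    return make_toy_receptor(
        [CavitySpec(center=np.array([0.0, 0.0, 0.0]), depth=10.0)], seed=0
    )


@pytest.fixture(scope="session")
def two_cavity_receptor():
    """Two buried hydrophobic chambers on the z axis."""
    return make_toy_receptor(
        [
            CavitySpec(center=np.array([0.0, 0.0, 4.5])),
            CavitySpec(center=np.array([0.0, 0.0, -4.5])),
        ],
        seed=1,
    )


def small_conformation(coord: np.ndarray, res_names=None, charges=None,
                       elements=None, radius=1.908, epsilon=0.086) -> Conformation:
    """Ad-hoc parameterized conformation around a coordinate array."""
    coord = np.asarray(coord, dtype=float).reshape(-1, 3)
    n = len(coord)
    return Conformation(
        serial=np.arange(1, n + 1),
        name=np.full(n, "CA", dtype="U4"),
        element=(np.asarray(elements, dtype="U2") if elements is not None
                 else np.full(n, "C", dtype="U2")),
        res_name=(np.asarray(res_names, dtype="U3") if res_names is not None
                  else np.full(n, "ALA", dtype="U3")),
        res_id=np.arange(1, n + 1),
        chain_id=np.full(n, "A", dtype="U2"),
        coord=coord,
        radius=np.full(n, radius),
        partial_charge=(np.asarray(charges, dtype=float) if charges is not None
                        else np.zeros(n)),
        epsilon=np.full(n, epsilon),
    )


SMALL_PIPELINE_CONFIG = dict(
    n_frames=14,
    tail_sequences=["DATADEQGEFEEEEGEDEA"],
    tail_n_conformers=6,
    tail_dock_conformers=2,
    n_restarts=6,
    n_local_steps=100,
)


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One finished small pipeline run (config + output paths/results)."""
    out = tmp_path_factory.mktemp("pipeline") / "run"
    config = PipelineConfig(out_dir=str(out), **SMALL_PIPELINE_CONFIG)
    return config, run_pipeline(config)
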