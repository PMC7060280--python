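import numpy as np
import pandas as pd
import pytest

from pathmeta.effect_size import CASE, CONTROL, StudyData


def make_study(ctrl: np.ndarray, case: np.ndarray, study_id: str = "s",
               genes=None) -> StudyData:
    """Assemble a StudyData from control and case value blocks (genes x samples)."""
    ctrl = np.atleast_2d(ctrl)
    case = np.atleast_2d(case)
    n_genes = ctrl.shape[0]
    if genes is None:
        genes = [f"g{i:04d}" for i in range(n_genes)]
    samples = [f"c{i}" for i in range(ctrl.shape[1])] + [
        f"t{i}" for i in range(case.shape[1])
    ]
    matrix = pd.DataFrame(np.hstack([ctrl, case]), index=genes, columns=samples)
    groups = pd.Series(
        [CONTROL] * ctrl.shape[1] + [CASE] * case.shape[1], index=samples
    )
    return StudyData(study_id, matrix, groups)


@pytest.fixture(scope="session")
def small_workspace():
    """A small simulated workspace shared across tests (read-only)."""
    from pathmeta.synth import SimulationConfig, simulate_pathways, simulate_studies

    cfg = SimulationConfig(
        n_genes=400, n_studies=4, samples_per_group=15, de_fraction=0.1,
        n_pathways=12, pathway_size_range=(10, 20), planted_de_nodes=10,
        seed=2024,
    )
    studies, truth = simulate_studies(cfg)
    pathways, planted = simulate_pathways(cfg, truth)
    return cfg, studies, truth, pathways, planted
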