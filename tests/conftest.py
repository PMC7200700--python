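import numpy as np
import pytest

from thetalock.experiments import ExperimentConfig, SyntheticCell, run_theta
from thetalock.morphology import MorphSpec, generate_morphology


@pytest.fixture(scope="session")
def default_morph():
    return generate_morphology(MorphSpec(), seed=1)


@pytest.fixture(scope="session")
def tiny_morph():
    """Few-compartment reduction for fast simulation tests."""
    return generate_morphology(
        MorphSpec(n_basal=1, n_apical=1, depth=1, trunk_sections=1), seed=0
    )


@pytest.fixture(scope="session")
def small_morph():
    """~20-compartment cell tall enough to host every input pathway."""
    return generate_morphology(
        MorphSpec(n_basal=2, n_apical=2, depth=2, trunk_sections=3,
                  mean_seg_length=40.0), seed=0
    )


def _run_profile(cell_seed: int, profile: str, manipulation=None, n_cycles=200,
                 seed=42):
    morph = generate_morphology(MorphSpec(), seed=100 + cell_seed)
    cell = SyntheticCell(morph, name=f"cell{cell_seed}")
    cfg = ExperimentConfig(n_cycles=n_cycles, sublayer=profile,
                           manipulation=manipulation or {}, seed=seed)
    sps, _ = run_theta(cell, cfg)
    return sps


@pytest.fixture(scope="session")
def sublayer_panel():
    """Deep vs superficial profiles on a panel of 8 synthetic cells.

    200 theta cycles per condition; conditions share the event-stream
    seed per cell so the contrast is paired.
    """
    out = {"deep": [], "superficial": []}
    for i in range(8):
        for prof in ("deep", "superficial"):
            sps = _run_profile(i, prof)
            out[prof].append(sps)
    return out


@pytest.fixture(scope="session")
def pv_removal_panel():
    """Baseline vs full PV-basket removal on 4 synthetic cells."""
    out = {"baseline": [], "pv_removed": []}
    for i in range(4):
        out["baseline"].append(_run_profile(i, "none"))
        out["pv_removed"].append(_run_profile(i, "none", manipulation={"PV": 0.0}))
    return out
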