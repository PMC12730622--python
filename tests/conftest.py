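import numpy as np
import pytest

import karstsdm as k


@pytest.fixture(scope="session")
def landscape():
    """One moderately sized seeded landscape shared across tests."""
    return k.generate_landscape(k.LandscapeConfig(n_rows=64, n_cols=64, seed=7))


@pytest.fixture(scope="session")
def fitted_problem():
    """A full small training problem: stack, mask, table with strong signal."""
    cfg = k.LandscapeConfig(n_rows=64, n_cols=64, seed=11)
    stack = k.generate_landscape(cfg)
    truth = k.TrueModel(-0.5, {"elev_m": 2.5, "SAND_05cm": -1.5})
    occ = k.generate_occurrences(stack, truth, 60, seed=3)
    elev = stack.extract(occ.xy[:, 0], occ.xy[:, 1], ["elev_m"])[:, 0]
    band = k.elevation_band(elev)
    mask = k.build_mask(stack, band)
    stack_z, params = k.standardize(stack, mask.cells)
    bg = k.sample_background(mask, occ, seed=5, n_total=1200)
    report = k.CollinearityReport(kept=["elev_m", "SAND_05cm", "CEC_05cm"])
    table = k.assemble_training(stack_z, occ, bg, report)
    return {
        "stack": stack, "stack_z": stack_z, "mask": mask, "occ": occ,
        "table": table, "params": params, "truth": truth,
    }
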