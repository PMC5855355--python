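import numpy as np
import pandas as pd
import pytest

from qlseq import (
    CountMatrix,
    build_design,
    estimate_dispersion,
    filter_low_counts,
    fit_genes,
    tmm_factors,
)
from qlseq.simulate import SimConfig, simulate_experiment


@pytest.fixture(scope="session")
def small_experiment():
    """A 400-gene default-structure experiment with known truth."""
    cfg = SimConfig(genes=400, seed=11)
    return simulate_experiment(cfg)


@pytest.fixture(scope="session")
def fitted(small_experiment):
    """Filtered counts, design, dispersions and full fits for the small
    experiment."""
    cm, st, truth = small_experiment
    mask = filter_low_counts(cm)
    cmf = CountMatrix(cm.counts.loc[mask.to_numpy()], cm.lib_sizes)
    factors = tmm_factors(cmf)
    design = build_design(st)
    offsets = np.log(factors.effective_lib_sizes(cmf.lib_sizes).to_numpy(float))
    disp = estimate_dispersion(cmf, design, offsets)
    fits = fit_genes(cmf, design, offsets, disp.phi_trend)
    return {
        "counts": cmf,
        "samples": st,
        "truth": truth,
        "design": design,
        "offsets": offsets,
        "dispersions": disp,
        "fits": fits,
    }


@pytest.fixture()
def toy_counts():
    df = pd.DataFrame(
        [[1, 2], [3, 4], [0, 0]],
        index=["g1", "g2", "g3"],
        columns=["s1", "s2"],
    )
    return CountMatrix(df)


@pytest.fixture()
def full_sample_table():
    rows = [
        {
            "sample_id": f"{sp}{i}_{p}",
            "individual": f"{sp}{i}",
            "species": sp,
            "brain_part": p,
        }
        for sp in ("Na", "Ve")
        for i in range(1, 6)
        for p in ("BS", "CE", "DI", "OB", "OT", "TE")
    ]
    return pd.DataFrame(rows)
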