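import numpy as np
import pandas as pd
import pytest

from cardiomir.datatypes import CountMatrix, SampleTable


@pytest.fixture
def tiny_counts() -> CountMatrix:
    df = pd.DataFrame([[0, 1], [2, 3]], index=["miR-1", "miR-2"],
                      columns=["s1", "s2"])
    return CountMatrix(df)


@pytest.fixture
def small_cohort() -> tuple[CountMatrix, SampleTable]:
    """40 samples, 300 null NB features: enough for a quick model fit."""
    rng = np.random.default_rng(1234)
    n, g = 40, 300
    ages = np.sort(rng.uniform(8, 19, n))
    lib = np.exp(rng.uniform(np.log(0.5), np.log(2.0), n))
    base = rng.uniform(5, 9, g)
    mu = np.exp2(base[:, None]) * lib[None, :]
    size = 10.0  # dispersion 0.1
    counts = rng.negative_binomial(size, size / (size + mu))
    ids = [f"g{i:03d}" for i in range(g)]
    cols = [f"s{j:02d}" for j in range(n)]
    cm = CountMatrix(pd.DataFrame(counts, index=ids, columns=cols))
    st = SampleTable(pd.DataFrame({"gestational_age": ages}, index=cols))
    return cm, st


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full default synthetic pipeline run, shared across tests."""
    from cardiomir import pipeline as pl
    from cardiomir.config import PipelineConfig
    from cardiomir.simulate import SimulationConfig

    outdir = tmp_path_factory.mktemp("default_run")
    spec = pl.RunSpec(True, PipelineConfig(seed=1),
                      SimulationConfig(seed=1), {})
    summary = pl.run_pipeline(spec, outdir)
    return spec, outdir, summary
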