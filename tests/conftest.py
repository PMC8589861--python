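import numpy as np
import pandas as pd
import pytest

from scnadriver import simulate


def small_config(seed: int = 0, **overrides) -> simulate.SimulationConfig:
    """A reduced cohort (2 chromosomes x 80 genes, 60 tumors) for fast tests;
    keeps the default event/dosage/noise structure at desk scale."""
    genome = (
        simulate.ChromosomeSpec("1", n_genes=80),
        simulate.ChromosomeSpec("13", n_genes=80),
    )
    spacing = genome[0].spacing
    events = (
        simulate.ScnaEvent("del_13q", "13", 20 * spacing, 60 * spacing, "loss", 0.4, -0.7),
        simulate.ScnaEvent("gain_1q", "1", 20 * spacing, 60 * spacing, "gain", 0.3, +0.6),
    )
    dosage = tuple(f"g13_{i:04d}" for i in range(20, 40))
    templates = (
        simulate.TemplateSpec("S1", tuple(f"g1_{i:04d}" for i in range(0, 15)),
                              tuple(1 if i % 2 == 0 else -1 for i in range(15))),
    )
    cfg = simulate.SimulationConfig(
        n_pt_dcn=60, n_pt_expression=58, n_intersection=56, n_nt_expression=20,
        genome=genome, scna_events=events, dosage_genes=dosage,
        driver_gene="g13_0030", templates=templates, seed=seed,
    )
    for key, val in overrides.items():
        setattr(cfg, key, val)
    return cfg


@pytest.fixture(scope="session")
def small_cohort():
    return simulate.simulate_cohort(small_config(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


@pytest.fixture()
def toy_annotation():
    rows = [
        ("gA", "1", 100, 200, "gA", ""),
        ("gB", "1", 0, 100, "gB", ""),
        ("gC", "2", 50, 150, "gC", ""),
    ]
    df = pd.DataFrame(rows, columns=["gene_id", "chromosome", "start", "end", "symbol", "tags"])
    return df.set_index("gene_id")
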