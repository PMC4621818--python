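import numpy as np
import pandas as pd
import pytest

from drylysim import synth


@pytest.fixture(scope="session")
def climate17():
    """17-day noise-free diurnal climate at 10-min resolution."""
    return synth.simulate_climate(days=17, step_min=10, seed=2)


@pytest.fixture(scope="session")
def noisefree_run(climate17):
    """Noise-free lysimeter run: 7 pretreatment + 10 drought days."""
    truth = synth.LysimeterTruth("B118")
    return synth.simulate_lysimeter_run(truth, climate17, phases=(7, 10, 0))


@pytest.fixture(scope="session")
def small_panel():
    """95-accession, 200-marker structured panel with pure-noise traits."""
    return synth.simulate_panel(n_acc=95, n_snp=200, truth=synth.PanelTruth(), seed=7)


@pytest.fixture(scope="session")
def expr_sim():
    """Default factorial expression simulation with 60 planted DEGs."""
    ids = [f"UG{i:05d}" for i in range(60)]
    truth = synth.ExpressionTruth(
        true_degs={
            ("B47", "leaf"): {g: (2.0 if i % 2 else -2.0) for i, g in enumerate(ids)}
        }
    )
    return synth.simulate_expression(n_genes=800, truth=truth, seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(123)


def make_score_table(values: dict[str, np.ndarray], accessions=None) -> pd.DataFrame:
    """Long-form score table from {'<Trait><Year>': vector} (one replicate)."""
    rows = []
    for col, vec in values.items():
        trait, year = col[:-4], int(col[-4:])
        acc = accessions or [f"A{i:03d}" for i in range(len(vec))]
        for a, v in zip(acc, vec):
            rows.append(
                {"accession": a, "trait": trait, "year": year, "replicate": 1,
                 "score": int(v)}
            )
    return pd.DataFrame(rows)
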