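import numpy as np
import pandas as pd
import pytest

from phenolome import chromproc, simdata
from phenolome.config import PipelineConfig


def make_log_table(
    effect_maps: dict[str, pd.DataFrame],
    noise_sd: float = 0.25,
    n_reps: int = 4,
    baseline: float = 12.0,
    treatment: str = "I",
    seed: int = 0,
) -> pd.DataFrame:
    """Directly simulate a log2-scale metabolite table for ANOVA tests.

    Bypasses the chromatographic layer: each metabolite's value is
    baseline + planted (variety, day) drought effect (drought rows
    only) + iid Gaussian noise.
    """
    rng = np.random.default_rng(seed)
    any_map = next(iter(effect_maps.values()))
    varieties = list(any_map.index)
    days = list(any_map.columns)
    rows = []
    i = 0
    for v in varieties:
        for cond in ("control", "drought"):
            for d in days:
                for rep in range(1, n_reps + 1):
                    row = {
                        "sample_id": f"s{i}",
                        "variety": v,
                        "treatment": treatment,
                        "condition": cond,
                        "day": d,
                        "replicate": rep,
                        "sample_mass": 100.0,
                    }
                    for met, em in effect_maps.items():
                        y = baseline + rng.normal(0.0, noise_sd)
                        if cond == "drought":
                            y += em.loc[v, d]
                        row[met] = y
                    rows.append(row)
                    i += 1
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def benchmark():
    """Default planted-peak benchmark plus its preprocessing result."""
    chromset, truth = simdata.default_benchmark(seed=11)
    cfg = PipelineConfig(seed=11)
    result = chromproc.run_preprocessing(cfg, chromset)
    return chromset, truth, result


@pytest.fixture()
def small_design():
    return simdata.make_design(
        n_varieties=2,
        treatments=("I",),
        days_per_treatment={"I": (3, 6, 10)},
        n_reps=2,
        seed=0,
    )
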