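import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from epimemory.synthdata import SimDesign, simulate_dataset

settings.register_profile("ci", derandomize=True)
settings.load_profile("ci")


def make_sheet(
    n=8,
    tissue="cord",
    ga=None,
    sd=None,
    sex=None,
    batch=None,
    subjects=None,
    **overrides,
):
    """Minimal valid sample sheet for hand-built regression tests."""
    ga = np.linspace(24, 40, n) if ga is None else np.asarray(ga, float)
    sd = np.zeros(n) if sd is None else np.asarray(sd, float)
    sex = (["male", "female"] * n)[:n] if sex is None else list(sex)[:n]
    subjects = [f"S{i}" for i in range(n)] if subjects is None else subjects
    alt = ([0, 1] * n)[:n]
    df = pd.DataFrame({
        "sample_id": [f"{tissue[0].upper()}{i}" for i in range(n)],
        "subject_id": subjects,
        "tissue": tissue,
        "ga_weeks": ga,
        "bw_sd_score": sd,
        "sex": sex,
        "batch": batch if batch is not None else ["b0"] * n,
        "maternal_age": np.linspace(25, 40, n),
        "maternal_bmi": np.linspace(18, 28, n),
        "paternal_age": np.linspace(28, 44, n),
        "paternal_bmi": np.linspace(19, 29, n),
        "parity_gt0": alt,
        "cesarean": ([0, 0, 1] * n)[:n],
        "art": 0, "smoke_before": 0, "gdm": 0, "cam": 0,
        "iprom": 0, "preeclampsia": 0, "previa": 0,
        "postmenstrual_age_at_draw": ga,
        "interval_weeks": np.nan if tissue == "cord" else np.linspace(2, 16, n),
    })
    for k, v in overrides.items():
        df[k] = v
    return df


@pytest.fixture(scope="session")
def demo_design():
    d = SimDesign(
        n_cord=70, n_paired_postnatal=31, n_expr=36, n_cpgs=800,
        n_expr_probes=160, frac_ga_cpgs=0.25, frac_memory=0.4,
        n_planted_top_gene_cpgs=8, seed=11,
    )
    d.ga_effect_logit_per_week = d.ga_effect_for_tratio(6.0)
    return d


@pytest.fixture(scope="session")
def demo_data(demo_design):
    return simulate_dataset(demo_design)


@pytest.fixture(scope="session")
def demo_dir(demo_data, tmp_path_factory):
    from epimemory.synthdata import write_dataset

    path = tmp_path_factory.mktemp("demo_dataset")
    write_dataset(demo_data, path)
    return path
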