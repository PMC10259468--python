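import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import metaboflow as mf

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_config():
    return mf.make_default_config(seed=1)


@pytest.fixture(scope="session")
def default_dataset(default_config):
    """Default synthetic integral table with its ground truth."""
    table, truth = mf.simulate(default_config)
    return table, mf.truth_frame(truth)


@pytest.fixture(scope="session")
def noise_free_dataset(default_config):
    cfg = mf.SynthConfig(**{**default_config.__dict__, "log_sd": 0.0})
    table, truth = mf.simulate(cfg)
    return table, mf.truth_frame(truth)


def run_qualitative_pipeline(table):
    """Blank suppression -> split -> control correction -> presence matrix.

    Returns (presence, corrected fly table, fruit table, table after
    blank suppression)."""
    t = mf.remove_blank_ions(table)
    kinds = t.split_kinds()
    fly_c = mf.control_correct(kinds["fly"], kinds["control_fly"])
    combo = mf.FeatureTable(
        areas=pd.concat([kinds["fruit"].areas, fly_c.areas], axis=1),
        samples=pd.concat(
            [kinds["fruit"].samples, fly_c.samples], ignore_index=True
        ),
    )
    presence = mf.to_presence(combo)
    return presence, fly_c, kinds["fruit"], t


@pytest.fixture(scope="session")
def default_pipeline(default_dataset):
    table, truth = default_dataset
    presence, fly_c, fruit, after_blank = run_qualitative_pipeline(table)
    return {
        "truth": truth,
        "presence": presence,
        "fly_corrected": fly_c,
        "fruit": fruit,
        "after_blank": after_blank,
    }


@pytest.fixture(scope="session")
def noise_free_pipeline(noise_free_dataset):
    table, truth = noise_free_dataset
    presence, fly_c, fruit, after_blank = run_qualitative_pipeline(table)
    return {
        "truth": truth,
        "presence": presence,
        "fly_corrected": fly_c,
        "fruit": fruit,
        "after_blank": after_blank,
    }


@pytest.fixture()
def rng():
    # fresh, fixed-seed generator per test: results do not depend on
    # which other tests ran before
    return np.random.default_rng(20230606)


def tiny_table(areas, kinds=None, diets=None, generations=None):
    """Build a small FeatureTable from a dict {sample_id: [areas...]}."""
    df = pd.DataFrame(areas)
    df.index = [f"M{100 + i}T{10 + i}" for i in range(len(df))]
    n = df.shape[1]
    meta = pd.DataFrame(
        {
            "sample_id": list(df.columns),
            "kind": kinds or ["fly"] * n,
            "diet": diets or ["cherry"] * n,
            "generation": generations or [1] * n,
            "replicate": list(range(1, n + 1)),
        }
    )
    meta.loc[meta["kind"].isin(["fruit", "blank"]), "generation"] = None
    return mf.FeatureTable(areas=df, samples=meta)
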