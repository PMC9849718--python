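import numpy as np
import pandas as pd
import pytest

import policytextpanel as ptp
from policytextpanel.examples import worked_example_corpus

RELEVANCE = ("medical", "medicine", "health", "hospital")


@pytest.fixture(scope="session")
def lexicon():
    return ptp.demo_lexicon()


@pytest.fixture(scope="session")
def worked_example():
    return worked_example_corpus()


@pytest.fixture(scope="session")
def small_corpus():
    """Eight-prefecture synthetic corpus plus ground truth (fixed seed)."""
    spec = ptp.CorpusSpec(n_prefectures=8, seed=11)
    docs, truth = ptp.generate_corpus(spec)
    return spec, docs, truth


def make_small_panel(n_persons=12, n_waves=3, seed=0):
    """Tiny deterministic panel for estimator fixtures (<=200 rows)."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_persons):
        fe = rng.normal(0, 1)
        pref = f"p{i % 4}"
        for t in range(n_waves):
            x1 = rng.normal(0, 1)
            x2 = rng.normal(0, 1)
            y = 1.5 * x1 - 0.8 * x2 + fe + 0.3 * t + rng.normal(0, 0.5)
            rows.append(
                {
                    "person_id": f"i{i}",
                    "prefecture_id": pref,
                    "year": 2000 + t,
                    "x1": x1,
                    "x2": x2,
                    "y": y,
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture()
def small_panel():
    return make_small_panel()


def lsdv_fit(df, outcome, regressors, person_col="person_id", year_col="year"):
    """Independent LSDV oracle: explicit person and year dummies, plain lstsq."""
    X = [df[r].to_numpy(dtype=float) for r in regressors]
    person_d = pd.get_dummies(df[person_col], dtype=float)
    year_d = pd.get_dummies(df[year_col], drop_first=True, dtype=float)
    Z = np.column_stack(X + [year_d.to_numpy(), person_d.to_numpy()])
    beta, *_ = np.linalg.lstsq(Z, df[outcome].to_numpy(dtype=float), rcond=None)
    return dict(zip(regressors, beta[: len(regressors)]))
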