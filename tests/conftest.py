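import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_survey():
    """A modest synthetic survey with known effects for unit tests."""
    from scipy.special import logit

    from periocal.scoring import apply_outcome
    from periocal.simulate import SimConfig, simulate_survey

    cfg = SimConfig(
        n_subjects=300,
        sextants_per_subject=5,
        beta={"smoking": float(np.log(2))},
        intercept=float(logit(0.3)),
        sigma_u=0.5,
        se_by_rater=0.8,
        sp_by_rater=0.85,
        seed=42,
    )
    survey = simulate_survey(cfg)
    records = apply_outcome(survey.records, "combined")
    return cfg, survey, records


def make_2x2_records(s_exposed, m_exposed, s_unexposed, m_unexposed):
    """Independent-subject records realizing a 2x2 exposure/outcome table."""
    rows = []
    i = 0
    for x, s, m in ((1, s_exposed, m_exposed), (0, s_unexposed, m_unexposed)):
        for k in range(m):
            rows.append(
                {
                    "subject_id": i,
                    "rater_id": 0,
                    "region_id": 0,
                    "x": x,
                    "y": int(k < s),
                }
            )
            i += 1
    return pd.DataFrame(rows)
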