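import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ebvar.io_model import filter_valid_days, records_to_frame
from ebvar.synthetic import generate_cohort, preset_paperlike

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

ALL_OUTCOMES = [
    "tee_kcal",
    "paee_kcal",
    "pal",
    "sedentary_min",
    "light_min",
    "mvpa_min",
    "intake_kcal",
    "protein_pct",
    "fat_pct",
    "carb_pct",
    "alcohol_pct",
]


@pytest.fixture(scope="session")
def paperlike_cohort():
    """Study-shaped synthetic cohort, 33 subjects x 7 days, fixed seed."""
    return generate_cohort(preset_paperlike(seed=1))


@pytest.fixture(scope="session")
def paperlike_frame(paperlike_cohort):
    """Valid-day filtered long frame joined to subject covariates."""
    subjects, records = paperlike_cohort
    return records_to_frame(filter_valid_days(records), subjects)


def balanced_grid(n_subjects=5, n_days=4, sigma_b=0.2, sigma_w=0.1, seed=11):
    """Balanced covariate-free lognormal grid for the ANOVA oracle."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    rows = []
    u = rng.normal(0.0, sigma_b, n_subjects)
    for i in range(n_subjects):
        for j in range(n_days):
            rows.append(
                {
                    "subject_id": f"S{i:02d}",
                    "order_index": j + 1,
                    "day_of_week": "Mon",
                    "wear_minutes": 1440.0,
                    "wear_fraction": 1.0,
                    "y": float(np.exp(5.0 + u[i] + rng.normal(0.0, sigma_w))),
                }
            )
    return pd.DataFrame(rows)


def anova_components(df, outcome="y", group="subject_id"):
    """One-way random-effects ANOVA estimators on the log scale (oracle)."""
    logy = np.log(df[outcome].to_numpy())
    groups = df[group].to_numpy()
    ids, counts = np.unique(groups, return_counts=True)
    assert len(set(counts)) == 1, "oracle requires a balanced grid"
    k = counts[0]
    means = np.array([logy[groups == g].mean() for g in ids])
    grand = logy.mean()
    ms_between = k * ((means - grand) ** 2).sum() / (len(ids) - 1)
    ms_within = sum(
        ((logy[groups == g] - m) ** 2).sum() for g, m in zip(ids, means)
    ) / (len(ids) * (k - 1))
    return (ms_between - ms_within) / k, ms_within
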