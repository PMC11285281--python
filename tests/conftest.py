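import numpy as np
import pytest

from lprx.synthetic import SimParams, StepOutcome, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """60-patient cohort with short stays, shared across tests."""
    params = SimParams(
        n_patients=60,
        stay_range_days=(1.0, 3.0),
        outcome_model=StepOutcome(theta_star=0.30, p_below=0.10, p_above=0.70),
        seed=7,
    )
    records, truths = generate_cohort(params)
    return params, records, truths


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def pearson_oracle(x, y):
    """Textbook pairwise-complete Pearson correlation, plain Python.

    Independent of the package implementation: two-pass mean/deviation sums
    over the complete pairs.
    """
    import math

    pairs = [
        (float(a), float(b))
        for a, b in zip(x, y)
        if math.isfinite(a) and math.isfinite(b)
    ]
    n = len(pairs)
    if n < 2:
        return float("nan")
    mx = sum(a for a, _ in pairs) / n
    my = sum(b for _, b in pairs) / n
    sxy = sum((a - mx) * (b - my) for a, b in pairs)
    sxx = sum((a - mx) ** 2 for a, _ in pairs)
    syy = sum((b - my) ** 2 for _, b in pairs)
    if sxx == 0 or syy == 0:
        return float("nan")
    return sxy / math.sqrt(sxx * syy)
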