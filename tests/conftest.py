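import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from survrank.kaplan_meier import StepSurvivalCurve, fit_km

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_curve(times, survival, max_time=None, n_total=None):
    """Hand-built step survival curve with consistent bookkeeping columns."""
    times = np.asarray(times, dtype=float)
    survival = np.asarray(survival, dtype=float)
    k = times.size
    n_total = n_total or max(2, k + 1)
    return StepSurvivalCurve(
        times=times,
        survival=survival,
        n_at_risk=np.arange(n_total, n_total - k, -1),
        n_events=np.ones(k, dtype=int),
        n_censored=np.zeros(k, dtype=int),
        n_total=n_total,
        max_time=float(max_time if max_time is not None else (times[-1] if k else 0.0)),
    )


def random_km_curve(rng, n=30, rate=0.1, censor=20.0):
    """A KM curve fitted to a small random censored exponential sample."""
    t = rng.exponential(1.0 / rate, size=n)
    c = rng.uniform(0, censor, size=n)
    obs = np.minimum(t, c)
    ev = (t <= c).astype(int)
    if ev.sum() == 0:
        ev[0] = 1
    return fit_km(obs, ev)


@pytest.fixture(scope="session")
def study_cfg():
    from survrank.synthetic_cohort import study_like_config

    return study_like_config(seed=20200)


@pytest.fixture(scope="session")
def study_cohort(study_cfg):
    from survrank.synthetic_cohort import generate_cohort

    return generate_cohort(study_cfg)
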