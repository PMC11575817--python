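import numpy as np
import pandas as pd
import pytest

from vbtval.dataset import PairedDataset
from vbtval.models import SamplerSpec


def make_paired(seed: int, n_subjects: int = 20, n_reps: int = 30,
                alpha: float = 0.0, beta: float = 1.0, sigma: float = 0.0,
                tau0: float = 0.0, tau1: float = 0.0, rho: float = 0.0,
                mv_low: float = 0.1, mv_high: float = 1.0) -> PairedDataset:
    """Paired criterion/practical data with a known device error model."""
    rng = np.random.default_rng(seed)
    rows = []
    cov = np.array([[tau0 ** 2, rho * tau0 * tau1],
                    [rho * tau0 * tau1, tau1 ** 2]])
    chol_vals, chol_vecs = np.linalg.eigh(cov)
    chol = chol_vecs @ np.diag(np.sqrt(np.clip(chol_vals, 0, None)))
    for i in range(n_subjects):
        u = chol @ rng.standard_normal(2)
        x = rng.uniform(mv_low, mv_high, n_reps)
        y = (alpha + u[0]) + (beta + u[1]) * x + rng.normal(0.0, sigma, n_reps)
        for k, (xx, yy) in enumerate(zip(x, y)):
            rows.append(dict(subject_id=f"S{i:02d}", exercise="squat",
                             load_pct=50.0, set_index=k + 1, rep_index=1,
                             criterion_mv=float(xx), practical_mv=float(yy)))
    frame = pd.DataFrame(rows)
    return PairedDataset(frame, "device", len(frame), 0, 0)


@pytest.fixture(scope="session")
def fast_sampler():
    return SamplerSpec.fast(seed=0)


@pytest.fixture(scope="session")
def tiny_sampler():
    """Smallest spec meeting the >=1000 retained-draw contract."""
    return SamplerSpec(n_walkers=16, n_warmup=300, n_keep=63, thin=4, seed=0)
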