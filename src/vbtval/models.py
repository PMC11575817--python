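"""Bayesian linear mixed models for concurrent-validity analysis.

Two models are fit per practical device and exercise, mirroring the standard
method-comparison setup for velocity measurements:

* **Model 1** (calibration): practical mean velocity as a linear function of
  criterion mean velocity, with correlated subject-level random intercepts and
  slopes.  Its posterior yields proportional-bias summaries (intercept, slope),
  Bayesian R^2 (random error) and an RMSE computed from conditional posterior
  predictions (absolute precision).
* **Model 2** (mean difference): each repetition contributes one criterion and
  one practical row; velocity is modelled as a function of a binary *source*
  indicator.  The source coefficient delta is the mean device-criterion
  difference; divided by a reference SD it gives the standardized mean bias
  (SMB).

Both are Gaussian linear mixed models

    y_ij = (b0 + u0_i) + (b1 + u1_i) x_ij + eps_ij,
    (u0_i, u1_i) ~ MVN(0, Sigma),   eps_ij ~ N(0, sigma^2),

fitted on a standardized scale (centred/scaled by the criterion mean and SD)
with weakly informative priors: N(0,1) on standardized coefficients,
half-N(0,1) on sigma and the random-effect SDs, LKJ(2) on the random-effect
correlation.

Sampling strategy: the subject random effects are Gaussian and enter linearly,
so they are marginalized analytically (Woodbury identities on 2x2 blocks, in a
form that stays valid when a random-effect SD is exactly zero).  Ensemble MCMC
(emcee, differential-evolution moves) then explores only the six
hyperparameters (b0, b1, sigma, tau0, tau1, rho); subject effects are
recovered exactly from their conditional Gaussian for every retained draw.
This collapsed scheme avoids the funnel geometry of hierarchical posteriors
and makes each fit fast enough for simulation studies.  For diagnostics the
walkers are grouped into four long chains for split-Rhat, while ESS is
computed on the ungrouped walker chains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import PairedDataset

__all__ = [
    "PriorSpec",
    "SamplerSpec",
    "PosteriorSummary",
    "MixedModelFit",
    "Model1Fit",
    "Model2Fit",
    "hdi",
    "fit_model1",
    "fit_model2",
    "compute_smb",
    "compute_rmse",
    "compute_r2",
]

_RHAT_LIMIT = 1.01


def hdi(draws: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ``ceil(mass * n)`` sorted draws.

    For unimodal posteriors this is the highest density interval.
    """
    if not 0.0 < mass < 1.0:
        raise ValueError(f"mass must be in (0, 1), got {mass}")
    x = np.sort(np.asarray(draws, dtype=float).ravel())
    n = x.size
    if n < 100:
        raise ValueError(f"need at least 100 draws for an HDI, got {n}")
    k = int(np.ceil(mass * n))
    widths = x[k - 1:] - x[: n - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])


@dataclass(frozen=True)
class PriorSpec:
    """Weakly informative priors on the standardized scale."""

    beta_scale: float = 1.0       # N(0, beta_scale) on coefficients
    sigma_scale: float = 1.0      # half-N(0, sigma_scale) on residual SD
    tau_scale: float = 1.0        # half-N(0, tau_scale) on random-effect SDs
    lkj_eta: float = 2.0          # LKJ shape on the random-effect correlation

    def __post_init__(self) -> None:
        for name in ("beta_scale", "sigma_scale", "tau_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.lkj_eta < 1.0:
            raise ValueError("lkj_eta must be >= 1")


@dataclass(frozen=True)
class SamplerSpec:
    """Ensemble-MCMC settings.

    ``n_walkers`` interacting walkers are run for ``n_warmup`` discarded steps
    followed by ``n_keep * thin`` retained steps; the kept chain is thinned by
    ``thin``, giving ``n_walkers * n_keep`` posterior draws.
    """

    n_walkers: int = 32
    n_warmup: int = 1500
    n_keep: int = 125
    thin: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_walkers < 4:
            raise ValueError("need at least 4 walkers (chains)")
        if self.n_walkers * self.n_keep < 1000:
            raise ValueError("sampler must retain at least 1000 draws")

    @property
    def n_draws(self) -> int:
        return self.n_walkers * self.n_keep

    @classmethod
    def fast(cls, seed: int = 0) -> "SamplerSpec":
        """Reduced-draw settings for simulation studies."""
        return cls(n_walkers=32, n_warmup=1000, n_keep=100, thin=10, seed=seed)


@dataclass(frozen=True)
class PosteriorSummary:
    """Posterior mean and 95% HDI for one scalar validity statistic."""

    name: str
    mean: float
    hdi_low: float
    hdi_high: float
    draws: np.ndarray = field(repr=False)
    rhat_max: float = float("nan")
    ess_min: float = float("nan")
    flagged: bool = False

    def direction_probability(self, threshold: float, side: str) -> float:
        if side == "below":
            return float(np.mean(self.draws < threshold))
        if side == "above":
            return float(np.mean(self.draws > threshold))
        raise ValueError(f"side must be 'below' or 'above', got {side!r}")


# ---------------------------------------------------------------------------
# sufficient statistics and the marginal log posterior
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _GroupStats:
    """Per-subject sufficient statistics of (x, y) under design Z = [1, x]."""

    subjects: np.ndarray
    n: np.ndarray
    sx: np.ndarray
    sxx: np.ndarray
    sy: np.ndarray
    syy: np.ndarray
    sxy: np.ndarray

    @classmethod
    def from_arrays(cls, x: np.ndarray, y: np.ndarray, groups: np.ndarray) -> "_GroupStats":
        df = pd.DataFrame({"g": groups, "x": x, "y": y})
        df["xx"] = df.x * df.x
        df["yy"] = df.y * df.y
        df["xy"] = df.x * df.y
        agg = df.groupby("g", sort=True).agg(
            n=("x", "size"), sx=("x", "sum"), sxx=("xx", "sum"),
            sy=("y", "sum"), syy=("yy", "sum"), sxy=("xy", "sum"))
        return cls(
            subjects=agg.index.to_numpy(),
            n=agg.n.to_numpy(dtype=float),
            sx=agg.sx.to_numpy(), sxx=agg.sxx.to_numpy(),
            sy=agg.sy.to_numpy(), syy=agg.syy.to_numpy(), sxy=agg.sxy.to_numpy())

    @property
    def n_total(self) -> float:
        return float(self.n.sum())


_BOUNDS_LOW = np.array([-50.0, -50.0, 1e-6, 0.0, 0.0, -0.999])
_BOUNDS_HIGH = np.array([50.0, 50.0, 20.0, 20.0, 20.0, 0.999])


def _marginal_blocks(th: np.ndarray, stats: _GroupStats):
    """Shared 2x2 Woodbury blocks for the marginal likelihood.

    ``th`` (W, 6) holds b0, b1, sigma, tau0, tau1, rho on natural scales.
    The formulation never inverts Sigma, so tau = 0 is admissible.
    Returns broadcastable per-(walker, subject) arrays.
    """
    b0 = th[:, 0:1]
    b1 = th[:, 1:2]
    sig2 = th[:, 2:3] ** 2
    s00 = th[:, 3:4] ** 2
    s01 = th[:, 5:6] * th[:, 3:4] * th[:, 4:5]
    s11 = th[:, 4:5] ** 2

    n, sx, sxx = stats.n, stats.sx, stats.sxx
    # B = sigma^2 I + (Z'Z) Sigma, per subject
    b00 = sig2 + n * s00 + sx * s01
    b01 = n * s01 + sx * s11
    b10 = sx * s00 + sxx * s01
    b11 = sig2 + sx * s01 + sxx * s11
    det_b = b00 * b11 - b01 * b10
    # H = Sigma B^{-1} (symmetric); entries via 2x2 inverse
    h00 = (s00 * b11 - s01 * b10) / det_b
    h01 = (-s00 * b01 + s01 * b00) / det_b
    h10 = (s01 * b11 - s11 * b10) / det_b
    h11 = (-s01 * b01 + s11 * b00) / det_b
    h01 = 0.5 * (h01 + h10)  # symmetrize against round-off

    a = stats.sy - n * b0 - sx * b1
    c = stats.sxy - sx * b0 - sxx * b1
    rr = (stats.syy - 2 * b0 * stats.sy - 2 * b1 * stats.sxy
          + n * b0 ** 2 + 2 * b0 * b1 * sx + b1 ** 2 * sxx)
    return sig2, det_b, h00, h01, h11, a, c, rr


def _log_posterior(theta: np.ndarray, stats: _GroupStats, priors: PriorSpec) -> np.ndarray:
    """Vectorized log posterior with subject effects marginalized analytically."""
    theta = np.atleast_2d(theta)
    ok = np.all((theta >= _BOUNDS_LOW) & (theta <= _BOUNDS_HIGH), axis=1)
    out = np.full(theta.shape[0], -np.inf)
    if not ok.any():
        return out
    th = theta[ok]
    sig2, det_b, h00, h01, h11, a, c, rr = _marginal_blocks(th, stats)
    n = stats.n
    # r' V^{-1} r = rr / sig2 - (Z'r)' H (Z'r) / sig2
    quad = (rr - (h00 * a ** 2 + 2 * h01 * a * c + h11 * c ** 2)) / sig2
    # log det V = (n - 2) log sig2 + log det B
    logdet_v = (n - 2) * np.log(sig2) + np.log(det_b)
    ll = -0.5 * np.sum(n * np.log(2 * np.pi) + logdet_v + quad, axis=1)

    sig, t0, t1, r = th[:, 2], th[:, 3], th[:, 4], th[:, 5]
    lp = (-0.5 * (th[:, 0] ** 2 + th[:, 1] ** 2) / priors.beta_scale ** 2
          - 0.5 * sig ** 2 / priors.sigma_scale ** 2
          - 0.5 * (t0 ** 2 + t1 ** 2) / priors.tau_scale ** 2
          + (priors.lkj_eta - 1.0) * np.log1p(-r ** 2))

    val = ll + lp
    val[~np.isfinite(val)] = -np.inf
    out[ok] = val
    return out


def _initial_guess(x: np.ndarray, y: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Moment-based starting point on the standardized scale."""
    X = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    sig = max(float(np.std(resid)), 1e-3)
    # between-subject spread of per-subject OLS coefficients
    per = []
    for g in np.unique(groups):
        m = groups == g
        if m.sum() >= 3 and np.ptp(x[m]) > 1e-6:
            cg, *_ = np.linalg.lstsq(X[m], y[m], rcond=None)
            per.append(cg)
    if len(per) >= 3:
        per_arr = np.array(per)
        tau = np.clip(per_arr.std(axis=0), 1e-3, 1.0)
    else:
        tau = np.array([0.1, 0.1])
    return np.array([coef[0], coef[1], sig, tau[0], tau[1], 0.0])


def _run_sampler(stats: _GroupStats, init: np.ndarray, priors: PriorSpec,
                 sampler_spec: SamplerSpec) -> np.ndarray:
    """Return posterior draws with shape (n_walkers, n_keep, 6)."""
    import emcee

    rng = np.random.default_rng(sampler_spec.seed)
    w = sampler_spec.n_walkers
    scatter = np.array([0.02, 0.02, 0.2 * init[2], 0.2 * init[3] + 0.01,
                        0.2 * init[4] + 0.01, 0.05])
    margin = np.array([0.0, 0.0, 1e-5, 0.0, 0.0, 1e-3])
    p0 = init[None, :] + scatter * rng.standard_normal((w, 6))
    p0 = np.clip(p0, _BOUNDS_LOW + margin, _BOUNDS_HIGH - margin)
    lp0 = _log_posterior(p0, stats, priors)
    bad = ~np.isfinite(lp0)
    tries = 0
    while bad.any() and tries < 50:
        p0[bad] = np.clip(
            init[None, :] + scatter * rng.standard_normal((int(bad.sum()), 6)),
            _BOUNDS_LOW + margin, _BOUNDS_HIGH - margin)
        lp0 = _log_posterior(p0, stats, priors)
        bad = ~np.isfinite(lp0)
        tries += 1
    if bad.any():
        raise RuntimeError("could not initialize walkers at finite posterior density")

    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
    sampler = emcee.EnsembleSampler(
        w, 6, _log_posterior, args=(stats, priors), vectorize=True, moves=moves)
    sampler.random_state = np.random.RandomState(
        int(rng.integers(0, 2 ** 31 - 1))).get_state()
    n_steps = sampler_spec.n_warmup + sampler_spec.n_keep * sampler_spec.thin
    sampler.run_mcmc(p0, n_steps, progress=False, skip_initial_state_check=True)
    chain = sampler.get_chain(discard=sampler_spec.n_warmup, thin=sampler_spec.thin)
    return np.moveaxis(chain, 0, 1)  # (walker, step, 6)


def _diagnostics(posterior: dict[str, np.ndarray],
                 n_chain_groups: int = 4) -> tuple[dict, dict]:
    """Split-Rhat and bulk ESS via arviz.

    Walkers of the ensemble are grouped into ``n_chain_groups`` long chains
    for Rhat (walkers interact, so many short walker-chains overstate
    disagreement); ESS is computed on the ungrouped walkers, which is the
    conservative direction for autocorrelated draws.
    """
    import arviz as az

    def _grouped(v: np.ndarray) -> np.ndarray:
        w = v.shape[0]
        g = n_chain_groups if w % n_chain_groups == 0 else 1
        return v.reshape(g, -1)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        idata_r = az.from_dict(posterior={k: _grouped(v) for k, v in posterior.items()})
        idata_e = az.from_dict(posterior=dict(posterior))
        rhat = {k: float(v.values) for k, v in az.rhat(idata_r).items()}
        ess = {k: float(v.values) for k, v in az.ess(idata_e).items()}
    return rhat, ess


def _conditional_effects(theta_flat: np.ndarray, stats: _GroupStats,
                         seed: int) -> np.ndarray:
    """Exact conditional draws of subject effects, shape (n_draws, S, 2).

    Given hyperparameters, u_i | y ~ N(H Z'r_i, sigma^2 H) with
    H = Sigma (sigma^2 I + Z'Z Sigma)^{-1}; singular Sigma collapses the
    corresponding effect to zero, as it should.
    """
    rng = np.random.default_rng(seed)
    sig2, _, h00, h01, h11, a, c, _ = _marginal_blocks(theta_flat, stats)
    mean0 = h00 * a + h01 * c
    mean1 = h01 * a + h11 * c
    # Cholesky of sigma^2 H in closed 2x2 form, tolerant of zero variances
    c00 = np.maximum(sig2 * h00, 0.0)
    c01 = sig2 * h01
    c11 = np.maximum(sig2 * h11, 0.0)
    l00 = np.sqrt(c00)
    with np.errstate(divide="ignore", invalid="ignore"):
        l10 = np.where(l00 > 0, c01 / np.where(l00 > 0, l00, 1.0), 0.0)
    l11 = np.sqrt(np.maximum(c11 - l10 ** 2, 0.0))
    z = rng.standard_normal((theta_flat.shape[0], stats.n.size, 2))
    u0 = mean0 + l00 * z[:, :, 0]
    u1 = mean1 + l10 * z[:, :, 0] + l11 * z[:, :, 1]
    return np.stack([u0, u1], axis=-1)


# ---------------------------------------------------------------------------
# fit containers
# ---------------------------------------------------------------------------


@dataclass
class MixedModelFit:
    """Posterior of one Gaussian linear mixed model.

    ``posterior`` arrays are on the *natural* scale where applicable
    (intercept, slope, sigma); random-effect SDs and the correlation are kept
    on the standardized fitting scale.
    """

    posterior: dict[str, np.ndarray]        # each (chain, draw)
    u_std: np.ndarray                       # (n_draws, S, 2), standardized scale
    theta_std: np.ndarray                   # (n_draws, 6), standardized scale
    stats_std: _GroupStats                  # standardized sufficient statistics
    subjects: np.ndarray
    y_center: float
    y_scale: float
    x_center: float
    x_scale: float
    rhat: dict[str, float]
    ess: dict[str, float]
    converged: bool
    seed: int
    n_obs: int

    @property
    def rhat_max(self) -> float:
        return max(self.rhat.values())

    @property
    def ess_min(self) -> float:
        return min(self.ess.values())

    def draws(self, name: str) -> np.ndarray:
        return self.posterior[name].reshape(-1)

    def summary(self, name: str, mass: float = 0.95) -> PosteriorSummary:
        d = self.draws(name)
        lo, hi = hdi(d, mass)
        return PosteriorSummary(
            name=name, mean=float(d.mean()), hdi_low=lo, hdi_high=hi, draws=d,
            rhat_max=self.rhat_max, ess_min=self.ess_min, flagged=not self.converged)


class Model1Fit(MixedModelFit):
    """Calibration model: practical velocity ~ criterion velocity."""


class Model2Fit(MixedModelFit):
    """Mean-difference model: velocity ~ source indicator."""


def _fit_lmm(x: np.ndarray, y: np.ndarray, groups: np.ndarray,
             y_center: float, y_scale: float, x_center: float, x_scale: float,
             priors: PriorSpec, sampler: SamplerSpec,
             cls: type[MixedModelFit]) -> MixedModelFit:
    xs = (x - x_center) / x_scale
    ys = (y - y_center) / y_scale
    stats = _GroupStats.from_arrays(xs, ys, groups)
    if stats.subjects.size < 2:
        raise ValueError("mixed model needs at least 2 subjects")
    init = _initial_guess(xs, ys, groups)
    chain = _run_sampler(stats, init, priors, sampler)  # (W, D, 6)
    w, d, _ = chain.shape
    theta_flat = chain.reshape(-1, 6)

    # natural-scale transforms
    slope = chain[:, :, 1] * (y_scale / x_scale)
    intercept = y_center + y_scale * chain[:, :, 0] - slope * x_center
    sigma = y_scale * chain[:, :, 2]
    posterior = {
        "intercept": intercept,
        "slope": slope,
        "sigma": sigma,
        "tau0": chain[:, :, 3],
        "tau1": chain[:, :, 4],
        "rho": chain[:, :, 5],
    }
    rhat, ess = _diagnostics(posterior)
    converged = max(rhat.values()) < _RHAT_LIMIT
    if not converged:
        warnings.warn(
            f"sampler did not converge (max Rhat = {max(rhat.values()):.4f}); "
            "summaries are flagged", RuntimeWarning, stacklevel=3)
    u = _conditional_effects(theta_flat, stats, seed=sampler.seed + 1)
    return cls(
        posterior=posterior, u_std=u, theta_std=theta_flat, stats_std=stats,
        subjects=stats.subjects, y_center=y_center, y_scale=y_scale,
        x_center=x_center, x_scale=x_scale, rhat=rhat, ess=ess,
        converged=converged, seed=sampler.seed, n_obs=int(stats.n_total))


def fit_model1(data: PairedDataset, priors: PriorSpec | None = None,
               sampler: SamplerSpec | None = None) -> Model1Fit:
    """Fit the calibration model on criterion/practical velocity pairs.

    Both axes are centred and scaled by the criterion mean velocity
    statistics before fitting; reported intercept/slope/sigma are
    back-transformed to m/s.
    """
    priors = priors or PriorSpec()
    sampler = sampler or SamplerSpec()
    df = data.frame
    if df.empty:
        raise ValueError("empty paired dataset")
    x = df["criterion_mv"].to_numpy(dtype=float)
    y = df["practical_mv"].to_numpy(dtype=float)
    g = df["subject_id"].to_numpy()
    mu = float(x.mean())
    s = float(x.std(ddof=1))
    if s <= 0:
        raise ValueError("criterion velocities are constant; cannot standardize")
    fit = _fit_lmm(x, y, g, y_center=mu, y_scale=s, x_center=mu, x_scale=s,
                   priors=priors, sampler=sampler, cls=Model1Fit)
    return fit


def fit_model2(data: PairedDataset, priors: PriorSpec | None = None,
               sampler: SamplerSpec | None = None) -> Model2Fit:
    """Fit the mean-difference (source-indicator) model.

    Each paired repetition contributes two rows: the criterion velocity with
    source = 0 and the practical velocity with source = 1.  The source
    coefficient (reported as ``slope``, in m/s) is the posterior mean
    device-criterion difference delta.
    """
    priors = priors or PriorSpec()
    sampler = sampler or SamplerSpec()
    df = data.frame
    if df.empty:
        raise ValueError("empty paired dataset")
    crit = df["criterion_mv"].to_numpy(dtype=float)
    prac = df["practical_mv"].to_numpy(dtype=float)
    g = df["subject_id"].to_numpy()
    y = np.concatenate([crit, prac])
    x = np.concatenate([np.zeros_like(crit), np.ones_like(prac)])
    groups = np.concatenate([g, g])
    mu = float(crit.mean())
    s = float(crit.std(ddof=1))
    if s <= 0:
        raise ValueError("criterion velocities are constant; cannot standardize")
    # y standardized by criterion stats; the binary source stays as-is
    return _fit_lmm(x, y, groups, y_center=mu, y_scale=s, x_center=0.0, x_scale=1.0,
                    priors=priors, sampler=sampler, cls=Model2Fit)


# ---------------------------------------------------------------------------
# derived validity statistics
# ---------------------------------------------------------------------------


def _prediction_moments(fit: MixedModelFit) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-draw SSE, Var(yhat) and Var(y - yhat) on the standardized scale.

    Predictions are conditional means (fixed + subject effects, no residual
    draw), evaluated through the per-subject sufficient statistics.
    """
    st = fit.stats_std
    th = fit.theta_std
    c0 = th[:, 0:1] + fit.u_std[:, :, 0]  # (D, S)
    c1 = th[:, 1:2] + fit.u_std[:, :, 1]
    n, sx, sxx = st.n, st.sx, st.sxx
    sy, syy, sxy = st.sy, st.syy, st.sxy
    sse_i = (syy - 2 * c0 * sy - 2 * c1 * sxy
             + n * c0 ** 2 + 2 * c0 * c1 * sx + c1 ** 2 * sxx)
    sum_hat = c0 * n + c1 * sx
    sum_hat2 = c0 ** 2 * n + 2 * c0 * c1 * sx + c1 ** 2 * sxx
    ntot = st.n_total
    sse = sse_i.sum(axis=1)
    mean_hat = sum_hat.sum(axis=1) / ntot
    var_hat = sum_hat2.sum(axis=1) / ntot - mean_hat ** 2
    sum_res = st.sy.sum() - sum_hat.sum(axis=1)
    var_res = sse / ntot - (sum_res / ntot) ** 2
    return sse, var_hat, var_res


def compute_rmse(fit: Model1Fit, data: PairedDataset | None = None,
                 mass: float = 0.95) -> PosteriorSummary:
    """Posterior RMSE of conditional predictions, in m/s.

    Per draw, RMSE = sqrt(mean((yhat - y)^2)) with yhat the draw's conditional
    expectation (group and subject effects, no residual noise added).
    """
    sse, _, _ = _prediction_moments(fit)
    rmse = fit.y_scale * np.sqrt(sse / fit.stats_std.n_total)
    lo, hi = hdi(rmse, mass)
    return PosteriorSummary("rmse", float(rmse.mean()), lo, hi, rmse,
                            fit.rhat_max, fit.ess_min, not fit.converged)


def compute_r2(fit: Model1Fit, data: PairedDataset | None = None,
               mass: float = 0.95) -> PosteriorSummary:
    """Bayesian R^2: Var(yhat) / (Var(yhat) + Var(y - yhat)) per draw."""
    _, var_hat, var_res = _prediction_moments(fit)
    r2 = var_hat / (var_hat + var_res)
    lo, hi = hdi(r2, mass)
    return PosteriorSummary("r2", float(r2.mean()), lo, hi, r2,
                            fit.rhat_max, fit.ess_min, not fit.converged)


def compute_smb(fit: Model2Fit, scale_sd: float, mass: float = 0.95) -> PosteriorSummary:
    """Standardized mean bias: the source effect delta divided by ``scale_sd``.

    ``scale_sd`` is the SD of the criterion mean velocities of the analyzed
    dataset (exercise x device), making the bias unit-free.
    """
    if scale_sd <= 0:
        raise ValueError(f"scale_sd must be positive, got {scale_sd}")
    delta = fit.draws("slope")  # source coefficient, m/s
    smb = delta / scale_sd
    lo, hi = hdi(smb, mass)
    return PosteriorSummary("smb", float(smb.mean()), lo, hi, smb,
                            fit.rhat_max, fit.ess_min, not fit.converged)
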