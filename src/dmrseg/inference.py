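"""Posterior inference engines for the region-level Bayesian GLM.

The model per region, with N samples and N_p covariates:

    b       ~ Normal(0, sigma_b^2 I)                 (coefficients)
    sigma_E^2 ~ Gamma(alpha_E, beta_E)               (shape-rate; noise variance)
    Y       ~ Normal(D b, sigma_E^2 I)               (latent per-sample logits)
    theta   = sigmoid(Y)                             (methylation fraction)
    N_BS,C_i ~ Binomial(N_BS_i, p_i)
    p_i     = p("C"|5mC)_i * theta_i + p("C"|C)_i * (1 - theta_i)

Inference runs on the unconstrained vector phi = (b, u, Y) with
u = log sigma_E^2 (Jacobian included).  The log density and its gradient are
analytic and vectorized over arbitrary leading axes, with per-region data
broadcast along the second-to-last axis; this lets HMC run all chains (and
regions) in lock-step and lets ADVI fit thousands of regions in one
optimization.

Two engines are provided:

* :func:`sample_hmc` - Hamiltonian Monte Carlo with leapfrog integration,
  dual-averaging step-size adaptation and a diagonal mass matrix estimated
  during warmup (per chain x region).
* :func:`fit_advi` - mean-field Gaussian variational inference with
  reparameterization-trick gradients and Adam.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, gammaln

_P_EPS = 1e-12


@dataclass
class RegionBatchData:
    """Observed data for a batch of R regions sharing one design matrix.

    nbs, nc: (R, N) aggregated counts; p_meth, p_unmeth: (R, N) or (N,)
    conditional "C" probabilities; design: (N, Np).
    """

    nbs: np.ndarray
    nc: np.ndarray
    p_meth: np.ndarray
    p_unmeth: np.ndarray
    design: np.ndarray
    sigma_b2: float
    alpha_e: float
    beta_e: float

    def __post_init__(self) -> None:
        self.nbs = np.atleast_2d(np.asarray(self.nbs, dtype=float))
        self.nc = np.atleast_2d(np.asarray(self.nc, dtype=float))
        self.design = np.asarray(self.design, dtype=float)
        n = self.design.shape[0]
        self.p_meth = np.broadcast_to(np.asarray(self.p_meth, dtype=float), self.nbs.shape)
        self.p_unmeth = np.broadcast_to(np.asarray(self.p_unmeth, dtype=float), self.nbs.shape)
        if self.nbs.shape[1] != n:
            raise ValueError("count columns do not match design rows")

    @property
    def n_regions(self) -> int:
        return self.nbs.shape[0]

    @property
    def n_samples(self) -> int:
        return self.design.shape[0]

    @property
    def n_covariates(self) -> int:
        return self.design.shape[1]

    @property
    def dim(self) -> int:
        """Unconstrained dimension: Np coefficients + log-variance + N logits."""
        return self.n_covariates + 1 + self.n_samples


def unpack(phi: np.ndarray, data: RegionBatchData):
    npar = data.n_covariates
    b = phi[..., :npar]
    u = phi[..., npar]
    y = phi[..., npar + 1:]
    return b, u, y


def log_posterior_and_grad(phi: np.ndarray, data: RegionBatchData):
    """Unnormalised log posterior and gradient at phi, shape (..., R, D).

    Returns (logp of shape (..., R), grad of shape like phi).  Overflow from
    far-out-of-mass states (divergent leapfrog excursions) yields non-finite
    values that the samplers reject; the warnings are suppressed here.
    """
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        return _logp_grad_impl(phi, data)


def _logp_grad_impl(phi: np.ndarray, data: RegionBatchData):
    npar, n = data.n_covariates, data.n_samples
    b, u, y = unpack(phi, data)
    sig2 = np.exp(np.clip(u, -700.0, 700.0))
    m = b @ data.design.T  # (..., R, N)
    resid = y - m

    theta = expit(y)
    p = data.p_unmeth + (data.p_meth - data.p_unmeth) * theta
    p = np.clip(p, _P_EPS, 1.0 - _P_EPS)

    lp = (
        -0.5 * (b**2).sum(axis=-1) / data.sigma_b2
        + data.alpha_e * u - data.beta_e * sig2
        - 0.5 * n * u - 0.5 * (resid**2).sum(axis=-1) / sig2
        + (data.nc * np.log(p) + (data.nbs - data.nc) * np.log1p(-p)).sum(axis=-1)
    )

    grad = np.empty_like(phi)
    inv_sig2 = 1.0 / sig2
    grad[..., :npar] = (resid * inv_sig2[..., None]) @ data.design - b / data.sigma_b2
    grad[..., npar] = (data.alpha_e - data.beta_e * sig2 - 0.5 * n
                       + 0.5 * (resid**2).sum(axis=-1) * inv_sig2)
    dl_dp = data.nc / p - (data.nbs - data.nc) / (1.0 - p)
    dp_dy = (data.p_meth - data.p_unmeth) * theta * (1.0 - theta)
    grad[..., npar + 1:] = -resid * inv_sig2[..., None] + dl_dp * dp_dy
    return lp, grad


def log_prior_normalizer(data: RegionBatchData) -> float:
    """Constant terms dropped from :func:`log_posterior_and_grad` (prior parts)."""
    npar, n = data.n_covariates, data.n_samples
    return float(
        -0.5 * npar * np.log(2 * np.pi * data.sigma_b2)
        + data.alpha_e * np.log(data.beta_e) - gammaln(data.alpha_e)
        - 0.5 * n * np.log(2 * np.pi)
    )


# ---------------------------------------------------------------------------
# HMC

@dataclass
class HMCResult:
    """Posterior draws and diagnostics from :func:`sample_hmc`.

    draws: (n_samples, n_chains, R, D); divergences: (n_chains, R) counts;
    accept_rate: (n_chains, R); step_size: (n_chains, R).
    """

    draws: np.ndarray
    divergences: np.ndarray
    accept_rate: np.ndarray
    step_size: np.ndarray


def _leapfrog(phi, mom, eps, inv_mass, data, n_steps):
    lp, grad = log_posterior_and_grad(phi, data)
    for _ in range(n_steps):
        mom = mom + 0.5 * eps[..., None] * grad
        phi = phi + eps[..., None] * inv_mass * mom
        lp, grad = log_posterior_and_grad(phi, data)
        mom = mom + 0.5 * eps[..., None] * grad
    return phi, mom, lp


def sample_hmc(
    data: RegionBatchData,
    n_chains: int = 4,
    warmup: int = 1000,
    n_samples: int = 1000,
    seed: int | np.random.Generator = 0,
    max_leapfrog: int = 16,
    target_accept: float = 0.8,
    init_scale: float = 1.0,
) -> HMCResult:
    """HMC over all chains and regions in lock-step.

    Warmup runs in two phases: identity-mass with dual-averaging step-size
    adaptation, then a diagonal mass matrix estimated from the second half of
    phase one, with the step size re-adapted.  The number of leapfrog steps is
    jittered uniformly in [1, max_leapfrog] each iteration (shared across
    chains) to avoid periodic orbits.  Divergences are transitions with an
    energy error above 1000 after warmup.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    R, D = data.n_regions, data.dim
    shape = (n_chains, R, D)
    phi = rng.uniform(-init_scale, init_scale, size=shape)

    inv_mass = np.ones(shape)
    eps = np.full((n_chains, R), 0.1)
    divergences = np.zeros((n_chains, R), dtype=np.int64)
    accept_acc = np.zeros((n_chains, R))

    # dual-averaging state
    gamma_da, t0, kappa = 0.05, 10.0, 0.75

    def run(n_iter, adapt, store=None, collect=None, da_state=None):
        nonlocal phi, eps
        if da_state is None and adapt:
            da_state = {"mu": np.log(10.0 * eps), "log_eps_bar": np.zeros_like(eps),
                        "h_bar": np.zeros_like(eps), "m": 0}
        lp0, _ = log_posterior_and_grad(phi, data)
        for it in range(n_iter):
            n_steps = int(rng.integers(1, max_leapfrog + 1))
            mom = rng.standard_normal(shape) / np.sqrt(inv_mass)
            with np.errstate(over="ignore", invalid="ignore"):
                h0 = -lp0 + 0.5 * (mom**2 * inv_mass).sum(axis=-1)
                new_phi, new_mom, lp1 = _leapfrog(phi, mom, eps, inv_mass, data, n_steps)
                h1 = -lp1 + 0.5 * (new_mom**2 * inv_mass).sum(axis=-1)
                dh = h0 - h1
            dh = np.where(np.isnan(dh), -np.inf, dh)
            accept_prob = np.minimum(1.0, np.exp(np.minimum(dh, 0.0)))
            acc = rng.uniform(size=dh.shape) < accept_prob
            phi = np.where(acc[..., None], new_phi, phi)
            lp0 = np.where(acc, lp1, lp0)
            if store is not None:
                store.append(phi.copy())
                divergences[:] += (-dh > 1000.0)
                accept_acc[:] += accept_prob
            if collect is not None:
                collect.append(phi.copy())
            if adapt:
                da_state["m"] += 1
                m = da_state["m"]
                da_state["h_bar"] = ((1 - 1 / (m + t0)) * da_state["h_bar"]
                                     + (target_accept - accept_prob) / (m + t0))
                log_eps = da_state["mu"] - np.sqrt(m) / gamma_da * da_state["h_bar"]
                eta = m ** -kappa
                da_state["log_eps_bar"] = eta * log_eps + (1 - eta) * da_state["log_eps_bar"]
                eps = np.exp(log_eps)
        return da_state

    # phase A: step-size adaptation with identity mass
    half = max(warmup // 2, 1)
    collectA: list[np.ndarray] = []
    daA = run(half, adapt=True, collect=collectA)
    eps = np.exp(daA["log_eps_bar"])

    # mass from second half of phase A draws
    tail = np.asarray(collectA[len(collectA) // 2:])  # (n, C, R, D)
    if tail.shape[0] >= 10:
        var = tail.var(axis=0)
        n_est = tail.shape[0]
        w = n_est / (n_est + 5.0)  # shrink toward unit metric
        inv_mass = np.maximum(w * var + (1 - w), 1e-8)

    # phase B: re-adapt step size under the new metric
    daB = run(warmup - half, adapt=True,
              da_state={"mu": np.log(10.0 * eps), "log_eps_bar": np.log(eps),
                        "h_bar": np.zeros_like(eps), "m": 0})
    # freeze the averaged (not the last, noisy) step size for sampling
    eps = np.maximum(np.exp(daB["log_eps_bar"]), 1e-8)

    store: list[np.ndarray] = []
    run(n_samples, adapt=False, store=store)
    draws = np.asarray(store)
    return HMCResult(draws=draws, divergences=divergences,
                     accept_rate=accept_acc / n_samples, step_size=eps)


# ---------------------------------------------------------------------------
# ADVI

@dataclass
class ADVIResult:
    """Mean-field Gaussian fit: mu/sd per unconstrained parameter, plus trace."""

    mu: np.ndarray       # (R, D)
    sd: np.ndarray       # (R, D)
    elbo_trace: np.ndarray
    n_steps: int

    def sample(self, n_draws: int, rng: np.random.Generator) -> np.ndarray:
        """Draws from q, shape (n_draws, R, D)."""
        eps = rng.standard_normal((n_draws,) + self.mu.shape)
        return self.mu + self.sd * eps


def fit_advi(
    data: RegionBatchData,
    steps: int = 10000,
    mc_samples: int = 4,
    seed: int | np.random.Generator = 0,
    learning_rate: float = 0.1,
    rel_tol: float = 1e-4,
    check_every: int = 100,
) -> ADVIResult:
    """Mean-field ADVI over all regions at once.

    Maximizes the Monte-Carlo ELBO with reparameterized gradients and Adam.
    Stops early when the windowed mean ELBO changes by less than ``rel_tol``
    relative between consecutive windows of ``check_every`` steps.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    R, D = data.n_regions, data.dim
    mu = np.zeros((R, D))
    omega = np.full((R, D), -1.0)  # log sd

    b1, b2, adam_eps = 0.9, 0.999, 1e-8
    m_mu = np.zeros_like(mu); v_mu = np.zeros_like(mu)
    m_om = np.zeros_like(omega); v_om = np.zeros_like(omega)

    elbo_trace = []
    prev_window = -np.inf
    window_acc = 0.0
    n_done = 0
    for step in range(1, steps + 1):
        noise = rng.standard_normal((mc_samples, R, D))
        sd = np.exp(omega)
        z = mu + sd * noise
        lp, grad = log_posterior_and_grad(z, data)
        g_mu = grad.mean(axis=0)
        g_om = (grad * noise).mean(axis=0) * sd + 1.0  # +1 from the entropy term
        elbo = lp.mean(axis=0).sum() + (omega.sum() + 0.5 * D * R * np.log(2 * np.pi * np.e))

        # Adam ascent
        for g, mm, vv, par in ((g_mu, m_mu, v_mu, mu), (g_om, m_om, v_om, omega)):
            mm *= b1; mm += (1 - b1) * g
            vv *= b2; vv += (1 - b2) * g * g
            mhat = mm / (1 - b1**step)
            vhat = vv / (1 - b2**step)
            par += learning_rate * mhat / (np.sqrt(vhat) + adam_eps)

        elbo_trace.append(elbo)
        window_acc += elbo
        n_done = step
        if step % check_every == 0:
            cur = window_acc / check_every
            window_acc = 0.0
            if np.isfinite(prev_window):
                denom = max(abs(prev_window), 1.0)
                if abs(cur - prev_window) / denom < rel_tol:
                    break
            prev_window = cur

    return ADVIResult(mu=mu, sd=np.exp(omega),
                      elbo_trace=np.asarray(elbo_trace), n_steps=n_done)
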