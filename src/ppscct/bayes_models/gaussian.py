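"""Hierarchical Gaussian models for CCE-difference hypotheses.

The observation model is

    y_i = sum_e beta_e * x_e(i) + b_{p(i)} + eps_i,
    b_p ~ N(0, tau^2),  eps_i ~ N(0, sigma^2),

with independent normal priors on the effect coefficients determined by
a :class:`~ppscct.bayes_models.hypotheses.HypothesisSpec` and conjugate
inverse-gamma priors on the variance components.  All conditionals are
conjugate, so the posterior sampler is a plain Gibbs sweep.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hypotheses import HypothesisSpec

__all__ = [
    "RegressionProblem",
    "LinearModelParams",
    "GaussianModelView",
    "GaussianFamily",
    "PosteriorDraws",
    "problem_from_table",
    "loglik_linear",
    "sample_posterior_linear",
    "analytic_log_marginal_normal",
]

_LOG2PI = math.log(2.0 * math.pi)


@dataclass
class RegressionProblem:
    """Data and design columns shared by every hypothesis in a space."""

    y: np.ndarray
    columns: dict[str, np.ndarray]
    participant: np.ndarray | None = None  # integer codes 0..P-1
    sigma: float | None = None  # known residual SD; sampled when None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.columns = {k: np.asarray(v, dtype=float)
                        for k, v in self.columns.items()}
        for name, col in self.columns.items():
            if col.shape != self.y.shape:
                raise ValueError(f"column {name!r} has wrong length")
        if self.participant is not None:
            self.participant = np.asarray(self.participant, dtype=int)
            if self.participant.shape != self.y.shape:
                raise ValueError("participant index has wrong length")
        if self.sigma is not None and self.sigma <= 0:
            raise ValueError("known sigma must be positive")

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def n_participants(self) -> int:
        if self.participant is None or self.participant.size == 0:
            return 0
        return int(self.participant.max()) + 1


def problem_from_table(
    table: pd.DataFrame,
    effect_of: str = "condition",
    y_col: str = "d_ms",
    sigma: float | None = None,
) -> RegressionProblem:
    """Build a problem with one indicator column per level of ``effect_of``."""
    y = table[y_col].to_numpy(dtype=float)
    levels = sorted(map(str, table[effect_of].unique()))
    columns = {lev: (table[effect_of].astype(str) == lev).to_numpy(dtype=float)
               for lev in levels}
    part = None
    if "participant_id" in table.columns:
        part = pd.Categorical(table["participant_id"]).codes.astype(int)
    return RegressionProblem(y=y, columns=columns, participant=part,
                             sigma=sigma)


@dataclass(frozen=True)
class LinearModelParams:
    """Fixed parameter values for exact likelihood evaluation."""

    mu: dict[str, float]
    tau_ms: float
    sigma_ms: float

    def __post_init__(self) -> None:
        if self.tau_ms < 0:
            raise ValueError("tau_ms must be non-negative")
        if self.sigma_ms <= 0:
            raise ValueError("sigma_ms must be positive")


def loglik_linear(data: pd.DataFrame, params: LinearModelParams,
                  effect_of: str = "condition",
                  y_col: str = "d_ms") -> float:
    """Exact log joint density with participant effects integrated out.

    Per participant the marginal of the observation vector is multivariate
    normal with covariance ``sigma^2 I + tau^2 J``; the determinant and
    quadratic form are evaluated in closed form (rank-one update), so the
    result is deterministic — no Monte Carlo involved.
    """
    sigma2 = params.sigma_ms ** 2
    tau2 = params.tau_ms ** 2
    mu = data[effect_of].astype(str).map(params.mu)
    if mu.isna().any():
        missing = sorted(set(data[effect_of].astype(str)) - set(params.mu))
        raise ValueError(f"no mu for level(s) {missing}")
    resid = data[y_col].to_numpy(dtype=float) - mu.to_numpy(dtype=float)

    if "participant_id" in data.columns and tau2 > 0:
        groups = pd.Series(resid).groupby(
            data["participant_id"].to_numpy())
        total = 0.0
        for _, r in groups:
            r = r.to_numpy()
            n = r.size
            s = r.sum()
            logdet = n * math.log(sigma2) + math.log1p(n * tau2 / sigma2)
            quad = (r @ r) / sigma2 - tau2 * s * s / (
                sigma2 * (sigma2 + n * tau2))
            total += -0.5 * (n * _LOG2PI + logdet + quad)
        return float(total)
    n = resid.size
    return float(-0.5 * (n * _LOG2PI + n * math.log(sigma2)
                         + (resid @ resid) / sigma2))


def analytic_log_marginal_normal(
    data: np.ndarray,
    known_sigma: float,
    prior_mean: float,
    prior_sd: float,
) -> float:
    """Closed-form log marginal of N(mu, sigma^2) data under mu ~ N(m0, s0^2).

    The marginal of the data vector is multivariate normal with covariance
    ``sigma^2 I + s0^2 J``.  Zero observations give log marginal 0.
    """
    if known_sigma <= 0:
        raise ValueError("known_sigma must be positive")
    if prior_sd <= 0:
        raise ValueError("prior_sd must be positive")
    y = np.asarray(data, dtype=float)
    n = y.size
    if n == 0:
        return 0.0
    sigma2 = known_sigma ** 2
    s02 = prior_sd ** 2
    r = y - prior_mean
    s = r.sum()
    logdet = n * math.log(sigma2) + math.log1p(n * s02 / sigma2)
    quad = (r @ r) / sigma2 - s02 * s * s / (sigma2 * (sigma2 + n * s02))
    return float(-0.5 * (n * _LOG2PI + logdet + quad))


# ---------------------------------------------------------------------------
# Gibbs machinery


class GaussianModelView:
    """One hypothesis' free parameters against a shared problem."""

    def __init__(self, problem: RegressionProblem, hypothesis: HypothesisSpec):
        unknown = [e for e in hypothesis.effect_labels
                   if e not in problem.columns]
        if unknown:
            raise ValueError(
                f"hypothesis {hypothesis.id!r} references effect(s) "
                f"{unknown} absent from the problem design")
        self.problem = problem
        self.hypothesis = hypothesis
        self.names = hypothesis.free_effects
        self.p = len(self.names)
        if self.p:
            self.X = np.column_stack([problem.columns[e] for e in self.names])
        else:
            self.X = np.zeros((problem.n, 0))
        priors = [hypothesis.prior_for(e) for e in self.names]
        self.prior_mean = np.array([pr.mean for pr in priors])
        self.prior_sd = np.array([pr.sd for pr in priors])
        self._xtx = np.einsum("ij,ij->j", self.X, self.X)

    def init_beta(self, rng: np.random.Generator) -> np.ndarray:
        return self.prior_mean + self.prior_sd * rng.standard_normal(self.p)

    def predict(self, beta: np.ndarray) -> np.ndarray:
        return self.X @ beta if self.p else np.zeros(self.problem.n)

    def update_beta(self, beta: np.ndarray, shared: dict,
                    rng: np.random.Generator) -> np.ndarray:
        """One coordinate-wise conjugate Gibbs sweep over the coefficients."""
        beta = beta.copy()
        sigma2 = shared["sigma2"]
        resid = self.problem.y - self.predict(beta)
        if shared["b"] is not None:
            resid = resid - shared["b"][self.problem.participant]
        for j in range(self.p):
            xj = self.X[:, j]
            resid += xj * beta[j]
            prec = self._xtx[j] / sigma2 + 1.0 / self.prior_sd[j] ** 2
            mean = ((xj @ resid) / sigma2
                    + self.prior_mean[j] / self.prior_sd[j] ** 2) / prec
            beta[j] = mean + rng.standard_normal() / math.sqrt(prec)
            resid -= xj * beta[j]
        return beta

    def loglik(self, beta: np.ndarray, shared: dict) -> float:
        resid = self.problem.y - self.predict(beta)
        if shared["b"] is not None:
            resid = resid - shared["b"][self.problem.participant]
        n = self.problem.n
        if n == 0:
            return 0.0
        sigma2 = shared["sigma2"]
        return -0.5 * (n * (_LOG2PI + math.log(sigma2))
                       + (resid @ resid) / sigma2)

    def log_prior(self, beta: np.ndarray) -> float:
        if self.p == 0:
            return 0.0
        z = (beta - self.prior_mean) / self.prior_sd
        return float(-0.5 * (self.p * _LOG2PI + z @ z)
                     - np.log(self.prior_sd).sum())


@dataclass
class GaussianFamily:
    """A hypothesis space over one shared Gaussian regression problem.

    Shared (model-independent) state: participant intercepts ``b`` with
    variance ``tau2`` and residual variance ``sigma2``; both variances get
    conjugate inverse-gamma priors unless ``problem.sigma`` is known.
    """

    problem: RegressionProblem
    hypotheses: list[HypothesisSpec]
    sigma2_prior: tuple[float, float] = (2.0, 2500.0)  # IG(a, b), mean 50^2
    tau2_prior: tuple[float, float] = (2.0, 900.0)     # IG(a, b), mean 30^2
    models: list[GaussianModelView] = field(init=False)

    def __post_init__(self) -> None:
        if not self.hypotheses:
            raise ValueError("hypothesis list is empty")
        ids = [h.id for h in self.hypotheses]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate hypothesis ids")
        self.models = [GaussianModelView(self.problem, h)
                       for h in self.hypotheses]

    @property
    def model_ids(self) -> list[str]:
        return [h.id for h in self.hypotheses]

    def init_shared(self, rng: np.random.Generator) -> dict:
        P = self.problem.n_participants
        if self.problem.sigma is not None:
            sigma2 = self.problem.sigma ** 2
        elif self.problem.n > 1 and np.var(self.problem.y) > 0:
            sigma2 = float(np.var(self.problem.y))
        else:
            sigma2 = self.sigma2_prior[1] / (self.sigma2_prior[0] + 1.0)
        return {
            "b": np.zeros(P) if P else None,
            "tau2": self.tau2_prior[1] / (self.tau2_prior[0] + 1.0),
            "sigma2": sigma2,
        }

    def update_shared(self, model: GaussianModelView, beta: np.ndarray,
                      shared: dict, rng: np.random.Generator) -> None:
        y = self.problem.y
        part = self.problem.participant
        resid = y - model.predict(beta)

        if shared["b"] is not None:
            P = self.problem.n_participants
            sigma2, tau2 = shared["sigma2"], shared["tau2"]
            n_p = np.bincount(part, minlength=P).astype(float)
            s_p = np.bincount(part, weights=resid, minlength=P)
            prec = n_p / sigma2 + 1.0 / tau2
            mean = (s_p / sigma2) / prec
            shared["b"] = mean + rng.standard_normal(P) / np.sqrt(prec)
            a, b0 = self.tau2_prior
            shared["tau2"] = _inv_gamma(a + P / 2.0,
                                        b0 + 0.5 * shared["b"] @ shared["b"],
                                        rng)
            resid = resid - shared["b"][part]

        if self.problem.sigma is None:
            a, b0 = self.sigma2_prior
            shared["sigma2"] = _inv_gamma(a + self.problem.n / 2.0,
                                          b0 + 0.5 * resid @ resid, rng)


def _inv_gamma(shape: float, scale: float, rng: np.random.Generator) -> float:
    return float(scale / rng.gamma(shape))


# ---------------------------------------------------------------------------
# Single-model posterior sampling


@dataclass
class PosteriorDraws:
    """Chains from a single-model sampler.

    ``beta`` has shape (n_chains, n_samples, p); shared components are
    (n_chains, n_samples) each.  ``rhat`` holds split-R-hat per parameter
    (NaN with a single chain).
    """

    names: list[str]
    beta: np.ndarray
    shared: dict[str, np.ndarray]
    rhat: dict[str, float]

    def pooled(self, name: str) -> np.ndarray:
        if name in self.names:
            return self.beta[:, :, self.names.index(name)].reshape(-1)
        return self.shared[name].reshape(-1)

    @property
    def warnings(self) -> list[str]:
        return [f"split-R-hat {v:.3f} > 1.05 for {k}"
                for k, v in self.rhat.items()
                if np.isfinite(v) and v > 1.05]


def _run_single_model(family: GaussianFamily | "object", model,
                      config, rng: np.random.Generator):
    beta = model.init_beta(rng)
    shared = family.init_shared(rng)
    kept_beta = np.empty((config.n_samples, model.p))
    kept_shared = {"sigma2": np.empty(config.n_samples),
                   "tau2": np.empty(config.n_samples)}
    for it in range(config.burn_in + config.n_samples):
        beta = model.update_beta(beta, shared, rng)
        family.update_shared(model, beta, shared, rng)
        if it >= config.burn_in:
            k = it - config.burn_in
            kept_beta[k] = beta
            kept_shared["sigma2"][k] = shared["sigma2"]
            kept_shared["tau2"][k] = shared["tau2"]
    return kept_beta, kept_shared


def sample_posterior_linear(
    problem: RegressionProblem | pd.DataFrame,
    hypothesis: HypothesisSpec,
    config,
    seed: int,
    effect_of: str = "condition",
    y_col: str = "d_ms",
    **family_kwargs,
) -> PosteriorDraws:
    """Gibbs-sample one hypothesis' posterior.

    Accepts either a prepared :class:`RegressionProblem` or a tidy
    DataFrame (converted with :func:`problem_from_table`).  Returns
    ``config.n_chains`` chains of ``config.n_samples`` post-burn-in draws.
    Non-convergence (split-R-hat > 1.05) is reported in ``warnings``, not
    raised.
    """
    from .diagnostics import split_rhat

    if isinstance(problem, pd.DataFrame):
        problem = problem_from_table(problem, effect_of=effect_of, y_col=y_col)
    family = GaussianFamily(problem, [hypothesis], **family_kwargs)
    model = family.models[0]
    seeds = np.random.SeedSequence(seed).spawn(config.n_chains)
    betas, shareds = [], []
    for ss in seeds:
        b, s = _run_single_model(family, model, config, np.random.default_rng(ss))
        betas.append(b)
        shareds.append(s)
    beta = np.stack(betas)
    shared = {k: np.stack([s[k] for s in shareds]) for k in shareds[0]}
    rhat = {name: split_rhat(beta[:, :, j])
            for j, name in enumerate(model.names)}
    if problem.sigma is None:
        rhat["sigma2"] = split_rhat(shared["sigma2"])
    return PosteriorDraws(names=list(model.names), beta=beta,
                          shared=shared, rhat=rhat)
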