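"""Hierarchical cumulative-logit models for 1..K Likert scores.

Latent linear predictor eta_i = sum_e beta_e x_e(i) + b_{p(i)} with
fixed equidistant cut-points symmetric about 0; the probability of
category k is F(c_k - eta) - F(c_{k-1} - eta) with logistic F.  Effect
coefficients get normal priors from the hypothesis labels (typically
"high"/"low"); participant intercepts are normal with an inverse-gamma
variance.  Coefficients and intercepts are updated by random-walk
Metropolis within Gibbs; the intercept variance update is conjugate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gaussian import PosteriorDraws, _inv_gamma
from .hypotheses import HypothesisSpec

__all__ = [
    "OrdinalProblem",
    "LogitModelParams",
    "category_probabilities",
    "loglik_ordinal_logit",
    "OrdinalModelView",
    "OrdinalFamily",
    "ordinal_problem_from_table",
    "sample_posterior_logit",
]

_LOG2PI = math.log(2.0 * math.pi)


def _cutpoints(n_categories: int, spacing: float = 1.0) -> np.ndarray:
    return spacing * (np.arange(1, n_categories) - n_categories / 2.0)


def category_probabilities(eta, n_categories: int = 10,
                           spacing: float = 1.0) -> np.ndarray:
    """Probabilities over the K categories for linear predictor(s) eta.

    Returns shape ``(..., K)``; rows sum to 1 by construction (telescoping
    difference of the logistic CDF).
    """
    eta = np.atleast_1d(np.asarray(eta, dtype=float))
    cuts = _cutpoints(n_categories, spacing)
    z = cuts[None, :] - eta[..., None]
    cdf = 1.0 / (1.0 + np.exp(-z))
    full = np.concatenate([np.zeros(eta.shape + (1,)), cdf,
                           np.ones(eta.shape + (1,))], axis=-1)
    return np.diff(full, axis=-1)


@dataclass
class OrdinalProblem:
    """Likert scores with design columns and participant codes."""

    scores: np.ndarray  # integers in 1..n_categories
    columns: dict[str, np.ndarray]
    participant: np.ndarray | None = None
    n_categories: int = 10
    cut_spacing: float = 1.0

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=int)
        if self.scores.size and (
                self.scores.min() < 1 or self.scores.max() > self.n_categories):
            raise ValueError(
                f"scores must lie in 1..{self.n_categories}")
        self.columns = {k: np.asarray(v, dtype=float)
                        for k, v in self.columns.items()}
        for name, col in self.columns.items():
            if col.shape != self.scores.shape:
                raise ValueError(f"column {name!r} has wrong length")
        if self.participant is not None:
            self.participant = np.asarray(self.participant, dtype=int)
        cuts = _cutpoints(self.n_categories, self.cut_spacing)
        # per-observation bracketing cut-points, +-inf at the ends
        ext = np.concatenate([[-np.inf], cuts, [np.inf]])
        self._lo = ext[self.scores - 1]
        self._hi = ext[self.scores]

    @property
    def n(self) -> int:
        return self.scores.size

    @property
    def n_participants(self) -> int:
        if self.participant is None or self.participant.size == 0:
            return 0
        return int(self.participant.max()) + 1

    def log_prob(self, eta: np.ndarray) -> np.ndarray:
        """Per-observation log P(score | eta), numerically safe."""
        # P = F(hi - eta) - F(lo - eta) with logistic F; _sigmoid is
        # overflow-safe by construction
        p = _sigmoid(self._hi - eta) - _sigmoid(self._lo - eta)
        return np.log(np.clip(p, 1e-300, None))


def _sigmoid(z):
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def ordinal_problem_from_table(
    table: pd.DataFrame,
    cell_cols: tuple[str, ...] = ("condition", "time"),
    score_col: str = "score",
    n_categories: int = 10,
) -> OrdinalProblem:
    """One indicator column per cell, cells named 'level:level'."""
    scores = table[score_col].to_numpy(dtype=int)
    cell = table[list(cell_cols)].astype(str).agg(":".join, axis=1)
    columns = {lev: (cell == lev).to_numpy(dtype=float)
               for lev in sorted(cell.unique())}
    part = None
    if "participant_id" in table.columns:
        part = pd.Categorical(table["participant_id"]).codes.astype(int)
    return OrdinalProblem(scores=scores, columns=columns, participant=part,
                          n_categories=n_categories)


@dataclass(frozen=True)
class LogitModelParams:
    """Fixed coefficient values for likelihood evaluation."""

    coef: dict[str, float]
    intercept_sd: float = 0.0

    def __post_init__(self) -> None:
        for name, v in self.coef.items():
            if not np.isfinite(v):
                raise ValueError(f"non-finite coefficient {name!r}")
        if self.intercept_sd < 0:
            raise ValueError("intercept_sd must be non-negative")


def loglik_ordinal_logit(data: OrdinalProblem | pd.DataFrame,
                         params: LogitModelParams,
                         b: np.ndarray | None = None, **table_kwargs) -> float:
    """Deterministic cumulative-logit log likelihood at fixed parameters.

    ``b`` optionally supplies participant intercepts (defaults to 0).
    """
    if isinstance(data, pd.DataFrame):
        data = ordinal_problem_from_table(data, **table_kwargs)
    eta = np.zeros(data.n)
    for name, value in params.coef.items():
        if name not in data.columns:
            raise ValueError(f"unknown effect {name!r}")
        eta += value * data.columns[name]
    if b is not None and data.participant is not None:
        eta += np.asarray(b, dtype=float)[data.participant]
    return float(data.log_prob(eta).sum())


# ---------------------------------------------------------------------------
# MH-within-Gibbs machinery (same family interface as the Gaussian case)


class OrdinalModelView:
    # a few inner random-walk sweeps per Gibbs cycle keep the effective
    # autocorrelation of the MH coordinates comparable to the conjugate
    # updates of the Gaussian family
    n_sweeps = 3

    def __init__(self, problem: OrdinalProblem, hypothesis: HypothesisSpec,
                 step: float = 0.8):
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
        self.step = step
        if self.p:
            self.X = np.column_stack([problem.columns[e] for e in self.names])
        else:
            self.X = np.zeros((problem.n, 0))
        priors = [hypothesis.prior_for(e) for e in self.names]
        self.prior_mean = np.array([pr.mean for pr in priors])
        self.prior_sd = np.array([pr.sd for pr in priors])

    def init_beta(self, rng: np.random.Generator) -> np.ndarray:
        """Likelihood-informed start: invert the expected-score curve per
        cell.  Prior-mean starts leave conflicted cells (e.g. a "high"
        prior on floor-level data) many posterior SDs from the mode, and
        random-walk transit then dominates short-run diagnostics."""
        beta = self.prior_mean.copy()
        if self.problem.n == 0:
            return beta
        grid = np.linspace(-12.0, 12.0, 241)
        probs = category_probabilities(grid, self.problem.n_categories,
                                       self.problem.cut_spacing)
        escore = probs @ np.arange(1, self.problem.n_categories + 1)
        for j in range(self.p):
            mask = self.X[:, j] > 0
            if mask.any():
                m = float(self.problem.scores[mask].mean())
                beta[j] = float(np.interp(m, escore, grid))
        return beta

    def _eta(self, beta: np.ndarray, shared: dict) -> np.ndarray:
        eta = self.X @ beta if self.p else np.zeros(self.problem.n)
        if shared["b"] is not None:
            eta = eta + shared["b"][self.problem.participant]
        return eta

    def update_beta(self, beta: np.ndarray, shared: dict,
                    rng: np.random.Generator) -> np.ndarray:
        beta = beta.copy()
        eta = self._eta(beta, shared)
        ll = self.problem.log_prob(eta).sum()
        for _ in range(self.n_sweeps):
            for j in range(self.p):
                prop = beta[j] + self.step * rng.standard_normal()
                eta_prop = eta + (prop - beta[j]) * self.X[:, j]
                ll_prop = self.problem.log_prob(eta_prop).sum()
                lr = (ll_prop - ll
                      - 0.5 * ((prop - self.prior_mean[j]) ** 2
                               - (beta[j] - self.prior_mean[j]) ** 2)
                      / self.prior_sd[j] ** 2)
                if math.log(rng.random()) < lr:
                    beta[j], eta, ll = prop, eta_prop, ll_prop
        return beta

    def loglik(self, beta: np.ndarray, shared: dict) -> float:
        if self.problem.n == 0:
            return 0.0
        return float(self.problem.log_prob(self._eta(beta, shared)).sum())

    def log_prior(self, beta: np.ndarray) -> float:
        if self.p == 0:
            return 0.0
        z = (beta - self.prior_mean) / self.prior_sd
        return float(-0.5 * (self.p * _LOG2PI + z @ z)
                     - np.log(self.prior_sd).sum())


@dataclass
class OrdinalFamily:
    problem: OrdinalProblem
    hypotheses: list[HypothesisSpec]
    # IG(5, 4): mean intercept variance 1 on the logit scale with a light
    # tail — a heavy-tailed prior lets saturated floor/ceiling likelihoods
    # drift along the intercept/coefficient ridge and wrecks mixing
    tau2_prior: tuple[float, float] = (5.0, 4.0)
    b_step: float = 0.5
    models: list[OrdinalModelView] = field(init=False)

    def __post_init__(self) -> None:
        if not self.hypotheses:
            raise ValueError("hypothesis list is empty")
        self.models = [OrdinalModelView(self.problem, h)
                       for h in self.hypotheses]

    @property
    def model_ids(self) -> list[str]:
        return [h.id for h in self.hypotheses]

    def init_shared(self, rng: np.random.Generator) -> dict:
        P = self.problem.n_participants
        return {
            "b": np.zeros(P) if P else None,
            "tau2": self.tau2_prior[1] / (self.tau2_prior[0] + 1.0),
            # sigma2 kept for interface parity with the Gaussian family
            "sigma2": 1.0,
        }

    def update_shared(self, model: OrdinalModelView, beta: np.ndarray,
                      shared: dict, rng: np.random.Generator) -> None:
        if shared["b"] is None:
            return
        b = shared["b"]
        P = b.size
        part = self.problem.participant
        eta_fixed = model.X @ beta if model.p else np.zeros(self.problem.n)
        if not hasattr(self, "_by_part"):
            self._by_part = [np.nonzero(part == i)[0] for i in range(P)]
        tau2 = shared["tau2"]

        def _lp(idx: np.ndarray, eta_i: np.ndarray) -> float:
            p = (_sigmoid(self.problem._hi[idx] - eta_i)
                 - _sigmoid(self.problem._lo[idx] - eta_i))
            return float(np.log(np.clip(p, 1e-300, None)).sum())

        for i in range(P):
            idx = self._by_part[i]
            prop = b[i] + self.b_step * rng.standard_normal()
            lr = (_lp(idx, eta_fixed[idx] + prop)
                  - _lp(idx, eta_fixed[idx] + b[i])
                  - 0.5 * (prop ** 2 - b[i] ** 2) / tau2)
            if math.log(rng.random()) < lr:
                b[i] = prop

        # translation move along the coefficient/intercept ridge: shift
        # every beta by delta and every intercept by -delta.  The
        # likelihood is invariant, so the acceptance ratio involves only
        # the priors; this breaks the slow random-walk exploration of the
        # ridge that otherwise dominates mixing with few participants.
        if model.p:
            delta = self.b_step * rng.standard_normal()
            lr = (model.log_prior(beta + delta) - model.log_prior(beta)
                  - 0.5 * (((b - delta) ** 2).sum() - b @ b) / tau2)
            if math.log(rng.random()) < lr:
                beta += delta  # in place: the caller keeps this array
                b -= delta
        a, b0 = self.tau2_prior
        shared["tau2"] = _inv_gamma(a + P / 2.0, b0 + 0.5 * b @ b, rng)


def sample_posterior_logit(
    problem: OrdinalProblem | pd.DataFrame,
    hypothesis: HypothesisSpec,
    config,
    seed: int,
    **table_kwargs,
) -> PosteriorDraws:
    """MH-within-Gibbs chains for one ordinal-logit hypothesis."""
    from .diagnostics import split_rhat
    from .gaussian import _run_single_model

    if isinstance(problem, pd.DataFrame):
        problem = ordinal_problem_from_table(problem, **table_kwargs)
    family = OrdinalFamily(problem, [hypothesis])
    model = family.models[0]
    seeds = np.random.SeedSequence(seed).spawn(config.n_chains)
    betas, shareds = [], []
    for ss in seeds:
        b, s = _run_single_model(family, model, config,
                                 np.random.default_rng(ss))
        betas.append(b)
        shareds.append(s)
    beta = np.stack(betas)
    shared = {k: np.stack([s[k] for s in shareds]) for k in shareds[0]}
    rhat = {name: split_rhat(beta[:, :, j])
            for j, name in enumerate(model.names)}
    return PosteriorDraws(names=list(model.names), beta=beta,
                          shared=shared, rhat=rhat)
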