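"""Transdimensional product-space sampler for Bayesian model comparison.

The sampler carries the parameters of *every* hypothesis in the space at
all times, together with a categorical model index.  One Gibbs cycle:

1. update the active model's parameters against the likelihood;
2. update the shared (model-independent) nuisance state;
3. redraw every inactive model's parameters from its pseudo-prior
   (a proper linking density, here a moment-matched normal per
   coefficient fitted from single-model pilot runs);
4. draw the index from its full conditional, proportional to
   ``model_prior * likelihood * prior / pseudo-prior`` (evaluated in log
   space with max-subtraction).

Posterior model probabilities are the visit proportions of the index
over the kept draws, pooled across chains.  Correctness requires the
estimates to be insensitive to the pseudo-prior choice, which the test
suite checks explicitly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .bayes_models.diagnostics import split_rhat
from .bayes_models.gaussian import _run_single_model

__all__ = [
    "MCMCConfig",
    "PseudoPriorSpec",
    "ModelPosterior",
    "SavageDickeyResult",
    "fit_pseudo_priors",
    "run_product_space",
    "savage_dickey_bf",
    "mc_se",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class MCMCConfig:
    n_chains: int = 3
    burn_in: int = 1000
    n_samples: int = 10000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if self.burn_in < 0 or self.n_samples < 1:
            raise ValueError("invalid burn_in / n_samples")

    @property
    def total_kept(self) -> int:
        return self.n_chains * self.n_samples


@dataclass
class PseudoPriorSpec:
    """Per-model moment-matched normal linking densities.

    ``moments[model_id]`` is a pair of arrays (means, sds) over that
    model's free parameters, in the model's parameter order.
    """

    moments: dict[str, tuple[np.ndarray, np.ndarray]]
    provenance: str = "pilot-run posterior moments"

    def __post_init__(self) -> None:
        clean = {}
        for mid, (mean, sd) in self.moments.items():
            mean = np.asarray(mean, dtype=float)
            sd = np.asarray(sd, dtype=float)
            if np.any(sd <= 0):
                raise ValueError(
                    f"pseudo-prior sds for {mid!r} must be positive "
                    "(improper linking densities are not allowed)")
            clean[mid] = (mean, sd)
        self.moments = clean

    def draw(self, model_id: str, rng: np.random.Generator) -> np.ndarray:
        mean, sd = self.moments[model_id]
        return mean + sd * rng.standard_normal(mean.size)

    def logpdf(self, model_id: str, beta: np.ndarray) -> float:
        mean, sd = self.moments[model_id]
        if mean.size == 0:
            return 0.0
        z = (beta - mean) / sd
        return float(-0.5 * (mean.size * math.log(2 * math.pi) + z @ z)
                     - np.log(sd).sum())

    def inflated(self, factor: float) -> "PseudoPriorSpec":
        """A widened copy — used to test pseudo-prior insensitivity."""
        return PseudoPriorSpec(
            moments={mid: (m.copy(), s * factor)
                     for mid, (m, s) in self.moments.items()},
            provenance=f"{self.provenance} (sd x {factor})")


@dataclass
class ModelPosterior:
    """Visit counts, probabilities and diagnostics of a product-space run."""

    model_ids: list[str]
    visit_counts: dict[str, int]
    pi: dict[str, float]
    se: dict[str, float]
    rhat_index: float
    per_chain_counts: list[dict[str, int]]
    parameter_means: dict[str, dict[str, float]]
    warnings: list[str] = field(default_factory=list)
    config: dict = field(default_factory=dict)

    @property
    def best(self) -> list[str]:
        """Highest-probability hypothesis id(s); ties all reported."""
        top = max(self.pi.values())
        return [m for m in self.model_ids if self.pi[m] == top]

    def ranked(self) -> list[tuple[str, float]]:
        return sorted(self.pi.items(), key=lambda kv: (-kv[1], kv[0]))

    def to_dict(self) -> dict:
        return {
            "model_ids": self.model_ids,
            "visit_counts": self.visit_counts,
            "pi": self.pi,
            "mc_se": self.se,
            "rank": {m: r + 1 for r, (m, _) in enumerate(self.ranked())},
            "best": self.best,
            "rhat_index": self.rhat_index,
            "per_chain_counts": self.per_chain_counts,
            "parameter_means": self.parameter_means,
            "warnings": self.warnings,
            "config": self.config,
        }


class PilotConvergenceError(RuntimeError):
    pass


def fit_pseudo_priors(
    family,
    pilot_config: MCMCConfig | None = None,
    seed: int = 0,
    rhat_limit: float = 2.0,
    sd_floor: float = 1e-3,
) -> PseudoPriorSpec:
    """Fit normal pseudo-priors from per-model pilot runs.

    Each hypothesis is sampled on its own (no index moves) and the
    marginal mean/SD of each free coefficient becomes its linking
    density.  Pilot chains whose split-R-hat exceeds ``rhat_limit``
    raise :class:`PilotConvergenceError` with the offending values.
    The default limit is deliberately loose: pseudo-priors only need
    approximate moments (final estimates must be insensitive to them),
    so the check is for catastrophic failures, not borderline mixing.
    """
    pilot_config = pilot_config or MCMCConfig(n_chains=2, burn_in=200,
                                              n_samples=500)
    seeds = np.random.SeedSequence(seed).spawn(len(family.models))
    moments: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for model, ss in zip(family.models, seeds):
        chains = []
        for chain_ss in ss.spawn(pilot_config.n_chains):
            beta, _ = _run_single_model(family, model, pilot_config,
                                        np.random.default_rng(chain_ss))
            chains.append(beta)
        beta = np.stack(chains)  # (chains, draws, p)
        bad = {}
        for j, name in enumerate(model.names):
            r = split_rhat(beta[:, :, j])
            if np.isfinite(r) and r > rhat_limit:
                bad[name] = r
        if bad:
            msg = (f"pilot run for {model.hypothesis.id!r} did not "
                   "converge: "
                   + ", ".join(f"{k}: R-hat={v:.3f}"
                               for k, v in bad.items()))
            # split-R-hat is only a trustworthy signal with multiple
            # chains and a reasonable number of kept draws; on smaller
            # pilots an elevated value is mostly autocorrelation noise
            if pilot_config.n_chains >= 2 and pilot_config.n_samples >= 400:
                raise PilotConvergenceError(msg)
            log.warning("%s (short pilot: R-hat unreliable, continuing)",
                        msg)
        flat = beta.reshape(-1, model.p)
        mean = flat.mean(axis=0) if model.p else np.empty(0)
        sd = np.maximum(flat.std(axis=0, ddof=1), sd_floor) if model.p \
            else np.empty(0)
        moments[model.hypothesis.id] = (mean, sd)
    return PseudoPriorSpec(moments=moments)


def run_product_space(
    family,
    pseudo: PseudoPriorSpec,
    config: MCMCConfig,
    model_prior: np.ndarray | None = None,
    seed: int | None = None,
) -> ModelPosterior:
    """Run the product-space sampler and return visit-proportion estimates.

    ``family`` bundles the data, the hypothesis list and the within-model
    update kernels (Gaussian or ordinal).  ``model_prior`` defaults to
    uniform over hypotheses and must sum to 1.
    """
    models = family.models
    ids = family.model_ids
    M = len(models)
    missing = [mid for mid in ids if mid not in pseudo.moments]
    if missing:
        raise ValueError(f"pseudo-priors missing for models: {missing}")
    if model_prior is None:
        model_prior = np.full(M, 1.0 / M)
    model_prior = np.asarray(model_prior, dtype=float)
    if model_prior.shape != (M,) or np.any(model_prior < 0):
        raise ValueError("model_prior must be M non-negative probabilities")
    if not math.isclose(model_prior.sum(), 1.0, rel_tol=0, abs_tol=1e-9):
        raise ValueError("model_prior must sum to 1")
    log_model_prior = np.where(model_prior > 0,
                               np.log(np.clip(model_prior, 1e-300, None)),
                               -np.inf)

    if seed is None:
        seed = config.seed if config.seed is not None else 0
    chain_seeds = np.random.SeedSequence(seed).spawn(config.n_chains)

    index_chains = np.empty((config.n_chains, config.n_samples), dtype=int)
    param_sums = [np.zeros(m.p) for m in models]
    param_counts = np.zeros(M, dtype=int)

    for c, ss in enumerate(chain_seeds):
        rng = np.random.default_rng(ss)
        betas = [pseudo.draw(mid, rng) for mid in ids]
        shared = family.init_shared(rng)
        k = int(rng.integers(M))
        logw = np.empty(M)
        for it in range(config.burn_in + config.n_samples):
            betas[k] = models[k].update_beta(betas[k], shared, rng)
            family.update_shared(models[k], betas[k], shared, rng)
            for m in range(M):
                if m != k:
                    betas[m] = pseudo.draw(ids[m], rng)
                logw[m] = (log_model_prior[m]
                           + models[m].loglik(betas[m], shared)
                           + models[m].log_prior(betas[m])
                           - pseudo.logpdf(ids[m], betas[m]))
            w = np.exp(logw - logw.max())
            k = min(int(np.searchsorted(np.cumsum(w), rng.random() * w.sum(),
                                        side="right")), M - 1)
            if it >= config.burn_in:
                index_chains[c, it - config.burn_in] = k
                param_sums[k] += betas[k]
                param_counts[k] += 1

    flat = index_chains.reshape(-1)
    counts = np.bincount(flat, minlength=M)
    pi = counts / counts.sum()

    se = {}
    for m, mid in enumerate(ids):
        per_chain_var = []
        for c in range(config.n_chains):
            s = mc_se((index_chains[c] == m).astype(float),
                      min_batches=min(20, max(2, math.isqrt(
                          config.n_samples))))
            per_chain_var.append(s ** 2)
        se[mid] = float(np.sqrt(np.sum(per_chain_var)) / config.n_chains)

    rhat = split_rhat(index_chains.astype(float)) if config.n_chains > 1 \
        else float("nan")

    warnings = []
    if pi.max() > 0.99 and M > 1:
        warnings.append(
            f"index chain spent {100 * pi.max():.1f}% of kept draws in "
            f"{ids[int(pi.argmax())]!r}; verify with an independent Bayes "
            "factor (e.g. savage_dickey_bf) if unexpected")

    parameter_means = {}
    for m, mid in enumerate(ids):
        if param_counts[m] > 0:
            means = param_sums[m] / param_counts[m]
            parameter_means[mid] = {
                name: float(v) for name, v in zip(models[m].names, means)}
        else:
            parameter_means[mid] = {}

    return ModelPosterior(
        model_ids=list(ids),
        visit_counts={mid: int(counts[m]) for m, mid in enumerate(ids)},
        pi={mid: float(pi[m]) for m, mid in enumerate(ids)},
        se=se,
        rhat_index=rhat,
        per_chain_counts=[
            {mid: int((index_chains[c] == m).sum())
             for m, mid in enumerate(ids)}
            for c in range(config.n_chains)],
        parameter_means=parameter_means,
        warnings=warnings,
        config={"n_chains": config.n_chains, "burn_in": config.burn_in,
                "n_samples": config.n_samples, "seed": seed,
                "model_prior": model_prior.tolist()},
    )


@dataclass(frozen=True)
class SavageDickeyResult:
    bf: float  # BF in favour of the nested (point) hypothesis
    posterior_density: float
    prior_density: float
    n_near: int
    wide_interval: bool

    def __float__(self) -> float:
        return self.bf


def savage_dickey_bf(
    draws: np.ndarray,
    prior_density_at_point: float,
    test_point: float = 0.0,
) -> SavageDickeyResult:
    """Savage-Dickey Bayes factor for a point-nested comparison.

    ``draws`` are posterior samples of the tested coefficient from the
    encompassing model; the BF for the nested model is the ratio of the
    kernel-estimated posterior density to the prior density at
    ``test_point``.  A ``wide_interval`` flag is set when fewer than 50
    draws fall within one KDE bandwidth of the point.
    """
    from scipy.stats import gaussian_kde

    draws = np.asarray(draws, dtype=float).reshape(-1)
    if draws.size < 10:
        raise ValueError("need at least 10 posterior draws")
    if prior_density_at_point <= 0:
        raise ValueError("prior density at the point must be positive")
    if np.std(draws) == 0:
        post = math.inf if draws[0] == test_point else 0.0
        return SavageDickeyResult(post / prior_density_at_point, post,
                                  prior_density_at_point, 0, True)
    kde = gaussian_kde(draws)
    post = float(kde(test_point)[0])
    bw = float(kde.factor * draws.std(ddof=1))
    n_near = int(np.sum(np.abs(draws - test_point) <= bw))
    wide = n_near < 50
    if wide:
        log.warning("savage_dickey_bf: only %d draws within one bandwidth "
                    "of the test point; estimate is imprecise", n_near)
    return SavageDickeyResult(post / prior_density_at_point, post,
                              prior_density_at_point, n_near, wide)


def mc_se(series: np.ndarray, min_batches: int = 20) -> float:
    """Batch-means Monte Carlo standard error of a mean.

    Uses ~sqrt(n) batches; raises when fewer than ``min_batches`` batches
    are available.
    """
    x = np.asarray(series, dtype=float).reshape(-1)
    n = x.size
    n_batches = int(math.floor(math.sqrt(n)))
    if n_batches < min_batches:
        raise ValueError(
            f"series too short for batch means: {n_batches} batches "
            f"< {min_batches}")
    batch = n // n_batches
    means = x[: n_batches * batch].reshape(n_batches, batch).mean(axis=1)
    if np.allclose(means, means[0]):
        return 0.0
    return float(np.sqrt(means.var(ddof=1) / n_batches))
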