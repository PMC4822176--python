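"""Small MCMC diagnostics shared by the samplers."""

from __future__ import annotations

import numpy as np

__all__ = ["split_rhat"]


def split_rhat(chains: np.ndarray) -> float:
    """Split-R-hat of a (n_chains, n_draws) array.

    Each chain is split in half before computing the usual
    between/within variance ratio.  Returns 1.0 for a constant array and
    NaN when fewer than 4 draws per half-chain are available.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim == 1:
        chains = chains[None, :]
    n = chains.shape[1] // 2
    if n < 4:
        return float("nan")
    halves = np.concatenate([chains[:, :n], chains[:, n:2 * n]], axis=0)
    if np.allclose(halves, halves[0, 0]):
        return 1.0
    m = halves.shape[0]
    chain_means = halves.mean(axis=1)
    w = halves.var(axis=1, ddof=1).mean()
    b = n * chain_means.var(ddof=1)
    if w == 0:
        return float("inf")
    var_hat = (n - 1) / n * w + b / n
    return float(np.sqrt(var_hat / w))
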