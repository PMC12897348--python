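"""Sampling estimator of Shapley feature attributions.

Monte-Carlo (permutation) Shapley values for an arbitrary scalar model
``f(X) -> (n,)``: for each sampled permutation of the features, the
marginal contribution of feature j is the change in ``f`` when feature j
of a background row is switched to the explained row's value, holding the
features before j (in the permutation) already switched.  Averaging over
permutations and background rows converges to the exact Shapley value of
the interventional game.  Seeded, hence deterministic.
"""

from __future__ import annotations

import numpy as np


def sampling_shapley(
    f,
    X: np.ndarray,
    background: np.ndarray | None = None,
    n_permutations: int = 16,
    max_background: int = 32,
    seed: int = 0,
) -> np.ndarray:
    """Estimate Shapley values of ``f`` for every row of ``X``.

    Parameters
    ----------
    f : callable
        Maps an (m, d) array to (m,) model outputs.
    X : ndarray, shape (n, d)
        Rows to explain.
    background : ndarray, optional
        Reference distribution; defaults to ``X`` itself (subsampled to
        ``max_background`` rows).
    n_permutations : int
        Feature permutations sampled per explained row.
    seed : int
        RNG seed; fixed seed gives identical attributions.

    Returns
    -------
    ndarray, shape (n, d) of attributions; for each row they sum (in
    expectation) to ``f(x) - E[f(background)]``.
    """
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    rng = np.random.default_rng(seed)
    bg = X if background is None else np.asarray(background, dtype=float)
    if len(bg) > max_background:
        bg = bg[rng.choice(len(bg), size=max_background, replace=False)]
    phi = np.zeros((n, d))
    for _ in range(n_permutations):
        perm = rng.permutation(d)
        z = bg[rng.integers(len(bg), size=n)]  # one background row per explained row
        current = z.copy()
        prev = f(current)
        for j in perm:
            current[:, j] = X[:, j]
            cur = f(current)
            phi[:, j] += cur - prev
            prev = cur
    return phi / n_permutations
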