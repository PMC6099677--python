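"""Y-randomization: permutation-null robustness check for a fitted model.

The response vector is shuffled uniformly at random, the whole modelling
pipeline (column filter, block scaling, PLS, leave-one-out q²) is refit on
the shuffled activities, and the internal statistics are recorded per
iteration.  A model built on real structure–activity signal must collapse
under shuffling: the check passes when every randomized refit has
q² < 0.5 and r²_ncv < 0.6.

By default the original model's component count is reused for the
randomized refits; ``reselect_n=True`` re-optimizes N inside each
iteration instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .pls import PreprocessSpec, loo_q2, summarize_model

__all__ = ["RandomizationResult", "y_randomize"]


@dataclass
class RandomizationResult:
    iteration: int
    q2: float
    r2_ncv: float
    seed: int


def y_randomize(
    matrix,
    y: np.ndarray,
    n_components: int,
    n_iterations: int = 10,
    seed: int = 0,
    preprocess: PreprocessSpec | None = None,
    reselect_n: bool = False,
    permutation_hook: Callable[[int], np.ndarray] | None = None,
) -> tuple[list[RandomizationResult], bool]:
    """Shuffle y, refit, and report per-iteration q² / r²_ncv plus a verdict.

    ``permutation_hook(iteration) -> index array`` overrides the random
    permutation (used for testing, e.g. forcing the identity).  Per-iteration
    seeds are spawned deterministically from the master ``seed``.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    y = np.asarray(y, dtype=float)
    n = len(y)
    child_seeds = np.random.SeedSequence(seed).generate_state(n_iterations)
    results: list[RandomizationResult] = []
    for it in range(1, n_iterations + 1):
        iter_seed = int(child_seeds[it - 1] % (2**31))
        if permutation_hook is not None:
            perm = np.asarray(permutation_hook(it))
        else:
            perm = np.random.default_rng(iter_seed).permutation(n)
        y_shuffled = y[perm]
        cv = loo_q2(matrix, y_shuffled, max_components=n_components, preprocess=preprocess)
        N = cv["optimal_n"] if reselect_n else n_components
        q2 = float(cv["q2"][N - 1])
        summary = summarize_model(matrix, y_shuffled, N, preprocess=preprocess, q2=q2)
        results.append(
            RandomizationResult(iteration=it, q2=q2, r2_ncv=summary.r2_ncv, seed=iter_seed)
        )
    verdict = all(r.q2 < 0.5 and r.r2_ncv < 0.6 for r in results)
    return results, verdict
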