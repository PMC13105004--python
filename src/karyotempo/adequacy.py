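"""Posterior predictive model adequacy checks.

For a subsample of posterior draws, replicate tip datasets are simulated under
each draw's rate matrix (root state drawn from the root policy's distribution
given that draw), and the observed chromosome-count variance and entropy are
compared against their posterior predictive distributions. Extreme posterior
predictive p-values flag model inadequacy.

Entropy is Shannon entropy in nats over the empirical frequencies of the raw
(unbinned) counts; the base only rescales and the choice is recorded here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .likelihood import LikelihoodEngine, RootPolicy
from .mcmc import PosteriorSample
from .model import StateSpace, build_rate_matrix, build_state_space
from .simulate import simulate_counts
from .trees import TimeTree

__all__ = ["AdequacyResult", "tip_statistics", "posterior_predictive_check"]


@dataclass
class AdequacyResult:
    observed: dict[str, float]
    predictive: dict[str, np.ndarray]
    ppp: dict[str, float]  # one-sided, P(replicate >= observed), add-one estimator
    ppp_two_sided: dict[str, float]
    n_replicates: int

    def to_dict(self) -> dict:
        return {
            "observed": self.observed,
            "ppp": self.ppp,
            "ppp_two_sided": self.ppp_two_sided,
            "n_replicates": self.n_replicates,
        }


def tip_statistics(karyotypes: pd.DataFrame) -> dict[str, float]:
    """Sample variance (N−1 denominator) and Shannon entropy (nats) of counts."""
    counts = np.asarray(karyotypes["haploid_n"], dtype=float)
    if counts.size < 2:
        raise ValueError("need at least 2 species for tip statistics")
    _, freq = np.unique(counts, return_counts=True)
    p = freq / freq.sum()
    entropy = float(-(p * np.log(p)).sum())
    return {"variance": float(counts.var(ddof=1)), "entropy": entropy}


def posterior_predictive_check(
    tree: TimeTree,
    karyotypes: pd.DataFrame,
    sample: PosteriorSample,
    root: RootPolicy = RootPolicy(),
    n_replicates: int = 200,
    seed: int = 0,
    *,
    space: StateSpace | None = None,
) -> AdequacyResult:
    """Simulate replicate datasets under posterior draws and locate the data.

    Draws are subsampled without replacement (``n_replicates`` must not exceed
    the number of retained draws). For each draw, the root state is sampled
    from the root policy's distribution under that draw — FitzJohn weights are
    recomputed per draw, propagating root uncertainty — and tip counts are
    simulated by the exact Gillespie sampler. The posterior predictive p-value
    uses the add-one estimator ``(#{rep >= obs} + 1) / (n + 1)``, which can
    never return 0 or exceed 1.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if n_replicates > sample.n_draws:
        raise ValueError(
            f"n_replicates ({n_replicates}) exceeds posterior draws ({sample.n_draws})"
        )
    space = space or build_state_space(karyotypes)
    observed = tip_statistics(karyotypes)
    if np.ptp(sample.draws, axis=0).max() == 0:
        warnings.warn("degenerate posterior (all draws identical); proceeding")
    rng = np.random.default_rng(seed)
    chosen = np.sort(rng.choice(sample.n_draws, size=n_replicates, replace=False))
    engine = LikelihoodEngine(tree, karyotypes, space, root)
    stats = {"variance": np.empty(n_replicates), "entropy": np.empty(n_replicates)}
    for r, i in enumerate(chosen):
        params = sample.rate_params(int(i))
        root_state = _draw_root_state(engine, params, root, space, rng)
        rep_seed = int(rng.integers(2**31 - 1))
        rep, _ = simulate_counts(tree, space, params, root_state, rep_seed)
        s = tip_statistics(rep)
        stats["variance"][r] = s["variance"]
        stats["entropy"][r] = s["entropy"]
    ppp = {}
    two_sided = {}
    for name, vec in stats.items():
        p = (np.sum(vec >= observed[name]) + 1.0) / (n_replicates + 1.0)
        ppp[name] = float(p)
        two_sided[name] = float(2.0 * min(p, 1.0 - p))
    return AdequacyResult(
        observed=observed,
        predictive=stats,
        ppp=ppp,
        ppp_two_sided=two_sided,
        n_replicates=n_replicates,
    )


def _draw_root_state(
    engine: LikelihoodEngine,
    params,
    root: RootPolicy,
    space: StateSpace,
    rng: np.random.Generator,
) -> int:
    if root.mode == "fixed":
        return int(root.state)
    if root.mode == "uniform":
        return int(space.count(int(rng.integers(space.size))))
    Q = build_rate_matrix(space, params)
    L, _ = engine.root_conditionals(Q)
    total = L.sum()
    if total <= 0:  # data impossible under this draw; fall back to uniform
        return int(space.count(int(rng.integers(space.size))))
    return int(space.count(int(rng.choice(space.size, p=L / total))))
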