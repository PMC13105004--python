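"""The four-rate continuous-time Markov model of haploid chromosome number.

States are haploid counts ``n`` on ``[n_min, n_max]``. Four event types move
between them: single-chromosome gain (``n -> n+1``, ascending dysploidy), loss
(``n -> n-1``, descending dysploidy), polyploidy (``n -> 2n``, whole-genome
duplication) and demiploidy (``n -> 1.5n``, e.g. via a triploid bridge; odd
counts split half/half between floor and ceil of ``1.5n``). Rates are
state-independent constants, expressed per unit of tree depth.

Saltational targets beyond ``n_max`` are truncated onto ``n_max`` rather than
dropped, so generator rows always sum to zero and no probability mass leaks.
A target that coincides with the source state (only possible at the boundary)
is a null event and contributes nothing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.linalg import expm

logger = logging.getLogger(__name__)

__all__ = [
    "StateSpace",
    "RateParams",
    "PARAM_NAMES",
    "build_state_space",
    "build_rate_matrix",
    "transition_matrix",
    "transition_matrices",
]

PARAM_NAMES = ("gain", "loss", "poly", "demi")


@dataclass(frozen=True)
class StateSpace:
    """Contiguous haploid-count state space ``[n_min, n_max]``."""

    n_min: int
    n_max: int

    def __post_init__(self) -> None:
        if self.n_min < 1:
            raise ValueError("n_min must be >= 1 (a haploid count cannot be 0)")
        if self.n_max < self.n_min:
            raise ValueError("n_max must be >= n_min")

    @property
    def size(self) -> int:
        return self.n_max - self.n_min + 1

    @property
    def counts(self) -> np.ndarray:
        return np.arange(self.n_min, self.n_max + 1)

    def index(self, count: int) -> int:
        if not (self.n_min <= count <= self.n_max):
            raise ValueError(f"count {count} outside state space [{self.n_min}, {self.n_max}]")
        return int(count) - self.n_min

    def count(self, index: int) -> int:
        return self.n_min + int(index)


@dataclass(frozen=True)
class RateParams:
    """Event rates, in events per unit tree depth (unless stated otherwise)."""

    gain: float = 0.0
    loss: float = 0.0
    poly: float = 0.0
    demi: float = 0.0
    units: str = "per_unit_tree"

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"rate {name}={v} must be finite and >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.gain, self.loss, self.poly, self.demi])

    def to_dict(self) -> dict[str, float]:
        d = {name: float(getattr(self, name)) for name in PARAM_NAMES}
        d["units"] = self.units
        return d

    def with_rates(self, **kwargs: float) -> "RateParams":
        return replace(self, **kwargs)


def build_state_space(karyotypes, padding_factor: float = 2.0) -> StateSpace:
    """State space covering observed counts with head-room for polyploidy.

    ``n_min`` is fixed at 1; ``n_max = ceil(padding_factor * max observed)``.
    The default padding of 2 keeps one round of whole-genome duplication from
    the largest observed count inside the space, making boundary truncation
    rare for realistic data.
    """
    counts = np.asarray(karyotypes["haploid_n"] if hasattr(karyotypes, "columns") else karyotypes)
    counts = counts[~np.isnan(counts.astype(float))] if counts.dtype.kind == "f" else counts
    if counts.size == 0:
        raise ValueError("cannot build a state space from an empty karyotype table")
    n_max = int(math.ceil(padding_factor * int(counts.max())))
    return StateSpace(n_min=1, n_max=max(n_max, int(counts.max())))


def build_rate_matrix(space: StateSpace, params: RateParams) -> np.ndarray:
    """Dense generator matrix Q over the state space.

    Off-diagonals hold event rates (rates to a shared target accumulate); the
    diagonal is minus the row sum, so rows sum to zero exactly. Demiploidy from
    an odd count ``n`` places ``demi/2`` on each of ``floor(1.5n)`` and
    ``ceil(1.5n)``.
    """
    S = space.size
    Q = np.zeros((S, S))
    for i, n in enumerate(space.counts):
        targets: list[tuple[int, float]] = []
        if n + 1 <= space.n_max:
            targets.append((n + 1, params.gain))
        if n - 1 >= space.n_min:
            targets.append((n - 1, params.loss))
        targets.append((min(2 * n, space.n_max), params.poly))
        if n % 2 == 0:
            targets.append((min(3 * n // 2, space.n_max), params.demi))
        else:
            targets.append((min((3 * n - 1) // 2, space.n_max), params.demi / 2.0))
            targets.append((min((3 * n + 1) // 2, space.n_max), params.demi / 2.0))
        for m, rate in targets:
            if m != n and rate > 0:
                Q[i, space.index(m)] += rate
    Q[np.diag_indices(S)] = -Q.sum(axis=1)
    return Q


def transition_matrix(Q: np.ndarray, t: float) -> np.ndarray:
    """Finite-time transition probabilities ``P(t) = exp(Qt)``.

    Entries are clipped to [0, 1] after exponentiation (deviations beyond 1e-9
    are logged); rows sum to 1 within 1e-9 for any valid generator.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    P = expm(Q * t)
    if not np.all(np.isfinite(P)):
        raise FloatingPointError(f"non-finite transition probabilities at t={t}")
    lo, hi = P.min(), P.max()
    if lo < -1e-9 or hi > 1 + 1e-9:
        logger.warning("transition probabilities outside [0,1] by %.3g at t=%g", max(-lo, hi - 1), t)
    return np.clip(P, 0.0, 1.0)


def transition_matrices(Q: np.ndarray, ts: np.ndarray) -> np.ndarray:
    """Batch ``P(t)`` for many branch lengths sharing one generator.

    Computed by uniformization: with ``Λ = max_i (-Q_ii)`` the matrix
    ``A = I + Q/Λ`` is stochastic and ``P(t) = Σ_k Pois(k; Λt) A^k``. Every
    term is non-negative, so the sum is unconditionally stable (no
    cancellation, unlike eigendecomposition for skewed generators), and the
    truncation point is chosen so the neglected Poisson tail is below 1e-13
    at the largest branch length. Falls back to scaling-and-squaring ``expm``
    per branch when ``Λ·t_max`` is too large for the series to pay off.
    Results agree with per-branch ``expm`` to tight tolerance.
    """
    ts = np.asarray(ts, dtype=float)
    S = Q.shape[0]
    lam = float(np.max(-np.diag(Q)))
    tmax = float(ts.max()) if ts.size else 0.0
    mu = lam * tmax
    if lam == 0.0:
        return np.broadcast_to(np.eye(S), (ts.size, S, S)).copy()
    if mu > 500.0:
        out = np.empty((ts.size, S, S))
        for k, t in enumerate(ts):
            out[k] = transition_matrix(Q, float(t))
        return out
    K = int(math.ceil(mu + 10.0 * math.sqrt(mu + 1.0) + 10.0))
    powers = np.empty((K + 1, S * S))
    A = np.eye(S) + Q / lam
    acc = np.eye(S)
    powers[0] = acc.ravel()
    for k in range(1, K + 1):
        acc = acc @ A
        powers[k] = acc.ravel()
    # Poisson weights in log space; lt == 0 rows collapse to the identity term
    lt = lam * ts
    ks = np.arange(K + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        logw = -lt[:, None] + ks[None, :] * np.log(lt)[:, None] - _LGAMMA_K(K)
    W = np.exp(logw)
    W[lt == 0.0] = 0.0
    W[lt == 0.0, 0] = 1.0
    P = (W @ powers).reshape(ts.size, S, S)
    return np.clip(P, 0.0, 1.0, out=P)


def _LGAMMA_K(K: int) -> np.ndarray:
    from scipy.special import gammaln

    return gammaln(np.arange(K + 1) + 1.0)
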