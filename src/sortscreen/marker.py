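"""Latent-marker bin model: Gaussian bin masses and the Dirichlet-multinomial.

A FACS sort partitions a continuous marker into ``J`` ordered gates
("bins").  Under the null, the marker is standard normal and the gates are
described by cumulative probabilities ``t = (t_0=0, t_1, ..., t_J=1)``.  A
perturbation with effect size ``beta`` (in marker standard deviations)
shifts the marker; the probability mass it places in bin ``j`` is

    q_j = Pr( Phi^-1(t_{j-1}) < Z - beta < Phi^-1(t_j) ),   Z ~ N(0, 1)

so a positive ``beta`` moves mass toward the LOW bins (bin 1 is the lowest
marker gate).  The sign is a labelling convention; the simulator and the
inference model share it, so effect signs are consistent end to end.

Sequencing counts across bins are modelled as Dirichlet-multinomial with
total concentration ``phi`` (small ``phi`` = overdispersed relative to the
multinomial; ``phi -> inf`` recovers it).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, ndtr, ndtri

__all__ = [
    "BinScheme",
    "bin_masses",
    "bin_masses_vec",
    "cutpoints_from_masses",
    "dirmult_logpmf",
    "dirmult_sample",
]

_MASS_TOL = 1e-8


@dataclass(frozen=True)
class BinScheme:
    """Ordered FACS gates as cumulative null-marker probabilities.

    ``t`` has length ``J + 1`` with ``t[0] = 0``, ``t[J] = 1``, strictly
    increasing.  ``t[j]`` is the null probability of falling at or below
    the upper boundary of bin ``j``.
    """

    t: np.ndarray = field(repr=True)

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        if t.ndim != 1 or t.size < 3:
            raise ValueError("bin scheme needs J >= 2, i.e. at least 3 cumulative points")
        if abs(t[0]) > _MASS_TOL or abs(t[-1] - 1.0) > _MASS_TOL:
            raise ValueError(f"cumulative masses must start at 0 and end at 1, got {t[0]}..{t[-1]}")
        if np.any(np.diff(t) <= 0):
            raise ValueError("cumulative masses must be strictly increasing")
        t = t.copy()
        t[0], t[-1] = 0.0, 1.0
        t.setflags(write=False)
        object.__setattr__(self, "t", t)

    @property
    def n_bins(self) -> int:
        return self.t.size - 1

    @property
    def masses(self) -> np.ndarray:
        """Per-bin null masses (differences of ``t``)."""
        return np.diff(self.t)

    def cutpoints(self) -> np.ndarray:
        """Gate boundaries on the marker scale: Phi^-1(t), with +-inf ends."""
        with np.errstate(divide="ignore"):
            return ndtri(self.t)


def bin_masses(scheme: BinScheme, beta: float) -> np.ndarray:
    """Probability mass a guide with effect ``beta`` places in each bin.

    Returns a length-``J`` vector summing to 1.  ``beta`` is in marker-SD
    units; ``beta = 0`` recovers the null masses exactly.
    """
    beta = float(beta)
    if not np.isfinite(beta):
        raise ValueError(f"effect size must be finite, got {beta}")
    return bin_masses_vec(scheme.t, np.array([beta]))[0]


def bin_masses_vec(t: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Vectorized :func:`bin_masses`: shape ``beta.shape + (J,)``.

    ``t`` is the cumulative vector of a valid :class:`BinScheme`; no
    validation is done here (hot path).
    """
    beta = np.asarray(beta, dtype=float)
    with np.errstate(divide="ignore"):
        z = ndtri(t)  # -inf ... +inf
    # ndtr handles +-inf exactly (0 and 1); shifting inf by finite beta is safe.
    cdf = ndtr(z + beta[..., None])
    q = np.diff(cdf, axis=-1)
    # clip tiny negative round-off from differencing
    np.clip(q, 0.0, 1.0, out=q)
    return q


def cutpoints_from_masses(w: np.ndarray) -> BinScheme:
    """Build a :class:`BinScheme` from per-bin masses (inverse of ``masses``)."""
    w = np.asarray(w, dtype=float)
    if w.ndim != 1 or w.size < 2:
        raise ValueError("need at least 2 bin masses")
    if np.any(w < 0):
        raise ValueError("bin masses must be nonnegative")
    if abs(w.sum() - 1.0) > _MASS_TOL:
        raise ValueError(f"bin masses must sum to 1, got {w.sum()!r}")
    t = np.concatenate([[0.0], np.cumsum(w / w.sum())])
    t[-1] = 1.0
    return BinScheme(t)


def dirmult_logpmf(counts: np.ndarray, total: int, phi: float, q: np.ndarray) -> float:
    """Log pmf of ``counts ~ DirMult(total, phi * q)``.

    ``phi`` is the total concentration; ``q`` the mean bin-mass vector.
    Bins with ``q_j == 0`` are allowed iff their count is zero (they
    contribute probability one); a positive count there gives ``-inf``.
    """
    counts = np.asarray(counts)
    if counts.ndim != 1:
        raise ValueError("counts must be a vector")
    if np.any(counts < 0) or counts.sum() != total:
        raise ValueError(f"counts must be nonnegative and sum to total={total}")
    if not (phi > 0):
        raise ValueError("dispersion phi must be positive")
    return float(dirmult_logpmf_vec(counts[None, :], phi * np.asarray(q, float)[None, :])[0])


def dirmult_logpmf_vec(counts: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Row-wise Dirichlet-multinomial log pmf (hot path, minimal checks).

    ``counts``: integer array ``(..., J)``; ``alpha``: concentrations
    broadcastable to the same shape.  Zero concentrations are treated as
    structural zeros (count must be 0, else ``-inf``).
    """
    counts = np.asarray(counts, dtype=float)
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), counts.shape)
    total = counts.sum(axis=-1)
    a0 = alpha.sum(axis=-1)
    pos = alpha > 0
    safe_a = np.where(pos, alpha, 1.0)
    term = np.where(
        pos,
        gammaln(counts + safe_a) - gammaln(safe_a) - gammaln(counts + 1.0),
        np.where(counts > 0, -np.inf, 0.0),
    )
    return gammaln(total + 1.0) + gammaln(a0) - gammaln(total + a0) + term.sum(axis=-1)


def dirmult_sample(total: int, phi: float, q: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw one Dirichlet-multinomial vector with mean ``total * q``."""
    if total < 0:
        raise ValueError("total must be nonnegative")
    q = np.asarray(q, dtype=float)
    if total == 0:
        return np.zeros(q.size, dtype=np.int64)
    alpha = phi * q
    # gamma(0) == 0 handles structural-zero bins; renormalise the rest
    g = rng.gamma(np.maximum(alpha, 0.0))
    s = g.sum()
    if s == 0:  # all-zero concentrations: degenerate, put everything in argmax q
        p = np.zeros_like(q)
        p[np.argmax(q)] = 1.0
    else:
        p = g / s
    return rng.multinomial(total, p)
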