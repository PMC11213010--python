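"""Joint probability model for gene-level screen inference.

Hierarchy (one screen, genes g, guides h, replicates n):

    psi_g | pi            ~ Bernoulli(pi)                 gene included?
    mu_g  | psi_g, sigma2 ~ psi_g N(0, sigma2) + (1 - psi_g) delta_0
    beta_h| mu_g, tau2    ~ N(mu_{g(h)}, tau2)            guide effect
    B_nh  | c_nh, ...     ~ DirMult(c_nh, phi_n q(t_n, beta_h))

Control guides are clamped at beta = 0 and carry no effect-prior term;
they pin down the null bin masses t_n and the dispersions phi_n.  The
per-replicate bin-mass simplex w_n (cutpoints t_n are derived, never
sampled directly, so monotonicity holds by construction) gets a
Dirichlet(alpha_t * w0) prior; because t_n is learned per replicate it
absorbs both drifting FACS gates and unequal per-bin collection or
sequencing depth.

Hyperprior defaults are weakly informative: half-Cauchy on the slab sd
and the guide-around-gene sd, Beta(1, 9) on the inclusion proportion
(screens typically have ~10% true hits), Gamma on the count dispersions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .marker import BinScheme, bin_masses_vec, dirmult_logpmf_vec
from .screen_io import BinCountTable, GuideLibrary

__all__ = ["Hyperparameters", "ModelState", "log_joint", "sample_prior", "init_bins_from_controls"]


@dataclass(frozen=True)
class Hyperparameters:
    """Priors of the hierarchy; all fields overridable, all strictly positive.

    sigma_scale / tau_scale: half-Cauchy scales for the slab sd sigma and
    the guide-around-gene sd tau_beta.  pi_a, pi_b: Beta prior on the
    inclusion proportion pi.  alpha_t: total Dirichlet concentration for
    the bin-mass simplex (defaults to J at construction of the model);
    w0: base bin masses (None = equal).  phi_shape / phi_rate: Gamma prior
    on the replicate dispersions (defaults give mean 100).  credible_q:
    level for calling, i.e. (1 - q) credible intervals and PIP > 1 - q.
    """

    sigma_scale: float = 1.0
    tau_scale: float = 0.5
    pi_a: float = 1.0
    pi_b: float = 9.0
    alpha_t: float | None = None
    w0: np.ndarray | None = None
    phi_shape: float = 2.0
    phi_rate: float = 0.02
    credible_q: float = 0.10

    def __post_init__(self) -> None:
        for name in ("sigma_scale", "tau_scale", "pi_b", "phi_shape", "phi_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.pi_a < 0:  # pi_a == 0 means a point mass at pi = 0 (no inclusions)
            raise ValueError("pi_a must be nonnegative")
        if not 0 < self.credible_q < 1:
            raise ValueError("credible_q must be in (0, 1)")
        if self.w0 is not None:
            w0 = np.asarray(self.w0, dtype=float)
            if np.any(w0 <= 0) or abs(w0.sum() - 1.0) > 1e-8:
                raise ValueError("w0 must be positive and sum to 1")
            object.__setattr__(self, "w0", w0)

    def resolved(self, n_bins: int) -> "Hyperparameters":
        """Fill in J-dependent defaults (alpha_t = J, equal w0)."""
        out = self
        if out.alpha_t is None:
            out = replace(out, alpha_t=float(n_bins))
        if out.w0 is None:
            out = replace(out, w0=np.full(n_bins, 1.0 / n_bins))
        elif out.w0.size != n_bins:
            raise ValueError(f"w0 has {out.w0.size} entries for {n_bins} bins")
        return out


@dataclass
class ModelState:
    """All latent variables of one screen fit.

    ``psi``: 0/1 inclusion per gene.  ``mu``: gene effects (0 when
    excluded).  ``beta``: per-guide effects, identically 0 for controls.
    ``w``: per-replicate bin-mass simplex, shape (N, J).  ``phi``:
    per-replicate dispersions.  ``sigma``/``tau``: slab and guide sds.
    ``pi``: inclusion proportion.
    """

    psi: np.ndarray
    mu: np.ndarray
    beta: np.ndarray
    w: np.ndarray
    phi: np.ndarray
    sigma: float
    tau: float
    pi: float

    def validate(self, library: GuideLibrary) -> None:
        psi = np.asarray(self.psi)
        if not np.isin(psi, (0, 1)).all():
            raise ValueError("psi must be 0/1")
        if np.any((psi == 0) & (np.asarray(self.mu) != 0.0)):
            raise ValueError("mu must be exactly 0 for excluded genes")
        if np.any(np.asarray(self.beta)[library.is_control] != 0.0):
            raise ValueError("control guides must have beta = 0")
        if np.any(np.asarray(self.phi) <= 0):
            raise ValueError("phi must be positive")
        if not (self.sigma > 0 and self.tau > 0):
            raise ValueError("sigma and tau must be positive")
        if not 0.0 <= self.pi <= 1.0:
            raise ValueError("pi must lie in [0, 1]")
        w = np.asarray(self.w)
        if np.any(w <= 0) or np.any(np.abs(w.sum(axis=1) - 1.0) > 1e-8):
            raise ValueError("each replicate's bin masses must be positive and sum to 1")

    def bin_schemes(self) -> list[BinScheme]:
        return [BinScheme(np.concatenate([[0.0], np.cumsum(wn / wn.sum())[:-1], [1.0]]))
                for wn in self.w]


def _cumulative(w: np.ndarray) -> np.ndarray:
    """(N, J) masses -> (N, J+1) cumulative with exact 0/1 ends."""
    w = np.atleast_2d(w)
    t = np.concatenate([np.zeros((w.shape[0], 1)), np.cumsum(w, axis=1)], axis=1)
    t[:, -1] = 1.0
    return t


def loglik_all(counts: np.ndarray, w: np.ndarray, phi: np.ndarray,
               beta: np.ndarray) -> np.ndarray:
    """Per-(replicate, guide) DirMult log likelihood matrix, shape (N, H)."""
    t = _cumulative(w)
    out = np.empty(counts.shape[:2])
    for n in range(counts.shape[0]):
        q = bin_masses_vec(t[n], beta)            # (H, J)
        out[n] = dirmult_logpmf_vec(counts[n], phi[n] * q)
    return out


def _log_half_cauchy(x: float, scale: float) -> float:
    if x <= 0:
        return -np.inf
    return np.log(2.0) + stats.cauchy.logpdf(x, scale=scale)


def log_joint(state: ModelState, data: BinCountTable, library: GuideLibrary,
              hyper: Hyperparameters) -> float:
    """Full log joint density of (state, data); error on malformed state.

    -inf is reserved for valid states of zero density (e.g. psi = 1 under
    pi = 0); structurally invalid states raise instead.
    """
    state.validate(library)
    hyper = hyper.resolved(data.n_bins)
    gidx, genes = library.gene_index()
    if state.psi.size != len(genes) or state.beta.size != data.n_guides:
        raise ValueError("state dimensions do not match data/library")

    ll = float(loglik_all(data.counts, state.w, state.phi, state.beta).sum())

    psi = state.psi.astype(bool)
    with np.errstate(divide="ignore"):
        lp_psi = float(np.where(psi, np.log(state.pi), np.log1p(-state.pi)).sum())
    lp_mu = float(stats.norm.logpdf(state.mu[psi], 0.0, state.sigma).sum())
    tg = ~library.is_control
    lp_beta = float(stats.norm.logpdf(state.beta[tg], state.mu[gidx[tg]], state.tau).sum())

    lp_hyper = _log_half_cauchy(state.sigma, hyper.sigma_scale)
    lp_hyper += _log_half_cauchy(state.tau, hyper.tau_scale)
    if hyper.pi_a > 0:
        lp_hyper += float(stats.beta.logpdf(np.clip(state.pi, 1e-12, 1 - 1e-12),
                                            hyper.pi_a, hyper.pi_b))
    alpha = hyper.alpha_t * hyper.w0
    lp_hyper += float(sum(stats.dirichlet.logpdf(wn / wn.sum(), alpha) for wn in state.w))
    lp_hyper += float(stats.gamma.logpdf(state.phi, hyper.phi_shape,
                                         scale=1.0 / hyper.phi_rate).sum())
    return ll + lp_psi + lp_mu + lp_beta + lp_hyper


def sample_prior(library: GuideLibrary, n_replicates: int, n_bins: int,
                 hyper: Hyperparameters, rng: np.random.Generator) -> ModelState:
    """Draw one ModelState from the prior hierarchy."""
    if n_replicates < 1 or n_bins < 2:
        raise ValueError("need >= 1 replicate and >= 2 bins")
    hyper = hyper.resolved(n_bins)
    gidx, genes = library.gene_index()
    G = len(genes)
    sigma = abs(rng.standard_cauchy()) * hyper.sigma_scale
    tau = abs(rng.standard_cauchy()) * hyper.tau_scale
    pi = 0.0 if hyper.pi_a == 0 else float(rng.beta(hyper.pi_a, hyper.pi_b))
    psi = (rng.random(G) < pi).astype(np.int64)
    mu = np.where(psi == 1, rng.normal(0.0, sigma, G), 0.0)
    beta = np.zeros(library.n_guides)
    tg = ~library.is_control
    beta[tg] = mu[gidx[tg]] + rng.normal(0.0, tau, int(tg.sum()))
    w = rng.dirichlet(hyper.alpha_t * hyper.w0, size=n_replicates)
    phi = rng.gamma(hyper.phi_shape, 1.0 / hyper.phi_rate, size=n_replicates)
    return ModelState(psi=psi, mu=mu, beta=beta, w=w, phi=phi,
                      sigma=float(sigma), tau=float(tau), pi=pi)


def init_bins_from_controls(data: BinCountTable, library: GuideLibrary,
                            hyper: Hyperparameters | None = None,
                            fallback_all_guides: bool | None = None) -> list[BinScheme]:
    """Per-replicate bin schemes from pooled control counts (initialization).

    Conjugate posterior-mean masses under the Dirichlet(alpha_t * w0)
    prior: (pooled_counts + alpha) / (total + sum(alpha)).  Used only to
    initialize the sampler; t_n remains a sampled latent.

    Without usable controls the fallback (automatic when the library
    declares no controls, opt-in otherwise) uses the median per-bin
    composition across all guides — the "most guides are null" assumption.
    """
    hyper = (hyper or Hyperparameters()).resolved(data.n_bins)
    alpha = hyper.alpha_t * hyper.w0
    is_ctrl = np.array([g in set(library.guide_id[library.is_control])
                        for g in data.guide_id])
    if fallback_all_guides is None:
        fallback_all_guides = not library.is_control.any()

    schemes = []
    for n in range(data.n_replicates):
        pooled = data.counts[n][is_ctrl].sum(axis=0) if is_ctrl.any() else np.zeros(data.n_bins)
        if pooled.sum() > 0 and not (fallback_all_guides and not is_ctrl.any()):
            masses = (pooled + alpha) / (pooled.sum() + alpha.sum())
        elif fallback_all_guides:
            totals = data.totals[n]
            keep = totals > 0
            if not keep.any():
                raise ValueError(f"replicate {data.replicate_labels[n]!r} has no counts")
            props = data.counts[n][keep] / totals[keep, None]
            med = np.median(props, axis=0)
            scale = float(np.median(totals[keep]))
            masses = (med / med.sum() * scale + alpha) / (scale + alpha.sum())
        else:
            raise ValueError(
                f"replicate {data.replicate_labels[n]!r} has all-zero control counts "
                "and fallback_all_guides is disabled"
            )
        schemes.append(BinScheme(np.concatenate([[0.0], np.cumsum(masses / masses.sum())[:-1], [1.0]])))
    return schemes
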