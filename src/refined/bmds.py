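"""Bayesian metric multidimensional scaling on the unit square.

Model
-----
Observed pairwise feature distances ``d_jk`` are modelled as truncated-normal
perturbations of the latent planar distances::

    d_jk ~ N(delta_jk, sigma^2) I(d_jk > 0),
    delta_jk = || s_j - s_k ||,   s_j in [0, 1]^2,
    s_j ~ U([0, 1]^2),            sigma^2 ~ IG(a, b),  a > 2, b > 0.

With ``q = p (p - 1) / 2`` distances, the unnormalized log posterior is::

    -(q/2 + a + 1) log sigma^2
      - (1 / (2 sigma^2)) * sum_{j<k} (d_jk - delta_jk)^2
      - sum_{j<k} log Phi(delta_jk / sigma)
      - b / sigma^2

where ``Phi`` is the standard normal CDF (the truncation penalty).  The
conditional posterior of the locations has no closed form, so locations are
updated one feature at a time by Metropolis steps (Gaussian proposals
reflected at the unit-square boundary) inside a Gibbs scan; ``sigma^2`` is
then drawn from its large-``q`` inverse-gamma approximation
``IG(q/2 + a, 0.5 * sum (d - delta)^2 + b)``.  The point estimate of the
locations is the maximum-a-posteriori state visited by the chain; retained
posterior draws can serve as alternative maps for data augmentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.special import log_ndtr

from .data import DistanceMatrix, ValidationError

__all__ = [
    "LocationSet",
    "BmdsConfig",
    "BmdsState",
    "BayesianMDS",
    "BMDSResults",
    "log_posterior",
    "sample_sigma2",
    "metropolis_update_location",
    "run_bmds",
    "posterior_draw_maps",
]


@dataclass
class LocationSet:
    """``p`` labelled 2-D coordinates on the unit square."""

    labels: list
    s: np.ndarray

    def __post_init__(self):
        self.s = np.asarray(self.s, dtype=float)
        if self.s.shape != (len(self.labels), 2):
            raise ValidationError(f"coordinates shape {self.s.shape} != ({len(self.labels)}, 2)")
        if np.any(self.s < -1e-12) or np.any(self.s > 1 + 1e-12):
            raise ValidationError("coordinates outside the unit square")
        self.s = np.clip(self.s, 0.0, 1.0)

    @property
    def p(self) -> int:
        return len(self.labels)

    def distance_matrix(self) -> DistanceMatrix:
        """Pairwise Euclidean distances delta induced by the locations."""
        return DistanceMatrix(labels=list(self.labels), d=squareform(pdist(self.s)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.s, index=self.labels, columns=["x", "y"])

    def write_csv(self, path) -> None:
        frame = self.to_frame()
        frame.index.name = "feature"
        frame.to_csv(path)


@dataclass
class BmdsConfig:
    """Sampler configuration.

    ``a``/``b`` are the inverse-gamma prior shape/scale for sigma^2 (shape
    must exceed 2 for a finite prior variance); ``n_iter`` counts total Gibbs
    sweeps, of which ``burn_in`` are discarded; retained sweeps are thinned by
    ``thin``; ``proposal_sd`` scales the Gaussian Metropolis step.
    """

    a: float = 3.0
    b: float = 1.0
    n_iter: int = 2000
    burn_in: int = 1000
    proposal_sd: float = 0.05
    thin: int = 10
    seed: int = 0
    polish: bool = True  # refine the best visited state to a local mode

    def __post_init__(self):
        if self.a <= 2:
            raise ValidationError("IG shape a must be > 2")
        if self.b <= 0:
            raise ValidationError("IG scale b must be > 0")
        if not 0 <= self.burn_in < self.n_iter:
            raise ValidationError("need 0 <= burn_in < n_iter")
        if self.proposal_sd <= 0:
            raise ValidationError("proposal_sd must be > 0")
        if self.thin < 1:
            raise ValidationError("thin must be >= 1")


@dataclass
class BmdsState:
    """Current sampler state: locations, variance, and cached log posterior."""

    locations: LocationSet
    sigma2: float
    log_post: float = np.nan

    def __post_init__(self):
        if self.sigma2 <= 0:
            raise ValidationError("sigma2 must be positive")

    @property
    def q(self) -> int:
        p = self.locations.p
        return p * (p - 1) // 2


def _check_labels(locations: LocationSet, d: DistanceMatrix) -> None:
    if list(locations.labels) != list(d.labels):
        raise ValidationError("location labels do not match distance-matrix labels")


def _residual_ss_and_trunc(s: np.ndarray, d_cond: np.ndarray, sigma: float):
    delta = pdist(s)
    ss = float(np.sum((d_cond - delta) ** 2))
    trunc = float(np.sum(log_ndtr(delta / sigma)))
    return ss, trunc


def log_posterior(state: BmdsState, d: DistanceMatrix, cfg: BmdsConfig) -> float:
    """Unnormalized log posterior of (locations, sigma^2) given distances."""
    _check_labels(state.locations, d)
    if state.sigma2 <= 0:
        raise ValidationError("sigma2 must be positive")
    q = state.q
    sigma2 = state.sigma2
    ss, trunc = _residual_ss_and_trunc(state.locations.s, d.condensed(), np.sqrt(sigma2))
    return (
        -(q / 2.0 + cfg.a + 1.0) * np.log(sigma2)
        - ss / (2.0 * sigma2)
        - trunc
        - cfg.b / sigma2
    )


def sample_sigma2(
    d: DistanceMatrix, locations: LocationSet, cfg: BmdsConfig, rng: np.random.Generator
) -> float:
    """One draw from the approximate conditional IG(q/2 + a, SS/2 + b).

    SS is the sum of squared residuals between observed and induced
    distances; the truncation term is dropped, which is accurate when the
    number of distances q is large.
    """
    _check_labels(locations, d)
    delta = pdist(locations.s)
    ss = float(np.sum((d.condensed() - delta) ** 2))
    p = locations.p
    q = p * (p - 1) // 2
    shape = q / 2.0 + cfg.a
    scale = ss / 2.0 + cfg.b
    return scale / rng.gamma(shape)


def _polish_mode(s0, sigma2_0, d_full, cfg):
    """L-BFGS-B ascent of the log posterior from the best visited state.

    The visited-state maximum of a finite chain wanders on the flat plateau
    around the mode; a short gradient climb turns it into an actual local
    mode of the posterior.  sigma^2 is optimized on the log scale; locations
    are box-constrained to the unit square.
    """
    from scipy.optimize import minimize

    p = s0.shape[0]
    q = p * (p - 1) // 2
    coef = q / 2.0 + cfg.a + 1.0

    def neg_lp_and_grad(theta):
        s = theta[:-1].reshape(p, 2)
        t = theta[-1]
        sigma2 = np.exp(t)
        sigma = np.exp(t / 2.0)
        diff = s[:, None, :] - s[None, :, :]
        delta = np.sqrt(np.einsum("jkl,jkl->jk", diff, diff))
        np.fill_diagonal(delta, 1.0)  # avoid 0-division; diagonal masked below
        z = delta / sigma
        # r(z) = phi(z)/Phi(z), stable for z > 0
        r = np.exp(-0.5 * z**2 - 0.5 * np.log(2 * np.pi) - log_ndtr(z))
        resid = d_full - delta
        mask = ~np.eye(p, dtype=bool)
        ss = float(np.sum(resid[mask] ** 2) / 2.0)
        trunc = float(np.sum(log_ndtr(z)[np.triu_indices(p, 1)]))
        lp = -coef * t - ss / (2.0 * sigma2) - trunc - cfg.b / sigma2
        # gradient w.r.t. locations
        w = np.where(mask, resid / sigma2 - r / sigma, 0.0)
        u = diff / np.maximum(delta, 1e-12)[:, :, None]
        gs = np.einsum("jk,jkl->jl", w, u)
        # gradient w.r.t. t = log sigma^2
        gt = (
            -coef
            + ss / (2.0 * sigma2)
            + 0.5 * float(np.sum((delta * r)[np.triu_indices(p, 1)])) / sigma
            + cfg.b / sigma2
        )
        grad = np.concatenate([gs.ravel(), [gt]])
        return -lp, -grad

    theta0 = np.concatenate([s0.ravel(), [np.log(sigma2_0)]])
    bounds = [(0.0, 1.0)] * (2 * p) + [(None, None)]
    res = minimize(neg_lp_and_grad, theta0, jac=True, method="L-BFGS-B", bounds=bounds)
    s = res.x[:-1].reshape(p, 2)
    return s, float(np.exp(res.x[-1])), -float(res.fun)


def _reflect_unit(x: np.ndarray) -> np.ndarray:
    """Reflect coordinates into [0, 1] (billiard reflection, any overshoot)."""
    y = np.mod(x, 2.0)
    return np.where(y > 1.0, 2.0 - y, y)


def metropolis_update_location(
    state: BmdsState,
    j: int,
    d: DistanceMatrix,
    cfg: BmdsConfig,
    rng: np.random.Generator,
) -> BmdsState:
    """Metropolis update of feature j's location with the Eq.-of-state ratio.

    Proposes a Gaussian step reflected into the unit square and accepts with
    the posterior ratio; the reflected random walk is symmetric, so no
    Hastings correction is needed.
    """
    _check_labels(state.locations, d)
    s = state.locations.s.copy()
    p = s.shape[0]
    if not 0 <= j < p:
        raise ValidationError(f"feature index {j} out of range")
    sigma2 = state.sigma2
    sigma = np.sqrt(sigma2)
    others = np.arange(p) != j
    d_row = d.d[j, others]

    old_delta = np.sqrt(np.sum((s[others] - s[j]) ** 2, axis=1))
    prop = _reflect_unit(s[j] + rng.normal(0.0, cfg.proposal_sd, size=2))
    new_delta = np.sqrt(np.sum((s[others] - prop) ** 2, axis=1))

    d_ss = np.sum((d_row - new_delta) ** 2) - np.sum((d_row - old_delta) ** 2)
    d_trunc = np.sum(log_ndtr(new_delta / sigma)) - np.sum(log_ndtr(old_delta / sigma))
    dlp = -d_ss / (2.0 * sigma2) - d_trunc

    if np.log(rng.uniform()) < dlp:
        s[j] = prop
    locations = LocationSet(list(state.locations.labels), s)
    new_state = BmdsState(locations=locations, sigma2=sigma2)
    new_state.log_post = log_posterior(new_state, d, cfg)
    return new_state


class BayesianMDS:
    """Bayesian metric MDS model for one observed distance matrix.

    Examples
    --------
    >>> model = BayesianMDS(dmat, BmdsConfig(seed=1))
    >>> res = model.fit(init=init_locations)
    >>> res.point_estimate.s.shape
    (p, 2)
    """

    def __init__(self, d: DistanceMatrix, config: BmdsConfig | None = None):
        self.d = d
        self.config = config if config is not None else BmdsConfig()

    def fit(self, init: LocationSet) -> "BMDSResults":
        d, cfg = self.d, self.config
        _check_labels(init, d)
        rng = np.random.default_rng(cfg.seed)
        p = init.p
        q = p * (p - 1) // 2
        labels = list(init.labels)
        d_full = d.d
        d_cond = d.condensed()

        s = init.s.copy()
        sigma2 = cfg.b / (cfg.a - 1.0)  # prior mean as starting variance

        def full_lp(s_arr, sig2):
            ss, trunc = _residual_ss_and_trunc(s_arr, d_cond, np.sqrt(sig2))
            return (
                -(q / 2.0 + cfg.a + 1.0) * np.log(sig2)
                - ss / (2.0 * sig2)
                - trunc
                - cfg.b / sig2,
                ss,
            )

        lp, ss = full_lp(s, sigma2)
        best_lp, best_s, best_sigma2 = lp, s.copy(), sigma2
        draws: list[LocationSet] = []
        trace = {"iteration": [], "sigma2": [], "log_post": [], "accept_rate": []}
        n_prop = 0
        n_acc = 0

        for it in range(cfg.n_iter):
            sigma = np.sqrt(sigma2)
            for j in range(p):
                others_mask = np.arange(p) != j
                d_row = d_full[j, others_mask]
                diff = s[others_mask] - s[j]
                old_delta = np.sqrt(np.einsum("ij,ij->i", diff, diff))
                prop = _reflect_unit(s[j] + rng.normal(0.0, cfg.proposal_sd, size=2))
                diff = s[others_mask] - prop
                new_delta = np.sqrt(np.einsum("ij,ij->i", diff, diff))
                d_ss = np.sum((d_row - new_delta) ** 2) - np.sum((d_row - old_delta) ** 2)
                d_trunc = float(
                    np.sum(log_ndtr(new_delta / sigma)) - np.sum(log_ndtr(old_delta / sigma))
                )
                dlp = -d_ss / (2.0 * sigma2) - d_trunc
                n_prop += 1
                if np.log(rng.uniform()) < dlp:
                    s[j] = prop
                    n_acc += 1

            # sigma^2 Gibbs step from the large-q IG approximation
            delta = pdist(s)
            ss = float(np.sum((d_cond - delta) ** 2))
            sigma2 = (ss / 2.0 + cfg.b) / rng.gamma(q / 2.0 + cfg.a)

            lp, ss = full_lp(s, sigma2)
            if not np.isfinite(lp):
                raise ValidationError(f"non-finite log posterior at sweep {it}")
            if lp > best_lp:
                best_lp, best_s, best_sigma2 = lp, s.copy(), sigma2
            trace["iteration"].append(it)
            trace["sigma2"].append(sigma2)
            trace["log_post"].append(lp)
            trace["accept_rate"].append(n_acc / n_prop)
            if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
                draws.append(LocationSet(labels, s.copy()))

        if cfg.polish:
            ps, psig2, plp = _polish_mode(best_s, best_sigma2, d_full, cfg)
            if plp >= best_lp:
                best_s, best_sigma2, best_lp = ps, psig2, plp
        point = LocationSet(labels, best_s)
        return BMDSResults(
            model=self,
            point_estimate=point,
            map_sigma2=best_sigma2,
            map_log_post=best_lp,
            draws=draws,
            trace=pd.DataFrame(trace),
        )


@dataclass
class BMDSResults:
    """Fit results: MAP locations, posterior draws, and the sampler trace."""

    model: BayesianMDS
    point_estimate: LocationSet
    map_sigma2: float
    map_log_post: float
    draws: list
    trace: pd.DataFrame

    def estimated_distances(self) -> DistanceMatrix:
        """delta-hat: distances induced by the MAP locations (the hill-climbing benchmark)."""
        return self.point_estimate.distance_matrix()

    def posterior_draw_maps(self, k: int) -> list:
        return posterior_draw_maps(self.draws, k)

    def write_trace_csv(self, path) -> None:
        self.trace.to_csv(path, index=False)

    def summary(self) -> str:
        post = self.trace.iloc[self.model.config.burn_in :]
        lines = [
            "Bayesian metric MDS (unit square)",
            f"  features (p):            {self.point_estimate.p}",
            f"  distances (q):           {self.point_estimate.p * (self.point_estimate.p - 1) // 2}",
            f"  sweeps (burn-in):        {self.model.config.n_iter} ({self.model.config.burn_in})",
            f"  retained draws:          {len(self.draws)}",
            f"  MAP log posterior:       {self.map_log_post:.4f}",
            f"  MAP sigma^2:             {self.map_sigma2:.6f}",
            f"  posterior mean sigma^2:  {post['sigma2'].mean():.6f}",
            f"  final acceptance rate:   {self.trace['accept_rate'].iloc[-1]:.3f}",
        ]
        return "\n".join(lines)


def run_bmds(d: DistanceMatrix, init: LocationSet, cfg: BmdsConfig):
    """Functional wrapper: returns (point estimate, posterior draws, trace)."""
    res = BayesianMDS(d, cfg).fit(init)
    return res.point_estimate, res.draws, res.trace


def posterior_draw_maps(draws: list, k: int) -> list:
    """k evenly spaced retained posterior location sets (k=1 gives the last)."""
    if k < 1:
        raise ValidationError("k must be >= 1")
    if k > len(draws):
        raise ValidationError(f"requested {k} draws but only {len(draws)} retained")
    idx = np.round(np.linspace(len(draws) - 1, 0, k)).astype(int)[::-1]
    return [draws[i] for i in idx]
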