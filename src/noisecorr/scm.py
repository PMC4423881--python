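"""Structured covariance model (SCM): Gibbs sampler and posterior summaries.

Each log-scale measurement is modeled as

    X_ij = L_{i,l[j]} * G_{l[j]} + T_{i,t[j]} + E_{i,k[j]} + R_ij + nu_j

where L_i ~ N2(0, Psi) are the denoised latent (protein, mRNA) levels with
unit marginal variance and free correlation psi12; G_l > 0 carries the
per-molecule-type scale (its square is the log-variance of true levels);
T, E and R are zero-mean Gaussian technology, experiment (batch) and
replicate noise with variances tau_t, xi_k and theta_j; and nu_j absorbs
per-replicate normalization offsets.  Missingness is non-ignorable: a cell
is detected with probability expit(eta0_k + eta1_k * X_ij), so low-value
cells are preferentially missing and unobserved values must be imputed
jointly with the parameters.

Priors: psi12 marginally uniform on (-1, 1) (the 2x2 marginally-uniform
correlation-matrix prior); Inv-Gamma(3/2, 3/10) on tau_t, xi_k and theta_j;
flat priors on G_l (constrained positive) and nu_j; independent
Cauchy(0, 2.5) on eta0_k and eta1_k.

Inference is a fixed-scan Gibbs sampler with eight conditional updates per
sweep (latents; psi12 by random-walk Metropolis on the atanh scale; G by
conjugate weighted regression truncated to G > 0; the three variance strata
by conjugate inverse-gamma draws and nu by its normal conditional;
imputation by a Metropolis-Hastings independence sampler proposing from the
model-implied Gaussian, accepted with the ratio of missingness likelihoods;
and eta by random-walk Metropolis on the logistic-regression posterior).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .data import ExpressionMatrix, ReplicateMeta

__all__ = [
    "McmcConfig",
    "ScmState",
    "ScmSamples",
    "PosteriorSummary",
    "ScmSampler",
    "init_state",
    "gibbs_sweep",
    "fit_scm",
    "amplification_estimate",
    "detection_curve",
    "sample_representative_expression",
]

# Inv-Gamma(3/2, 3/10) shared by the replicate, experiment and technology
# variance strata: weak (three pseudo-observations, scale 1/5), present
# mainly to keep early-chain draws away from degenerate values.
_IG_SHAPE = 1.5
_IG_RATE = 0.3
_CAUCHY_SCALE = 2.5
_VAR_FLOOR = 1e-3


@dataclass(frozen=True)
class McmcConfig:
    """Chain settings (the model itself fixes no chain lengths)."""

    n_iterations: int = 4000
    n_burnin: int = 2000
    thin: int = 2
    n_chains: int = 2
    seed: int = 0
    psi_proposal_scale: float = 0.05  # random-walk sd on atanh(psi12)
    eta_proposal_scale: float = 0.15  # initial sd for (eta0, eta1) proposals
    nmar: bool = True  # model non-ignorable missingness (off = MAR imputation)

    def __post_init__(self) -> None:
        if not self.n_iterations > self.n_burnin >= 0:
            raise ValueError("need n_iterations > n_burnin >= 0")
        if self.thin < 1 or self.n_chains < 1:
            raise ValueError("thin and n_chains must be >= 1")


@dataclass
class ScmState:
    """One complete set of latent variables and parameters (one MCMC state)."""

    L: np.ndarray          # (n, 2) latent levels, column 0 protein, 1 mRNA
    psi12: float           # latent correlation
    G: np.ndarray          # (2,) positive scales
    T: np.ndarray          # (n, N_T) technology effects
    tau_t: np.ndarray      # (N_T,) technology variances
    E: np.ndarray          # (n, N_E) experiment (batch) effects
    xi_k: np.ndarray       # (N_E,) experiment variances
    theta_j: np.ndarray    # (N_R,) replicate noise variances
    nu_j: np.ndarray       # (N_R,) replicate offsets
    eta0_k: np.ndarray     # (N_E,) detection intercepts
    eta1_k: np.ndarray     # (N_E,) detection slopes
    X_full: np.ndarray     # (n, N_R) observed values + current imputations

    def copy(self) -> "ScmState":
        return ScmState(
            self.L.copy(), float(self.psi12), self.G.copy(), self.T.copy(),
            self.tau_t.copy(), self.E.copy(), self.xi_k.copy(),
            self.theta_j.copy(), self.nu_j.copy(), self.eta0_k.copy(),
            self.eta1_k.copy(), self.X_full.copy(),
        )


@dataclass
class ScmSamples:
    """Thinned posterior draws plus accumulated per-gene latent summaries."""

    psi12: np.ndarray           # (S,)
    G: np.ndarray               # (S, 2)
    tau_t: np.ndarray           # (S, N_T)
    xi_k: np.ndarray            # (S, N_E)
    theta_j: np.ndarray         # (S, N_R)
    nu_j: np.ndarray            # (S, N_R)
    eta0_k: np.ndarray          # (S, N_E)
    eta1_k: np.ndarray          # (S, N_E)
    gene_mean: np.ndarray       # (n, 2) posterior mean of G_l * L_il
    gene_sd: np.ndarray         # (n, 2) posterior sd of G_l * L_il
    gene_ids: np.ndarray
    experiment_ids: list
    chain_id: np.ndarray        # (S,) chain index per draw


@dataclass
class PosteriorSummary:
    psi12_mean: float
    psi12_sd: float
    amplification_mean: float
    amplification_sd: float
    gene_summary: pd.DataFrame  # gene, mean/sd log mRNA, mean/sd log protein
    detection_params: pd.DataFrame  # experiment, eta0/eta1 posterior mean & sd
    rhat_psi12: float
    n_draws: int


def _logistic_log1m(linear: np.ndarray) -> np.ndarray:
    """log(1 - expit(linear)) = log P(missing | x), numerically stable."""
    return -np.logaddexp(0.0, linear)


class ScmSampler:
    """Gibbs sampler bound to one dataset.

    ``fixed`` names parameter blocks excluded from updating (e.g. {"G",
    "nu"} for sampler-correctness checks where their flat priors make the
    joint improper).
    """

    def __init__(
        self,
        x: ExpressionMatrix,
        meta: ReplicateMeta,
        cfg: McmcConfig,
        rng: np.random.Generator | None = None,
        fixed: frozenset[str] | set[str] = frozenset(),
    ) -> None:
        if not x.log_scale:
            raise ValueError("SCM expects log-scale data")
        missing_meta = set(x.replicate_ids) - set(meta.replicate_ids)
        if missing_meta:
            raise ValueError(f"replicates without metadata: {sorted(missing_meta)}")
        meta = meta.subset(list(x.replicate_ids))
        # keep meta ordered as the matrix columns
        order = {r: i for i, r in enumerate(meta.replicate_ids)}
        col_order = [order[r] for r in x.replicate_ids]
        self.meta = ReplicateMeta(meta.table.iloc[col_order].reset_index(drop=True))
        self.l_j = self.meta.molecule_index
        self.t_j = self.meta.technology_index
        self.k_j = self.meta.experiment_index
        if len(set(self.l_j)) < 2:
            raise ValueError("need replicates of both molecule types")
        keep = x.observed.any(axis=1)
        if not keep.all():
            warnings.warn(
                f"excluding {(~keep).sum()} genes with no observation in any replicate"
            )
        self.gene_ids = x.gene_ids[keep]
        self.obs = x.observed[keep]
        self.X_obs = np.where(self.obs, x.values[keep], 0.0)
        self.n, self.R = self.obs.shape
        self.NT = len(self.meta.technology_ids)
        self.NE = len(self.meta.experiment_ids)
        self.cfg = cfg
        self.rng = rng if rng is not None else np.random.default_rng(cfg.seed)
        self.fixed = frozenset(fixed)
        # per-experiment column lists
        self.cols_of_exp = [np.where(self.k_j == k)[0] for k in range(self.NE)]
        self.cols_of_type = [np.where(self.l_j == l)[0] for l in range(2)]
        for l, cols in enumerate(self.cols_of_type):
            if len(cols) == 0:
                raise ValueError("degenerate layout: a molecule type has no replicates")
        # adaptive eta proposal scales, tuned during burn-in
        self.eta_scale = np.full(self.NE, cfg.eta_proposal_scale)
        self._eta_accept = np.zeros(self.NE)
        self._eta_tries = 0
        self.state = self._init_state()

    # ------------------------------------------------------------------ init
    def _init_state(self) -> ScmState:
        """Deterministic method-of-moments initialization."""
        obs, X = self.obs, self.X_obs
        n_obs_col = np.maximum(obs.sum(axis=0), 1)
        nu = X.sum(axis=0) / n_obs_col
        centered = np.where(obs, X - nu, np.nan)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            col_sd = np.nanstd(centered, axis=0)
        col_sd = np.where((col_sd > 0) & np.isfinite(col_sd), col_sd, 1.0)
        # per-type gene means of column-standardized values; missing -> 0
        L = np.zeros((self.n, 2))
        G = np.ones(2)
        for l, cols in enumerate(self.cols_of_type):
            z = centered[:, cols] / col_sd[cols]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                m = np.nanmean(z, axis=1)
            L[:, l] = np.where(np.isfinite(m), m, 0.0)
            sd_l = L[:, l].std()
            if sd_l > 0:
                L[:, l] /= sd_l
            # pooled within-type SD carries the initial scale
            pooled = centered[:, cols][obs[:, cols]]
            G[l] = max(pooled.std(), 0.1) if pooled.size else 1.0
        good = (L[:, 0] != 0) & (L[:, 1] != 0)
        psi12 = float(np.corrcoef(L[good, 0], L[good, 1])[0, 1]) if good.sum() > 2 else 0.0
        psi12 = float(np.clip(psi12, -0.98, 0.98))
        # residual variances, split evenly across the strata they stack into
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            resid_var = np.nanvar(centered - (L[:, self.l_j] * G[self.l_j]), axis=0)
        resid_var = np.where(np.isfinite(resid_var), resid_var, 1.0)
        theta = np.maximum(resid_var / 3.0, _VAR_FLOOR)
        tau = np.array([
            max(resid_var[self.t_j == t].mean() / 3.0, _VAR_FLOOR)
            for t in range(self.NT)
        ])
        xi = np.array([
            max(resid_var[self.k_j == k].mean() / 3.0, _VAR_FLOOR)
            for k in range(self.NE)
        ])
        T = np.zeros((self.n, self.NT))
        E = np.zeros((self.n, self.NE))
        # detection model: slope 1, intercept matched to the observed rate
        eta1 = np.ones(self.NE)
        eta0 = np.zeros(self.NE)
        fitted = L[:, self.l_j] * G[self.l_j] + nu
        for k, cols in enumerate(self.cols_of_exp):
            vals = np.where(obs[:, cols], X[:, cols], fitted[:, cols]).ravel()
            target = obs[:, cols].mean()
            # deterministic 1-d solve for the intercept
            lo, hi = -30.0, 30.0
            for _ in range(60):
                mid = 0.5 * (lo + hi)
                if expit(mid + vals).mean() > target:
                    hi = mid
                else:
                    lo = mid
            eta0[k] = 0.5 * (lo + hi)
        X_full = np.where(obs, X, fitted)
        return ScmState(
            L=L, psi12=psi12, G=G, T=T, tau_t=tau, E=E, xi_k=xi,
            theta_j=theta, nu_j=nu.copy(), eta0_k=eta0, eta1_k=eta1,
            X_full=X_full,
        )

    # ------------------------------------------------------------- utilities
    def _design(self, G: np.ndarray) -> np.ndarray:
        """Replicate -> latent-block design matrix A (R x d)."""
        d = 2 + self.NT + self.NE
        A = np.zeros((self.R, d))
        A[np.arange(self.R), self.l_j] = G[self.l_j]
        A[np.arange(self.R), 2 + self.t_j] = 1.0
        A[np.arange(self.R), 2 + self.NT + self.k_j] = 1.0
        return A

    def fitted_mean(self, state: ScmState | None = None) -> np.ndarray:
        """Model mean L G + T + E + nu for every cell."""
        s = state or self.state
        return (
            s.L[:, self.l_j] * s.G[self.l_j]
            + s.T[:, self.t_j]
            + s.E[:, self.k_j]
            + s.nu_j
        )

    # ----------------------------------------------------------- Gibbs steps
    def _draw_latents(self) -> None:
        """Step 1: jointly draw (L_i, T_i, E_i) per gene from the conditional MVN."""
        s = self.state
        A = self._design(s.G)
        winv = 1.0 / s.theta_j
        rho = s.psi12
        psi_inv = np.array([[1.0, -rho], [-rho, 1.0]]) / (1.0 - rho**2)
        d = 2 + self.NT + self.NE
        P0 = np.zeros((d, d))
        P0[:2, :2] = psi_inv
        P0[np.arange(2, 2 + self.NT), np.arange(2, 2 + self.NT)] = 1.0 / s.tau_t
        P0[np.arange(2 + self.NT, d), np.arange(2 + self.NT, d)] = 1.0 / s.xi_k
        Q = P0 + (A.T * winv) @ A
        cov = np.linalg.inv(Q)
        cov = 0.5 * (cov + cov.T)
        chol = np.linalg.cholesky(cov)
        B = (A.T * winv).T @ cov.T        # (R, d)
        mu = (s.X_full - s.nu_j) @ B      # (n, d)
        Z = mu + self.rng.standard_normal((self.n, d)) @ chol.T
        s.L = Z[:, :2]
        s.T = Z[:, 2:2 + self.NT]
        s.E = Z[:, 2 + self.NT:]

    def _draw_psi(self) -> None:
        """Step 2: random-walk Metropolis on atanh(psi12), uniform prior on psi12."""
        s = self.state
        S11 = float(s.L[:, 0] @ s.L[:, 0])
        S22 = float(s.L[:, 1] @ s.L[:, 1])
        S12 = float(s.L[:, 0] @ s.L[:, 1])
        n = self.n

        def logpost_z(rho: float) -> float:
            # includes the atanh-transform Jacobian log(1 - rho^2)
            one = 1.0 - rho**2
            return (
                -0.5 * n * np.log(one)
                - (S11 + S22 - 2.0 * rho * S12) / (2.0 * one)
                + np.log(one)
            )

        z = np.arctanh(s.psi12)
        z_new = z + self.rng.normal(0.0, self.cfg.psi_proposal_scale)
        rho_new = float(np.tanh(z_new))
        if np.log(self.rng.random()) < logpost_z(rho_new) - logpost_z(s.psi12):
            s.psi12 = rho_new

    def _draw_G(self) -> None:
        """Step 3: conjugate weighted regression of residualized X on L, G > 0."""
        s = self.state
        resid = s.X_full - s.T[:, self.t_j] - s.E[:, self.k_j] - s.nu_j
        for l, cols in enumerate(self.cols_of_type):
            winv = 1.0 / s.theta_j[cols]
            ll = float(s.L[:, l] @ s.L[:, l])
            prec = ll * winv.sum()
            num = float(winv @ (resid[:, cols].T @ s.L[:, l]))
            m, sd = num / prec, 1.0 / np.sqrt(prec)
            a = (0.0 - m) / sd  # truncate to the identifiable half-line G > 0
            s.G[l] = stats.truncnorm.rvs(a, np.inf, loc=m, scale=sd,
                                         random_state=self.rng)

    def _draw_invgamma(self, shape: float, rate: float | np.ndarray) -> np.ndarray:
        return rate / self.rng.gamma(shape, 1.0, size=np.shape(rate))

    def _draw_variances(self) -> None:
        """Steps 4-5: conjugate Inv-Gamma draws for tau_t and xi_k."""
        s = self.state
        ss_t = (s.T**2).sum(axis=0)
        s.tau_t = np.maximum(
            self._draw_invgamma(_IG_SHAPE + 0.5 * self.n, _IG_RATE + 0.5 * ss_t),
            _VAR_FLOOR,
        )
        ss_e = (s.E**2).sum(axis=0)
        s.xi_k = np.maximum(
            self._draw_invgamma(_IG_SHAPE + 0.5 * self.n, _IG_RATE + 0.5 * ss_e),
            _VAR_FLOOR,
        )

    def _draw_replicate_params(self) -> None:
        """Step 6: nu_j (flat prior, normal conditional) then theta_j (Inv-Gamma)."""
        s = self.state
        base = (
            s.L[:, self.l_j] * s.G[self.l_j]
            + s.T[:, self.t_j]
            + s.E[:, self.k_j]
        )
        resid = s.X_full - base
        if "nu" not in self.fixed:
            m = resid.mean(axis=0)
            s.nu_j = m + np.sqrt(s.theta_j / self.n) * self.rng.standard_normal(self.R)
        ss = ((resid - s.nu_j) ** 2).sum(axis=0)
        s.theta_j = np.maximum(
            self._draw_invgamma(_IG_SHAPE + 0.5 * self.n, _IG_RATE + 0.5 * ss),
            _VAR_FLOOR,
        )

    def _impute(self) -> None:
        """Step 7: MH independence sampler for unobserved cells.

        Proposals come from the model-implied Gaussian N(fitted, theta_j);
        the model-likelihood terms then cancel in the acceptance ratio,
        leaving the ratio of missingness likelihoods P(I=0 | x*) / P(I=0 | x).
        """
        s = self.state
        miss = ~self.obs
        if not miss.any():
            return
        fitted = self.fitted_mean()
        prop = fitted + np.sqrt(s.theta_j) * self.rng.standard_normal((self.n, self.R))
        if self.cfg.nmar:
            eta0 = s.eta0_k[self.k_j]
            eta1 = s.eta1_k[self.k_j]
            log_acc = (
                _logistic_log1m(eta0 + eta1 * prop)
                - _logistic_log1m(eta0 + eta1 * s.X_full)
            )
            accept = miss & (np.log(self.rng.random((self.n, self.R))) < log_acc)
        else:
            accept = miss  # ignorable missingness: plain model draw
        s.X_full = np.where(accept, prop, s.X_full)

    def _eta_logpost(self, k: int, eta0: float, eta1: float) -> float:
        cols = self.cols_of_exp[k]
        x = self.state.X_full[:, cols].ravel()
        obs = self.obs[:, cols].ravel()
        lin = eta0 + eta1 * x
        ll = -np.logaddexp(0.0, np.where(obs, -lin, lin)).sum()
        prior = (
            stats.cauchy.logpdf(eta0, scale=_CAUCHY_SCALE)
            + stats.cauchy.logpdf(eta1, scale=_CAUCHY_SCALE)
        )
        return float(ll + prior)

    def _draw_eta(self, adapt: bool = False) -> None:
        """Step 8: Metropolis update of the logistic detection parameters."""
        s = self.state
        self._eta_tries += 1
        for k in range(self.NE):
            cur = self._eta_logpost(k, s.eta0_k[k], s.eta1_k[k])
            step = self.eta_scale[k] * self.rng.standard_normal(2)
            e0, e1 = s.eta0_k[k] + step[0], s.eta1_k[k] + step[1]
            if np.log(self.rng.random()) < self._eta_logpost(k, e0, e1) - cur:
                s.eta0_k[k], s.eta1_k[k] = e0, e1
                self._eta_accept[k] += 1
        if adapt and self._eta_tries % 50 == 0:
            rate = self._eta_accept / 50.0
            self.eta_scale *= np.where(rate > 0.35, 1.3, np.where(rate < 0.15, 0.7, 1.0))
            self._eta_accept[:] = 0.0

    def sweep(self, adapt: bool = False) -> ScmState:
        """One full Gibbs sweep over the eight conditional updates."""
        self._draw_latents()
        if "psi" not in self.fixed:
            self._draw_psi()
        if "G" not in self.fixed:
            self._draw_G()
        self._draw_variances()
        self._draw_replicate_params()
        self._impute()
        if self.cfg.nmar and "eta" not in self.fixed:
            self._draw_eta(adapt=adapt)
        if not np.isfinite(self.state.X_full).all() or not np.isfinite(self.state.L).all():
            raise FloatingPointError("non-finite state: sampler diverged")
        return self.state

    # -------------------------------------------------------------- sampling
    def run_chain(self) -> ScmSamples:
        cfg = self.cfg
        keep = []
        gm = np.zeros((self.n, 2))
        gm2 = np.zeros((self.n, 2))
        n_kept = 0
        for it in range(cfg.n_iterations):
            self.sweep(adapt=it < cfg.n_burnin)
            if it >= cfg.n_burnin and (it - cfg.n_burnin) % cfg.thin == 0:
                s = self.state
                keep.append((
                    s.psi12, s.G.copy(), s.tau_t.copy(), s.xi_k.copy(),
                    s.theta_j.copy(), s.nu_j.copy(), s.eta0_k.copy(),
                    s.eta1_k.copy(),
                ))
                denoised = s.L * s.G
                gm += denoised
                gm2 += denoised**2
                n_kept += 1
        gene_mean = gm / n_kept
        gene_var = np.maximum(gm2 / n_kept - gene_mean**2, 0.0)
        return ScmSamples(
            psi12=np.array([k[0] for k in keep]),
            G=np.array([k[1] for k in keep]),
            tau_t=np.array([k[2] for k in keep]),
            xi_k=np.array([k[3] for k in keep]),
            theta_j=np.array([k[4] for k in keep]),
            nu_j=np.array([k[5] for k in keep]),
            eta0_k=np.array([k[6] for k in keep]),
            eta1_k=np.array([k[7] for k in keep]),
            gene_mean=gene_mean,
            gene_sd=np.sqrt(gene_var),
            gene_ids=self.gene_ids,
            experiment_ids=self.meta.experiment_ids,
            chain_id=np.zeros(n_kept, dtype=int),
        )


def init_state(x: ExpressionMatrix, meta: ReplicateMeta, cfg: McmcConfig) -> ScmState:
    """Deterministic initialization (column means, pooled SDs, moment residuals)."""
    return ScmSampler(x, meta, cfg).state


def gibbs_sweep(
    state: ScmState,
    x: ExpressionMatrix,
    meta: ReplicateMeta,
    cfg: McmcConfig,
    rng: np.random.Generator | None = None,
) -> ScmState:
    """Advance one Gibbs sweep from an arbitrary consistent state."""
    sampler = ScmSampler(x, meta, cfg, rng=rng)
    sampler.state = state
    return sampler.sweep()


def _concat_samples(chains: list[ScmSamples]) -> ScmSamples:
    weights = np.array([len(c.psi12) for c in chains], dtype=float)
    gene_mean = sum(w * c.gene_mean for w, c in zip(weights, chains)) / weights.sum()
    second = sum(
        w * (c.gene_sd**2 + c.gene_mean**2) for w, c in zip(weights, chains)
    ) / weights.sum()
    return ScmSamples(
        psi12=np.concatenate([c.psi12 for c in chains]),
        G=np.concatenate([c.G for c in chains]),
        tau_t=np.concatenate([c.tau_t for c in chains]),
        xi_k=np.concatenate([c.xi_k for c in chains]),
        theta_j=np.concatenate([c.theta_j for c in chains]),
        nu_j=np.concatenate([c.nu_j for c in chains]),
        eta0_k=np.concatenate([c.eta0_k for c in chains]),
        eta1_k=np.concatenate([c.eta1_k for c in chains]),
        gene_mean=gene_mean,
        gene_sd=np.sqrt(np.maximum(second - gene_mean**2, 0.0)),
        gene_ids=chains[0].gene_ids,
        experiment_ids=chains[0].experiment_ids,
        chain_id=np.concatenate([
            np.full(len(c.psi12), i) for i, c in enumerate(chains)
        ]),
    )


def _split_rhat(x: np.ndarray, chain_id: np.ndarray) -> float:
    """Split-chain potential scale reduction factor for a scalar parameter."""
    halves = []
    for c in np.unique(chain_id):
        v = x[chain_id == c]
        h = len(v) // 2
        if h >= 2:
            halves.extend([v[:h], v[h:2 * h]])
    if len(halves) < 2:
        return np.nan
    m = min(len(h) for h in halves)
    draws = np.array([h[:m] for h in halves])
    w = draws.var(axis=1, ddof=1).mean()
    b = m * draws.mean(axis=1).var(ddof=1)
    if w == 0:
        return 1.0
    return float(np.sqrt(((m - 1) / m * w + b / m) / w))


def fit_scm(
    x: ExpressionMatrix, meta: ReplicateMeta, cfg: McmcConfig = McmcConfig()
) -> tuple[ScmSamples, PosteriorSummary]:
    """Run burn-in plus sampling sweeps and summarize the posterior.

    Multiple chains start from the same deterministic initialization with
    different RNG streams; convergence is screened by split-Rhat on psi12.
    """
    chains = []
    for c in range(cfg.n_chains):
        rng = np.random.default_rng(cfg.seed + c)
        sampler = ScmSampler(x, meta, cfg, rng=rng)
        chains.append(sampler.run_chain())
    samples = _concat_samples(chains)
    amp = amplification_estimate(samples)
    mol = {0: "protein", 1: "mrna"}
    gene_summary = pd.DataFrame({
        "gene": samples.gene_ids,
        **{
            f"mean_log_{mol[l]}": samples.gene_mean[:, l] for l in (1, 0)
        },
        **{
            f"sd_log_{mol[l]}": samples.gene_sd[:, l] for l in (1, 0)
        },
    })
    detection = pd.DataFrame({
        "experiment": samples.experiment_ids,
        "eta0_mean": samples.eta0_k.mean(axis=0),
        "eta0_sd": samples.eta0_k.std(axis=0),
        "eta1_mean": samples.eta1_k.mean(axis=0),
        "eta1_sd": samples.eta1_k.std(axis=0),
    })
    summary = PosteriorSummary(
        psi12_mean=float(samples.psi12.mean()),
        psi12_sd=float(samples.psi12.std(ddof=1)),
        amplification_mean=float(amp.mean()),
        amplification_sd=float(amp.std(ddof=1)),
        gene_summary=gene_summary,
        detection_params=detection,
        rhat_psi12=_split_rhat(samples.psi12, samples.chain_id),
        n_draws=len(samples.psi12),
    )
    return samples, summary


def amplification_estimate(samples: ScmSamples) -> np.ndarray:
    """Posterior draws of the amplification exponent A = G_protein / G_mRNA.

    A is the log-log slope of protein on mRNA implied by the latent scales:
    at steady state P is approximately M**A.
    """
    return samples.G[:, 0] / samples.G[:, 1]


def detection_curve(
    samples: ScmSamples, experiment, grid: np.ndarray | None = None
) -> pd.DataFrame:
    """Posterior detection-probability curve for one experiment.

    Detection probability is expit(eta0 + eta1 * x); it crosses 0.5 at
    x = -eta0/eta1.  Returns posterior mean and a pointwise 95% credible
    band over a grid of measurement values.
    """
    k = samples.experiment_ids.index(experiment)
    if grid is None:
        grid = np.linspace(-6.0, 6.0, 121)
    curves = expit(
        samples.eta0_k[:, k][:, None] + samples.eta1_k[:, k][:, None] * grid[None, :]
    )
    lo, hi = np.percentile(curves, [2.5, 97.5], axis=0)
    return pd.DataFrame({
        "x": grid,
        "p_detect_mean": curves.mean(axis=0),
        "p_detect_lo": lo,
        "p_detect_hi": hi,
    })


def sample_representative_expression(
    samples: ScmSamples, seed: int | np.random.Generator = 0
) -> pd.DataFrame:
    """One representative per-gene draw of denoised (log mRNA, log protein).

    Point estimates (posterior means) are over-smoothed for global views;
    drawing each gene's levels from N(mean, sd) restores representative
    dispersion, and the across-gene correlation of the draw is consistent
    with the posterior latent correlation.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draw = samples.gene_mean + samples.gene_sd * rng.standard_normal(
        samples.gene_mean.shape
    )
    return pd.DataFrame({
        "gene": samples.gene_ids,
        "log_mrna": draw[:, 1],
        "log_protein": draw[:, 0],
    })
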