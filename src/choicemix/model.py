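"""Bayesian hierarchical mixed logit with correlated random coefficients.

Each individual i holds a coefficient vector over the K = 8 design
columns (intercept, access, cattle per 100 head, cons150, cons75, cult,
small stock per 200 head, wage per 10,000 KSh):

    b_i ~ MVN(m + G z_i,  diag(s) R diag(s))
    P(choice_ir = 1) = logistic(b_i . x_ir)

where z_i are respondent covariates, m the population-mean coefficients
at z = 0, G the covariate loadings, s the random-coefficient standard
deviations and R their correlation matrix. Priors: Normal(0, 5) on m and
G, half-Normal(0, 2.5) on s, LKJ(2) on R. Sampling uses NUTS on the
non-centered parameterization (b_i = m + G z_i + diag(s) L u_i with
L = chol(R), u_i standard normal; R enters through canonical partial
correlations, which are independent shifted-Beta under the LKJ prior).
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, betaln
from scipy.stats import norm

from ._hmc import nuts_chain
from .data_io import ChoicePanel

K_COEF = 8
COEFFICIENT_NAMES = ("intercept", "access", "cattle", "cons150", "cons75",
                     "cult", "smlstk", "wage")
MODEL3_COVARIATES = ("sexF", "consY", "land", "cattle51plus", "smlstk101plus",
                     "buildingsMud", "buildingsIron", "vehicle", "ageset2",
                     "ageset3", "ageset4", "educated", "settlementYears",
                     "hhsize", "olmareiHead", "leadership")


@dataclass(frozen=True)
class PriorConfig:
    """Weakly informative defaults; every reported fit states these."""
    m_sd: float = 5.0
    g_sd: float = 5.0
    s_sd: float = 2.5
    lkj_eta: float = 2.0


@dataclass
class ModelSpec:
    """What to fit and how to sample.

    ``covariates`` empty gives Model 1 (attributes only); ("sexF",
    "consY") gives Model 2; :data:`MODEL3_COVARIATES` gives Model 3.
    """
    seed: int
    covariates: tuple = ()
    priors: PriorConfig = field(default_factory=PriorConfig)
    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    target_accept: float = 0.8
    max_treedepth: int = 10
    store_b: bool = False
    fix_s: np.ndarray | float | None = None   # pin random-coefficient sds
    fix_R: np.ndarray | None = None           # pin the correlation matrix

    @classmethod
    def model1(cls, seed: int, **kw) -> "ModelSpec":
        return cls(seed=seed, covariates=(), **kw)

    @classmethod
    def model2(cls, seed: int, **kw) -> "ModelSpec":
        return cls(seed=seed, covariates=("sexF", "consY"), **kw)

    @classmethod
    def model3(cls, seed: int, **kw) -> "ModelSpec":
        return cls(seed=seed, covariates=MODEL3_COVARIATES, **kw)


@dataclass
class Parameters:
    """A single (population-level) parameter setting, plus optional b_i.

    ``b`` is an (n_individuals, K) array aligned with the panel's
    individual order.
    """
    m: np.ndarray
    G: np.ndarray = None
    s: np.ndarray = None
    R: np.ndarray = None
    b: np.ndarray = None

    def __post_init__(self):
        self.m = np.asarray(self.m, dtype=float)
        K = self.m.size
        if self.G is None:
            self.G = np.zeros((K, 0))
        self.G = np.asarray(self.G, dtype=float).reshape(K, -1)
        if self.s is None:
            self.s = np.ones(K)
        self.s = np.asarray(self.s, dtype=float)
        if self.R is None:
            self.R = np.eye(K)
        self.R = np.asarray(self.R, dtype=float)
        if self.b is not None:
            self.b = np.asarray(self.b, dtype=float).reshape(-1, K)

    @property
    def covariance(self) -> np.ndarray:
        return self.R * np.outer(self.s, self.s)


# ---------------------------------------------------------------------------
# Elementary model operations
# ---------------------------------------------------------------------------

def choice_probability(b: np.ndarray, x: np.ndarray) -> float:
    """P(second option chosen) = logistic(b . x); x leads with the intercept 1."""
    b = np.asarray(b, dtype=float)
    x = np.asarray(x, dtype=float)
    if b.shape != x.shape:
        raise ValueError(f"dimension mismatch: b has {b.shape}, x has {x.shape}")
    return float(expit(b @ x))


def log_likelihood(panel: ChoicePanel, params: Parameters) -> float:
    """Bernoulli log likelihood of the panel under per-individual b_i.

    Numerically stable for utilities up to |b.x| ~ 500: uses
    y*eta - log(1 + exp(eta)) via logaddexp.
    """
    if params.b is None:
        raise ValueError("params.b (per-individual coefficients) required")
    if params.b.shape != (panel.n_individuals, panel.X.shape[1]):
        raise ValueError(
            f"params.b has shape {params.b.shape}, panel needs "
            f"{(panel.n_individuals, panel.X.shape[1])}")
    eta = np.einsum("ij,ij->i", panel.X, params.b[panel.row_individual])
    return float(panel.y @ eta - np.logaddexp(0.0, eta).sum())


def lkj_normalizer(K: int, eta: float) -> float:
    """log of the LKJ normalizing constant c with density det(R)^(eta-1)/c."""
    log_c = 0.0
    for k in range(1, K):
        log_c += (2 * eta - 2 + K - k) * (K - k) * math.log(2.0)
        log_c += (K - k) * betaln(eta + (K - 1 - k) / 2.0, eta + (K - 1 - k) / 2.0)
    return log_c


def lkj_logpdf(R: np.ndarray, eta: float) -> float:
    """LKJ log density over correlation matrices; -inf if R is not one."""
    R = np.asarray(R, dtype=float)
    K = R.shape[0]
    if not np.allclose(R, R.T) or not np.allclose(np.diag(R), 1.0):
        return -math.inf
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0:
        return -math.inf
    return (eta - 1.0) * logdet - lkj_normalizer(K, eta)


def log_prior(params: Parameters, priors: PriorConfig = PriorConfig(),
              Z: np.ndarray | None = None) -> float:
    """Joint log prior density, including the MVN of each b_i when present.

    Returns -inf for s <= 0 or a non-positive-definite R (sentinel, not
    an exception).
    """
    K = params.m.size
    lp = float(norm.logpdf(params.m, scale=priors.m_sd).sum())
    lp += float(norm.logpdf(params.G, scale=priors.g_sd).sum())
    if np.any(params.s <= 0):
        return -math.inf
    # half-Normal(0, s_sd): twice the normal density on the positive axis
    lp += float(norm.logpdf(params.s, scale=priors.s_sd).sum()) + K * math.log(2.0)
    lkj = lkj_logpdf(params.R, priors.lkj_eta)
    if not np.isfinite(lkj):
        return -math.inf
    lp += lkj
    if params.b is not None:
        n = params.b.shape[0]
        Sigma = params.covariance
        try:
            L = np.linalg.cholesky(Sigma)
        except np.linalg.LinAlgError:
            return -math.inf
        mean = params.m + (Z @ params.G.T if Z is not None and params.G.size else 0.0)
        dev = params.b - mean
        sol = np.linalg.solve(L, dev.T)
        lp += -0.5 * float((sol ** 2).sum())
        lp += -n * (0.5 * K * math.log(2 * math.pi) + np.log(np.diag(L)).sum())
    return lp


# ---------------------------------------------------------------------------
# Unconstrained posterior with analytic gradients
# ---------------------------------------------------------------------------

def _build_corr_chol(z_lower: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cholesky factor of a correlation matrix from canonical partial
    correlations (strictly-lower matrix); also returns the running
    products W with L[i, j] = z[i, j] * W[i, j] and L[i, i] = W[i, i]."""
    K = z_lower.shape[0]
    S = np.sqrt(np.clip(1.0 - z_lower ** 2, 1e-12, None))
    S[np.triu_indices(K)] = 1.0
    W = np.ones((K, K + 1))
    W[:, 1:] = np.cumprod(S, axis=1)
    L = z_lower * W[:, :K]
    idx = np.arange(K)
    L[idx, idx] = W[idx, idx]
    return L, W


class MixedLogitPosterior:
    """log density and gradient of the non-centered hierarchical mixed logit.

    Parameter vector layout: m (K), vec G (K*C), log s (K, if free),
    atanh partial correlations (K(K-1)/2, if free), vec U (n*K).
    """

    def __init__(self, panel: ChoicePanel, spec: ModelSpec):
        self.X = panel.X
        self.y = panel.y
        self.K = panel.X.shape[1]
        self.Z = panel.covariate_matrix(list(spec.covariates))
        self.C = self.Z.shape[1]
        self.n = panel.n_individuals
        self.row_individual = panel.row_individual
        # rows are sorted by individual in assemble_panel
        self.group_starts = np.flatnonzero(
            np.r_[True, np.diff(panel.row_individual) != 0])
        counts = np.diff(np.r_[self.group_starts, len(panel.y)])
        if self.n and np.all(counts == counts[0]):
            # uniform panel: batched einsum path (no fancy indexing)
            c = int(counts[0])
            self._Xr = panel.X.reshape(self.n, c, self.K)
            self._yr = panel.y.reshape(self.n, c)
        else:
            self._Xr = None
        self.priors = spec.priors
        self.free_s = spec.fix_s is None
        self.free_R = spec.fix_R is None
        if not self.free_s:
            self.s_fixed = np.broadcast_to(
                np.asarray(spec.fix_s, dtype=float), (self.K,)).copy()
        if not self.free_R:
            self.L_fixed = np.linalg.cholesky(np.asarray(spec.fix_R, dtype=float))
        K = self.K
        self.D = K * (K - 1) // 2 if self.free_R else 0
        self.tril = np.tril_indices(K, k=-1)
        # LKJ via independent shifted-Betas on the partial correlations:
        # an entry in column j (0-based) sits at vine tree level j+1
        self.beta_coef = spec.priors.lkj_eta + (K - 2 - self.tril[1]) / 2.0
        sizes = [K, K * self.C, K if self.free_s else 0, self.D, self.n * K]
        edges = np.cumsum([0] + sizes)
        self.slices = [slice(edges[i], edges[i + 1]) for i in range(len(sizes))]
        self.n_params = edges[-1]

    def _unpack(self, theta):
        K, C, n = self.K, self.C, self.n
        m = theta[self.slices[0]]
        G = theta[self.slices[1]].reshape(K, C)
        logs = theta[self.slices[2]] if self.free_s else None
        yv = theta[self.slices[3]] if self.free_R else None
        U = theta[self.slices[4]].reshape(n, K)
        return m, G, logs, yv, U

    def _structure(self, logs, yv):
        s = np.exp(logs) if self.free_s else self.s_fixed
        if self.free_R:
            z = np.zeros((self.K, self.K))
            z[self.tril] = np.tanh(yv)
            L, W = _build_corr_chol(z)
        else:
            z, W, L = None, None, self.L_fixed
        return s, z, W, L

    def logp_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        pr = self.priors
        m, G, logs, yv, U = self._unpack(theta)
        s, z, W, L = self._structure(logs, yv)
        A = s[:, None] * L                       # diag(s) @ chol(R)
        b = m + (self.Z @ G.T if self.C else 0.0) + U @ A.T
        if self._Xr is not None:
            eta = np.einsum("nck,nk->nc", self._Xr, b)
            lp = float((self._yr * eta).sum() - np.logaddexp(0.0, eta).sum())
            resid = self._yr - expit(eta)
            gb = np.einsum("nck,nc->nk", self._Xr, resid)
        else:
            eta = np.einsum("ij,ij->i", self.X, b[self.row_individual])
            lp = float(self.y @ eta - np.logaddexp(0.0, eta).sum())
            resid = self.y - expit(eta)
            if self.n:
                gb = np.add.reduceat(resid[:, None] * self.X,
                                     self.group_starts, axis=0)
            else:
                gb = np.zeros((0, self.K))

        grad = np.empty_like(theta)
        # population means and covariate loadings, Normal(0, sd) priors
        lp += -0.5 * float(m @ m) / pr.m_sd ** 2
        grad[self.slices[0]] = gb.sum(axis=0) - m / pr.m_sd ** 2
        if self.C:
            lp += -0.5 * float((G ** 2).sum()) / pr.g_sd ** 2
            grad[self.slices[1]] = (gb.T @ self.Z - G / pr.g_sd ** 2).ravel()
        # non-centered individual effects, standard normal
        lp += -0.5 * float((U ** 2).sum())
        grad[self.slices[4]] = (gb @ A - U).ravel()

        gA = gb.T @ U                            # (K, K): d lp / d A
        if self.free_s:
            # half-Normal(0, s_sd) with the log-s Jacobian
            lp += float(-0.5 * (s ** 2).sum() / pr.s_sd ** 2 + logs.sum())
            grad[self.slices[2]] = ((gA * L).sum(axis=1) * s
                                    - s ** 2 / pr.s_sd ** 2 + 1.0)
        if self.free_R:
            gL = s[:, None] * gA
            P = L * gL
            Tsum = np.cumsum(P[:, ::-1], axis=1)[:, ::-1]   # sum over l >= j
            zl = z[self.tril]
            one_minus = np.clip(1.0 - zl ** 2, 1e-12, None)
            i_idx, j_idx = self.tril
            dz = W[self.tril] * gL[self.tril] \
                - zl / one_minus * Tsum[i_idx, j_idx + 1]
            # LKJ shifted-Beta prior plus tanh Jacobian: beta * log(1 - z^2)
            lp += float((self.beta_coef * np.log(one_minus)).sum())
            grad[self.slices[3]] = dz * one_minus - 2.0 * zl * self.beta_coef
        return lp, grad

    def initial_point(self, rng: np.random.Generator) -> np.ndarray:
        theta = 0.1 * rng.standard_normal(self.n_params)
        if self.free_s:
            theta[self.slices[2]] = math.log(0.5) + 0.1 * rng.standard_normal(self.K)
        return theta

    def constrain(self, draws: np.ndarray, store_b: bool = False) -> dict:
        """Map an array of unconstrained draws to constrained parameters."""
        n_draws = draws.shape[0]
        K, C = self.K, self.C
        out = {"m": np.empty((n_draws, K)), "G": np.empty((n_draws, K, C)),
               "s": np.empty((n_draws, K)), "R": np.empty((n_draws, K, K))}
        if store_b:
            out["b"] = np.empty((n_draws, self.n, K))
        for t in range(n_draws):
            m, G, logs, yv, U = self._unpack(draws[t])
            s, _, _, L = self._structure(logs, yv)
            out["m"][t] = m
            out["G"][t] = G
            out["s"][t] = s
            out["R"][t] = L @ L.T
            if store_b:
                out["b"][t] = m + (self.Z @ G.T if C else 0.0) + U @ (s[:, None] * L).T
        return out


# ---------------------------------------------------------------------------
# Posterior draws container
# ---------------------------------------------------------------------------

@dataclass
class PosteriorDraws:
    """MCMC draws keyed by parameter, shaped (chains, draws, ...)."""

    params: dict
    coefficient_names: tuple = COEFFICIENT_NAMES
    covariate_names: tuple = ()
    covariate_transforms: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)
    diagnostics: pd.DataFrame = None
    converged: bool = True

    @property
    def n_chains(self) -> int:
        return next(iter(self.params.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.params.values())).shape[1]

    def stacked(self, name: str) -> np.ndarray:
        """Draws with chains flattened: (chains*draws, ...)."""
        a = self.params[name]
        return a.reshape(-1, *a.shape[2:])

    def coef_index(self, name: str) -> int:
        try:
            return self.coefficient_names.index(name)
        except ValueError:
            raise KeyError(f"unknown coefficient {name!r}; have "
                           f"{self.coefficient_names}") from None

    @classmethod
    def constant(cls, params: Parameters, covariate_names=(), n_draws: int = 1,
                 **kw) -> "PosteriorDraws":
        """Degenerate draws repeating one parameter setting (for worked
        examples and plug-in arithmetic)."""
        reps = {}
        for name in ("m", "G", "s", "R"):
            v = getattr(params, name)
            reps[name] = np.broadcast_to(v, (1, n_draws, *v.shape)).copy()
        return cls(params=reps, covariate_names=tuple(covariate_names), **kw)

    # -- persistence: long-format CSV plus a JSON metadata sidecar --------
    def save(self, path_prefix: str | Path) -> None:
        prefix = Path(path_prefix)
        rows = []
        for name, a in self.params.items():
            chains, draws = a.shape[:2]
            flat = a.reshape(chains, draws, -1)
            labels = self._labels(name, a.shape[2:])
            for c in range(chains):
                for comp, lab in enumerate(labels):
                    rows.append(pd.DataFrame({
                        "chain": c + 1, "iteration": np.arange(1, draws + 1),
                        "parameter": lab, "value": flat[c, :, comp]}))
        pd.concat(rows, ignore_index=True).to_csv(
            prefix.with_suffix(".csv"), index=False)
        meta = dict(self.meta, coefficient_names=list(self.coefficient_names),
                    covariate_names=list(self.covariate_names),
                    covariate_transforms={k: list(v) for k, v
                                          in self.covariate_transforms.items()},
                    shapes={k: list(v.shape) for k, v in self.params.items()},
                    converged=bool(self.converged))
        prefix.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    def _labels(self, name: str, shape: tuple) -> list[str]:
        coef = self.coefficient_names
        cov = self.covariate_names
        if name == "m":
            return [f"m[{c}]" for c in coef]
        if name == "s":
            return [f"s[{c}]" for c in coef]
        if name == "G":
            return [f"G[{c},{v}]" for c in coef for v in cov]
        if name == "R":
            return [f"R[{a},{b}]" for a in coef for b in coef]
        return [f"{name}[{i}]" for i in range(int(np.prod(shape)))]

    @classmethod
    def load(cls, path_prefix: str | Path) -> "PosteriorDraws":
        prefix = Path(path_prefix)
        meta = json.loads(prefix.with_suffix(".json").read_text())
        df = pd.read_csv(prefix.with_suffix(".csv"))
        shapes = {k: tuple(v) for k, v in meta.pop("shapes").items()}
        coef = tuple(meta.pop("coefficient_names"))
        cov = tuple(meta.pop("covariate_names"))
        transforms = {k: tuple(v) for k, v in meta.pop("covariate_transforms").items()}
        converged = meta.pop("converged", True)
        self = cls(params={}, coefficient_names=coef, covariate_names=cov,
                   covariate_transforms=transforms, meta=meta, converged=converged)
        wide = df.pivot_table(index=["chain", "iteration"], columns="parameter",
                              values="value", sort=False)
        for name, shape in shapes.items():
            labels = self._labels(name, shape[2:])
            arr = wide[labels].to_numpy().reshape(shape)
            self.params[name] = arr
        return self


# ---------------------------------------------------------------------------
# Convergence diagnostics
# ---------------------------------------------------------------------------

def _split_chains(x: np.ndarray) -> np.ndarray:
    chains, draws = x.shape
    half = draws // 2
    return np.concatenate([x[:, :half], x[:, half:2 * half]], axis=0)


def split_rhat(x: np.ndarray) -> float:
    """Classic split-Rhat for one scalar parameter, x shaped (chains, draws)."""
    x = _split_chains(np.asarray(x, dtype=float))
    m, n = x.shape
    means = x.mean(axis=1)
    W = x.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    if W == 0:
        return 1.0
    var_plus = (n - 1) / n * W + B / n
    return float(math.sqrt(var_plus / W))


def effective_sample_size(x: np.ndarray) -> float:
    """Split-chain ESS with Geyer's initial monotone positive sequence."""
    x = _split_chains(np.asarray(x, dtype=float))
    m, n = x.shape
    if n < 4:
        raise ValueError("need at least 4 draws per chain")
    acov = np.empty((m, n))
    for c in range(m):
        d = x[c] - x[c].mean()
        f = np.fft.rfft(d, 2 * n)
        acov[c] = np.fft.irfft(f * np.conj(f), 2 * n)[:n] / n
    means = x.mean(axis=1)
    B_over_n = means.var(ddof=1) if m > 1 else 0.0
    var_plus = (n - 1) / n * np.mean(acov[:, 0]) + B_over_n
    if var_plus == 0:
        return float(m * n)
    rho = 1.0 - (np.mean(acov[:, 0]) - acov.mean(axis=0)) / var_plus
    rho[0] = 1.0
    # Geyer: sum consecutive pairs while positive, enforce monotonicity
    tau = 0.0
    prev_pair = math.inf
    t = 1
    tau = rho[0]  # will add pairs of lags (1,2), (3,4), ...
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair < 0:
            break
        pair = min(pair, prev_pair)
        prev_pair = pair
        tau += 2.0 * pair
        t += 2
    ess = m * n / max(tau, 1e-12)
    return float(min(ess, m * n))


def diagnose(draws: PosteriorDraws, names=("m", "G", "s")) -> pd.DataFrame:
    """Split-Rhat and effective sample size per scalar parameter."""
    if draws.n_chains < 2:
        raise ValueError("diagnostics need at least 2 chains")
    if draws.n_draws < 4:
        raise ValueError("diagnostics need at least 4 draws per chain")
    records = []
    for name in names:
        if name not in draws.params:
            continue
        a = draws.params[name]
        flat = a.reshape(a.shape[0], a.shape[1], -1)
        labels = draws._labels(name, a.shape[2:])
        for comp, lab in enumerate(labels):
            x = flat[:, :, comp]
            if np.allclose(x.std(), 0):
                records.append({"parameter": lab, "rhat": 1.0,
                                "ess": float(x.shape[0] * x.shape[1])})
                continue
            records.append({"parameter": lab, "rhat": split_rhat(x),
                            "ess": effective_sample_size(x)})
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _panel_fingerprint(panel: ChoicePanel) -> str:
    h = hashlib.sha1()
    h.update(panel.rows.to_csv(index=False).encode())
    h.update(panel.respondents.to_csv(index=False).encode())
    return h.hexdigest()[:16]


def fit_model(panel: ChoicePanel, spec: ModelSpec) -> PosteriorDraws:
    """Sample the posterior of the hierarchical mixed logit by NUTS.

    Runs ``spec.chains`` chains (reproducible given ``spec.seed``),
    transforms draws back to (m, G, s, R), attaches split-Rhat/ESS
    diagnostics, and flags (with a warning, not an error) any fit whose
    population-level split-Rhat exceeds 1.01.
    """
    if panel.n_individuals < 2:
        raise ValueError("panel has fewer than 2 individuals; the hierarchical "
                         "model is not identified")
    post = MixedLogitPosterior(panel, spec)
    seeds = np.random.SeedSequence(spec.seed).spawn(spec.chains)
    per_chain = []
    chain_stats = []
    for c in range(spec.chains):
        rng = np.random.default_rng(seeds[c])
        theta0 = post.initial_point(rng)
        raw, stats = nuts_chain(post.logp_grad, theta0, spec.warmup, spec.draws,
                                rng, target_accept=spec.target_accept,
                                max_treedepth=spec.max_treedepth)
        per_chain.append(post.constrain(raw, store_b=spec.store_b))
        chain_stats.append(stats)
    params = {name: np.stack([pc[name] for pc in per_chain])
              for name in per_chain[0]}
    draws = PosteriorDraws(
        params=params,
        covariate_names=tuple(spec.covariates),
        covariate_transforms=dict(panel.covariate_transforms),
        meta={"seed": spec.seed, "chains": spec.chains, "warmup": spec.warmup,
              "draws": spec.draws, "covariates": list(spec.covariates),
              "priors": vars(spec.priors),
              "data_fingerprint": _panel_fingerprint(panel),
              "divergences": int(sum(s.divergences for s in chain_stats)),
              "step_sizes": [s.step_size for s in chain_stats]})
    if spec.chains >= 2 and spec.draws >= 4:
        diag = diagnose(draws)
        draws.diagnostics = diag
        max_rhat = float(diag["rhat"].max())
        draws.meta["max_rhat"] = max_rhat
        if max_rhat > 1.01:
            draws.converged = False
            warnings.warn(f"fit flagged: max split-Rhat {max_rhat:.3f} > 1.01; "
                          "summaries are still produced", stacklevel=2)
    return draws


def sample_prior(spec: ModelSpec, K: int = K_COEF, n_covariates: int = 0,
                 coefficient_names=COEFFICIENT_NAMES) -> PosteriorDraws:
    """Prior-only sampling (zero-information data): the posterior must
    reproduce the prior; used as a sampler calibration check."""

    # reuse the posterior machinery with an empty panel: build by hand
    post = MixedLogitPosterior.__new__(MixedLogitPosterior)
    post.X = np.zeros((0, K))
    post.y = np.zeros(0)
    post.K = K
    post.Z = np.zeros((0, n_covariates))
    post.C = n_covariates
    post.n = 0
    post.row_individual = np.zeros(0, dtype=int)
    post.group_starts = np.zeros(0, dtype=int)
    post._Xr = None
    post.priors = spec.priors
    post.free_s = spec.fix_s is None
    post.free_R = spec.fix_R is None
    if not post.free_s:
        post.s_fixed = np.broadcast_to(np.asarray(spec.fix_s, float), (K,)).copy()
    if not post.free_R:
        post.L_fixed = np.linalg.cholesky(np.asarray(spec.fix_R, float))
    post.D = K * (K - 1) // 2 if post.free_R else 0
    post.tril = np.tril_indices(K, k=-1)
    post.beta_coef = spec.priors.lkj_eta + (K - 2 - post.tril[1]) / 2.0
    sizes = [K, K * n_covariates, K if post.free_s else 0, post.D, 0]
    edges = np.cumsum([0] + sizes)
    post.slices = [slice(edges[i], edges[i + 1]) for i in range(len(sizes))]
    post.n_params = edges[-1]

    seeds = np.random.SeedSequence(spec.seed).spawn(spec.chains)
    per_chain = []
    for c in range(spec.chains):
        rng = np.random.default_rng(seeds[c])
        raw, _ = nuts_chain(post.logp_grad, post.initial_point(rng),
                            spec.warmup, spec.draws, rng,
                            target_accept=spec.target_accept,
                            max_treedepth=spec.max_treedepth)
        per_chain.append(post.constrain(raw))
    params = {name: np.stack([pc[name] for pc in per_chain])
              for name in per_chain[0]}
    return PosteriorDraws(params=params, coefficient_names=tuple(coefficient_names),
                          meta={"prior_only": True, "seed": spec.seed})
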