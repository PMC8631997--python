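"""Per-bin logistic models for target-vs-distractor fixation counts.

Each 20-ms bin contributes, per cluster (participant, or participant x
item cell), a binomial count: ``y`` samples on the target out of ``n``
samples on target or distractor.  The per-bin test asks whether the
log-odds of fixating the target exceed chance (intercept beta0 vs 0).

Three fitting routes are provided:

* :func:`fit_bin_glm` — the pooled intercept-only GLM, available in closed
  form (beta0 = ln(sum target / sum distractor)); it is the zero-variance
  limit of the mixed model and the terminal fallback.
* :func:`fit_bin_glmm` — the Laplace-approximated binomial mixed model with
  a random intercept per participant and, optionally, a crossed random
  intercept per item.  For a fixed variance the intercept and the random
  effects are maximized jointly by damped Newton (penalized IRLS, the
  lme4-style profiling); the Laplace profile deviance is then minimized
  over the log random-effect SD(s).  Deterministic: fixed starting values,
  no randomness.
* :func:`marginal_loglik_quadrature` — a slow adaptive-quadrature evaluation
  of the exact marginal likelihood (single random intercept), kept as an
  independent reference for validating the Laplace route.

P-values are two-sided Wald tests; Benjamini-Hochberg adjustment across
bins lives in :func:`bh_adjust`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, optimize, stats
from scipy.special import expit, gammaln
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

_SIGMA_FLOOR = 1e-4       # below this the variance is treated as zero
_LOG_SIGMA_BOUNDS = (np.log(1e-4), np.log(5.0))


@dataclass
class AnalysisConfig:
    """Knobs of the divergence analysis."""

    alpha: float = 0.05
    correction: str = "fdr"                 # fdr | bonferroni | none
    random_effects: str = "participant+item"  # participant | participant+item
    require_positive_direction: bool = True
    min_run: int = 1   # consecutive significant bins required (1 = first hit)

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.correction not in ("fdr", "bonferroni", "none"):
            raise ValueError(f"unknown correction {self.correction!r}")
        if self.random_effects not in ("participant", "participant+item"):
            raise ValueError(
                f"unknown random_effects {self.random_effects!r}")
        if self.min_run < 1:
            raise ValueError("min_run must be >= 1")


@dataclass
class BinFit:
    """Result of one per-bin fit."""

    bin_start_ms: float
    beta0: float
    se: float
    z: float
    p: float
    p_adj: float = np.nan
    converged: bool = True
    method: str = "glm"
    sigma_participant: float = 0.0
    sigma_item: float = np.nan
    n_clusters: int = 0
    n_target: int = 0
    n_distractor: int = 0


def _wald(beta0: float, se: float) -> tuple[float, float]:
    z = beta0 / se
    p = 2.0 * stats.norm.sf(abs(z))
    return z, p


def fit_bin_glm(n_target, n_distractor, bin_start_ms: float = np.nan) -> BinFit:
    """Pooled intercept-only binomial GLM in closed form.

    beta0 = ln(s/f), se = sqrt(1/s + 1/f) with s = total target and
    f = total distractor samples.  Complete separation (s == 0 or f == 0)
    is non-estimable: flagged, p set to 1 with a warning.
    """
    s = int(np.sum(n_target))
    f = int(np.sum(n_distractor))
    n_clusters = np.size(n_target)
    if s == 0 and f == 0:
        raise ValueError("no target or distractor samples in this bin")
    if s == 0 or f == 0:
        warnings.warn(
            "complete separation (all samples on one picture); "
            "bin flagged non-estimable", stacklevel=2)
        return BinFit(bin_start_ms, beta0=np.nan, se=np.nan, z=np.nan, p=1.0,
                      converged=False, method="non_estimable",
                      n_clusters=n_clusters, n_target=s, n_distractor=f)
    beta0 = np.log(s / f)
    se = np.sqrt(1.0 / s + 1.0 / f)
    z, p = _wald(beta0, se)
    return BinFit(bin_start_ms, beta0=beta0, se=se, z=z, p=p, method="glm",
                  n_clusters=n_clusters, n_target=s, n_distractor=f)


# ------------------------------------------------------------ Laplace GLMM

class _LaplaceCore:
    """Joint Newton + Laplace profile deviance for crossed random intercepts.

    Observation cells carry binomial (y, n); design maps each cell to one
    level of each random factor.  ``factors`` is a list of integer index
    arrays (one per random factor), ``n_levels`` the matching level counts.
    """

    def __init__(self, y, n, factors, n_levels):
        self.y = np.asarray(y, dtype=float)
        self.n = np.asarray(n, dtype=float)
        self.factors = [np.asarray(f) for f in factors]
        self.n_levels = list(n_levels)
        self.q = int(sum(n_levels))
        self.offsets = np.cumsum([0] + self.n_levels[:-1])
        # cell -> column index per factor, shifted into the stacked u vector
        self.cols = [f + off for f, off in zip(self.factors, self.offsets)]

    def _eta(self, beta, u):
        eta = np.full(self.y.shape, beta)
        for col in self.cols:
            eta = eta + u[col]
        return eta

    def _loglik(self, eta):
        return float(np.sum(self.y * eta - self.n * np.log1p(np.exp(eta))))

    def _dinv(self, sigmas):
        d = np.empty(self.q)
        for k, (m, off) in enumerate(zip(self.n_levels, self.offsets)):
            d[off:off + m] = 1.0 / sigmas[k] ** 2
        return d

    def joint_mode(self, sigmas, start=None, tol=1e-10, max_iter=100):
        """Damped Newton for (beta, u) at fixed sigmas.

        Returns (beta, u, H, converged) where H is the negative Hessian of
        the penalized log-likelihood over (beta, u).
        """
        dinv = self._dinv(sigmas)
        dim = 1 + self.q
        x = np.zeros(dim) if start is None else start.copy()

        def value(x):
            eta = self._eta(x[0], x[1:])
            return self._loglik(eta) - 0.5 * float(np.sum(dinv * x[1:] ** 2))

        f_cur = value(x)
        converged = False
        for _ in range(max_iter):
            eta = self._eta(x[0], x[1:])
            mu = self.n * expit(eta)
            w = mu * (1.0 - mu / np.where(self.n > 0, self.n, 1.0))
            resid = self.y - mu
            grad = np.zeros(dim)
            grad[0] = resid.sum()
            for col in self.cols:
                np.add.at(grad, 1 + col, resid)
            grad[1:] -= dinv * x[1:]

            H = np.zeros((dim, dim))
            H[0, 0] = w.sum()
            for col in self.cols:
                np.add.at(H[0], 1 + col, w)
            H[:, 0] = H[0]
            for ci in self.cols:
                np.add.at(H, (1 + ci, 1 + ci), w)
                for cj in self.cols:
                    if cj is not ci:
                        np.add.at(H, (1 + ci, 1 + cj), w)
            H[np.arange(1, dim), np.arange(1, dim)] += dinv

            if np.max(np.abs(grad)) < tol:
                converged = True
                break
            try:
                step = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError:
                step = grad / np.maximum(np.diag(H), 1e-8)
            lam = 1.0
            for _ in range(30):  # backtracking damping
                x_new = x + lam * step
                f_new = value(x_new)
                if f_new >= f_cur - 1e-12:
                    break
                lam *= 0.5
            x, f_cur = x_new, f_new
        else:
            converged = np.max(np.abs(grad)) < 1e-6
        return x[0], x[1:], H, converged

    def profile_neg_loglik(self, log_sigmas, state):
        """Negative Laplace log marginal likelihood, beta profiled out."""
        sigmas = np.exp(np.asarray(log_sigmas, dtype=float))
        beta, u, H, ok = self.joint_mode(sigmas, start=state.get("x"))
        state["x"] = np.concatenate([[beta], u])
        state["H"] = H
        state["beta"] = beta
        state["ok"] = ok
        eta = self._eta(beta, u)
        dinv = self._dinv(sigmas)
        pen = self._loglik(eta) - 0.5 * float(np.sum(dinv * u ** 2))
        # Laplace over u only: logdet of the u-block of the Hessian
        Huu = H[1:, 1:]
        sign, logdet = np.linalg.slogdet(Huu)
        if sign <= 0:
            return np.inf
        log_det_d = float(np.sum(np.log(1.0 / dinv)))
        lm = pen - 0.5 * log_det_d - 0.5 * logdet
        return -lm


def fit_bin_glmm(
    n_target,
    n_distractor,
    participants,
    items=None,
    config: AnalysisConfig | None = None,
    bin_start_ms: float = np.nan,
) -> BinFit:
    """Laplace binomial mixed model for one bin, with fallback chain.

    Clusters with zero denominators are dropped.  When the variance
    estimate hits the zero boundary the result collapses to the pooled GLM
    (identical beta0/se/z).  Non-convergence with participant+item effects
    triggers a refit with participant-only effects, then the fixed-effects
    GLM; each step is recorded in ``method``.
    """
    config = config or AnalysisConfig()
    y = np.asarray(n_target, dtype=float)
    f = np.asarray(n_distractor, dtype=float)
    n = y + f
    keep = n > 0
    y, f, n = y[keep], f[keep], n[keep]
    part = np.asarray(participants)[keep]
    if items is not None:
        items = np.asarray(items)[keep]

    glm = fit_bin_glm(y, f, bin_start_ms)
    if glm.method == "non_estimable":
        return glm

    p_levels, p_idx = np.unique(part, return_inverse=True)
    if len(p_levels) < 2:
        glm.method = "glm"
        return glm

    want_item = config.random_effects == "participant+item" and items is not None
    attempts = (["participant+item", "participant"] if want_item
                else ["participant"])
    for structure in attempts:
        fit = _fit_structure(y, n, p_idx, items, structure, glm, bin_start_ms)
        if fit is not None:
            return fit
        logger.info("GLMM (%s) did not converge; falling back", structure)
    logger.info("GLMM fell back to the pooled GLM")
    out = fit_bin_glm(y, f, bin_start_ms)
    out.method = "glm_fallback"
    return out


def _fit_structure(y, n, p_idx, items, structure, glm, bin_start_ms):
    if structure == "participant+item":
        i_levels, i_idx = np.unique(items, return_inverse=True)
        if len(i_levels) < 2:
            return None
        factors = [p_idx, i_idx]
        n_levels = [p_idx.max() + 1, i_idx.max() + 1]
    else:
        factors = [p_idx]
        n_levels = [p_idx.max() + 1]
    core = _LaplaceCore(y, n, factors, n_levels)
    k = len(factors)
    state: dict = {}

    try:
        if k == 1:
            res = optimize.minimize_scalar(
                lambda ls: core.profile_neg_loglik([ls], state),
                bounds=_LOG_SIGMA_BOUNDS, method="bounded",
                options={"xatol": 1e-4},
            )
            log_sig = np.array([res.x])
            ok = res.success
        else:
            start = np.full(k, np.log(0.1))
            res = optimize.minimize(
                lambda ls: core.profile_neg_loglik(ls, state), start,
                method="Nelder-Mead",
                options={"xatol": 1e-4, "fatol": 1e-9, "maxiter": 300},
            )
            log_sig = np.clip(res.x, *_LOG_SIGMA_BOUNDS)
            ok = res.success
    except (np.linalg.LinAlgError, FloatingPointError):
        return None
    if not ok and not state.get("ok", False):
        return None

    sigmas = np.exp(log_sig)
    # evaluate at the optimum to refresh state
    core.profile_neg_loglik(np.log(np.maximum(sigmas, _SIGMA_FLOOR)), state)
    if not state.get("ok", False):
        return None

    if np.all(sigmas <= 10 * _SIGMA_FLOOR):
        # boundary: the mixed model degenerates to the pooled GLM
        out = BinFit(bin_start_ms, beta0=glm.beta0, se=glm.se, z=glm.z,
                     p=glm.p, converged=True,
                     method=f"glmm_{structure.replace('+', '_')}_boundary",
                     sigma_participant=0.0,
                     sigma_item=0.0 if k == 2 else np.nan,
                     n_clusters=glm.n_clusters, n_target=glm.n_target,
                     n_distractor=glm.n_distractor)
        return out

    beta = float(state["beta"])
    H = state["H"]
    try:
        cov00 = np.linalg.inv(H)[0, 0]
    except np.linalg.LinAlgError:
        return None
    if cov00 <= 0:
        return None
    se = float(np.sqrt(cov00))
    z, p = _wald(beta, se)
    return BinFit(bin_start_ms, beta0=beta, se=se, z=z, p=p, converged=True,
                  method=f"glmm_{structure.replace('+', '_')}",
                  sigma_participant=float(sigmas[0]),
                  sigma_item=float(sigmas[1]) if k == 2 else np.nan,
                  n_clusters=int(p_idx.max() + 1),
                  n_target=int(y.sum()), n_distractor=int((n - y).sum()))


# --------------------------------------------------------------- reference

def marginal_loglik_quadrature(beta0, sigma, n_target, n_distractor):
    """Exact marginal log-likelihood by adaptive quadrature (one factor).

    Integrates the binomial likelihood over a single Gaussian random
    intercept per cluster with scipy.integrate.quad.  Slow; used only to
    validate the Laplace route.  Includes the binomial coefficients, which
    cancel in any likelihood-ratio or argmax comparison.
    """
    y = np.atleast_1d(np.asarray(n_target, dtype=float))
    f = np.atleast_1d(np.asarray(n_distractor, dtype=float))
    n = y + f
    total = 0.0
    for yi, ni in zip(y, n):
        const = gammaln(ni + 1) - gammaln(yi + 1) - gammaln(ni - yi + 1)
        if sigma < 1e-8:
            eta = beta0
            total += const + yi * eta - ni * np.log1p(np.exp(eta))
            continue

        def integrand(u, yi=yi, ni=ni):
            eta = beta0 + u
            ll = yi * eta - ni * np.log1p(np.exp(eta))
            return np.exp(ll) * stats.norm.pdf(u, scale=sigma)

        val, _ = integrate.quad(integrand, -10 * sigma, 10 * sigma,
                                limit=200, epsabs=1e-13, epsrel=1e-11)
        total += const + np.log(val)
    return float(total)


# ---------------------------------------------------------------- BH / FDR

def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def adjust_pvalues(pvals, correction: str) -> np.ndarray:
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if correction == "fdr":
        return bh_adjust(p)
    if correction == "bonferroni":
        return np.minimum(p * p.size, 1.0)
    if correction == "none":
        return p.copy()
    raise ValueError(f"unknown correction {correction!r}")
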