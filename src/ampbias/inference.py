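"""Bayesian multinomial logistic-normal regression for PCR calibration data.

Model (counts ``Y`` are D x N, design ``X`` is p x N):

    Y_n    ~ Multinomial(depth_n, pi_n)
    pi_n   = phi_inverse(eta_n)
    eta_n  ~ N(Lambda X_n, Sigma)
    Lambda ~ MatrixNormal(Theta0, Sigma, Gamma0)     (rows x covariates)
    Sigma  ~ InverseWishart(Xi0, upsilon0)

Fitting follows the collapse -> Laplace -> uncollapse strategy:

1. *Collapse*: Lambda and Sigma are conjugate and integrate out
   analytically, leaving ``eta`` with a matrix-t prior
   ``p(eta) \\propto |Xi0 + (eta - Theta0 X) K^{-1} (eta - Theta0 X)^T|^{-(upsilon0+N)/2}``
   with ``K = I_N + X^T Gamma0 X``.
2. *Laplace*: the collapsed posterior ``p(eta | Y)`` is maximized
   (quasi-Newton with analytic gradient, then Newton polish with the exact
   dense Hessian) and approximated by a Gaussian at the mode with covariance
   equal to the inverse negative Hessian.
3. *Uncollapse*: for every Gaussian draw of ``eta``, Sigma is drawn from its
   conjugate inverse-Wishart conditional and Lambda from its conjugate
   matrix-normal conditional, yielding index-aligned joint draws of
   (Lambda, Sigma, eta).

The per-community baseline columns of Lambda are the cycle-0 log-ratio
compositions ``alpha``; the cycle-covariate column is the per-cycle
amplification bias ``beta``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize
from scipy.special import gammaln, multigammaln
from scipy.stats import invwishart

from .compositions import ContrastMatrix, make_contrast_matrix
from .synthetic import CountMatrix, DesignMatrix

__all__ = [
    "PosteriorDraws",
    "PriorSpec",
    "collapsed_log_posterior",
    "collapsed_prior_logpdf",
    "default_prior",
    "extract_alpha_beta",
    "fit_mln",
    "multinomial_loglik",
    "summarize_posterior",
]


@dataclass
class PriorSpec:
    """Matrix-normal--inverse-Wishart prior hyperparameters."""

    theta0: np.ndarray  # (D-1, p) prior mean of Lambda
    gamma0: np.ndarray  # (p, p) column covariance
    xi0: np.ndarray  # (D-1, D-1) inverse-Wishart scale
    upsilon0: float  # degrees of freedom

    def __post_init__(self) -> None:
        th = np.asarray(self.theta0, dtype=float)
        g = np.asarray(self.gamma0, dtype=float)
        xi = np.asarray(self.xi0, dtype=float)
        r, p = th.shape
        if g.shape != (p, p) or xi.shape != (r, r):
            raise ValueError("prior hyperparameter shapes are inconsistent")
        for name, m in (("gamma0", g), ("xi0", xi)):
            if np.max(np.abs(m - m.T)) > 1e-10:
                raise ValueError(f"{name} must be symmetric")
            try:
                linalg.cholesky(m, lower=True)
            except linalg.LinAlgError as exc:
                raise ValueError(f"{name} must be positive definite") from exc
        if not self.upsilon0 > r:
            raise ValueError(f"upsilon0 must exceed D-1 = {r}")
        self.theta0, self.gamma0, self.xi0 = th, (g + g.T) / 2, (xi + xi.T) / 2

    @property
    def r(self) -> int:
        return self.theta0.shape[0]

    @property
    def p(self) -> int:
        return self.theta0.shape[1]


def default_prior(D: int, p: int, gamma_scale: float = 100.0) -> PriorSpec:
    """Weakly informative default centered on "no bias, no structure".

    ``Theta0 = 0``, ``upsilon0 = D + 3`` and ``Xi0 = (upsilon0 - D) I`` so
    that the prior mean of Sigma is the identity on contrast coordinates.
    ``Gamma0 = gamma_scale * I_p``: in the conjugate matrix-normal prior the
    coefficient variance is ``Sigma (x) Gamma0``, i.e. tied to the residual
    scale, so a unit Gamma0 would shrink cycle-0 baselines hard exactly when
    replicates agree well.  The default makes each coefficient's prior sd
    ten residual sds — permissive on the scale of log-ratio compositions.
    """
    if D < 2 or p < 1:
        raise ValueError("need D >= 2 taxa and p >= 1 covariates")
    upsilon0 = D + 3.0
    return PriorSpec(
        theta0=np.zeros((D - 1, p)),
        gamma0=gamma_scale * np.eye(p),
        xi0=(upsilon0 - D) * np.eye(D - 1),
        upsilon0=upsilon0,
    )


class _CollapsedModel:
    """Collapsed log posterior over eta with analytic gradient and Hessian.

    eta is handled as an (r, N) matrix; flattened vectors use column-major
    (Fortran) order so each sample occupies a contiguous block.
    """

    def __init__(self, counts: np.ndarray, X: np.ndarray, prior: PriorSpec, psi: ContrastMatrix):
        Y = np.asarray(counts, dtype=float)
        X = np.asarray(X, dtype=float)
        D, N = Y.shape
        r, p = D - 1, X.shape[0]
        if prior.r != r or prior.p != p or psi.D != D or X.shape[1] != N:
            raise ValueError("counts, design, prior and basis dimensions are inconsistent")
        self.Y, self.X, self.prior, self.psi = Y, X, prior, psi
        self.D, self.N, self.r, self.p = D, N, r, p
        self.depths = Y.sum(axis=0)
        self.A = psi.pinv  # (D, r): log pi = A eta - lse(A eta)
        self.M = prior.theta0 @ X  # (r, N)
        K = np.eye(N) + X.T @ prior.gamma0 @ X
        self.K_inv = linalg.inv((K + K.T) / 2)
        self.a = prior.upsilon0 + N  # matrix-t exponent (x2)
        sign, logdet_K = np.linalg.slogdet(K)
        sign_xi, logdet_xi = np.linalg.slogdet(prior.xi0)
        self.mt_const = (
            -0.5 * r * N * np.log(np.pi)
            - 0.5 * r * logdet_K
            + 0.5 * prior.upsilon0 * logdet_xi
            + multigammaln(0.5 * (prior.upsilon0 + N), r)
            - multigammaln(0.5 * prior.upsilon0, r)
        )
        self.mult_const = float(
            (gammaln(self.depths + 1) - gammaln(Y + 1).sum(axis=0)).sum()
        )

    # -- pieces ---------------------------------------------------------
    def _log_pi(self, eta: np.ndarray) -> np.ndarray:
        U = self.A @ eta  # (D, N)
        U = U - U.max(axis=0, keepdims=True)
        return U - np.log(np.exp(U).sum(axis=0, keepdims=True))

    def multinomial(self, eta: np.ndarray) -> float:
        return float((self.Y * self._log_pi(eta)).sum()) + self.mult_const

    def _S(self, eta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        E = eta - self.M
        EB = E @ self.K_inv
        S = self.prior.xi0 + EB @ E.T
        return E, (S + S.T) / 2

    def matrix_t(self, eta: np.ndarray) -> float:
        _, S = self._S(eta)
        sign, logdet_S = np.linalg.slogdet(S)
        return self.mt_const - 0.5 * self.a * logdet_S

    def value(self, eta: np.ndarray) -> float:
        return self.multinomial(eta) + self.matrix_t(eta)

    def grad(self, eta: np.ndarray) -> np.ndarray:
        P = np.exp(self._log_pi(eta))  # (D, N)
        g_mult = self.A.T @ (self.Y - self.depths * P)
        E, S = self._S(eta)
        g_mt = -self.a * linalg.solve(S, E @ self.K_inv, assume_a="pos")
        return g_mult + g_mt

    def hessian(self, eta: np.ndarray) -> np.ndarray:
        """Exact dense Hessian of the collapsed log posterior, (rN, rN)."""
        r, N, a = self.r, self.N, self.a
        P = np.exp(self._log_pi(eta))
        H = np.zeros((r * N, r * N))
        for n in range(N):  # multinomial term is block diagonal per sample
            pn = P[:, n]
            Hn = -self.depths[n] * self.A.T @ (np.diag(pn) - np.outer(pn, pn)) @ self.A
            sl = slice(n * r, (n + 1) * r)
            H[sl, sl] += Hn
        E, S = self._S(eta)
        S_inv = linalg.inv(S)
        B = self.K_inv
        F = S_inv @ E @ B  # (r, N)
        W = B @ E.T @ S_inv @ E @ B  # (N, N)
        # commutation matrix: vec(E) -> vec(E^T), column-major
        idx = np.arange(r * N)
        i, j = idx % r, idx // r
        comm = np.zeros((r * N, r * N))
        comm[j + N * i, idx] = 1.0
        H_mt = a * (np.kron(W, S_inv) + np.kron(F.T, F) @ comm - np.kron(B, S_inv))
        return H + H_mt


def _check_inputs(counts: CountMatrix, design: DesignMatrix, prior, psi):
    if counts.N != design.N:
        raise ValueError("counts and design have different sample counts")
    sv = np.linalg.svd(design.X, compute_uv=False)
    if sv[-1] <= max(design.X.shape) * np.finfo(float).eps * sv[0]:
        raise ValueError("design matrix is rank deficient; coefficients are not identifiable")
    if psi is None:
        psi = make_contrast_matrix("alr", counts.D)
    if prior is None:
        prior = default_prior(counts.D, design.p)
    return prior, psi


def collapsed_log_posterior(eta, counts: CountMatrix, design: DesignMatrix, prior=None, psi=None) -> float:
    """Log of p(Y | eta) p(eta): multinomial likelihood plus the matrix-t
    prior obtained by marginalizing (Lambda, Sigma) analytically."""
    prior, psi = _check_inputs(counts, design, prior, psi)
    model = _CollapsedModel(counts.counts, design.X, prior, psi)
    return model.value(np.asarray(eta, dtype=float))


def collapsed_prior_logpdf(eta, design: DesignMatrix, prior: PriorSpec, psi=None) -> float:
    """Matrix-t log density of eta with (Lambda, Sigma) marginalized out."""
    r = prior.r
    if psi is None:
        psi = make_contrast_matrix("alr", r + 1)
    dummy = np.ones((r + 1, design.N))
    model = _CollapsedModel(dummy, design.X, prior, psi)
    return model.matrix_t(np.asarray(eta, dtype=float))


def multinomial_loglik(eta, counts: CountMatrix, psi=None) -> float:
    """Multinomial log likelihood of the counts given latent log-ratios eta."""
    if psi is None:
        psi = make_contrast_matrix("alr", counts.D)
    X = np.zeros((1, counts.N))
    prior = default_prior(counts.D, 1)
    model = _CollapsedModel(counts.counts, X + 1.0, prior, psi)
    return model.multinomial(np.asarray(eta, dtype=float))


@dataclass
class PosteriorDraws:
    """Index-aligned joint posterior draws from the fitted model."""

    lambda_draws: np.ndarray  # (S, D-1, p)
    sigma_draws: np.ndarray  # (S, D-1, D-1)
    eta_draws: np.ndarray  # (S, D-1, N)
    psi: ContrastMatrix
    covariate_names: list[str]
    cycle_row: int
    eta_mode: np.ndarray  # (D-1, N) Laplace mode, independent of S

    def __post_init__(self) -> None:
        S = self.lambda_draws.shape[0]
        if S < 1 or self.sigma_draws.shape[0] != S or self.eta_draws.shape[0] != S:
            raise ValueError("draws must be index-aligned with S >= 1")
        self.covariate_names = list(self.covariate_names)

    @property
    def S(self) -> int:
        return self.lambda_draws.shape[0]

    @property
    def communities(self) -> list[str]:
        return [n for i, n in enumerate(self.covariate_names) if i != self.cycle_row]


def fit_mln(
    counts: CountMatrix,
    design: DesignMatrix,
    prior: PriorSpec | None = None,
    psi: ContrastMatrix | None = None,
    n_draws: int = 2000,
    seed: int = 0,
    max_iter: int = 10_000,
    gtol: float = 1e-6,
) -> PosteriorDraws:
    """Fit the model by collapse -> Laplace -> uncollapse.

    Raises ``RuntimeError`` with diagnostics if the optimizer cannot reach
    gradient max-norm below ``gtol`` within the iteration budget.
    """
    prior, psi = _check_inputs(counts, design, prior, psi)
    model = _CollapsedModel(counts.counts, design.X, prior, psi)
    r, N = model.r, model.N

    # deterministic warm start: pseudo-count log-ratios of the observed counts
    comp0 = counts.compositions(pseudo_count=0.5)
    eta = psi.matrix @ np.log(comp0)

    def neg(v):
        e = v.reshape(r, N, order="F")
        return -model.value(e), -model.grad(e).flatten(order="F")

    res = optimize.minimize(
        neg,
        eta.flatten(order="F"),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": 1e-14, "gtol": 1e-8, "maxfun": 5 * max_iter},
    )
    eta = res.x.reshape(r, N, order="F")

    # Newton polish with the exact Hessian to drive the gradient to gtol
    for _ in range(60):
        g = model.grad(eta)
        if np.max(np.abs(g)) < gtol:
            break
        H = model.hessian(eta)
        negH = -(H + H.T) / 2
        jitter = 0.0
        for _try in range(8):
            try:
                cf = linalg.cho_factor(negH + jitter * np.eye(negH.shape[0]), lower=True)
                break
            except linalg.LinAlgError:
                jitter = max(jitter * 10.0, 1e-8)
        step = linalg.cho_solve(cf, g.flatten(order="F")).reshape(r, N, order="F")
        # near the mode the objective change is below float precision, so
        # accept any step that shrinks the gradient norm
        g_norm, f0 = np.max(np.abs(g)), model.value(eta)
        accepted = False
        t = 1.0
        while t > 1e-8:
            cand = eta + t * step
            if np.max(np.abs(model.grad(cand))) < g_norm or model.value(cand) > f0:
                eta, accepted = cand, True
                break
            t *= 0.5
        if not accepted:
            break
    grad_norm = float(np.max(np.abs(model.grad(eta))))
    if grad_norm > gtol:
        raise RuntimeError(
            "collapsed-posterior optimization did not converge: "
            f"grad max-norm {grad_norm:.3e} > {gtol:.1e} "
            f"(L-BFGS iterations {res.nit}, message {res.message!r})"
        )

    # Laplace covariance from the exact negative Hessian at the mode
    H = model.hessian(eta)
    negH = -(H + H.T) / 2
    jitter = 0.0
    while True:
        try:
            L = linalg.cholesky(negH + jitter * np.eye(negH.shape[0]), lower=True)
            break
        except linalg.LinAlgError:
            jitter = max(jitter * 10.0, 1e-10)
            if jitter > 1e-2:
                raise RuntimeError("Laplace Hessian is not negative definite at the mode")

    rng = np.random.default_rng(seed)
    S = int(n_draws)
    if S < 1:
        raise ValueError("n_draws must be >= 1")
    z = rng.standard_normal((r * N, S))
    eta_flat = eta.flatten(order="F")[:, None] + linalg.solve_triangular(L.T, z, lower=False)
    eta_draws = eta_flat.T.reshape(S, N, r).transpose(0, 2, 1)  # undo column-major flatten
    # note: reshape(S, N, r) then transpose restores (r, N) per draw because
    # the flat layout is column-major in (r, N)

    # conjugate uncollapse
    X = design.X
    g0_inv = linalg.inv(prior.gamma0)
    gN_inv = g0_inv + X @ X.T
    gamma_N = linalg.inv((gN_inv + gN_inv.T) / 2)
    gamma_N = (gamma_N + gamma_N.T) / 2
    chol_gamma_N = linalg.cholesky(gamma_N, lower=True)
    base = prior.theta0 @ g0_inv
    prior_quad = prior.theta0 @ g0_inv @ prior.theta0.T
    upsilon_N = prior.upsilon0 + N

    lambda_draws = np.empty((S, r, design.p))
    sigma_draws = np.empty((S, r, r))
    for s in range(S):
        eta_s = eta_draws[s]
        theta_N = (base + eta_s @ X.T) @ gamma_N
        xi_N = prior.xi0 + prior_quad + eta_s @ eta_s.T - theta_N @ gN_inv @ theta_N.T
        xi_N = (xi_N + xi_N.T) / 2
        sigma_s = invwishart.rvs(df=upsilon_N, scale=xi_N, random_state=rng)
        sigma_s = np.atleast_2d(sigma_s)
        chol_sigma = linalg.cholesky((sigma_s + sigma_s.T) / 2, lower=True)
        lambda_draws[s] = theta_N + chol_sigma @ rng.standard_normal((r, design.p)) @ chol_gamma_N.T
        sigma_draws[s] = sigma_s

    return PosteriorDraws(
        lambda_draws=lambda_draws,
        sigma_draws=sigma_draws,
        eta_draws=eta_draws,
        psi=psi,
        covariate_names=design.covariate_names,
        cycle_row=design.cycle_row,
        eta_mode=eta,
    )


def extract_alpha_beta(draws: PosteriorDraws, community: str) -> tuple[np.ndarray, np.ndarray]:
    """Slice a community's baseline column and the shared bias column.

    Returns ``(alpha_draws, beta_draws)``, each (S, D-1), taken from the
    same joint Lambda draws so downstream estimands keep the posterior
    correlation between alpha and beta.
    """
    if community not in draws.covariate_names:
        raise ValueError(f"unknown community {community!r}; have {draws.communities}")
    col = draws.covariate_names.index(community)
    if col == draws.cycle_row:
        raise ValueError(f"{community!r} is the cycle covariate, not a community")
    return draws.lambda_draws[:, :, col], draws.lambda_draws[:, :, draws.cycle_row]


def summarize_posterior(draws: PosteriorDraws) -> pd.DataFrame:
    """Tidy per-coefficient summary: mean, SD, and 2.5/50/97.5 percentiles."""
    rows = []
    for ci, cname in enumerate(draws.covariate_names):
        for li in range(draws.lambda_draws.shape[1]):
            v = draws.lambda_draws[:, li, ci]
            lo, med, hi = np.percentile(v, [2.5, 50.0, 97.5])
            rows.append(
                {
                    "covariate": cname,
                    "contrast": li,
                    "mean": v.mean(),
                    "sd": v.std(ddof=1),
                    "p2.5": lo,
                    "p50": med,
                    "p97.5": hi,
                }
            )
    return pd.DataFrame(rows)
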