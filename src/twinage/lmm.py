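"""Linear mixed models for twin cohorts, written from the likelihood.

Two fitting paths share one model family

    y = X beta + sum_k Z_k u_k + e,   u_k ~ N(0, sigma2_k I),  e ~ N(0, sigma2_e I)

* :func:`fit_lmm` — a general dense engine for arbitrary crossed random
  intercept factors (family, primer index, sequencing date...).  The
  marginal covariance is profiled as ``sigma2_e * (I + sum_k gamma_k Z_k Z_k')``
  and the variance ratios ``gamma_k`` are optimised numerically; ``beta``
  and ``sigma2_e`` have closed forms given the ratios.

* :class:`FamilyRotation` + the ``*_batch`` functions — a fast path for the
  common case of a single family random effect over twin pairs and
  singletons.  ``Z Z'`` is block diagonal with known eigenvectors
  (within-pair sum and difference), so one sparse rotation turns every
  likelihood evaluation into a weighted least squares with at most three
  distinct weights.  This is what makes permutation scans over thousands of
  features affordable.

* :func:`fit_ace` — REML twin ACE decomposition with age as a fixed effect:
  2x2 family blocks with off-diagonal ``sigma2_A + sigma2_C`` (MZ) or
  ``sigma2_A/2 + sigma2_C`` (DZ), components box-constrained at zero.  The
  age variance share is ``beta_age^2 * Var(age)`` so that all components
  are on one scale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize, stats

from .exceptions import ContractError, ValidationError

logger = logging.getLogger(__name__)

LOG2PI = math.log(2.0 * math.pi)

# optimisation box for log variance ratios; exp(-20) ~ 2e-9 is numerically zero
_LOG_GAMMA_BOUNDS = (-20.0, 12.0)


# ---------------------------------------------------------------------------
# general dense engine


@dataclass
class FitResult:
    """A fitted mixed (or fixed-effect) model."""

    beta: np.ndarray
    beta_se: np.ndarray
    beta_names: list[str]
    varcomps: dict[str, float]          # sigma2 per random factor
    sigma2_resid: float
    loglik: float
    method: str                          # "ML" or "REML"
    converged: bool
    residuals_marginal: np.ndarray       # y - X beta
    residuals_conditional: np.ndarray    # y - X beta - Z u  (BLUP-adjusted)
    n: int
    n_fixed: int

    def coef(self, name: str) -> float:
        return float(self.beta[self.beta_names.index(name)])

    def coef_se(self, name: str) -> float:
        return float(self.beta_se[self.beta_names.index(name)])


def _drop_aliased(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str]]:
    """Drop linearly dependent columns (keeping the earliest) with a warning."""
    if X.shape[1] == 0:
        return X, names
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        keep = sorted(piv[:rank])
        dropped = [names[i] for i in range(X.shape[1]) if i not in keep]
        logger.warning("dropping aliased fixed-effect column(s): %s", dropped)
        return X[:, keep], [names[i] for i in keep]
    return X, names


def _indicator(labels) -> np.ndarray:
    labels = np.asarray(labels)
    _, codes = np.unique(labels, return_inverse=True)
    Z = np.zeros((labels.size, codes.max() + 1))
    Z[np.arange(labels.size), codes] = 1.0
    return Z


def fit_lmm(
    y,
    X,
    random: dict | None = None,
    method: str = "ML",
    names: list[str] | None = None,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> FitResult:
    """Fit a linear mixed model with crossed random intercepts.

    Parameters
    ----------
    y : (n,) response (already normalised upstream).
    X : (n, p) fixed-effect design (include the intercept explicitly).
    random : mapping factor-name -> (n,) group labels.  May be empty/None,
        in which case the fit is ordinary least squares.
    method : "ML" for likelihood-ratio testing, "REML" for variance
        components.

    Non-convergence is reported through ``converged=False`` rather than an
    exception so that per-feature scans can skip and log.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = y.size
    if X.shape[0] != n:
        raise ValidationError(f"fit_lmm: response length {n} != design rows {X.shape[0]}")
    if not np.all(np.isfinite(y)) or not np.all(np.isfinite(X)):
        raise ValidationError("fit_lmm: missing/non-finite values must be dropped upstream")
    if method not in ("ML", "REML"):
        raise ContractError(f"fit_lmm: unknown method '{method}'")
    names = list(names) if names is not None else [f"x{i}" for i in range(X.shape[1])]
    X, names = _drop_aliased(X, names)
    p = X.shape[1]

    random = dict(random or {})
    for key, labels in random.items():
        if np.unique(np.asarray(labels)).size < 2:
            raise ValidationError(f"fit_lmm: random factor '{key}' has < 2 levels")
    Zs = [_indicator(lab) for lab in random.values()]
    ZZt = [Z @ Z.T for Z in Zs]
    K = len(Zs)

    def _components(log_gamma: np.ndarray):
        gam = np.exp(log_gamma)
        V0 = np.eye(n)
        for g, M in zip(gam, ZZt):
            V0 += g * M
        c, low = linalg.cho_factor(V0, lower=True)
        logdet = 2.0 * np.log(np.diag(c)).sum()
        ViX = linalg.cho_solve((c, low), X)
        Viy = linalg.cho_solve((c, low), y)
        XtViX = X.T @ ViX
        beta = linalg.solve(XtViX, X.T @ Viy, assume_a="pos")
        r = y - X @ beta
        quad = float(r @ linalg.cho_solve((c, low), r))
        return gam, (c, low), logdet, XtViX, beta, r, quad

    def neg2ll(log_gamma: np.ndarray) -> float:
        try:
            _, _, logdet, XtViX, _, _, quad = _components(log_gamma)
        except linalg.LinAlgError:
            return 1e12
        if method == "ML":
            s2 = quad / n
            return n * (LOG2PI + math.log(max(s2, 1e-300))) + logdet + n
        s2 = quad / (n - p)
        sign, ld2 = np.linalg.slogdet(XtViX)
        return (n - p) * (LOG2PI + math.log(max(s2, 1e-300))) + logdet + ld2 + (n - p)

    converged = True
    if K == 0:
        opt_x = np.zeros(0)
    else:
        res = optimize.minimize(
            neg2ll,
            x0=np.zeros(K),
            method="L-BFGS-B",
            bounds=[_LOG_GAMMA_BOUNDS] * K,
            options={"ftol": tol, "maxiter": max_iter},
        )
        opt_x = res.x
        converged = bool(res.success)
        if not converged:
            logger.warning("fit_lmm: optimiser did not converge (%s)", res.message)
        # flat directions (e.g. every group of size 1) leave the variance
        # split unidentified; prefer the zero-variance boundary then
        best = neg2ll(opt_x)
        for k in range(K):
            cand = opt_x.copy()
            cand[k] = _LOG_GAMMA_BOUNDS[0]
            val = neg2ll(cand)
            if val <= best + 1e-7:
                opt_x, best = cand, val

    gam, chol, logdet, XtViX, beta, r_marg, quad = _components(opt_x)
    dof = n if method == "ML" else n - p
    sigma2_e = quad / dof
    cov_beta = sigma2_e * linalg.inv(XtViX)
    beta_se = np.sqrt(np.maximum(np.diag(cov_beta), 0.0))
    loglik = -0.5 * neg2ll(opt_x)

    # BLUPs and conditional residuals
    Vi_r = linalg.cho_solve(chol, r_marg)
    r_cond = r_marg.copy()
    varcomps: dict[str, float] = {}
    for key, g, Z in zip(random.keys(), gam, Zs):
        u = g * (Z.T @ Vi_r)
        r_cond -= Z @ u
        varcomps[key] = float(g * sigma2_e)

    return FitResult(
        beta=beta,
        beta_se=beta_se,
        beta_names=names,
        varcomps=varcomps,
        sigma2_resid=float(sigma2_e),
        loglik=float(loglik),
        method=method,
        converged=converged,
        residuals_marginal=r_marg,
        residuals_conditional=r_cond,
        n=n,
        n_fixed=p,
    )


def lrt_nested(full: FitResult, reduced: FitResult) -> tuple[float, float]:
    """Likelihood-ratio test of one extra fixed term; chi-square with 1 df.

    The statistic ``2 (l_full - l_reduced)`` is clipped at zero (solver
    noise can make it marginally negative for a true null).
    """
    if full.method != "ML" or reduced.method != "ML":
        raise ContractError("lrt_nested: both fits must be ML, not REML")
    if full.n != reduced.n:
        raise ContractError("lrt_nested: fits are on different rows")
    stat = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    return stat, float(stats.chi2.sf(stat, df=1))


# ---------------------------------------------------------------------------
# fast path: single family random effect over pairs/singletons


class FamilyRotation:
    """Orthonormal rotation diagonalising the family covariance.

    For a family random intercept over pairs and singletons ``Z Z'`` is block
    diagonal; its eigenvectors are the within-pair sum ``(e_i + e_j)/sqrt(2)``
    (eigenvalue 2), the within-pair difference (eigenvalue 0) and the
    singleton coordinates (eigenvalue 1).  After rotating response and
    design, the marginal covariance is diagonal with at most three distinct
    entries ``1 + gamma * lambda``, so each profile-likelihood evaluation is
    a small weighted least squares.
    """

    def __init__(self, family_labels):
        fam = np.asarray(family_labels)
        order: dict = {}
        for idx, f in enumerate(fam):
            order.setdefault(f, []).append(idx)
        ii, jj, ss = [], [], []
        for members in order.values():
            if len(members) == 2:
                ii.append(members[0])
                jj.append(members[1])
            elif len(members) == 1:
                ss.append(members[0])
            else:
                raise ValidationError("FamilyRotation: a family has more than 2 samples")
        self.ii = np.array(ii, dtype=int)
        self.jj = np.array(jj, dtype=int)
        self.ss = np.array(ss, dtype=int)
        self.n = fam.size
        lam_parts, group_parts = [], []
        if len(ii):
            lam_parts += [np.full(len(ii), 2.0), np.zeros(len(ii))]
        if len(ss):
            lam_parts += [np.ones(len(ss))]
        self.lam = np.concatenate(lam_parts) if lam_parts else np.zeros(0)
        # distinct eigenvalue groups and their sizes
        self.lam_values, inv = np.unique(self.lam, return_inverse=True)
        self.group_index = inv
        self.group_sizes = np.bincount(inv).astype(float)

    def rotate(self, M: np.ndarray) -> np.ndarray:
        """Apply the rotation along the sample axis (last axis = samples)."""
        M = np.asarray(M, dtype=float)
        vec = M.ndim == 1
        if vec:
            M = M[None, :]
        inv_sqrt2 = 1.0 / math.sqrt(2.0)
        parts = []
        if len(self.ii):
            parts.append((M[:, self.ii] + M[:, self.jj]) * inv_sqrt2)
            parts.append((M[:, self.ii] - M[:, self.jj]) * inv_sqrt2)
        if len(self.ss):
            parts.append(M[:, self.ss])
        out = np.concatenate(parts, axis=1)
        return out[0] if vec else out


@dataclass
class BatchFit:
    """Profile-ML solutions for many features sharing one design."""

    gamma: np.ndarray        # (F,) family-to-residual variance ratio
    loglik: np.ndarray       # (F,) maximised log-likelihood
    beta: np.ndarray         # (F, p)
    sigma2: np.ndarray       # (F,) residual variance (ML)
    n: int


def _profile_ml_batch(Yr: np.ndarray, Xr: np.ndarray, rot: FamilyRotation) -> BatchFit:
    """Maximise the single-ratio profile ML likelihood for every row of Yr.

    Grid search over the variance ratio followed by vectorised golden-section
    refinement; the grid guards against the (rare) flat or boundary optimum
    and refinement brings the ratio to ~1e-8 relative precision.
    """
    F, n = Yr.shape
    p = Xr.shape[1]
    lamv = rot.lam_values            # (G,)
    G = lamv.size
    gi = rot.group_index
    m = rot.group_sizes              # (G,)

    A = np.zeros((G, p, p))
    B = np.zeros((G, p, F))
    C = np.zeros((G, F))
    for g in range(G):
        sel = gi == g
        Xg = Xr[sel]
        A[g] = Xg.T @ Xg
        B[g] = Xg.T @ Yr[:, sel].T
        C[g] = (Yr[:, sel] ** 2).sum(axis=1)

    def nll(gamma: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        w = 1.0 / (1.0 + gamma[:, None] * lamv[None, :])           # (F, G)
        M = np.einsum("fg,gpq->fpq", w, A)
        R = np.einsum("fg,gpf->fp", w, B)
        quad0 = np.einsum("fg,gf->f", w, C)
        beta = np.linalg.solve(M, R[..., None])[..., 0]
        rss = np.maximum(quad0 - np.einsum("fp,fp->f", R, beta), 1e-300)
        logdet = (m[None, :] * np.log1p(gamma[:, None] * lamv[None, :])).sum(axis=1)
        return n * np.log(rss / n) + logdet, beta, rss

    grid = np.concatenate([[0.0], np.logspace(-4, 3, 36)])
    vals = np.empty((grid.size, F))
    for k, g in enumerate(grid):
        vals[k], _, _ = nll(np.full(F, g))
    best = vals.argmin(axis=0)
    lo = grid[np.maximum(best - 1, 0)]
    hi = grid[np.minimum(best + 1, grid.size - 1)]

    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = lo.copy(), hi.copy()
    c1 = b - invphi * (b - a)
    c2 = a + invphi * (b - a)
    f1, _, _ = nll(c1)
    f2, _, _ = nll(c2)
    for _ in range(60):
        take1 = f1 < f2
        b = np.where(take1, c2, b)
        a = np.where(take1, a, c1)
        c1 = b - invphi * (b - a)
        c2 = a + invphi * (b - a)
        f1, _, _ = nll(c1)
        f2, _, _ = nll(c2)
    gamma = 0.5 * (a + b)
    gamma = np.maximum(gamma, 0.0)
    final, beta, rss = nll(gamma)
    # the exact boundary gamma = 0 is a valid candidate; keep the better of the two
    zero_val, zero_beta, zero_rss = nll(np.zeros(F))
    use0 = zero_val <= final + 1e-7          # flat profiles snap to the boundary
    gamma = np.where(use0, 0.0, gamma)
    final = np.where(use0, zero_val, final)
    beta = np.where(use0[:, None], zero_beta, beta)
    rss = np.where(use0, zero_rss, rss)
    loglik = -0.5 * (final + n + n * LOG2PI)
    return BatchFit(gamma=gamma, loglik=loglik, beta=beta, sigma2=rss / n, n=n)


def age_scan_batch(
    Y: np.ndarray,
    X_reduced: np.ndarray,
    age: np.ndarray,
    family_labels,
    rot: FamilyRotation | None = None,
    reduced_fit: BatchFit | None = None,
):
    """LRT for an age effect on every feature with a family random intercept.

    ``Y`` is (features, samples); ``X_reduced`` the covariate design without
    age; the full design appends the age column.  Returns a dict with the
    signed age coefficient, the chi-square(1) LRT statistic and nominal p,
    plus both batch fits (the reduced fit can be reused across permutations
    of age, which leave it untouched).
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if rot is None:
        rot = FamilyRotation(family_labels)
    Yr = rot.rotate(Y)
    if reduced_fit is None:
        Xr_red = rot.rotate(np.asarray(X_reduced, dtype=float).T).T
        reduced_fit = _profile_ml_batch(Yr, Xr_red, rot)
    X_full = np.column_stack([X_reduced, np.asarray(age, dtype=float)])
    Xr_full = rot.rotate(X_full.T).T
    full_fit = _profile_ml_batch(Yr, Xr_full, rot)
    lrt = np.maximum(0.0, 2.0 * (full_fit.loglik - reduced_fit.loglik))
    pvals = stats.chi2.sf(lrt, df=1)
    return {
        "beta_age": full_fit.beta[:, -1],
        "lrt": lrt,
        "p": pvals,
        "full": full_fit,
        "reduced": reduced_fit,
        "rotation": rot,
    }


def whitened_residuals_batch(Y: np.ndarray, X: np.ndarray, family_labels) -> np.ndarray:
    """Family-decorrelated (whitened) residuals, per feature.

    ``V0^{-1/2} (y - X beta)`` with the per-feature fitted family variance
    ratio.  Unlike BLUP conditional residuals — which leave a negative
    within-pair correlation that makes downstream iid test statistics
    conservative against exchangeable permutation nulls — whitened
    residuals are exchangeable under the fitted model, which is what the
    interaction scans need.  Sample order is preserved.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    X = np.asarray(X, dtype=float)
    rot = FamilyRotation(family_labels)
    Yr = rot.rotate(Y)
    Xr = rot.rotate(X.T).T
    fit = _profile_ml_batch(Yr, Xr, rot)
    r = Y - fit.beta @ X.T
    gam = fit.gamma[:, None]
    out = r.copy()
    if len(rot.ii):
        # V0^{-1/2} on a pair block is a*I + b*J with a = 1 and
        # a + 2b = 1/sqrt(1 + 2 gamma)
        b = 0.5 * (1.0 / np.sqrt(1.0 + 2.0 * gam) - 1.0)
        s = r[:, rot.ii] + r[:, rot.jj]
        out[:, rot.ii] = r[:, rot.ii] + b * s
        out[:, rot.jj] = r[:, rot.jj] + b * s
    if len(rot.ss):
        out[:, rot.ss] = r[:, rot.ss] / np.sqrt(1.0 + gam)
    return out


def conditional_residuals_batch(Y: np.ndarray, X: np.ndarray, family_labels) -> np.ndarray:
    """Conditional residuals (fixed effects and family BLUPs removed), per feature.

    Equivalent to fitting each feature with :func:`fit_lmm` with a family
    random intercept and returning ``residuals_conditional``, but vectorised
    through the family rotation.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    X = np.asarray(X, dtype=float)
    rot = FamilyRotation(family_labels)
    Yr = rot.rotate(Y)
    Xr = rot.rotate(X.T).T
    fit = _profile_ml_batch(Yr, Xr, rot)
    r = Y - fit.beta @ X.T                       # marginal residuals (F, n)
    gam = fit.gamma[:, None]
    out = r.copy()
    if len(rot.ii):
        s = r[:, rot.ii] + r[:, rot.jj]
        shrink = gam * s / (1.0 + 2.0 * gam)
        out[:, rot.ii] = r[:, rot.ii] - shrink
        out[:, rot.jj] = r[:, rot.jj] - shrink
    if len(rot.ss):
        out[:, rot.ss] = r[:, rot.ss] / (1.0 + gam)
    return out


# ---------------------------------------------------------------------------
# twin ACE (+ age) variance decomposition


@dataclass
class VarianceComponents:
    """ACE variance components with the age share on the same scale."""

    sigma2_a: float
    sigma2_c: float
    sigma2_e: float
    sigma2_age: float
    beta_age: float
    loglik: float
    converged: bool
    n_pairs_mz: int
    n_pairs_dz: int

    @property
    def total(self) -> float:
        return self.sigma2_a + self.sigma2_c + self.sigma2_e + self.sigma2_age

    @property
    def h2(self) -> float:
        return self.sigma2_a / self.total

    @property
    def pve_age(self) -> float:
        return self.sigma2_age / self.total

    @property
    def proportions(self) -> dict[str, float]:
        t = self.total
        return {
            "A": self.sigma2_a / t,
            "C": self.sigma2_c / t,
            "E": self.sigma2_e / t,
            "age": self.sigma2_age / t,
        }


def fit_ace(values, samples, min_pairs: int = 20) -> VarianceComponents:
    """REML ACE decomposition with age as fixed effect, on complete twin pairs.

    Family blocks are 2x2 with diagonal ``sA + sC + sE`` and off-diagonal
    ``sA + sC`` (MZ) or ``sA/2 + sC`` (DZ); components are constrained
    non-negative.  ``sigma2_age = beta_age^2 * Var(age)`` puts the age
    contribution on the variance scale of the other components.

    ``values`` must align with ``samples`` (one value per sample row).
    Raises if fewer than ``min_pairs`` complete pairs or if only one
    zygosity is present (A and C are then non-identifiable).
    """
    y_all = np.asarray(values, dtype=float).ravel()
    mz = samples.complete_pairs("MZ")
    dz = samples.complete_pairs("DZ")
    if len(mz) == 0 or len(dz) == 0:
        raise ValidationError(
            "fit_ace: both MZ and DZ complete pairs are required "
            f"(got {len(mz)} MZ, {len(dz)} DZ) — A and C are not identifiable otherwise"
        )
    if len(mz) + len(dz) < min_pairs:
        raise ValidationError(f"fit_ace: need >= {min_pairs} complete pairs, got {len(mz) + len(dz)}")

    pairs = np.array(mz + dz)
    is_mz = np.concatenate([np.ones(len(mz), bool), np.zeros(len(dz), bool)])
    ages = samples.ages
    Yp = y_all[pairs]                               # (P, 2)
    age_p = ages[pairs[:, 0]]                       # co-twins share age
    P = len(pairs)
    n = 2 * P
    Xp = np.zeros((P, 2, 2))
    Xp[:, :, 0] = 1.0
    Xp[:, :, 1] = age_p[:, None]
    p = 2

    kin_off = np.where(is_mz, 1.0, 0.5)            # coefficient of sigma2_A off-diagonal
    var_y = float(np.var(y_all[pairs].ravel()))
    floor = max(var_y, 1e-12) * 1e-8

    def neg2remll(theta: np.ndarray) -> float:
        sa, sc, se = theta
        t = sa + sc + se
        c = kin_off * sa + sc
        det = t * t - c * c
        if np.any(det <= 0) or t <= 0:
            return 1e12
        # blockwise inverse: [[t, -c], [-c, t]] / det
        inv_tt = t / det
        inv_tc = -c / det
        XtViX = np.zeros((p, p))
        XtViy = np.zeros(p)
        quad_y = 0.0
        # X block rows are [1, age], identical within a pair
        # Vi @ x for x constant within pair: (inv_tt + inv_tc) * x
        s = inv_tt + inv_tc                        # (P,)
        ones_q = 2.0 * s                           # 1' Vi 1 per block
        XtViX[0, 0] = ones_q.sum()
        XtViX[0, 1] = XtViX[1, 0] = (ones_q * age_p).sum()
        XtViX[1, 1] = (ones_q * age_p**2).sum()
        y1, y2 = Yp[:, 0], Yp[:, 1]
        Viy1 = inv_tt * y1 + inv_tc * y2
        Viy2 = inv_tc * y1 + inv_tt * y2
        XtViy[0] = (Viy1 + Viy2).sum()
        XtViy[1] = (age_p * (Viy1 + Viy2)).sum()
        try:
            beta = np.linalg.solve(XtViX, XtViy)
        except np.linalg.LinAlgError:
            return 1e12
        mu = beta[0] + beta[1] * age_p
        r1, r2 = y1 - mu, y2 - mu
        quad_y = (r1 * (inv_tt * r1 + inv_tc * r2) + r2 * (inv_tc * r1 + inv_tt * r2)).sum()
        logdetV = np.log(det).sum()
        sign, logdetX = np.linalg.slogdet(XtViX)
        return float(logdetV + logdetX + quad_y + (n - p) * LOG2PI)

    x0 = np.full(3, max(var_y, 1e-6) / 3.0)
    res = optimize.minimize(
        neg2remll,
        x0=x0,
        method="L-BFGS-B",
        bounds=[(0.0, None), (0.0, None), (floor, None)],
        options={"ftol": 1e-12, "maxiter": 1000},
    )
    sa, sc, se = res.x

    # fixed effects at the optimum for beta_age
    t = sa + sc + se
    c = kin_off * sa + sc
    det = t * t - c * c
    s = (t - c) / det
    ones_q = 2.0 * s
    XtViX = np.array(
        [
            [ones_q.sum(), (ones_q * age_p).sum()],
            [(ones_q * age_p).sum(), (ones_q * age_p**2).sum()],
        ]
    )
    inv_tt, inv_tc = t / det, -c / det
    y1, y2 = Yp[:, 0], Yp[:, 1]
    Viy_sum = (inv_tt + inv_tc) * (y1 + y2)
    XtViy = np.array([Viy_sum.sum(), (age_p * Viy_sum).sum()])
    beta = np.linalg.solve(XtViX, XtViy)
    beta_age = float(beta[1])
    sigma2_age = beta_age**2 * float(np.var(ages[pairs].ravel()))

    return VarianceComponents(
        sigma2_a=float(sa),
        sigma2_c=float(sc),
        sigma2_e=float(se),
        sigma2_age=float(sigma2_age),
        beta_age=beta_age,
        loglik=float(-0.5 * res.fun),
        converged=bool(res.success),
        n_pairs_mz=len(mz),
        n_pairs_dz=len(dz),
    )
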