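"""Cross-tissue sharing of age effects via Storey's pi1.

For an ordered tissue pair (discovery, replication) the nominal p-values
in the replication tissue are collected for the features significant in
the discovery tissue.  The Storey estimator

    pi0(lambda) = #{p > lambda} / (n * (1 - lambda)),   lambda in {0.05..0.95}

is smoothed with a cubic smoothing spline in lambda and evaluated at the
largest lambda; ``pi1 = 1 - pi0`` estimates the proportion of discovery
signals that replicate.  The pairwise matrix is directed — swapping
discovery and replication changes the conditioning set — and need not be
symmetric.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import UnivariateSpline

from .exceptions import ValidationError

logger = logging.getLogger(__name__)

DEFAULT_LAMBDAS = np.round(np.arange(0.05, 0.951, 0.05), 2)


@dataclass
class Pi1Estimate:
    pi0: float
    pi1: float
    n: int
    lambdas: np.ndarray = field(default_factory=lambda: DEFAULT_LAMBDAS.copy())
    pi0_raw: np.ndarray | None = None
    n_dropped: int = 0
    discovery: str = ""
    replication: str = ""


def crosstissue_pvalues(
    discovery: pd.DataFrame,
    replication: pd.DataFrame,
    alpha: float = 0.05,
    p_column: str = "nominal_p",
    sig_column: str = "significant",
) -> tuple[np.ndarray, int]:
    """Replication-tissue p-values for the discovery tissue's significant features.

    Both frames are feature-indexed scan results.  Features significant in
    discovery but absent from the replication scan are dropped and counted.
    Returns ``(pvalues, n_dropped)``.
    """
    hits = discovery.index[discovery[sig_column].astype(bool)]
    if len(hits) == 0:
        raise ValidationError("crosstissue_pvalues: discovery tissue has no significant features")
    present = hits.intersection(replication.index)
    if len(present) == 0:
        raise ValidationError("crosstissue_pvalues: no discovery hits present in replication results")
    dropped = len(hits) - len(present)
    if dropped:
        logger.info("crosstissue_pvalues: %d discovery hits absent in replication", dropped)
    return replication.loc[present, p_column].to_numpy(dtype=float), dropped


def estimate_pi1(
    pvalues,
    lambdas: np.ndarray = DEFAULT_LAMBDAS,
    method: str = "smoother",
    n_boot: int = 100,
    seed: int = 0,
) -> Pi1Estimate:
    """Storey pi0/pi1 from a vector of p-values.

    ``method="smoother"`` (default) fits a cubic smoothing spline to
    pi0(lambda) and evaluates it at max(lambda); ``method="bootstrap"``
    picks the lambda minimising the bootstrap mean squared error around the
    minimum raw estimate.  The estimate is clipped to [0, 1].
    """
    p = np.asarray(pvalues, dtype=float).ravel()
    if p.size < 100:
        raise ValidationError(f"estimate_pi1: need >= 100 p-values, got {p.size}")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValidationError("estimate_pi1: p-values outside [0, 1]")
    lambdas = np.asarray(lambdas, dtype=float)
    pi0_raw = np.array([(p > lam).mean() / (1.0 - lam) for lam in lambdas])

    if method == "smoother":
        # cubic smoothing spline; the smoothing level is tied to the
        # binomial noise of the raw estimates so the spline stays stiff
        w = 1.0 - lambdas
        spl = UnivariateSpline(lambdas, pi0_raw, w=w, k=3)
        pi0 = float(spl(lambdas.max()))
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        min_pi0 = pi0_raw.min()
        mse = np.zeros(lambdas.size)
        for _ in range(n_boot):
            pb = p[rng.integers(0, p.size, p.size)]
            pi0_b = np.array([(pb > lam).mean() / (1.0 - lam) for lam in lambdas])
            mse += (pi0_b - min_pi0) ** 2
        pi0 = float(pi0_raw[int(np.argmin(mse))])
    else:
        raise ValidationError(f"estimate_pi1: unknown method '{method}'")

    pi0 = float(np.clip(pi0, 0.0, 1.0))
    return Pi1Estimate(pi0=pi0, pi1=1.0 - pi0, n=p.size, lambdas=lambdas, pi0_raw=pi0_raw)


def pi1_matrix(
    results: dict[str, pd.DataFrame],
    alpha: float = 0.05,
    method: str = "smoother",
) -> pd.DataFrame:
    """Directed pi1 matrix across tissues (rows = discovery, cols = replication)."""
    tissues = list(results)
    out = pd.DataFrame(np.nan, index=tissues, columns=tissues)
    for disc in tissues:
        for repl in tissues:
            if disc == repl:
                continue
            try:
                pvals, _ = crosstissue_pvalues(results[disc], results[repl], alpha=alpha)
                est = estimate_pi1(pvals, method=method)
            except ValidationError as exc:
                logger.warning("pi1 %s->%s unavailable: %s", disc, repl, exc)
                continue
            out.loc[disc, repl] = est.pi1
    return out
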