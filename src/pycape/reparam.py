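"""Reparametrization of pairwise epistasis into directed influences.

For a marker pair fitted on N eigentraits, the N interaction coefficients
beta12^(j) are explained by two directed, phenotype-independent influence
coefficients (m12, m21) through the identity

    beta12^(j) = m12 * beta2^(j) + m21 * beta1^(j),    j = 1..N

where m12 is the influence of marker 1 (source) on marker 2 (target): the
source's presence rescales the target's effective allele dose.  For N = 2
the system is square and the solution exact (the pairwise fit's residuals
are unchanged); for N > 2 the least-squares solution is taken.  Standard
errors come from first-order (delta-method) propagation of the per-ET
coefficient covariances, and significance is judged on the standardized
effects z = m / SE (negative = suppressive, positive = enhancing).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "InfluenceEstimate",
    "solve_influences",
    "propagate_errors",
    "standardized_effects",
    "influence_jacobian",
    "reparametrize_pairs",
    "influence_table",
    "DEFAULT_COND_TOL",
]

DEFAULT_COND_TOL = 1e8


@dataclass
class InfluenceEstimate:
    """Directed influences for one marker pair.

    m12: influence of marker_1 on marker_2; m21 the reverse.  z = m/SE.
    status: "resolved", "unresolved" (ill-conditioned system or failed
    propagation) or "degenerate" (resolved but SE = 0, excluded from
    testing).
    """

    pair: tuple[str, str]
    m12: float = np.nan
    m21: float = np.nan
    se_m12: float = np.nan
    se_m21: float = np.nan
    z_m12: float = np.nan
    z_m21: float = np.nan
    status: str = "unresolved"


def _system(beta1, beta2, beta12):
    beta1 = np.asarray(beta1, dtype=float)
    beta2 = np.asarray(beta2, dtype=float)
    beta12 = np.asarray(beta12, dtype=float)
    if beta1.shape != beta2.shape or beta1.shape != beta12.shape:
        raise ValueError("beta1, beta2, beta12 must have equal length")
    if beta1.ndim != 1 or len(beta1) < 2:
        raise ValueError("need coefficients for at least 2 eigentraits")
    M = np.column_stack([beta2, beta1])
    return M, beta12


def solve_influences(beta1, beta2, beta12,
                     cond_tol: float = DEFAULT_COND_TOL) -> np.ndarray | None:
    """Solve the per-pair system for (m12, m21).

    Exact 2x2 solve for two ETs; least squares for more.  Returns None
    (unresolved) when the N x 2 system's singular-value ratio exceeds
    ``cond_tol`` — near-parallel main-effect vectors make the direction
    unidentifiable.
    """
    M, b = _system(beta1, beta2, beta12)
    if not np.all(np.isfinite(M)) or not np.all(np.isfinite(b)):
        return None
    s = np.linalg.svd(M, compute_uv=False)
    if s[-1] <= 0 or s[0] / s[-1] > cond_tol:
        return None
    if M.shape[0] == 2:
        return np.linalg.solve(M, b)
    return np.linalg.lstsq(M, b, rcond=None)[0]


def influence_jacobian(beta1, beta2, beta12, m: np.ndarray) -> np.ndarray:
    """Analytic Jacobian of (m12, m21) w.r.t. theta = (beta1_j, beta2_j, beta12_j)_j.

    Differentiating the normal equations (M^T M) m = M^T b gives
    dm = (M^T M)^{-1} (dM^T r - M^T dM m + M^T db) with r = b - M m; for the
    square N = 2 case r = 0 and this reduces to the exact-inverse Jacobian.
    Returns a 2 x 3N matrix, theta blocks of 3 per ET.
    """
    M, b = _system(beta1, beta2, beta12)
    N = M.shape[0]
    m = np.asarray(m, dtype=float)
    r = b - M @ m
    A = np.linalg.inv(M.T @ M)
    J = np.zeros((2, 3 * N))
    for j in range(N):
        Mj = M[j]  # (beta2_j, beta1_j)
        # d beta1_j: M's column 1 gains e_j
        J[:, 3 * j + 0] = A @ (np.array([0.0, r[j]]) - Mj * m[1])
        # d beta2_j: M's column 0 gains e_j
        J[:, 3 * j + 1] = A @ (np.array([r[j], 0.0]) - Mj * m[0])
        # d beta12_j
        J[:, 3 * j + 2] = A @ Mj
    return J


def propagate_errors(beta1, beta2, beta12, covariances, m: np.ndarray
                     ) -> tuple[float, float] | None:
    """Delta-method standard errors of (m12, m21).

    ``covariances`` is an iterable of per-ET 3x3 covariance matrices of
    (beta1, beta2, beta12); cross-ET covariances are taken as zero (the ETs
    are orthogonal and fitted in separate regressions).  Returns
    (se_m12, se_m21) or None when the Jacobian is non-finite.
    """
    J = influence_jacobian(beta1, beta2, beta12, m)
    if not np.all(np.isfinite(J)):
        return None
    cov_m = np.zeros((2, 2))
    for j, S in enumerate(covariances):
        Jj = J[:, 3 * j:3 * j + 3]
        cov_m += Jj @ np.asarray(S, dtype=float) @ Jj.T
    var = np.diag(cov_m)
    if np.any(var < 0) or not np.all(np.isfinite(var)):
        return None
    se = np.sqrt(var)
    return float(se[0]), float(se[1])


def standardized_effects(est: InfluenceEstimate) -> tuple[float, float]:
    """Standardized effects z = m / SE for both directions.

    The sign of z matches the sign of m: negative influences are
    suppressive, positive enhancing.  SE = 0 is undefined (the estimate is
    flagged degenerate and excluded from testing).
    """
    if est.status != "resolved":
        raise ValueError(f"cannot standardize a {est.status} estimate")
    if est.se_m12 <= 0 or est.se_m21 <= 0:
        raise ValueError("zero standard error: degenerate estimate")
    return est.m12 / est.se_m12, est.m21 / est.se_m21


def reparametrize_pairs(pairscan, cond_tol: float = DEFAULT_COND_TOL
                        ) -> list[InfluenceEstimate]:
    """Reparametrize every resolved pair of a :class:`PairScanResult`."""
    out = []
    for p_i, pair in enumerate(pairscan.pairs):
        est = InfluenceEstimate(pair=pair)
        out.append(est)
        if not pairscan.status[p_i]:
            continue
        b1 = pairscan.coef[p_i, :, 0]
        b2 = pairscan.coef[p_i, :, 1]
        b12 = pairscan.coef[p_i, :, 2]
        m = solve_influences(b1, b2, b12, cond_tol=cond_tol)
        if m is None:
            continue
        se = propagate_errors(b1, b2, b12, pairscan.cov[p_i], m)
        if se is None:
            continue
        est.m12, est.m21 = float(m[0]), float(m[1])
        est.se_m12, est.se_m21 = se
        if est.se_m12 <= 0 or est.se_m21 <= 0:
            est.status = "degenerate"
            continue
        est.status = "resolved"
        est.z_m12, est.z_m21 = standardized_effects(est)
    return out


def influence_table(estimates: list[InfluenceEstimate]) -> pd.DataFrame:
    """Tidy per-pair influence table (one row per pair)."""
    rows = [
        (e.pair[0], e.pair[1], e.m12, e.m21, e.se_m12, e.se_m21,
         e.z_m12, e.z_m21, e.status)
        for e in estimates
    ]
    return pd.DataFrame(
        rows, columns=["marker_1", "marker_2", "m12", "m21",
                       "se_m12", "se_m21", "z_m12", "z_m21", "status"]
    )
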