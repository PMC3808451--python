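"""Single-marker and two-locus (pair) regression scans on eigentraits.

The pair scan fits, for every testable marker pair and every selected ET,

    ET ~ 1 + covariates + x1 + x2 + x1*x2

by ordinary least squares on jointly observed samples, keeping the
coefficients (beta1, beta2, beta12) and their 3x3 covariance.  Pairs whose
two-locus genotype classes are too sparse to identify the interaction term
(linkage disequilibrium in a cross) are excluded beforehand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cross_io import Cross
from .eigentraits import EigentraitBasis

__all__ = [
    "PairFilterReport",
    "PairScanResult",
    "single_scan",
    "select_marker_covariates",
    "enumerate_testable_pairs",
    "pair_scan",
]

DEFAULT_MIN_CLASS_COUNT = 6


def _ols_multi(X: np.ndarray, Y: np.ndarray):
    """OLS of each column of Y on X.

    Returns (beta p x k, xtx_inv p x p, sigma2 length k, df) or None when X
    is rank deficient (or df <= 0).
    """
    n, p = X.shape
    if n <= p:
        return None
    XtX = X.T @ X
    if np.linalg.matrix_rank(XtX, hermitian=True) < p:
        return None
    XtY = X.T @ Y
    xtx_inv = np.linalg.inv(XtX)
    beta = xtx_inv @ XtY
    resid = Y - X @ beta
    df = n - p
    sigma2 = np.einsum("ij,ij->j", resid, resid) / df
    return beta, xtx_inv, sigma2, df


def _aligned_genotypes(cross: Cross, basis: EigentraitBasis) -> pd.DataFrame:
    return cross.genotypes.loc[basis.sample_index]


def single_scan(cross: Cross, basis: EigentraitBasis,
                covariates: list[str] | None = None) -> pd.DataFrame:
    """Genome-wide single-marker scan per selected ET.

    Fits ET ~ 1 + covariates + marker for each marker and each selected ET
    on jointly observed samples.  Markers with a rank-deficient design
    (e.g. a marker also listed as covariate) are flagged ``unresolved``.

    Returns a tidy DataFrame with columns
    marker, et, coef, se, tstat, n_used, status.
    """
    covariates = list(covariates or [])
    G = _aligned_genotypes(cross, basis)
    E = basis.ets()
    cov_mat = G[covariates].to_numpy(dtype=float) if covariates else None
    rows = []
    for marker in G.columns:
        x = G[marker].to_numpy(dtype=float)
        mask = ~np.isnan(x)
        cols = [np.ones(mask.sum()), ]
        if cov_mat is not None:
            cmask = ~np.isnan(cov_mat).any(axis=1)
            mask = mask & cmask
            cols = [np.ones(mask.sum())] + [cov_mat[mask, j]
                                            for j in range(cov_mat.shape[1])]
        X = np.column_stack(cols + [x[mask]])
        fit = _ols_multi(X, E[mask])
        for e_i, et in enumerate(basis.selected):
            if fit is None:
                rows.append((marker, et + 1, np.nan, np.nan, np.nan,
                             int(mask.sum()), "unresolved"))
                continue
            beta, xtx_inv, sigma2, df = fit
            se = float(np.sqrt(sigma2[e_i] * xtx_inv[-1, -1]))
            coef = float(beta[-1, e_i])
            t = coef / se if se > 0 else np.nan
            rows.append((marker, et + 1, coef, se, t, int(mask.sum()), "ok"))
    return pd.DataFrame(
        rows, columns=["marker", "et", "coef", "se", "tstat", "n_used", "status"]
    )


def select_marker_covariates(scan: pd.DataFrame, threshold: float) -> list[str]:
    """Markers whose max |t| across the selected ETs exceeds ``threshold``.

    Strong main-effect markers can mask interactions between other pairs;
    the returned list is intended to be passed as regression covariates to
    :func:`pair_scan` at the user's discretion.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    ok = scan[scan["status"] == "ok"]
    tmax = ok.assign(abs_t=ok["tstat"].abs()).groupby("marker", sort=False)[
        "abs_t"].max()
    return [m for m in scan["marker"].unique() if tmax.get(m, 0.0) > threshold]


@dataclass
class PairFilterReport:
    """Outcome of candidate-pair enumeration.

    ``tested_pairs`` are unordered (map-order) marker pairs that pass the
    two-locus class-count filter; ``excluded_ld`` maps a pair to its four
    class counts ((0,0), (0,1), (1,0), (1,1)); ``excluded_other`` holds
    pairs with no jointly observed samples.
    """

    tested_pairs: list[tuple[str, str]]
    excluded_ld: dict[tuple[str, str], tuple[int, int, int, int]]
    excluded_other: list[tuple[str, str]] = field(default_factory=list)
    min_class_count: int = DEFAULT_MIN_CLASS_COUNT

    @property
    def n_candidates(self) -> int:
        return len(self.tested_pairs) + len(self.excluded_ld) + len(self.excluded_other)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for a, b in self.tested_pairs:
            rows.append((a, b, "tested", *[np.nan] * 4))
        for (a, b), counts in self.excluded_ld.items():
            rows.append((a, b, "excluded_ld", *counts))
        for a, b in self.excluded_other:
            rows.append((a, b, "excluded_other", *[np.nan] * 4))
        return pd.DataFrame(
            rows, columns=["marker_1", "marker_2", "status",
                           "n00", "n01", "n10", "n11"]
        )


def enumerate_testable_pairs(cross: Cross,
                             min_class_count: int = DEFAULT_MIN_CLASS_COUNT
                             ) -> PairFilterReport:
    """Enumerate unordered marker pairs identifiable for interaction testing.

    For every pair, genotypes are binarized (dosage >= 0.5 -> 1; only for
    this filter, never for regression) and the 2x2 table of jointly observed
    two-locus classes is counted.  A pair in which any class has fewer than
    ``min_class_count`` observations is excluded as LD-confounded, with its
    counts recorded.  Covariate pseudo-markers participate as candidates.
    """
    markers = list(cross.genotypes.columns)
    G = cross.genotypes.to_numpy(dtype=float)
    obs = (~np.isnan(G)).astype(float)
    B = np.where(np.nan_to_num(G, nan=0.0) >= 0.5, 1.0, 0.0) * obs
    # class-count matrices via masked matmuls
    n11 = B.T @ B
    n10 = B.T @ (obs - B)
    n01 = (obs - B).T @ B
    n00 = (obs - B).T @ (obs - B)
    tested, excluded_ld, excluded_other = [], {}, []
    for i in range(len(markers)):
        for j in range(i + 1, len(markers)):
            counts = (int(n00[i, j]), int(n01[i, j]),
                      int(n10[i, j]), int(n11[i, j]))
            pair = (markers[i], markers[j])
            if sum(counts) == 0:
                excluded_other.append(pair)
            elif min(counts) < min_class_count:
                excluded_ld[pair] = counts
            else:
                tested.append(pair)
    return PairFilterReport(tested, excluded_ld, excluded_other, min_class_count)


@dataclass
class PairScanResult:
    """Per-(pair, ET) two-locus regression results.

    ``coef`` holds (beta1, beta2, beta12) and ``cov`` their 3x3 covariance,
    both indexed [pair, et, ...] over ``pairs`` and ``et_indices`` (0-based
    ET indices).  ``status`` is False for rank-deficient (unresolved) pairs.
    """

    pairs: list[tuple[str, str]]
    et_indices: tuple[int, ...]
    coef: np.ndarray        # n_pairs x n_ets x 3
    cov: np.ndarray         # n_pairs x n_ets x 3 x 3
    intercept: np.ndarray   # n_pairs x n_ets
    covar_coef: np.ndarray  # n_pairs x n_ets x n_covariates
    resid_df: np.ndarray    # n_pairs
    n_used: np.ndarray      # n_pairs
    status: np.ndarray      # n_pairs, bool
    covariates: tuple[str, ...]
    skipped: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def main_effect_stats(self) -> pd.DataFrame:
        """Standardized main effects per (pair, member, ET).

        One row per pair member per ET with the member's coefficient, SE and
        t-statistic from that pair's model — the variant-to-phenotype
        statistics pooled into permutation nulls and consolidated into
        marker main effects.
        """
        rows = []
        for p_i, (a, b) in enumerate(self.pairs):
            if not self.status[p_i]:
                continue
            for e_i, et in enumerate(self.et_indices):
                for m_i, marker in enumerate((a, b)):
                    coef = self.coef[p_i, e_i, m_i]
                    var = self.cov[p_i, e_i, m_i, m_i]
                    se = np.sqrt(var) if var > 0 else np.nan
                    t = coef / se if se and se > 0 else np.nan
                    rows.append((a, b, marker, et + 1, coef, se, t))
        return pd.DataFrame(
            rows, columns=["marker_1", "marker_2", "marker", "et",
                           "coef", "se", "tstat"]
        )

    def beta12_matrix(self, et: int, markers: list[str]) -> pd.DataFrame:
        """Symmetric interaction-coefficient matrix for one ET (1-based)."""
        e_i = list(self.et_indices).index(et - 1)
        M = pd.DataFrame(np.nan, index=markers, columns=markers)
        for p_i, (a, b) in enumerate(self.pairs):
            if not self.status[p_i]:
                continue
            M.at[a, b] = M.at[b, a] = self.coef[p_i, e_i, 2]
        return M


def pair_scan(cross: Cross, basis: EigentraitBasis,
              pairs: list[tuple[str, str]],
              covariates: list[str] | None = None,
              ets: np.ndarray | None = None) -> PairScanResult:
    """Two-locus regression with interaction for each pair and selected ET.

    Pairs containing a declared regression covariate are skipped (recorded
    in ``skipped``) to avoid collinearity by construction.  ``ets``
    optionally overrides the basis ET matrix (rows aligned to
    ``basis.sample_index``) — used by permutation testing.
    """
    covariates = list(covariates or [])
    G = _aligned_genotypes(cross, basis)
    garr = G.to_numpy(dtype=float)
    col_ix = {m: i for i, m in enumerate(G.columns)}
    E = basis.ets() if ets is None else np.asarray(ets, dtype=float)
    if E.shape[0] != garr.shape[0]:
        raise ValueError("ET matrix rows do not match the retained samples")
    n_ets = len(basis.selected)
    cov_ix = [col_ix[c] for c in covariates]
    cov_set = set(covariates)

    kept, skipped = [], []
    for pair in pairs:
        (skipped if (pair[0] in cov_set or pair[1] in cov_set) else kept
         ).append(tuple(pair))

    n_pairs = len(kept)
    n_cov = len(covariates)
    coef = np.full((n_pairs, n_ets, 3), np.nan)
    cov = np.full((n_pairs, n_ets, 3, 3), np.nan)
    intercept = np.full((n_pairs, n_ets), np.nan)
    covar_coef = np.full((n_pairs, n_ets, n_cov), np.nan)
    resid_df = np.zeros(n_pairs, dtype=int)
    n_used = np.zeros(n_pairs, dtype=int)
    status = np.zeros(n_pairs, dtype=bool)

    cov_block = garr[:, cov_ix] if n_cov else None
    for p_i, (a, b) in enumerate(kept):
        x1 = garr[:, col_ix[a]]
        x2 = garr[:, col_ix[b]]
        mask = ~np.isnan(x1) & ~np.isnan(x2)
        if cov_block is not None:
            mask &= ~np.isnan(cov_block).any(axis=1)
        n = int(mask.sum())
        n_used[p_i] = n
        parts = [np.ones(n)]
        if cov_block is not None:
            parts.append(cov_block[mask])
        x1m, x2m = x1[mask], x2[mask]
        parts.extend([x1m[:, None], x2m[:, None], (x1m * x2m)[:, None]])
        X = np.hstack([p if p.ndim == 2 else p[:, None] for p in parts])
        fit = _ols_multi(X, E[mask])
        if fit is None:
            continue
        beta, xtx_inv, sigma2, df = fit
        sl = slice(1 + n_cov, 4 + n_cov)
        block = xtx_inv[sl, sl]
        status[p_i] = True
        resid_df[p_i] = df
        intercept[p_i] = beta[0]
        if n_cov:
            covar_coef[p_i] = beta[1:1 + n_cov].T
        coef[p_i] = beta[sl].T
        cov[p_i] = sigma2[:, None, None] * block[None, :, :]
    return PairScanResult(
        pairs=kept, et_indices=tuple(basis.selected), coef=coef, cov=cov,
        intercept=intercept, covar_coef=covar_coef, resid_df=resid_df,
        n_used=n_used, status=status, covariates=tuple(covariates),
        skipped=skipped,
    )
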