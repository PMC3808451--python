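"""Phenotype normalization and eigentrait (SVD) decomposition.

Multiple correlated quantitative phenotypes are rank-normalized, then
decomposed into orthogonal eigentraits (ETs) — the left singular vectors of
the normalized phenotype matrix.  Regressions downstream are fitted to the
ETs rather than the raw phenotypes; effects estimated in ET space are
rotated back to phenotype space for reporting via the singular values and
phenotype loadings.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cross_io import ContentError

__all__ = [
    "ColumnNormalization",
    "NormalizationRecord",
    "EigentraitBasis",
    "normalize_phenotypes",
    "decompose",
    "variance_fractions",
    "select_ets",
    "back_project_effects",
    "project_to_ets",
    "et_report",
]

MAX_ETS = 12
BLOM_OFFSET = 0.375  # Blom's rank offset for the inverse-normal transform


@dataclass
class ColumnNormalization:
    """Enough state to apply one column's rank-Z transform to new values."""

    sorted_values: np.ndarray  # observed (non-missing) training values, sorted
    mean: float                # mean of the Blom scores before z-scoring
    sd: float                  # sd (ddof=1) of the Blom scores

    def apply(self, values: np.ndarray) -> np.ndarray:
        """Transform held-out values with the stored reference ranks."""
        v = np.asarray(values, dtype=float)
        out = np.full(v.shape, np.nan)
        obs = ~np.isnan(v)
        n = len(self.sorted_values)
        lo = np.searchsorted(self.sorted_values, v[obs], side="left")
        hi = np.searchsorted(self.sorted_values, v[obs], side="right")
        rank = (lo + hi) / 2.0 + 0.5  # mid-rank among training values, 1-based
        q = np.clip((rank - BLOM_OFFSET) / (n + 0.25), 1e-12, 1 - 1e-12)
        out[obs] = (stats.norm.ppf(q) - self.mean) / self.sd
        return out


@dataclass
class NormalizationRecord:
    columns: dict[str, ColumnNormalization] = field(default_factory=dict)


@dataclass
class EigentraitBasis:
    """Thin SVD of the normalized phenotype matrix.

    ``left_vectors`` (U, n_used x r) holds the eigentraits as orthonormal
    columns; ``right_vectors`` (V, n_phenotypes x r) holds the phenotype
    loadings; the normalized matrix equals U diag(sigma) V^T on the retained
    samples.  ``selected`` are the 0-based ET indices used downstream.
    """

    left_vectors: np.ndarray
    singular_values: np.ndarray
    right_vectors: np.ndarray
    phenotype_names: list[str]
    sample_index: pd.Index
    normalization: NormalizationRecord
    selected: tuple[int, ...] = (0, 1)
    dropped_samples: list = field(default_factory=list)

    @property
    def n_ets(self) -> int:
        return len(self.selected)

    def ets(self) -> np.ndarray:
        """ET matrix restricted to the selected components (n_used x k)."""
        return self.left_vectors[:, list(self.selected)]

    def ets_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.ets(), index=self.sample_index,
            columns=[f"ET{i + 1}" for i in self.selected],
        )


def normalize_phenotypes(P: pd.DataFrame) -> tuple[pd.DataFrame, NormalizationRecord]:
    """Rank-based inverse-normal transform, then z-score, per phenotype.

    Each column's non-missing values are converted to average ranks, mapped
    through the Blom quantile (rank - 3/8)/(n + 1/4) and the standard normal
    inverse CDF, then standardized to mean 0 and unit sample variance.
    Missing values stay missing in place.

    Raises :class:`ContentError` for a column with fewer than 3 observed
    values or zero variance.
    """
    out = P.copy().astype(float)
    record = NormalizationRecord()
    for name in P.columns:
        col = out[name].to_numpy(dtype=float)
        obs = ~np.isnan(col)
        vals = col[obs]
        if len(vals) < 3:
            raise ContentError(f"phenotype {name!r}: fewer than 3 observed values")
        if np.nanvar(vals) == 0:
            raise ContentError(f"phenotype {name!r} is constant")
        ranks = stats.rankdata(vals, method="average")
        q = (ranks - BLOM_OFFSET) / (len(vals) + 0.25)
        z = stats.norm.ppf(q)
        mean, sd = z.mean(), z.std(ddof=1)
        col[obs] = (z - mean) / sd
        out[name] = col
        record.columns[name] = ColumnNormalization(np.sort(vals), mean, sd)
    return out, record


def decompose(P_norm: pd.DataFrame,
              normalization: NormalizationRecord | None = None) -> EigentraitBasis:
    """Thin SVD of the normalized phenotype matrix into eigentraits.

    Rows with any missing phenotype are dropped (and reported on the
    returned basis) before decomposition.  Sign convention: each right
    vector's largest-magnitude loading is positive, which fixes U's signs
    too.  By default the first two ETs are selected.
    """
    if P_norm.shape[1] < 2:
        raise ContentError("need at least 2 phenotypes to decompose")
    complete = P_norm.notna().all(axis=1)
    dropped = list(P_norm.index[~complete])
    X = P_norm.loc[complete].to_numpy(dtype=float)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    V = Vt.T
    for k in range(V.shape[1]):
        j = int(np.argmax(np.abs(V[:, k])))
        if V[j, k] < 0:
            V[:, k] = -V[:, k]
            U[:, k] = -U[:, k]
    return EigentraitBasis(
        left_vectors=U,
        singular_values=s,
        right_vectors=V,
        phenotype_names=list(P_norm.columns),
        sample_index=P_norm.index[complete],
        normalization=normalization or NormalizationRecord(),
        selected=(0, 1),
        dropped_samples=dropped,
    )


def variance_fractions(basis: EigentraitBasis) -> np.ndarray:
    """Fraction of total phenotype variance captured by each ET."""
    s2 = basis.singular_values ** 2
    return s2 / s2.sum()


def select_ets(basis: EigentraitBasis, k: int = 2) -> EigentraitBasis:
    """Select the first ``k`` eigentraits (2 <= k <= min(12, r))."""
    r = len(basis.singular_values)
    if not 2 <= k <= min(MAX_ETS, r):
        raise ValueError(
            f"k={k} out of range: need 2 <= k <= min({MAX_ETS}, r={r})"
        )
    return dataclasses.replace(basis, selected=tuple(range(k)))


def back_project_effects(beta_et: np.ndarray, basis: EigentraitBasis,
                         cov_et: np.ndarray | None = None):
    """Rotate effects on the selected ETs back to phenotype space.

    The phenotype-space effect is sum_i beta_et[i] * sigma_i * V[:, i] over
    the selected ETs.  When ``cov_et`` (k x k) is given, it is propagated
    through the same linear map and the pair (effect, covariance) returned.
    """
    beta_et = np.asarray(beta_et, dtype=float)
    sel = list(basis.selected)
    if beta_et.shape != (len(sel),):
        raise ValueError(
            f"expected {len(sel)} ET effects, got shape {beta_et.shape}"
        )
    J = basis.right_vectors[:, sel] * basis.singular_values[sel]
    effect = J @ beta_et
    if cov_et is None:
        return effect
    cov_et = np.asarray(cov_et, dtype=float)
    return effect, J @ cov_et @ J.T


def project_to_ets(effect_phen: np.ndarray, basis: EigentraitBasis) -> np.ndarray:
    """Inverse of :func:`back_project_effects` on the selected-ET subspace."""
    sel = list(basis.selected)
    return (basis.right_vectors[:, sel].T @ np.asarray(effect_phen, dtype=float)
            ) / basis.singular_values[sel]


def et_report(basis: EigentraitBasis) -> pd.DataFrame:
    """ET summary table: index, variance fraction, loading per phenotype."""
    fr = variance_fractions(basis)
    rows = []
    for i in range(len(basis.singular_values)):
        row = {"et": i + 1, "variance_fraction": fr[i]}
        for p, name in enumerate(basis.phenotype_names):
            row[f"loading_{name}"] = basis.right_vectors[p, i]
        rows.append(row)
    return pd.DataFrame(rows)
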