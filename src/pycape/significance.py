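"""Permutation nulls, empirical p-values and multiple-testing correction.

Null distributions are built by permuting the eigentrait rows against the
fixed genotypes (preserving both marker linkage and inter-ET structure),
re-running the pair scan and reparametrization, and pooling all
standardized effects across permutations — one pool for variant-to-variant
influences and one for variant-to-phenotype (main) effects.  Pooling makes
a modest number of permutations sufficient for the whole genome of tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cross_io import Cross
from .eigentraits import EigentraitBasis
from .reparam import DEFAULT_COND_TOL, reparametrize_pairs
from .scans import pair_scan

__all__ = [
    "NullDistribution",
    "permute_cross",
    "build_null",
    "empirical_p",
    "empirical_p_many",
    "adjust",
]

MAX_PERM_SEED = 2 ** 31 - 1


@dataclass
class NullDistribution:
    """Pooled permutation null for one kind of standardized effect."""

    kind: str               # "variant_variant" | "variant_phenotype"
    values: np.ndarray      # pooled standardized effects, finite
    n_perm: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.values = self.values[np.isfinite(self.values)]
        self._sorted_abs = np.sort(np.abs(self.values))

    def __len__(self) -> int:
        return len(self.values)


def permute_cross(cross: Cross, basis: EigentraitBasis, seed: int,
                  permutation: np.ndarray | None = None) -> np.ndarray:
    """Return the ET matrix with rows jointly permuted.

    All selected ET columns are permuted by the same uniformly random
    permutation of sample indices, which breaks genotype-phenotype
    association while preserving the correlation structure among ETs and
    the linkage structure among (unpermuted) genotypes.  Deterministic
    given ``seed``; ``permutation`` overrides the draw (test hook).
    """
    E = basis.ets()
    if permutation is None:
        rng = np.random.default_rng(seed)
        permutation = rng.permutation(E.shape[0])
    return E[np.asarray(permutation)]


def build_null(cross: Cross, basis: EigentraitBasis,
               pairs: list[tuple[str, str]],
               covariates: list[str] | None = None,
               n_perm: int = 100, seed: int = 0,
               cond_tol: float = DEFAULT_COND_TOL
               ) -> tuple[NullDistribution, NullDistribution]:
    """Build pooled variant-variant and variant-phenotype nulls.

    Per permutation the ET rows are shuffled, the pair scan re-fitted on the
    same pair list and the pairs reparametrized; all resolved influence
    z-scores join the variant_variant pool and all main-effect t-statistics
    the variant_phenotype pool.  Per-permutation seeds are derived from the
    master ``seed`` so results are reproducible and order-independent.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    perm_seeds = rng.integers(0, MAX_PERM_SEED, size=n_perm)
    vv_pool, vp_pool = [], []
    for ps in perm_seeds:
        ets = permute_cross(cross, basis, int(ps))
        scan = pair_scan(cross, basis, pairs, covariates, ets=ets)
        ests = reparametrize_pairs(scan, cond_tol=cond_tol)
        z = np.array([[e.z_m12, e.z_m21] for e in ests
                      if e.status == "resolved"], dtype=float).ravel()
        vv_pool.append(z[np.isfinite(z)])
        t = scan.main_effect_stats()["tstat"].to_numpy(dtype=float)
        vp_pool.append(t[np.isfinite(t)])
    return (
        NullDistribution("variant_variant", np.concatenate(vv_pool) if vv_pool
                         else np.empty(0), n_perm),
        NullDistribution("variant_phenotype", np.concatenate(vp_pool) if vp_pool
                         else np.empty(0), n_perm),
    )


def empirical_p(observed_z: float, null: NullDistribution) -> float:
    """Two-sided add-one empirical p-value against a pooled null.

    p = (1 + #{|null| >= |z|}) / (1 + |null|); ties count, and the add-one
    convention keeps p > 0.
    """
    return float(empirical_p_many(np.array([observed_z]), null)[0])


def empirical_p_many(observed_z: np.ndarray, null: NullDistribution
                     ) -> np.ndarray:
    """Vectorized :func:`empirical_p`."""
    if len(null) == 0:
        raise RuntimeError("empty null distribution")
    sa = null._sorted_abs
    M = len(sa)
    below = np.searchsorted(sa, np.abs(np.asarray(observed_z, dtype=float)),
                            side="left")
    return (1.0 + (M - below)) / (1.0 + M)


def _lfdr(observed_z: np.ndarray, null: NullDistribution) -> np.ndarray:
    """Local FDR as a null/observed kernel-density ratio with pi0 = 1.

    Both densities use a shared absolute bandwidth — Silverman's rule
    evaluated on the pooled null — so the ratio is not distorted by
    differing smoothing scales.  Conservative (pi0 = 1), clipped at 1.
    """
    z = np.asarray(observed_z, dtype=float)
    nv = null.values
    sd = nv.std(ddof=1)
    iqr = np.subtract(*np.percentile(nv, [75, 25]))
    h = 0.9 * min(sd, iqr / 1.34 if iqr > 0 else sd) * len(nv) ** (-0.2)
    f0 = stats.gaussian_kde(nv, bw_method=h / nv.std(ddof=1))
    if len(z) > 1 and z.std(ddof=1) > 0:
        f = stats.gaussian_kde(z, bw_method=h / z.std(ddof=1))
    else:
        f = f0
    with np.errstate(divide="ignore", invalid="ignore"):
        lf = f0(z) / np.maximum(f(z), 1e-300)
    return np.clip(lf, 0.0, 1.0)


def adjust(pvalues, method: str = "fdr", level: float = 0.01,
           observed_z=None, null: NullDistribution | None = None
           ) -> pd.DataFrame:
    """Multiple-testing adjustment of empirical p-values.

    method "holm": step-down adjusted p with running max, clipped at 1;
    "fdr": Benjamini-Hochberg q-values (step-up running min); "lfdr":
    kernel local FDR (requires ``observed_z`` and the pooled ``null``).
    Returns a DataFrame with columns p, adjusted, method, significant
    (adjusted <= level), aligned with the input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if method == "holm":
        adjusted = multipletests(p, alpha=level, method="holm")[1]
    elif method == "fdr":
        adjusted = multipletests(p, alpha=level, method="fdr_bh")[1]
    elif method == "lfdr":
        if observed_z is None or null is None:
            raise ValueError("lfdr requires observed_z and the pooled null")
        adjusted = _lfdr(observed_z, null)
    else:
        raise ValueError(f"unknown method {method!r}; use holm, fdr or lfdr")
    return pd.DataFrame({
        "p": p,
        "adjusted": adjusted,
        "method": method,
        "significant": adjusted <= level,
    })
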