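"""Statistics for community metabolic metrics.

The regression at the center of the SynCom analysis is a quasi-Poisson
GLM: a log-link count model with variance mu*phi, fit by IRLS with the
Poisson deviance, the dispersion phi estimated from Pearson residuals
(chi-square / df) and standard errors scaled by sqrt(phi).  The model of
the count response (number of producible / core metabolites) uses
SynCom size S, mean genome size G, mean phylogenetic distance P and a
degree-2 term P^2 capturing the humped distance response.  The reported
pseudo-R2 is 1 - residual deviance / null deviance.

Also here: Cliff's delta effect sizes, Jaccard and Bray-Curtis
distances, complete-linkage hierarchical clustering, classical PCoA and
a permutation PERMANOVA.  The clustering, ordination and permutation
test are implemented in-package so their tie-breaking, eigenvalue
handling and p-value convention are pinned (scikit-bio and scipy serve
as independent cross-checks in the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.spatial.distance import braycurtis as _scipy_braycurtis

__all__ = [
    "GlmSpec",
    "GlmFit",
    "fit_quasipoisson",
    "cliffs_delta",
    "jaccard_distance",
    "braycurtis",
    "complete_linkage",
    "pcoa",
    "permanova",
]


# ---------------------------------------------------------------------------
# Quasi-Poisson GLM


@dataclass(frozen=True)
class GlmSpec:
    """Which count response to model, and with which covariates.

    Default covariate set is the full design: S (community size),
    G (mean genome size), P (mean phylogenetic distance) and P^2.
    """

    response: str = "n_ppm"  # or "n_cppm"
    covariates: Tuple[str, ...] = ("size", "mean_genome", "avg_pd", "avg_pd_sq")

    def __post_init__(self) -> None:
        if self.response not in ("n_ppm", "n_cppm"):
            raise ValueError(f"unknown response {self.response!r}")


@dataclass
class GlmFit:
    """A fitted quasi-Poisson regression."""

    beta: Dict[str, float]
    se: Dict[str, float]
    dispersion: float
    null_deviance: float
    residual_deviance: float
    r2: float
    n_obs: int

    def to_dict(self) -> dict:
        return {
            "beta": self.beta,
            "se": self.se,
            "dispersion": self.dispersion,
            "null_deviance": self.null_deviance,
            "residual_deviance": self.residual_deviance,
            "r2": self.r2,
            "n_obs": self.n_obs,
        }


def fit_quasipoisson(
    records: pd.DataFrame,
    spec: GlmSpec = GlmSpec(),
    *,
    max_size: Optional[int] = 12,
    maxiter: int = 100,
    tol: float = 1e-8,
) -> GlmFit:
    """Fit the quasi-Poisson GLM by IRLS.

    ``records`` is a SynCom table (see :func:`rootscope.syncom.syncom_table`);
    rows above ``max_size`` members are dropped before fitting (the
    count responses plateau beyond that size and would only add
    leverage-free replication), as is any whole-community flag row.
    The missing ``avg_pd_sq`` column is derived on the fly.  Dispersion
    is the Pearson chi-square over residual df; standard errors carry
    the sqrt(dispersion) inflation.  R2 = 1 - residual/null deviance.
    """
    data = records.copy()
    if "is_whole_community" in data.columns:
        data = data[~data["is_whole_community"]]
    if max_size is not None:
        data = data[data["size"] <= max_size]
    if "avg_pd_sq" in spec.covariates and "avg_pd_sq" not in data.columns:
        data["avg_pd_sq"] = data["avg_pd"] ** 2
    y = data[spec.response].to_numpy(dtype=float)
    X = data[list(spec.covariates)].to_numpy(dtype=float) if spec.covariates else None
    if X is not None:
        X = sm.add_constant(X, has_constant="add")
        names = ["intercept", *spec.covariates]
    else:
        X = np.ones((len(y), 1))
        names = ["intercept"]
    if len(y) < X.shape[1] + 2:
        raise ValueError(
            f"need at least p+2={X.shape[1] + 2} records, got {len(y)}"
        )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    model = sm.GLM(y, X, family=sm.families.Poisson())
    fit = model.fit(maxiter=maxiter, tol=tol)
    if not fit.converged:
        raise RuntimeError(
            f"IRLS did not converge in {maxiter} iterations "
            f"(final deviance {fit.deviance:.6g})"
        )
    # Quasi-likelihood: point estimates are the Poisson IRLS solution;
    # the Pearson dispersion rescales the covariance (SE * sqrt(phi)).
    df_resid = len(y) - X.shape[1]
    dispersion = float(fit.pearson_chi2 / df_resid) if df_resid > 0 else float("nan")
    se_scale = np.sqrt(dispersion) if dispersion > 0 else 1.0
    # A constant response has zero null deviance: nothing to explain.
    r2 = 1.0 - fit.deviance / fit.null_deviance if fit.null_deviance > 0 else 0.0
    return GlmFit(
        beta=dict(zip(names, map(float, fit.params))),
        se=dict(zip(names, (float(s * se_scale) for s in fit.bse))),
        dispersion=dispersion,
        null_deviance=float(fit.null_deviance),
        residual_deviance=float(fit.deviance),
        r2=float(r2),
        n_obs=int(len(y)),
    )


# ---------------------------------------------------------------------------
# Effect sizes and distances


def cliffs_delta(x: Sequence[float], y: Sequence[float]) -> float:
    """Cliff's delta: P(x > y) - P(x < y) over all cross pairs.

    Nonparametric effect size in [-1, 1]; ties contribute zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    diff = x[:, None] - y[None, :]
    return float((np.sign(diff)).sum() / (x.size * y.size))


def jaccard_distance(a: Iterable, b: Iterable) -> float:
    """1 - |A intersect B| / |A union B|; two empty sets give 0."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        return 0.0
    return 1.0 - len(a & b) / len(union)


def braycurtis(u: Sequence[float], v: Sequence[float]) -> float:
    """Bray-Curtis dissimilarity on non-negative count vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("count vectors must share a length")
    if (u < 0).any() or (v < 0).any():
        raise ValueError("Bray-Curtis requires non-negative counts")
    if not (u.any() or v.any()):
        raise ValueError("Bray-Curtis undefined for two all-zero vectors")
    return float(_scipy_braycurtis(u, v))


# ---------------------------------------------------------------------------
# Clustering, ordination, permutation test


def _check_square(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0):
        raise ValueError("distance matrix must have a zero diagonal")
    return d


def complete_linkage(dist: np.ndarray) -> List[Tuple[int, int, float, int]]:
    """Complete-linkage agglomeration of a square distance matrix.

    Returns the merge list in scipy linkage convention: each row
    (i, j, height, size) merges clusters i and j (original points are
    0..n-1, merged clusters n, n+1, ... in order of creation) at the
    maximum inter-cluster distance.  Ties are broken deterministically
    by the lowest (i, j) index pair.
    """
    d = _check_square(dist)
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least two points to cluster")
    clusters: Dict[int, List[int]] = {i: [i] for i in range(n)}
    cluster_dist: Dict[Tuple[int, int], float] = {
        (i, j): d[i, j] for i in range(n) for j in range(i + 1, n)
    }
    merges: List[Tuple[int, int, float, int]] = []
    next_id = n
    while len(clusters) > 1:
        (ci, cj), height = min(
            cluster_dist.items(), key=lambda kv: (kv[1], kv[0])
        )
        members = clusters.pop(ci) + clusters.pop(cj)
        for (a, b) in list(cluster_dist):
            if a in (ci, cj) or b in (ci, cj):
                del cluster_dist[(a, b)]
        for other, other_members in clusters.items():
            dmax = max(d[p, q] for p in members for q in other_members)
            key = (min(other, next_id), max(other, next_id))
            cluster_dist[key] = dmax
        clusters[next_id] = members
        merges.append((ci, cj, float(height), len(members)))
        next_id += 1
    return merges


def pcoa(dist: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Classical scaling (principal coordinate analysis).

    Double-centers -1/2 D^2, eigendecomposes, orders axes by descending
    eigenvalue and keeps only the positive ones; all eigenvalues —
    including any negative ones induced by non-Euclidean distances — are
    returned for inspection.  Coordinates are eigenvectors scaled by
    sqrt(eigenvalue).  Axis signs are fixed so the largest-magnitude
    loading of each axis is positive.
    """
    d = _check_square(dist)
    n = d.shape[0]
    centering = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * centering @ (d**2) @ centering
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    keep = eigvals > 1e-10 * max(1.0, abs(eigvals[0]))
    coords = eigvecs[:, keep] * np.sqrt(eigvals[keep])
    for k in range(coords.shape[1]):
        pivot = np.argmax(np.abs(coords[:, k]))
        if coords[pivot, k] < 0:
            coords[:, k] = -coords[:, k]
    return coords, eigvals


def permanova(
    dist: np.ndarray,
    groups: Sequence,
    n_perm: int = 999,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[float, float, float]:
    """Permutational multivariate ANOVA on a distance matrix.

    Partitions the total sum of squared distances (SS_total =
    sum_{i<j} d_ij^2 / n) into between- and within-group components,
    forms the pseudo-F, and assesses it by permuting group labels.
    Returns (pseudo-F, R2, p) with p = (1 + #{F_perm >= F_obs}) /
    (1 + n_perm) and R2 = SS_between / SS_total.
    """
    d = _check_square(dist)
    if rng is None:
        rng = np.random.default_rng()
    labels = np.asarray(groups)
    n = d.shape[0]
    if labels.shape[0] != n:
        raise ValueError("one group label per observation required")
    uniq, inverse = np.unique(labels, return_inverse=True)
    a = uniq.size
    if a < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    counts = np.bincount(inverse)
    if (counts < 2).any():
        small = [str(uniq[i]) for i in np.flatnonzero(counts < 2)]
        raise ValueError(f"singleton group(s): {small}")

    d2 = d**2
    ss_total = d2.sum() / (2 * n)

    def ss_within(assign: np.ndarray) -> float:
        total = 0.0
        for g in range(a):
            idx = np.flatnonzero(assign == g)
            total += d2[np.ix_(idx, idx)].sum() / (2 * idx.size)
        return total

    ss_w = ss_within(inverse)
    ss_b = ss_total - ss_w
    f_obs = (ss_b / (a - 1)) / (ss_w / (n - a))

    # Vectorized permutation null: indicator-matrix quadratic forms.
    perms = rng.permuted(np.tile(inverse, (n_perm, 1)), axis=1)
    ss_w_perm = np.zeros(n_perm)
    for g in range(a):
        mask = (perms == g).astype(float)  # (n_perm, n)
        quad = np.einsum("pi,ij,pj->p", mask, d2, mask)
        ss_w_perm += quad / (2 * counts[g])
    ss_b_perm = ss_total - ss_w_perm
    f_perm = (ss_b_perm / (a - 1)) / (ss_w_perm / (n - a))
    p_value = (1 + int((f_perm >= f_obs).sum())) / (1 + n_perm)
    r2 = ss_b / ss_total
    return float(f_obs), float(r2), float(p_value)
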