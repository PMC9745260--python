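"""Ex-situ seed-bank design by maximizing pooled gene diversity.

The pooled gene diversity of a seed mixture with population contribution
vector ``c`` is ``D = 1 - sum_ij f_ij c_i c_j`` where ``f_ij`` is the
average coancestry (gene identity) between populations i and j. The
optimal bank maximizes D over the probability simplex; typically only a
few populations receive non-zero contributions. Leave-one-out
contributions (the proportional change of within-population gene
diversity and of average between-population Nei minimum distance when a
population is dropped) describe each population's role, and a random-
contribution baseline quantifies the gain from optimization.

Dominant markers do not expose genotypes, so allele frequencies are
recovered from band-absence frequencies with the square-root estimator
(optionally Lynch-Milligan small-sample corrected) before any coancestry
or distance computation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from rguc_kit.aflp_io import BandMatrix

__all__ = [
    "CoancestryMatrix",
    "SeedBankPlan",
    "allele_frequencies",
    "coancestry",
    "maximize_dmax",
    "leave_one_out_contributions",
    "random_pool_baseline",
]

log = logging.getLogger(__name__)


def allele_frequencies(bm: BandMatrix, *, model: str = "lynch-milligan") -> pd.DataFrame:
    """Per-population recessive-allele frequencies ``q`` from band data.

    The band-absence phenotype frequency ``x`` estimates ``q**2`` (null
    homozygotes), so ``q = sqrt(x)``. ``model='lynch-milligan'`` applies
    the small-sample Taylor correction ``q = sqrt(x)/(1 - Var(x)/(8 x^2))``
    with ``Var(x) = x(1-x)/n``; ``model='sqrt'`` uses the raw square root.
    Loci fixed for band presence in a population (``x = 0``) are clamped
    to allele frequency ``1/(2n+1)`` and logged.

    Returns a ``locus x population`` DataFrame of ``q``.
    """
    if model not in ("lynch-milligan", "sqrt"):
        raise ValueError(f"unknown allele model {model!r}")
    cols = {}
    for pop in bm.population_labels:
        rows = bm.rows_of(pop)
        n = int(rows.sum())
        x = 1.0 - bm.values[rows].mean(axis=0)
        fixed = x <= 0
        if fixed.any():
            log.info("coancestry: %d loci fixed for the band in population %s; "
                     "allele frequency clamped to 1/(2n+1)", int(fixed.sum()), pop)
        q = np.sqrt(np.where(fixed, 0.0, x))
        if model == "lynch-milligan":
            with np.errstate(divide="ignore", invalid="ignore"):
                corr = 1.0 - (x * (1.0 - x) / n) / (8.0 * x**2)
            corr = np.where(fixed | (corr < 0.5), 1.0, corr)
            q = q / corr
        q = np.where(fixed, 1.0 / (2 * n + 1), np.clip(q, 0.0, 1.0))
        cols[pop] = q
    return pd.DataFrame(cols, index=pd.Index(bm.locus_ids, name="locus"))


@dataclass
class CoancestryMatrix:
    """Average coancestry ``f_ij`` between populations (gene identity)."""

    values: np.ndarray
    populations: list[str]

    def __post_init__(self) -> None:
        F = np.asarray(self.values, float)
        if F.ndim != 2 or F.shape[0] != F.shape[1] or F.shape[0] != len(self.populations):
            raise ValueError("coancestry matrix must be square and match population list")
        if not np.allclose(F, F.T, atol=1e-10):
            raise ValueError("coancestry matrix must be symmetric")
        if F.min() < -1e-12 or F.max() > 1 + 1e-12:
            raise ValueError("coancestry entries must be in [0, 1]")
        self.values = (F + F.T) / 2

    @property
    def n(self) -> int:
        return len(self.populations)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.populations, columns=self.populations)


def coancestry(bm: BandMatrix, *, model: str = "lynch-milligan") -> CoancestryMatrix:
    """Average coancestry matrix from band data.

    ``f_ij`` = mean over loci of ``p_i p_j + q_i q_j`` — the probability
    that one allele drawn from population i and one from population j are
    identical, averaged over loci. ``f_ii`` is the uncorrected expected
    gene identity within population i.
    """
    q = allele_frequencies(bm, model=model).to_numpy()
    p = 1.0 - q
    F = (p.T @ p + q.T @ q) / q.shape[0]
    return CoancestryMatrix(F, bm.population_labels)


# ---------------------------------------------------------------------------
# D_max optimization


@dataclass
class SeedBankPlan:
    """Result of the contribution optimization for one scope."""

    contributions: pd.Series  # per population, sums to 1
    d_max: float
    scope: str = "full"
    pool_counts: pd.Series = field(default=None)  # type: ignore[assignment]
    pool_size: int = 1000

    def __post_init__(self) -> None:
        if self.pool_counts is None:
            self.pool_counts = (self.contributions * self.pool_size).round().astype(int)


def _project_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection onto the probability simplex."""
    u = np.sort(v)[::-1]
    css = np.cumsum(u) - 1.0
    rho = np.flatnonzero(u - css / np.arange(1, len(v) + 1) > 0)[-1]
    theta = css[rho] / (rho + 1.0)
    return np.maximum(v - theta, 0.0)


def maximize_dmax(F: CoancestryMatrix, replicates: int = 100, seed: int | None = None,
                  *, scope: str = "full", pool_size: int = 1000,
                  max_iter: int = 2000, tol: float = 1e-12) -> SeedBankPlan:
    """Maximize pooled diversity ``1 - c'Fc`` over the simplex.

    Projected-gradient descent on ``c'Fc`` from ``replicates`` random
    Dirichlet starting points (plus the uniform start), keeping the best.
    Contributions below 1e-6 are reported as exactly 0 and the rest
    renormalized. The pool size only sets the granularity of the
    reported seed counts.
    """
    A = F.values
    n = F.n
    rng = np.random.default_rng(seed)
    step = 1.0 / (2.0 * max(np.linalg.norm(A, 2), 1e-12))

    def solve(c0: np.ndarray) -> tuple[np.ndarray, float]:
        c = c0.copy()
        obj = float(c @ A @ c)
        for _ in range(max_iter):
            c_new = _project_simplex(c - step * 2.0 * (A @ c))
            obj_new = float(c_new @ A @ c_new)
            if abs(obj - obj_new) < tol:
                c, obj = c_new, obj_new
                break
            c, obj = c_new, obj_new
        return c, obj

    starts = [np.full(n, 1.0 / n)]
    starts += [rng.dirichlet(np.ones(n)) for _ in range(replicates)]
    best_c, best_obj = None, np.inf
    for c0 in starts:
        c, obj = solve(c0)
        if obj < best_obj:
            best_c, best_obj = c, obj
    assert best_c is not None
    best_c = np.where(best_c < 1e-6, 0.0, best_c)
    best_c = best_c / best_c.sum()
    d_max = 1.0 - float(best_c @ A @ best_c)
    return SeedBankPlan(pd.Series(best_c, index=F.populations), d_max, scope=scope,
                        pool_size=pool_size)


def random_pool_baseline(F: CoancestryMatrix, reps: int = 100,
                         seed: int | None = None) -> float:
    """Mean pooled diversity of uniformly random contribution vectors."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    A = F.values
    vals = []
    for _ in range(reps):
        c = rng.dirichlet(np.ones(F.n))
        vals.append(1.0 - float(c @ A @ c))
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# Leave-one-out contributions


def _h_within(q: np.ndarray) -> np.ndarray:
    """Expected heterozygosity per population from allele frequencies."""
    return (2.0 * (1.0 - q) * q).mean(axis=0)


def _nei_minimum_distance(q: np.ndarray) -> np.ndarray:
    """Pairwise Nei minimum distance matrix from allele frequencies.

    ``D_ij`` = mean over loci of ``((p_i - p_j)^2 + (q_i - q_j)^2) / 2``.
    """
    L, n = q.shape
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dq = q[:, i] - q[:, j]
            D[i, j] = D[j, i] = float(np.mean(dq**2))  # p-diff equals -q-diff
    return D


def leave_one_out_contributions(bm: BandMatrix, populations: list[str] | None = None,
                                *, model: str = "lynch-milligan") -> pd.DataFrame:
    """Leave-one-out diversity and distance contributions (in %).

    For the scope (all populations by default): ``H_S`` is the mean
    within-population gene diversity and ``D`` the mean pairwise Nei
    minimum distance. Dropping population i,
    ``dH_nei(i) = 100 (H_all - H_without_i)/H_all`` (and likewise
    ``dH_dist``); positive values mean the indicator decreases when the
    population is removed. ``dH_t`` is their sum.
    """
    scope = populations if populations is not None else bm.population_labels
    if len(scope) < 3:
        raise ValueError("leave-one-out contributions need at least 3 populations")
    q = allele_frequencies(bm.subset_populations(scope), model=model)[scope].to_numpy()
    h = _h_within(q)
    D = _nei_minimum_distance(q)
    n = len(scope)
    iu = np.triu_indices(n, k=1)
    h_all = float(h.mean())
    d_all = float(D[iu].mean())
    rows = []
    for i, pop in enumerate(scope):
        keep = [j for j in range(n) if j != i]
        h_wo = float(h[keep].mean())
        sub = D[np.ix_(keep, keep)]
        d_wo = float(sub[np.triu_indices(n - 1, k=1)].mean())
        dh_nei = 100.0 * (h_all - h_wo) / h_all if h_all else 0.0
        dh_dist = 100.0 * (d_all - d_wo) / d_all if d_all else 0.0
        rows.append({"population": pop, "dH_nei": dh_nei, "dH_dist": dh_dist,
                     "dH_t": dh_nei + dh_dist})
    return pd.DataFrame(rows).set_index("population")
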