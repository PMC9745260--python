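"""Population-structure diagnostics: isolation by distance, AMOVA, clusters.

The isolation-by-distance toolkit correlates individual-pairwise genetic
distances (proportion of mismatched loci) with log-scaled great-circle
distances (Mantel test) and profiles the mean genetic distance across
geographic distance classes (spatial autocorrelation, the A_y statistic).
Differentiation is quantified by Phi_ST from an AMOVA on squared Euclidean
distances between binary band phenotypes, with a permutation test. When
externally estimated genetic-cluster labels (e.g. from a Bayesian
structure program) are not supplied, a seeded k-means on population
band-frequency vectors serves as a surrogate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from rguc_kit.aflp_io import BandMatrix, band_frequencies

__all__ = [
    "DistanceMatrices",
    "PhiStResult",
    "distance_matrices",
    "haversine_km",
    "mantel_test",
    "spatial_autocorrelation",
    "phi_st",
    "surrogate_clusters",
]

_EARTH_RADIUS_KM = 6371.0


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km on a WGS84 sphere (R = 6371 km)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * _EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


@dataclass
class DistanceMatrices:
    """Individual-pairwise genetic and geographic distances.

    ``genetic`` holds proportions of mismatched loci in [0, 1];
    ``geographic`` great-circle km. Both symmetric with zero diagonal.
    """

    genetic: np.ndarray
    geographic: np.ndarray

    def __post_init__(self) -> None:
        g, d = np.asarray(self.genetic, float), np.asarray(self.geographic, float)
        if g.shape != d.shape or g.ndim != 2 or g.shape[0] != g.shape[1]:
            raise ValueError("matrices must be square and conformable")
        for name, m in (("genetic", g), ("geographic", d)):
            if not np.allclose(m, m.T) or not np.allclose(np.diag(m), 0):
                raise ValueError(f"{name} matrix must be symmetric with zero diagonal")
        if g.min() < 0 or g.max() > 1:
            raise ValueError("genetic distances must be in [0, 1]")
        self.genetic, self.geographic = g, d

    @property
    def n(self) -> int:
        return self.genetic.shape[0]

    def log_geographic(self) -> np.ndarray:
        """Natural log of (km + 1); the +1 guards zero distances."""
        return np.log(self.geographic + 1.0)


def distance_matrices(bm: BandMatrix, pf: pd.DataFrame) -> DistanceMatrices:
    """Build the genetic/geographic distance pair from data.

    Individuals inherit their population's coordinates (within-population
    geographic distance is 0).
    """
    v = bm.values.astype(float)
    # mismatch proportion via cross-products: xor counts
    same = v @ v.T + (1 - v) @ (1 - v).T
    genetic = 1.0 - same / bm.n_loci
    np.fill_diagonal(genetic, 0.0)
    genetic = np.clip((genetic + genetic.T) / 2, 0.0, 1.0)

    meta = pf.set_index("population") if "population" in pf.columns else pf
    lon = np.array([meta.loc[p, "longitude"] for p in bm.populations], float)
    lat = np.array([meta.loc[p, "latitude"] for p in bm.populations], float)
    geo = haversine_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :])
    np.fill_diagonal(geo, 0.0)
    return DistanceMatrices(genetic, (geo + geo.T) / 2)


# ---------------------------------------------------------------------------
# Mantel test


def mantel_test(dm: DistanceMatrices, n_perm: int = 999, seed: int | None = None) -> tuple[float, float]:
    """Mantel correlation of genetic vs log-geographic distance.

    r is the Pearson correlation of the lower triangles; significance
    from permuting individuals (rows+columns of the genetic matrix),
    one-sided for positive association, with the +1/(n+1) convention.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    n = dm.n
    iu = np.triu_indices(n, k=1)
    x = dm.log_geographic()[iu]
    y_mat = dm.genetic
    y = y_mat[iu]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant distance matrix: Mantel r undefined")
    x = (x - x.mean()) / x.std()

    def corr(yv: np.ndarray) -> float:
        ys = (yv - yv.mean()) / yv.std()
        return float((x * ys).mean())

    r_obs = corr(y)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yp = y_mat[np.ix_(perm, perm)][iu]
        if corr(yp) >= r_obs:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return r_obs, p


# ---------------------------------------------------------------------------
# Spatial autocorrelation (distance-class profile)


def spatial_autocorrelation(dm: DistanceMatrices, n_classes: int = 10,
                            n_perm: int = 1000, seed: int | None = None) -> pd.DataFrame:
    """Mean genetic distance per geographic distance class (A_y).

    Classes are equal-pair-count bins of geographic distance. For each
    class, a two-sided permutation p-value is computed by shuffling
    genotypes among locations (permuting the genetic matrix) with class
    membership held fixed; resolution is 1/(n_perm + 1).

    Returns a DataFrame with columns ``class`` (1-based rank), ``d_max``
    (upper geographic bound), ``n_pairs``, ``A_y``, ``p``.
    """
    if n_classes < 2:
        raise ValueError("need at least 2 distance classes")
    n = dm.n
    iu = np.triu_indices(n, k=1)
    geo = dm.geographic[iu]
    gen_mat = dm.genetic
    gen = gen_mat[iu]
    order = np.argsort(geo, kind="stable")
    splits = np.array_split(order, n_classes)
    if any(len(s) == 0 for s in splits):
        raise ValueError("empty distance class: reduce n_classes")
    membership = np.empty(len(geo), dtype=int)
    for k, s in enumerate(splits):
        membership[s] = k

    a_obs = np.array([gen[membership == k].mean() for k in range(n_classes)])
    rng = np.random.default_rng(seed)
    ge = np.zeros(n_classes)  # perms with A >= obs
    le = np.zeros(n_classes)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        gp = gen_mat[np.ix_(perm, perm)][iu]
        a_perm = np.array([gp[membership == k].mean() for k in range(n_classes)])
        ge += a_perm >= a_obs
        le += a_perm <= a_obs
    p = np.minimum(1.0, 2.0 * np.minimum(ge + 1, le + 1) / (n_perm + 1))
    return pd.DataFrame(
        {
            "class": np.arange(1, n_classes + 1),
            "d_max": [geo[membership == k].max() for k in range(n_classes)],
            "n_pairs": [int((membership == k).sum()) for k in range(n_classes)],
            "A_y": a_obs,
            "p": p,
        }
    )


# ---------------------------------------------------------------------------
# AMOVA Phi_ST


@dataclass
class PhiStResult:
    phi_st: float
    sigma2_among: float
    sigma2_within: float
    p_value: float
    n_permutations: int


def _amova_phi(d2: np.ndarray, groups: np.ndarray) -> tuple[float, float, float]:
    """Variance components from an AMOVA on a squared-distance matrix."""
    n = len(groups)
    labels, counts = np.unique(groups, return_counts=True)
    G = len(labels)
    ss_total = d2.sum() / (2 * n)
    ss_within = 0.0
    for g, ng in zip(labels, counts):
        idx = np.flatnonzero(groups == g)
        ss_within += d2[np.ix_(idx, idx)].sum() / (2 * ng)
    ss_among = ss_total - ss_within
    df_among, df_within = G - 1, n - G
    sigma2_w = ss_within / df_within
    n_bar = (n - (counts**2).sum() / n) / df_among
    sigma2_a = (ss_among / df_among - sigma2_w) / n_bar
    denom = sigma2_a + sigma2_w
    phi = sigma2_a / denom if denom > 0 else 0.0
    return float(phi), float(sigma2_a), float(sigma2_w)


def phi_st(bm: BandMatrix, grouping: dict[str, object] | None = None,
           n_perm: int = 999, seed: int | None = None) -> PhiStResult:
    """AMOVA Phi_ST on binary band phenotypes.

    Squared Euclidean distance between individuals (= number of
    mismatched bands); groups default to populations, or populations can
    be merged into higher-level groups via ``grouping`` (population ->
    group label). Significance from permuting individuals among groups.
    Set ``n_perm=0`` to skip the permutation test (p reported as 1.0).
    """
    if grouping is None:
        groups = np.asarray(bm.populations)
    else:
        groups = np.asarray([grouping[p] for p in bm.populations])
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    if counts.min() < 2:
        raise ValueError("every group needs at least 2 individuals")

    v = bm.values.astype(float)
    sq = (v**2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2 * v @ v.T
    np.fill_diagonal(d2, 0.0)
    d2 = np.clip(d2, 0.0, None)

    phi, s2a, s2w = _amova_phi(d2, groups)
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            gp = rng.permutation(groups)
            if _amova_phi(d2, gp)[0] >= phi:
                count += 1
        p = (count + 1) / (n_perm + 1)
    else:
        p = 1.0
    return PhiStResult(phi, s2a, s2w, p, n_perm)


# ---------------------------------------------------------------------------
# Cluster-label surrogate


def surrogate_clusters(bm: BandMatrix, K: int | None = None, *, n_restarts: int = 50,
                       seed: int | None = None) -> dict[str, int]:
    """K-means on population band-frequency vectors -> labels 1..K.

    A stand-in for externally supplied Bayesian cluster labels so
    synthetic pipelines run end to end. If ``K`` is None it is chosen by
    silhouette score over 2..n_pops-1. Labels are renumbered in order of
    first appearance along the population list.
    """
    freqs = band_frequencies(bm).drop(columns="overall")
    pops = list(freqs.columns)
    X = freqs.to_numpy().T
    if K is not None and not 1 <= K <= len(pops):
        raise ValueError(f"K must be in [1, {len(pops)}]")
    if K == 1:
        return {p: 1 for p in pops}
    if K == len(pops):
        return {p: i + 1 for i, p in enumerate(pops)}
    if K is None:
        best, K = -np.inf, 2
        for k in range(2, len(pops)):
            km = KMeans(n_clusters=k, n_init=n_restarts, random_state=_as_random_state(seed))
            lab = km.fit_predict(X)
            s = silhouette_score(X, lab)
            if s > best:
                best, K = s, k
    km = KMeans(n_clusters=K, n_init=n_restarts, random_state=_as_random_state(seed))
    raw = km.fit_predict(X)
    remap: dict[int, int] = {}
    for r in raw:
        if r not in remap:
            remap[r] = len(remap) + 1
    return {p: remap[r] for p, r in zip(pops, raw)}


def _as_random_state(seed: int | None) -> int | None:
    if seed is None:
        return None
    return int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31))
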