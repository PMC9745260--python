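"""Synthetic AFLP data with the structure the analysis pipeline assumes.

The generator emulates a range-wide survey of a structured tree species:
``K`` genetic clusters of populations, each population scored for ~200
dominant binary bands, with

* hierarchical drift — population band frequencies are drawn from a
  Balding-Nichols-style beta around cluster means, themselves drawn
  around species-wide ancestral frequencies, with the drift intensity
  split between the two levels so the realized AMOVA differentiation
  lands on ``fst_target``;
* rare bands — a configurable fraction of loci seeded at overall carrier
  frequency below 10% and occupancy below 40% of populations,
  concentrated in a "home" cluster (so preferred sampling areas are
  recoverable);
* climate-linked bands — a subset of loci whose population frequencies
  follow a logistic function of one bioclimatic layer with slope ``beta``.

Everything is driven by one seed through :class:`numpy.random.SeedSequence`
spawning, so band matrix and climate stack can be regenerated
independently yet consistently, and a repeated run is bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from rguc_kit.aflp_io import BandMatrix, ClimateStack, validate_population_frame

__all__ = ["SimConfig", "simulate_band_matrix", "simulate_climate"]

# Study-region-like defaults: 11 populations in 3 clusters, sample sizes
# and locus count matching a range-wide AFLP survey of a Mediterranean
# conifer; bounding box ~North Africa at 0.4 degree cells.
_DEFAULT_POPS_PER_CLUSTER = (5, 4, 2)
_DEFAULT_N_PER_POP = (24, 23, 26, 24, 25, 17, 18, 23, 24, 24, 27)
_DEFAULT_LAYERS = ("bio1", "bio3", "bio4", "bio13", "bio14")


@dataclass
class SimConfig:
    """Knobs of the synthetic study.

    ``fst_target`` is the overall AMOVA-style differentiation among
    populations; ``cluster_share`` is the fraction of that drift placed
    between clusters (the rest within clusters). ``rare_fraction`` of the
    loci are seeded rare (overall frequency < ``rare_freq``, occupancy
    < ``rare_occ`` of populations). ``n_adaptive_loci`` loci respond to
    ``adaptive_layer`` with logistic slope ``beta`` on the standardized
    layer value at each population.
    """

    seed: int = 0
    K: int = 3
    pops_per_cluster: Sequence[int] = _DEFAULT_POPS_PER_CLUSTER
    n_per_pop: Sequence[int] | int = _DEFAULT_N_PER_POP
    n_loci: int = 203
    fst_target: float = 0.247
    cluster_share: float = 0.5
    rare_fraction: float = 0.30
    rare_freq: float = 0.10
    rare_occ: float = 0.40
    n_adaptive_loci: int = 10
    beta: float = 2.0
    drift_heterogeneity: float = 0.5
    adaptive_layer: str = "bio4"
    layer_names: Sequence[str] = _DEFAULT_LAYERS
    grid_shape: tuple[int, int] = (20, 40)
    bbox: tuple[float, float, float, float] = (-9.0, 30.0, 7.0, 38.0)  # W,S,E,N

    def __post_init__(self) -> None:
        if self.K < 1 or len(self.pops_per_cluster) != self.K:
            raise ValueError("pops_per_cluster must list one count per cluster")
        if any(c < 1 for c in self.pops_per_cluster):
            raise ValueError("all cluster sizes must be >= 1")
        if not 0 < self.fst_target < 1:
            raise ValueError("fst_target must be in (0, 1)")
        if not 0 <= self.rare_fraction < 1:
            raise ValueError("rare_fraction must be in [0, 1)")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        n_pops = self.n_pops
        if isinstance(self.n_per_pop, int):
            self.n_per_pop = (self.n_per_pop,) * n_pops
        if len(self.n_per_pop) != n_pops:
            raise ValueError(f"n_per_pop must give {n_pops} sizes")
        if any(n < 2 for n in self.n_per_pop):
            raise ValueError("every population needs >= 2 individuals")
        if self.grid_shape[0] < 5 or self.grid_shape[1] < 5:
            raise ValueError("grid must be at least 5x5")
        n_rare = round(self.rare_fraction * self.n_loci)
        if n_rare + self.n_adaptive_loci > self.n_loci:
            raise ValueError("rare + adaptive loci exceed n_loci")
        max_occ = math.ceil(self.rare_occ * n_pops) - 1
        if n_rare > 0 and max_occ < 1:
            raise ValueError("rare_occ too small: no admissible occupancy")

    @property
    def n_pops(self) -> int:
        return int(sum(self.pops_per_cluster))

    def _children(self) -> list[np.random.SeedSequence]:
        return np.random.SeedSequence(self.seed).spawn(3)  # layout, climate, genetics


# ---------------------------------------------------------------------------


def _simulate_layout(cfg: SimConfig) -> pd.DataFrame:
    """Population coordinates: cluster centers spread across the bbox,
    populations jittered around their center."""
    rng = np.random.default_rng(cfg._children()[0])
    w, s, e, n = cfg.bbox
    pad_x, pad_y = 0.12 * (e - w), 0.18 * (n - s)
    centers_x = np.linspace(w + pad_x, e - pad_x, cfg.K)
    centers_y = rng.uniform(s + pad_y, n - pad_y, size=cfg.K)
    rows = []
    pop_idx = 0
    spread_x = 0.5 * (e - w) / max(cfg.K, 2)
    spread_y = 0.25 * (n - s)
    for k, n_in_cluster in enumerate(cfg.pops_per_cluster):
        for _ in range(n_in_cluster):
            pop_idx += 1
            lon = float(np.clip(centers_x[k] + rng.normal(0, spread_x / 2), w + 0.01, e - 0.01))
            lat = float(np.clip(centers_y[k] + rng.normal(0, spread_y / 2), s + 0.01, n - 0.01))
            rows.append(
                {
                    "population": str(pop_idx),
                    "longitude": lon,
                    "latitude": lat,
                    "n_individuals": int(cfg.n_per_pop[pop_idx - 1]),
                    "cluster": k + 1,
                }
            )
    return validate_population_frame(pd.DataFrame(rows))


def simulate_climate(cfg: SimConfig, pf: pd.DataFrame) -> tuple[ClimateStack, pd.DataFrame]:
    """Smooth synthetic bioclimatic layers plus their values at populations.

    Each layer is a low-order spatial trend (random linear + quadratic
    terms in lon/lat) plus Gaussian-smoothed noise. Returns the stack and
    a per-population covariate table (population + one column per layer).
    """
    rng = np.random.default_rng(cfg._children()[1])
    nrow, ncol = cfg.grid_shape
    w, s, e, n = cfg.bbox
    cellsize = (e - w) / ncol
    # grid tall enough to cover the bbox height
    nrow = max(nrow, int(math.ceil((n - s) / cellsize)))
    lon = w + (np.arange(ncol) + 0.5) * cellsize
    lat = s + (nrow - 1 - np.arange(nrow) + 0.5) * cellsize
    LON, LAT = np.meshgrid(lon, lat)
    x = (LON - LON.mean()) / (LON.std() + 1e-12)
    y = (LAT - LAT.mean()) / (LAT.std() + 1e-12)
    layers: dict[str, np.ndarray] = {}
    for name in cfg.layer_names:
        a = rng.normal(0, 1, size=6)
        trend = a[0] + a[1] * x + a[2] * y + 0.5 * (a[3] * x * y + a[4] * x**2 + a[5] * y**2)
        noise = ndimage.gaussian_filter(rng.normal(0, 1, size=(nrow, ncol)), sigma=2.0)
        layers[name] = trend + 0.6 * noise
    stack = ClimateStack(layers, xllcorner=w, yllcorner=s, cellsize=cellsize)
    cov = stack.sample(pf["longitude"], pf["latitude"])
    cov.insert(0, "population", pf["population"].to_numpy())
    return stack, cov


# ---------------------------------------------------------------------------


def _bn_draw(rng: np.random.Generator, mean: np.ndarray, drift: float) -> np.ndarray:
    """Balding-Nichols beta draw around ``mean`` with drift parameter F."""
    if drift <= 0:
        return mean.copy()
    m = np.clip(mean, 0.01, 0.99)
    scale = (1.0 - drift) / drift
    return rng.beta(m * scale, (1.0 - m) * scale)


def simulate_band_matrix(cfg: SimConfig) -> tuple[BandMatrix, pd.DataFrame, dict]:
    """Simulate a band matrix plus population frame and a truth record.

    The truth record holds the planted structure: ``cluster_of`` labels,
    ``rare_loci`` and ``adaptive_loci`` ids, the climate layer the
    adaptive loci respond to, and the population band-frequency matrix
    the Bernoulli sampling used.
    """
    pf = _simulate_layout(cfg)
    _, cov = simulate_climate(cfg, pf)
    rng = np.random.default_rng(cfg._children()[2])

    n_pops = cfg.n_pops
    cluster_of = pf["cluster"].to_numpy(int)
    sizes = np.asarray(cfg.n_per_pop, dtype=int)
    total_n = int(sizes.sum())

    n_rare = round(cfg.rare_fraction * cfg.n_loci)
    locus_ids = [f"L{i + 1:03d}" for i in range(cfg.n_loci)]
    all_idx = np.arange(cfg.n_loci)
    rare_idx = all_idx[:n_rare]
    adaptive_idx = all_idx[n_rare : n_rare + cfg.n_adaptive_loci]
    neutral_idx = all_idx[n_rare + cfg.n_adaptive_loci :]

    # Per-population drift multipliers: populations differ in effective
    # size, so some both retain diversity and harbor more rare variants.
    mult = np.exp(rng.normal(0.0, cfg.drift_heterogeneity, size=n_pops))
    mult /= mult.mean()
    rare_weight = (1.0 / mult) ** 2  # rare bands persist where drift is weak

    freq = np.zeros((n_pops, cfg.n_loci))

    # adaptive loci first: logistic response to the designated layer
    if len(adaptive_idx):
        z = cov[cfg.adaptive_layer].to_numpy(float)
        z = (z - z.mean()) / (z.std() + 1e-12)
        for j in adaptive_idx:
            a = rng.uniform(-0.5, 0.5)
            freq[:, j] = 1.0 / (1.0 + np.exp(-(a + cfg.beta * z)))

    # rare loci: low overall frequency, few populations, clustered home
    max_occ = math.ceil(cfg.rare_occ * n_pops) - 1
    home = rng.integers(1, cfg.K + 1, size=n_rare)
    for slot, j in enumerate(rare_idx):
        freq[:, j] = _rare_band_frequencies(cfg, rng, sizes, cluster_of, int(home[slot]),
                                            max_occ, rare_weight)

    # Neutral loci: ancestral -> cluster -> population Balding-Nichols.
    # The rare and adaptive loci above contribute their own (mostly weak)
    # differentiation, so the neutral drift is solved analytically such
    # that the EXPECTED AMOVA ratio over the whole matrix hits fst_target:
    # among = F*V + s_fixed, within = (1-F)*V + w_fixed.
    f0 = rng.uniform(0.1, 0.9, size=len(neutral_idx))
    V = float((f0 * (1.0 - f0)).sum())
    fixed = np.concatenate([rare_idx, adaptive_idx]).astype(int)
    s_fixed = float(freq[:, fixed].var(axis=0).sum()) if len(fixed) else 0.0
    w_fixed = float((freq[:, fixed] * (1 - freq[:, fixed])).mean(axis=0).sum()) if len(fixed) else 0.0
    if V > 0:
        f_eff = (cfg.fst_target * (V + s_fixed + w_fixed) - s_fixed) / V
        f_eff = float(np.clip(f_eff, 0.01, 0.9))
        f_between = cfg.cluster_share * f_eff
        f_within = (f_eff - f_between) / (1.0 - f_between)
        pop_drift = np.clip(f_within * mult, 0.005, 0.95)
        for slot, j in enumerate(neutral_idx):
            cluster_f = _bn_draw(rng, np.full(cfg.K, f0[slot]), f_between)
            means = cluster_f[cluster_of - 1]
            freq[:, j] = np.array(
                [_bn_draw(rng, means[i : i + 1], pop_drift[i])[0] for i in range(n_pops)]
            )

    # Bernoulli individuals; re-assert the rare invariants on the realized
    # matrix and resample violating rare loci.
    values = (rng.random((total_n, cfg.n_loci)) < np.repeat(freq, sizes, axis=0)).astype(np.int8)
    pop_of_row = np.repeat(np.arange(n_pops), sizes)
    for slot, j in enumerate(rare_idx):
        for _ in range(200):
            carriers = values[:, j]
            occ = len(np.unique(pop_of_row[carriers == 1]))
            if carriers.sum() >= 1 and carriers.mean() < cfg.rare_freq and occ / n_pops < cfg.rare_occ:
                break
            freq[:, j] = _rare_band_frequencies(cfg, rng, sizes, cluster_of, int(home[slot]),
                                                max_occ, rare_weight)
            values[:, j] = rng.random(total_n) < np.repeat(freq[:, j], sizes)
        else:  # pragma: no cover - astronomically unlikely at sane configs
            raise RuntimeError(f"could not realize rare locus {locus_ids[j]}")

    populations = [str(p + 1) for p in pop_of_row]
    individual_ids = []
    counter: dict[str, int] = {}
    for p in populations:
        counter[p] = counter.get(p, 0) + 1
        individual_ids.append(f"P{p}_{counter[p]:02d}")
    bm = BandMatrix(values, individual_ids, locus_ids, populations)

    truth = {
        "cluster_of": {str(i + 1): int(c) for i, c in enumerate(cluster_of)},
        "rare_loci": [locus_ids[j] for j in rare_idx],
        "adaptive_loci": [locus_ids[j] for j in adaptive_idx],
        "adaptive_layer": cfg.adaptive_layer,
        "rare_home_cluster": {locus_ids[j]: int(home[s]) for s, j in enumerate(rare_idx)},
        "pop_frequencies": pd.DataFrame(
            freq.T, index=locus_ids, columns=[str(i + 1) for i in range(n_pops)]
        ),
    }
    return bm, pf, truth


def _rare_band_frequencies(cfg: SimConfig, rng: np.random.Generator, sizes: np.ndarray,
                           cluster_of: np.ndarray, home: int, max_occ: int,
                           weight: np.ndarray) -> np.ndarray:
    """Per-population frequencies for one rare band.

    Occupied populations come from the home cluster first (spilling over
    only if the requested occupancy exceeds the cluster), drawn without
    replacement with probability proportional to ``weight`` (populations
    with weak drift retain rare variants more often).
    """
    n_pops = len(sizes)
    occ = int(rng.integers(1, max_occ + 1))

    def pick(pool: np.ndarray, k: int) -> np.ndarray:
        w = weight[pool] / weight[pool].sum()
        return rng.choice(pool, size=k, replace=False, p=w)

    home_pops = np.flatnonzero(cluster_of == home)
    others = np.flatnonzero(cluster_of != home)
    k_home = min(occ, len(home_pops))
    chosen = pick(home_pops, k_home)
    if occ > k_home:
        chosen = np.concatenate([chosen, pick(others, occ - k_home)])
    f = np.zeros(n_pops)
    f[chosen] = rng.uniform(0.05, 0.30, size=occ)
    # keep expected overall carrier fraction safely under the threshold
    expected = float((f * sizes).sum() / sizes.sum())
    cap = 0.6 * cfg.rare_freq
    if expected > cap:
        f *= cap / expected
    return f
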