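"""Rare-band sampling theory and selection of conservation units (RGUCs).

Rare bands — loci below an overall-frequency threshold and present in
fewer than a threshold fraction of populations — carry the distinctive
variation a sampling design should not lose. The probability that a rare
band of frequency ``p`` present in ``N`` populations is missed is
``L = (1 - p)^(2N)``. Regressing ``-ln L`` on mean band frequency for the
observed occupancies (L_o) and for single-population sampling (L_e, N=1)
gives two slopes whose ratio, the R-value, estimates the proportion of
rare bands captured when sampling a single population.

The number of populations needed to retain a fraction ``P`` of total
diversity follows from ``P = 1 - F_ST^n``; rare bands are assigned to a
preferred sampling area (PSA, the genetic cluster where their capture is
most likely); and the populations with the highest gene diversity within
each cluster become the Relevant Genetic Units for Conservation, checked
against a randomized-selection baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from rguc_kit.aflp_io import BandMatrix, band_frequencies

__all__ = [
    "LossRegression",
    "find_rare_bands",
    "loss_probability",
    "r_value",
    "assign_psa",
    "n_populations",
    "integer_populations",
    "optimal_proportions",
    "select_rgucs",
    "capture_percent",
    "random_capture_baseline",
]


def find_rare_bands(bm: BandMatrix, freq_thresh: float = 0.10,
                    occ_thresh: float = 0.40) -> pd.DataFrame:
    """Table of rare bands (one row per locus meeting both criteria).

    A band is rare when its overall carrier frequency is strictly below
    ``freq_thresh`` AND it is present in strictly fewer than
    ``occ_thresh`` of the populations (but in at least one). Columns:
    ``p_overall``, ``occupancy`` (populations with >= 1 carrier),
    ``mean_freq_occupied``, ``L_o`` (loss probability at observed
    occupancy), ``L_e`` (at occupancy 1).
    """
    if not (0 < freq_thresh < 1 and 0 < occ_thresh < 1):
        raise ValueError("thresholds must be in (0, 1)")
    freqs = band_frequencies(bm)
    pop_cols = [c for c in freqs.columns if c != "overall"]
    n_pops = len(pop_cols)
    present = freqs[pop_cols] > 0
    occ = present.sum(axis=1)
    rows = []
    for locus in freqs.index:
        p = float(freqs.loc[locus, "overall"])
        N = int(occ[locus])
        if N == 0 or p >= freq_thresh or N / n_pops >= occ_thresh:
            continue
        mean_occ = float(freqs.loc[locus, pop_cols][present.loc[locus]].mean())
        rows.append(
            {
                "locus": locus,
                "p_overall": p,
                "occupancy": N,
                "mean_freq_occupied": mean_occ,
                "L_o": loss_probability(mean_occ, N),
                "L_e": loss_probability(mean_occ, 1),
            }
        )
    return pd.DataFrame(rows, columns=["locus", "p_overall", "occupancy",
                                       "mean_freq_occupied", "L_o", "L_e"]).set_index("locus")


def rare_records_in_scope(bm: BandMatrix, loci: Sequence[str],
                          populations: Sequence[str]) -> pd.DataFrame:
    """Re-evaluate rare-band records within a subset of populations.

    Cluster-level R-values use the range-wide rare-band set but recount
    occupancy and mean frequency over the cluster's populations only.
    Bands absent from the scope are dropped.
    """
    sub = bm.subset_populations(populations)
    freqs = band_frequencies(sub)
    pop_cols = [c for c in freqs.columns if c != "overall"]
    rows = []
    for locus in loci:
        present = freqs.loc[locus, pop_cols] > 0
        N = int(present.sum())
        if N == 0:
            continue
        mean_occ = float(freqs.loc[locus, pop_cols][present].mean())
        if mean_occ >= 1.0:
            continue  # fixed within scope: loss model undefined
        rows.append({
            "locus": locus,
            "p_overall": float(freqs.loc[locus, "overall"]),
            "occupancy": N,
            "mean_freq_occupied": mean_occ,
            "L_o": loss_probability(mean_occ, N),
            "L_e": loss_probability(mean_occ, 1),
        })
    return pd.DataFrame(rows, columns=["locus", "p_overall", "occupancy",
                                       "mean_freq_occupied", "L_o", "L_e"]).set_index("locus")


def loss_probability(p: float, N: int) -> float:
    """Probability ``(1-p)^(2N)`` that a band of frequency ``p`` present
    in ``N`` populations is lost when those populations are not sampled."""
    if not 0 < p < 1:
        raise ValueError("band frequency must be in (0, 1)")
    if N < 1 or int(N) != N:
        raise ValueError("occupancy must be a positive integer")
    return float((1.0 - p) ** (2 * int(N)))


@dataclass
class LossRegression:
    """Slopes of -ln L against mean band frequency, and their ratio."""

    slope_observed: float
    slope_expected: float
    intercept_observed: float
    intercept_expected: float
    r_value: float  # in (0, 1]

    @property
    def r_percent(self) -> float:
        return 100.0 * self.r_value


def r_value(records: pd.DataFrame) -> LossRegression:
    """R-value from the loss-probability regressions.

    OLS (with intercept) of ``-ln L_o`` and of ``-ln L_e`` against the
    mean band frequency across occupied populations; R is the ratio of
    the expected (single-population) slope to the observed slope, the
    estimated proportion of rare bands captured by sampling one
    population. When every band has occupancy N the ratio is exactly 1/N.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 rare bands")
    x = records["mean_freq_occupied"].to_numpy(float)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in mean band frequency")
    y_o = -np.log(records["L_o"].to_numpy(float))
    y_e = -np.log(records["L_e"].to_numpy(float))
    X = np.column_stack([np.ones_like(x), x])
    (b0_o, b1_o), *_ = np.linalg.lstsq(X, y_o, rcond=None)
    (b0_e, b1_e), *_ = np.linalg.lstsq(X, y_e, rcond=None)
    if b1_o <= 0 or b1_e <= 0:
        raise ValueError("degenerate regression: non-positive slope")
    return LossRegression(float(b1_o), float(b1_e), float(b0_o), float(b0_e),
                          float(b1_e / b1_o))


def assign_psa(records: pd.DataFrame, clusters: Mapping[str, int],
               bm: BandMatrix) -> pd.DataFrame:
    """Assign each rare band a preferred sampling area (PSA).

    Per cluster two statistics are computed for the band: (a) the
    fraction of the cluster's populations carrying it, (b) the number of
    carrier individuals in the cluster. The PSA is the cluster maximizing
    (a); ties broken by (b), then by the lower cluster index. Returns the
    records with ``psa`` (and the per-cluster diagnostics) added.
    """
    pops = bm.population_labels
    missing = [p for p in pops if p not in clusters]
    if missing:
        raise ValueError(f"cluster labels missing for populations: {missing}")
    ks = sorted(set(int(clusters[p]) for p in pops))
    counts = {p: bm.values[bm.rows_of(p)].sum(axis=0) for p in pops}
    locus_pos = {l: j for j, l in enumerate(bm.locus_ids)}

    psa, frac_best, carriers_best = [], [], []
    for locus in records.index:
        j = locus_pos[locus]
        stats = []
        for k in ks:
            members = [p for p in pops if int(clusters[p]) == k]
            frac = sum(counts[p][j] > 0 for p in members) / len(members)
            carriers = int(sum(counts[p][j] for p in members))
            stats.append((frac, carriers, -k))
        if all(s[1] == 0 for s in stats):
            raise ValueError(f"rare band {locus!r} absent from every population")
        best = max(range(len(ks)), key=lambda i: stats[i])
        psa.append(ks[best])
        frac_best.append(stats[best][0])
        carriers_best.append(stats[best][1])
    out = records.copy()
    out["psa"] = psa
    out["psa_pop_fraction"] = frac_best
    out["psa_carriers"] = carriers_best
    return out


def n_populations(f_st: float, P: float) -> tuple[float, int]:
    """Populations needed to retain fraction ``P`` of total diversity.

    Solves ``P = 1 - F_ST^n`` for n: ``n = ln(1-P)/ln(F_ST)``. The
    integer recommendation always rounds up so the conservation goal is
    not underestimated.
    """
    if not 0 < f_st < 1:
        raise ValueError("F_ST must be in (0, 1)")
    if not 0 < P < 1:
        raise ValueError("diversity target P must be in (0, 1)")
    n_real = math.log(1.0 - P) / math.log(f_st)
    return n_real, integer_populations(n_real)


def integer_populations(n_real: float) -> int:
    """Round a continuous population count up (never down)."""
    if n_real <= 0:
        raise ValueError("population count must be positive")
    return int(math.ceil(n_real))


def optimal_proportions(psa_shares: Mapping[int, float], r_values: Mapping[int, float],
                        strategy: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None,
                        ) -> dict[int, float]:
    """Sampling proportions per cluster from PSA shares and R-values.

    Default strategy: arithmetic mean of the normalized PSA share and
    the normalized R-value, renormalized to sum to 1. A different
    combination rule can be supplied as ``strategy(shares, rvals) ->
    weights`` (weights are renormalized).
    """
    ks = sorted(psa_shares)
    if sorted(r_values) != ks:
        raise ValueError("psa_shares and r_values must cover the same clusters")
    shares = np.array([psa_shares[k] for k in ks], float)
    rvals = np.array([r_values[k] for k in ks], float)
    if shares.sum() <= 0 or rvals.sum() <= 0:
        raise ValueError("shares and R-values must have positive sums")
    if not np.isclose(shares.sum(), 1.0, atol=1e-6):
        shares = shares / shares.sum()
    if strategy is None:
        w = 0.5 * (shares / shares.sum() + rvals / rvals.sum())
    else:
        w = np.asarray(strategy(shares, rvals), float)
    w = w / w.sum()
    return {k: float(v) for k, v in zip(ks, w)}


def select_rgucs(descriptors: pd.DataFrame, clusters: Mapping[str, int],
                 n_per_cluster: Mapping[int, int]) -> dict[int, list[str]]:
    """Pick the RGUC populations: top-n by Nei gene diversity per cluster.

    ``descriptors`` is the table from :func:`rguc_kit.divrar.pop_descriptors`
    (needs ``nei_gd`` and ``dw`` columns, populations as index). Ties on
    gene diversity are broken by DW, then by population label order.
    """
    out: dict[int, list[str]] = {}
    for k, n in n_per_cluster.items():
        members = [p for p in descriptors.index if int(clusters[p]) == int(k)]
        if n > len(members):
            raise ValueError(f"cluster {k}: requested {n} of {len(members)} populations")
        order = sorted(
            members,
            key=lambda p: (-descriptors.loc[p, "nei_gd"], -descriptors.loc[p, "dw"],
                           members.index(p)),
        )
        out[int(k)] = order[:n]
    return out


def capture_percent(bm: BandMatrix, selected: Sequence[str],
                    rare_loci: Sequence[str] | None = None) -> tuple[float, float]:
    """(% of all bands, % of rare bands) present in >= 1 selected population."""
    sel = list(selected)
    mask = np.zeros(bm.n_individuals, dtype=bool)
    for p in sel:
        mask |= bm.rows_of(p)
    present_all = bm.values.sum(axis=0) > 0
    captured = bm.values[mask].sum(axis=0) > 0
    pct_all = 100.0 * captured[present_all].sum() / max(present_all.sum(), 1)
    if rare_loci is None:
        return float(pct_all), float("nan")
    idx = [bm.locus_ids.index(l) for l in rare_loci]
    if not idx:
        return float(pct_all), float("nan")
    pct_rare = 100.0 * captured[idx].sum() / len(idx)
    return float(pct_all), float(pct_rare)


def random_capture_baseline(bm: BandMatrix, clusters: Mapping[str, int],
                            n_per_cluster: Mapping[int, int],
                            rare_loci: Sequence[str] | None = None,
                            reps: int = 100, seed: int | None = None) -> tuple[float, float]:
    """Mean capture of a random selection of n populations per cluster.

    Uniform sampling without replacement within each cluster, averaged
    over ``reps`` repetitions; returns mean (% all bands, % rare bands).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    pops = list(dict.fromkeys(bm.populations))
    members = {k: [p for p in pops if int(clusters[p]) == int(k)] for k in n_per_cluster}
    tot_all = tot_rare = 0.0
    for _ in range(reps):
        chosen: list[str] = []
        for k, n in n_per_cluster.items():
            chosen.extend(rng.choice(members[k], size=n, replace=False))
        a, r = capture_percent(bm, chosen, rare_loci)
        tot_all += a
        tot_rare += 0.0 if np.isnan(r) else r
    return tot_all / reps, (tot_rare / reps if rare_loci else float("nan"))
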