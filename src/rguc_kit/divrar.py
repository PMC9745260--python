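"""Per-population diversity and rarity descriptors for dominant markers.

For each population the module reports the band counts (total, %
polymorphic, private), Nei's gene diversity, and the frequency
down-weighted marker value (DW), a rarity score that credits a
population with its share of every band's total occurrences.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from rguc_kit.aflp_io import BandMatrix, ClimateStack

__all__ = [
    "nei_gene_diversity",
    "dw_rarity",
    "pop_descriptors",
    "interpolate_surface",
]


def nei_gene_diversity(bm: BandMatrix, pop: str, *, method: str = "phenotype") -> float:
    """Nei's gene diversity of one population.

    ``method='phenotype'`` (default) treats band presence as a two-state
    phenotype: GD is the mean over all loci of ``n/(n-1) * 2 f (1-f)``
    where ``f`` is the within-population carrier frequency and ``n`` the
    population size — the convention of the AFLPdat toolkit for dominant
    data. ``method='allele'`` first converts carrier frequencies to allele
    frequencies via the square-root (null-homozygote) estimator
    ``q = sqrt(1-f)`` and averages ``n/(n-1) * 2 p q``. Loci monomorphic
    in the whole dataset are included (they contribute 0).
    """
    rows = bm.rows_of(pop)
    n = int(rows.sum())
    if n < 2:
        raise ValueError(f"population {pop!r} has fewer than 2 individuals")
    f = bm.values[rows].mean(axis=0)
    if method == "phenotype":
        h = 2.0 * f * (1.0 - f)
    elif method == "allele":
        q = np.sqrt(1.0 - f)
        h = 2.0 * (1.0 - q) * q
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(np.mean(n / (n - 1) * h))


def dw_rarity(bm: BandMatrix, pop: str) -> float:
    """Frequency down-weighted marker value (DW) of one population.

    Sum over bands of (occurrences in the population) / (occurrences in
    the whole dataset). A band private to the population contributes
    exactly 1; bands absent from the dataset contribute 0. Across
    populations the contributions of any present band sum to 1.
    """
    rows = bm.rows_of(pop)
    pop_counts = bm.values[rows].sum(axis=0).astype(float)
    total_counts = bm.values.sum(axis=0).astype(float)
    present = total_counts > 0
    return float((pop_counts[present] / total_counts[present]).sum())


def pop_descriptors(bm: BandMatrix, *, gd_method: str = "phenotype") -> pd.DataFrame:
    """Diversity/rarity descriptor table, one row per population.

    Columns: ``n`` (individuals), ``frag_tot`` (bands present),
    ``frag_poly`` (% of those polymorphic within the population, i.e.
    0 < f < 1), ``frag_priv`` (bands found in no other population),
    ``nei_gd``, ``dw``.
    """
    pops = bm.population_labels
    presence = {}
    for p in pops:
        rows = bm.rows_of(p)
        presence[p] = bm.values[rows].sum(axis=0)
    n_pops_with_band = np.sum([presence[p] > 0 for p in pops], axis=0)

    out = []
    for p in pops:
        rows = bm.rows_of(p)
        n = int(rows.sum())
        f = bm.values[rows].mean(axis=0)
        present = presence[p] > 0
        frag_tot = int(present.sum())
        poly = int(((f > 0) & (f < 1)).sum())
        frag_poly = 100.0 * poly / frag_tot if frag_tot else 0.0
        frag_priv = int((present & (n_pops_with_band == 1)).sum())
        out.append(
            {
                "population": p,
                "n": n,
                "frag_tot": frag_tot,
                "frag_poly": frag_poly,
                "frag_priv": frag_priv,
                "nei_gd": nei_gene_diversity(bm, p, method=gd_method),
                "dw": dw_rarity(bm, p),
            }
        )
    return pd.DataFrame(out).set_index("population")


def interpolate_surface(values: pd.Series | dict, pf: pd.DataFrame,
                        stack: ClimateStack, *, power: float = 2.0) -> np.ndarray:
    """Inverse-distance-weighted surface of per-population values.

    A plain IDW interpolation (power 2 by default) over the stack's grid,
    exact at the cells containing the populations; intended for visual
    inspection of diversity/rarity patterns, not for analysis. Masked
    cells stay NaN.
    """
    values = pd.Series(values)
    pf = pf.set_index("population") if "population" in pf.columns else pf
    common = [p for p in values.index if p in pf.index]
    if len(common) < 3:
        raise ValueError("need values for at least 3 populations")
    lon = pf.loc[common, "longitude"].to_numpy(float)
    lat = pf.loc[common, "latitude"].to_numpy(float)
    v = values.loc[common].to_numpy(float)

    cells = [stack.cell_of(lo, la) for lo, la in zip(lon, lat)]
    seen: dict[tuple[int, int], float] = {}
    for cell, val in zip(cells, v):
        if cell in seen and not np.isclose(seen[cell], val):
            raise ValueError(f"coincident populations with different values at cell {cell}")
        seen[cell] = val

    LON, LAT = stack.cell_coordinates()
    surface = np.full(stack.shape, np.nan)
    d2 = (LON[..., None] - lon) ** 2 + (LAT[..., None] - lat) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        w = d2 ** (-power / 2.0)
        num = (w * v).sum(axis=-1)
        den = w.sum(axis=-1)
        idw = num / den  # NaN where a population sits exactly on a cell center
    ok = ~stack.mask
    surface[ok] = idw[ok]
    for (r, c), val in seen.items():  # exact at population cells
        if not stack.mask[r, c]:
            surface[r, c] = val
    return surface
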