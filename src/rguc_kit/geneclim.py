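"""Genotype-environment turnover: gradient-forest fit, transform, maps.

A random-forest classifier is fitted per locus (band presence/absence of
each individual against population-level bioclimatic predictors). Loci
whose out-of-bag error beats the majority-class null are retained, and
their split-impurity improvements are aggregated — binned along each
predictor's range and weighted by the locus's out-of-bag performance —
into monotone *cumulative importance* functions. Passing an
environmental value through its predictor's function yields a "genetic
importance" value: predictors become commensurable axes of expected
genetic turnover. PCA plus Ward clustering of the transformed values
then partitions the landscape into groups of similar expected genetic
composition, and future scenarios are projected with frozen centroids so
group identities stay comparable across time slices.

The density standardization of the reference gradient-forest method is
simplified here to fixed-width binning of raw split improvements.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier

from rguc_kit.aflp_io import BandMatrix, ClimateStack

__all__ = [
    "TurnoverModel",
    "GeneticImportanceMap",
    "vif_filter",
    "fit_turnover",
    "transform",
    "transform_stack",
    "map_groups",
    "scenario_average",
]

log = logging.getLogger(__name__)

_N_BINS = 200


def vif_filter(samples: pd.DataFrame, r2_thresh: float = 0.7) -> list[str]:
    """Drop collinear predictors until no pair exceeds the R² threshold.

    Iteratively finds the pair with the largest squared Pearson
    correlation; of the two, the layer with the larger mean R² against
    all other retained layers is dropped (ties: the later column).
    Constant layers cannot be correlated and are always retained.
    """
    cols = [c for c in samples.columns if c not in ("population", "row", "col")]
    if len(cols) < 2:
        raise ValueError("need at least 2 predictor columns")
    if len(samples) < len(cols) + 2:
        raise ValueError("need at least n_predictors + 2 sample rows")
    X = samples[cols].to_numpy(float)
    sd = X.std(axis=0)
    if (sd == 0).all():
        raise ValueError("all layers degenerate (constant)")
    retained = list(cols)
    while True:
        sub = samples[retained].to_numpy(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            r2 = np.corrcoef(sub, rowvar=False) ** 2
        r2 = np.nan_to_num(r2, nan=0.0)
        np.fill_diagonal(r2, 0.0)
        if r2.max() <= r2_thresh:
            break
        i, j = np.unravel_index(np.argmax(r2), r2.shape)
        mean_i = r2[i].sum() / (len(retained) - 1)
        mean_j = r2[j].sum() / (len(retained) - 1)
        drop = retained[j] if (mean_j > mean_i or np.isclose(mean_i, mean_j) and j > i) else retained[i]
        log.info("vif_filter: dropping %s (pair r2=%.3f)", drop, r2[i, j])
        retained.remove(drop)
        if len(retained) == 1:
            break
    return retained


@dataclass
class TurnoverModel:
    """Per-predictor cumulative genetic-importance functions.

    ``bin_edges[p]`` has ``len(cumulative[p]) + 1`` entries spanning the
    predictor's training range; ``cumulative[p]`` is non-decreasing with
    maximum equal to ``importance[p]`` (the predictor's overall
    importance). ``loci`` summarizes every polymorphic locus with its
    out-of-bag error, null error, and retention flag.
    """

    predictors: list[str]
    importance: pd.Series
    bin_edges: dict[str, np.ndarray]
    cumulative: dict[str, np.ndarray]
    loci: pd.DataFrame
    n_trees: int = 500

    @property
    def retained_loci(self) -> list[str]:
        return list(self.loci.index[self.loci["retained"]])


def _split_improvements(tree, n_features: int) -> list[tuple[int, float, float]]:
    """(feature, threshold, weighted impurity decrease) for every split."""
    t = tree.tree_
    total_w = t.weighted_n_node_samples[0]
    out = []
    for node in range(t.node_count):
        f = t.feature[node]
        if f < 0:
            continue
        left, right = t.children_left[node], t.children_right[node]
        w, wl, wr = (t.weighted_n_node_samples[i] for i in (node, left, right))
        dec = (w / total_w) * (
            t.impurity[node]
            - (wl / w) * t.impurity[left]
            - (wr / w) * t.impurity[right]
        )
        if dec > 0:
            out.append((int(f), float(t.threshold[node]), float(dec)))
    return out


def fit_turnover(bm: BandMatrix, predictors: pd.DataFrame, n_trees: int = 500,
                 seed: int | None = None, *, max_oob_error: float | None = None) -> TurnoverModel:
    """Fit one random forest per locus and aggregate into turnover curves.

    ``predictors``: population-level predictor table (index or
    ``population`` column = population labels); each individual inherits
    its population's values. A locus is retained when its out-of-bag
    error is strictly below the majority-class null error (and, if
    ``max_oob_error`` is given, additionally at or below that absolute
    error). Monomorphic loci are skipped with a log entry.
    """
    pred = predictors.set_index("population") if "population" in predictors.columns else predictors
    names = [str(c) for c in pred.columns]
    if not names:
        raise ValueError("need at least one predictor")
    n_pops = pred.shape[0]
    if n_pops < 5 and bm.n_individuals < 30:
        raise ValueError("need >=5 populations or >=30 individuals")
    X = np.asarray([pred.loc[p].to_numpy(float) for p in bm.populations])

    ss = np.random.SeedSequence(seed)
    ranges = {p: (float(X[:, j].min()), float(X[:, j].max())) for j, p in enumerate(names)}
    edges = {}
    for j, p in enumerate(names):
        lo, hi = ranges[p]
        if hi <= lo:
            hi = lo + 1e-9  # constant predictor: degenerate range, zero importance
        edges[p] = np.linspace(lo, hi, _N_BINS + 1)

    binned = {p: np.zeros(_N_BINS) for p in names}
    weighted_share = {p: [] for p in names}
    locus_rows = []
    for jl, locus in enumerate(bm.locus_ids):
        y = bm.values[:, jl]
        if y.min() == y.max():
            log.info("fit_turnover: locus %s monomorphic, skipped", locus)
            continue
        null_err = 1.0 - max(y.mean(), 1.0 - y.mean())
        child = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
        rf = RandomForestClassifier(n_estimators=n_trees, oob_score=True,
                                    random_state=child, n_jobs=1)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # few-tree OOB coverage warnings
            rf.fit(X, y)
        oob_err = 1.0 - rf.oob_score_
        retained = oob_err < null_err
        if max_oob_error is not None:
            retained = retained and oob_err <= max_oob_error
        locus_rows.append({"locus": locus, "oob_error": oob_err,
                           "null_error": null_err, "retained": retained})
        if not retained:
            continue
        w = max(0.0, 1.0 - oob_err / null_err)  # OOB performance weight
        raw = np.zeros(len(names))
        for tree in rf.estimators_:
            for f, thr, dec in _split_improvements(tree, len(names)):
                raw[f] += dec / n_trees
                e = edges[names[f]]
                b = int(np.clip(np.searchsorted(e, thr, side="right") - 1, 0, _N_BINS - 1))
                binned[names[f]][b] += w * dec / n_trees
        total = raw.sum()
        if total > 0:
            for j, p in enumerate(names):
                weighted_share[p].append(w * raw[j] / total)
        else:
            for p in names:
                weighted_share[p].append(0.0)

    loci = pd.DataFrame(locus_rows).set_index("locus") if locus_rows else pd.DataFrame(
        columns=["oob_error", "null_error", "retained"])
    n_ret = int(loci["retained"].sum()) if len(loci) else 0
    importance = pd.Series(
        {p: (float(np.mean(weighted_share[p])) if weighted_share[p] else 0.0) for p in names}
    )
    cumulative = {}
    for p in names:
        cum = np.cumsum(binned[p])
        if cum[-1] > 0:
            cum = cum * (importance[p] / cum[-1])
        else:
            cum = np.zeros(_N_BINS)
        cumulative[p] = cum
    log.info("fit_turnover: %d/%d polymorphic loci retained", n_ret, len(loci))
    return TurnoverModel(names, importance, edges, cumulative, loci, n_trees)


def transform(model: TurnoverModel, data: pd.DataFrame) -> pd.DataFrame:
    """Map environmental values through the cumulative importance curves.

    Each predictor column is replaced by the value of its cumulative
    importance function: 0 below the training range, the predictor's
    total importance above it (out-of-range values are clamped; the
    count is logged).
    """
    missing = [p for p in model.predictors if p not in data.columns]
    if missing:
        raise ValueError(f"missing predictor columns: {missing}")
    out = {}
    clamped = 0
    for p in model.predictors:
        v = data[p].to_numpy(float)
        e, cum = model.bin_edges[p], model.cumulative[p]
        clamped += int(((v < e[0]) | (v > e[-1])).sum())
        b = np.searchsorted(e, v, side="right") - 1
        below = b < 0
        b = np.clip(b, 0, len(cum) - 1)
        t = cum[b]
        t[below] = 0.0
        out[p] = t
    if clamped:
        log.info("transform: %d values outside training range clamped", clamped)
    return pd.DataFrame(out, index=data.index)


def transform_stack(model: TurnoverModel, stack: ClimateStack) -> pd.DataFrame:
    """Transform every non-masked cell; returns row, col + transformed columns."""
    tab = stack.table()
    t = transform(model, tab)
    t.insert(0, "row", tab["row"].to_numpy())
    t.insert(1, "col", tab["col"].to_numpy())
    return t


@dataclass
class GeneticImportanceMap:
    """Pixel-level genetic-importance projection and group partition.

    ``groups`` is an int grid (0 = masked, 1..G = group); populations
    carry their PCA scores and group in ``population_table``. ``pca``
    and ``centroids`` are kept so future scenarios can be projected into
    the same space with frozen group identities.
    """

    groups: np.ndarray
    pixel_scores: pd.DataFrame  # row, col, pc1..pcA
    population_table: pd.DataFrame  # population, pc1.., group
    centroids: np.ndarray
    pca: PCA
    linkage_matrix: np.ndarray | None = None
    n_axes: int = 3


def map_groups(model: TurnoverModel, population_predictors: pd.DataFrame,
               stack: ClimateStack, n_groups: int = 3, n_axes: int = 3) -> GeneticImportanceMap:
    """PCA + Ward clustering of transformed values; assign pixels to groups.

    The PCA is fitted on the transformed grid cells; populations are
    projected into that space and Ward-clustered (cut at ``n_groups``);
    every pixel joins the nearest group centroid (Euclidean distance in
    the first ``n_axes`` PCA scores).
    """
    popp = population_predictors.set_index("population") if "population" in population_predictors.columns else population_predictors
    if n_groups > popp.shape[0]:
        raise ValueError("n_groups exceeds number of populations")
    t_grid = transform_stack(model, stack)
    grid_vals = t_grid[model.predictors].to_numpy()
    n_axes = min(n_axes, len(model.predictors))
    pca = PCA(n_components=n_axes)
    grid_scores = pca.fit_transform(grid_vals)
    pop_scores = pca.transform(transform(model, popp[model.predictors]).to_numpy())

    if np.unique(np.round(pop_scores, 12), axis=0).shape[0] < n_groups:
        raise ValueError("populations do not separate into the requested number of groups")
    Z = linkage(pop_scores, method="ward")
    raw = fcluster(Z, t=n_groups, criterion="maxclust")
    remap: dict[int, int] = {}
    for r in raw:
        if r not in remap:
            remap[r] = len(remap) + 1
    pop_groups = np.array([remap[r] for r in raw])
    centroids = np.vstack([pop_scores[pop_groups == g].mean(axis=0)
                           for g in range(1, n_groups + 1)])

    groups_grid = _assign_pixels(grid_scores, t_grid, centroids, stack.shape)
    score_cols = {f"pc{i + 1}": grid_scores[:, i] for i in range(n_axes)}
    pixel_scores = pd.DataFrame({"row": t_grid["row"], "col": t_grid["col"], **score_cols})
    pop_table = pd.DataFrame(
        {"population": list(popp.index),
         **{f"pc{i + 1}": pop_scores[:, i] for i in range(n_axes)},
         "group": pop_groups}
    )
    return GeneticImportanceMap(groups_grid, pixel_scores, pop_table, centroids, pca, Z, n_axes)


def _assign_pixels(scores: np.ndarray, pixel_index: pd.DataFrame,
                   centroids: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    d = ((scores[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    lab = d.argmin(axis=1) + 1
    grid = np.zeros(shape, dtype=int)
    grid[pixel_index["row"].to_numpy(int), pixel_index["col"].to_numpy(int)] = lab
    return grid


def scenario_average(stacks: Sequence[ClimateStack], model: TurnoverModel,
                     reference: GeneticImportanceMap) -> GeneticImportanceMap:
    """Average transformed future stacks and re-assign with frozen centroids.

    Each stack is transformed through the fitted turnover curves; the
    transformed values are averaged per pixel, projected with the
    reference map's PCA, and assigned to the reference group centroids,
    so a pixel's group is directly comparable with the current-climate
    map.
    """
    if not stacks:
        raise ValueError("need at least one stack")
    geom = stacks[0].geometry()
    for s in stacks[1:]:
        if s.geometry() != geom:
            raise ValueError("scenario stacks disagree on grid geometry")
    tables = [transform_stack(model, s) for s in stacks]
    base = tables[0][["row", "col"]]
    mean_vals = np.mean([t[model.predictors].to_numpy() for t in tables], axis=0)
    scores = reference.pca.transform(mean_vals)
    grid = _assign_pixels(scores, base, reference.centroids, stacks[0].shape)
    n_axes = reference.n_axes
    pixel_scores = pd.DataFrame(
        {"row": base["row"], "col": base["col"],
         **{f"pc{i + 1}": scores[:, i] for i in range(scores.shape[1])}}
    )
    return GeneticImportanceMap(grid, pixel_scores, reference.population_table.copy(),
                                reference.centroids, reference.pca, None, n_axes)
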