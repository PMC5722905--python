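"""Tree-ensemble regulator->target scoring (GENIE3-style).

Each candidate target gene is regressed on the feature profiles of all
candidate regulators (excluding itself) with a random forest, and each
regulator is scored by permutation importance: the mean drop in predictive
accuracy when that regulator's values are shuffled.  Scores across targets
are assembled into a regulators x targets matrix from which a global edge
ranking is read off.

The engine is feature-agnostic: it accepts raw expression profiles, RANGES
or ExRANGES step matrices, or any genes x observations table — columns are
treated as exchangeable observations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from sklearn.ensemble import RandomForestRegressor

from .containers import StepMatrix, ValidationError

__all__ = ["InferenceConfig", "EdgeScoreMatrix", "score_target", "infer_network", "rank_edges"]

MIN_OBSERVATIONS = 10
_VAR_EPS = 1e-12


@dataclass
class InferenceConfig:
    """Forest and importance settings.

    Parameters
    ----------
    n_trees : int
        Trees per target forest.  Default 2000; drop to ~100 for large
        target sets where run time matters more than score stability.
    importance : {"permutation", "variance"}
        "permutation" (default): mean decrease in out-of-bag accuracy when a
        regulator's values are randomly permuted, ``n_permutations`` shuffles
        per tree.  "variance": impurity-based variance reduction, the
        canonical GENIE3 importance, kept for cross-checking.
    max_features : int, float, or "sqrt"
        Regulators sampled per split (default sqrt of the regulator count).
    standardize : bool
        Center/scale each gene's feature row to unit variance before fitting
        (default True, the GENIE3 convention).  Observation columns are also
        put in a canonical sort order before fitting, so scores are exactly
        invariant to permutations of the observations.
    normalize : bool
        Rescale each target's importance vector to sum to 1 before pooling
        into the global ranking (default False; negative permutation
        importances are clipped to 0 first when enabled).  Off by default
        because out-of-bag accuracy drops are already on a comparable scale
        across targets, whereas sum-normalisation awards a full unit of
        score even to targets whose forests explain nothing, promoting
        noise edges in the global ranking.
    seed : int
        Root seed; each target gets its own substream, so results do not
        depend on ``n_jobs`` or target evaluation order.
    """

    n_trees: int = 2000
    importance: str = "permutation"
    n_permutations: int = 1
    max_features: object = "sqrt"
    standardize: bool = True
    normalize: bool = False
    seed: int = 0
    n_jobs: int = 1

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.importance not in ("permutation", "variance"):
            raise ValueError(f"unknown importance type {self.importance!r}")


@dataclass
class EdgeScoreMatrix:
    """Regulators x targets importance scores.

    Self-edges are NaN and are excluded from rankings.  ``meta`` records the
    feature type and the configuration used.
    """

    scores: pd.DataFrame
    meta: dict

    @property
    def regulators(self) -> pd.Index:
        return self.scores.index

    @property
    def targets(self) -> pd.Index:
        return self.scores.columns


def _standardize_rows(m: np.ndarray) -> np.ndarray:
    mu = m.mean(axis=1, keepdims=True)
    sd = m.std(axis=1, ddof=1, keepdims=True)
    sd = np.where(sd < _VAR_EPS, 1.0, sd)
    return (m - mu) / sd


def _permutation_importance(forest, x, y, n_repeats, rng) -> np.ndarray:
    """Out-of-bag mean decrease in accuracy under feature permutation.

    For every tree, prediction error is measured on the samples the tree did
    not see (its out-of-bag set) before and after permuting one regulator's
    values; the error increases, averaged over trees and scaled by the
    target's variance, are the importances.  Out-of-bag evaluation keeps
    noise features near zero importance, unlike training-set permutation,
    which rewards memorisation.  All permuted copies per tree go through a
    single ``predict`` call for speed.
    """
    n, p = x.shape
    var = float(np.var(y))
    sums = np.zeros(p)
    n_trees = 0
    for tree in forest.estimators_:
        # reproduce the bootstrap draw sklearn made for this tree
        # (random_state.randint(0, n, n) with max_samples=None)
        sampled = np.random.RandomState(tree.random_state).randint(0, n, n)
        mask = np.ones(n, dtype=bool)
        mask[sampled] = False
        m = int(mask.sum())
        if m < 2:
            continue
        xo, yo = x[mask], y[mask]
        blocks = [xo]
        for j in range(p):
            for _ in range(n_repeats):
                xp = xo.copy()
                xp[:, j] = xp[rng.permutation(m), j]
                blocks.append(xp)
        preds = tree.predict(np.vstack(blocks)).reshape(1 + p * n_repeats, m)
        errs = np.mean((preds - yo) ** 2, axis=1)
        sums += errs[1:].reshape(p, n_repeats).mean(axis=1) - errs[0]
        n_trees += 1
    if n_trees == 0:
        return np.zeros(p)
    return sums / n_trees / var


def score_target(
    target_profile: np.ndarray,
    regulator_profiles: np.ndarray,
    cfg: InferenceConfig | None = None,
    *,
    random_state: int | None = None,
) -> np.ndarray:
    """Importance of each regulator for one target gene.

    Fits a random forest of ``cfg.n_trees`` regression trees of the target's
    profile on the regulator profiles (rows = regulators, columns =
    observations) and returns one importance per regulator.  A target with no
    variance yields an all-zero vector without fitting.
    """
    cfg = cfg or InferenceConfig()
    y = np.asarray(target_profile, dtype=float)
    x = np.asarray(regulator_profiles, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValidationError("need at least 2 regulator profiles")
    if y.shape[0] != x.shape[1]:
        raise ValidationError(
            f"target has {y.shape[0]} observations but regulators have {x.shape[1]}"
        )
    if y.shape[0] < MIN_OBSERVATIONS:
        raise ValidationError(
            f"{y.shape[0]} observations < minimum of {MIN_OBSERVATIONS}"
        )
    if float(np.var(y)) < _VAR_EPS:
        return np.zeros(x.shape[0])
    seed = cfg.seed if random_state is None else random_state
    forest = RandomForestRegressor(
        n_estimators=cfg.n_trees,
        max_features=cfg.max_features,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(x.T, y)
    if cfg.importance == "variance":
        return forest.feature_importances_
    rng = np.random.default_rng(seed)
    return _permutation_importance(forest, x.T, y, cfg.n_permutations, rng)


def _target_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2**31 - 1)) for c in ss.spawn(n)]


def infer_network(
    features,
    regulators,
    targets=None,
    cfg: InferenceConfig | None = None,
) -> EdgeScoreMatrix:
    """Score all regulator->target edges from a genes x observations matrix.

    Parameters
    ----------
    features : pandas.DataFrame or StepMatrix
        Rows = genes, columns = observations (samples or time steps).
    regulators : sequence of gene ids
        Candidate regulators; must all be present in ``features``.
    targets : sequence of gene ids, optional
        Genes to score (default: all genes in ``features``).  Regulators may
        appear as targets; their self-edge is excluded.
    """
    cfg = cfg or InferenceConfig()
    feature_type = "features"
    if isinstance(features, StepMatrix):
        feature_type = "step_matrix"
        features = features.values
    regulators = list(regulators)
    if not regulators:
        raise ValidationError("regulator set is empty")
    missing = [r for r in regulators if r not in features.index]
    if missing:
        raise ValidationError(f"regulators absent from feature matrix: {missing}")
    if targets is None:
        targets = list(features.index)
    else:
        targets = list(targets)
        missing = [t for t in targets if t not in features.index]
        if missing:
            raise ValidationError(f"targets absent from feature matrix: {missing}")

    mat = features.to_numpy(dtype=float)
    if cfg.standardize:
        mat = _standardize_rows(mat)
    # canonical observation order: columns carry no meaning to the model,
    # so sort them lexically to make scores permutation-invariant exactly
    mat = mat[:, np.lexsort(mat[::-1])]
    gene_pos = {g: i for i, g in enumerate(features.index)}
    reg_rows = mat[[gene_pos[r] for r in regulators]]
    seeds = _target_seeds(cfg.seed, len(targets))

    def one_target(t, seed):
        y = mat[gene_pos[t]]
        if t in regulators:
            keep = [i for i, r in enumerate(regulators) if r != t]
            if len(keep) < 2:
                return np.full(len(regulators), np.nan)
            imp = score_target(y, reg_rows[keep], cfg, random_state=seed)
            full = np.full(len(regulators), np.nan)
            full[keep] = imp
        else:
            full = score_target(y, reg_rows, cfg, random_state=seed)
        if cfg.normalize:
            pos = np.clip(np.nan_to_num(full, nan=0.0), 0.0, None)
            total = pos.sum()
            if total > 0:
                scaled = pos / total
                scaled[np.isnan(full)] = np.nan
                return scaled
            full = np.where(np.isnan(full), np.nan, 0.0)
        return full

    # threads: forest fitting releases the GIL, and per-target seeds make the
    # result independent of scheduling
    cols = Parallel(n_jobs=cfg.n_jobs, prefer="threads")(
        delayed(one_target)(t, s) for t, s in zip(targets, seeds)
    )
    scores = pd.DataFrame(
        np.column_stack(cols), index=pd.Index(regulators, name="regulator"),
        columns=pd.Index(targets, name="target"),
    )
    meta = {"feature_type": feature_type, "config": vars(cfg).copy()}
    return EdgeScoreMatrix(scores=scores, meta=meta)


def rank_edges(
    scores: EdgeScoreMatrix | pd.DataFrame,
    top_fraction: float | None = None,
    top_k: int | None = None,
) -> pd.DataFrame:
    """Flatten an edge-score matrix into a ranked edge list.

    Edges are sorted by descending score, ties broken deterministically by
    (regulator, target) lexical order; self-edges (NaN scores) are dropped.
    ``top_fraction`` keeps the top ``ceil(fraction * n_edges)`` edges.
    """
    df = scores.scores if isinstance(scores, EdgeScoreMatrix) else scores
    if df.size == 0:
        raise ValidationError("empty edge-score matrix")
    long = df.reset_index(names="regulator").melt(
        id_vars="regulator", var_name="target", value_name="score"
    )
    long = long.dropna(subset=["score"]).reset_index(drop=True)  # self-edges
    if not np.isfinite(long["score"]).all():
        raise ValidationError("non-finite edge scores")
    long = long.sort_values(
        ["score", "regulator", "target"], ascending=[False, True, True]
    ).reset_index(drop=True)
    if top_fraction is not None:
        if not (0 < top_fraction <= 1):
            raise ValueError("top_fraction must be in (0, 1]")
        top_k = math.ceil(top_fraction * len(long))
    if top_k is not None:
        long = long.head(top_k).reset_index(drop=True)
    return long
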