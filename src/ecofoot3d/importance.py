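"""Out-of-bag permutation importance for random-forest regressions.

Given a regression of a footprint indicator on the nine socioeconomic
indicators X1-X9, the importance of a variable nu is measured entirely on
out-of-bag (OOB) data:

1. for each tree t, the OOB mean squared error
   MSE_t = (1/N_t) * sum_{i in OOB_t} (y_i - yhat_{i,t})^2;
2. nu's values are permuted within the tree's OOB rows and the error is
   recomputed as MSE_t(nu);
3. VI(nu) = (1/n) * sum_t (MSE_t(nu) - MSE_t), the mean OOB error increase
   (negative values are truncated to zero before normalization);
4. R(nu) = VI(nu) / sum_nu VI(nu), the importance ratio.

The forest itself is built here — bootstrap sampling, in-bag/OOB index
bookkeeping, per-tree permutation streams — with CART regression trees
delegated to scikit-learn.  Ensemble OOB R^2 uses each observation's average
prediction over the trees for which it is out of bag.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeRegressor

from .data_io import (
    INDICATOR_CATEGORIES,
    INDICATOR_NAMES,
    AnalysisConfig,
    CityYearRecord,
)
from .errors import ValidationError
from .threedef import ThreeDEFResult

logger = logging.getLogger(__name__)


@dataclass
class ForestModel:
    """A fitted regression forest with explicit in-bag/OOB index sets."""

    trees: list[DecisionTreeRegressor]
    inbag: list[np.ndarray]
    oob: list[np.ndarray]
    feature_names: tuple[str, ...]
    seed: int

    @property
    def n_trees(self) -> int:
        return len(self.trees)


@dataclass
class ImportanceResult:
    """Importance ratios and OOB fit for one response on one time slice."""

    target_name: str
    slice_label: str
    vi: Mapping[str, float]
    ratio: Mapping[str, float]
    category_ratio: Mapping[str, float]
    oob_r2: float
    per_tree_oob_mse: np.ndarray = field(repr=False, default=None)

    def as_row(self) -> dict:
        row: dict[str, object] = {"response": self.target_name, "slice": self.slice_label}
        for name in self.ratio:
            row[name] = self.ratio[name]
        for cat in ("economic", "social", "environment"):
            row[f"cat_{cat}"] = self.category_ratio.get(cat, 0.0)
        row["oob_r2"] = self.oob_r2
        return row


def _as_matrix(X) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), tuple(map(str, X.columns))
    arr = np.asarray(X, dtype=float)
    return arr, tuple(f"X{i + 1}" for i in range(arr.shape[1]))


def fit_forest(X, y, config: AnalysisConfig | None = None) -> ForestModel:
    """Fit a bootstrap ensemble of CART regression trees.

    Each tree sees a size-n bootstrap sample; variables tried per split
    default to max(1, p // 3).  Fully reproducible from ``config.seed``.
    """
    config = config or AnalysisConfig()
    Xm, names = _as_matrix(X)
    yv = np.asarray(y, dtype=float)
    n, p = Xm.shape
    if n < 5:
        raise ValidationError(f"need at least 5 observations, got {n}")
    if np.isnan(Xm).any() or np.isnan(yv).any():
        raise ValidationError("missing values are not supported")
    mtry = config.mtry if config.mtry is not None else max(1, p // 3)
    # on tiny cross-sections (the 8-city single-year fits) a fixed leaf of 5
    # would forbid any split; cap the leaf at n // 4 so trees can grow
    min_leaf = min(config.min_leaf, max(1, n // 4))

    rng = np.random.default_rng(config.seed)
    trees, inbag, oob = [], [], []
    all_idx = np.arange(n)
    for t in range(config.n_trees):
        boot = rng.integers(0, n, size=n)
        mask = np.ones(n, dtype=bool)
        mask[boot] = False
        tree = DecisionTreeRegressor(
            max_features=mtry,
            min_samples_leaf=min_leaf,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(Xm[boot], yv[boot])
        trees.append(tree)
        inbag.append(boot)
        oob.append(all_idx[mask])
    n_empty = sum(1 for o in oob if o.size == 0)
    if n_empty:
        logger.warning("%d/%d trees have an empty OOB set and are excluded "
                       "from OOB statistics", n_empty, len(trees))
    return ForestModel(trees=trees, inbag=inbag, oob=oob, feature_names=names,
                       seed=config.seed)


def oob_mse(forest: ForestModel, X, y) -> np.ndarray:
    """Per-tree OOB mean squared error; empty-OOB trees yield NaN."""
    Xm, _ = _as_matrix(X)
    yv = np.asarray(y, dtype=float)
    out = np.full(forest.n_trees, np.nan)
    for t, (tree, idx) in enumerate(zip(forest.trees, forest.oob)):
        if idx.size == 0:
            continue
        pred = tree.predict(Xm[idx])
        out[t] = np.mean((yv[idx] - pred) ** 2)
    return out


def permuted_oob_mse(forest: ForestModel, X, y, variable: str, seed: int = 0) -> np.ndarray:
    """Per-tree OOB MSE after permuting ``variable`` within each tree's OOB rows.

    Each tree draws a fresh permutation from the seeded stream, so the
    statistic is an average over independent shuffles.
    """
    Xm, names = _as_matrix(X)
    if variable not in forest.feature_names:
        raise ValidationError(f"unknown variable {variable!r}")
    col = forest.feature_names.index(variable)
    yv = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    out = np.full(forest.n_trees, np.nan)
    for t, (tree, idx) in enumerate(zip(forest.trees, forest.oob)):
        if idx.size == 0:
            continue
        Xp = Xm[idx].copy()
        Xp[:, col] = Xp[rng.permutation(idx.size), col]
        pred = tree.predict(Xp)
        out[t] = np.mean((yv[idx] - pred) ** 2)
    return out


def variable_importance(forest: ForestModel, X, y, seed: int = 0) -> dict[str, float]:
    """Mean OOB error increase VI(nu) per variable.

    Per-variable permutation streams are derived from ``seed`` so each call
    is reproducible and variables are permuted independently.
    """
    base = oob_mse(forest, X, y)
    valid = ~np.isnan(base)
    if not valid.any():
        raise ValidationError("no tree has OOB data; increase n_trees or n")
    vi = {}
    for j, name in enumerate(forest.feature_names):
        sub_seed = int(np.random.SeedSequence(entropy=seed, spawn_key=(j,)).generate_state(1)[0]
                       % (2**31 - 1))
        permuted = permuted_oob_mse(forest, X, y, name, seed=sub_seed)
        vi[name] = float(np.mean(permuted[valid] - base[valid]))
    return vi


def importance_ratio(vi: Mapping[str, float], negative_vi: str = "truncate") -> dict[str, float]:
    """Normalize VI to ratios R(nu) summing to 1.

    Negative VI (a permutation that *improved* OOB error, pure noise) is
    truncated to zero by default; ``negative_vi='absolute'`` uses |VI|.
    """
    if negative_vi == "truncate":
        adj = {k: max(v, 0.0) for k, v in vi.items()}
    elif negative_vi == "absolute":
        adj = {k: abs(v) for k, v in vi.items()}
    else:
        raise ValidationError(f"unknown negative_vi policy {negative_vi!r}")
    total = sum(adj.values())
    if total <= 0:
        raise ValidationError("all variable importances are zero; ratios undefined")
    return {k: v / total for k, v in adj.items()}


def oob_r2(forest: ForestModel, X, y) -> float:
    """Ensemble OOB goodness of fit: 1 - OOB MSE / sample variance of y."""
    Xm, _ = _as_matrix(X)
    yv = np.asarray(y, dtype=float)
    if yv.var(ddof=1) == 0:
        raise ValidationError("OOB R^2 undefined for constant response")
    n = len(yv)
    pred_sum = np.zeros(n)
    pred_count = np.zeros(n)
    for tree, idx in zip(forest.trees, forest.oob):
        if idx.size == 0:
            continue
        pred_sum[idx] += tree.predict(Xm[idx])
        pred_count[idx] += 1
    covered = pred_count > 0
    if not covered.all():
        logger.warning("%d observation(s) never OOB; excluded from R^2",
                       int((~covered).sum()))
    resid = yv[covered] - pred_sum[covered] / pred_count[covered]
    return 1.0 - float(np.mean(resid**2)) / float(yv[covered].var(ddof=1))


def category_importance(
    ratio: Mapping[str, float],
    categories: Mapping[str, str] = INDICATOR_CATEGORIES,
) -> dict[str, float]:
    """Aggregate importance ratios into economic/social/environment sums."""
    missing = [v for v in ratio if v not in categories]
    if missing:
        raise ValidationError(f"variables without a category: {missing}")
    out: dict[str, float] = {}
    for var, r in ratio.items():
        out[categories[var]] = out.get(categories[var], 0.0) + r
    return out


def run_importance_analysis(
    records: Sequence[CityYearRecord],
    results: Sequence[ThreeDEFResult],
    config: AnalysisConfig | None = None,
) -> list[ImportanceResult]:
    """Fit ln(size) and ln(depth) forests per year and pooled, as one table.

    For every time slice (each panel year separately plus all years pooled)
    two regressions are fitted: response ln per-capita EF_size and
    ln EF_depth, predictors X1..X9.  Slices as small as the 8-city
    cross-section run, but their OOB statistics rest on very few
    observations per tree — a loud warning is emitted below n = 15.
    """
    config = config or AnalysisConfig()
    by_key = {(r.city, r.year): r for r in results}
    rows, y_size, y_depth, years = [], [], [], []
    for rec in records:
        res = by_key.get((rec.city, rec.year))
        if res is None:
            raise ValidationError(f"no 3D result for ({rec.city}, {rec.year})")
        size_pc = res.ef_size if res.per_capita else res.ef_size / rec.population
        if size_pc <= 0:
            raise ValidationError(
                f"({rec.city}, {rec.year}): EF_size = {size_pc} outside the log domain"
            )
        rows.append(rec.indicators)
        y_size.append(math.log(size_pc))
        y_depth.append(math.log(res.ef_depth))
        years.append(rec.year)

    X = pd.DataFrame(rows, columns=list(INDICATOR_NAMES))
    y_size = np.asarray(y_size)
    y_depth = np.asarray(y_depth)
    years = np.asarray(years)

    slices: list[tuple[str, np.ndarray]] = [
        (str(yr), years == yr) for yr in sorted(set(years.tolist()))
    ]
    slices.append(("pooled", np.ones(len(years), dtype=bool)))

    out = []
    for label, mask in slices:
        if mask.sum() < 15:
            logger.warning(
                "slice %r has only %d observations; OOB importance and R^2 "
                "are unstable at this sample size", label, int(mask.sum())
            )
        for target, yv in (("ln_ef_size", y_size), ("ln_ef_depth", y_depth)):
            forest = fit_forest(X[mask], yv[mask], config)
            vi = variable_importance(forest, X[mask], yv[mask], seed=config.seed)
            try:
                ratio = importance_ratio(vi, config.negative_vi)
            except ValidationError:
                # every permutation left OOB error unchanged or improved it —
                # the slice carries no usable signal; report undefined ratios
                logger.warning("slice %r, response %r: all importances zero; "
                               "ratios undefined", label, target)
                ratio = {name: float("nan") for name in forest.feature_names}
            out.append(
                ImportanceResult(
                    target_name=target,
                    slice_label=label,
                    vi=vi,
                    ratio=ratio,
                    category_ratio=category_importance(ratio),
                    oob_r2=oob_r2(forest, X[mask], yv[mask]),
                    per_tree_oob_mse=oob_mse(forest, X[mask], yv[mask]),
                )
            )
    return out
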