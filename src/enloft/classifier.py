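"""Balanced-resampling random-forest training and genome-wide scoring.

Protocol: the positive (LoF-tolerant) pool is much larger than the 49-ish
negative set, so each repeat draws a balanced batch of positives (default
50), pairs it with all negatives, runs a hyperparameter search (random
search followed by a local grid refinement) scored by stratified k-fold
mean AUROC, and records its fold metrics. Batches are consumed from
reshuffled permutations of the positive pool so every positive is seen at
least once whenever repeats x batch-size covers the pool. The final model
is the refit of the repeat with the highest mean AUROC (ties: higher mean
AUPRC, then lower repeat index). Scores are the mean predicted class-1
probabilities of the trees in the forest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .curation import LabelSet
from .features import FeatureMatrix

log = logging.getLogger(__name__)

P_BINARY = 0.5
P_CONFIDENT_HIGH = 0.95
P_CONFIDENT_LOW = 0.05

SEARCH_SPACE: dict[str, list] = {
    "n_estimators": [100, 200, 300, 500],
    "max_depth": [None, 4, 6, 10],
    "max_features": ["sqrt", 0.3, 0.5],
    "min_samples_leaf": [1, 2, 4],
}


@dataclass(frozen=True)
class SearchBudget:
    n_random: int = 8
    n_refine: int = 6


@dataclass
class TrainingRun:
    repeat_index: int
    sampled_positive_ids: tuple[str, ...]
    negative_ids: tuple[str, ...]
    hyperparameters: dict
    fold_aurocs: list[float]
    fold_auprcs: list[float]
    mean_auroc: float
    mean_auprc: float
    seed: int

    @property
    def sd_auroc(self) -> float:
        return float(np.std(self.fold_aurocs))


@dataclass
class SelectedModel:
    ensemble: RandomForestClassifier
    winning_repeat: TrainingRun
    feature_schema: tuple[str, ...]
    with_conservation: bool


@dataclass(frozen=True)
class ScoreRecord:
    enhancer_id: str
    p_lof_tol: float
    binary_call: str
    confident_call: str | None


@dataclass
class TrainingResult:
    runs: list[TrainingRun]
    selected: SelectedModel

    @property
    def mean_of_means(self) -> float:
        return float(np.mean([r.mean_auroc for r in self.runs]))

    @property
    def sd_of_means(self) -> float:
        return float(np.std([r.mean_auroc for r in self.runs]))


def classify_probability(
    p: float,
    p_binary: float = P_BINARY,
    p_high: float = P_CONFIDENT_HIGH,
    p_low: float = P_CONFIDENT_LOW,
) -> tuple[str, str | None]:
    """Binary and confident calls for one LoF-tolerance probability.

    p >= 0.5 is called tolerant; p > 0.95 / p < 0.05 are the confident
    tolerant / low-tolerance calls.
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"probability outside [0,1]: {p}")
    binary = "tolerant" if p >= p_binary else "low-tolerance"
    confident = None
    if p > p_high:
        confident = "tolerant"
    elif p < p_low:
        confident = "low-tolerance"
    return binary, confident


def _draw_positive_batches(
    positives: Sequence[str], repeats: int, k: int, rng: np.random.Generator
) -> list[tuple[str, ...]]:
    """Batches of k positives per repeat, cycling reshuffled permutations.

    Guarantees every positive appears in >=1 batch whenever repeats*k covers
    the pool, and no duplicate ids within a batch.
    """
    if len(positives) < k:
        raise ValueError(f"need >= {k} positives, have {len(positives)}")
    deck: list[str] = []
    batches = []
    for _ in range(repeats):
        if len(deck) < k:
            batch = list(deck)
            fresh = [p for p in rng.permutation(list(positives)) if p not in set(batch)]
            need = k - len(batch)
            batch += fresh[:need]
            deck = fresh[need:]
        else:
            batch, deck = deck[:k], deck[k:]
        batches.append(tuple(batch))
    return batches


def _candidate_configs(rng: np.random.Generator, budget: SearchBudget) -> list[dict]:
    keys = sorted(SEARCH_SPACE)
    seen: set[tuple] = set()
    configs: list[dict] = []
    while len(configs) < budget.n_random:
        cfg = {k: SEARCH_SPACE[k][rng.integers(len(SEARCH_SPACE[k]))] for k in keys}
        sig = tuple(cfg[k] for k in keys)
        if sig not in seen:
            seen.add(sig)
            configs.append(cfg)
        if len(seen) >= np.prod([len(SEARCH_SPACE[k]) for k in keys]):
            break
    return configs


def _refine_configs(best: dict, n_refine: int) -> list[dict]:
    """Local grid around the random-search winner: step each axis +/-1."""
    out = []
    keys = sorted(SEARCH_SPACE)
    for k in keys:
        grid = SEARCH_SPACE[k]
        i = grid.index(best[k])
        for j in (i - 1, i + 1):
            if 0 <= j < len(grid):
                cfg = dict(best)
                cfg[k] = grid[j]
                out.append(cfg)
    return out[:n_refine]


def _cv_scores(
    X: np.ndarray,
    y: np.ndarray,
    cfg: dict,
    folds: int,
    fold_seed: int,
    clf_seed: int,
) -> tuple[list[float], list[float]]:
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=fold_seed)
    aurocs, auprcs = [], []
    for train_idx, test_idx in skf.split(X, y):
        if len(np.unique(y[test_idx])) < 2:  # degenerate fold; should not occur
            continue
        clf = RandomForestClassifier(**cfg, random_state=clf_seed, n_jobs=1)
        clf.fit(X[train_idx], y[train_idx])
        p = clf.predict_proba(X[test_idx])[:, 1]
        aurocs.append(roc_auc_score(y[test_idx], p))
        auprcs.append(average_precision_score(y[test_idx], p))
    return aurocs, auprcs


def _matrix_columns(matrix: FeatureMatrix, with_conservation: bool) -> list[str]:
    cols = list(matrix.data.columns)
    if not with_conservation:
        cols = [c for c in cols if c != "conservation"]
    return cols


def _search_one_repeat(
    X: np.ndarray,
    y: np.ndarray,
    folds: int,
    budget: SearchBudget,
    rng: np.random.Generator,
    repeat_seed: int,
) -> tuple[dict, list[float], list[float]]:
    fold_seed = int(repeat_seed % (2**31 - 1))
    clf_seed = int((repeat_seed + 1) % (2**31 - 1))
    candidates = _candidate_configs(rng, budget)
    scored = []
    for cfg in candidates:
        aurocs, _ = _cv_scores(X, y, cfg, folds, fold_seed, clf_seed)
        scored.append((float(np.mean(aurocs)), cfg))
    best_score, best_cfg = max(scored, key=lambda t: t[0])
    for cfg in _refine_configs(best_cfg, budget.n_refine):
        aurocs, _ = _cv_scores(X, y, cfg, folds, fold_seed, clf_seed)
        score = float(np.mean(aurocs))
        if score > best_score:
            best_score, best_cfg = score, cfg
    aurocs, auprcs = _cv_scores(X, y, best_cfg, folds, fold_seed, clf_seed)
    return best_cfg, aurocs, auprcs


def balanced_repeat_train(
    matrix: FeatureMatrix,
    labels: LabelSet,
    repeats: int = 50,
    pos_per_repeat: int = 50,
    folds: int = 10,
    search_budget: SearchBudget | None = None,
    seed: int = 0,
    with_conservation: bool = True,
) -> TrainingResult:
    """Run the balanced-resampling training protocol and select the model."""
    budget = search_budget or SearchBudget()
    positives = sorted(labels.lof_tolerant)
    negatives = sorted(labels.low_tolerance)
    missing = (set(positives) | set(negatives)) - set(matrix.data.index)
    if missing:
        raise ValueError(f"labeled ids missing from matrix: {sorted(missing)[:5]}")
    cols = _matrix_columns(matrix, with_conservation)
    rng = np.random.default_rng(seed)
    batches = _draw_positive_batches(positives, repeats, pos_per_repeat, rng)
    repeat_seeds = rng.integers(0, 2**31 - 1, size=repeats)

    runs: list[TrainingRun] = []
    for r, batch in enumerate(batches, start=1):
        ids = list(batch) + negatives
        X = matrix.data.loc[ids, cols].to_numpy(dtype=float)
        y = np.array([1] * len(batch) + [0] * len(negatives))
        rseed = int(repeat_seeds[r - 1])
        cfg, aurocs, auprcs = _search_one_repeat(
            X, y, folds, budget, np.random.default_rng(rseed), rseed
        )
        runs.append(
            TrainingRun(
                repeat_index=r,
                sampled_positive_ids=batch,
                negative_ids=tuple(negatives),
                hyperparameters=cfg,
                fold_aurocs=aurocs,
                fold_auprcs=auprcs,
                mean_auroc=float(np.mean(aurocs)),
                mean_auprc=float(np.mean(auprcs)),
                seed=rseed,
            )
        )

    winner = max(runs, key=lambda r: (r.mean_auroc, r.mean_auprc, -r.repeat_index))
    ids = list(winner.sampled_positive_ids) + negatives
    X = matrix.data.loc[ids, cols].to_numpy(dtype=float)
    y = np.array([1] * len(winner.sampled_positive_ids) + [0] * len(negatives))
    ensemble = RandomForestClassifier(
        **winner.hyperparameters, random_state=winner.seed, n_jobs=1
    )
    ensemble.fit(X, y)
    selected = SelectedModel(
        ensemble=ensemble,
        winning_repeat=winner,
        feature_schema=tuple(cols),
        with_conservation=with_conservation,
    )
    log.info(
        "selected repeat %d: mean AUROC %.4f +/- %.4f (across-repeat mean %.4f +/- %.4f)",
        winner.repeat_index, winner.mean_auroc, winner.sd_auroc,
        float(np.mean([r.mean_auroc for r in runs])),
        float(np.std([r.mean_auroc for r in runs])),
    )
    return TrainingResult(runs=runs, selected=selected)


@dataclass
class NullModelResult:
    mean_aurocs: list[float]

    @property
    def mean(self) -> float:
        return float(np.mean(self.mean_aurocs))

    @property
    def sd(self) -> float:
        return float(np.std(self.mean_aurocs))


def null_model_check(
    matrix: FeatureMatrix,
    labels: LabelSet,
    repeats: int = 50,
    pos_per_repeat: int = 50,
    n_pseudo: int = 50,
    folds: int = 10,
    search_budget: SearchBudget | None = None,
    seed: int = 0,
    with_conservation: bool = True,
) -> NullModelResult:
    """Overfitting check with pseudo-negatives drawn from the unlabeled pool.

    Each repeat keeps real sampled positives but replaces the negative set
    with random unlabeled enhancers; a mean-of-means near 0.5 certifies
    that the small negative set does not cause small-sample overfitting.
    """
    budget = search_budget or SearchBudget()
    positives = sorted(labels.lof_tolerant)
    unlabeled = sorted(
        set(matrix.data.index) - labels.lof_tolerant - labels.low_tolerance
    )
    if len(unlabeled) < n_pseudo:
        raise ValueError(f"need >= {n_pseudo} unlabeled enhancers, have {len(unlabeled)}")
    cols = _matrix_columns(matrix, with_conservation)
    rng = np.random.default_rng(seed)
    batches = _draw_positive_batches(positives, repeats, pos_per_repeat, rng)
    repeat_seeds = rng.integers(0, 2**31 - 1, size=repeats)
    mean_aurocs = []
    for r, batch in enumerate(batches):
        pseudo = list(rng.choice(unlabeled, size=n_pseudo, replace=False))
        ids = list(batch) + pseudo
        X = matrix.data.loc[ids, cols].to_numpy(dtype=float)
        y = np.array([1] * len(batch) + [0] * len(pseudo))
        rseed = int(repeat_seeds[r])
        _, aurocs, _ = _search_one_repeat(
            X, y, folds, budget, np.random.default_rng(rseed), rseed
        )
        mean_aurocs.append(float(np.mean(aurocs)))
    return NullModelResult(mean_aurocs=mean_aurocs)


def predict_scores(
    model: SelectedModel,
    matrix: FeatureMatrix,
    exclude_ids: Iterable[str] = (),
) -> list[ScoreRecord]:
    """Score every non-excluded enhancer with the trained forest."""
    schema = list(model.feature_schema)
    have = set(matrix.data.columns)
    missing = [c for c in schema if c not in have]
    extra = sorted(have - set(schema) - {"conservation"})
    if missing:
        raise ValueError(f"matrix missing model columns: {missing}; extra: {extra}")
    excluded = set(exclude_ids)
    ids = [i for i in matrix.data.index if i not in excluded]
    X = matrix.data.loc[ids, schema].to_numpy(dtype=float)
    probs = model.ensemble.predict_proba(X)[:, 1]
    records = []
    for eid, p in zip(ids, probs):
        binary, confident = classify_probability(float(p))
        records.append(ScoreRecord(eid, float(p), binary, confident))
    return records


FEATURE_GROUPS = ("gene", "conservation", "enhancer", "edge")


def feature_group(name: str) -> str:
    """Map a feature name to its collective-importance group.

    Gene features: GIS/GID/GCC/GDC/GPRC/GEC aggregates plus per-tissue GIDa
    blocks. Enhancer features: ETU and EOD (global and per-tissue). Edge
    features: EGTUa/EGTUv. Conservation stands alone.
    """
    base = name.split("__", 1)[1] if "__" in name else name
    if base == "conservation":
        return "conservation"
    if base.startswith(("GIS", "GID", "GCC", "GDC", "GPRC", "GEC")):
        return "gene"
    if base.startswith("EGTU"):
        return "edge"
    if base in ("EOD", "ETU"):
        return "enhancer"
    raise ValueError(f"feature {name!r} does not belong to a known group")


@dataclass
class ImportanceReport:
    per_feature: pd.Series
    group_sums: dict[str, float]


def feature_importance_report(model: SelectedModel) -> ImportanceReport:
    """Mean-decrease-impurity importances, normalized, with group sums."""
    imp = np.asarray(model.ensemble.feature_importances_, dtype=float)
    total = imp.sum()
    if total > 0:
        imp = imp / total
    series = pd.Series(imp, index=list(model.feature_schema)).sort_values(
        ascending=False
    )
    sums = {g: 0.0 for g in FEATURE_GROUPS}
    for name, value in series.items():
        sums[feature_group(name)] += float(value)
    return ImportanceReport(per_feature=series, group_sums=sums)
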