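"""Per-cell nodal risk score (NRS).

The NRS is a random-forest score in [0, 1] assigned to every epithelial
cancer cell: the fraction of trees voting that the cell comes from a
node-positive (LN+) tumor.  Class imbalance (LN+ tumors contribute far more
cells) is handled by balanced bootstrapping — each tree is grown on a
bootstrap that draws the same number of cells from each class, equal to the
smallest class size.  Tree count and the number of features tried per split
(mtry) are tuned by stratified 5-fold cross-validated AUC; out-of-bag error
is recorded for the refit model.

Cells from poorly differentiated (G3) tumors are excluded upstream: the model
is built on well/moderately differentiated (G1/G2) tumors only, with G3
handled by a separate cutoff pathway at the patient level.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

POSITIVE_CLASS = "LN+"
CELL_CUTOFF = 0.5


@dataclass
class RFConfig:
    """Tuning grids and sampling policy for the NRS forest."""

    n_trees_grid: tuple[int, ...] = (100, 250, 500)
    mtry_grid: tuple[str, ...] = ("sqrt", "third", "fifth")
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.n_trees_grid or not self.mtry_grid:
            raise ValueError("tuning grids must be nonempty")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")

    @staticmethod
    def resolve_mtry(rule: str | int, p: int) -> int:
        if isinstance(rule, int):
            return max(1, min(rule, p))
        return max(1, {"sqrt": int(math.sqrt(p)), "third": p // 3, "fifth": p // 5}[rule])


class BalancedVoteForest:
    """Random forest with smallest-class balanced bootstraps and hard-vote
    scores.

    Each of ``n_trees`` trees is fitted on a bootstrap drawing, with
    replacement, ``n_min`` cells from *each* class, where ``n_min`` is the
    smallest class size.  The score of a sample is the fraction of trees
    voting the positive class, so score × n_trees is always an integer.
    """

    def __init__(
        self,
        n_trees: int = 100,
        mtry: int | None = None,
        seed: int = 0,
        positive: str = POSITIVE_CLASS,
    ):
        self.n_trees = n_trees
        self.mtry = mtry
        self.seed = seed
        self.positive = positive
        self.trees_: list[DecisionTreeClassifier] = []
        self.bootstrap_indices_: list[np.ndarray] = []
        self.classes_: np.ndarray | None = None
        self.oob_error_: float | None = None

    def fit(self, x: np.ndarray, y: np.ndarray, compute_oob: bool = True) -> "BalancedVoteForest":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y)
        if not np.isfinite(x).all():
            bad = np.where(~np.isfinite(x).all(axis=0))[0]
            raise ValueError(f"non-finite features in columns {bad.tolist()}")
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("need both classes present to train")
        if self.positive not in self.classes_:
            self.positive = self.classes_[-1]
        idx_by_class = [np.where(y == c)[0] for c in self.classes_]
        n_min = min(len(i) for i in idx_by_class)
        rng = np.random.default_rng(self.seed)
        mtry = self.mtry or max(1, int(math.sqrt(x.shape[1])))

        self.trees_ = []
        self.bootstrap_indices_ = []
        vote_pos = np.zeros(len(y))
        vote_n = np.zeros(len(y))
        pos = self.positive
        neg = self.classes_[self.classes_ != pos][0]
        for t in range(self.n_trees):
            boot = np.concatenate([rng.choice(idx, size=n_min, replace=True) for idx in idx_by_class])
            tree = DecisionTreeClassifier(
                max_features=mtry, random_state=int(rng.integers(2**31 - 1))
            )
            tree.fit(x[boot], y[boot])
            self.trees_.append(tree)
            self.bootstrap_indices_.append(boot)
            if compute_oob:
                oob = np.ones(len(y), bool)
                oob[boot] = False
                if oob.any():
                    pred = tree.predict(x[oob])
                    vote_pos[oob] += pred == pos
                    vote_n[oob] += 1
        if compute_oob:
            seen = vote_n > 0
            oob_pred = np.where(vote_pos[seen] / vote_n[seen] >= 0.5, pos, neg)
            self.oob_error_ = float((oob_pred != y[seen]).mean()) if seen.any() else float("nan")
        return self

    def score_samples(self, x: np.ndarray) -> np.ndarray:
        """Vote fraction for the positive class, in [0, 1]."""
        if not self.trees_:
            raise ValueError("forest not fitted")
        x = np.asarray(x, dtype=float)
        pos = self.positive
        votes = np.zeros(len(x))
        for tree in self.trees_:
            votes += tree.predict(x) == pos
        return votes / self.n_trees

    def bootstrap_class_counts(self, y: np.ndarray) -> list[dict]:
        """Per-tree class composition of the bootstraps (policy audit)."""
        out = []
        for boot in self.bootstrap_indices_:
            vals, counts = np.unique(np.asarray(y)[boot], return_counts=True)
            out.append(dict(zip(vals.tolist(), counts.tolist())))
        return out


# ---------------------------------------------------------------------------
# splitting


@dataclass
class CellSplit:
    """Train/test assignment of cells; ``train`` is a boolean mask."""

    train: pd.Series
    seed: int
    mode: str  # "cell" | "grouped"
    fraction: float


def split_cells(
    cells: pd.DataFrame, fraction: float = 0.8, seed: int = 0, mode: str = "cell"
) -> CellSplit:
    """Random train/test split of cells.

    ``mode="cell"`` splits at the cell level (train size = floor(fraction·n)),
    sharing patients across partitions — the design used to build the original
    model.  ``mode="grouped"`` assigns whole patients to one partition
    (floor(fraction·n_patients) patients to train), which is the
    leakage-free evaluation."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    if mode == "cell":
        n = len(cells)
        n_train = int(math.floor(fraction * n))
        perm = rng.permutation(n)
        mask = np.zeros(n, bool)
        mask[perm[:n_train]] = True
    elif mode == "grouped":
        patients = cells["patient_id"].unique()
        perm = rng.permutation(len(patients))
        n_train = int(math.floor(fraction * len(patients)))
        train_patients = set(patients[perm[:n_train]])
        mask = cells["patient_id"].isin(train_patients).to_numpy()
    else:
        raise ValueError(f"unknown split mode {mode!r}")
    return CellSplit(
        train=pd.Series(mask, index=cells.index, name="train"),
        seed=seed, mode=mode, fraction=fraction,
    )


# ---------------------------------------------------------------------------
# tuning / training / scoring


@dataclass
class NRSModel:
    forest: BalancedVoteForest
    feature_names: list[str]
    registry_hash: str
    n_trees: int
    mtry: int
    oob_error: float
    cv_results: pd.DataFrame
    seed: int

    def metadata(self) -> dict:
        return {
            "feature_names": self.feature_names,
            "registry_hash": self.registry_hash,
            "n_trees": self.n_trees,
            "mtry": self.mtry,
            "oob_error": self.oob_error,
            "seed": self.seed,
        }


def tune_and_train(
    cells: pd.DataFrame,
    feature_names: list[str],
    config: RFConfig | None = None,
    label_col: str = "ln_status",
    registry_hash: str = "",
) -> NRSModel:
    """Grid-search (n_trees, mtry) by stratified 5-fold CV AUC, then refit on
    all training cells with OOB error recorded."""
    config = config or RFConfig()
    x = cells[feature_names].to_numpy(dtype=float)
    y = cells[label_col].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("both LN classes must be present in training cells")
    if not np.isfinite(x).all():
        bad = [feature_names[i] for i in np.where(~np.isfinite(x).all(axis=0))[0]]
        raise ValueError(f"non-finite features: {bad}")

    p = x.shape[1]
    grid = [(nt, RFConfig.resolve_mtry(mt, p)) for nt in config.n_trees_grid for mt in config.mtry_grid]
    grid = sorted(set(grid))
    records = []
    if len(grid) == 1:  # nothing to tune; skip the CV pass
        nt, mtry = grid[0]
        forest = BalancedVoteForest(n_trees=nt, mtry=mtry, seed=config.seed)
        forest.fit(x, y)
        return NRSModel(
            forest=forest, feature_names=list(feature_names), registry_hash=registry_hash,
            n_trees=nt, mtry=mtry, oob_error=forest.oob_error_,
            cv_results=pd.DataFrame([{"n_trees": nt, "mtry": mtry, "cv_auc": float("nan")}]),
            seed=config.seed,
        )
    skf = StratifiedKFold(n_splits=config.cv_folds, shuffle=True, random_state=config.seed)
    folds = list(skf.split(x, y))
    for nt, mtry in grid:
        aucs = []
        for k, (tr, te) in enumerate(folds):
            f = BalancedVoteForest(n_trees=nt, mtry=mtry, seed=config.seed + 1000 * k)
            f.fit(x[tr], y[tr], compute_oob=False)
            s = f.score_samples(x[te])
            aucs.append(roc_auc_score(y[te] == POSITIVE_CLASS, s))
        records.append({"n_trees": nt, "mtry": mtry, "cv_auc": float(np.mean(aucs))})
    cv = pd.DataFrame(records)
    best = cv.sort_values(["cv_auc", "n_trees"], ascending=[False, True]).iloc[0]

    forest = BalancedVoteForest(n_trees=int(best.n_trees), mtry=int(best.mtry), seed=config.seed)
    forest.fit(x, y)
    return NRSModel(
        forest=forest,
        feature_names=list(feature_names),
        registry_hash=registry_hash,
        n_trees=int(best.n_trees),
        mtry=int(best.mtry),
        oob_error=forest.oob_error_,
        cv_results=cv,
        seed=config.seed,
    )


def score_cells(model: NRSModel, cells: pd.DataFrame, registry_hash: str | None = None) -> pd.DataFrame:
    """NRS per cell (vote fraction for LN+), with the ≥0.5 positive flag."""
    if registry_hash is not None and model.registry_hash and registry_hash != model.registry_hash:
        raise ValueError(
            f"feature registry mismatch: model trained on {model.registry_hash}, got {registry_hash}"
        )
    missing = [f for f in model.feature_names if f not in cells.columns]
    if missing:
        raise ValueError(f"cells lack model features: {missing}")
    scores = model.forest.score_samples(cells[model.feature_names].to_numpy(dtype=float))
    out = cells[[c for c in ("cell_id", "object_id", "patient_id", "roi_id") if c in cells.columns]].copy()
    out["nrs"] = scores
    out["positive"] = scores >= CELL_CUTOFF
    return out


def export_forest(forest: BalancedVoteForest) -> dict:
    """Implementation-neutral forest export: every tree's structure (children,
    split feature/threshold, leaf vote) so scores are re-derivable without
    unpickling."""
    trees = []
    for tree in forest.trees_:
        t = tree.tree_
        leaf_class = [
            str(tree.classes_[int(np.argmax(t.value[i]))]) for i in range(t.node_count)
        ]
        trees.append({
            "children_left": t.children_left.tolist(),
            "children_right": t.children_right.tolist(),
            "feature": t.feature.tolist(),
            "threshold": t.threshold.tolist(),
            "leaf_class": leaf_class,
        })
    return {"n_trees": forest.n_trees, "positive": forest.positive, "trees": trees}


def score_from_export(export: dict, x: np.ndarray) -> np.ndarray:
    """Re-derive NRS vote fractions from an exported forest."""
    x = np.asarray(x, dtype=float)
    votes = np.zeros(len(x))
    for tree in export["trees"]:
        left, right = tree["children_left"], tree["children_right"]
        feat, thr, leaf = tree["feature"], tree["threshold"], tree["leaf_class"]
        for i, row in enumerate(x):
            node = 0
            while left[node] != -1:
                node = left[node] if row[feat[node]] <= thr[node] else right[node]
            votes[i] += leaf[node] == export["positive"]
    return votes / export["n_trees"]


def save_model(model: NRSModel, path: str | Path, export_trees: bool = False) -> None:
    import joblib

    path = Path(path)
    joblib.dump(model.forest, path.with_suffix(".joblib"))
    meta = model.metadata()
    if export_trees:
        meta["forest"] = export_forest(model.forest)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
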