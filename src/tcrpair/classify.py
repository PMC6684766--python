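"""Gradient-boosted lineage classification from TCR feature vectors.

Each unique clonotype is encoded as a fixed-length vector per chain:
one-hot V gene, one-hot J gene, CDR3 length, CDR3 net charge, and the 20
amino-acid usage frequencies of the CDR3.  Four classifier modes are
compared under repeated stratified cross-validation:

- ``alpha`` / ``beta``: a single-chain model,
- ``paired``: one model on the concatenated αβ vector,
- ``additive``: separate α and β models whose predicted CD4 probabilities
  are averaged (soft voting) — the expectation if the chains contribute
  independently.

The paired model can only beat the additive ensemble if αβ pairing itself
carries information (synergy), which is what the mode comparison tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import RepeatedStratifiedKFold
from xgboost import XGBClassifier

from .core import AA_ALPHABET, Lineage, Repertoire, Scope, cdr3_charge

Mode = Literal["alpha", "beta", "additive", "paired"]


@dataclass
class ModelConfig:
    """Boosting hyperparameters, fixed for reproducibility."""

    max_depth: int = 6
    n_estimators: int = 200
    learning_rate: float = 0.3
    n_jobs: int = 1
    tree_method: str = "hist"

    def make(self, seed: int) -> XGBClassifier:
        return XGBClassifier(
            max_depth=self.max_depth,
            n_estimators=self.n_estimators,
            learning_rate=self.learning_rate,
            n_jobs=self.n_jobs,
            tree_method=self.tree_method,
            random_state=seed,
            eval_metric="logloss",
            verbosity=0,
        )


@dataclass
class GeneUniverse:
    """Fixed gene vocabularies defining the one-hot layout."""

    v_alpha: tuple[str, ...]
    j_alpha: tuple[str, ...]
    v_beta: tuple[str, ...]
    j_beta: tuple[str, ...]

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "GeneUniverse":
        return cls(
            v_alpha=tuple(sorted(table["v_a"].unique())),
            j_alpha=tuple(sorted(table["j_a"].unique())),
            v_beta=tuple(sorted(table["v_b"].unique())),
            j_beta=tuple(sorted(table["j_b"].unique())),
        )


def _chain_block(v, j, cdr3, v_universe, j_universe) -> np.ndarray:
    """Encode one chain: one-hot V, one-hot J, length, charge, 20 AA
    frequencies.  Deterministic for a fixed universe."""
    v_idx = {g: i for i, g in enumerate(v_universe)}
    j_idx = {g: i for i, g in enumerate(j_universe)}
    n = len(cdr3)
    x = np.zeros((n, len(v_universe) + len(j_universe) + 2 + 20))
    for row, (vg, jg, s) in enumerate(zip(v, j, cdr3)):
        if vg not in v_idx:
            raise KeyError(f"V gene {vg!r} absent from configured universe")
        if jg not in j_idx:
            raise KeyError(f"J gene {jg!r} absent from configured universe")
        x[row, v_idx[vg]] = 1.0
        x[row, len(v_universe) + j_idx[jg]] = 1.0
        base = len(v_universe) + len(j_universe)
        x[row, base] = len(s)
        x[row, base + 1] = cdr3_charge(s)
        for aa in s:
            x[row, base + 2 + AA_ALPHABET.index(aa)] += 1.0
        x[row, base + 2:base + 22] /= len(s)
    return x


def encode(table: pd.DataFrame, mode: Mode, universe: GeneUniverse) -> np.ndarray:
    """Encode a paired clonotype table into the feature matrix for a mode.

    ``alpha``/``beta`` use one chain's block; ``paired`` concatenates both.
    ``additive`` is handled at training time from the two chain blocks.
    """
    blocks = {}
    if mode in ("alpha", "additive", "paired"):
        blocks["alpha"] = _chain_block(table["v_a"], table["j_a"],
                                       table["cdr3_a"], universe.v_alpha,
                                       universe.j_alpha)
    if mode in ("beta", "additive", "paired"):
        blocks["beta"] = _chain_block(table["v_b"], table["j_b"],
                                      table["cdr3_b"], universe.v_beta,
                                      universe.j_beta)
    if mode == "alpha":
        return blocks["alpha"]
    if mode == "beta":
        return blocks["beta"]
    return np.hstack([blocks["alpha"], blocks["beta"]])


@dataclass
class Dataset:
    """Unique labeled clonotypes with lineage-ambiguous ones removed."""

    table: pd.DataFrame  # columns v_a, j_a, cdr3_a, v_b, j_b, cdr3_b
    y: np.ndarray  # 1 = CD4, 0 = CD8
    universe: GeneUniverse


def prepare_dataset(cd4: Repertoire, cd8: Repertoire,
                    universe: GeneUniverse | None = None) -> Dataset:
    """Build the training table: unique paired clonotypes only, with any
    clonotype present in both lineages removed."""
    if cd4.scope != Scope.PAIRED or cd8.scope != Scope.PAIRED:
        raise ValueError("paired-scope repertoires required")
    shared = cd4.members & cd8.members
    cols = ["v_a", "j_a", "cdr3_a", "v_b", "j_b", "cdr3_b"]
    t4 = cd4.table.loc[~cd4.table.index.isin(shared), cols]
    t8 = cd8.table.loc[~cd8.table.index.isin(shared), cols]
    if len(t4) == 0 or len(t8) == 0:
        raise ValueError("a lineage is empty after removing shared clonotypes")
    table = pd.concat([t4, t8], ignore_index=True)
    y = np.concatenate([np.ones(len(t4), dtype=int), np.zeros(len(t8), dtype=int)])
    return Dataset(table=table, y=y,
                   universe=universe or GeneUniverse.from_table(table))


@dataclass
class CVResult:
    mode: Mode
    fold_auc: np.ndarray
    fold_accuracy: np.ndarray
    roc_points: pd.DataFrame  # pooled out-of-fold fpr/tpr of the first repeat
    n_splits: int
    n_repeats: int
    seed: int

    @property
    def mean_auc(self) -> float:
        return float(self.fold_auc.mean())

    @property
    def sd_auc(self) -> float:
        return float(self.fold_auc.std(ddof=1))


def cross_validate(
    dataset: Dataset,
    mode: Mode,
    model_config: ModelConfig | None = None,
    seed: int = 0,
    n_splits: int = 5,
    n_repeats: int = 10,
) -> CVResult:
    """Stratified k-fold CV repeated with distinct seeded shuffles.

    AUC and ROC are computed from the predicted CD4 probability; accuracy
    uses the 50% threshold.  ``additive`` trains separate α and β models
    per fold and averages their predicted probabilities (soft voting).
    Fold assignments, and hence results, are reproducible from the seed.
    """
    cfg = model_config or ModelConfig()
    y = dataset.y
    if len(y) < 100:
        raise ValueError("need at least 100 clonotypes")
    if len(np.unique(y)) < 2:
        raise ValueError("both lineages required")
    if mode == "additive":
        xs = {"alpha": encode(dataset.table, "alpha", dataset.universe),
              "beta": encode(dataset.table, "beta", dataset.universe)}
    else:
        xs = {mode: encode(dataset.table, mode, dataset.universe)}

    cv = RepeatedStratifiedKFold(n_splits=n_splits, n_repeats=n_repeats,
                                 random_state=seed)
    aucs, accs = [], []
    first_repeat_prob = np.full(len(y), np.nan)
    for fold_i, (tr, te) in enumerate(cv.split(next(iter(xs.values())), y)):
        probs = []
        for x in xs.values():
            model = cfg.make(seed + fold_i)
            model.fit(x[tr], y[tr])
            probs.append(model.predict_proba(x[te])[:, 1])
        p_cd4 = np.mean(probs, axis=0)
        aucs.append(roc_auc_score(y[te], p_cd4))
        accs.append(float(np.mean((p_cd4 > 0.5).astype(int) == y[te])))
        if fold_i < n_splits:
            first_repeat_prob[te] = p_cd4
    fpr, tpr, _ = roc_curve(y, first_repeat_prob)
    return CVResult(
        mode=mode,
        fold_auc=np.asarray(aucs),
        fold_accuracy=np.asarray(accs),
        roc_points=pd.DataFrame({"fpr": fpr, "tpr": tpr}),
        n_splits=n_splits, n_repeats=n_repeats, seed=seed)


def compare_modes(results: Sequence[CVResult]) -> pd.DataFrame:
    """Pairwise two-sided rank-sum tests on fold-level AUCs, plus summary
    means ± SD.  All results must come from the same CV layout."""
    n_folds = {len(r.fold_auc) for r in results}
    if len(n_folds) != 1:
        raise ValueError("fold counts differ between modes")
    rows = []
    for i, r1 in enumerate(results):
        for r2 in results[i + 1:]:
            if np.allclose(r1.fold_auc, r2.fold_auc):
                p = 1.0
            else:
                p = float(stats.mannwhitneyu(r1.fold_auc, r2.fold_auc,
                                             alternative="two-sided").pvalue)
            rows.append({
                "mode_1": r1.mode, "mode_2": r2.mode,
                "auc_1": r1.mean_auc, "sd_1": r1.sd_auc,
                "auc_2": r2.mean_auc, "sd_2": r2.sd_auc,
                "delta": r1.mean_auc - r2.mean_auc,
                "p_value": p,
            })
    return pd.DataFrame(rows)
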