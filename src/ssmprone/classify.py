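"""Classification of SSM-prone genes from genomic features.

Two learners distinguish genes with an excess of splice-site mutations
(envelope category Upper) from genes with the expected number: a random
forest (500 trees, sqrt(p) features per split, the library defaults) and an
additive-logit logistic regression. The protocol in both cases:

* a single stratified 2/3 train / 1/3 holdout split per seed, repeated over
  seeds for a mean +/- SD of the AUC;
* the majority class (Expected) is randomly downsampled in the training
  portion to the frequency of the rarest class before fitting;
* variable importance is the mean decrease in accuracy when one feature is
  permuted on held-out data, with the sign of each feature's association
  taken from the difference of class-conditional means;
* genome-wide prediction calls a gene SSM-prone when its predicted
  probability exceeds a threshold (default 0.6).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import train_test_split
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

POSITIVE_LABEL = "Upper"


class SsmProneModel:
    """Feature-based classifier of splice-site-mutation-prone genes.

    Parameters
    ----------
    features
        Numeric gene-by-feature table (index: gene ids).
    labels
        Envelope categories aligned with ``features``; the positive class is
        'Upper', everything else is treated as the negative class.
    method
        'rf' (random forest) or 'lr' (logistic regression).
    n_trees, max_features
        Forest size and per-split feature sample (rf only).
    """

    def __init__(self, features: pd.DataFrame, labels: Sequence[str] | pd.Series,
                 method: str = "rf", n_trees: int = 500,
                 max_features: str | float = "sqrt") -> None:
        if method not in ("rf", "lr"):
            raise ValueError(f"unknown method {method!r}")
        features = pd.DataFrame(features)
        labels = pd.Series(np.asarray(labels), index=features.index)
        if len(labels) != len(features):
            raise ValueError("features and labels must align")
        y = (labels == POSITIVE_LABEL).astype(int)
        if y.nunique() < 2:
            raise ValueError("need both classes present to train")
        self.features = features
        self.y = y
        self.method = method
        self.n_trees = n_trees
        self.max_features = max_features

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_col: str = "label",
                       method: str = "rf", **kwargs) -> "SsmProneModel":
        feats = df.drop(columns=[label_col]).select_dtypes(include=[np.number])
        return cls(feats, df[label_col], method=method, **kwargs)

    def _estimator(self, seed: int):
        if self.method == "rf":
            return RandomForestClassifier(
                n_estimators=self.n_trees, max_features=self.max_features,
                random_state=seed, n_jobs=1)
        # unpenalised additive logit (C=inf disables regularisation)
        return make_pipeline(
            StandardScaler(),
            LogisticRegression(C=np.inf, max_iter=2000, random_state=seed))

    def fit(self, seed: int = 0, holdout_fraction: float = 1 / 3,
            downsample: bool = True, importance_repeats: int = 10,
            compute_importance: bool = True) -> "SsmProneResults":
        """Train on a stratified 2/3 split and evaluate on the 1/3 holdout."""
        X, y = self.features, self.y
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, y, test_size=holdout_fraction, stratify=y, random_state=seed)
        if downsample:
            X_tr, y_tr = _downsample_majority(X_tr, y_tr, seed)
        est = self._estimator(seed)
        est.fit(X_tr.to_numpy(), y_tr.to_numpy())

        prob_te = est.predict_proba(X_te.to_numpy())[:, 1]
        auc = float(roc_auc_score(y_te, prob_te))
        fpr, tpr, thr = roc_curve(y_te, prob_te)
        roc = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})

        importance = None
        if compute_importance:
            imp = permutation_importance(
                est, X_te.to_numpy(), y_te.to_numpy(), scoring="accuracy",
                n_repeats=importance_repeats, random_state=seed)
            signs = np.sign(
                X[y == 1].mean(axis=0) - X[y == 0].mean(axis=0)).replace(0, 1)
            importance = pd.DataFrame({
                "feature": X.columns,
                "mean_decrease_accuracy": imp.importances_mean,
                "sd": imp.importances_std,
                "sign": signs.to_numpy(),
            }).sort_values("mean_decrease_accuracy", ascending=False, ignore_index=True)

        return SsmProneResults(
            model=self, estimator=est, seed=seed, auc=auc, roc=roc,
            importance=importance, holdout_probabilities=pd.Series(prob_te, index=X_te.index),
            holdout_labels=y_te)

    def fit_over_seeds(self, seeds: Sequence[int]) -> pd.DataFrame:
        """Replicate the single-split protocol over seeds (AUC mean +/- SD)."""
        aucs = [self.fit(seed=s, compute_importance=False).auc for s in seeds]
        return pd.DataFrame({"seed": list(seeds), "auc": aucs})


def _downsample_majority(X: pd.DataFrame, y: pd.Series, seed: int):
    """Random under-sampling of the majority class to the minority count."""
    rng = np.random.default_rng(seed)
    counts = y.value_counts()
    minority = counts.idxmin()
    n_min = int(counts.min())
    keep = []
    for cls, idx in y.groupby(y).groups.items():
        idx = np.asarray(list(idx))
        if cls != minority and len(idx) > n_min:
            idx = rng.choice(idx, size=n_min, replace=False)
        keep.extend(idx)
    keep = pd.Index(keep)
    return X.loc[keep], y.loc[keep]


@dataclass
class SsmProneResults:
    """A fitted classifier with its holdout diagnostics."""

    model: SsmProneModel
    estimator: object
    seed: int
    auc: float
    roc: pd.DataFrame
    importance: pd.DataFrame | None
    holdout_probabilities: pd.Series
    holdout_labels: pd.Series

    @property
    def feature_names(self) -> list[str]:
        return list(self.model.features.columns)

    def predict_proba(self, features: pd.DataFrame) -> pd.Series:
        """SSM-prone probability for new genes (columns must match training)."""
        missing = [c for c in self.feature_names if c not in features.columns]
        if missing:
            raise ValueError(f"missing features: {missing}")
        X = features[self.feature_names].to_numpy()
        return pd.Series(self.estimator.predict_proba(X)[:, 1], index=features.index,
                         name="prob_ssm_prone")

    def predict_genomewide(self, features: pd.DataFrame,
                           prob_threshold: float = 0.6) -> pd.DataFrame:
        """Predicted SSM-prone set among unlabeled genes.

        Returns every gene with its probability and a boolean
        ``ssm_prone`` flag (probability strictly above the threshold).
        """
        prob = self.predict_proba(features)
        return pd.DataFrame({"prob": prob, "ssm_prone": prob > prob_threshold})

    def summary(self) -> str:
        lines = [
            "SSM-prone gene classifier",
            "=" * 40,
            f"method:    {self.model.method}",
            f"features:  {len(self.feature_names)}",
            f"genes:     {len(self.model.features)} "
            f"(positives: {int(self.model.y.sum())})",
            f"holdout AUC (seed {self.seed}): {self.auc:.3f}",
        ]
        if self.importance is not None:
            lines.append("top features by mean decrease in accuracy:")
            for r in self.importance.head(8).itertuples(index=False):
                arrow = "+" if r.sign > 0 else "-"
                lines.append(f"  {r.feature:<28} {r.mean_decrease_accuracy:+.4f} ({arrow})")
        return "\n".join(lines)

    def plot_roc(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _fig, ax = plt.subplots(figsize=(5, 5))
        ax.plot(self.roc["fpr"], self.roc["tpr"],
                label=f"{self.model.method} AUC={self.auc:.3f}")
        ax.plot([0, 1], [0, 1], ls="--", c="gray")
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.legend(frameon=False)
        return ax


# ---------------------------------------------------------------------------
# Functional surface
# ---------------------------------------------------------------------------

def train_rf(features: pd.DataFrame, labels, seed: int = 0, **kwargs) -> SsmProneResults:
    """Random-forest classifier under the standard split protocol."""
    return SsmProneModel(features, labels, method="rf").fit(seed=seed, **kwargs)


def train_lr(features: pd.DataFrame, labels, seed: int = 0, **kwargs) -> SsmProneResults:
    """Logistic-regression classifier under the same protocol."""
    return SsmProneModel(features, labels, method="lr").fit(seed=seed, **kwargs)


def drop_feature_retrain(features: pd.DataFrame, labels, feature_name: str,
                         seed: int = 0, method: str = "rf") -> float:
    """Holdout AUC after removing one feature column (identical protocol)."""
    if feature_name not in features.columns:
        raise ValueError(f"no such feature: {feature_name!r}")
    reduced = features.drop(columns=[feature_name])
    res = SsmProneModel(reduced, labels, method=method).fit(
        seed=seed, compute_importance=False)
    return res.auc
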