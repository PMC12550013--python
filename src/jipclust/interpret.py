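"""Post-hoc cluster explanation: a surrogate classifier over the input
features, Monte-Carlo permutation Shapley attributions, per-cluster
clinical profile tables, and joint-prevalence matrices for mannequin-style
displays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import HistGradientBoostingClassifier

from .cohort import Cohort, compute_das, joint_counts
from .preprocess import FeatureMatrix


@dataclass
class SurrogateModel:
    """Gradient-boosted-trees classifier mimicking the cluster assignment."""

    model: HistGradientBoostingClassifier
    feature_names: list[str]
    classes: np.ndarray
    training_accuracy: float

    def predict_proba(self, X) -> np.ndarray:
        return self.model.predict_proba(X)


def fit_surrogate(features: FeatureMatrix, labels,
                  seed: int = 0) -> SurrogateModel:
    """Fit the surrogate (gradient-boosted trees) to the cluster labels."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("need >= 2 clusters to fit a surrogate")
    X = features.values
    clf = HistGradientBoostingClassifier(random_state=seed)
    clf.fit(X, labels)
    acc = float((clf.predict(X) == labels).mean())
    return SurrogateModel(model=clf, feature_names=list(features.columns),
                          classes=clf.classes_, training_accuracy=acc)


@dataclass
class AttributionMatrix:
    """Shapley attributions for one explained patient: phi[class, feature],
    per-class base rates (mean prediction over the background), Monte-Carlo
    standard errors and the local-accuracy residual."""

    phi: np.ndarray
    base: np.ndarray
    se: np.ndarray
    residual: np.ndarray
    feature_names: list[str]
    classes: np.ndarray


def shapley_attributions(surrogate: SurrogateModel, x, background,
                         m: int = 200, seed: int | None = None
                         ) -> AttributionMatrix:
    """Monte-Carlo permutation estimate of Shapley values for one patient.

    For each of ``m`` random feature orderings, features are switched from
    background values to the patient's values one at a time; the change in
    mean predicted class probability (over the background sample) is the
    marginal contribution credited to the switched feature. The estimator
    is unbiased and telescopes exactly, so attributions sum to
    f(x) - base per class up to clipping noise (residual reported).
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    x = np.asarray(x, dtype=float).ravel()
    bg = np.atleast_2d(np.asarray(background, dtype=float))
    if bg.shape[0] < 1:
        raise ValueError("background must be non-empty")
    d = len(surrogate.feature_names)
    if x.shape[0] != d or bg.shape[1] != d:
        raise ValueError("feature layout mismatch with surrogate")
    rng = np.random.default_rng(seed)
    B = bg.shape[0]
    n_cls = len(surrogate.classes)
    base = surrogate.predict_proba(bg).mean(axis=0)
    fx = surrogate.predict_proba(x[None, :])[0]

    contribs = np.zeros((m, n_cls, d))
    for t in range(m):
        order = rng.permutation(d)
        # stack the B background rows at each of the d+1 coalition stages
        Z = np.tile(bg, (d + 1, 1)).reshape(d + 1, B, d)
        for step, j in enumerate(order, start=1):
            Z[step:, :, j] = x[j]
        probs = surrogate.predict_proba(
            Z.reshape((d + 1) * B, d)).reshape(d + 1, B, n_cls).mean(axis=1)
        deltas = np.diff(probs, axis=0)           # (d, n_cls)
        contribs[t, :, order] = deltas            # credited per feature
    phi = contribs.mean(axis=0).reshape(n_cls, d)
    se = (contribs.std(axis=0, ddof=1) / np.sqrt(m)).reshape(n_cls, d) \
        if m > 1 else np.zeros((n_cls, d))
    residual = fx - (base + phi.sum(axis=1))
    return AttributionMatrix(phi=phi, base=base, se=se, residual=residual,
                             feature_names=list(surrogate.feature_names),
                             classes=surrogate.classes)


def _iqr_text(v) -> str:
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return f"{med:.1f} ({q1:.1f}-{q3:.1f})"


def cluster_profile(cohort: Cohort, labels) -> pd.DataFrame:
    """Baseline characteristics per cluster, formatted like a Table-1:
    n, % female, age mean (SD), RF/ACPA %, ESR median (IQR), SJC/TJC
    medians (IQR), DAS44(3)/DAS28(3) medians (IQR)."""
    df = cohort.df
    if isinstance(labels, pd.Series) and isinstance(
            labels.dtype, pd.CategoricalDtype):
        categories = list(labels.cat.categories)
        labels = labels.to_numpy()
    else:
        labels = np.asarray(labels)
        categories = list(pd.unique(labels))
    rows = {}
    for c in categories:
        m = labels == c
        sub = df.loc[m]
        if len(sub) == 0:
            import warnings
            warnings.warn(f"cluster {c!r} is empty; omitted")
            continue
        counts = [joint_counts(r, cohort.atlas) for _, r in sub.iterrows()]
        tjc44 = np.array([jc.tjc44 for jc in counts])
        sjc44 = np.array([jc.sjc44 for jc in counts])
        tjc28 = np.array([jc.tjc28 for jc in counts])
        sjc28 = np.array([jc.sjc28 for jc in counts])
        esr = sub["esr"].to_numpy()
        das44 = np.array([compute_das(t, s, e, "das44_3")
                          for t, s, e in zip(tjc44, sjc44, esr)])
        das28 = np.array([compute_das(t, s, e, "das28_3")
                          for t, s, e in zip(tjc28, sjc28, esr)])
        rows[c] = {
            "n": int(len(sub)),
            "female_pct": 100 * (sub["sex"] == "female").mean(),
            "age_mean": sub["age"].mean(),
            "age_sd": sub["age"].std(),
            "rf_pct": 100 * sub["rf"].mean(),
            "acpa_pct": 100 * sub["acpa"].mean(),
            "esr": _iqr_text(esr),
            "sjc": _iqr_text(sjc44),
            "tjc": _iqr_text(tjc44),
            "das44_3": _iqr_text(das44),
            "das28_3": _iqr_text(das28),
        }
    return pd.DataFrame(rows).T


def joint_prevalence(cohort: Cohort, labels) -> pd.DataFrame:
    """Per cluster x joint: fraction of patients with the joint involved
    (tender OR swollen) — the numbers behind mannequin heatmaps."""
    df = cohort.df
    labels = np.asarray(labels)
    jids = cohort.atlas.joint_ids
    involved = {jid: (df[f"tender_{jid}"].to_numpy(dtype=float) +
                      df[f"swollen_{jid}"].to_numpy(dtype=float) > 0)
                for jid in jids}
    out = {}
    for c in pd.unique(labels):
        m = labels == c
        if m.sum() == 0:
            continue
        out[c] = {jid: float(involved[jid][m].mean()) for jid in jids}
    return pd.DataFrame(out).T[jids]
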