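"""End-to-end patient clustering: embedding -> kNN-Jaccard graph -> Louvain,
plus bootstrap stability, external-cohort projection and neighbourhood
label-mixing (LISI) diagnostics.

:class:`PhenoGraphClusterer` clusters a fixed embedding;
:class:`JIPClusterPipeline` owns the whole chain (feature encoding,
autoencoder, graph clustering) behind one seed, and supports projecting new
cohorts through the frozen transform and encoder without any refitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.base import BaseEstimator, ClusterMixin, clone
from sklearn.neighbors import NearestNeighbors
from sklearn.utils.validation import check_is_fitted

from .autoencoder import MultimodalAutoencoder
from .cohort import Cohort
from .graph import adjusted_rand_index, build_knn_graph, louvain
from .preprocess import (ClinicalFeatureEncoder, FeatureMatrix,
                         apply_transform)


class PhenoGraphClusterer(BaseEstimator, ClusterMixin):
    """kNN-Jaccard-Louvain community detection on an embedding.

    k defaults to 30, the published default of the PhenoGraph algorithm.
    """

    def __init__(self, k: int = 30, random_state=None):
        self.k = k
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.graph_ = build_knn_graph(X, self.k)
        part = louvain(self.graph_, seed=self.random_state)
        self.partition_ = part
        self.labels_ = part.labels
        self.modularity_ = part.modularity
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


@dataclass
class StabilityReport:
    """Co-clustering stability over subsampled re-clustering runs."""

    iterations: int
    subsample_fraction: float
    per_patient: np.ndarray          # matched-assignment frequency in [0,1]
    coclustering: np.ndarray         # pairwise co-cluster frequency
    mean_stability: float
    ari_per_iteration: list[float] = field(default_factory=list)


class JIPClusterPipeline(BaseEstimator):
    """Frozen cluster model: transform params + encoder + reference
    embedding/partition + per-cluster centroids.

    ``fit`` trains the feature encoder, the autoencoder and the graph
    clustering from one seed. ``predict`` projects new patients using only
    frozen parameters: encode, then majority vote among the
    ``projection_k`` nearest reference embeddings (ties broken by the
    nearest cluster centroid). It never refits.
    """

    def __init__(self, k: int = 30, projection_k: int = 30,
                 autoencoder: MultimodalAutoencoder | None = None,
                 min_community_fraction: float = 0.0,
                 random_state=None):
        self.k = k
        self.projection_k = projection_k
        self.autoencoder = autoencoder
        self.min_community_fraction = min_community_fraction
        self.random_state = random_state

    def _make_autoencoder(self) -> MultimodalAutoencoder:
        if self.autoencoder is not None:
            ae = clone(self.autoencoder)
            if ae.random_state is None:
                ae.set_params(random_state=self.random_state)
            return ae
        return MultimodalAutoencoder(random_state=self.random_state)

    def fit(self, cohort_or_features, y=None):
        if isinstance(cohort_or_features, FeatureMatrix):
            features = cohort_or_features
            self.encoder_ = None
        else:
            self.encoder_ = ClinicalFeatureEncoder().fit(cohort_or_features)
            features = self.encoder_.transform(cohort_or_features)
        self.transform_params_ = features.params
        self.autoencoder_ = self._make_autoencoder().fit(features)
        self.embedding_ = self.autoencoder_.transform(features)
        self.clusterer_ = PhenoGraphClusterer(
            k=self.k, random_state=self.random_state).fit(self.embedding_)
        self.partition_ = self.clusterer_.partition_
        self.labels_ = self.partition_.labels
        self.centroids_ = np.vstack([
            self.embedding_[self.labels_ == c].mean(axis=0)
            for c in range(self.partition_.n_communities)])
        self.row_ids_ = list(features.row_ids)
        return self

    # -- projection ---------------------------------------------------

    def encode(self, cohort: Cohort) -> np.ndarray:
        """Frozen transform + frozen encoder for a new cohort."""
        check_is_fitted(self, "embedding_")
        features = apply_transform(cohort, self.transform_params_)
        return self.autoencoder_.transform(features)

    def predict(self, cohort_or_embedding) -> np.ndarray:
        check_is_fitted(self, "embedding_")
        emb = (cohort_or_embedding if isinstance(cohort_or_embedding,
                                                 np.ndarray)
               else self.encode(cohort_or_embedding))
        k = min(self.projection_k, len(self.embedding_))
        nn = NearestNeighbors(n_neighbors=k).fit(self.embedding_)
        _, ind = nn.kneighbors(emb)
        votes = self.labels_[ind]                       # (m, k)
        n_comm = self.partition_.n_communities
        out = np.empty(len(emb), dtype=int)
        for i in range(len(emb)):
            counts = np.bincount(votes[i], minlength=n_comm)
            top = counts.max()
            winners = np.flatnonzero(counts == top)
            if len(winners) == 1:
                out[i] = winners[0]
            else:  # tie: nearest centroid among tied communities
                d = ((self.centroids_[winners] - emb[i]) ** 2).sum(axis=1)
                out[i] = winners[int(np.argmin(d))]
        return out

    # -- stability ----------------------------------------------------

    def stability(self, iterations: int = 1000,
                  subsample_fraction: float = 0.8,
                  seed: int | None = None,
                  mode: str = "frozen_embedding",
                  features: FeatureMatrix | None = None) -> StabilityReport:
        """Re-cluster random subsamples and measure how often patients stay
        with their reference cluster.

        mode="frozen_embedding" (default) re-runs graph + Louvain on a
        subsample of the trained embedding; mode="retrain" refits the
        autoencoder per subsample (needs ``features``). Subsample
        communities are matched to the reference partition by
        maximum-overlap (Hungarian) assignment; per-patient stability is
        the fraction of a patient's inclusions in which they land in their
        matched reference cluster; the pairwise co-clustering matrix counts
        how often co-included pairs co-cluster.
        """
        check_is_fitted(self, "embedding_")
        if iterations < 2:
            raise ValueError("iterations must be >= 2")
        if not 0.0 < subsample_fraction < 1.0:
            raise ValueError("subsample_fraction must lie in (0, 1)")
        n = len(self.embedding_)
        m = int(round(subsample_fraction * n))
        if m <= self.k:
            raise ValueError("subsample smaller than k + 1")
        rng = np.random.default_rng(seed)
        ref = self.labels_
        n_ref = self.partition_.n_communities

        included = np.zeros(n)
        matched = np.zeros(n)
        co_inc = np.zeros((n, n))
        co_clu = np.zeros((n, n))
        aris = []
        for it in range(iterations):
            idx = rng.choice(n, size=m, replace=False)
            if mode == "frozen_embedding":
                emb = self.embedding_[idx]
            elif mode == "retrain":
                if features is None:
                    raise ValueError("mode='retrain' needs features")
                sub = _subset_features(features, idx)
                ae = self._make_autoencoder()
                ae.set_params(random_state=int(rng.integers(2 ** 31)))
                emb = ae.fit(sub).transform(sub)
            else:
                raise ValueError(f"unknown mode {mode!r}")
            part = louvain(build_knn_graph(emb, self.k),
                           seed=int(rng.integers(2 ** 31)))
            labels = part.labels
            aris.append(adjusted_rand_index(ref[idx], labels))
            # Hungarian maximum-overlap matching on the contingency table
            n_sub = part.n_communities
            cont = np.zeros((n_ref, n_sub))
            np.add.at(cont, (ref[idx], labels), 1)
            rows, cols = linear_sum_assignment(-cont)
            sub_to_ref = np.full(n_sub, -1)
            sub_to_ref[cols] = rows
            ok = sub_to_ref[labels] == ref[idx]
            included[idx] += 1
            matched[idx[ok]] += 1
            same = labels[:, None] == labels[None, :]
            co_inc[np.ix_(idx, idx)] += 1
            co_clu[np.ix_(idx, idx)] += same

        with np.errstate(invalid="ignore", divide="ignore"):
            per_patient = np.where(included > 0, matched / included, np.nan)
            cocluster = np.where(co_inc > 0, co_clu / co_inc, np.nan)
        np.fill_diagonal(cocluster, 1.0)
        mean_stab = float(np.nanmean(per_patient))
        return StabilityReport(
            iterations=iterations, subsample_fraction=subsample_fraction,
            per_patient=per_patient, coclustering=cocluster,
            mean_stability=mean_stab, ari_per_iteration=aris)


def _subset_features(features: FeatureMatrix, idx) -> FeatureMatrix:
    return FeatureMatrix(
        numeric=features.numeric[idx], categorical=features.categorical[idx],
        numeric_cols=features.numeric_cols,
        categorical_cols=features.categorical_cols,
        row_ids=[features.row_ids[i] for i in idx], params=features.params)


def fit_cluster_model(features: FeatureMatrix,
                      mmae: MultimodalAutoencoder | None = None,
                      k: int = 30, seed: int | None = None
                      ) -> JIPClusterPipeline:
    """Train the embedding + clustering chain on an encoded cohort."""
    return JIPClusterPipeline(k=k, autoencoder=mmae,
                              random_state=seed).fit(features)


def project_patients(model: JIPClusterPipeline, cohort: Cohort) -> np.ndarray:
    """Assign new patients to the learned clusters via the frozen pipeline."""
    return model.predict(cohort)


def stability_analysis(model: JIPClusterPipeline, iterations: int,
                       subsample_fraction: float = 0.8,
                       seed: int | None = None,
                       mode: str = "frozen_embedding",
                       features: FeatureMatrix | None = None
                       ) -> StabilityReport:
    """Functional wrapper over :meth:`JIPClusterPipeline.stability`."""
    return model.stability(iterations=iterations,
                           subsample_fraction=subsample_fraction,
                           seed=seed, mode=mode, features=features)


def lisi(emb: np.ndarray, labels, perplexity: float = 30.0) -> np.ndarray:
    """Local Inverse Simpson's Index per patient.

    For each patient a Gaussian-kernel neighbourhood is tuned by binary
    search on the bandwidth so its entropy matches log(perplexity); the
    kernel-weighted label proportions p_c give LISI = 1 / sum p_c^2, the
    effective number of label categories locally (in [1, C]).
    """
    emb = np.asarray(emb, dtype=float)
    labels = np.asarray(labels)
    n = len(emb)
    if perplexity >= n:
        raise ValueError("perplexity must be < n")
    cats, codes = np.unique(labels, return_inverse=True)
    C = len(cats)
    if C == 1:
        return np.ones(n)
    log_perp = np.log(perplexity)
    d2 = ((emb[:, None, :] - emb[None, :, :]) ** 2).sum(-1)
    np.fill_diagonal(d2, np.inf)
    out = np.empty(n)
    for i in range(n):
        di = d2[i] - d2[i].min()
        lo, hi = 0.0, np.inf
        beta = 1.0
        for _ in range(64):
            w = np.exp(-beta * di)
            sw = w.sum()
            p = w / sw
            mask = p > 0
            h = -(p[mask] * np.log(p[mask])).sum()
            if abs(h - log_perp) < 1e-5:
                break
            if h > log_perp:     # too flat -> sharpen
                lo = beta
                beta = beta * 2 if not np.isfinite(hi) else (beta + hi) / 2
            else:
                hi = beta
                beta = beta / 2 if lo == 0.0 else (beta + lo) / 2
        pc = np.bincount(codes, weights=w / sw, minlength=C)
        out[i] = 1.0 / (pc ** 2).sum()
    return out
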