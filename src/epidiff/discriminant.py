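"""Multivariate discrimination of samples from region methylation vectors.

Each sample is a vector of mean methylation levels over regions (group-wise
DMRs or tiling windows).  Dimensionality is first reduced by PCA (four
components by default); linear discriminant functions are then fit on the
component scores; the two leading discriminant coordinates feed Ward
hierarchical clustering with the squared-Euclidean minimum-variance
criterion; group separation is quantified by Pillai's trace with its F
approximation; and classification is validated by repeated stratified
k-fold cross-validation of the PCA+LDA pipeline, corroborated by a
linear-kernel SVM.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats
from scipy.cluster import hierarchy

from .matrix import MethylomeMatrix

logger = logging.getLogger(__name__)

RIDGE = 1e-6  # fraction of mean diagonal added to singular within-scatter


def region_feature_matrix(regions: pd.DataFrame, matrix: MethylomeMatrix
                          ) -> pd.DataFrame:
    """Sample-by-region matrix of pooled methylation levels.

    ``regions`` needs chrom/start/end (1-based inclusive) and optionally
    context; each cell is sum(meth)/sum(cov) over the region's sites for
    that sample.  Regions with zero coverage in any sample are dropped and
    logged.  Returns a DataFrame indexed by sample.
    """
    if len(regions) == 0:
        raise ValueError("no regions supplied")
    chrom_arr = matrix.sites["chrom"].to_numpy()
    pos_arr = matrix.sites["pos"].to_numpy()
    ctx_arr = matrix.sites["context"].to_numpy()
    cols = {}
    dropped = 0
    for _, reg in regions.iterrows():
        sel = (chrom_arr == reg["chrom"]) & (pos_arr >= reg["start"]) & \
              (pos_arr <= reg["end"])
        if "context" in regions.columns and pd.notna(reg.get("context")):
            sel &= ctx_arr == reg["context"]
        m = matrix.meth[sel].sum(axis=0)
        c = matrix.cov[sel].sum(axis=0)
        if (c == 0).any():
            dropped += 1
            continue
        name = f"{reg['chrom']}:{int(reg['start'])}-{int(reg['end'])}"
        if "context" in regions.columns and pd.notna(reg.get("context")):
            name += f":{reg['context']}"
        cols[name] = m / c
    if dropped:
        logger.info("dropped %d regions with zero coverage in some sample",
                    dropped)
    if not cols:
        raise ValueError("all regions dropped (zero coverage)")
    return pd.DataFrame(cols, index=matrix.samples)


@dataclass
class PcaResult:
    scores: np.ndarray              # (n_samples, k)
    variance_fractions: np.ndarray  # (k,)
    components: np.ndarray          # (k, n_features) rows are axes
    mean: np.ndarray                # (n_features,)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) @ self.components.T


def pca_reduce(X: np.ndarray | pd.DataFrame, n_components: int = 4
               ) -> PcaResult:
    """Principal components of the (column-centred, unscaled) data.

    Components are ordered by decreasing eigenvalue of the sample
    covariance; each axis's sign is fixed so its largest-magnitude loading
    is positive.  ``n_components`` is clipped to min(n_samples-1,
    n_features) with a warning.
    """
    Xa = np.asarray(X, dtype=float)
    n, d = Xa.shape
    if n < 2:
        raise ValueError("PCA needs at least two samples")
    max_k = min(n - 1, d)
    if n_components > max_k:
        warnings.warn(f"n_components clipped from {n_components} to {max_k}")
        n_components = max_k
    mean = Xa.mean(axis=0)
    Xc = Xa - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign: largest-|loading| coordinate positive per axis
    for i in range(len(s)):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] *= -1.0
            U[:, i] *= -1.0
    var = s ** 2 / (n - 1)
    total = var.sum()
    k = n_components
    return PcaResult(
        scores=U[:, :k] * s[:k],
        variance_fractions=var[:k] / total if total > 0 else np.zeros(k),
        components=Vt[:k], mean=mean)


def _scatter_matrices(X: np.ndarray, labels: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Between-group (H) and within-group (E) scatter, plus group list."""
    Xa = np.asarray(X, dtype=float)
    labs = np.asarray(labels)
    groups = np.unique(labs)
    grand = Xa.mean(axis=0)
    d = Xa.shape[1]
    H = np.zeros((d, d))
    E = np.zeros((d, d))
    for g in groups:
        Xg = Xa[labs == g]
        mg = Xg.mean(axis=0)
        dev = (mg - grand)[:, None]
        H += len(Xg) * dev @ dev.T
        R = Xg - mg
        E += R.T @ R
    return H, E, groups


def _regularise(E: np.ndarray) -> np.ndarray:
    d = E.shape[0]
    tr = np.trace(E)
    eps = RIDGE * (tr / d if tr > 0 else 1.0)
    return E + eps * np.eye(d)


@dataclass
class LdaResult:
    coordinates: np.ndarray       # (n_samples, n_functions)
    directions: np.ndarray        # (n_features_in, n_functions)
    eigenvalues: np.ndarray
    group_centroids: pd.DataFrame  # groups x functions
    region_loadings: np.ndarray | None = None  # back-projected via PCA

    def transform(self, X: np.ndarray, mean: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - mean) @ self.directions


def lda_fit(scores: np.ndarray, labels, n_functions: int = 2,
            pca: PcaResult | None = None) -> LdaResult:
    """Fisher linear discriminant functions on (PCA-reduced) scores.

    Solves the generalized eigenproblem of between- vs within-group
    scatter; the within-scatter is ridge-regularized when singular.  At
    most min(groups-1, dims) functions are returned.  When ``pca`` is
    given, discriminant directions are also mapped back through the PCA
    rotation to region space for reporting loadings.
    """
    Xa = np.asarray(scores, dtype=float)
    labs = np.asarray(labels)
    H, E, groups = _scatter_matrices(Xa, labs)
    if len(groups) < 2:
        raise ValueError("LDA needs at least two groups")
    n_functions = min(n_functions, len(groups) - 1, Xa.shape[1])
    evals, evecs = linalg.eigh(H, _regularise(E))
    order = np.argsort(evals)[::-1][:n_functions]
    W = evecs[:, order]
    evals = evals[order]
    for i in range(W.shape[1]):  # reproducible sign
        j = np.argmax(np.abs(W[:, i]))
        if W[j, i] < 0:
            W[:, i] *= -1.0
    mean = Xa.mean(axis=0)
    coords = (Xa - mean) @ W
    cents = pd.DataFrame(
        [coords[labs == g].mean(axis=0) for g in groups],
        index=groups, columns=[f"LD{i + 1}" for i in range(W.shape[1])])
    loadings = pca.components.T @ W if pca is not None else None
    return LdaResult(coordinates=coords, directions=W, eigenvalues=evals,
                     group_centroids=cents, region_loadings=loadings)


def ward_cluster(coordinates: np.ndarray, k: int
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Ward minimum-variance agglomeration; cut into k clusters.

    Returns (linkage matrix, labels).  Ward's criterion merges the pair
    whose union minimizes the increase in within-cluster squared-Euclidean
    variance; merge order is deterministic.
    """
    Xa = np.asarray(coordinates, dtype=float)
    if Xa.ndim == 1:
        Xa = Xa[:, None]
    n = len(Xa)
    if n < 2:
        raise ValueError("clustering needs at least two points")
    if k > n:
        raise ValueError(f"k={k} exceeds number of points {n}")
    Z = hierarchy.linkage(Xa, method="ward")
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return Z, labels


def pillai_trace(X: np.ndarray, labels) -> tuple[float, float]:
    """Pillai's trace V = tr(H (H+E)^-1) and its F-approximation p-value.

    H and E are the between- and within-group scatter matrices of the
    observations; 0 <= V <= min(groups-1, dims).  Within-scatter
    singularity (tiny groups) is handled by ridge regularization.
    """
    Xa = np.asarray(X, dtype=float)
    if Xa.ndim == 1:
        Xa = Xa[:, None]
    H, E, groups = _scatter_matrices(Xa, labels)
    g = len(groups)
    if g < 2:
        raise ValueError("need at least two groups")
    N, d = Xa.shape
    T = H + _regularise(E)
    V = float(np.trace(H @ np.linalg.inv(T)))
    s = min(d, g - 1)
    m = (abs(d - g + 1) - 1) / 2.0
    nn = (N - g - d - 1) / 2.0
    df1 = s * (2 * m + s + 1)
    df2 = s * (2 * nn + s + 1)
    if df2 <= 0 or V >= s:
        p = 0.0 if V > 0.999 * s else np.nan
    else:
        F = ((2 * nn + s + 1) / (2 * m + s + 1)) * (V / s) / (1 - V / s)
        p = float(stats.f.sf(F, df1, df2))
    return V, p


class _LdaCentroidClassifier:
    """Nearest-centroid classification in discriminant space."""

    def __init__(self, n_functions: int | None = None):
        self.n_functions = n_functions

    def fit(self, X, y):
        labs = np.asarray(y)
        k = self.n_functions or (len(np.unique(labs)) - 1)
        self._mean = np.asarray(X, dtype=float).mean(axis=0)
        self._lda = lda_fit(X, labs, n_functions=k)
        self._groups = self._lda.group_centroids.index.to_numpy()
        return self

    def predict(self, X):
        coords = self._lda.transform(X, self._mean)
        cents = self._lda.group_centroids.to_numpy()
        dist = ((coords[:, None, :] - cents[None, :, :]) ** 2).sum(axis=2)
        return self._groups[np.argmin(dist, axis=1)]


def _make_classifier(name: str):
    if name == "lda":
        return _LdaCentroidClassifier()
    if name == "svm":
        from sklearn.svm import SVC
        return SVC(kernel="linear", C=1.0)
    raise ValueError(f"unknown classifier {name!r}")


@dataclass
class CvResult:
    mean_accuracy: float
    sd_accuracy: float
    per_repeat: np.ndarray
    folds: int


def _stratified_folds(labels: np.ndarray, k: int, rng: np.random.Generator
                      ) -> list[np.ndarray]:
    folds: list[list[int]] = [[] for _ in range(k)]
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        rng.shuffle(idx)
        for i, ix in enumerate(idx):
            folds[i % k].append(int(ix))
    return [np.array(sorted(f), dtype=int) for f in folds]


def cross_validate(X, labels, classifier: str = "lda", folds: int = 10,
                   repeats: int = 1000, seed: int = 0,
                   n_components: int = 4) -> CvResult:
    """Repeated stratified k-fold CV of the PCA+classifier pipeline.

    k is capped at the size of the smallest class and at n (k = n is
    leave-one-out), the faithful small-n reading of "10-fold".  PCA and the
    classifier are refit inside every training fold — no leakage.
    Deterministic given ``seed``.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    Xa = np.asarray(X, dtype=float)
    labs = np.asarray(labels)
    n = len(labs)
    class_sizes = pd.Series(labs).value_counts()
    k = int(min(folds, class_sizes.min(), n))
    if k < 2:
        raise ValueError("smallest class too small for cross-validation")
    rng = np.random.default_rng(seed)
    accs = np.empty(repeats)
    for r in range(repeats):
        fold_idx = _stratified_folds(labs, k, rng)
        correct = 0
        for test in fold_idx:
            train = np.setdiff1d(np.arange(n), test)
            if len(np.unique(labs[train])) < len(np.unique(labs)):
                raise RuntimeError("a class is absent from a training fold")
            pca = pca_reduce(Xa[train], n_components=min(
                n_components, len(train) - 1, Xa.shape[1]))
            clf = _make_classifier(classifier)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                clf.fit(pca.scores, labs[train])
                pred = clf.predict(pca.transform(Xa[test]))
            correct += int((pred == labs[test]).sum())
        accs[r] = correct / n
    return CvResult(float(accs.mean()), float(accs.std(ddof=1) if repeats > 1
                                              else 0.0), accs, k)


def discriminant_report(X: pd.DataFrame, labels: dict[str, str],
                        n_components: int = 4, n_functions: int = 2,
                        k_clusters: int | None = None,
                        cv_folds: int = 10, cv_repeats: int = 100,
                        seed: int = 0) -> dict:
    """End-to-end discriminant analysis of a sample-by-region matrix.

    Returns a dict with pc scores and variance fractions, LD coordinates
    and region loadings, Ward tree and k-cut labels, Pillai's trace with
    its p-value, and LDA/SVM cross-validation summaries.
    """
    samples = list(X.index)
    labs = np.array([labels[s] for s in samples])
    groups = np.unique(labs)
    k_clusters = k_clusters or len(groups)
    pca = pca_reduce(X, n_components=n_components)
    lda = lda_fit(pca.scores, labs, n_functions=n_functions, pca=pca)
    Z, cluster_labels = ward_cluster(lda.coordinates, k_clusters)
    pillai, pillai_p = pillai_trace(lda.coordinates, labs)
    cv_lda = cross_validate(X, labs, "lda", folds=cv_folds,
                            repeats=cv_repeats, seed=seed,
                            n_components=n_components)
    cv_svm = cross_validate(X, labs, "svm", folds=cv_folds,
                            repeats=cv_repeats, seed=seed + 1,
                            n_components=n_components)
    return {
        "samples": samples, "labels": labs,
        "pca": pca, "lda": lda, "linkage": Z,
        "cluster_labels": cluster_labels,
        "pillai": pillai, "pillai_p": pillai_p,
        "cv_lda": cv_lda, "cv_svm": cv_svm,
    }
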