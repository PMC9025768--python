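"""Template construction: silhouette-selected K-means over beat embeddings,
centroid-distance ranking, 30-beat template averaging and rule-based typing.

The number of morphology clusters K is chosen by maximising the silhouette
coefficient

    SC = (1/M) * sum_i (b(i) - a(i)) / max(a(i), b(i))

where a(i) is the mean distance from beat i to the other members of its own
cluster and b(i) the smallest mean distance to any other cluster.  Within
each cluster, members are ranked by squared Euclidean distance to the
centroid and the closest 30 are averaged (on the band-pass-filtered
waveforms) into the cluster template.  Templates are then typed PVC or
Non_PVC from three features — QRS height, QRS width and correlation with the
dominant (most populous, assumed sinus) template — using configurable
clinical-convention thresholds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

__all__ = [
    "Clustering", "Template", "QRSFeatures", "RuleConfig",
    "silhouette_coefficient", "select_k_and_cluster",
    "rank_by_centroid_distance", "build_template", "qrs_features",
    "classify_template", "build_typed_templates",
]


@dataclass
class Clustering:
    k: int
    labels: np.ndarray
    centroids: np.ndarray
    sc: float

    @property
    def m(self) -> int:
        return len(self.labels)

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k)


@dataclass
class Template:
    tw: np.ndarray
    type: str = ""  # 'PVC' / 'Non_PVC'; set by classify_template
    member_count: int = 0
    source_cluster: int = -1


@dataclass
class QRSFeatures:
    height: float          # mV, max - min inside the QRS region
    width_ms: float        # span where |TW - baseline| > 20% of height
    corr_with_dominant: float


@dataclass
class RuleConfig:
    """Thresholds of the morphological template-typing rule."""
    width_thresh_ms: float = 120.0
    corr_thresh: float = 0.8
    height_ratio: float = 1.2
    width_ratio: float = 1.4
    qrs_halfwidth_ms: float = 100.0  # search radius around R for QRS features


def silhouette_coefficient(embeddings, labels) -> float:
    """Mean silhouette over all points (Euclidean distances).

    Singleton-cluster members contribute 0, as does the 0/0 case of
    coincident points.
    """
    X = np.asarray(embeddings, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    D = cdist(X, X)
    s = np.zeros(len(X))
    for i in range(len(X)):
        own = labels == labels[i]
        n_own = own.sum()
        if n_own <= 1:
            continue  # singleton: contributes 0
        a = D[i, own].sum() / (n_own - 1)
        b = min(D[i, labels == lab].mean() for lab in uniq if lab != labels[i])
        denom = max(a, b)
        s[i] = (b - a) / denom if denom > 0 else 0.0
    return float(s.mean())


def select_k_and_cluster(embeddings, k_min: int = 2, k_max: int = 8,
                         seed: int = 0, n_restarts: int = 10) -> Clustering:
    """K-means for each K in [k_min, min(k_max, M-1)]; keep the silhouette
    maximiser (ties favour the smaller K)."""
    X = np.asarray(embeddings, dtype=float)
    m = len(X)
    if m < 2:
        raise ValueError("need at least 2 embeddings to cluster")
    if k_min < 2:
        raise ValueError("k_min must be >= 2")
    best: Clustering | None = None
    for k in range(k_min, min(k_max, m) + 1):
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        labels = km.fit_predict(X)
        if len(np.unique(labels)) < 2:
            continue
        sc = silhouette_coefficient(X, labels)
        if best is None or sc > best.sc:
            best = Clustering(k, labels, km.cluster_centers_, sc)
    if best is None:
        raise ValueError("clustering failed for every candidate K")
    return best


def rank_by_centroid_distance(member_indices, embeddings, centroid) -> np.ndarray:
    """Cluster members sorted by ascending squared distance to the centroid
    (stable: original order breaks ties)."""
    member_indices = np.asarray(member_indices, dtype=int)
    if len(member_indices) == 0:
        raise ValueError("cluster has no members")
    X = np.asarray(embeddings, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    c = np.atleast_1d(np.asarray(centroid, dtype=float))
    d2 = np.sum((X[member_indices] - c) ** 2, axis=1)
    order = np.argsort(d2, kind="stable")
    return member_indices[order]


def build_template(sorted_members, beats, n_template: int = 30,
                   source_cluster: int = -1) -> Template:
    """Average the (filtered) waveforms of the ``n_template`` best-ranked
    members; smaller clusters use all members."""
    sorted_members = np.asarray(sorted_members, dtype=int)
    if len(sorted_members) == 0:
        raise ValueError("cannot build a template from an empty cluster")
    take = sorted_members[:n_template]
    if len(sorted_members) < n_template:
        logger.info("cluster %d has only %d members (< %d); using all",
                    source_cluster, len(sorted_members), n_template)
    tw = np.mean([beats[i].hw for i in take], axis=0)
    return Template(tw=tw, member_count=len(take), source_cluster=source_cluster)


def qrs_features(template: Template, dominant: Template, fs: float,
                 n_pre: int, rules: RuleConfig | None = None) -> QRSFeatures:
    """Height, width and dominant-correlation of a template's QRS complex.

    Baseline is the median of the first ``n_pre // 2`` samples (the quiet
    stretch before the P/QRS); the QRS region is +/-``qrs_halfwidth_ms``
    around the R position; width is the span of samples in that region whose
    |deviation from baseline| exceeds 20% of the height.
    """
    rules = rules or RuleConfig()
    tw = np.asarray(template.tw, dtype=float)
    if len(tw) != len(dominant.tw):
        raise ValueError("template lengths differ")
    baseline = float(np.median(tw[:max(1, n_pre // 2)]))
    half = int(round(rules.qrs_halfwidth_ms / 1000 * fs))
    lo, hi = max(0, n_pre - half), min(len(tw), n_pre + half + 1)
    region = tw[lo:hi]
    height = float(np.ptp(region))
    dev = np.abs(region - baseline)
    above = np.nonzero(dev > 0.2 * height)[0]
    width_ms = ((above[-1] - above[0] + 1) / fs * 1000.0) if len(above) else 0.0
    tv, dv = tw - tw.mean(), dominant.tw - np.mean(dominant.tw)
    denom = np.sqrt((tv ** 2).sum() * (dv ** 2).sum())
    corr = float((tv * dv).sum() / denom) if denom > 0 else 0.0
    return QRSFeatures(height, width_ms, corr)


def classify_template(template: Template, dominant: Template, fs: float,
                      n_pre: int, rules: RuleConfig | None = None) -> str:
    """Type one template PVC/Non_PVC against the dominant (sinus) template.

    PVC iff the QRS is wide (> ``width_thresh_ms``), the waveform is
    dissimilar to the dominant template (corr < ``corr_thresh``), and it is
    either taller (height > ``height_ratio`` x dominant) or much wider
    (width > ``width_ratio`` x dominant).  The dominant template itself is
    always Non_PVC.
    """
    rules = rules or RuleConfig()
    if template is dominant:
        return "Non_PVC"
    feats = qrs_features(template, dominant, fs, n_pre, rules)
    dom_feats = qrs_features(dominant, dominant, fs, n_pre, rules)
    is_pvc = (
        feats.width_ms > rules.width_thresh_ms
        and feats.corr_with_dominant < rules.corr_thresh
        and (feats.height > rules.height_ratio * dom_feats.height
             or feats.width_ms > rules.width_ratio * dom_feats.width_ms)
    )
    return "PVC" if is_pvc else "Non_PVC"


def build_typed_templates(clustering: Clustering, embeddings, beats_filtered,
                          fs: float, n_template: int = 30,
                          rules: RuleConfig | None = None) -> list[Template]:
    """One typed template per cluster; the most populous cluster is the
    dominant (sinus) one and is typed Non_PVC."""
    templates = []
    for j in range(clustering.k):
        members = np.nonzero(clustering.labels == j)[0]
        ranked = rank_by_centroid_distance(members, embeddings,
                                           clustering.centroids[j])
        tpl = build_template(ranked, beats_filtered, n_template,
                             source_cluster=j)
        tpl.member_count_total = int(len(members))
        templates.append(tpl)
    sizes = clustering.sizes
    dom_idx = int(np.argmax(sizes))
    dominant = templates[dom_idx]
    dominant.type = "Non_PVC"
    n_pre = beats_filtered[0].n_pre
    for j, tpl in enumerate(templates):
        if j != dom_idx:
            tpl.type = classify_template(tpl, dominant, fs, n_pre, rules)
    return templates
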