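"""Representation-space analytics.

Covers: classical morphological features (area, aspect ratio, mean
intensity) from nucleus crops; top/bottom expression grouping; clustering of
representations with two-cluster evaluation; the annotation-free
perturbation screen (RBF-kernel maximum mean discrepancy against a negative
control, group-size balancing, Q3 + 1.5*IQR significance flagging);
change-vector cosine similarity across perturbations; and classification /
regression metric suites.

The screening pipeline follows the published order of operations: subsample
the negative control (10% by default), derive the RBF gamma from the
control's pairwise distances, balance every perturbation group to the
control size by over/downsampling, compute squared MMD per group, then flag
outliers with the IQR rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist
from sklearn import metrics as skm
from sklearn.cluster import AgglomerativeClustering, KMeans, SpectralClustering
from sklearn.mixture import GaussianMixture
from sklearn.neighbors import kneighbors_graph

from .corpus import NucleusImage

__all__ = [
    "morph_features",
    "high_low_groups",
    "cluster_reps",
    "eval_clustering",
    "rbf_gamma_from_control",
    "mmd_rbf",
    "balance_group",
    "SignificanceRule",
    "flag_significant",
    "change_vectors",
    "cosine_matrix",
    "run_perturbation_screen",
    "ScreenResult",
    "classification_report",
    "regression_report",
    "genewise_pcc",
]


# ---------------------------------------------------------------------------
# Morphological features
# ---------------------------------------------------------------------------

def morph_features(
    image: NucleusImage | np.ndarray, mask: np.ndarray | None = None
) -> tuple[float, float, float]:
    """(area, aspect_ratio, mean_intensity) of one nucleus crop.

    The foreground mask defaults to an Otsu threshold of the crop. Area is
    the foreground pixel count; the aspect ratio is the long/short side
    ratio (>= 1) of the smallest bounding rectangle aligned with the
    nucleus's principal (longest) axis; mean intensity is the mean over all
    pixels on the crop's native scale.
    """
    px = np.asarray(image.pixels if isinstance(image, NucleusImage) else image, dtype=np.float64)
    if mask is None:
        from skimage.filters import threshold_otsu

        if px.max() <= px.min():
            raise ValueError("constant image: foreground undefined without a mask")
        mask = px > threshold_otsu(px)
    mask = np.asarray(mask, dtype=bool)
    area = int(mask.sum())
    if area == 0:
        raise ValueError("empty foreground: features undefined")
    coords = np.column_stack(np.nonzero(mask)).astype(np.float64)
    mean_intensity = float(px.mean())
    if area < 2:
        return float(area), 1.0, mean_intensity
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / area
    _, vecs = np.linalg.eigh(cov)  # ascending; last column = principal axis
    proj = centered @ vecs
    extents = proj.max(axis=0) - proj.min(axis=0) + 1.0  # pixel extent along each axis
    long_side, short_side = max(extents), min(extents)
    aspect = float(long_side / short_side) if short_side > 0 else float("inf")
    return float(area), aspect, mean_intensity


def high_low_groups(
    expression: np.ndarray | pd.Series, pct: float = 5.0
) -> tuple[np.ndarray, np.ndarray]:
    """Indices of the top / bottom ``pct`` percent of cells by expression.

    Group sizes are floor(pct/100 * n); ties are broken by stable cell
    order (earlier cells win), so all-equal inputs still produce
    deterministic groups.
    """
    if not 0 < pct < 50:
        raise ValueError("pct must be in (0, 50)")
    x = np.asarray(expression, dtype=np.float64)
    n = len(x)
    k = int(np.floor(pct / 100.0 * n))
    order = np.argsort(x, kind="stable")
    low = np.sort(order[:k])
    high = np.sort(order[n - k :])
    return high, low


# ---------------------------------------------------------------------------
# Clustering of representations
# ---------------------------------------------------------------------------

def cluster_reps(
    reps: np.ndarray,
    method: str = "gmm",
    k: int = 2,
    resolution: float = 1.0,
    knn: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """Cluster representation vectors into ``k`` groups.

    Vector methods (agglomerative, kmeans, gmm, spectral) operate directly
    on the vectors; graph methods (knn_spectral, leiden) first build a
    k-nearest-neighbour graph with k=10 neighbours. Leiden's cluster count
    is governed by ``resolution`` rather than ``k``.
    """
    X = np.asarray(reps, dtype=np.float64)
    if len(X) < k:
        raise ValueError("need at least k points")
    if method == "agglomerative":
        return AgglomerativeClustering(n_clusters=k).fit_predict(X)
    if method == "kmeans":
        return KMeans(n_clusters=k, random_state=seed, n_init=10).fit_predict(X)
    if method == "gmm":
        return GaussianMixture(n_components=k, random_state=seed, n_init=3).fit_predict(X)
    if method == "spectral":
        return SpectralClustering(
            n_clusters=k, random_state=seed, assign_labels="kmeans"
        ).fit_predict(X)
    if method == "knn_spectral":
        g = kneighbors_graph(X, n_neighbors=min(knn, len(X) - 1), include_self=False)
        affinity = 0.5 * (g + g.T)
        return SpectralClustering(
            n_clusters=k, affinity="precomputed", random_state=seed
        ).fit_predict(affinity)
    if method == "leiden":
        import igraph as ig
        import leidenalg

        g = kneighbors_graph(X, n_neighbors=min(knn, len(X) - 1), include_self=False)
        sources, targets = g.nonzero()
        graph = ig.Graph(n=len(X), edges=list(zip(sources.tolist(), targets.tolist())))
        part = leidenalg.find_partition(
            graph,
            leidenalg.RBConfigurationVertexPartition,
            resolution_parameter=resolution,
            seed=seed,
        )
        return np.asarray(part.membership)
    raise ValueError(f"unknown clustering method {method!r}")


def eval_clustering(
    pred: np.ndarray, truth: np.ndarray
) -> dict[str, float]:
    """Two-cluster agreement metrics after optimal label alignment.

    Cluster ids are matched to the binary ground truth by the permutation
    that maximizes F1, then precision, accuracy, recall and F1 are reported.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    t_vals = np.unique(truth)
    p_vals = np.unique(pred)
    if len(t_vals) != 2 or len(p_vals) > 2:
        raise ValueError("two-cluster evaluation requires binary truth and <= 2 clusters")
    t = (truth == t_vals[1]).astype(int)
    best = None
    for positive in p_vals:
        p = (pred == positive).astype(int)
        f1 = skm.f1_score(t, p, zero_division=0)
        if best is None or f1 > best[0]:
            best = (f1, p)
    f1, p = best
    return {
        "precision": float(skm.precision_score(t, p, zero_division=0)),
        "accuracy": float(skm.accuracy_score(t, p)),
        "recall": float(skm.recall_score(t, p, zero_division=0)),
        "f1": float(f1),
    }


# ---------------------------------------------------------------------------
# MMD perturbation screening
# ---------------------------------------------------------------------------

def rbf_gamma_from_control(control: np.ndarray) -> float:
    """RBF bandwidth from the negative control: the median heuristic.

    gamma = 1 / median(pairwise squared Euclidean distances) among control
    points. Degenerate controls (all points identical) fall back to 1/d.
    """
    X = np.asarray(control, dtype=np.float64)
    if len(X) < 2:
        raise ValueError("need at least 2 control points")
    d2 = cdist(X, X, "sqeuclidean")
    med = float(np.median(d2[np.triu_indices(len(X), k=1)]))
    if med <= 0:
        import warnings

        warnings.warn("degenerate control (zero median distance); using gamma = 1/d")
        return 1.0 / X.shape[1]
    return 1.0 / med


def mmd_rbf(A: np.ndarray, B: np.ndarray, gamma: float, unbiased: bool = False) -> float:
    """Squared maximum mean discrepancy with an RBF kernel.

    The default is the biased V-statistic
    ``mean(k(A,A)) + mean(k(B,B)) - 2 mean(k(A,B))`` with
    ``k(x,y) = exp(-gamma ||x-y||^2)``; it is 0 exactly when A and B are the
    same multiset and non-negative in general. Set ``unbiased`` for the
    U-statistic (diagonal terms excluded), which can go slightly negative.
    """
    A = np.atleast_2d(np.asarray(A, dtype=np.float64))
    B = np.atleast_2d(np.asarray(B, dtype=np.float64))
    if A.shape[1] != B.shape[1]:
        raise ValueError("representation dimensions differ")
    if len(A) == 0 or len(B) == 0:
        raise ValueError("both sample sets must be non-empty")
    Kaa = np.exp(-gamma * cdist(A, A, "sqeuclidean"))
    Kbb = np.exp(-gamma * cdist(B, B, "sqeuclidean"))
    Kab = np.exp(-gamma * cdist(A, B, "sqeuclidean"))
    if unbiased:
        na, nb = len(A), len(B)
        if na < 2 or nb < 2:
            raise ValueError("unbiased estimator needs >= 2 points per set")
        term_a = (Kaa.sum() - np.trace(Kaa)) / (na * (na - 1))
        term_b = (Kbb.sum() - np.trace(Kbb)) / (nb * (nb - 1))
        return float(term_a + term_b - 2.0 * Kab.mean())
    return float(max(Kaa.mean() + Kbb.mean() - 2.0 * Kab.mean(), 0.0))


def balance_group(reps: np.ndarray, target_n: int, seed: int = 0) -> np.ndarray:
    """Resample a group to exactly ``target_n`` members.

    Larger groups are downsampled without replacement; smaller groups are
    oversampled with replacement; exact-size groups pass through unchanged.
    """
    X = np.asarray(reps)
    if len(X) == 0:
        raise ValueError("cannot balance an empty group")
    if target_n < 1:
        raise ValueError("target_n must be >= 1")
    if len(X) == target_n:
        return X
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(X), size=target_n, replace=len(X) < target_n)
    return X[idx]


@dataclass
class SignificanceRule:
    """Q3 + 1.5*IQR outlier rule over a set of MMD values."""

    q3: float
    iqr: float

    @property
    def threshold(self) -> float:
        return self.q3 + 1.5 * self.iqr


def flag_significant(mmd_values) -> tuple[SignificanceRule, np.ndarray]:
    """Flag perturbations whose MMD strictly exceeds Q3 + 1.5*IQR.

    Quartiles use linear interpolation (numpy's default); with all-equal
    values the IQR is 0 and nothing is flagged (strict inequality).
    """
    v = np.asarray(list(mmd_values) if not isinstance(mmd_values, np.ndarray) else mmd_values,
                   dtype=np.float64)
    if len(v) < 4:
        raise ValueError("need at least 4 MMD values for the IQR rule")
    q1, q3 = np.percentile(v, [25, 75])
    rule = SignificanceRule(q3=float(q3), iqr=float(q3 - q1))
    return rule, v > rule.threshold


def change_vectors(
    group_reps: dict[str, np.ndarray], control: np.ndarray
) -> dict[str, np.ndarray]:
    """Mean representation of each group minus the mean control profile."""
    c = np.asarray(control, dtype=np.float64)
    if len(c) == 0:
        raise ValueError("control must be non-empty")
    c_mean = c.mean(axis=0)
    return {g: np.asarray(r, dtype=np.float64).mean(axis=0) - c_mean for g, r in group_reps.items()}


def cosine_matrix(vectors: dict[str, np.ndarray]) -> pd.DataFrame:
    """Pairwise cosine similarity between change vectors.

    Rows/columns with zero-norm vectors are reported as NaN (undefined),
    never as 0. Diagonal entries for nonzero vectors are exactly 1.
    """
    names = list(vectors.keys())
    V = np.stack([vectors[n] for n in names]).astype(np.float64)
    norms = np.linalg.norm(V, axis=1)
    C = np.full((len(names), len(names)), np.nan)
    ok = norms > 0
    if ok.any():
        Vn = V[ok] / norms[ok, None]
        sub = np.clip(Vn @ Vn.T, -1.0, 1.0)
        C[np.ix_(ok, ok)] = sub
    np.fill_diagonal(C, np.where(ok, 1.0, np.nan))
    return pd.DataFrame(C, index=names, columns=names)


@dataclass
class ScreenResult:
    """Output of the MMD perturbation screen."""

    table: pd.DataFrame  # group_id, modality, n, mmd, significant
    rule: SignificanceRule
    gamma: float
    cosine: pd.DataFrame  # change-vector cosine among significant groups
    metadata: dict = field(default_factory=dict)


def run_perturbation_screen(
    group_reps: dict[str, np.ndarray],
    control: np.ndarray,
    modalities: dict[str, str] | None = None,
    control_frac: float = 0.1,
    seed: int = 0,
    unbiased: bool = False,
) -> ScreenResult:
    """Annotation-free perturbation screen against a negative control.

    Order of operations: (1) randomly subsample the control to
    ``control_frac`` of its cells, (2) derive the RBF gamma from the
    subsampled control, (3) balance every perturbation group to the control
    size by over/downsampling, (4) compute squared MMD per group, (5) flag
    groups above Q3 + 1.5*IQR, (6) compute change-vector cosine similarity
    among the significant groups (change vectors use the full, unbalanced
    group means).
    """
    rng = np.random.default_rng(seed)
    control = np.asarray(control, dtype=np.float64)
    n_ctrl = max(int(round(control_frac * len(control))), 2)
    ctrl = control[rng.choice(len(control), size=min(n_ctrl, len(control)), replace=False)]
    gamma = rbf_gamma_from_control(ctrl)
    rows = []
    for g, reps in group_reps.items():
        balanced = balance_group(np.asarray(reps, dtype=np.float64), len(ctrl),
                                 seed=int(rng.integers(2**31)))
        rows.append(
            {
                "group_id": g,
                "modality": (modalities or {}).get(g, "CP"),
                "n": len(reps),
                "mmd": mmd_rbf(balanced, ctrl, gamma, unbiased=unbiased),
            }
        )
    table = pd.DataFrame(rows)
    rule, flags = flag_significant(table["mmd"].to_numpy())
    table["significant"] = flags
    sig = table.loc[table["significant"], "group_id"].tolist()
    vecs = change_vectors({g: group_reps[g] for g in sig}, control) if sig else {}
    cos = cosine_matrix(vecs) if vecs else pd.DataFrame()
    meta = {
        "gamma": gamma,
        "seed": seed,
        "estimator": "unbiased" if unbiased else "biased",
        "control_frac": control_frac,
        "n_control_used": len(ctrl),
        "threshold": rule.threshold,
    }
    return ScreenResult(table=table, rule=rule, gamma=gamma, cosine=cos, metadata=meta)


# ---------------------------------------------------------------------------
# Metric suites
# ---------------------------------------------------------------------------

def classification_report(scores: np.ndarray, truth: np.ndarray) -> dict[str, float]:
    """Multiclass classification metrics from per-class probability scores.

    Reports accuracy; macro-averaged F1, precision, recall and one-vs-rest
    AUROC; multiclass Matthews correlation; and Cohen's kappa. Classes
    absent from the truth are excluded from the macro AUROC with a warning.
    """
    scores = np.asarray(scores, dtype=np.float64)
    truth = np.asarray(truth)
    if scores.ndim != 2 or scores.shape[1] < 2:
        raise ValueError("scores must be (n, n_classes) with >= 2 classes")
    pred = scores.argmax(axis=1)
    present = np.unique(truth)
    aucs = []
    for c in range(scores.shape[1]):
        if c not in present or len(present) < 2:
            continue
        aucs.append(skm.roc_auc_score((truth == c).astype(int), scores[:, c]))
    if len(aucs) < scores.shape[1]:
        import warnings

        warnings.warn("classes absent from truth excluded from macro AUROC")
    return {
        "accuracy": float(skm.accuracy_score(truth, pred)),
        "f1_macro": float(skm.f1_score(truth, pred, average="macro", zero_division=0)),
        "precision_macro": float(skm.precision_score(truth, pred, average="macro", zero_division=0)),
        "recall_macro": float(skm.recall_score(truth, pred, average="macro", zero_division=0)),
        "auroc_macro": float(np.mean(aucs)) if aucs else float("nan"),
        "mcc": float(skm.matthews_corrcoef(truth, pred)),
        "cohen_kappa": float(skm.cohen_kappa_score(truth, pred)),
    }


def regression_report(
    pred: np.ndarray, truth: np.ndarray, n_predictors: int = 1, quantile_tau: float = 0.5
) -> dict[str, float]:
    """Regression metric suite over flattened predictions.

    PCC, SCC, R^2, adjusted R^2 (default p = 1 predictor), concordance
    correlation (CCC), explained variance, RMSE, MSE, MAE and quantile
    (pinball) loss at tau = 0.5 by default.
    """
    p = np.asarray(pred, dtype=np.float64).ravel()
    t = np.asarray(truth, dtype=np.float64).ravel()
    if p.shape != t.shape:
        raise ValueError("pred and truth must have the same shape")
    n = len(t)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.var(t) == 0:
        pcc = scc = float("nan")
    else:
        pcc = float(stats.pearsonr(p, t)[0])
        scc = float(stats.spearmanr(p, t)[0])
    r2 = float(skm.r2_score(t, p))
    adj = float(1.0 - (1.0 - r2) * (n - 1) / (n - n_predictors - 1))
    mp, mt = p.mean(), t.mean()
    vp, vt = p.var(), t.var()
    cov = ((p - mp) * (t - mt)).mean()
    ccc = float(2 * cov / (vp + vt + (mp - mt) ** 2)) if (vp + vt + (mp - mt) ** 2) > 0 else float("nan")
    mse = float(skm.mean_squared_error(t, p))
    return {
        "pcc": pcc,
        "scc": scc,
        "r2": r2,
        "adjusted_r2": adj,
        "ccc": ccc,
        "explained_variance": float(skm.explained_variance_score(t, p)),
        "rmse": float(np.sqrt(mse)),
        "mse": mse,
        "mae": float(skm.mean_absolute_error(t, p)),
        "quantile_loss": float(skm.mean_pinball_loss(t, p, alpha=quantile_tau)),
    }


def genewise_pcc(pred: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Pearson correlation between predicted and true expression per gene
    (column). Zero-variance truth columns are reported as NaN."""
    P = np.asarray(pred, dtype=np.float64)
    T = np.asarray(truth, dtype=np.float64)
    if P.shape != T.shape:
        raise ValueError("pred and truth must have the same shape")
    out = np.full(P.shape[1], np.nan)
    for j in range(P.shape[1]):
        if np.var(T[:, j]) > 0 and np.var(P[:, j]) > 0:
            out[j] = stats.pearsonr(P[:, j], T[:, j])[0]
    return out
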