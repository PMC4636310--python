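"""CAZotype discovery: community typing of gut metagenomes by their
CAZyme family profiles.

The procedure mirrors enterotype-style typing: root Jensen-Shannon
divergence between per-sample relative abundance profiles as the distance,
partitioning around medoids (PAM) for each candidate cluster count, the
Calinski-Harabasz (CH) index for choosing k, between-class analysis (BCA)
for 2-D ordination around the class centers of gravity, and one-sided
Welch t-tests with BH correction plus a fold-ratio gate for CAZotype
marker families.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .association import benjamini_hochberg
from .profiles import AbundanceProfile, relative_abundance

logger = logging.getLogger(__name__)

#: Pseudo-probability assigned to zero entries before JSD, then renormalized.
JSD_EPSILON = 1e-9


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def sample_distance(
    profile: AbundanceProfile | pd.DataFrame,
    metric: str = "jsd",
) -> pd.DataFrame:
    """Pairwise sample distance matrix.

    ``"jsd"`` (default): square root of the Jensen-Shannon divergence,
    base-2 logs, between relative family profiles — a metric bounded by 1,
    with zero probabilities replaced by ``JSD_EPSILON`` and renormalized.
    ``"euclidean"``: Euclidean distance on the rows as given (intended for
    range-scaled Z-score profiles).
    """
    if isinstance(profile, AbundanceProfile):
        mat = relative_abundance(profile)
    else:
        mat = profile
    x = mat.to_numpy(dtype=float)
    if metric == "jsd":
        if np.any(x.sum(axis=1) == 0):
            raise ValueError("all-zero profile row")
        p = x / x.sum(axis=1, keepdims=True)
        p = np.where(p == 0.0, JSD_EPSILON, p)
        p = p / p.sum(axis=1, keepdims=True)
        n = p.shape[0]
        d = np.zeros((n, n))
        # H(M) - (H(P)+H(Q))/2 in bits, via entropies (vectorized per row pair)
        plogp = np.where(p > 0, p * np.log2(p), 0.0).sum(axis=1)
        for i in range(n):
            m = (p[i] + p) / 2.0
            hm = -np.where(m > 0, m * np.log2(m), 0.0).sum(axis=1)
            jsd = hm + (plogp[i] + plogp) / 2.0
            d[i] = np.sqrt(np.clip(jsd, 0.0, None))
        np.fill_diagonal(d, 0.0)
        d = (d + d.T) / 2.0
    elif metric == "euclidean":
        sq = np.sum(x**2, axis=1)
        d2 = sq[:, None] + sq[None, :] - 2.0 * x @ x.T
        d = np.sqrt(np.clip(d2, 0.0, None))
        np.fill_diagonal(d, 0.0)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return pd.DataFrame(d, index=mat.index, columns=mat.index)


# ---------------------------------------------------------------------------
# PAM (k-medoids) with deterministic BUILD + SWAP
# ---------------------------------------------------------------------------

def pam(dist: np.ndarray, k: int, max_iter: int = 200) -> tuple[np.ndarray, np.ndarray]:
    """Partition around medoids on a precomputed distance matrix.

    Deterministic: the BUILD phase greedily seeds medoids (ties to the
    lowest index) and the SWAP phase applies the single best
    cost-decreasing swap per iteration until none remains.

    Returns ``(labels, medoids)`` with labels in 0..k-1 numbered by
    ascending medoid index.
    """
    d = np.asarray(dist, dtype=float)
    n = d.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside [1, {n}]")
    # BUILD
    medoids = [int(np.argmin(d.sum(axis=0)))]
    nearest = d[medoids[0]].copy()
    while len(medoids) < k:
        gain = np.maximum(nearest[None, :] - d, 0.0).sum(axis=1)
        gain[medoids] = -np.inf
        c = int(np.argmax(gain))
        medoids.append(c)
        nearest = np.minimum(nearest, d[c])
    med = np.array(sorted(medoids))
    # SWAP
    for _ in range(max_iter):
        dm = d[med]                      # k x n distances to medoids
        order = np.argsort(dm, axis=0, kind="stable")
        d1 = dm[order[0], np.arange(n)]  # nearest medoid distance
        d2 = dm[order[1], np.arange(n)] if k > 1 else np.full(n, np.inf)
        near_idx = order[0]              # index into med of nearest medoid
        best_delta, best_swap = -1e-12, None
        for mi in range(k):
            mask = near_idx == mi        # points whose nearest medoid is med[mi]
            # cost change of swapping med[mi] for each candidate h (n-vector)
            contrib_near = np.minimum(d[:, mask], d2[mask][None, :]) - d1[mask][None, :]
            contrib_other = np.minimum(d[:, ~mask] - d1[~mask][None, :], 0.0)
            delta = contrib_near.sum(axis=1) + contrib_other.sum(axis=1)
            delta[med] = np.inf
            h = int(np.argmin(delta))
            if delta[h] < best_delta:
                best_delta, best_swap = float(delta[h]), (mi, h)
        if best_swap is None:
            break
        mi, h = best_swap
        med[mi] = h
        med = np.array(sorted(med))
    labels = np.argmin(d[med], axis=0)
    return labels, med


def calinski_harabasz(dist: np.ndarray, labels: np.ndarray) -> float:
    """CH pseudo-F from a distance matrix.

    Uses the identity (exact for Euclidean-embeddable distances, which the
    root-JSD metric is up to numerical precision) that a cluster's
    within-sum-of-squares equals the sum of its squared pairwise distances
    divided by twice its size.
    """
    d2 = np.asarray(dist, dtype=float) ** 2
    n = d2.shape[0]
    ks = np.unique(labels)
    k = ks.size
    if k < 2 or k >= n:
        raise ValueError("CH index needs 2 <= k < n")
    total = d2.sum() / (2.0 * n)
    within = 0.0
    for c in ks:
        idx = np.flatnonzero(labels == c)
        within += d2[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
    between = total - within
    if within <= 0:
        return np.inf
    return float((between / (k - 1)) / (within / (n - k)))


def silhouette(dist: np.ndarray, labels: np.ndarray) -> float:
    from sklearn.metrics import silhouette_score

    return float(silhouette_score(dist, labels, metric="precomputed"))


@dataclass
class CazotypeModel:
    """Fitted community typing model."""

    distances: pd.DataFrame
    k: int
    labels: pd.Series                   # sample -> cazotype id (1..k)
    medoids: list[str]
    ch_index_by_k: dict[int, float]
    silhouette_by_k: dict[int, float]
    bca_coordinates: pd.DataFrame | None = None   # samples x 2
    class_centroids: pd.DataFrame | None = None   # k x 2


def cluster_and_select_k(
    dist: pd.DataFrame,
    k_range=range(2, 7),
) -> CazotypeModel:
    """PAM at each k in ``k_range``; keep the k maximizing the CH index.

    Ties in the CH index resolve to the smaller k.  Labels are renumbered
    1..k by ascending medoid position.
    """
    ks = sorted(k_range)
    n = len(dist)
    if not ks or ks[0] < 2 or ks[-1] > n - 1:
        raise ValueError(f"k_range must lie within [2, {n - 1}]")
    d = dist.to_numpy(dtype=float)
    ch_by_k: dict[int, float] = {}
    sil_by_k: dict[int, float] = {}
    fits: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for k in ks:
        labels, med = pam(d, k)
        if np.unique(labels).size < k:   # collapsed solution cannot score
            ch_by_k[k] = -np.inf
            sil_by_k[k] = np.nan
            continue
        fits[k] = (labels, med)
        ch_by_k[k] = calinski_harabasz(d, labels)
        sil_by_k[k] = silhouette(d, labels)
    best_k = max(ch_by_k, key=lambda k: (ch_by_k[k], -k))
    labels, med = fits[best_k]
    samples = list(dist.index)
    return CazotypeModel(
        distances=dist,
        k=best_k,
        labels=pd.Series(labels + 1, index=pd.Index(samples, name="sample_id"),
                         name="cazotype"),
        medoids=[samples[m] for m in med],
        ch_index_by_k=ch_by_k,
        silhouette_by_k=sil_by_k,
    )


# ---------------------------------------------------------------------------
# Between-class analysis (BCA)
# ---------------------------------------------------------------------------

def bca_ordination(
    matrix: pd.DataFrame, labels: pd.Series
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Principal components of the class centers of gravity.

    The between-class covariance — class means weighted by class size
    around the grand mean — is eigendecomposed; samples and class means
    are projected onto the top two axes.  With k classes only k-1 axes are
    informative, so for k = 2 the second axis carries zero variance.  Axis
    signs are fixed by making each axis' largest-magnitude loading
    positive.
    """
    labels = labels.reindex(matrix.index)
    x = matrix.to_numpy(dtype=float)
    lvls = sorted(labels.unique())
    if len(lvls) < 2:
        raise ValueError("BCA needs at least 2 classes")
    for lvl in lvls:
        if (labels == lvl).sum() == 1:
            warnings.warn(f"class {lvl!r} has a single member", stacklevel=2)
    n = x.shape[0]
    weights = np.array([(labels == lvl).sum() / n for lvl in lvls])
    means = np.vstack([x[(labels == lvl).to_numpy()].mean(axis=0) for lvl in lvls])
    grand = weights @ means
    centered_means = means - grand
    b_cov = (centered_means * weights[:, None]).T @ centered_means
    evals, evecs = np.linalg.eigh(b_cov)
    order = np.argsort(evals)[::-1][:2]
    axes = evecs[:, order]
    if axes.shape[1] < 2:  # rank-1 feature space: second axis is null
        axes = np.hstack([axes, np.zeros((axes.shape[0], 2 - axes.shape[1]))])
    for j in range(axes.shape[1]):
        i = int(np.argmax(np.abs(axes[:, j])))
        if axes[i, j] < 0:
            axes[:, j] = -axes[:, j]
    coords = (x - grand) @ axes
    cents = centered_means @ axes
    coord_df = pd.DataFrame(coords, index=matrix.index, columns=["bca1", "bca2"])
    cent_df = pd.DataFrame(cents, index=pd.Index(lvls, name="cazotype"),
                           columns=["bca1", "bca2"])
    return coord_df, cent_df


# ---------------------------------------------------------------------------
# Marker detection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MarkerRecord:
    family: str
    cazotype: int
    mean_in: float
    mean_out: float
    ratio: float
    p_value: float
    p_adjusted: float
    is_marker: bool


def detect_markers(
    rates: pd.DataFrame,
    labels: pd.Series,
    alpha: float = 0.05,
    min_ratio: float = 1.5,
) -> list[MarkerRecord]:
    """CAZotype-specific marker families.

    Per family x cazotype: one-sided Welch t-test (in-group greater than
    all others), BH adjustment across every test performed, and a marker
    call requiring adjusted p < ``alpha`` AND in/out mean ratio >
    ``min_ratio``.  Tests with zero variance in both groups are flagged
    degenerate and excluded from the adjustment.
    """
    labels = labels.reindex(rates.index)
    lvls = sorted(labels.unique())
    for lvl in lvls:
        if (labels == lvl).sum() < 3:
            raise ValueError(f"cazotype {lvl!r} has fewer than 3 samples")
    raw: list[tuple[str, int, float, float, float]] = []
    for fam in rates.columns:
        col = rates[fam].to_numpy(dtype=float)
        for lvl in lvls:
            mask = (labels == lvl).to_numpy()
            a, b = col[mask], col[~mask]
            if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
                continue
            t = stats.ttest_ind(a, b, equal_var=False, alternative="greater")
            raw.append((fam, int(lvl), float(a.mean()), float(b.mean()),
                        float(t.pvalue)))
    if not raw:
        return []
    adj = benjamini_hochberg([r[4] for r in raw])
    out = []
    for (fam, lvl, mi, mo, p), pa in zip(raw, adj):
        ratio = np.inf if mo == 0 else mi / mo
        out.append(MarkerRecord(
            family=fam, cazotype=lvl, mean_in=mi, mean_out=mo, ratio=float(ratio),
            p_value=p, p_adjusted=float(pa),
            is_marker=bool(pa < alpha and ratio > min_ratio),
        ))
    return out


def markers_frame(records: list[MarkerRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def cazotype_preference_table(
    labels: pd.Series, geography: pd.Series
) -> pd.DataFrame:
    """Geography x cazotype percentage table (rows sum to 100)."""
    geography = geography.reindex(labels.index)
    ok = geography.notna() & (geography != "")
    tab = pd.crosstab(geography[ok], labels[ok])
    tab = tab.loc[tab.sum(axis=1) > 0]
    return tab.div(tab.sum(axis=1), axis=0) * 100.0
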