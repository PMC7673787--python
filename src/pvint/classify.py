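"""Unbiased physiological subtype discovery.

The clustering substrate is the seven-feature intrinsic record (AP
half-width, firing frequency at 2x and 3x threshold, adaptation ratio at
2x, input resistance, rheobase, sag index), log10-transformed and
z-scored per feature.  The number of clusters is selected by majority
vote of five cluster-validity indices (silhouette, Calinski-Harabasz,
Davies-Bouldin, Hartigan, gap statistic) evaluated on K-means partitions
over k = 2..8; the partition itself is K-means (k-means++ with restarts)
and is cross-validated against Ward-linkage agglomerative clustering via
the adjusted Rand index.  Clusters receive semantic labels by ranking
their mean firing frequency at 2x threshold: the fastest cluster is FS,
the slowest NFS, and with three clusters the middle one is IS.

Clustering operates on the feature space directly; PCA coordinates are
computed for reporting and plots only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from sklearn.cluster import AgglomerativeClustering, KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import (
    adjusted_rand_score,
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_samples,
    silhouette_score,
)

from .core import CompositionTable, SUBTYPES

CLUSTER_FEATURES = ("ap_halfwidth", "ff_2x", "ff_3x", "ar_2x",
                    "rin", "rheobase", "sag_index")
#: z-score SD floor so constant columns survive toy inputs
SD_FLOOR = 1e-12
#: Hartigan's rule: add clusters while H(k) exceeds this
HARTIGAN_THRESHOLD = 10.0


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def normalize(matrix) -> pd.DataFrame:
    """log10 transform then per-feature z-score.

    All values must be strictly positive; a nonpositive entry raises with
    the offending cell and feature named.
    """
    df = pd.DataFrame(matrix).copy()
    bad = df.le(0) | ~np.isfinite(df)
    if bad.any().any():
        cell = bad.any(axis=1).idxmax()
        feat = bad.loc[cell].idxmax()
        raise ValueError(
            f"normalize requires positive values: cell {cell!r}, "
            f"feature {feat!r} = {df.loc[cell, feat]!r}")
    logged = np.log10(df)
    sd = logged.std(axis=0, ddof=0).clip(lower=SD_FLOOR)
    return (logged - logged.mean(axis=0)) / sd


# ---------------------------------------------------------------------------
# K-means and validity indices
# ---------------------------------------------------------------------------

def cluster(X, k: int, seed: int = 0, n_restarts: int = 100) -> np.ndarray:
    """K-means partition (k-means++, best of ``n_restarts`` by WCSS)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    X = np.asarray(X, dtype=float)
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    return km.fit_predict(X)


def _wcss(X, labels) -> float:
    w = 0.0
    for c in np.unique(labels):
        pts = X[labels == c]
        w += float(((pts - pts.mean(axis=0)) ** 2).sum())
    return w


def gap_statistic(X, k_values, seed: int = 0, n_ref: int = 50,
                  n_restarts: int = 5):
    """Gap statistic against uniform-box reference sets.

    Returns (gap, s) arrays aligned with ``k_values``; the selected k is
    the smallest with gap(k) >= gap(k+1) - s(k+1).
    """
    X = np.asarray(X, dtype=float)
    rng = np.random.default_rng(seed)
    lo, hi = X.min(axis=0), X.max(axis=0)
    log_w = np.array([math.log(_wcss(X, cluster(X, k, seed, n_restarts)))
                      for k in k_values])
    log_w_ref = np.empty((n_ref, len(k_values)))
    for b in range(n_ref):
        ref = rng.uniform(lo, hi, size=X.shape)
        ref_seed = int(rng.integers(0, 2**31 - 1))
        for j, k in enumerate(k_values):
            log_w_ref[b, j] = math.log(_wcss(ref, cluster(ref, k, ref_seed,
                                                          n_restarts)))
    gap = log_w_ref.mean(axis=0) - log_w
    s = log_w_ref.std(axis=0, ddof=0) * math.sqrt(1.0 + 1.0 / n_ref)
    return gap, s


def select_k(Xn, k_range=(2, 8), seed: int = 0, n_restarts: int = 100,
             gap_veto: bool = True):
    """Choose the cluster number by validity-index majority vote.

    Five indices each cast one vote over ``k_range``: silhouette (max),
    Calinski-Harabasz (max), Davies-Bouldin (min), Hartigan (smallest k
    with H(k) <= 10), and the gap statistic (Tibshirani rule, evaluated
    from k = 1 so it can declare the data unclustered).  Ties are broken
    by mean silhouette.  With ``gap_veto``, a gap vote for k = 1 overrides
    the others: ``chosen_k`` is returned as 1 with ``votes`` recording the
    dissent — the degenerate-input guard against slicing one blob in two.

    Returns (chosen_k, votes dict, diagnostics dict).
    """
    X = np.asarray(Xn, dtype=float)
    k_min, k_max = k_range
    n = len(X)
    if n < k_max + 1:
        raise ValueError(f"need at least {k_max + 1} cells, got {n}")
    if n < 3 * k_max:
        import warnings

        warnings.warn(f"select_k: only {n} cells for k_max={k_max}")
    ks = list(range(k_min, k_max + 1))
    parts = {k: cluster(X, k, seed, n_restarts) for k in ks}
    sil = {k: silhouette_score(X, parts[k]) for k in ks}
    ch = {k: calinski_harabasz_score(X, parts[k]) for k in ks}
    db = {k: davies_bouldin_score(X, parts[k]) for k in ks}

    w = {1: _wcss(X, np.zeros(n, dtype=int))}
    w.update({k: _wcss(X, parts[k]) for k in ks})
    w[k_max + 1] = _wcss(X, cluster(X, k_max + 1, seed, n_restarts))
    hart_k = ks[-1]
    for k in ks:
        h = (w[k] / w[k + 1] - 1.0) * (n - k - 1)
        if h <= HARTIGAN_THRESHOLD:
            hart_k = k
            break

    gap_ks = list(range(1, k_max + 1))
    gap, s = gap_statistic(X, gap_ks, seed=seed)
    gap_k = gap_ks[-1]
    for j, k in enumerate(gap_ks[:-1]):
        if gap[j] >= gap[j + 1] - s[j + 1]:
            gap_k = k
            break

    votes = {
        "silhouette": max(ks, key=lambda k: sil[k]),
        "calinski_harabasz": max(ks, key=lambda k: ch[k]),
        "davies_bouldin": min(ks, key=lambda k: db[k]),
        "hartigan": hart_k,
        "gap": gap_k,
    }
    diagnostics = {"silhouette": sil, "calinski_harabasz": ch,
                   "davies_bouldin": db, "gap": dict(zip(gap_ks, gap)),
                   "wcss": w}
    if gap_veto and gap_k == 1:
        return 1, votes, diagnostics
    counts = pd.Series([v for v in votes.values() if v >= k_min]).value_counts()
    top = counts[counts == counts.max()].index
    chosen = max(top, key=lambda k: sil[k]) if len(top) > 1 else int(top[0])
    return int(chosen), votes, diagnostics


def ward_check(Xn, k: int, kmeans_labels=None):
    """Ward-linkage partition at k and its ARI against the K-means one."""
    X = np.asarray(Xn, dtype=float)
    ward = AgglomerativeClustering(n_clusters=k, linkage="ward").fit_predict(X)
    ari = None
    if kmeans_labels is not None:
        ari = float(adjusted_rand_score(kmeans_labels, ward))
    return ward, ari


def label_subtypes(partition, matrix) -> pd.Series:
    """Map raw cluster indices to FS/IS/NFS by mean FF at 2x threshold.

    Ranks clusters by mean ``ff_2x``: fastest = FS, slowest = NFS,
    middle (k = 3) = IS.  Partitions beyond 3 clusters fall back to
    generic C1..Ck labels (ordered fast to slow) with a warning.
    """
    df = pd.DataFrame(matrix)
    partition = np.asarray(partition)
    clusters = np.unique(partition)
    means = {c: df.loc[partition == c, "ff_2x"].mean() for c in clusters}
    order = sorted(clusters, key=lambda c: -means[c])
    k = len(clusters)
    if k == 1:
        import warnings

        warnings.warn("single cluster: labeling all cells FS")
        names = {order[0]: "FS"}
    elif k == 2:
        names = {order[0]: "FS", order[1]: "NFS"}
    elif k == 3:
        names = {order[0]: "FS", order[1]: "IS", order[2]: "NFS"}
    else:
        import warnings

        warnings.warn(f"{k} clusters: using generic labels C1..C{k}")
        names = {c: f"C{i + 1}" for i, c in enumerate(order)}
    return pd.Series([names[c] for c in partition], index=df.index,
                     name="subtype")


# ---------------------------------------------------------------------------
# composition statistics
# ---------------------------------------------------------------------------

def composition(labels, genotypes, subtypes=SUBTYPES) -> CompositionTable:
    """Subtype counts per genotype (zero rows kept for empty genotypes)."""
    labels = pd.Series(labels).reset_index(drop=True)
    genotypes = pd.Series(genotypes).reset_index(drop=True)
    rows = list(pd.unique(genotypes))
    cols = [s for s in subtypes if s in set(labels)] or list(subtypes)
    extra = [s for s in pd.unique(labels) if s not in cols]
    cols = cols + extra
    counts = np.zeros((len(rows), len(cols)), dtype=int)
    for g, l in zip(genotypes, labels):
        counts[rows.index(g), cols.index(l)] += 1
    return CompositionTable(genotypes=rows, subtypes=cols, counts=counts)


def layer_percentages(labels, layers) -> pd.DataFrame:
    """Nearest-integer subtype percentages per layer."""
    df = pd.DataFrame({"layer": pd.Series(layers).values,
                       "subtype": pd.Series(labels).values})
    tab = df.groupby(["layer", "subtype"]).size().unstack(fill_value=0)
    pct = tab.div(tab.sum(axis=1), axis=0) * 100.0
    return pct.round(0).astype(int)


def _log_p_table(table, lr, lc, ln_fact_n):
    """log probability of an r x c table under fixed margins."""
    return (sum(gammaln(m + 1) for m in lr) + sum(gammaln(m + 1) for m in lc)
            - ln_fact_n - gammaln(np.asarray(table) + 1).sum())


def fisher_exact_rc(table, max_enumeration: int = 2_000_000,
                    n_mc: int = 1_000_000, seed: int = 0):
    """Two-sided exact test of independence for an r x c table.

    Full enumeration of tables with the observed margins, summing the
    probability of every table no more probable than the observed one
    (the probability-ordering criterion; for 2 x 2 this is the classical
    two-sided Fisher test).  Above the enumeration budget it falls back
    to Monte-Carlo sampling with fixed margins and the result carries
    ``method = "monte-carlo"``.

    Returns (p_value, method).
    """
    t = np.asarray(table, dtype=int)
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    if t.sum() == 0:
        return 1.0, "enumeration"
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    n = int(t.sum())
    ln_fact_n = gammaln(n + 1)
    logp_obs = _log_p_table(t, row, col, ln_fact_n)
    tol = 1e-7

    # crude bound on the enumeration size: product over free cells of
    # (min(row, col) + 1)
    est = 1
    for i in range(len(row) - 1):
        for j in range(len(col) - 1):
            est *= min(row[i], col[j]) + 1
            if est > max_enumeration:
                break
    if est <= max_enumeration:
        total = 0.0
        r_, c_ = t.shape

        def rec(i, j, work, row_rem, col_rem):
            nonlocal total
            if i == r_ - 1:
                # last row fully determined
                last = col_rem.copy()
                if (last < 0).any():
                    return
                work[i, :] = last
                lp = _log_p_table(work, row, col, ln_fact_n)
                if lp <= logp_obs + tol:
                    total += math.exp(lp)
                return
            if j == c_ - 1:
                v = row_rem[i]
                if v < 0 or v > col_rem[j]:
                    return
                work[i, j] = v
                rec(i + 1, 0, work, row_rem - (np.arange(r_) == i) * 0,
                    col_rem - (np.arange(c_) == j) * v)
                return
            hi = min(row_rem[i], col_rem[j])
            for v in range(hi + 1):
                work[i, j] = v
                rr = row_rem.copy()
                rr[i] -= v
                cc = col_rem.copy()
                cc[j] -= v
                rec(i, j + 1, work, rr, cc)

        rec(0, 0, np.zeros_like(t), row.copy(), col.copy())
        return min(total, 1.0), "enumeration"

    # Monte-Carlo with fixed margins via permutation of category vectors
    rng = np.random.default_rng(seed)
    rows_vec = np.repeat(np.arange(len(row)), row)
    cols_vec = np.repeat(np.arange(len(col)), col)
    hits = 0
    for _ in range(n_mc):
        perm = rng.permutation(cols_vec)
        sim = np.zeros_like(t)
        np.add.at(sim, (rows_vec, perm), 1)
        if _log_p_table(sim, row, col, ln_fact_n) <= logp_obs + tol:
            hits += 1
    return (hits + 1) / (n_mc + 1), "monte-carlo"


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class SubtypeModel:
    """Physiological subtype-discovery model over a feature table.

    Parameters
    ----------
    data : DataFrame
        One row per cell; must contain the seven clustering features and,
        optionally, ``genotype`` and ``layer`` columns.  Cells with any
        missing clustering feature are excluded (and reported).
    k : int, optional
        Fix the cluster number instead of selecting it by index vote.
    k_range : (int, int)
        Search range for the validity-index vote.
    n_restarts : int
        K-means restarts per partition.
    gap_veto : bool
        Let a gap-statistic vote for k = 1 declare the data unclustered.

    Examples
    --------
    >>> model = SubtypeModel(features_df)
    >>> res = model.fit(seed=0)
    >>> print(res.summary())
    """

    def __init__(self, data: pd.DataFrame, k: int | None = None,
                 k_range=(2, 8), n_restarts: int = 100,
                 gap_veto: bool = True):
        data = pd.DataFrame(data)
        missing = [c for c in CLUSTER_FEATURES if c not in data.columns]
        if missing:
            raise ValueError(f"data lacks clustering features {missing}")
        usable = data[list(CLUSTER_FEATURES)].notna().all(axis=1)
        self.data = data
        self.excluded = list(data.index[~usable])
        self.frame = data.loc[usable, list(CLUSTER_FEATURES)].astype(float)
        self.genotypes = (data.loc[usable, "genotype"]
                          if "genotype" in data.columns
                          else pd.Series("WT", index=self.frame.index))
        self.layers = (data.loc[usable, "layer"]
                       if "layer" in data.columns else None)
        self.k = k
        self.k_range = k_range
        self.n_restarts = n_restarts
        self.gap_veto = gap_veto

    @classmethod
    def from_records(cls, records, **kwargs) -> "SubtypeModel":
        """Build from a list of IntrinsicFeatures records."""
        from .features import features_dataframe

        return cls(features_dataframe(records), **kwargs)

    def fit(self, seed: int = 0) -> "SubtypeResults":
        Xn = normalize(self.frame)
        votes, diagnostics = {}, {}
        if self.k is not None:
            chosen = self.k
        else:
            chosen, votes, diagnostics = select_k(
                Xn, self.k_range, seed=seed, n_restarts=self.n_restarts,
                gap_veto=self.gap_veto)
        k_eff = max(chosen, 2) if chosen == 1 else chosen
        raw = cluster(Xn, k_eff, seed=seed, n_restarts=self.n_restarts)
        labels = label_subtypes(raw, self.frame)
        ward_labels, ari = ward_check(Xn, k_eff, raw)
        sil = silhouette_samples(Xn, raw) if k_eff > 1 else np.zeros(len(Xn))
        pca = PCA(n_components=2).fit(Xn)
        coords = pca.transform(Xn)
        return SubtypeResults(
            model=self, chosen_k=chosen, votes=votes,
            diagnostics=diagnostics, raw_labels=raw, labels=labels,
            ward_labels=ward_labels, ward_agreement=ari,
            silhouette_values=pd.Series(sil, index=self.frame.index),
            pca_coords=pd.DataFrame(coords, index=self.frame.index,
                                    columns=["PC1", "PC2"]),
            pca_explained=pca.explained_variance_ratio_,
            normalized=Xn, seed=seed,
        )


@dataclass
class SubtypeResults:
    """Fitted subtype partition with diagnostics."""

    model: SubtypeModel
    chosen_k: int
    votes: dict
    diagnostics: dict
    raw_labels: np.ndarray
    labels: pd.Series
    ward_labels: np.ndarray
    ward_agreement: float | None
    silhouette_values: pd.Series
    pca_coords: pd.DataFrame
    pca_explained: np.ndarray
    normalized: pd.DataFrame
    seed: int = 0

    @property
    def no_structure(self) -> bool:
        return self.chosen_k == 1

    def composition(self) -> CompositionTable:
        return composition(self.labels, self.model.genotypes)

    def layer_percentages(self) -> pd.DataFrame | None:
        if self.model.layers is None:
            return None
        return layer_percentages(self.labels, self.model.layers)

    def fisher_test(self, genotype_a: str, genotype_b: str):
        """Exact test of subtype-composition difference between genotypes."""
        tab = self.composition()
        ia = tab.genotypes.index(genotype_a)
        ib = tab.genotypes.index(genotype_b)
        sub = tab.counts[[ia, ib]]
        sub = sub[:, sub.sum(axis=0) > 0]
        return fisher_exact_rc(sub)

    def feature_table(self) -> pd.DataFrame:
        """Mean +/- SEM of every clustering feature per subtype."""
        df = self.model.frame.copy()
        df["subtype"] = self.labels
        g = df.groupby("subtype")
        mean = g.mean().T
        sem = g.sem().T
        out = {}
        for st in mean.columns:
            out[f"{st} (n={int((self.labels == st).sum())})"] = [
                f"{mean.loc[f, st]:.3g} ± {sem.loc[f, st]:.2g}"
                for f in mean.index]
        return pd.DataFrame(out, index=mean.index)

    def summary(self) -> str:
        lines = ["Subtype discovery summary",
                 "=" * 60,
                 f"cells included: {len(self.labels)}"
                 f" (excluded for missing features: {len(self.model.excluded)})",
                 f"chosen k: {self.chosen_k}"
                 + (" (no cluster structure detected)" if self.no_structure else ""),
                 f"index votes: {self.votes}",
                 f"mean silhouette: {self.silhouette_values.mean():.3f}",
                 f"K-means vs Ward ARI: "
                 + (f"{self.ward_agreement:.3f}" if self.ward_agreement is not None
                    else "n/a"),
                 "",
                 "Per-subtype features (mean ± SEM):",
                 self.feature_table().to_string(),
                 "",
                 "Composition (counts):"]
        tab = self.composition()
        comp = pd.DataFrame(tab.counts, index=tab.genotypes, columns=tab.subtypes)
        lines.append(comp.to_string())
        lines.append("")
        lines.append("Composition (percent, nearest integer):")
        pct = pd.DataFrame(tab.percentages(), index=tab.genotypes,
                           columns=tab.subtypes)
        lines.append(pct.to_string())
        return "\n".join(lines)

    def plot(self, path=None):
        """PCA scatter colored by subtype; saves to ``path`` if given."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        for st in sorted(self.labels.unique()):
            m = self.labels == st
            ax.scatter(self.pca_coords.loc[m, "PC1"],
                       self.pca_coords.loc[m, "PC2"], label=st, s=18)
        ax.set_xlabel(f"PC1 ({self.pca_explained[0]:.0%})")
        ax.set_ylabel(f"PC2 ({self.pca_explained[1]:.0%})")
        ax.legend(frameon=False)
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=150)
            plt.close(fig)
        return fig
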