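"""Multi-line k-mer abundance trends across evolutionary groups.

Given a normalized panel of k-mer counts over lines labeled with
ordered groups (e.g. teosinte < landrace < improved), this module
filters highly variable k-mers (abundant in some lines, nearly absent
in others), tests group effects with one-way ANOVA under Bonferroni
correction, clusters max-scaled abundance profiles with a
shared-covariance Gaussian mixture chosen by BIC, summarizes lines by
PCA, and tabulates annotated k-mers by their direction of change along
the group order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture

__all__ = [
    "GroupedPanel",
    "ClusterModel",
    "highly_variable_filter",
    "group_anova",
    "bonferroni",
    "scale_profiles",
    "gmm_cluster",
    "pca_lines",
    "group_trend_table",
]


@dataclass
class GroupedPanel:
    """Normalized counts (k-mers x lines) plus an ordered group per line."""

    counts: pd.DataFrame
    groups: pd.Series  # line -> group label
    group_order: list[str]

    def __post_init__(self) -> None:
        self.groups = self.groups.reindex(self.counts.columns)
        if self.groups.isna().any():
            raise ValueError("every line must carry a group label")
        sizes = self.groups.value_counts()
        if len(sizes) < 2 or (sizes < 2).any():
            raise ValueError("need >= 2 groups with >= 2 lines each")

    def group_means(self, kmers=None) -> pd.DataFrame:
        sub = self.counts if kmers is None else self.counts.loc[kmers]
        return sub.T.groupby(self.groups).mean().T[self.group_order]


@dataclass
class ClusterModel:
    """Fitted shared-covariance Gaussian mixture over profile rows."""

    G: int
    means: np.ndarray  # (G, n_lines)
    covariance: np.ndarray  # shared (n_lines, n_lines)
    assignments: pd.Series  # k-mer -> component index
    bic: pd.Series  # candidate G -> BIC (sklearn sign: lower is better)


def highly_variable_filter(counts: pd.DataFrame, high: float = 1000,
                           n_high: int = 5, low: float = 10,
                           n_low: int = 5) -> list[str]:
    """K-mers strictly above ``high`` in >= n_high lines and strictly below
    ``low`` in >= n_low lines (thresholds strict on both sides)."""
    if n_high + n_low > counts.shape[1]:
        raise ValueError("n_high + n_low exceeds the number of lines")
    X = counts.to_numpy(dtype=float)
    keep = ((X > high).sum(axis=1) >= n_high) & ((X < low).sum(axis=1) >= n_low)
    return list(counts.index[keep])


def group_anova(values: pd.Series, groups: pd.Series) -> tuple[float, float]:
    """One-way fixed-effects ANOVA of one k-mer's counts across groups.

    Returns (F, p); when within-group variance is zero everywhere with
    equal group means, F is undefined and p is reported as 1.
    """
    groups = groups.reindex(values.index)
    arrays = [values[groups == g].to_numpy(dtype=float)
              for g in groups.unique()]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("need >= 2 groups with >= 2 lines each")
    grand = np.concatenate(arrays).mean()
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    df_b = len(arrays) - 1
    df_w = sum(a.size for a in arrays) - len(arrays)
    if ssw == 0:
        if ssb == 0:
            return float("nan"), 1.0
        return float("inf"), 0.0
    F = (ssb / df_b) / (ssw / df_w)
    p = float(stats.f.sf(F, df_b, df_w))
    return float(F), p


def bonferroni(p_values, alpha: float = 0.05) -> np.ndarray:
    """Boolean mask of p-values significant at alpha/m (m = number of tests)."""
    p = np.asarray(p_values, dtype=float)
    return p < alpha / p.size


def scale_profiles(counts: pd.DataFrame) -> pd.DataFrame:
    """Row-wise division by each k-mer's maximum count (entries in [0, 1])."""
    X = counts.to_numpy(dtype=float)
    rowmax = X.max(axis=1)
    dead = np.flatnonzero(rowmax <= 0)
    if dead.size:
        raise ValueError(
            f"all-zero profile for k-mer(s): {list(counts.index[dead])}")
    return counts.astype(float).div(rowmax, axis=0)


def gmm_cluster(scaled: pd.DataFrame, G_range=range(1, 13), n_init: int = 10,
                seed: int = 0, max_iter: int = 500) -> ClusterModel:
    """Shared-covariance Gaussian-mixture clustering, G chosen by BIC.

    All components share one full covariance matrix (the equal
    volume/shape/orientation parameterization); EM is initialized with
    k-means and the best of ``n_init`` restarts is kept, with a small
    covariance ridge for stability.
    """
    X = scaled.to_numpy(dtype=float)
    G_range = [g for g in G_range if 2 * g <= X.shape[0]]
    if not G_range:
        raise ValueError("too few profiles for any candidate G")
    fits, bics = {}, {}
    for g in G_range:
        gm = GaussianMixture(
            n_components=g, covariance_type="tied", n_init=n_init,
            init_params="kmeans", reg_covar=1e-6, max_iter=max_iter,
            random_state=seed)
        gm.fit(X)
        fits[g] = gm
        bics[g] = float(gm.bic(X))
    best_g = min(bics, key=bics.get)
    gm = fits[best_g]
    labels = gm.predict(X)
    return ClusterModel(
        G=best_g, means=gm.means_, covariance=gm.covariances_,
        assignments=pd.Series(labels, index=scaled.index),
        bic=pd.Series(bics))


def pca_lines(counts: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Centered (unscaled) PCA of lines over a k-mer set.

    Lines are observations, k-mers are variables. Returns per-line
    coordinates and the variance-explained fraction per component
    (fractions sum to 1 over all retained components).
    """
    X = counts.to_numpy(dtype=float).T  # lines x kmers
    if X.shape[0] < 3 or X.shape[1] < 2:
        raise ValueError("need >= 3 lines and >= 2 k-mers")
    if np.ptp(X) == 0:
        raise ValueError("constant matrix has no principal components")
    n_comp = min(X.shape[0], X.shape[1])
    pca = PCA(n_components=n_comp)
    coords = pca.fit_transform(X)
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return (pd.DataFrame(coords, index=counts.columns, columns=cols),
            pca.explained_variance_ratio_)


def cluster_directions(model: ClusterModel, panel: GroupedPanel,
                       flat_frac: float = 0.2) -> pd.Series:
    """Direction of each cluster's mean profile along the group order.

    A cluster is "decrease" when its first-group mean exceeds its
    last-group mean by more than ``flat_frac`` of the profile scale,
    "increase" for the reverse, else "flat". Profiles are max-scaled
    (each row's maximum is 1), so the data range is the unit interval
    and the threshold is ``flat_frac`` in scaled units; a cluster whose
    group means differ only at noise scale is flat by construction.
    """
    line_groups = panel.groups
    first, last = panel.group_order[0], panel.group_order[-1]
    out = {}
    for g in range(model.G):
        mean_profile = pd.Series(model.means[g], index=panel.counts.columns)
        by_group = mean_profile.groupby(line_groups).mean()
        scale = max(float(np.abs(model.means[g]).max()), 1e-12)
        delta = by_group[first] - by_group[last]
        if abs(delta) <= flat_frac * scale:
            out[g] = "flat"
        else:
            out[g] = "decrease" if delta > 0 else "increase"
    return pd.Series(out)


def group_trend_table(model: ClusterModel, panel: GroupedPanel,
                      annotations: pd.Series,
                      flat_frac: float = 0.2) -> pd.DataFrame:
    """Annotated k-mer counts per repeat class per direction of change.

    Clusters are labeled decrease/increase/flat from their mean profile
    along the group order (first vs last group, 20%-of-range rule);
    k-mers inherit their cluster's direction and flat clusters are
    excluded from the decrease/increase columns.
    """
    directions = cluster_directions(model, panel, flat_frac)
    kdir = model.assignments.map(directions)
    ann = annotations.reindex(model.assignments.index).fillna("unannotated")
    tab = (pd.DataFrame({"class": ann, "direction": kdir})
           .groupby(["class", "direction"], as_index=False).size()
           .pivot(index="class", columns="direction", values="size")
           .fillna(0).astype(int))
    for col in ("decrease", "increase"):
        if col not in tab.columns:
            tab[col] = 0
    return tab[["decrease", "increase"]]
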