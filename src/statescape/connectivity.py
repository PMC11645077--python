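"""ROI-to-ROI connectivity and spatial pairwise cluster (SPC) inference.

Connectivity between two regions is the Fisher z-transform (atanh) of the
Pearson correlation of their time series.  Group contrasts are edge-wise
two-sample T-statistics (control = -1, patient = +1, pooled variance,
df = n1 + n2 - 2).  SPC-style inference hierarchically orders the ROIs
(complete linkage with optimal leaf ordering), thresholds the ordered
T-matrix at a two-sided height p-value, groups suprathreshold edges into
4-connected clusters on the upper triangle, and evaluates each cluster's
mass (sum of |T|) against a group-label permutation null: per-permutation
maximum masses give FWE-corrected p-values, the pooled null mass
distribution gives uncorrected p-values, and Benjamini-Hochberg across
clusters gives FDR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as st
from scipy.cluster.hierarchy import leaves_list, linkage, optimal_leaf_ordering
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

__all__ = [
    "connectivity_matrix",
    "edge_group_ttest",
    "hierarchical_order",
    "SPCResult",
    "spc_cluster_inference",
    "bonferroni_roi_reduction",
]

_R_CLIP = 1.0 - 1e-7


def connectivity_matrix(ts) -> pd.DataFrame:
    """Fisher-z ROI-to-ROI connectivity of one recording (diagonal NaN)."""
    from .signals import _as_frame

    df = _as_frame(ts)
    if df.shape[0] < 3:
        raise ValueError("need at least 3 time points")
    values = df.to_numpy(dtype=float)
    if (values.std(axis=0) == 0).any():
        bad = [df.columns[i] for i in np.flatnonzero(values.std(axis=0) == 0)]
        raise ValueError(f"constant ROI column(s): {bad}")
    r = np.corrcoef(values, rowvar=False)
    z = np.arctanh(np.clip(r, -_R_CLIP, _R_CLIP))
    np.fill_diagonal(z, np.nan)
    return pd.DataFrame(z, index=df.columns, columns=df.columns)


def _stack(mats) -> tuple[np.ndarray, list]:
    first = mats[0]
    names = list(first.columns) if isinstance(first, pd.DataFrame) else list(range(np.asarray(first).shape[0]))
    arr = np.stack([np.asarray(m, dtype=float) for m in mats])
    return arr, names


def edge_group_ttest(mats, groups, contrast=(-1, 1)) -> tuple[pd.DataFrame, int]:
    """Edge-wise pooled-variance two-sample T map over subjects.

    ``groups`` holds "control"/"patient" per matrix; the default contrast
    (-1, +1) makes positive T mean patient > control.  Returns (T map, df)
    with df = n1 + n2 - 2.
    """
    zs, names = _stack(mats)
    groups = np.asarray(list(groups))
    ctrl, pat = zs[groups == "control"], zs[groups == "patient"]
    n1, n2 = len(ctrl), len(pat)
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 subjects per group")
    m1, m2 = ctrl.mean(axis=0), pat.mean(axis=0)
    v1, v2 = ctrl.var(axis=0, ddof=1), pat.var(axis=0, ddof=1)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    diff = contrast[0] * m1 + contrast[1] * m2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    t[(sp2 == 0) & (diff == 0)] = 0.0  # identical groups: no evidence either way
    np.fill_diagonal(t, np.nan)
    return pd.DataFrame(t, index=names, columns=names), df


def hierarchical_order(mats, coords=None, blend: float = 0.0) -> list:
    """Complete-linkage ROI ordering with optimal leaf ordering.

    Dissimilarity between two ROIs is ``1 - corr`` of their edge profiles in
    the subject-mean z matrix, optionally blended (weight ``blend``) with
    normalized Euclidean distance between supplied ROI coordinates.
    Deterministic given inputs; returns the ROI names/indices in leaf order.
    """
    zs, names = _stack(mats)
    mean_z = zs.mean(axis=0)
    n = mean_z.shape[0]
    # edge-profile correlation of ROIs i and j over the other N-2 ROIs:
    # their own columns (undefined diagonal, trivially shared edge) are excluded
    c = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            keep = [k for k in range(n) if k not in (i, j)]
            a, b = mean_z[i, keep], mean_z[j, keep]
            sa, sb = a.std(), b.std()
            c[i, j] = c[j, i] = (
                0.0 if sa == 0 or sb == 0 else np.corrcoef(a, b)[0, 1]
            )
    d_fun = 1.0 - c
    if coords is not None and blend > 0:
        xyz = np.asarray(coords, dtype=float)
        d_anat = np.linalg.norm(xyz[:, None] - xyz[None, :], axis=-1)
        if d_anat.max() > 0:
            d_anat = d_anat / d_anat.max() * d_fun.max()
        d_fun = (1 - blend) * d_fun + blend * d_anat
    d_fun = (d_fun + d_fun.T) / 2
    np.fill_diagonal(d_fun, 0.0)
    condensed = squareform(d_fun, checks=False)
    Z = optimal_leaf_ordering(linkage(condensed, method="complete"), condensed)
    return [names[i] for i in leaves_list(Z)]


@dataclass
class SPCResult:
    """Suprathreshold edge clusters with mass/size and permutation p-values."""

    clusters: list[dict] = field(default_factory=list)
    ordering: list = field(default_factory=list)
    n_permutations: int = 0
    n_possible_clusters: int = 0
    height_threshold: float = 0.0
    df: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "cluster": i + 1,
                "mass": c["mass"],
                "size": c["size"],
                "p_unc": c["p_unc"],
                "p_FDR": c["p_FDR"],
                "p_FWE": c["p_FWE"],
                "edges": ";".join(f"{a}--{b}" for a, b in c["edges"]),
            }
            for i, c in enumerate(self.clusters)
        ]
        return pd.DataFrame(rows)


def _cluster_masses(tmat_ordered: np.ndarray, t_crit: float):
    """4-connected suprathreshold components on the upper triangle.

    Returns a list of (mass, list-of-(row, col)) in the *ordered* index
    space, sorted by descending mass.
    """
    n = tmat_ordered.shape[0]
    absT = np.abs(tmat_ordered)
    mask = np.triu(np.ones((n, n), dtype=bool), k=1) & (absT > t_crit)
    if not mask.any():
        return []
    struct = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    labels, n_lab = ndimage.label(mask, structure=struct)
    out = []
    for lab in range(1, n_lab + 1):
        cells = np.argwhere(labels == lab)
        mass = float(absT[labels == lab].sum())
        out.append((mass, [tuple(c) for c in cells]))
    out.sort(key=lambda x: (-x[0], x[1]))
    return out


def _t_maps_permuted(zs_tri, groups, n_perm, rng, df, n1, n2):
    """Pooled-variance T per edge for label permutations, vectorized.

    ``zs_tri``: (n_subjects, n_edges) upper-triangle z values.
    Yields arrays of shape (n_perm, n_edges).
    """
    S = zs_tri.shape[0]
    perms = np.stack([rng.permutation(S) for _ in range(n_perm)])
    is_pat = np.zeros((n_perm, S))
    pat_mask = (np.asarray(list(groups)) == "patient").astype(float)
    for i in range(n_perm):
        is_pat[i] = pat_mask[perms[i]]
    sum_all = zs_tri.sum(axis=0)
    ss_all = (zs_tri ** 2).sum(axis=0)
    sum_pat = is_pat @ zs_tri
    ss_pat = is_pat @ (zs_tri ** 2)
    sum_ctrl = sum_all - sum_pat
    ss_ctrl = ss_all - ss_pat
    m2, m1 = sum_pat / n2, sum_ctrl / n1
    v2 = (ss_pat - n2 * m2 ** 2) / (n2 - 1)
    v1 = (ss_ctrl - n1 * m1 ** 2) / (n1 - 1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m2 - m1) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    return t


def spc_cluster_inference(mats, groups, height_p: float = 0.05, n_perm: int = 1000,
                          seed=None, order=None) -> SPCResult:
    """Permutation cluster-mass inference on the ordered edge T-matrix.

    See the module docstring for the algorithm.  ``order`` overrides the
    data-driven hierarchical ordering (useful for reproducing a fixed
    layout).  An empty result (no suprathreshold edge) is returned as such,
    not as an error.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    zs, names = _stack(mats)
    groups = np.asarray(list(groups))
    n1 = int((groups == "control").sum())
    n2 = int((groups == "patient").sum())
    tmat, df = edge_group_ttest(mats, groups)
    if order is None:
        order = hierarchical_order(mats)
    idx = [names.index(o) for o in order]
    t_crit = float(st.t.isf(height_p / 2, df))
    n = len(names)
    n_nodes = 2 * n - 1  # dendrogram nodes (leaves + merges)
    n_possible = n_nodes * (n_nodes + 1) // 2  # candidate block count

    t_ordered = tmat.to_numpy()[np.ix_(idx, idx)]
    observed = _cluster_masses(t_ordered, t_crit)

    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n, k=1)
    # permutations operate on the ordered matrix's upper triangle
    zs_ord = zs[:, idx][:, :, idx]
    zs_tri = zs_ord[:, iu[0], iu[1]]
    t_perm = _t_maps_permuted(zs_tri, groups, n_perm, rng, df, n1, n2)

    null_max = np.zeros(n_perm)
    null_pool: list[float] = []
    grid = np.full((n, n), np.nan)
    for b in range(n_perm):
        grid[iu] = t_perm[b]
        comps = _cluster_masses(grid, t_crit)
        masses = [m for m, _ in comps]
        null_pool.extend(masses)
        null_max[b] = max(masses) if masses else 0.0
    null_pool_arr = np.asarray(null_pool)

    clusters = []
    for mass, cells in observed:
        edges = sorted((order[i], order[j]) for i, j in cells)
        if null_pool_arr.size:
            p_unc = (1 + (null_pool_arr >= mass).sum()) / (1 + null_pool_arr.size)
        else:
            p_unc = 1.0 / (1 + n_perm)
        p_fwe = (1 + (null_max >= mass).sum()) / (1 + n_perm)
        clusters.append({
            "mass": mass, "size": len(cells), "edges": edges,
            "p_unc": float(p_unc), "p_FWE": float(p_fwe), "p_FDR": np.nan,
        })
    if clusters:
        _, p_fdr, _, _ = multipletests([c["p_unc"] for c in clusters], method="fdr_bh")
        for c, p in zip(clusters, p_fdr):
            c["p_FDR"] = float(p)
    return SPCResult(
        clusters=clusters, ordering=list(order), n_permutations=n_perm,
        n_possible_clusters=n_possible, height_threshold=t_crit, df=df,
    )


def bonferroni_roi_reduction(result: SPCResult, alpha: float = 0.05) -> list:
    """ROIs incident to clusters surviving Bonferroni over candidate blocks.

    Keeps clusters with ``p_unc < alpha / n_possible_clusters`` and returns
    the sorted union of the ROIs touched by their edges.
    """
    if result.n_possible_clusters <= 0:
        raise ValueError("result lacks a positive n_possible_clusters")
    cut = alpha / result.n_possible_clusters
    rois = set()
    for c in result.clusters:
        if c["p_unc"] < cut:
            for a, b in c["edges"]:
                rois |= {a, b}
    return sorted(rois, key=lambda r: result.ordering.index(r) if r in result.ordering else r)
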