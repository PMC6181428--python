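"""Weighted co-methylation networks over VMR representative probes.

Each VMR is summarised by its most variable probe; the Pearson
correlation matrix of these profiles is raised elementwise to a soft
threshold power (default 6, unsigned: |r|^6) to form the adjacency, which
is transformed into the topological overlap matrix (TOM).  Modules are
branches of the average-linkage dendrogram of 1 - TOM extracted by a
dynamic branch decomposition (minimum size 10), refined by module
eigengenes: members must correlate with their module eigengene at
|kME| >= 0.7, and unassigned VMRs whose best |kME| clears the same bar
are rescued into that module.  Within-module VMR pairs on different
chromosomes are trans associations, cis otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .core_io import BetaMatrix, logger
from .vmr_detection import VMRSet


@dataclass
class NetworkParams:
    soft_power: int = 6
    candidate_powers: tuple = tuple(range(1, 21))
    scale_free_fit_min: float = 0.8
    min_module_size: int = 10
    kme_min: float = 0.7
    edge_abs_r_min: float = 0.7
    min_pairwise_samples: int = 10
    reassign_by_kme: bool = True
    # a branch counts as a module only if its mean internal dissimilarity is
    # below branch_gap times the height at which it merges with its sibling;
    # loose branches (internal dissimilarity ~ merge height) stay unassigned
    branch_gap: float = 0.95

    def __post_init__(self) -> None:
        if self.soft_power < 1:
            raise ValueError("soft_power must be >= 1")


def representative_matrix(beta: BetaMatrix, vmrs: VMRSet) -> pd.DataFrame:
    """Samples x VMRs matrix of each VMR's representative-probe betas."""
    cols = {}
    for v in vmrs.vmrs:
        pid = v.representative_probe_id
        if pid not in beta.values.columns:
            raise KeyError(f"representative probe {pid} of {v.vmr_id} absent from beta")
        cols[v.vmr_id] = beta.values[pid]
    return pd.DataFrame(cols, index=beta.values.index)


def correlation_matrix(rep: pd.DataFrame, min_pairwise_samples: int = 10) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations; under-observed pairs set to 0."""
    if rep.isna().any().any():
        r = rep.corr(method="pearson", min_periods=min_pairwise_samples)
        n_flagged = int(r.isna().sum().sum())
        if n_flagged:
            logger.warning("%d VMR pairs with < %d overlapping samples; r set to 0",
                           n_flagged // 2, min_pairwise_samples)
        r = r.fillna(0.0)
    else:
        x = rep.to_numpy()
        with np.errstate(invalid="ignore"):
            r = pd.DataFrame(np.corrcoef(x, rowvar=False), index=rep.columns,
                             columns=rep.columns).fillna(0.0)
    np.fill_diagonal(r.values, 1.0)
    return r


def adjacency(r: pd.DataFrame, power: int = 6) -> pd.DataFrame:
    """Unsigned soft-threshold adjacency |r|^power."""
    return np.abs(r) ** power


def scale_free_fit(r: pd.DataFrame, candidate_powers=None,
                   params: NetworkParams | None = None) -> tuple[pd.DataFrame, int]:
    """Scale-free topology fit index per soft power, and the chosen power.

    For each power the node connectivity is k_i = sum_{j != i} |r_ij|^p;
    k is binned into 10 equal-width bins and the index is the squared
    Pearson correlation between log10(mean k per bin) and log10(bin
    frequency).  The chosen power is the smallest whose index reaches
    ``scale_free_fit_min``; if none qualifies (or the fit is undefined)
    the default soft power is used.
    """
    params = params or NetworkParams()
    powers = list(candidate_powers or params.candidate_powers)
    rows = []
    absr = np.abs(r.to_numpy())
    np.fill_diagonal(absr, 0.0)
    for p in powers:
        a = absr ** p
        k = a.sum(axis=0)
        fit = np.nan
        if np.ptp(k) > 0:
            edges = np.linspace(k.min(), k.max(), 11)
            which = np.clip(np.digitize(k, edges[1:-1]), 0, 9)
            mean_k, freq = [], []
            for b in range(10):
                sel = which == b
                if sel.sum() > 0 and k[sel].mean() > 0:
                    mean_k.append(k[sel].mean())
                    freq.append(sel.sum())
            if len(mean_k) >= 3:
                lx, ly = np.log10(mean_k), np.log10(freq)
                if np.ptp(lx) > 0 and np.ptp(ly) > 0:
                    fit = float(np.corrcoef(lx, ly)[0, 1] ** 2)
        rows.append({"power": p, "fit_index": fit, "mean_connectivity": float(k.mean())})
    table = pd.DataFrame(rows)
    ok = table.dropna(subset=["fit_index"])
    ok = ok[ok["fit_index"] >= params.scale_free_fit_min]
    if len(ok):
        chosen = int(ok["power"].min())
    else:
        chosen = params.soft_power
        logger.warning("no candidate power reaches fit %.2f; falling back to %d",
                       params.scale_free_fit_min, chosen)
    return table, chosen


def tom(a: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Unsigned topological overlap matrix.

    TOM_ij = (sum_u A_iu A_uj + A_ij) / (min(k_i, k_j) + 1 - A_ij) for
    i != j with k_i = sum_{u != i} A_iu; TOM_ii = 1.
    """
    A = np.asarray(a, dtype=float).copy()
    if A.shape[0] != A.shape[1] or not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("adjacency must be square and symmetric")
    np.fill_diagonal(A, 0.0)
    k = A.sum(axis=0)
    L = A @ A  # diagonal of A is zero, so u == i and u == j terms vanish
    num = L + A
    den = np.minimum.outer(k, k) + 1.0 - A
    t = num / den
    np.fill_diagonal(t, 1.0)
    return t


@dataclass
class ModuleAssignment:
    labels: pd.Series                       # vmr_id -> module int (0 = unassigned)
    eigengenes: pd.DataFrame | None = None  # samples x modules
    kme: pd.DataFrame | None = None         # vmr x modules Pearson r
    cis_trans: pd.DataFrame | None = None

    def members(self, module: int) -> list:
        return list(self.labels.index[self.labels == module])

    @property
    def module_ids(self) -> list:
        return sorted(set(self.labels) - {0})


def _mean_intra(d: np.ndarray, leaves: list) -> float:
    if len(leaves) < 2:
        return 0.0
    sub = d[np.ix_(leaves, leaves)]
    n = len(leaves)
    return float((sub.sum() - np.trace(sub)) / (n * (n - 1)))


def detect_modules(tom_matrix: np.ndarray, params: NetworkParams | None = None,
                   vmr_ids=None) -> ModuleAssignment:
    """Dynamic branch decomposition of the average-linkage tree of 1 - TOM.

    The dendrogram is split recursively at internal merge heights; a
    branch is accepted as a module when it has >= min_module_size leaves,
    none of its sub-branches was itself accepted, and its mean
    intra-branch dissimilarity is below ``branch_gap`` times the height
    at which it merges with its sibling.  Leaves in no accepted branch
    are unassigned (0).
    Labels are ordered by module size, largest first.
    """
    params = params or NetworkParams()
    t = np.asarray(tom_matrix, dtype=float)
    n = t.shape[0]
    ids = list(vmr_ids) if vmr_ids is not None else list(range(n))
    if n < params.min_module_size:
        logger.warning("fewer nodes (%d) than min module size; all unassigned", n)
        return ModuleAssignment(pd.Series(0, index=ids))
    d = 1.0 - t
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2
    z = hierarchy.linkage(squareform(d, checks=False), method="average")
    root = hierarchy.to_tree(z)

    modules: list[list[int]] = []

    def harvest(node, merge_height: float) -> list:
        if node.get_count() < params.min_module_size:
            return []
        subs = []
        if not node.is_leaf():
            subs = harvest(node.left, node.dist) + harvest(node.right, node.dist)
        if subs:
            return subs
        leaves = node.pre_order(lambda x: x.id)
        if _mean_intra(d, leaves) < params.branch_gap * merge_height:
            return [leaves]
        return []

    import sys
    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 2 * n + 100))
    try:
        modules = harvest(root, np.inf)
    finally:
        sys.setrecursionlimit(old)

    modules.sort(key=len, reverse=True)
    labels = pd.Series(0, index=ids)
    for m, leaves in enumerate(modules, start=1):
        labels.iloc[leaves] = m
    return ModuleAssignment(labels)


def module_membership(rep: pd.DataFrame, assignment: ModuleAssignment,
                      params: NetworkParams | None = None) -> ModuleAssignment:
    """Eigengenes, kME, and kME-based membership filtering.

    The module eigengene is the first principal component of the
    z-scored member columns, signed to correlate positively with the mean
    member profile.  Members with |kME| below ``kme_min`` are dropped;
    when ``reassign_by_kme`` is set, unassigned VMRs whose best |kME|
    reaches the bar join that module.  Modules shrinking below
    ``min_module_size`` are dissolved.
    """
    params = params or NetworkParams()
    labels = assignment.labels.copy()

    def eigengene(cols: list) -> np.ndarray:
        x = rep[cols].to_numpy(dtype=float)
        x = np.where(np.isfinite(x), x, np.nanmean(x, axis=0, keepdims=True))
        sd = x.std(axis=0, ddof=0)
        keep = sd > 0
        if keep.sum() == 0:
            return np.zeros(x.shape[0])
        z = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]
        u, s, _ = np.linalg.svd(z, full_matrices=False)
        e = u[:, 0] * s[0]
        if np.corrcoef(e, z.mean(axis=1))[0, 1] < 0:
            e = -e
        return e

    eig = {}
    for m in assignment.module_ids:
        members = assignment.members(m)
        if len(members) < 2:
            labels[labels == m] = 0
            continue
        eig[m] = eigengene(members)
    if not eig:
        return ModuleAssignment(labels.replace(dict.fromkeys(assignment.module_ids, 0)))

    eigdf = pd.DataFrame(eig, index=rep.index)
    kme = pd.DataFrame(index=rep.columns, columns=eigdf.columns, dtype=float)
    x = rep.to_numpy(dtype=float)
    for m in eigdf.columns:
        e = eigdf[m].to_numpy()
        for j, v in enumerate(rep.columns):
            col = x[:, j]
            ok = np.isfinite(col)
            if ok.sum() >= 3 and col[ok].std() > 0 and e[ok].std() > 0:
                kme.loc[v, m] = float(np.corrcoef(col[ok], e[ok])[0, 1])
            else:
                kme.loc[v, m] = np.nan
                logger.warning("kME undefined for %s; removed from module", v)

    for v in rep.columns:
        m = labels[v]
        if m != 0:
            val = kme.loc[v, m]
            if pd.isna(val) or abs(val) < params.kme_min:
                labels[v] = 0
        elif params.reassign_by_kme:
            row = kme.loc[v].abs()
            if row.notna().any() and row.max() >= params.kme_min:
                labels[v] = int(row.idxmax())

    for m in list(eigdf.columns):
        if (labels == m).sum() < params.min_module_size:
            labels[labels == m] = 0
            eigdf = eigdf.drop(columns=m)

    # relabel by size, largest first
    sizes = labels[labels != 0].value_counts()
    remap = {old: new for new, old in enumerate(sizes.index, start=1)}
    labels = labels.map(lambda m: remap.get(m, 0))
    eigdf = eigdf.rename(columns=remap)[sorted(remap.values())] if remap else None
    kme = kme.rename(columns=remap)
    return ModuleAssignment(labels, eigengenes=eigdf, kme=kme)


def classify_cis_trans(assignment: ModuleAssignment, vmrs: VMRSet) -> pd.DataFrame:
    """Label within-module VMR pairs trans (different chromosome) or cis."""
    chrom = {v.vmr_id: v.chrom for v in vmrs.vmrs}
    rows = []
    for m in assignment.module_ids:
        members = assignment.members(m)
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                a, b = members[i], members[j]
                rows.append({"module": m, "vmr_i": a, "vmr_j": b,
                             "relation": "trans" if chrom[a] != chrom[b] else "cis"})
    pairs = pd.DataFrame(rows, columns=["module", "vmr_i", "vmr_j", "relation"])
    return pairs


def cis_trans_summary(pairs: pd.DataFrame) -> pd.DataFrame:
    if pairs.empty:
        return pd.DataFrame(columns=["module", "n_cis", "n_trans"])
    out = (pairs.assign(is_trans=pairs["relation"] == "trans")
           .groupby("module")
           .agg(n_cis=("is_trans", lambda s: int((~s).sum())),
                n_trans=("is_trans", "sum"))
           .reset_index())
    out["n_trans"] = out["n_trans"].astype(int)
    return out


def edge_list(r: pd.DataFrame, vmrs: VMRSet, edge_abs_r_min: float = 0.7) -> pd.DataFrame:
    """Upper-triangle pairs with |r| >= threshold, labelled cis/trans."""
    chrom = {v.vmr_id: v.chrom for v in vmrs.vmrs}
    ids = list(r.columns)
    rows = []
    mat = r.to_numpy()
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if abs(mat[i, j]) >= edge_abs_r_min:
                rows.append({"vmr_i": ids[i], "vmr_j": ids[j], "r": float(mat[i, j]),
                             "relation": "trans" if chrom.get(ids[i]) != chrom.get(ids[j])
                             else "cis"})
    return pd.DataFrame(rows, columns=["vmr_i", "vmr_j", "r", "relation"])
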