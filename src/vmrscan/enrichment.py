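"""Overlap-enrichment statistics for VMRs against annotation tracks.

Three flavours, all built on exact tail probabilities:

* probe-level feature enrichment — hits are probes whose CpG position
  falls inside a feature interval; fold enrichment is
  (k/n) / (K/N) with n VMR probes and N background probes, and the
  p-value the hypergeometric upper tail (lower tail for depletion);
* per-module TFBS enrichment — Fisher's exact 2x2 over VMRs
  (in-module vs not) x (overlapping a TF's sites, extended +/-500 bp,
  vs not);
* GO-term enrichment over VMR-linked genes against the background gene
  universe, hypergeometric with Benjamini-Hochberg FDR control.

VMRs are linked to genes by intersection with +/-2 kb TSS windows, plus
any auxiliary link tables (DHS-expression links, eQTMs) supplied by the
user.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import IntervalSet, ProbeManifest
from .vmr_detection import VMRSet


def _fold(k: int, n: int, K: int, N: int) -> float:
    if K == 0 or n == 0 or N == 0:
        return float("nan")
    return (k / n) / (K / N)


def hypergeom_enrichment(k: int, n: int, K: int, N: int) -> dict:
    """Fold + exact hypergeometric tails for k hits in n draws from a
    population of N with K successes."""
    if not 0 <= k <= min(n, K):
        raise ValueError(f"inconsistent counts k={k}, n={n}, K={K}, N={N}")
    if K == 0:
        return {"k": k, "n": n, "K": K, "N": N, "fold": float("nan"),
                "p_enrich": 1.0, "p_deplete": 1.0, "direction": "undefined"}
    p_enrich = float(stats.hypergeom.sf(k - 1, N, K, n))
    p_deplete = float(stats.hypergeom.cdf(k, N, K, n))
    fold = _fold(k, n, K, N)
    return {"k": k, "n": n, "K": K, "N": N, "fold": fold,
            "p_enrich": p_enrich, "p_deplete": p_deplete,
            "direction": "enriched" if fold >= 1 else "depleted"}


def probe_feature_enrichment(vmr_probes: set, background_probes: set,
                             feature: IntervalSet, manifest: ProbeManifest,
                             name: str | None = None) -> pd.DataFrame:
    """Probe-level enrichment of VMR probes in one feature track.

    Background is the full analysis probe set (the probes in >= 3-probe
    windows); ``vmr_probes`` must be a subset of it.
    """
    if not set(vmr_probes) <= set(background_probes):
        raise ValueError("vmr_probes must be a subset of background_probes")
    tab = manifest.table[manifest.table["probe_id"].isin(background_probes)]
    hit = feature.contains_points(tab["chrom"].to_numpy(), tab["pos"].to_numpy())
    hit = pd.Series(hit, index=tab["probe_id"].to_numpy())
    in_vmr = hit.index.isin(set(vmr_probes))
    k = int(hit[in_vmr].sum())
    n = int(in_vmr.sum())
    K = int(hit.sum())
    N = len(hit)
    res = hypergeom_enrichment(k, n, K, N)
    res["feature"] = name or feature.name
    res["method"] = "hypergeometric"
    return pd.DataFrame([res])


def tfbs_module_enrichment(module_vmrs: VMRSet, all_vmrs: VMRSet,
                           tfbs: IntervalSet, extend_bp: int = 500) -> pd.DataFrame:
    """Per-TF Fisher's exact test of module VMRs overlapping extended TFBS.

    Each TF's binding sites (grouped by the interval label) are extended
    by ``extend_bp`` on both sides; a VMR overlaps when it shares >= 1 bp
    with any extended site.  The 2x2 table is (in module vs not) x
    (overlap vs not) over all VMRs; the one-sided Fisher p tests
    enrichment, and Bonferroni across the tested TFs is reported.
    """
    if len(module_vmrs) == 0:
        raise ValueError("empty module")
    module_ids = {v.vmr_id for v in module_vmrs.vmrs}
    if not module_ids <= {v.vmr_id for v in all_vmrs.vmrs}:
        raise ValueError("module VMRs must be a subset of all VMRs")
    chroms = np.array([v.chrom for v in all_vmrs.vmrs])
    starts = np.array([v.start for v in all_vmrs.vmrs])
    ends = np.array([v.end for v in all_vmrs.vmrs])
    in_module = np.array([v.vmr_id in module_ids for v in all_vmrs.vmrs])

    rows = []
    tf_names = sorted(set(tfbs.table["label"]))
    for tf in tf_names:
        sites = IntervalSet(tf, tfbs.table[tfbs.table["label"] == tf]).extended(extend_bp)
        overlap = sites.overlaps_intervals(chroms, starts, ends)
        a = int((in_module & overlap).sum())        # module, overlapping
        b = int((in_module & ~overlap).sum())
        c = int((~in_module & overlap).sum())
        d = int((~in_module & ~overlap).sum())
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        n_mod, n_rest = a + b, c + d
        fold = _fold(a, n_mod, a + c, n_mod + n_rest)
        rows.append({"tf": tf, "n_module_overlap": a, "n_module": n_mod,
                     "n_background_overlap": a + c, "n_background": n_mod + n_rest,
                     "fold": fold, "odds_ratio": (a * d) / (b * c) if b * c else np.inf,
                     "p_raw": float(p), "method": "fisher"})
    out = pd.DataFrame(rows)
    out["p_bonferroni"] = np.minimum(out["p_raw"] * len(out), 1.0)
    return out.sort_values("p_raw").reset_index(drop=True)


def link_vmrs_to_genes(vmrs: VMRSet, tss: IntervalSet,
                       link_tables: dict | None = None,
                       tss_window_bp: int = 2000) -> pd.DataFrame:
    """Link VMRs to genes by +/-2 kb TSS windows plus auxiliary tables.

    ``tss`` holds single-position TSS intervals labelled with gene ids.
    A VMR [a, b] (1-based closed) links to a gene when it intersects the
    closed window [tss - tss_window_bp, tss + tss_window_bp].
    ``link_tables`` maps a link type (e.g. 'dhs_link', 'eqtm_link') to a
    DataFrame with columns vmr_id, gene_id.
    """
    rows = []
    tss_by_chrom = {}
    for r in tss.table.itertuples(index=False):
        tss_by_chrom.setdefault(r.chrom, []).append((r.start + 1, r.label))  # 1-based
    for v in vmrs.vmrs:
        for pos1, gene in tss_by_chrom.get(v.chrom, ()):
            if v.end >= pos1 - tss_window_bp and v.start <= pos1 + tss_window_bp:
                rows.append({"vmr_id": v.vmr_id, "gene_id": gene, "link_type": "tss_2kb"})
    if link_tables:
        for link_type, tab in link_tables.items():
            for r in tab.itertuples(index=False):
                rows.append({"vmr_id": r.vmr_id, "gene_id": r.gene_id,
                             "link_type": link_type})
    links = pd.DataFrame(rows, columns=["vmr_id", "gene_id", "link_type"]).drop_duplicates()
    return links


def linked_fraction(links: pd.DataFrame, vmrs: VMRSet) -> float:
    if len(vmrs) == 0:
        return float("nan")
    return links["vmr_id"].nunique() / len(vmrs)


def go_enrichment(study_genes: set, universe_genes: set, gene2go: pd.DataFrame,
                  min_term_genes: int = 3) -> pd.DataFrame:
    """Hypergeometric GO enrichment of a study gene set with BH FDR.

    ``gene2go`` has columns gene_id, go_term.  Terms annotated to fewer
    than ``min_term_genes`` universe genes are skipped.  A gene counts
    once regardless of how many VMRs link to it.
    """
    universe = set(universe_genes)
    if not universe:
        raise ValueError("empty gene universe")
    study = set(study_genes) & universe
    if not set(study_genes) <= universe:
        raise ValueError("study genes must be a subset of the universe")
    g2g = gene2go[gene2go["gene_id"].isin(universe)]
    N, n = len(universe), len(study)
    rows = []
    for term, grp in g2g.groupby("go_term"):
        term_genes = set(grp["gene_id"])
        K = len(term_genes)
        if K < min_term_genes:
            continue
        k = len(term_genes & study)
        res = hypergeom_enrichment(k, n, K, N)
        rows.append({"go_term": term, **res})
    out = pd.DataFrame(rows)
    if len(out):
        out["q_bh"] = multipletests(out["p_enrich"], method="fdr_bh")[1]
        out = out.sort_values("p_enrich").reset_index(drop=True)
    return out
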