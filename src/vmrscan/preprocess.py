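"""Probe/sample filtering and quantile normalization ahead of VMR calling.

Filters follow array-QC practice: per-cell detection-p masking, removal
of sex-chromosome probes, of probes whose CpG (or the 5 bp immediately
upstream) carries a common SNP, of probes inside a copy-number-variant
mask, and finally of probes failing in too large a fraction of samples.
The order is fixed (detection-p masking, sex-chromosome, SNP, CNV,
sample-fail drop) and each step's removals are counted in the report so
the numbers are interpretable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import BetaMatrix, IntervalSet, ProbeManifest, SEX_CHROMS, SchemaError, logger


@dataclass
class FilterParams:
    detection_p_max: float = 0.01
    sample_fail_frac_max: float = 0.05
    snp_maf_min: float = 0.05
    snp_window_upstream_bp: int = 5
    drop_sex_chroms: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.detection_p_max < 1:
            raise ValueError("detection_p_max must be in (0, 1)")
        if not 0 < self.sample_fail_frac_max <= 1:
            raise ValueError("sample_fail_frac_max must be in (0, 1]")


def _snp_hit_probes(manifest: ProbeManifest, snp_sites: IntervalSet,
                    params: FilterParams) -> np.ndarray:
    """Probes whose CpG dinucleotide or 5 bp upstream window holds a SNP.

    The checked window is the 1-based closed interval
    [pos - snp_window_upstream_bp, pos + 1]; pos + 1 covers the G of the
    CpG.  SNP labels parsed as floats are treated as minor allele
    frequencies and compared against ``snp_maf_min``; unparsable labels
    are assumed to pass the frequency threshold.
    """
    tab = snp_sites.table.copy()
    maf = pd.to_numeric(tab["label"], errors="coerce")
    keep = maf.isna() | (maf >= params.snp_maf_min)
    filtered = IntervalSet(snp_sites.name, tab.loc[keep])
    chroms = manifest.table["chrom"].to_numpy()
    pos = manifest.table["pos"].to_numpy()
    start1 = np.maximum(1, pos - params.snp_window_upstream_bp)
    end1 = pos + 1
    return filtered.overlaps_intervals(chroms, start1, end1)


def filter_probes(beta: BetaMatrix, manifest: ProbeManifest,
                  detp: pd.DataFrame | None = None,
                  snp_sites: IntervalSet | None = None,
                  cnv_mask: IntervalSet | None = None,
                  params: FilterParams | None = None):
    """Apply the probe filters; returns (filtered BetaMatrix, report dict)."""
    params = params or FilterParams()
    vals = beta.values.copy()
    report = {"n_probes_in": vals.shape[1], "n_samples": vals.shape[0]}

    if detp is not None:
        if detp.shape != beta.values.shape or list(detp.columns) != list(vals.columns):
            raise SchemaError("detection-p matrix shape/columns do not match beta")
        masked = detp.to_numpy() > params.detection_p_max
        report["n_cells_masked_detp"] = int(masked.sum())
        vals = vals.mask(pd.DataFrame(masked, index=vals.index, columns=vals.columns))
    else:
        report["n_cells_masked_detp"] = 0

    pos_map = manifest.positions()
    probe_chrom = pos_map["chrom"].reindex(vals.columns)

    if params.drop_sex_chroms:
        sex_probes = probe_chrom.isin(SEX_CHROMS)
        report["n_dropped_sex_chrom"] = int(sex_probes.sum())
        vals = vals.loc[:, ~sex_probes.to_numpy()]
    else:
        report["n_dropped_sex_chrom"] = 0

    if snp_sites is not None and len(snp_sites):
        sub = manifest.subset(vals.columns)
        hit = pd.Series(_snp_hit_probes(sub, snp_sites, params),
                        index=sub.probe_ids).reindex(vals.columns).fillna(False)
        report["n_dropped_snp"] = int(hit.sum())
        vals = vals.loc[:, ~hit.to_numpy()]
    else:
        report["n_dropped_snp"] = 0

    if cnv_mask is not None and len(cnv_mask):
        sub = manifest.subset(vals.columns)
        chroms = sub.table["chrom"].to_numpy()
        pos = sub.table["pos"].to_numpy()
        hit = pd.Series(cnv_mask.contains_points(chroms, pos),
                        index=sub.probe_ids).reindex(vals.columns).fillna(False)
        report["n_dropped_cnv"] = int(hit.sum())
        vals = vals.loc[:, ~hit.to_numpy()]
    else:
        report["n_dropped_cnv"] = 0

    fail_frac = vals.isna().mean(axis=0)
    failed = fail_frac > params.sample_fail_frac_max
    report["n_dropped_sample_fail"] = int(failed.sum())
    vals = vals.loc[:, ~failed.to_numpy()]

    report["n_probes_out"] = vals.shape[1]
    dropped = (report["n_dropped_sex_chrom"] + report["n_dropped_snp"]
               + report["n_dropped_cnv"] + report["n_dropped_sample_fail"])
    assert report["n_probes_in"] - dropped == report["n_probes_out"]
    return BetaMatrix(vals, beta.sample_meta.copy()), report


def quantile_normalize(beta: BetaMatrix) -> BetaMatrix:
    """Replace each sample's values by the mean of order statistics.

    With complete data every sample ends up with the identical sorted
    vector (the column-wise mean of the per-sample sorted values); tied
    values receive the average of the tied reference entries.  Samples
    with missing values are mapped through rank interpolation against the
    same reference distribution.
    """
    vals = beta.values.to_numpy(dtype=float).copy()
    n, m = vals.shape
    if n < 2:
        logger.warning("quantile_normalize: single sample, no-op")
        return BetaMatrix(beta.values.copy(), beta.sample_meta.copy())

    grid = (np.arange(m) + 0.5) / m
    per_sample_q = np.empty((n, m))
    counts = np.empty(n, dtype=int)
    for i in range(n):
        row = vals[i]
        obs = np.sort(row[np.isfinite(row)])
        counts[i] = obs.size
        if obs.size == 0:
            raise ValueError("sample with no observed values")
        if obs.size == m:
            per_sample_q[i] = obs
        else:
            p = (np.arange(obs.size) + 0.5) / obs.size
            per_sample_q[i] = np.interp(grid, p, obs)
    ref = per_sample_q.mean(axis=0)

    out = np.full_like(vals, np.nan)
    for i in range(n):
        row = vals[i]
        ok = np.isfinite(row)
        x = row[ok]
        k = x.size
        ser = pd.Series(x).rank(method="average").to_numpy()  # 1-based, ties averaged
        if k == m:
            out[i, ok] = np.interp((ser - 0.5) / m, grid, ref)
        else:
            out[i, ok] = np.interp((ser - 0.5) / k, grid, ref)
    res = pd.DataFrame(np.clip(out, 0.0, 1.0), index=beta.values.index,
                       columns=beta.values.columns)
    return BetaMatrix(res, beta.sample_meta.copy())
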