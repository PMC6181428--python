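"""Statistics separating heritable from environmental methylation variability.

Four views of the same question — how much of the variability captured by
VMRs tracks the environment rather than the genotype:

* monozygotic-twin discordance: per-CpG mean |beta_twin1 - beta_twin2|,
  a genotype-free measure of non-genetic variability;
* exposure (season-of-conception style) tests: per-CpG two-sample
  Student's t between exposure groups;
* heritability overlay: user-supplied per-probe heritability estimates
  compared between VMR and non-VMR probes;
* isogenic time-course VMR calling: the population caller run on a small
  cultured series (no sex stratification, no quantile normalization),
  with a per-VMR Spearman trend against the time index.

VMR-vs-background contrasts use the Wilcoxon rank-sum test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import BetaMatrix, ProbeManifest
from .vmr_detection import VMRParams, VMRSet, call_vmrs, enumerate_windows, probe_sd


def twin_discordance(beta: BetaMatrix, pair_map: dict | None = None) -> pd.DataFrame:
    """Per-probe mean absolute beta difference within twin pairs.

    ``pair_map`` maps pair id -> (sample_id_1, sample_id_2); when omitted
    it is built from the ``twin_pair_id`` metadata column.  Pairs with
    anything other than two samples raise.  Per probe, only pairs with
    both values present contribute.
    """
    if pair_map is None:
        meta = beta.sample_meta
        if "twin_pair_id" not in meta.columns:
            raise ValueError("no twin_pair_id metadata and no pair_map given")
        pair_map = {}
        for pid, grp in meta.groupby("twin_pair_id"):
            pair_map[pid] = tuple(grp.index)
    for pid, members in pair_map.items():
        if len(members) != 2:
            raise ValueError(f"twin pair {pid} has {len(members)} samples, expected 2")
    diffs = []
    for pid, (a, b) in pair_map.items():
        diffs.append(np.abs(beta.values.loc[a].to_numpy()
                            - beta.values.loc[b].to_numpy()))
    diffs = np.vstack(diffs)
    n_pairs = np.isfinite(diffs).sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean_abs = np.nanmean(diffs, axis=0)
    return pd.DataFrame({"probe_id": beta.values.columns,
                         "mean_abs_discordance": mean_abs,
                         "n_pairs": n_pairs})


def compare_vmr_vs_background(track: pd.Series, vmr_probes: set,
                              background_probes: set) -> dict:
    """Wilcoxon rank-sum contrast of a per-probe scalar, VMR vs non-VMR.

    ``background_probes`` must exclude the VMR probes.  Returns two-sided
    and one-sided (VMR greater) p-values plus group medians and sizes.
    """
    vmr_probes, background_probes = set(vmr_probes), set(background_probes)
    if vmr_probes & background_probes:
        raise ValueError("VMR and background probe sets overlap")
    x = track.loc[track.index.isin(vmr_probes)].dropna().to_numpy()
    y = track.loc[track.index.isin(background_probes)].dropna().to_numpy()
    if x.size == 0 or y.size == 0:
        raise ValueError("empty VMR or background group")
    two = stats.mannwhitneyu(x, y, alternative="two-sided")
    one = stats.mannwhitneyu(x, y, alternative="greater")
    return {"n_vmr": int(x.size), "n_background": int(y.size),
            "median_vmr": float(np.median(x)),
            "median_background": float(np.median(y)),
            "p_two_sided": float(two.pvalue), "p_vmr_greater": float(one.pvalue)}


def seasonal_test(beta: BetaMatrix, group_labels: pd.Series | None = None,
                  equal_var: bool = True, min_per_group: int = 3) -> pd.DataFrame:
    """Per-probe two-sample Student's t-test between two exposure groups.

    ``group_labels`` (defaulting to the ``group`` metadata column) must
    take exactly two values.  Probes with fewer than ``min_per_group``
    non-missing values in either group get NaN statistics.  Welch's
    version is available via ``equal_var=False``.
    """
    if group_labels is None:
        group_labels = beta.sample_meta["group"]
    groups = [g for g in pd.unique(group_labels.dropna())]
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {groups}")
    g1 = beta.values.loc[(group_labels == groups[0]).to_numpy()]
    g2 = beta.values.loc[(group_labels == groups[1]).to_numpy()]
    res = stats.ttest_ind(g1.to_numpy(), g2.to_numpy(), axis=0,
                          equal_var=equal_var, nan_policy="omit")
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    n1 = g1.notna().sum(axis=0).to_numpy()
    n2 = g2.notna().sum(axis=0).to_numpy()
    bad = (n1 < min_per_group) | (n2 < min_per_group)
    t[bad] = np.nan
    p[bad] = np.nan
    return pd.DataFrame({
        "probe_id": beta.values.columns,
        "t": t, "p": p,
        "neglog10_p": -np.log10(np.clip(p, 1e-320, None)),
        f"mean_{groups[0]}": g1.mean(axis=0).to_numpy(),
        f"mean_{groups[1]}": g2.mean(axis=0).to_numpy(),
    })


def heritability_overlay(h2: pd.Series, vmr_probes: set, background_probes: set,
                         vmr_sets_by_cell_type: dict | None = None) -> dict:
    """Compare per-probe heritability between VMR and non-VMR probes.

    Optionally stratifies VMR probes by sharing across cell types when
    ``vmr_sets_by_cell_type`` (cell type -> VMRSet) is given: probes found
    in more than one cell type's VMRs form the 'shared' stratum.
    """
    finite = h2.dropna()
    covered = len(set(vmr_probes) & set(finite.index))
    if vmr_probes and covered / len(vmr_probes) < 0.5:
        from .core_io import logger
        logger.warning("heritability missing for >50%% of VMR probes")
    out = {"overall": compare_vmr_vs_background(h2, vmr_probes, background_probes)}
    if vmr_sets_by_cell_type:
        counts: dict = {}
        for vs in vmr_sets_by_cell_type.values():
            for p in vs.probe_ids:
                counts[p] = counts.get(p, 0) + 1
        shared = {p for p, c in counts.items() if c > 1}
        specific = {p for p, c in counts.items() if c == 1}
        if shared and specific:
            sh = h2.loc[h2.index.isin(shared)].dropna()
            sp = h2.loc[h2.index.isin(specific)].dropna()
            one = stats.mannwhitneyu(sh, sp, alternative="greater")
            out["shared_vs_specific"] = {
                "n_shared": int(sh.size), "n_specific": int(sp.size),
                "median_shared": float(np.median(sh)),
                "median_specific": float(np.median(sp)),
                "p_shared_greater": float(one.pvalue),
            }
    return out


def timecourse_vmrs(beta: BetaMatrix, manifest: ProbeManifest,
                    params: VMRParams | None = None):
    """VMR calling over a small time-course series plus per-VMR trends.

    The population caller is reused unstratified, with the minimum-sample
    rule relaxed to the series length; quantile normalization is not
    applied at this sample size.  For each called VMR the Spearman
    correlation of its representative probe with the time index is
    reported.
    """
    if beta.n_samples < 3:
        raise ValueError("need >= 3 time-course samples")
    params = params or VMRParams()
    from dataclasses import replace
    params = replace(params, min_samples_per_probe=min(params.min_samples_per_probe,
                                                       beta.n_samples))
    windows, background = enumerate_windows(manifest, params)
    track = probe_sd(beta, stratum="timecourse", params=params)
    vmrs = call_vmrs(track, windows, params, id_prefix="tcVMR")

    if "time_point" in beta.sample_meta.columns:
        t = beta.sample_meta["time_point"].to_numpy(dtype=float)
    else:
        t = np.arange(beta.n_samples, dtype=float)
    rows = []
    for v in vmrs.vmrs:
        y = beta.values[v.representative_probe_id].to_numpy()
        ok = np.isfinite(y)
        rho, p = (np.nan, np.nan)
        if ok.sum() >= 3:
            rho, p = stats.spearmanr(t[ok], y[ok])
        rows.append({"vmr_id": v.vmr_id, "spearman_rho": rho, "p": p})
    return vmrs, pd.DataFrame(rows, columns=["vmr_id", "spearman_rho", "p"])
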