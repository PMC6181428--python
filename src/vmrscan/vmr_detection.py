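"""Sliding-window detection of Variably Methylated Regions (VMRs).

A VMR is a cluster of neighbouring CpG probes whose inter-individual
standard deviation of beta values sits in the top tail (by default the
95th percentile) of the per-probe SD distribution within a stratum.  The
caller anchors a 1 kb window at each probe position, qualifies windows by
an absolute count (>= 3 variable probes) and a fraction (>= 50% of the
window's probes variable), merges overlapping qualifying windows, and
reports the merged region spanning its variable member probes.

Because methylation differs systematically between the sexes (and sex
chromosomes cross-hybridise), calling is run separately per sex and the
two VMR sets are combined by interval union.

Notation: per-probe SD is the sample standard deviation (n-1 denominator)
over non-missing beta values; the percentile threshold is computed over
the background probe set — probes lying in windows with at least
``min_variable_probes`` members — using linear interpolation between
order statistics, and probes exactly at the threshold count as variable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import BetaMatrix, ProbeManifest, logger


@dataclass
class VMRParams:
    window_bp: int = 1000
    min_variable_probes: int = 3
    min_variable_fraction: float = 0.5
    sd_percentile: float = 95.0
    min_samples_per_probe: int = 10

    def __post_init__(self) -> None:
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")
        if self.min_variable_probes < 2:
            raise ValueError("min_variable_probes must be >= 2")
        if not 0 < self.min_variable_fraction <= 1:
            raise ValueError("min_variable_fraction must be in (0, 1]")


@dataclass
class VariabilityTrack:
    """Per-probe SD of beta within one stratum, plus its percentile threshold."""

    sd: pd.Series  # indexed by probe_id; NaN where too few samples
    stratum: str
    n_samples: pd.Series
    percentile_threshold_value: float | None = None


@dataclass
class VMR:
    vmr_id: str
    chrom: str
    start: int  # 1-based closed
    end: int
    probe_ids: list
    representative_probe_id: str
    max_sd: float

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def span_bp(self) -> int:
        return self.end - self.start + 1


@dataclass
class VMRSet:
    vmrs: list
    stratum: str = "pooled"

    def __len__(self) -> int:
        return len(self.vmrs)

    @property
    def probe_ids(self) -> set:
        out = set()
        for v in self.vmrs:
            out.update(v.probe_ids)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "vmr_id": v.vmr_id,
                "chrom": v.chrom,
                "start": v.start,
                "end": v.end,
                "n_probes": v.n_probes,
                "span_bp": v.span_bp,
                "representative_probe_id": v.representative_probe_id,
                "max_sd": v.max_sd,
                "probe_ids": ",".join(v.probe_ids),
            }
            for v in self.vmrs
        ]
        cols = ["vmr_id", "chrom", "start", "end", "n_probes", "span_bp",
                "representative_probe_id", "max_sd", "probe_ids"]
        return pd.DataFrame(rows, columns=cols)


def probe_sd(beta: BetaMatrix, stratum_filter=None, stratum: str = "pooled",
             params: VMRParams | None = None) -> VariabilityTrack:
    """Per-probe sample SD (n-1) over non-missing values within a stratum.

    ``stratum_filter`` is a boolean mask / sample-id list selecting the
    stratum's samples.  Probes with fewer than ``min_samples_per_probe``
    non-missing values get SD = NaN and are excluded from the percentile.
    """
    params = params or VMRParams()
    vals = beta.values
    if stratum_filter is not None:
        vals = vals.loc[stratum_filter]
    if vals.shape[0] == 0:
        raise ValueError(f"empty stratum '{stratum}'")
    n_obs = vals.notna().sum(axis=0)
    sd = vals.std(axis=0, ddof=1)
    min_n = min(params.min_samples_per_probe, vals.shape[0])
    sd = sd.where(n_obs >= max(2, min_n))
    return VariabilityTrack(sd=sd, stratum=stratum, n_samples=n_obs)


@dataclass
class Window:
    chrom: str
    anchor_pos: int          # window is [anchor_pos, anchor_pos + window_bp)
    probe_ids: np.ndarray    # all probes whose position falls in the window
    positions: np.ndarray


def enumerate_windows(manifest: ProbeManifest, params: VMRParams | None = None):
    """Probe-anchored half-open windows and the background probe set.

    One window per probe: ``[pos, pos + window_bp)`` on the probe's
    chromosome.  Windows holding >= ``min_variable_probes`` probes are the
    candidates; the union of their member probes is the background probe
    set used for the SD percentile and for all enrichment analyses.
    """
    params = params or VMRParams()
    windows: list[Window] = []
    background: set = set()
    for chrom, grp in manifest.table.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        ids = grp["probe_id"].to_numpy()
        hi = np.searchsorted(pos, pos + params.window_bp, side="left")
        lo = np.arange(len(pos))
        for i in range(len(pos)):
            if hi[i] - lo[i] >= params.min_variable_probes:
                members = slice(lo[i], hi[i])
                windows.append(Window(chrom, int(pos[i]), ids[members], pos[members]))
                background.update(ids[members])
    return windows, background


def sd_threshold(track: VariabilityTrack, background: set,
                 params: VMRParams | None = None) -> float:
    """Percentile threshold of SD over the background probe set."""
    params = params or VMRParams()
    sds = track.sd.loc[track.sd.index.isin(background)].dropna().to_numpy()
    if sds.size == 0:
        raise ValueError("no probes available for percentile threshold")
    return float(np.percentile(sds, params.sd_percentile))


def call_vmrs(track: VariabilityTrack, windows, params: VMRParams | None = None,
              threshold: float | None = None, id_prefix: str = "VMR") -> VMRSet:
    """Qualify windows, merge overlapping ones, report merged VMRs.

    A window qualifies iff the number of member probes with SD >= threshold
    is at least ``min_variable_probes`` AND at least
    ``min_variable_fraction`` of its member probes are variable.  Probes
    with unknown SD (too few samples) count in the denominator but never
    as variable.  Overlapping qualifying windows on a chromosome are
    merged; the merged VMR spans the min..max position of the variable
    probes it contains, and its representative probe is the variable
    member with the highest SD (ties broken by lowest position).
    """
    params = params or VMRParams()
    if threshold is None:
        background = set()
        for w in windows:
            background.update(w.probe_ids)
        threshold = sd_threshold(track, background, params)
    sd = track.sd

    qualifying = []
    for w in windows:
        w_sd = sd.reindex(w.probe_ids).to_numpy()
        variable = np.nan_to_num(w_sd, nan=-np.inf) >= threshold
        n_var = int(variable.sum())
        if n_var >= params.min_variable_probes and n_var / len(w.probe_ids) >= params.min_variable_fraction:
            qualifying.append((w, variable))

    merged: list[VMR] = []
    current = None  # (chrom, win_start, win_end, var_ids, var_pos)
    for w, variable in qualifying:  # windows arrive sorted by (chrom, anchor)
        win_start, win_end = w.anchor_pos, w.anchor_pos + params.window_bp  # half-open
        var_ids = list(w.probe_ids[variable])
        var_pos = list(w.positions[variable])
        if current is not None and w.chrom == current[0] and win_start < current[2]:
            current = (current[0], current[1], max(current[2], win_end),
                       current[3] + var_ids, current[4] + var_pos)
        else:
            if current is not None:
                merged.append(current)
            current = (w.chrom, win_start, win_end, var_ids, var_pos)
    if current is not None:
        merged.append(current)

    vmrs = []
    for k, (chrom, _ws, _we, ids, pos) in enumerate(merged):
        uniq = {}
        for pid, p in zip(ids, pos):
            uniq[pid] = p
        pids = sorted(uniq, key=lambda pid: uniq[pid])
        positions = np.array([uniq[p] for p in pids])
        sds = sd.reindex(pids).to_numpy()
        best = int(np.lexsort((positions, -sds))[0])
        vmrs.append(
            VMR(
                vmr_id=f"{id_prefix}{k + 1:04d}",
                chrom=chrom,
                start=int(positions.min()),
                end=int(positions.max()),
                probe_ids=pids,
                representative_probe_id=pids[best],
                max_sd=float(sds[best]),
            )
        )
    return VMRSet(vmrs, stratum=track.stratum)


def _merge_vmr_lists(vmr_lists, id_prefix: str = "VMR") -> list:
    """Interval-union merge of VMRs from several strata (member-probe union)."""
    items = []
    for vmrs in vmr_lists:
        for v in vmrs:
            items.append(v)
    items.sort(key=lambda v: (v.chrom, v.start, v.end))
    merged = []
    for v in items:
        if merged and v.chrom == merged[-1]["chrom"] and v.start <= merged[-1]["end"]:
            m = merged[-1]
            m["end"] = max(m["end"], v.end)
            m["members"].append(v)
        else:
            merged.append({"chrom": v.chrom, "start": v.start, "end": v.end,
                           "members": [v]})
    out = []
    for k, m in enumerate(merged):
        probe_pos = {}
        best = None
        for v in m["members"]:
            if best is None or v.max_sd > best.max_sd:
                best = v
        all_ids = []
        for v in m["members"]:
            all_ids.extend(v.probe_ids)
        all_ids = sorted(set(all_ids))
        out.append(
            VMR(
                vmr_id=f"{id_prefix}{k + 1:04d}",
                chrom=m["chrom"],
                start=m["start"],
                end=m["end"],
                probe_ids=all_ids,
                representative_probe_id=best.representative_probe_id,
                max_sd=best.max_sd,
            )
        )
    return out


def call_vmrs_sex_stratified(beta: BetaMatrix, manifest: ProbeManifest,
                             params: VMRParams | None = None) -> VMRSet:
    """Run the caller separately per sex and combine the two VMR sets.

    Each sex gets its own SD track and percentile threshold; the resulting
    VMR sets are unioned, merging overlapping intervals and pooling member
    probes.  If fewer than two samples of each sex are available the
    caller falls back to a single pooled run (logged).
    """
    params = params or VMRParams()
    windows, _bg = enumerate_windows(manifest, params)
    sex = beta.sample_meta["sex"]
    sex_groups = {s: beta.sample_ids[(sex == s).to_numpy()] for s in ("M", "F")}
    usable = {s: ids for s, ids in sex_groups.items() if len(ids) >= 2}
    if len(usable) < 2:
        logger.warning("sex metadata insufficient for stratification; pooled call")
        track = probe_sd(beta, stratum="pooled", params=params)
        return call_vmrs(track, windows, params)
    per_sex = []
    for s, ids in usable.items():
        track = probe_sd(beta, stratum_filter=list(ids), stratum=f"sex={s}", params=params)
        per_sex.append(call_vmrs(track, windows, params, id_prefix=f"{s}_VMR").vmrs)
    combined = _merge_vmr_lists(per_sex)
    return VMRSet(combined, stratum="sex-combined")


def overlap_vmrs(query: VMRSet, reference: VMRSet, min_bp: int = 1,
                 background_probes: set | None = None):
    """Replication of query VMRs in a reference set (>= min_bp overlap).

    Returns a per-query table with a ``replicated`` flag plus a summary
    with the probe-level enrichment of the observed sharing over chance:
    with N background probes, n query-VMR probes and K reference-VMR
    probes, the expected shared count is n*K/N; fold = observed/expected
    and the p-value is the hypergeometric upper tail.
    """
    ref_iv = {}
    for v in reference.vmrs:
        ref_iv.setdefault(v.chrom, []).append((v.start, v.end))
    for chrom in ref_iv:
        ref_iv[chrom].sort()
    q_chroms = {v.chrom for v in query.vmrs}
    r_chroms = set(ref_iv)
    if q_chroms and r_chroms and not (q_chroms & r_chroms):
        logger.warning("query and reference VMRs share no chromosome names")

    rows = []
    for v in query.vmrs:
        hit = False
        for s, e in ref_iv.get(v.chrom, ()):  # 1-based closed both sides
            if min(e, v.end) - max(s, v.start) + 1 >= min_bp:
                hit = True
                break
        rows.append({"vmr_id": v.vmr_id, "chrom": v.chrom, "start": v.start,
                     "end": v.end, "replicated": hit})
    table = pd.DataFrame(rows)

    summary = {"n_query": len(query), "n_replicated": int(table["replicated"].sum())
               if len(table) else 0}
    if background_probes is not None:
        bg = set(background_probes)
        qp = query.probe_ids & bg
        rp = reference.probe_ids & bg
        k = len(qp & rp)
        n, K, N = len(qp), len(rp), len(bg)
        expected = n * K / N if N else float("nan")
        summary.update(
            n_query_probes=n, n_reference_probes=K, n_background=N,
            n_shared_probes=k, expected_shared=expected,
            fold=(k / expected) if expected else float("nan"),
            p_hypergeom=float(stats.hypergeom.sf(k - 1, N, K, n)) if N else float("nan"),
        )
    return table, summary


def shared_vmr_correlation(beta_a: BetaMatrix, beta_b: BetaMatrix,
                           shared_probe_ids, paired_sample_ids) -> pd.DataFrame:
    """Per-probe Pearson r between two cell types across paired individuals.

    ``paired_sample_ids`` is a list of (sample_in_a, sample_in_b) tuples,
    one per individual.  Requires at least 3 pairs.
    """
    pairs = list(paired_sample_ids)
    if len(pairs) < 3:
        raise ValueError("need >= 3 paired individuals")
    ids_a = [a for a, _ in pairs]
    ids_b = [b for _, b in pairs]
    probes = [p for p in shared_probe_ids
              if p in beta_a.values.columns and p in beta_b.values.columns]
    xa = beta_a.values.loc[ids_a, probes].to_numpy()
    xb = beta_b.values.loc[ids_b, probes].to_numpy()
    rs = np.full(len(probes), np.nan)
    for j in range(len(probes)):
        a, b = xa[:, j], xb[:, j]
        ok = np.isfinite(a) & np.isfinite(b)
        if ok.sum() >= 3 and a[ok].std() > 0 and b[ok].std() > 0:
            rs[j] = np.corrcoef(a[ok], b[ok])[0, 1]
    return pd.DataFrame({"probe_id": probes, "r": rs})
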