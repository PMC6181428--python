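"""Core containers and text-format I/O shared by all pipeline stages.

Coordinate conventions
----------------------
Probe positions are 1-based CpG coordinates, as in array manifests.
Internal genomic intervals (VMRs, TSS windows) are 1-based and closed,
``[start, end]``.  :class:`IntervalSet` holds BED-convention intervals
(0-based, half-open) because BED is the interchange format for every
annotation track; conversion happens only at that boundary: an internal
closed interval ``[a, b]`` is written as BED ``(a - 1, b)``.

All tables are plain delimited text (tab by default).  Result tables carry
a provenance block of ``# key: value`` comment lines so that every output
records the stage, parameters and seed that produced it.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from datetime import datetime, timezone

import numpy as np
import pandas as pd

logger = logging.getLogger("vmrscan")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("[vmrscan:%(levelname)s] %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)

MISSING_TOKENS = {"", "NA", "NaN", "nan", "na", "NULL", "null", "."}

SEX_CHROMS = {"chrX", "chrY", "X", "Y"}


class SchemaError(ValueError):
    """A file or table violates the expected schema."""


@dataclass
class ProbeManifest:
    """Ordered per-chromosome table of probe ids and 1-based CpG positions."""

    table: pd.DataFrame  # columns: probe_id, chrom, pos; sorted by (chrom, pos)

    def __post_init__(self) -> None:
        required = {"probe_id", "chrom", "pos"}
        missing = required - set(self.table.columns)
        if missing:
            raise SchemaError(f"manifest missing columns: {sorted(missing)}")
        if self.table["probe_id"].duplicated().any():
            dups = self.table.loc[self.table["probe_id"].duplicated(), "probe_id"]
            raise SchemaError(f"duplicate probe ids: {list(dups.head())}")
        if (self.table["pos"] < 1).any():
            raise SchemaError("probe positions must be >= 1 (1-based)")
        self.table = (
            self.table.sort_values(["chrom", "pos"], kind="mergesort")
            .reset_index(drop=True)
        )

    @property
    def probe_ids(self) -> np.ndarray:
        return self.table["probe_id"].to_numpy()

    def __len__(self) -> int:
        return len(self.table)

    def positions(self) -> pd.DataFrame:
        """probe_id-indexed frame of (chrom, pos)."""
        return self.table.set_index("probe_id")[["chrom", "pos"]]

    def subset(self, probe_ids) -> "ProbeManifest":
        keep = self.table["probe_id"].isin(set(probe_ids))
        return ProbeManifest(self.table.loc[keep].copy())


@dataclass
class BetaMatrix:
    """Samples x probes methylation fractions in [0, 1], plus sample metadata.

    ``values`` is indexed by sample id with one column per probe; NaN marks
    missing measurements.  ``sample_meta`` is indexed by the same sample ids
    and may carry sex ('M'/'F'/'unknown'), cell_type, twin_pair_id, group
    and time_point columns; absent columns are treated as unknown.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame = None

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise SchemaError("duplicate sample ids")
        vals = self.values.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("beta values outside [0, 1]")
        if self.sample_meta is None:
            self.sample_meta = pd.DataFrame(index=self.values.index)
        self.sample_meta = self.sample_meta.reindex(self.values.index)
        if "sex" not in self.sample_meta.columns:
            self.sample_meta["sex"] = "unknown"
        self.sample_meta["sex"] = self.sample_meta["sex"].fillna("unknown")

    @property
    def probe_ids(self) -> np.ndarray:
        return self.values.columns.to_numpy()

    @property
    def sample_ids(self) -> np.ndarray:
        return self.values.index.to_numpy()

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def subset_probes(self, probe_ids) -> "BetaMatrix":
        cols = [p for p in self.values.columns if p in set(probe_ids)]
        return BetaMatrix(self.values[cols].copy(), self.sample_meta.copy())

    def subset_samples(self, sample_ids) -> "BetaMatrix":
        idx = list(sample_ids)
        return BetaMatrix(self.values.loc[idx].copy(), self.sample_meta.loc[idx].copy())


@dataclass
class IntervalSet:
    """Named collection of BED-convention intervals (0-based, half-open)."""

    name: str
    table: pd.DataFrame  # columns: chrom, start, end, label (label optional)

    def __post_init__(self) -> None:
        tab = self.table
        if "label" not in tab.columns:
            tab = tab.assign(label="")
        tab = tab[["chrom", "start", "end", "label"]].copy()
        if len(tab) and (tab["start"] >= tab["end"]).any():
            raise ValueError(f"interval set '{self.name}' has start >= end")
        self.table = tab.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(
            drop=True
        )

    def __len__(self) -> int:
        return len(self.table)

    def _merged_by_chrom(self) -> dict:
        """Disjoint, sorted (starts, ends) arrays per chromosome (labels dropped)."""
        out = {}
        for chrom, grp in self.table.groupby("chrom", sort=False):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            ms, me = [], []
            for s, e in zip(starts, ends):
                if ms and s <= me[-1]:
                    me[-1] = max(me[-1], e)
                else:
                    ms.append(s)
                    me.append(e)
            out[chrom] = (np.asarray(ms), np.asarray(me))
        return out

    def contains_points(self, chroms, positions) -> np.ndarray:
        """Membership of 1-based points in any interval of the set."""
        chroms = np.asarray(chroms)
        pos0 = np.asarray(positions, dtype=np.int64) - 1  # to 0-based
        hit = np.zeros(len(pos0), dtype=bool)
        merged = self._merged_by_chrom()
        for chrom, (ms, me) in merged.items():
            sel = chroms == chrom
            if not sel.any():
                continue
            p = pos0[sel]
            j = np.searchsorted(ms, p, side="right") - 1
            ok = (j >= 0) & (p < me[np.clip(j, 0, None)])
            hit[sel] = ok
        return hit

    def overlaps_intervals(self, chroms, starts1, ends1, min_bp: int = 1) -> np.ndarray:
        """Overlap (>= min_bp) of 1-based closed query intervals with the set."""
        chroms = np.asarray(chroms)
        qs = np.asarray(starts1, dtype=np.int64) - 1  # 0-based half-open
        qe = np.asarray(ends1, dtype=np.int64)
        hit = np.zeros(len(qs), dtype=bool)
        merged = self._merged_by_chrom()
        for chrom, (ms, me) in merged.items():
            sel = chroms == chrom
            if not sel.any():
                continue
            s, e = qs[sel], qe[sel]
            res = np.zeros(len(s), dtype=bool)
            for i in range(len(s)):
                j = np.searchsorted(me, s[i] + min_bp - 1, side="right")
                # first merged interval ending after the query start (+min_bp slack)
                if j < len(ms) and ms[j] <= e[i] - min_bp:
                    res[i] = True
            hit[sel] = res
        return hit

    def extended(self, pad_bp: int) -> "IntervalSet":
        tab = self.table.copy()
        tab["start"] = np.maximum(0, tab["start"] - pad_bp)
        tab["end"] = tab["end"] + pad_bp
        return IntervalSet(self.name, tab)


# ---------------------------------------------------------------------------
# readers / writers


def read_manifest(path, sep: str = "\t") -> ProbeManifest:
    """Read a delimited probe manifest with columns probe_id, chrom, pos."""
    df = pd.read_csv(path, sep=sep)
    required = {"probe_id", "chrom", "pos"}
    if not required <= set(df.columns):
        raise SchemaError(
            f"manifest {path} missing columns {sorted(required - set(df.columns))}"
        )
    try:
        df["pos"] = df["pos"].astype(np.int64)
    except (ValueError, TypeError) as exc:
        raise SchemaError(f"non-integer pos in manifest {path}: {exc}") from exc
    return ProbeManifest(df[["probe_id", "chrom", "pos"]])


def write_manifest(manifest: ProbeManifest, path, sep: str = "\t") -> None:
    manifest.table.to_csv(path, sep=sep, index=False)


def read_beta(path, manifest: ProbeManifest | None = None, meta_path=None,
              sep: str = "\t") -> BetaMatrix:
    """Read a sample x probe beta matrix (first column sample_id).

    Values outside [0, 1] raise; missing tokens become NaN.  Columns not in
    the manifest are dropped with a warning; retained columns are ordered
    as in the manifest.
    """
    df = pd.read_csv(path, sep=sep, index_col=0, na_values=list(MISSING_TOKENS),
                     keep_default_na=True)
    df = df.astype(float)
    vals = df.to_numpy()
    finite = vals[np.isfinite(vals)]
    if finite.size and (finite.min() < 0 or finite.max() > 1):
        raise ValueError(f"beta matrix {path} contains values outside [0, 1]")
    if manifest is not None:
        known = [p for p in manifest.probe_ids if p in df.columns]
        unknown = set(df.columns) - set(manifest.probe_ids)
        if unknown:
            logger.warning("dropping %d probe columns absent from manifest", len(unknown))
        df = df[known]
    meta = None
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep=sep, index_col=0)
    return BetaMatrix(df, meta)


def write_beta(beta: BetaMatrix, path, meta_path=None, sep: str = "\t") -> None:
    beta.values.to_csv(path, sep=sep, index_label="sample_id")
    if meta_path is not None:
        beta.sample_meta.to_csv(meta_path, sep=sep, index_label="sample_id")


def read_bed(path, name: str | None = None) -> IntervalSet:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            label = parts[3] if len(parts) > 3 else ""
            rows.append((parts[0], int(parts[1]), int(parts[2]), label))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])
    return IntervalSet(name or str(path), df)


def write_bed(intervals, path) -> None:
    """Write an IntervalSet or VMRSet as BED (0-based half-open), unmerged.

    VMR intervals are internally 1-based closed; they are converted to
    ``(start - 1, end)`` here.
    """
    from .vmr_detection import VMRSet  # local import to avoid a cycle

    with open(path, "w") as fh:
        if isinstance(intervals, VMRSet):
            fh.write(f"# vmrscan VMR set: stratum={intervals.stratum}\n")
            for vmr in intervals.vmrs:
                fh.write(f"{vmr.chrom}\t{vmr.start - 1}\t{vmr.end}\t{vmr.vmr_id}\n")
        else:
            fh.write(f"# vmrscan interval set: {intervals.name}\n")
            for row in intervals.table.itertuples(index=False):
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.label}\n")


def provenance_block(stage: str, params: dict | None = None, seed=None) -> dict:
    return {
        "stage": stage,
        "parameters": params or {},
        "seed": seed,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }


def write_table(df: pd.DataFrame, path, provenance: dict | None = None,
                sep: str = "\t") -> None:
    """Write a result table with a '# provenance: {...}' comment header."""
    with open(path, "w") as fh:
        if provenance is not None:
            fh.write("# provenance: " + json.dumps(provenance, default=str) + "\n")
        df.to_csv(fh, sep=sep, index=False)


def read_table(path, sep: str = "\t") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, comment="#")
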