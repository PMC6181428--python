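"""Synthetic methylation-array data with planted, recoverable structure.

The generator emulates the statistical features the VMR analyses rely on:

* a manifest of CpG probes falling in tight clusters (most clusters put
  >= 3 probes inside 1 kb, so probe-anchored windows can qualify),
  separated by > 10 kb gaps;
* bimodal baseline methylation (peaks near beta = 0.1 and 0.9 with minor
  intermediate mass) plus iid Gaussian measurement noise, clamped to
  [0.001, 0.999];
* planted VMRs: clusters whose probes share a per-sample latent shift
  z_v ~ N(0, vmr_effect_sd), a subset of which load on shared trans
  module factors, z_v = s(loading * f_m + sqrt(1 - loading^2) * eps_v);
* a sex mean-offset at flagged non-VMR clusters (the confounder that
  motivates sex-stratified calling);
* twin-pair, two-group exposure, and 9-sample time-course designs for
  the environmental analyses.

Every generator takes a seed and returns ground-truth tables, so each
pipeline stage can be scored against what was planted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core_io import BetaMatrix, IntervalSet, ProbeManifest

CLAMP_LO, CLAMP_HI = 0.001, 0.999


@dataclass
class SimConfig:
    n_chrom: int = 5
    probes_per_chrom: int = 4000
    cluster_size_mean: int = 4          # cluster size ~ Poisson(mean) + 1
    intra_cluster_spacing_bp: int = 150
    n_samples: int = 100
    baseline_noise_sd: float = 0.02
    n_planted_vmrs: int = 50
    vmr_effect_sd: float = 0.15
    n_trans_modules: int = 3
    vmrs_per_module: int = 12
    module_loading: float = 0.9
    frac_env_vmrs: float = 0.4
    sex_effect_sd: float = 0.10
    n_sex_clusters: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_chrom", "probes_per_chrom", "cluster_size_mean",
                     "intra_cluster_spacing_bp", "n_samples"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.module_loading <= 1:
            raise ValueError("module_loading must be in (0, 1]")
        if not 0 <= self.frac_env_vmrs <= 1:
            raise ValueError("frac_env_vmrs must be in [0, 1]")


@dataclass
class TruthTables:
    planted_vmr_intervals: IntervalSet          # BED convention
    vmr_probe_ids: dict                         # planted vmr id -> list of probe ids
    vmr_to_module: dict                         # planted vmr id -> module index (1-based)
    env_responsive_vmrs: set
    imprinted_like_vmrs: set
    latent_factors: pd.DataFrame | None = None  # per-sample z_v and module factors
    sex_effect_clusters: list = field(default_factory=list)


def _rng(config: SimConfig, salt: int = 0) -> np.random.Generator:
    return np.random.default_rng((config.seed * 1_000_003 + salt) % (2**63))


def simulate_manifest(config: SimConfig):
    """Clustered probe manifest plus a cluster-truth table.

    Probes are laid down in clusters of size Poisson(cluster_size_mean)+1
    with ~intra_cluster_spacing_bp spacing, separated by gaps > 10 kb.
    Returns (manifest, cluster_truth) where cluster_truth has one row per
    cluster: cluster_id, chrom, start, end, n_probes, probe_ids.
    """
    rng = _rng(config, 1)
    rows, clusters = [], []
    probe_no = 0
    for c in range(config.n_chrom):
        chrom = f"chr{c + 1}"
        pos = 1000
        n_on_chrom = 0
        cl_no = 0
        while n_on_chrom < config.probes_per_chrom:
            size = int(rng.poisson(config.cluster_size_mean)) + 1
            size = min(size, config.probes_per_chrom - n_on_chrom)
            gaps = rng.integers(
                max(10, config.intra_cluster_spacing_bp // 2),
                config.intra_cluster_spacing_bp * 2,
                size=max(size - 1, 0),
            )
            positions = pos + np.concatenate([[0], np.cumsum(gaps)]).astype(np.int64)
            ids = []
            for p in positions:
                probe_no += 1
                pid = f"cg{probe_no:08d}"
                ids.append(pid)
                rows.append((pid, chrom, int(p)))
            cl_no += 1
            clusters.append(
                {
                    "cluster_id": f"{chrom}_cl{cl_no:05d}",
                    "chrom": chrom,
                    "start": int(positions[0]),
                    "end": int(positions[-1]),
                    "n_probes": size,
                    "probe_ids": ids,
                }
            )
            n_on_chrom += size
            pos = int(positions[-1]) + int(rng.integers(12_000, 40_000))
    manifest = ProbeManifest(pd.DataFrame(rows, columns=["probe_id", "chrom", "pos"]))
    return manifest, pd.DataFrame(clusters)


def _baseline_means(n_probes: int, rng: np.random.Generator) -> np.ndarray:
    """Bimodal per-probe baseline: peaks near 0.1 and 0.9, minor middle mass."""
    comp = rng.choice(3, size=n_probes, p=[0.45, 0.45, 0.10])
    mu = np.where(comp == 0, rng.normal(0.1, 0.05, n_probes),
                  np.where(comp == 1, rng.normal(0.9, 0.05, n_probes),
                           rng.normal(0.5, 0.10, n_probes)))
    return np.clip(mu, 0.05, 0.95)


def _eligible_clusters(cluster_truth: pd.DataFrame, window_bp: int = 1000,
                       min_probes: int = 3) -> pd.DataFrame:
    span = cluster_truth["end"] - cluster_truth["start"]
    return cluster_truth[(cluster_truth["n_probes"] >= min_probes) & (span < window_bp)]


def _plant_layout(manifest: ProbeManifest, cluster_truth: pd.DataFrame,
                  config: SimConfig):
    """Choose planted-VMR clusters (module VMRs spread over chromosomes),
    sex-effect clusters, and the env-responsive subset.

    Uses its own seed stream derived only from the config, so every study
    design (population, twins, exposure, time course) simulated from one
    config plants the same loci — cross-design overlap analyses then have
    a real shared signal to find.
    """
    rng = _rng(config, 97)
    eligible = _eligible_clusters(cluster_truth)
    n_module_vmrs = config.n_trans_modules * config.vmrs_per_module
    if config.n_planted_vmrs < n_module_vmrs:
        raise ValueError("n_planted_vmrs smaller than module VMR demand")
    if len(eligible) < config.n_planted_vmrs + config.n_sex_clusters:
        raise ValueError("not enough eligible clusters for requested planting")

    picked = eligible.sample(
        n=config.n_planted_vmrs + config.n_sex_clusters,
        random_state=np.random.RandomState(rng.integers(2**31)),
    )
    vmr_clusters = picked.iloc[: config.n_planted_vmrs]
    sex_clusters = picked.iloc[config.n_planted_vmrs:]

    # module VMRs round-robin across chromosomes so every module is trans
    by_chrom = vmr_clusters.sort_values(["chrom", "start"]).reset_index(drop=True)
    vmr_to_module = {}
    order = by_chrom.index.to_list()
    for rank, idx in enumerate(order):
        vid = f"pVMR{rank + 1:04d}"
        by_chrom.loc[idx, "planted_id"] = vid
        if rank < n_module_vmrs:
            vmr_to_module[vid] = rank % config.n_trans_modules + 1
    env_pool = [v for v in by_chrom["planted_id"]]
    n_env = int(round(config.frac_env_vmrs * config.n_planted_vmrs))
    env_ids = set(rng.choice(env_pool, size=n_env, replace=False)) if n_env else set()
    return by_chrom, sex_clusters, vmr_to_module, env_ids


def _truth_from_layout(by_chrom, sex_clusters, vmr_to_module, env_ids) -> TruthTables:
    iv = pd.DataFrame(
        {
            "chrom": by_chrom["chrom"].to_numpy(),
            "start": by_chrom["start"].to_numpy() - 1,  # BED convention
            "end": by_chrom["end"].to_numpy(),
            "label": by_chrom["planted_id"].to_numpy(),
        }
    )
    vmr_probes = dict(zip(by_chrom["planted_id"], by_chrom["probe_ids"]))
    imprinted = set(list(env_ids)[: max(1, len(env_ids) // 3)]) if env_ids else set()
    return TruthTables(
        planted_vmr_intervals=IntervalSet("planted_vmrs", iv),
        vmr_probe_ids=vmr_probes,
        vmr_to_module=dict(vmr_to_module),
        env_responsive_vmrs=set(env_ids),
        imprinted_like_vmrs=imprinted,
        sex_effect_clusters=sex_clusters["cluster_id"].to_list(),
    )


def _base_matrix(manifest: ProbeManifest, n_samples: int, noise_sd: float,
                 rng: np.random.Generator) -> np.ndarray:
    mu = _baseline_means(len(manifest), rng)
    return mu[None, :] + rng.normal(0.0, noise_sd, size=(n_samples, len(manifest)))


def _probe_index(manifest: ProbeManifest) -> dict:
    return {pid: j for j, pid in enumerate(manifest.probe_ids)}


def simulate_population(manifest: ProbeManifest, cluster_truth: pd.DataFrame,
                        config: SimConfig):
    """Population beta matrix with planted VMRs, trans modules and sex effects.

    Planted VMR probes are re-centred to intermediate baselines (uniform
    0.3-0.7) so the latent shift is not crushed by clamping, mirroring the
    wide per-individual spread real VMRs display.
    """
    rng = _rng(config, 2)
    by_chrom, sex_clusters, vmr_to_module, env_ids = _plant_layout(
        manifest, cluster_truth, config
    )
    truth = _truth_from_layout(by_chrom, sex_clusters, vmr_to_module, env_ids)

    n, m = config.n_samples, len(manifest)
    vals = _base_matrix(manifest, n, config.baseline_noise_sd, rng)
    idx = _probe_index(manifest)

    module_f = rng.normal(size=(n, config.n_trans_modules))
    z_table = {}
    for _, row in by_chrom.iterrows():
        vid = row["planted_id"]
        cols = [idx[p] for p in row["probe_ids"]]
        mod = truth.vmr_to_module.get(vid)
        eps = rng.normal(size=n)
        if mod is not None:
            lam = config.module_loading
            z = config.vmr_effect_sd * (lam * module_f[:, mod - 1]
                                        + np.sqrt(1 - lam**2) * eps)
        else:
            z = config.vmr_effect_sd * eps
        z_table[vid] = z
        base = rng.uniform(0.3, 0.7)
        vals[:, cols] = base + z[:, None] + rng.normal(
            0.0, config.baseline_noise_sd, size=(n, len(cols))
        )

    sexes = np.array(["M", "F"])[np.arange(n) % 2]
    male = sexes == "M"
    for _, row in sex_clusters.iterrows():
        cols = [idx[p] for p in row["probe_ids"]]
        vals[np.ix_(male, cols)] += config.sex_effect_sd

    vals = np.clip(vals, CLAMP_LO, CLAMP_HI)
    samples = [f"S{i + 1:04d}" for i in range(n)]
    beta = BetaMatrix(
        pd.DataFrame(vals, index=samples, columns=manifest.probe_ids),
        pd.DataFrame({"sex": sexes, "cell_type": "synthetic"}, index=samples),
    )
    lat = pd.DataFrame(z_table, index=samples)
    lat[[f"module_{k+1}" for k in range(config.n_trans_modules)]] = module_f
    truth.latent_factors = lat
    return beta, truth


def simulate_twins(manifest: ProbeManifest, cluster_truth: pd.DataFrame,
                   config: SimConfig, n_pairs: int = 100,
                   genetic_share: float = 0.6, env_sd: float = 0.10):
    """Monozygotic twin design: planted VMRs split into twin-shared
    (genetic) and per-individual (environmental) latents.

    ``genetic_share`` is the fraction of planted VMRs whose latent is
    shared exactly within a pair; the rest draw independent per-twin
    latents with SD ``env_sd``.  Measurement noise is always independent.
    """
    if n_pairs < 2:
        raise ValueError("need at least 2 twin pairs")
    rng = _rng(config, 3)
    by_chrom, sex_clusters, vmr_to_module, _ = _plant_layout(
        manifest, cluster_truth, config
    )
    ids = by_chrom["planted_id"].to_list()
    n_gen = int(round(genetic_share * len(ids)))
    genetic = set(rng.choice(ids, size=n_gen, replace=False)) if n_gen else set()
    env = set(ids) - genetic
    truth = _truth_from_layout(by_chrom, sex_clusters, vmr_to_module, env)

    n = 2 * n_pairs
    vals = _base_matrix(manifest, n, config.baseline_noise_sd, rng)
    idx = _probe_index(manifest)
    pair_ids = np.repeat([f"P{i + 1:04d}" for i in range(n_pairs)], 2)
    for _, row in by_chrom.iterrows():
        vid = row["planted_id"]
        cols = [idx[p] for p in row["probe_ids"]]
        if vid in genetic:
            z = np.repeat(rng.normal(0, config.vmr_effect_sd, size=n_pairs), 2)
        else:
            z = rng.normal(0, env_sd, size=n)
        base = rng.uniform(0.3, 0.7)
        vals[:, cols] = base + z[:, None] + rng.normal(
            0.0, config.baseline_noise_sd, size=(n, len(cols))
        )
    vals = np.clip(vals, CLAMP_LO, CLAMP_HI)
    samples = [f"T{i + 1:04d}" for i in range(n)]
    sexes = np.repeat(np.array(["M", "F"])[np.arange(n_pairs) % 2], 2)
    beta = BetaMatrix(
        pd.DataFrame(vals, index=samples, columns=manifest.probe_ids),
        pd.DataFrame({"sex": sexes, "cell_type": "whole_blood",
                      "twin_pair_id": pair_ids}, index=samples),
    )
    return beta, truth


def simulate_exposure(manifest: ProbeManifest, cluster_truth: pd.DataFrame,
                      config: SimConfig, n_per_group: int = 64,
                      delta: float = 0.05):
    """Two balanced exposure groups; env-responsive probes shift by delta
    in the 'rainy' group.  No per-sample latent variation is added, so the
    per-probe SD equals the measurement noise and the group test's effect
    size is delta / baseline_noise_sd.
    """
    rng = _rng(config, 4)
    by_chrom, sex_clusters, vmr_to_module, env_ids = _plant_layout(
        manifest, cluster_truth, config
    )
    truth = _truth_from_layout(by_chrom, sex_clusters, vmr_to_module, env_ids)
    n = 2 * n_per_group
    vals = _base_matrix(manifest, n, config.baseline_noise_sd, rng)
    idx = _probe_index(manifest)
    groups = np.array(["rainy"] * n_per_group + ["dry"] * n_per_group)
    rainy = groups == "rainy"
    # planted clusters sit at intermediate baselines (as in the population
    # design) so the group shift is not attenuated by boundary clamping
    for vid in truth.vmr_probe_ids:
        cols = [idx[p] for p in truth.vmr_probe_ids[vid]]
        base = rng.uniform(0.3, 0.7)
        vals[:, cols] = base + rng.normal(
            0.0, config.baseline_noise_sd, size=(n, len(cols)))
        if vid in truth.env_responsive_vmrs:
            vals[np.ix_(rainy, cols)] += delta
    vals = np.clip(vals, CLAMP_LO, CLAMP_HI)
    samples = [f"G{i + 1:04d}" for i in range(n)]
    beta = BetaMatrix(
        pd.DataFrame(vals, index=samples, columns=manifest.probe_ids),
        pd.DataFrame({"sex": "unknown", "cell_type": "cord_blood",
                      "group": groups}, index=samples),
    )
    return beta, truth


def simulate_timecourse(manifest: ProbeManifest, cluster_truth: pd.DataFrame,
                        config: SimConfig, n_timepoints: int = 9,
                        trend_magnitude: float = 0.3):
    """Isogenic culture time course: env-responsive probes drift linearly,
    beta(t) = beta0 + trend * t/(T-1) + noise; all other probes carry
    noise only.
    """
    if n_timepoints < 3:
        raise ValueError("need >= 3 time points")
    rng = _rng(config, 5)
    by_chrom, sex_clusters, vmr_to_module, env_ids = _plant_layout(
        manifest, cluster_truth, config
    )
    truth = _truth_from_layout(by_chrom, sex_clusters, vmr_to_module, env_ids)
    n = n_timepoints
    vals = _base_matrix(manifest, n, config.baseline_noise_sd, rng)
    idx = _probe_index(manifest)
    t = np.arange(n) / (n - 1)
    for vid in truth.env_responsive_vmrs:
        cols = [idx[p] for p in truth.vmr_probe_ids[vid]]
        base = rng.uniform(0.2, max(0.25, 0.7 - abs(trend_magnitude)))
        vals[:, cols] = base + trend_magnitude * t[:, None] + rng.normal(
            0.0, config.baseline_noise_sd, size=(n, len(cols))
        )
    vals = np.clip(vals, CLAMP_LO, CLAMP_HI)
    samples = [f"TP{i + 1}" for i in range(n)]
    beta = BetaMatrix(
        pd.DataFrame(vals, index=samples, columns=manifest.probe_ids),
        pd.DataFrame({"sex": "M", "cell_type": "fibroblast",
                      "time_point": np.arange(n)}, index=samples),
    )
    return beta, truth


def simulate_annotations(manifest: ProbeManifest, cluster_truth: pd.DataFrame,
                         truth: TruthTables, config: SimConfig,
                         tf_module_frac: float = 0.8,
                         tf_background_frac: float = 0.1,
                         go_enriched_frac: float = 0.8,
                         go_background_frac: float = 0.1):
    """Annotation tracks with planted enrichments.

    Returns (annotation dict of IntervalSet, gene2go DataFrame).  Gene
    models give each cluster a gene (TSS at cluster start, 5'UTR / CDS /
    intron / 3'UTR tiling); CGI classes tile every probe exactly once;
    one transcription factor ('TF_planted') covers ``tf_module_frac`` of
    module-1 planted VMRs versus ``tf_background_frac`` of other clusters;
    imprinted-like intervals cover a subset of env-responsive VMRs; the GO
    table links term 'GO:PLANTED' to module genes at an elevated rate.
    """
    rng = _rng(config, 6)
    genes, tss_rows = [], []
    feature_rows = {k: [] for k in ("tss", "utr5", "cds", "intron", "utr3")}
    for i, row in cluster_truth.iterrows():
        gid = f"GENE{i + 1:05d}"
        genes.append(gid)
        s0 = max(0, row["start"] - 1)  # BED 0-based
        e0 = row["end"]
        length = max(e0 - s0, 600)
        tss_rows.append((row["chrom"], s0, s0 + 1, gid))
        feature_rows["utr5"].append((row["chrom"], s0, s0 + length // 5, gid))
        feature_rows["cds"].append((row["chrom"], s0 + length // 5,
                                    s0 + 3 * length // 5, gid))
        feature_rows["intron"].append((row["chrom"], s0 + 3 * length // 5,
                                       s0 + 4 * length // 5, gid))
        feature_rows["utr3"].append((row["chrom"], s0 + 4 * length // 5,
                                     s0 + length, gid))
    annotations = {
        "tss": IntervalSet("tss", pd.DataFrame(
            tss_rows, columns=["chrom", "start", "end", "label"])),
    }
    for k in ("utr5", "cds", "intron", "utr3"):
        annotations[k] = IntervalSet(k, pd.DataFrame(
            feature_rows[k], columns=["chrom", "start", "end", "label"]))

    # CGI / shore / shelf / sea: an exact partition of each chromosome
    cgi_rows = []
    chrom_max = manifest.table.groupby("chrom")["pos"].max()
    for chrom, grp in cluster_truth.groupby("chrom"):
        bound = int(chrom_max[chrom]) + 5000
        cursor = 0
        for _, row in grp.iterrows():
            is_island = rng.random() < 0.3
            s0, e0 = max(0, row["start"] - 200), row["end"] + 200
            if not is_island:
                continue
            shore_lo = max(cursor, s0 - 2000)
            shelf_lo = max(cursor, s0 - 4000)
            if shelf_lo > cursor:
                cgi_rows.append((chrom, cursor, shelf_lo, "sea"))
            if shore_lo > shelf_lo:
                cgi_rows.append((chrom, shelf_lo, shore_lo, "shelf"))
            if s0 > shore_lo:
                cgi_rows.append((chrom, shore_lo, s0, "shore"))
            cgi_rows.append((chrom, s0, e0, "island"))
            cgi_rows.append((chrom, e0, e0 + 2000, "shore"))
            cgi_rows.append((chrom, e0 + 2000, e0 + 4000, "shelf"))
            cursor = e0 + 4000
        if cursor < bound:
            cgi_rows.append((chrom, cursor, bound, "sea"))
    annotations["cgi"] = IntervalSet("cgi", pd.DataFrame(
        cgi_rows, columns=["chrom", "start", "end", "label"]))

    # TFBS: planted TF at module-1 VMRs, background elsewhere
    module1 = [v for v, m in truth.vmr_to_module.items() if m == 1]
    planted_iv = truth.planted_vmr_intervals.table.set_index("label")
    tf_rows = []
    for vid in module1:
        if rng.random() < tf_module_frac:
            r = planted_iv.loc[vid]
            tf_rows.append((r["chrom"], r["start"], r["end"], "TF_planted"))
    vmr_cluster_starts = set(zip(planted_iv["chrom"], planted_iv["start"]))
    for _, row in cluster_truth.iterrows():
        key = (row["chrom"], row["start"] - 1)
        if key in vmr_cluster_starts:
            continue
        if rng.random() < tf_background_frac:
            tf_rows.append((row["chrom"], row["start"] - 1, row["end"], "TF_planted"))
        if rng.random() < tf_background_frac:
            tf_rows.append((row["chrom"], row["start"] - 1, row["end"], "TF_null"))
    annotations["tfbs"] = IntervalSet("tfbs", pd.DataFrame(
        tf_rows, columns=["chrom", "start", "end", "label"]))

    # imprinted-like regions over a subset of env-responsive VMRs
    imp_rows = []
    for vid in sorted(truth.imprinted_like_vmrs):
        r = planted_iv.loc[vid]
        imp_rows.append((r["chrom"], r["start"], r["end"], f"imprinted_{vid}"))
    annotations["imprinted"] = IntervalSet("imprinted", pd.DataFrame(
        imp_rows, columns=["chrom", "start", "end", "label"]))

    # gene -> GO table with one planted term over module genes
    cluster_by_id = cluster_truth.reset_index(drop=True)
    module_gene_idx = set()
    planted_keys = {(r["chrom"], r["start"]) for _, r in planted_iv.iterrows()
                    if r.name in truth.vmr_to_module}
    for i, row in cluster_by_id.iterrows():
        if (row["chrom"], row["start"] - 1) in planted_keys:
            module_gene_idx.add(i)
    go_rows = []
    for i, gid in enumerate(genes):
        p = go_enriched_frac if i in module_gene_idx else go_background_frac
        if rng.random() < p:
            go_rows.append((gid, "GO:PLANTED"))
        for term in ("GO:RAND1", "GO:RAND2", "GO:RAND3"):
            if rng.random() < 0.15:
                go_rows.append((gid, term))
    gene2go = pd.DataFrame(go_rows, columns=["gene_id", "go_term"])
    return annotations, gene2go
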