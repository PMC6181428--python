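"""VMR caller tests, centred on an independent brute-force window oracle."""

import numpy as np
import pandas as pd
import pytest

from vmrscan.core_io import ProbeManifest
from vmrscan.synthetic import SimConfig, simulate_manifest
from vmrscan.vmr_detection import (VMRParams, VMRSet, call_vmrs,
                                   call_vmrs_sex_stratified, enumerate_windows,
                                   overlap_vmrs, probe_sd, sd_threshold,
                                   shared_vmr_correlation, VariabilityTrack, VMR)

from conftest import make_beta


# ---------------------------------------------------------------------------
# brute-force oracle: evaluate every probe-anchored window independently,
# then merge overlapping qualifying windows and span the variable probes


def brute_force_vmrs(manifest: ProbeManifest, sd: pd.Series, threshold: float,
                     params: VMRParams):
    tab = manifest.table
    qualifying = []  # (chrom, win_start, win_end, set of variable (pos, probe))
    for _, row in tab.iterrows():
        chrom, anchor = row["chrom"], row["pos"]
        members = tab[(tab["chrom"] == chrom) & (tab["pos"] >= anchor)
                      & (tab["pos"] < anchor + params.window_bp)]
        variable = [(p, pid) for p, pid, s in
                    zip(members["pos"], members["probe_id"],
                        sd.reindex(members["probe_id"]))
                    if np.isfinite(s) and s >= threshold]
        n_var = len(variable)
        if (n_var >= params.min_variable_probes
                and n_var / len(members) >= params.min_variable_fraction):
            qualifying.append((chrom, anchor, anchor + params.window_bp,
                               set(variable)))
    merged = []
    for chrom, ws, we, var in qualifying:
        if merged and merged[-1][0] == chrom and ws < merged[-1][2]:
            prev = merged[-1]
            merged[-1] = (chrom, prev[1], max(prev[2], we), prev[3] | var)
        else:
            merged.append((chrom, ws, we, var))
    out = set()
    for chrom, _ws, _we, var in merged:
        positions = sorted(p for p, _ in var)
        out.add((chrom, positions[0], positions[-1],
                 frozenset(pid for _, pid in var)))
    return out


def as_tuples(vmrs: VMRSet) -> set:
    return {(v.chrom, v.start, v.end, frozenset(v.probe_ids)) for v in vmrs.vmrs}


def random_case(seed: int, n_probes=300):
    rng = np.random.default_rng(seed)
    chroms, pos = [], []
    for c in range(rng.integers(1, 4)):
        p = np.sort(rng.choice(np.arange(1, 50_000), size=n_probes // 3,
                               replace=False))
        pos.extend(p)
        chroms.extend([f"chr{c + 1}"] * len(p))
    manifest = ProbeManifest(pd.DataFrame({
        "probe_id": [f"cg{i}" for i in range(len(pos))],
        "chrom": chroms, "pos": pos}))
    sd = pd.Series(rng.gamma(2.0, 0.01, size=len(pos)),
                   index=manifest.probe_ids)
    return manifest, sd


class TestProbeSd:
    def test_constant_probe_has_zero_sd(self):
        b = make_beta(np.full((12, 3), 0.4))
        track = probe_sd(b)
        np.testing.assert_allclose(track.sd, 0, atol=1e-12)

    def test_two_value_hand_computation(self):
        b = make_beta(np.column_stack([np.array([0.2, 0.4])]))
        track = probe_sd(b, params=VMRParams(min_samples_per_probe=2))
        assert track.sd.iloc[0] == pytest.approx(0.1414213562, abs=1e-9)

    def test_percentile_threshold_by_linear_interpolation(self):
        sds = 0.001 * np.arange(1, 101)
        track = VariabilityTrack(sd=pd.Series(sds, index=[f"cg{i}" for i in range(100)]),
                                 stratum="x", n_samples=pd.Series(100, index=range(100)))
        thr = sd_threshold(track, set(track.sd.index))
        assert 0.095 <= thr <= 0.096

    def test_under_sampled_probes_excluded(self):
        vals = np.full((12, 2), 0.5)
        vals[:8, 1] = np.nan  # only 4 observations
        track = probe_sd(make_beta(vals), params=VMRParams(min_samples_per_probe=10))
        assert np.isnan(track.sd.iloc[1]) and not np.isnan(track.sd.iloc[0])

    def test_empty_stratum_errors(self):
        b = make_beta(np.full((4, 2), 0.5))
        with pytest.raises(ValueError, match="stratum"):
            probe_sd(b, stratum_filter=[])


class TestEnumerateWindows:
    def test_window_membership_brute_force_example(self, tiny_manifest):
        windows, background = enumerate_windows(tiny_manifest)
        by_anchor = {(w.chrom, w.anchor_pos): list(w.probe_ids) for w in windows}
        # chr1 probes at 100,500,900,2500: window at 100 holds first three
        assert by_anchor[("chr1", 100)] == ["cg0", "cg1", "cg2"]
        assert ("chr1", 2500) not in by_anchor  # single-probe window dropped
        # chr2 probes at 1000,1200,1400 qualify; 9000 isolated
        assert by_anchor[("chr2", 1000)] == ["cg4", "cg5", "cg6"]
        assert background == {"cg0", "cg1", "cg2", "cg4", "cg5", "cg6"}

    def test_half_open_window_excludes_pos_plus_1000(self):
        m = ProbeManifest(pd.DataFrame({
            "probe_id": ["a", "b", "c"], "chrom": ["chr1"] * 3,
            "pos": [100, 600, 1100]}))
        windows, _ = enumerate_windows(m, VMRParams(min_variable_probes=2))
        w = [w for w in windows if w.anchor_pos == 100][0]
        assert list(w.probe_ids) == ["a", "b"]  # 1100 outside [100, 1100)

    def test_empty_manifest_has_no_windows(self):
        m = ProbeManifest(pd.DataFrame({"probe_id": [], "chrom": [], "pos": []},
                                       dtype=object).astype({"pos": int}))
        windows, background = enumerate_windows(m)
        assert windows == [] and background == set()


class TestCallVmrs:
    def _track(self, manifest, sd_values):
        sd = pd.Series(sd_values, index=manifest.probe_ids)
        return VariabilityTrack(sd=sd, stratum="t",
                                n_samples=pd.Series(50, index=sd.index))

    def test_three_of_four_variable_window_qualifies(self):
        m = ProbeManifest(pd.DataFrame({
            "probe_id": list("abcd"), "chrom": ["chr1"] * 4,
            "pos": [100, 300, 500, 700]}))
        track = self._track(m, [0.2, 0.2, 0.2, 0.01])
        windows, _ = enumerate_windows(m)
        vmrs = call_vmrs(track, windows, threshold=0.1)
        assert len(vmrs) == 1
        assert set(vmrs.vmrs[0].probe_ids) == {"a", "b", "c"}

    def test_two_of_six_variable_fails_both_criteria(self):
        m = ProbeManifest(pd.DataFrame({
            "probe_id": list("abcdef"), "chrom": ["chr1"] * 6,
            "pos": [100, 200, 300, 400, 500, 600]}))
        track = self._track(m, [0.2, 0.2, 0.01, 0.01, 0.01, 0.01])
        windows, _ = enumerate_windows(m)
        assert len(call_vmrs(track, windows, threshold=0.1)) == 0

    def test_three_of_seven_fails_fraction_criterion_only(self):
        m = ProbeManifest(pd.DataFrame({
            "probe_id": list("abcdefg"), "chrom": ["chr1"] * 7,
            "pos": [100, 200, 300, 400, 500, 600, 700]}))
        track = self._track(m, [0.2, 0.2, 0.2, 0.01, 0.01, 0.01, 0.01])
        windows, _ = enumerate_windows(m)
        # the full 7-probe window fails 3/7 < 0.5, but no sub-window of the
        # three variable probes plus <=3 others qualifies either way: the
        # window anchored at 'a' holds all 7 -> fails; anchored at 'e' holds
        # 3 non-variable -> fails
        vmrs = call_vmrs(track, windows, threshold=0.1)
        oracle = brute_force_vmrs(m, track.sd, 0.1, VMRParams())
        assert as_tuples(vmrs) == oracle

    def test_representative_probe_is_highest_sd(self):
        m = ProbeManifest(pd.DataFrame({
            "probe_id": list("abc"), "chrom": ["chr1"] * 3,
            "pos": [100, 200, 300]}))
        track = self._track(m, [0.12, 0.30, 0.2])
        windows, _ = enumerate_windows(m)
        vmrs = call_vmrs(track, windows, threshold=0.1)
        assert vmrs.vmrs[0].representative_probe_id == "b"
        assert vmrs.vmrs[0].max_sd == pytest.approx(0.30)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_oracle_on_random_tracks(self, seed):
        manifest, sd = random_case(seed)
        params = VMRParams()
        windows, background = enumerate_windows(manifest, params)
        track = VariabilityTrack(sd=sd, stratum="t",
                                 n_samples=pd.Series(50, index=sd.index))
        thr = sd_threshold(track, background, params)
        vmrs = call_vmrs(track, windows, params, threshold=thr)
        assert as_tuples(vmrs) == brute_force_vmrs(manifest, sd, thr, params)

    def test_called_vmrs_satisfy_criteria_post_hoc(self):
        manifest, sd = random_case(99)
        params = VMRParams()
        windows, background = enumerate_windows(manifest, params)
        track = VariabilityTrack(sd=sd, stratum="t",
                                 n_samples=pd.Series(50, index=sd.index))
        thr = sd_threshold(track, background, params)
        vmrs = call_vmrs(track, windows, params, threshold=thr)
        tab = manifest.table
        for v in vmrs.vmrs:
            found = False
            for anchor in tab.loc[(tab["chrom"] == v.chrom), "pos"]:
                members = tab[(tab["chrom"] == v.chrom) & (tab["pos"] >= anchor)
                              & (tab["pos"] < anchor + params.window_bp)]
                n_var = int((sd.reindex(members["probe_id"]) >= thr).sum())
                if (n_var >= params.min_variable_probes
                        and n_var / len(members) >= params.min_variable_fraction
                        and members["pos"].between(v.start, v.end).any()):
                    found = True
                    break
            assert found, f"{v.vmr_id} has no qualifying constituent window"

    def test_monotonicity_in_percentile_and_min_probes(self):
        manifest, sd = random_case(7)
        track = VariabilityTrack(sd=sd, stratum="t",
                                 n_samples=pd.Series(50, index=sd.index))
        counts = []
        for pct in (80, 90, 95, 99):
            params = VMRParams(sd_percentile=pct)
            windows, background = enumerate_windows(manifest, params)
            thr = sd_threshold(track, background, params)
            counts.append(len(call_vmrs(track, windows, params, threshold=thr)))
        assert counts == sorted(counts, reverse=True)

        params3 = VMRParams(min_variable_probes=3)
        params2 = VMRParams(min_variable_probes=2)
        w3, b3 = enumerate_windows(manifest, params3)
        w2, b2 = enumerate_windows(manifest, params2)
        thr = sd_threshold(track, b3, params3)
        assert (len(call_vmrs(track, w2, params2, threshold=thr))
                >= len(call_vmrs(track, w3, params3, threshold=thr)))


class TestSexStratified:
    def _beta_with_sex_vmr(self, seed=0):
        """120 samples, 25 clusters of 3 probes; the first cluster is
        variable in males only.  Enough background probes that the 95th
        percentile falls below the planted SD."""
        rng = np.random.default_rng(seed)
        n_clusters = 25
        pos = np.concatenate([[20_000 * c + 100, 20_000 * c + 300,
                               20_000 * c + 500] for c in range(n_clusters)])
        m = ProbeManifest(pd.DataFrame({
            "probe_id": [f"cg{i}" for i in range(3 * n_clusters)],
            "chrom": ["chr1"] * (3 * n_clusters),
            "pos": pos.astype(int)}))
        vals = 0.5 + rng.normal(0, 0.02, (120, 3 * n_clusters))
        sexes = ["M"] * 60 + ["F"] * 60
        z = rng.normal(0, 0.2, 60)
        for j in range(3):  # first cluster variable in males only
            vals[:60, j] += z
        beta = make_beta(np.clip(vals, 0, 1), probe_ids=list(m.probe_ids),
                         sexes=sexes)
        return m, beta

    def test_male_only_vmr_present_in_combined_set(self):
        m, beta = self._beta_with_sex_vmr()
        vmrs = call_vmrs_sex_stratified(beta, m, VMRParams())
        assert any(v.start <= 100 and v.end >= 500 for v in vmrs.vmrs)

    def test_combined_set_contains_each_single_sex_call(self):
        m, beta = self._beta_with_sex_vmr(3)
        params = VMRParams()
        combined = call_vmrs_sex_stratified(beta, m, params)
        windows, _ = enumerate_windows(m, params)
        for sex in ("M", "F"):
            ids = beta.sample_ids[(beta.sample_meta["sex"] == sex).to_numpy()]
            track = probe_sd(beta, stratum_filter=list(ids), stratum=sex,
                             params=params)
            single = call_vmrs(track, windows, params)
            for v in single.vmrs:
                assert any(c.chrom == v.chrom and c.start <= v.start
                           and c.end >= v.end for c in combined.vmrs)

    def test_overlapping_sex_intervals_merge(self):
        from vmrscan.vmr_detection import _merge_vmr_lists
        male = [VMR("m1", "chr1", 1000, 1800, ["a", "b", "c"], "a", 0.3)]
        female = [VMR("f1", "chr1", 1500, 2300, ["c", "d", "e"], "d", 0.2)]
        merged = _merge_vmr_lists([male, female])
        assert len(merged) == 1
        v = merged[0]
        assert (v.start, v.end) == (1000, 2300)
        assert set(v.probe_ids) == {"a", "b", "c", "d", "e"}
        assert v.representative_probe_id == "a"  # highest max_sd wins

    def test_unknown_sex_falls_back_to_pooled(self):
        m, beta = self._beta_with_sex_vmr()
        beta.sample_meta["sex"] = "unknown"
        vmrs = call_vmrs_sex_stratified(beta, m, VMRParams())
        assert vmrs.stratum == "pooled"


class TestOverlapVmrs:
    def test_single_shared_bp_counts_as_replication(self):
        q = VMRSet([VMR("q1", "chr1", 100, 200, ["a"], "a", 0.1)])
        r = VMRSet([VMR("r1", "chr1", 200, 300, ["b"], "b", 0.1)])
        table, summary = overlap_vmrs(q, r)
        assert table["replicated"].all() and summary["n_replicated"] == 1

    def test_adjacent_but_disjoint_intervals_do_not_replicate(self):
        q = VMRSet([VMR("q1", "chr1", 100, 199, ["a"], "a", 0.1)])
        r = VMRSet([VMR("r1", "chr1", 200, 300, ["b"], "b", 0.1)])
        table, _ = overlap_vmrs(q, r)
        assert not table["replicated"].any()

    def test_identical_sets_fully_replicate_with_large_fold(self):
        vmrs = [VMR(f"v{i}", "chr1", 1000 * i + 1, 1000 * i + 400,
                    [f"p{i}a", f"p{i}b"], f"p{i}a", 0.1) for i in range(5)]
        q, r = VMRSet(vmrs), VMRSet(list(vmrs))
        background = {f"p{i}{s}" for i in range(50) for s in "ab"}
        table, summary = overlap_vmrs(q, r, background_probes=background)
        assert summary["n_replicated"] == 5
        assert summary["fold"] > 5
        assert summary["p_hypergeom"] < 1e-6

    def test_fold_and_p_match_permutation_oracle(self):
        # 50 single-probe clusters; 10 query and 10 reference VMR clusters
        # with 5 truly shared: permutation of cluster labels gives the
        # chance distribution of shared-probe counts
        rng = np.random.default_rng(0)
        clusters = [(f"chr{1 + i % 4}", 10_000 * (i + 1)) for i in range(50)]
        probes = {i: [f"c{i}a"] for i in range(50)}
        q_idx = list(range(10))
        r_idx = list(range(5)) + list(range(20, 25))

        def vmr_set(idx, tag):
            return VMRSet([VMR(f"{tag}{i}", clusters[i][0], clusters[i][1],
                               clusters[i][1] + 300, probes[i], probes[i][0], 0.1)
                           for i in idx])

        background = {p for ps in probes.values() for p in ps}
        _, summary = overlap_vmrs(vmr_set(q_idx, "q"), vmr_set(r_idx, "r"),
                                  background_probes=background)
        obs_shared = summary["n_shared_probes"]
        perm_shared = []
        for _ in range(10_000):
            qi = set(rng.choice(50, 10, replace=False))
            ri = set(rng.choice(50, 10, replace=False))
            perm_shared.append(len(qi & ri))
        perm_shared = np.array(perm_shared)
        assert summary["expected_shared"] == pytest.approx(perm_shared.mean(),
                                                           rel=0.1)
        p_perm = (np.sum(perm_shared >= obs_shared) + 1) / (len(perm_shared) + 1)
        assert summary["p_hypergeom"] == pytest.approx(p_perm, rel=0.5, abs=2e-3)


class TestSharedVmrCorrelation:
    def test_identity_gives_all_ones(self):
        rng = np.random.default_rng(1)
        a = make_beta(rng.uniform(0.2, 0.8, (10, 4)))
        pairs = [(s, s) for s in a.sample_ids]
        res = shared_vmr_correlation(a, a, list(a.probe_ids), pairs)
        np.testing.assert_allclose(res["r"], 1.0)

    def test_mirror_gives_minus_one(self):
        rng = np.random.default_rng(2)
        a = make_beta(rng.uniform(0.2, 0.8, (10, 4)))
        b = make_beta(1 - a.values.to_numpy())
        pairs = [(s, s) for s in a.sample_ids]
        res = shared_vmr_correlation(a, b, list(a.probe_ids), pairs)
        np.testing.assert_allclose(res["r"], -1.0)

    def test_attenuation_matches_shared_latent_model(self):
        # both tissues = loading * shared latent + noise; expected per-probe
        # r = loading^2 * var(latent) / (loading^2 var(latent) + noise var)
        rng = np.random.default_rng(3)
        n, m = 60, 40
        loading, lat_sd, noise = 0.9, 0.15, 0.02
        z = rng.normal(0, lat_sd, (n, m))
        a = 0.5 + loading * z + rng.normal(0, noise, (n, m))
        b = 0.5 + loading * z + rng.normal(0, noise, (n, m))
        ba, bb = make_beta(np.clip(a, 0, 1)), make_beta(np.clip(b, 0, 1))
        pairs = [(s, s) for s in ba.sample_ids]
        res = shared_vmr_correlation(ba, bb, list(ba.probe_ids), pairs)
        expected = (loading * lat_sd)**2 / ((loading * lat_sd)**2 + noise**2)
        assert res["r"].mean() == pytest.approx(expected, abs=0.05)

    def test_too_few_pairs_rejected(self):
        a = make_beta(np.full((4, 2), 0.5))
        with pytest.raises(ValueError, match="3"):
            shared_vmr_correlation(a, a, list(a.probe_ids),
                                   [(s, s) for s in a.sample_ids[:2]])
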