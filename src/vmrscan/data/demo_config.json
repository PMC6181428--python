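{
  "seed": 0,
  "out_dir": "vmrscan_demo",
  "sim": {
    "n_chrom": 5,
    "probes_per_chrom": 4000,
    "n_samples": 100,
    "baseline_noise_sd": 0.02,
    "n_planted_vmrs": 50,
    "vmr_effect_sd": 0.15,
    "n_trans_modules": 3,
    "vmrs_per_module": 12,
    "module_loading": 0.9,
    "frac_env_vmrs": 0.4
  },
  "sweep": {"n_seeds": 10},
  "twins": {"n_pairs": 100, "genetic_share": 0.6, "env_sd": 0.1},
  "exposure": {"n_per_group": 64, "delta": 0.05},
  "timecourse": {"n_timepoints": 9, "trend_magnitude": 0.3}
}
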