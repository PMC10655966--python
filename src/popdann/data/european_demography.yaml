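# Two-population out-of-Africa demographic model for European samples
# (Tennessen-style exome-sequencing model; generation time 25 years).
# Times are in generations before present; sizes are diploid Ne.
# Sampling is from the EUR population only; the AFR deme and migration are
# retained because they measurably inflate European diversity
# (Watterson Ne ~ 6,000 for the recombination-rate experiment).
label: european_out_of_africa
generation_time_years: 25.0
populations:
  - name: AFR
    # size at onset of recent growth; grows at r_AF to the present
    size_at_growth_onset: 14474.0
    growth_rate_recent: 0.0166
  - name: EUR
    size_at_growth_onset: 9279.2123494527
    growth_rate_recent: 0.0195
events:
  recent_growth_start_gen: 204.6          # 5,115 years ago
  eur_second_epoch:
    start_gen: 204.6
    end_gen: 920.0                        # 23,000 years ago
    growth_rate: 0.00307
    size_at_end: 1032.0
  eur_bottleneck:
    start_gen: 920.0
    end_gen: 2040.0                       # 51,000 years ago (out-of-Africa)
    size: 1861.0
  out_of_africa_split_gen: 2040.0
  african_expansion:
    end_gen: 5920.0                       # 148,000 years ago
    size: 14474.0
  ancestral_size: 7310.0
migration:
  recent_rate: 2.5e-5                     # AFR <-> EUR, symmetric, < 920 gen
  bottleneck_rate: 1.5e-4                 # during the out-of-Africa epoch
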