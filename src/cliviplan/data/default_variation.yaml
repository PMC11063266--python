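# Bundled anatomical-variation distribution for cohort simulation.
# Chosen once to reflect the qualitative variation spectrum of the
# retro-condylar region (vertebral-artery hypoplasia through gross
# dilatation, venous-sinus dominance, CN XI root height) and then frozen
# together with its master seed as a stable regression surface.
seed: 7
va_hypoplasia_prob: 0.15
va_hypoplasia_radius_mm: 0.8
va_radius_mean_mm: 2.1
va_radius_sd_mm: 1.0
va_radius_min_mm: 0.5
va_radius_max_mm: 4.5
sinus_dominance_alpha: 2.5
sinus_dominance_beta: 1.5
cn11_height_mean_mm: 6.0
cn11_height_sd_mm: 2.0
cn11_height_min_mm: 1.0
cn11_height_max_mm: 14.0
tubercle_size_mean_mm: 7.0
tubercle_size_sd_mm: 0.8
condyle_size_mean_mm: 10.0
condyle_size_sd_mm: 1.0
jitter_mm: 1.0
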