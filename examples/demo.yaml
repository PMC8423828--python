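# Two-group demonstration cohort: West-Eurasia-like group with 25.32-year
# generations vs an East-Asia-like reference at 28 years, sharing one
# Neanderthal pulse 55 kya and splitting 40 kya.  Runs in about a minute.
cohort:
  groups:
    - {name: WEU, n_individuals: 10, a_f: 25.32, a_m: 25.32}
    - {name: EAS, n_individuals: 10, a_f: 28.0, a_m: 28.0}
  chromosomes:
    - {name: chr1, length: 20000000}
    - {name: chr2, length: 20000000}
    - {name: chrX, length: 10000000, is_x: true}
    - {name: chrY, length: 5000000, is_y: true}
  admixture_time_years: 55000
  admixture_fraction: 0.02
  split_time_years: 40000
  ooa_time_years: 60000
  ancestral_mean_age: 28.0
  count_scale: 3.0
  seed: 1
reference_group: EAS
n_perm: 999
n_boot: 2000
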