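{
  "version": "1.0",
  "note": "synthetic surrogate staging tables; see docs/methods.md",
  "sha256": {
    "demirjian_scores_male_synthetic.csv": "0729b857fdaf8682e5ba77d7b996f55e7e95fc7452f6256e98cfcb793cc7fb11",
    "demirjian_age_norms_male_synthetic.csv": "ce08b9b6b5c28fba7d6f008a1d9a04d592fdf1d5a6d29b432b790260eecb8a60",
    "nolla_age_norms_male_synthetic.csv": "094744e354aa1ea62440655da62c1196768ec1f4a827243b74fe8d366556ba1c",
    "demirjian_scores_female_synthetic.csv": "56da36be1a6a9d0a826472cfad6be631d54429cddad9c3011b1ac01a56c7b08d",
    "demirjian_age_norms_female_synthetic.csv": "1187bef824192d63611cb2751426281c7aabfc6010088fb7284856e541b856d9",
    "nolla_age_norms_female_synthetic.csv": "989a0166dac9dc1f1bc5dd2ae406d2a0309a67a7d99321bd64c73258f4133082"
  }
}
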