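# Scaled three-population Out-of-Africa demographic model (N0 = 500).
# Times are in units of 2*N0 generations measured forward from t = 0.
# Migration values follow the 2N_recipient convention: value = 2*N_i(t)*m,
# where N_i(t) is the recipient population's diploid size at the epoch start
# and m the per-generation fraction of `pop` replaced by migrants from
# `source`.  Under this reading the printed rates reduce to a symmetric
# per-generation matrix (e.g. 6.133603671/(2*841.01) = 1.047236559/(2*143.59)
# = 3.65e-3), matching the published real-scale rates of the underlying
# Out-of-Africa fit once divided by kappa.
N0: 500
t_end: 0.607
populations: [AFR, EUR, ASN]
root_population: AFR
migration_convention: "2N_recipient"
kappa: 14.62
generation_time_years: 25.0
record_times:
  # European frequency recorded ~7,000 years before present
  eur_7kybp: 0.5895
events:
  - {time: 0.0, kind: size_change, pop: AFR, value: 0.1}
  - {time: 0.004, kind: size_change, pop: AFR, value: 10.0}
  - {time: 0.005, kind: size_change, pop: AFR, value: 1.68202}
  - {time: 0.211074, kind: split, pop: AFR, daughter: EUR}
  - {time: 0.211074, kind: size_change, pop: EUR, value: 0.170737565}
  - {time: 0.211074, kind: migration_change, pop: AFR, source: EUR, value: 6.133603671}
  - {time: 0.211074, kind: migration_change, pop: EUR, source: AFR, value: 1.047236559}
  - {time: 0.534772, kind: split, pop: EUR, daughter: ASN}
  - {time: 0.534772, kind: size_change, pop: EUR, value: 0.724763218}
  - {time: 0.534772, kind: size_change, pop: ASN, value: 0.162342748}
  - {time: 0.534772, kind: growth_rate_change, pop: EUR, value: 33.98}
  - {time: 0.534772, kind: growth_rate_change, pop: ASN, value: 62.27}
  - {time: 0.534772, kind: migration_change, pop: AFR, source: EUR, value: 0.741012229}
  - {time: 0.534772, kind: migration_change, pop: AFR, source: ASN, value: 0.472619025}
  - {time: 0.534772, kind: migration_change, pop: EUR, source: AFR, value: 0.091696045}
  - {time: 0.534772, kind: migration_change, pop: EUR, source: ASN, value: 0.41215962}
  - {time: 0.534772, kind: migration_change, pop: ASN, source: AFR, value: 0.013100056}
  - {time: 0.534772, kind: migration_change, pop: ASN, source: EUR, value: 0.092321359}
  - {time: 0.54805, kind: migration_change, pop: AFR, source: EUR, value: 0.0}
  - {time: 0.54805, kind: migration_change, pop: AFR, source: ASN, value: 0.0}
  - {time: 0.54805, kind: migration_change, pop: EUR, source: AFR, value: 0.0}
  - {time: 0.54805, kind: migration_change, pop: ASN, source: AFR, value: 0.0}
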