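# Demo configuration for `esc run-all` and the simulate subcommands.
seed: 20240601

locus:
  name: toyIGK
  flank_len: 60
  segments:
    - {name: V1, kind: V, spacer_class: 12}
    - {name: V2, kind: V, spacer_class: 12}
    - {name: V3, kind: V, spacer_class: 12}
    - {name: J1, kind: J, spacer_class: 23}
    - {name: J2, kind: J, spacer_class: 23}
    - {name: C, kind: constant}
    - {name: KDE, kind: KDE, spacer_class: 23}

simulate:
  n_founders: 6
  divisions: 5
  esc_replication_prob: 0.5
  segregation: binomial
  junction_assignment: distinct
  lam_n_reads: 800
  seq_error_rate: 0.002
  wgs_n_fragments: 800
  wgs_circle_fraction: 0.3

sv:
  n_sv: 30
  proportions: {none: 0.4, single: 0.4, double: 0.2}
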