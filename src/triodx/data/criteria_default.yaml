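# Default five-tier classification rule table.
# Ordered first-match semantics; every run records the version id.
# Inheritance mode, population frequency and prior-report quality dominate;
# the deleteriousness score is deliberately unused here (tie-breaker rules
# may be added in custom configs via score_ge).
version: triodx-default-1
rules:
  - name: common_benign
    tier: benign
    when: {af_gt: 0.05}
  - name: common_likely_benign
    tier: likely_benign
    when: {af_gt: 0.01}
  - name: informative_reported_pathogenic
    tier: pathogenic
    when:
      mode_in: [de_novo, x_linked_maternal, compound_het, homozygous_recessive]
      absent_from_population: true
      prior_in: [reported_variant_pathogenic]
      mechanism_consistent: true
  - name: informative_truncating_established
    tier: pathogenic
    when:
      mode_in: [de_novo, x_linked_maternal, compound_het, homozygous_recessive]
      absent_from_population: true
      prior_in: [established_gene_match]
      mechanism_consistent: true
      consequence_in: [nonsense, frameshift, canonical_splice]
  - name: informative_missense_established
    tier: likely_pathogenic
    when:
      mode_in: [de_novo, x_linked_maternal, compound_het, homozygous_recessive]
      absent_from_population: true
      prior_in: [established_gene_match]
      mechanism_consistent: true
      consequence_in: [missense, inframe]
  - name: informative_damaging_uncertain_prior
    tier: likely_pathogenic
    when:
      mode_in: [de_novo, x_linked_maternal, compound_het, homozygous_recessive]
      absent_from_population: true
      prior_in: [reported_variant_uncertain]
      mechanism_consistent: true
      consequence_in: [nonsense, frameshift, canonical_splice, missense, inframe]
  - name: unknown_mode_reported_pathogenic
    tier: pathogenic
    when:
      mode_in: [unknown, inherited_dominant]
      absent_from_population: true
      prior_in: [reported_variant_pathogenic]
      mechanism_consistent: true
  - name: unknown_mode_established
    tier: likely_pathogenic
    when:
      mode_in: [unknown, inherited_dominant]
      absent_from_population: true
      prior_in: [established_gene_match]
      mechanism_consistent: true
      consequence_in: [nonsense, frameshift, canonical_splice, missense, inframe]
  - name: mechanism_mismatch
    tier: VUS
    when:
      prior_in: [established_gene_match, reported_variant_pathogenic]
      mechanism_consistent: false
  - name: default_vus
    tier: VUS
    when: {}
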