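# Scallop tunable-parameter space.
# Names, defaults and flags transcribed from the Scallop v0.10.x README
# ("scallop --help"); bounds and coordinate-ascent step sizes are this
# package's choices. Verify flag spellings against the installed release
# before production use.
assembler: scallop
source: Scallop v0.10.x documentation
parameters:
  - {name: min_flank_length, kind: integer, default: 3, lower: 1, upper: 10, step: 1, flag: "--min_flank_length"}
  - {name: max_edit_distance, kind: integer, default: 10, lower: 0, upper: 50, step: 5, flag: "--max_edit_distance"}
  - {name: min_bundle_gap, kind: integer, default: 50, lower: 10, upper: 500, step: 20, flag: "--min_bundle_gap"}
  - {name: min_num_hits_in_bundle, kind: integer, default: 20, lower: 5, upper: 100, step: 5, flag: "--min_num_hits_in_bundle"}
  - {name: min_mapping_quality, kind: integer, default: 1, lower: 0, upper: 60, step: 5, flag: "--min_mapping_quality"}
  - {name: min_splice_boundary_hits, kind: integer, default: 1, lower: 1, upper: 10, step: 1, flag: "--min_splice_boundary_hits"}
  - {name: max_num_cigar, kind: integer, default: 7, lower: 1, upper: 20, step: 1, flag: "--max_num_cigar"}
  - {name: min_transcript_coverage, kind: real, default: 1.01, lower: 0.51, upper: 10.01, step: 0.5, flag: "--min_transcript_coverage"}
  - {name: min_single_exon_coverage, kind: real, default: 20.0, lower: 2.0, upper: 50.0, step: 2.0, flag: "--min_single_exon_coverage"}
  - {name: min_transcript_length_base, kind: integer, default: 150, lower: 50, upper: 500, step: 25, flag: "--min_transcript_length_base"}
  - {name: min_transcript_length_increase, kind: integer, default: 50, lower: 0, upper: 100, step: 10, flag: "--min_transcript_length_increase"}
  - {name: min_subregion_gap, kind: integer, default: 3, lower: 1, upper: 20, step: 1, flag: "--min_subregion_gap"}
  - {name: min_subregion_length, kind: integer, default: 15, lower: 5, upper: 50, step: 5, flag: "--min_subregion_length"}
  - {name: min_subregion_overlap, kind: real, default: 1.5, lower: 1.0, upper: 5.0, step: 0.5, flag: "--min_subregion_overlap"}
  - {name: max_intron_contamination_coverage, kind: real, default: 2.0, lower: 0.5, upper: 10.0, step: 0.5, flag: "--max_intron_contamination_coverage"}
  - {name: min_surviving_edge_weight, kind: real, default: 1.5, lower: 0.5, upper: 5.0, step: 0.5, flag: "--min_surviving_edge_weight"}
  - {name: uniquely_mapped_only, kind: boolean, default: false, flag: "--uniquely_mapped_only"}
  - {name: use_second_alignment, kind: boolean, default: false, flag: "--use_second_alignment"}
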