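# StringTie tunable-parameter space.
# Names, defaults and flags transcribed from the StringTie v2.x manual;
# bounds and coordinate-ascent step sizes are this package's choices.
# StringTie booleans are presence-style flags.
assembler: stringtie
source: StringTie v2.x documentation
parameters:
  - {name: min_isoform_fraction, kind: real, default: 0.01, lower: 0.01, upper: 0.51, step: 0.05, flag: "-f"}
  - {name: min_transcript_length, kind: integer, default: 200, lower: 50, upper: 600, step: 50, flag: "-m"}
  - {name: min_anchor_length, kind: integer, default: 10, lower: 2, upper: 30, step: 2, flag: "-a"}
  - {name: min_junction_coverage, kind: real, default: 1.0, lower: 0.0, upper: 10.0, step: 0.5, flag: "-j"}
  - {name: min_read_coverage, kind: real, default: 1.0, lower: 0.5, upper: 10.0, step: 0.5, flag: "-c"}
  - {name: bundle_gap, kind: integer, default: 50, lower: 0, upper: 500, step: 25, flag: "-g"}
  - {name: max_multihit_fraction, kind: real, default: 0.95, lower: 0.0, upper: 1.0, step: 0.05, flag: "-M"}
  - {name: disable_trimming, kind: boolean, default: false, flag: "-t"}
  - {name: no_multimapping_correction, kind: boolean, default: false, flag: "-u"}
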