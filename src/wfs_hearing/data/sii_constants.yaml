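# Octave-band constants for the unaided Speech Intelligibility Index.
#
# importance: band-importance weights for the six audiometric octaves
#   (ANSI-style octave-band weights; they sum to 1).
# band_speech_level: long-term average speech level per octave in dB HL
#   at average vocal effort (speech-banana approximation; editable to
#   match a specific device or transfer function).
# A band is fully audible when the threshold is at least
# (dynamic_range - peak_offset) dB below its speech level and inaudible
# peak_offset dB above it.
bands: [250, 500, 1000, 2000, 4000, 8000]
importance: [0.0617, 0.1671, 0.2373, 0.2648, 0.2142, 0.0549]
band_speech_level: [45.0, 45.0, 40.0, 35.0, 30.0, 25.0]
dynamic_range: 30.0
peak_offset: 15.0
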