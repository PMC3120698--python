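# Leading-peak pattern used by the 25-plex start search.
# Each entry: dye channel (1-4), minimum normalised peak height, and the
# maximum scan gap allowed to the NEXT entry's peak (null = unbounded).
# These defaults describe the synthetic 25-peak layout bundled with the
# package (first two markers on channels 1 and 2, ~40 scans apart); edit
# them to match a real multiplex panel.
entries:
  - {channel: 1, min_height: 100, max_gap: 50}
  - {channel: 2, min_height: 100, max_gap: null}
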