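# fsalign

Trace alignment and electronic size-standard embedding for
capillary-electrophoresis fragment analysis.

## The problem

Fragment analysis (for example SNaPshot primer-extension multiplexes used
for SNP-based identity control) sizes fluorescently labelled DNA fragments
against an internal ladder of size standards co-electrophoresed with every
sample. The labelled ladder is one of the most expensive reagents in the
assay. `fsalign` removes it from routine runs: one **reference** trace is
run *with* the size standards, every **target** trace is run *without*
them, and the software aligns the target electropherogram to the reference
and writes a modified target file in which the reference's size-standard
channel is electronically embedded. Ordinary fragment-sizing software can
then genotype the cheap, standard-free run as if the ladder had been there.

Traces of microsatellites are not suitable input: stutter makes their peak
pattern unpredictable, so the reference cannot serve as a blueprint.

## The method

Inputs are two ABIF container files (`.fsa`, or the `.ab1` sequencing
subtype): a reference with four dye channels plus the ladder in channel 5,
and a target with four dye channels. The pipeline is:

1. **Raw transform** — model-dependent correction of the raw stream (the
   310 model's channels are unmixed with the file's spectral matrix).
2. **Normalisation** — per channel: with mean `m` of all scans, the noise
   `n` is the mean of scans strictly below `m`; scans below `n` are zeroed
   and the rest divided by the scale factor `(m − n) / optimal`, so the
   average data signal lands on the chosen optimal value
   (50/100/200/400/800).
3. **Trimming** — the start is the first qualifying channel-1 peak, or in
   25-plex mode the first occurrence of a configurable leading-peak
   pattern; the target start is searched only within 200 scans past the
   reference start. Trailing scans where every channel is below 50 are
   dropped.
4. **Alignment** — greedy single-point warping: every 3 scans, the sum of
   absolute channel differences over the next 15 scans is compared with
   the score after duplicating or deleting the target's data point there;
   the best strictly improving edit is applied.
5. **Difference profile** — per scan and channel, with `d_c = ref − target`,
   the profile is `sign(d_c) · d_c² · √(Σ |d_c′|)` over the other channels
   changing in the opposite direction, so base substitutions show as
   bidirectional peaks.
6. **Output** — three aligned images (reference with the ladder overlaid
   in orange, difference profile, target) and the modified target file:
   channels 1–4 replaced by the aligned normalised values, channel 5
   overwritten with the reference's raw ladder, every other vendor tag
   preserved byte-for-byte (for the 310 model the matrix becomes the
   identity, since the channels now represent pure dyes).

## Worked example

No sequencer files at hand? The bundled synthetic generator produces a
25-peak multiplex pair with known ground truth — here with three
single-scan time warps distorting the target:

```python
from fsalign import example_25plex_spec, synth_pair, write_trace

spec = example_25plex_spec(seed=1, warp=[(400, "duplicate"), (600, "drop"), (900, "duplicate")])
reference, target, truth = synth_pair(spec)
write_trace(reference, "reference.fsa")   # 5 channels: 4 dyes + ladder
write_trace(target, "target.fsa")         # 4 channels, no size standard
```

```console
$ fsalign reference.fsa target.fsa --multiplex25 --out-dir results
sequencer model: 3100
first signal peak per dye (scan): ch1=300, ch2=340, ch3=380, ch4=420
reference analysis start (scan): 300
target analysis start (scan): 300
alignment edits applied: 45 (22 insert, 23 delete)
configuration: optimal_value=200.0, multiplex25=True, end_trim_threshold=50.0, start_search_window=200, stride=3, window=15
output: results/modified_target.fsa
output: results/reference.png
output: results/difference.png
output: results/target.png
```

Reading the report: both traces start their analysis at scan 300 (the
leading-peak pattern was found at the same scan in each), the aligner
applied 45 single-point edits to pull the warped target onto the
reference's coordinate system, and `modified_target.fsa` now carries the
reference ladder in channel 5 — `read_trace` on it shows five channels
whose peak apexes sit within ±2 scans of the reference's. Passing the same
file as reference and target turns the tool into a quick trace viewer
(zero edits, flat difference panel).

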