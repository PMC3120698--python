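# Methods

## Scope and model

`fsalign` aligns a target fragment-analysis electropherogram (run without
fluorescent size standards) to a reference electropherogram (run with
them) and writes a modified target trace file with the reference's
size-standard channel embedded. The underlying assumption is that two
runs of the same multiplex on the same instrument differ by (a) an overall
signal-intensity scale, (b) blank or noisy leading/trailing stretches, and
(c) small local migration-time distortions expressible as single-scan
duplications and deletions. Each pipeline stage addresses one of these.
The method presumes the reference reveals every peak the target can show
(in practice: a sample heterozygous at all markers, or a DNA mixture);
microsatellite traces violate the predictable-pattern assumption (stutter)
and are out of scope.

## Container I/O

ABIF files are parsed directly at the byte level (big-endian throughout,
per the public container specification): magic, version word, root
directory entry at byte 6, 28-byte directory entries, payloads inline when
≤ 4 bytes. Raw signal records (`DATA` 1–4, fifth channel 105) are
preferred over analysed ones (9–12, 205) because the embedding step must
transplant *raw* ladder data; which set was read is recorded in `is_raw`.
Writing has two modes. Fresh mode emits a minimal valid file (signal
records, model, dye names, matrix). Patch mode — used for the modified
target — keeps the original bytes, appends re-encoded signal payloads and
a relocated directory, and leaves every other tag's entry and payload
byte-identical, so vendor metadata survives verbatim. A stale tail
directory is truncated when possible. Channel values are rounded and
clipped to the signed 16-bit range of the `short` element type on write.

The container specification does not fix a single tag for an inline
spectral matrix; this package reads the full row-major float matrix from
either `("MTRX", 1)` or `("Mtrx", 1)` and writes both, covering the
historical conventions fragment-sizing consumers look for.

Malformed but salvageable files are tolerated rather than refused:
unequal-length signal records are truncated to the shortest with a
warning, and a missing instrument-model tag yields model `"unknown"`
(pass-through raw transform) instead of an error.

## Normalisation and trimming

Per channel with mean `m` over all scans: noise `n` = mean of scans
strictly below `m` (0 when that set is empty, e.g. a flat channel); scans
strictly below `n` are zeroed; the rest are divided by
`(m − n) / optimal`. "Below" comparisons are strict everywhere, including
end trimming, so a scan exactly at a threshold is kept. A channel that is
identically zero is flagged flat and left as zeros, avoiding a division by
zero while keeping the formulas literal. The identity
`avg_signal / scale_factor = optimal` is asserted as a property test.

A *peak* (never formally defined in this problem domain's informal usage)
is taken as a scan whose value is ≥ both neighbours, strictly greater than
its left neighbour (so a plateau counts once, at its first scan), and at
least the intensity threshold — reusing the end-trim constant 50, the one
intensity constant the method fixes. The generic start point is the first
such peak of channel 1. In 25-plex mode the start is the first occurrence
of a configurable leading-peak pattern (ordered entries of channel,
minimum normalised height, maximum scan gap to the next entry); the
bundled default (`data/pattern_25plex.yaml`: channel 1 then channel 2,
height ≥ 100, gap ≤ 50) describes the bundled synthetic layout, not a real
panel, and is meant to be edited. The target's start search is confined to
scans `[0, reference_start + 200]`, which is what defeats leading voltage
spikes: a spike matches no two-peak pattern, and a spurious peak beyond
the window cannot be selected.

End trimming removes the maximal trailing run of scans in which every
*data* channel (1–4) is strictly below 50. Channel 5 is excluded from the
criterion — the raw ladder would otherwise keep the tail alive — but is
sliced identically so channels stay in register. `trim` records the
retained span (`trim_span`) in pre-trim coordinates; the embedding step
uses it to place ladder and data on one coordinate system.

Normalisation runs before trimming and alignment, so the noise floor is
already zeroed when peaks are searched. Channel statistics are computed
after the raw matrix transform, since normalisation should operate on
dye-corrected data. The 310 model's unmixing multiplies each scan's
channel vector by the stored matrix and clamps negatives to zero; models
whose raw streams embed control values pass through a pluggable per-model
hook that defaults to a no-op (the concrete stream layout is
vendor-internal and undocumented).

## Alignment

Greedy progressive warping. Test positions run `0, s, 2s, …` through the
reference's end (stride `s` = 3 by default). At each position the window
score — the sum over the next `w` = 15 scans and all four channels of the
absolute reference/target difference, with overhangs counted against
zero — is compared to the score after duplicating, and after deleting, the
target's data point at that position (all four channels edited together so
they stay in register). The strictly best option is applied; ties with the
baseline leave the target untouched, and an insert/delete tie below
baseline deletes (minimal-intervention tie-breaks; the choice is
documented because the procedure itself does not fix one). At most one
edit per test position; larger shifts are absorbed across successive
positions. Local non-worsening (applied score ≤ baseline score) is
asserted inside the loop on every call. Absolute (not squared) differences
are used for the window score; squared differences would weight single
tall peaks more but the absolute form is the simpler reading and is fixed
here as the package's definition. The defaults 3/15 suit dense,
overlapping multiplex peaks; 5/30 (suited to long sequencing traces)
remains a valid parameterisation and is covered by a test.

After alignment the target is truncated or zero-padded to the reference
length for comparison, rendering and embedding.

On noiseless warped copies the greedy recovers k ≤ 10 well-separated
single-scan warps with exactly k edits and residuals below 5% of the
pre-alignment difference. On independently noised pairs it additionally
makes small insert/delete pairs in noise regions ("jitter" edits); these
are locally score-improving and harmless to peak positions, which is why
the end-to-end guarantee is stated in peak-apex terms (±2 scans) rather
than as a residual.

## Difference profile

For scan `i`, channel `c`, `d_c = ref_c[i] − tgt_c[i]`:
`value_c = sign(d_c) · d_c² · sqrt(Σ_{c′≠c, sign(d_c′)=−sign(d_c)} |d_c′|)`.
The kept sign renders bidirectional peaks above/below the axis; swapping
the inputs negates the profile exactly. A change confined to one channel
(peak present/absent, the typical multiplex genotype difference) gets
weight zero — the profile targets substitutions, and the rendered panels,
not the profile, are the check for presence/absence differences. No
capping, smoothing or rescaling is applied; the renderer autoscales.

## Embedding and output

The modified target record starts from the original target file
(patch-mode write): channels 1–4 become the aligned, normalised values
rounded and clipped to the 16-bit range; channel 5 becomes the reference's
raw, trimmed ladder verbatim (lengths must match the shared frame or the
operation fails with a coordinate mismatch); a missing reference ladder
skips the embedding with a notice and leaves four channels. A `DyeN 5`
tag is added when the target had none. For the 310 model the matrix is
replaced by the identity of the stored matrix's dimension — the one
parameter-free reading of "channels now represent pure dyes".

Rendering writes exactly three raster panels (reference with ladder
overlay in orange, difference, target) with identical pixel dimensions and
x-ranges; channel colours default to green/black/blue/red with no claim
that this order maps to particular nucleotides on every instrument. An
optional composite stacked page can be added.

## Synthetic data

The generator emulates what the pipeline depends on: Gaussian peaks
(width ~3 scans, so 40-scan-spaced peaks of the bundled layout partially
overlap as multiplex peaks do), additive Gaussian baseline noise clipped
at zero and rounded to integers, a ladder in channel 5, an optional
leading voltage-spike artifact (same apex in all four channels), and
single-scan duplicate/drop warps deriving a target from a reference with
independent noise. Defaults: 1600 scans, 25 peaks of 1440–2400 intensity
units cycling the four channels from scan 300 at 40-scan spacing (a
compact layout mirroring an assay confined to a short fragment-size
range), ladder peaks of 2800 every 140 scans, noise SD 2. Peak heights
are three orders of magnitude above the noise floor, as in real runs;
with much fainter peaks the noise-zeroing step cannot separate baseline
from signal and start detection degrades — a property of the method, not
of the generator. Not emulated: stutter, spectral bleed-through between
dyes, smooth continuous mobility drift. Passing tests therefore show
correctness of the pipeline's logic under the stated trace model, not
robustness to those artifacts.

## Numerical and degenerate-input choices

- All scoring and normalised channels are float64 in memory; quantisation
  to int16 happens only at file write.
- Empty channels, entirely blank traces, ragged record channels, missing
  magic bytes and truncated directories raise categorised `ValueError`s;
  the CLI maps error categories to distinct exit codes (2 missing file,
  1 processing, 3 output).
- The optimal-value restriction to {50, 100, 200, 400, 800} applies only
  at the CLI surface; the library accepts any positive value.
- Problem sizes in the test suite and the reproduction script (1600-scan
  traces, 25 peaks, sweeps of ~40–110 conditions) were chosen so the full
  pipeline stays in the tens-of-milliseconds range per run while keeping
  several peaks per alignment window.

## Known limitations

- The greedy aligner is local: a warp denser than one edit per stride, or
  systematic stretch accumulating faster than one scan per window, will
  not be recovered (dynamic-programming alignment is out of scope).
- Patch-mode writing copies vendor analysis tags verbatim; their semantic
  validity for the rewritten signals is not re-established.
- The control-number removal hook for 3100/3700 raw streams is a no-op
  pass-through until a concrete stream layout is supplied.
- The bundled leading-peak pattern is a placeholder validated only on the
  synthetic layout; real panels need their own pattern file.
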