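# Bundled synthetic 25-peak multiplex layout: 25 markers cycling the four
# dye channels at 40-scan spacing over a compact range (emulating an assay
# confined to a short fragment-size span), with a 9-step size-standard
# ladder in channel 5.  Positions/heights are synthetic, not a real panel.
length: 1600
noise_sd: 2.0
model: "3100"
ladder_width: 2.5
peaks:
  1:
    - [300, 2080, 3.0]
    - [460, 1920, 3.0]
    - [620, 1440, 3.0]
    - [780, 2400, 3.0]
    - [940, 1760, 3.0]
    - [1100, 2080, 3.0]
    - [1260, 1920, 3.0]
  2:
    - [340, 1760, 3.0]
    - [500, 2080, 3.0]
    - [660, 1920, 3.0]
    - [820, 1440, 3.0]
    - [980, 2400, 3.0]
    - [1140, 1760, 3.0]
  3:
    - [380, 2400, 3.0]
    - [540, 1760, 3.0]
    - [700, 2080, 3.0]
    - [860, 1920, 3.0]
    - [1020, 1440, 3.0]
    - [1180, 2400, 3.0]
  4:
    - [420, 1440, 3.0]
    - [580, 2400, 3.0]
    - [740, 1760, 3.0]
    - [900, 2080, 3.0]
    - [1060, 1920, 3.0]
    - [1220, 1440, 3.0]
ladder:
  - [220, 2800]
  - [360, 2800]
  - [500, 2800]
  - [640, 2800]
  - [780, 2800]
  - [920, 2800]
  - [1060, 2800]
  - [1200, 2800]
  - [1340, 2800]
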