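# epgkit

Analysis of speech production with **electropalatography (EPG)**: an
artificial palate carrying a grid of electrodes records, frame by frame,
where the tongue touches the hard palate during speech. `epgkit` is for
phoneticians and speech scientists who work with such recordings (e.g.
the MOCHA TIMIT corpus) and need to quantify **left–right asymmetry** —
both in the articulation itself and in the physical placement of the
electrodes on the palate.

The package provides:

- **Annotation formats** — read MOCHA-style `.lab` phoneme label files,
  read/write long-form Praat TextGrids, batch-convert between them.
- **Audio** — WAV loading and short-time Fourier spectrograms with
  optional phoneme-boundary overlays.
- **Palatograms** — a documented binary/text `.epg` frame format, the
  62-electrode Reading palate layout (any layout is configurable),
  per-frame asymmetry maps (symmetric / left-only / right-only),
  cumulative and cumulative-asymmetric activation maps, and montages.
- **Per-phoneme analysis** — cumulative contact maps and asymmetry
  metrics for every occurrence of chosen phonemes across a corpus.
- **CT segmentation** — a pipeline that segments cast, wires and
  electrodes from a CT of the electropalate by dual thresholding plus
  morphology, reflects electrode centroids through the sagittal symmetry
  plane, and measures electrode-placement asymmetry.
- **Synthetic fixtures** — simulated annotated EPG sentences with a
  controllable left bias, and CT phantoms with planted electrode offsets,
  so every pipeline can be validated against known ground truth.

## The asymmetry metrics

For a contact pattern with `n_L` and `n_R` activations on the left and
right halves of the palate:

- fractions `n_L/(n_L+n_R)` and `n_R/(n_L+n_R)` — a perfectly symmetric
  pattern scores 0.5/0.5, a fully one-sided one 1/0 or 0/1 (the two
  values always sum to 1);
- signed index `(n_R − n_L)/(n_R + n_L)` — 0 when symmetric, +1/−1 when
  fully right/left-sided.

Per phoneme, the metrics are computed on the cumulative map obtained by
summing all palatogram frames over the phoneme's duration. Patterns with
no contact at all have undefined metrics and are flagged, never counted
as symmetric. For the CT side, the *mirror distance* of an electrode is
the 3-D distance between it and the reflection of its contralateral
counterpart through the symmetry plane; comparing mirror distances with
nearest-neighbour electrode distances tells whether palatogram asymmetry
could be an artefact of electrode placement.

## Worked example

Simulate a short annotated utterance with a planted left bias of 0.6 and
extract per-phoneme asymmetry:

```python
from epgkit.synthetic import EPGSimSpec, simulate_sentence
from epgkit.phoneme_analysis import extract_phonemes

spec = EPGSimSpec(seed=42, left_bias=0.6)
timeline, seq, audio = simulate_sentence(
    spec, [("sil", 0.2), ("s", 0.15), ("ih", 0.10), ("ng", 0.12)])
print(f"{seq.n_frames} palatogram frames at {seq.frame_rate:g} Hz, "
      f"{audio.duration:.2f} s of audio")
for o in extract_phonemes([(timeline, seq, "demo")], ["s", "ng"]):
    m = o.metrics
    print(f"[{o.label}] frames {o.frame_range}: n_left={m.n_left} "
          f"n_right={m.n_right} left_fraction={m.left_fraction:.3f} "
          f"signed_index={m.signed_index:+.3f}")
```

```
114 palatogram frames at 200 Hz, 0.57 s of audio
[s] frames (40, 70): n_left=450 n_right=319 left_fraction=0.585 signed_index=-0.170
[ng] frames (90, 114): n_left=331 n_right=221 left_fraction=0.600 signed_index=-0.199
```

Both phonemes recover a left fraction near the planted bias of 0.6; the
negative signed index says contact is heavier on the left.

CT placement asymmetry on a phantom with known planted offsets:

```python
import numpy as np
from epgkit.synthetic import PhantomSpec, build_phantom, planted_offsets
from epgkit.ct import segment_palate

spec0 = PhantomSpec.small(seed=3)
offs = planted_offsets(spec0, mean_mag=4.5, sd_mag=1.8, seed=7)
vol, truth = build_phantom(PhantomSpec.small(seed=3, offsets=offs))
masks, es, plane, ma = segment_palate(vol, plane_offset=spec0.plane_x)
s = ma.summaries["mirror_vox"]
planted = np.linalg.norm(offs, axis=1); planted = planted[planted > 0]
print(f"{len(es)} electrodes; planted mean {planted.mean():.2f} vox; "
      f"recovered {s['mean']:.2f} +/- {s['sd']:.2f} vox")
```

```
62 electrodes; planted mean 3.69 vox; recovered 3.69 +/- 1.52 vox
```

All 62 electrodes are found and the mirror-distance distribution matches
the planted offsets to two decimals.

## Command line

```sh
epgkit convert corpus/                      # .lab -> .TextGrid
epgkit spectrogram s1.wav --labels s1.lab --png s1.png
epgkit palatogram s1.epg --cumulative --csv metrics.csv
epgkit phonemes --manifest corpus.tsv --phonemes d,s,ng --csv occ.csv
epgkit ct-segment scan_dir/ --out seg/      # DICOM series or .npy volume
epgkit simulate sentence --seed 1 --out sim/
```

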