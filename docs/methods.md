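# Methods

## Scope and model

`epgkit` analyses electropalatography (EPG) data: binary time series of
tongue–palate contact recorded by a grid of electrodes on a custom
artificial palate, together with the synchronised audio and phoneme
annotations, and — separately — CT scans of the artificial palate itself.
The package quantifies **left–right asymmetry** at two levels:

1. *Articulatory asymmetry*: which electrodes are active without their
   mirror-position partner during speech, per frame, accumulated over a
   sentence, or pooled over all occurrences of a phoneme.
2. *Placement asymmetry*: how far each electrode on the physical palate
   sits from the mirror image of its contralateral counterpart, measured
   in a CT volume of the palate on its plaster cast. This separates
   asymmetry caused by anatomy/manufacture from asymmetry caused by
   tongue movement: when the mirror distances are far smaller than the
   inter-electrode spacing, observed palatogram asymmetry must be
   articulatory.

### Asymmetry metrics

For a contact pattern (binary frame or accumulated count map) with
`n_L`/`n_R` activations on the left/right half of the palate:

- **Fractions** `(n_L/(n_L+n_R), n_R/(n_L+n_R))` — 0.5/0.5 when perfectly
  symmetric, 1/0 or 0/1 when one-sided; they always sum to 1.
- **Signed index** `(n_R − n_L)/(n_R + n_L)` — 0 when symmetric, ±1 when
  one-sided.

Both counts include *all* activations on a side, not only the unpaired
ones; this is what makes a fully mirror-symmetric frame score 0.5/0.5 and
index 0. With zero activations both metrics are undefined and flagged
(`defined = False`, NaN values); undefined occurrences are excluded from
averages rather than coerced to 0, which would fake perfect symmetry.
Midline electrodes (only possible on layouts with odd row widths) belong
to neither side: they are always classified symmetric when active and do
not enter `n_L`/`n_R`.

The per-phoneme metric is *activation-weighted*: it is computed from the
cumulative counts over the phoneme's frames, not from a per-frame average
of indices, so long/heavy contacts weigh proportionally.

### Palate layout

The default layout is the Reading-style 62-electrode palate (8 rows,
anterior row of 6, 8 in each remaining row), the type used by the MOCHA
TIMIT recordings. Layouts are data (`PalateLayout(row_widths)`); mirror
partner = reflected column within the row; column index increases from the
speaker's left, so the low-column half is "left".

### File formats

- `.lab`: whitespace-separated `start end label` per line, seconds;
  `#`-comments ignored; a 2-column `end label` dialect is available via a
  flag. Overlapping intervals are rejected (annotation corruption), not
  clipped.
- TextGrid: long (verbose) UTF-8 form only; tiers are tiled with
  empty-label filler intervals so boundaries chain exactly; fillers are
  dropped on reading. Round trips are exact to 1e-6 s (boundaries are
  written with 17 significant digits).
- `.epg`: the original hardware byte layout is proprietary and
  undocumented, so the package defines its own self-describing dialect:
  magic `EPG1`, an ASCII frame-rate line, then per frame
  `ceil(n_electrodes/8)` bytes, bits row-major anterior-first, MSB first.
  A plain-text dialect (one 0/1 string per line) is read and written too.
  Default frame rate 200 Hz (standard EPG3 hardware), always overridable.

### Spectrograms

Short-time Fourier analysis with `floor((n − L)/hop) + 1` columns, one-sided
spectra (`L/2 + 1` bins), window centres on the time axis. Defaults —
512-sample window (32 ms at 16 kHz), 50% overlap, Hann, dB display with a
−80 dB floor — are conventional speech-analysis settings chosen here; they
are not reproductions of any reference configuration, and all are
arguments. Linear mode is exactly linear in input amplitude and satisfies
Parseval per column; tests verify column-wise equality with a direct
O(N²) Fourier summation.

### CT pipeline

Dual ("Schmitt-trigger") thresholding: background below `t_low`, metal
candidates above `t_high`, middle band = cast candidate. Defaults come
from three-class multi-level Otsu; both thresholds are overridable. The
cast is refined by closing and opening with a ball of radius 2 voxels
(appropriate for ~0.3 mm isotropic voxels; configurable) and hole
filling; bright voxels inside the refined cast are metal artefacts and
are discarded. Wires are separated from electrodes by connected-component
size (strictly greater than `size_threshold`, default 300 voxels, is a
wire; a component exactly at the threshold is an electrode); a third
intensity threshold was deliberately not used because component size is
directly verifiable. Components are 26-connected; touching electrodes
merge (documented, not repaired). Electrode ids are assigned
anterior-to-posterior then left-to-right.

The sagittal symmetry plane is orthogonal to the x (left–right) axis. It
can be fixed manually (for a properly oriented acquisition it passes
through the gap between the two frontal teeth) or estimated by a 0.25-voxel
grid search minimising the mean mirror-pair distance, with a penalty for
unbalanced splits and a median fallback for degenerate sets. Reflection is
an exact involution. Mirror partners are found by greedy one-to-one
matching in ascending reflected distance — the labelling order of a
generic scan cannot be assumed to encode pairings. Distances are reported
in voxels (primary) and mm (`mm = spacing × voxels`). Summary statistics
use the sample standard deviation (ddof = 1). The overlap statistic is the
fraction of mirror distances exceeding the minimum neighbour distance; 0
means the two distributions are disjoint.

Metal-artefact *correction* is out of scope (streaks are tolerated via the
dual-threshold + cast-refinement route, not removed), as are registration
between scans and 3-D surface rendering.

## Synthetic data

The generators are first-class, tested code; they emulate the *structure*
of the real data, not its physics.

**Sentences** (`simulate_sentence`): per-phoneme contact templates are
coarse caricatures (alveolars anterior, velars posterior, laterals on the
margins, silence empty); frames are per-electrode Bernoulli draws. The
`left_bias` parameter reallocates each mirror pair's total probability
mass `m = p_L + p_R` as `(m·b, m·(1−b))`; when one share would exceed 1
the mass is scaled down so the ratio `b : (1−b)` is preserved, which makes
the expected left activation fraction of the generated frames equal `b`
exactly — the property the planted-bias recovery tests exercise. Audio is
a placeholder: one sinusoid per phoneme (frequency hashed from the label)
plus weak noise at 16 kHz — sufficient for spectrogram and alignment
tests, not speech. Passing tests therefore demonstrate correctness of the
*metrics and plumbing*, not robustness to real coarticulated speech or
hardware noise.

**Phantoms** (`build_phantom`): a dome-profiled cast slab with an internal
air pocket, 62 spherical electrodes (radius 2.5 voxels) in the 8-row
horseshoe at positions exactly mirror-symmetric about the mid-sagittal
plane, and two long wire tubes; intensities 0/500/2000 with Gaussian
noise (sd 20, i.e. class separations > 10 sd so Otsu thresholds succeed —
a high-noise spec demonstrates the failure mode). Because the plane
coordinate `(nx−1)/2` maps the voxel grid onto itself, the zero-offset
phantom voxelises into exact mirror images and the pipeline's mirror
distances are numerically zero. Planted placement asymmetry
(`planted_offsets`) displaces one side's electrodes by |Normal(mean, sd)|
magnitudes in random directions, with directions resampled (magnitudes
untouched) when a displacement would cross the plane or collide with a
neighbour; with the true plane, each planted mirror distance equals the
offset magnitude, giving exact ground truth. The phantom has no partial
volume effects, beam hardening or streaks; recovery results bound the
pipeline's geometric accuracy, not its robustness to real cone-beam
artefacts.

## Problem sizes and numerical choices

The test suite and acceptance checks run on the small phantom preset
(64×96×96 voxels, 62 electrodes) — segmentation in well under a second —
which the package considers sufficient because every geometric property
scales trivially; the acquisition-scale preset (250×333×333 at 0.3 mm) is
available via `PhantomSpec.fullsize()`. Corpus-level checks use 50
simulated sentences (100 phoneme occurrences). Frame/interval alignment
uses `i / frame_rate ∈ [start, end)` with a 1e-6 guard against float
boundary error. TextGrid equality tolerance is 1e-6 s. Spectrogram
brute-force equivalence is checked at 1e-9 relative on windows ≤ 64
samples.

## Known limitations

- WAV input via scipy supports PCM 8/16/32-bit and float; 24-bit PCM is
  not supported.
- Short-form TextGrids and point tiers are not parsed; forced alignment is
  out of scope.
- The `.epg` dialect is this package's own; reading a recording from the
  original hardware requires a converter to this dialect (a pluggable
  entry point, not reverse engineering, is the intended route).
- Electrode rendering geometry is schematic (grid positions), not the
  physical screen coordinates of any specific display tool.
- Touching electrodes in CT merge into one component; the electrode count
  then undercounts and must be caught by the user from the reported count.
- The symmetry-plane search assumes the scan's left–right axis is a voxel
  axis; an obliquely oriented acquisition must be resampled first.
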