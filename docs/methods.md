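# Methods

## Model and assumptions

The pipeline assumes a single-frame grayscale radiograph of the
head-and-neck region with a roughly vertical patient axis, in digital
detector convention (dense anatomy dark). Its premises are:

- after complementing, background (air) occupies the darkest part of
  the histogram and accounts for at least ~25 % of the pixels, so the
  first-quartile cut falls inside the background band;
- the patient silhouette is the largest connected foreground object
  after binarization;
- the silhouette's narrowest horizontal span is the neck, and the
  cervical vertebrae lie inside a full-height strip around it;
- the silhouette touches the top and bottom frame edges (as clinical
  frames do); a frame with fully empty rows makes the narrowest-row
  scan ill-posed and raises a no-neck error rather than guessing.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `fraction` | 0.25 | cumulative-histogram fraction defining the dynamic threshold; 0.25 is the first quartile and is the method's operating point. Raising it strips low-density tissue and over-crops (see below). |
| `apply_complement` | on | complement stage; disable for inputs already in film (dense = bright) convention, e.g. MONOCHROME1-style data. |
| `bit_depth` | from container | 8 or 16; inferred from the stored sample width, never from the observed maximum, so dark images keep their depth. |

Threshold definition: the smallest gray level whose cumulative count
reaches `⌈fraction·N⌉` — the standard empirical quantile for integer
levels, with ties resolved to the smallest level so the cut is
deterministic. Binarization uses a strict `> t` comparison so the
darkest quarter (background) is guaranteed to map to 0; the boundary
scan counts zeros as background, so background must be 0.

Coordinates are 0-based, row-major, and all crop intervals are
inclusive on both ends. The virtual boundary `m_c` is the silhouette
centroid column rounded half-up. Each half-image is scanned
independently, so the left and right bounds may come from different
rows; row ties resolve to the uppermost row. With multiple transitions
in a scan row (possible only with holes or stray pixels), the left
bound takes the first 0→1 change and the right bound the last 1→0
change, keeping the bound on the outside of the object so the crop
never cuts into it.

## Numerical and design choices

- **Equalization** uses the cdf-min-normalized mapping
  `out(g) = round((cdf(g) − cdf_min)/(N − cdf_min)·(2^d − 1))`,
  computed from the ROI's own histogram, which guarantees the output
  attains both 0 and the container maximum for any input with ≥ 2
  distinct levels and is monotone (rank-preserving) always. A constant
  ROI has no defined mapping and is returned unchanged with a warning.
- The crop and equalization operate on the **complement** image, so the
  saved ROI is in film convention; `--no-complement` switches the whole
  pipeline consistently.
- Equalization output keeps the input bit depth rather than rescaling
  to 8-bit: depth independence is a design goal and down-scaling would
  silently discard 16-bit contrast.
- Largest-object ties break on smallest (top, left) bbox corner, then
  label; connected components are 8-connected, matching closed-contour
  extraction of the silhouette. Interior holes are left as-is: they do
  not move the outer-edge transitions the bounds use.
- PNG is treated as an 8-bit container; 16-bit rasters round-trip
  through TIFF. Writing a 16-bit raster to PNG is a depth error, not a
  silent cast.

## The phantom generator

`phantom.generate_phantom` renders what the method needs from a
radiograph and nothing more: a head disc truncated by the top edge, a
vertical neck band (bone core, tissue, and a low-density outer margin)
and a shoulder slab to the bottom edge, over a background level, with
additive Gaussian noise at 2 % of the depth range, clipped to the valid
range and quantized. Intensity bands sit at fractions 0.85 / 0.55 /
0.25 / 0.06 of the range (bone / tissue / margin / background, film
convention) — ordered like real attenuation but not derived from
projection physics. The image is emitted in detector convention so the
complement stage is exercised.

The low-density neck margin is what makes the threshold-sensitivity
behavior reproducible: at fraction 0.25 the cut stays in the background
band and the detected columns equal the generated neck columns; pushing
the fraction toward 0.45 moves the cut above the margin level, the
silhouette shrinks into the denser neck, and the crop loses outer neck
columns — the over-threshold failure mode.

The default suite (`generate_suite`) draws neck half-widths uniformly
from 0.21–0.33 of the image width, which maps full-height crops onto
size reductions of roughly 34–58 % — inside the 30–60 % band the
method is characterized by, with margin for sampling noise. Suites are
generated per bit depth with matched geometry and noise pattern, so
8-bit and 16-bit results are directly comparable. All sizes default to
512×512, large enough for ±2 px recovery tolerances to be meaningful
and small enough that the whole suite runs in seconds.

What the phantoms do **not** emulate: vertebra-level texture, patient
tilt, scatter/heel-effect gradients, collimator markers, or implants.
Passing tests therefore demonstrate the geometric and histogram logic
of the pipeline, not robustness to clinical artifacts; on real data the
silhouette assumptions above are the operative caveats.

## Known limitations

- A tilted patient axis shifts the narrowest-row estimate; no rotation
  correction is attempted.
- Images whose background falls below ~25 % of pixels push the
  first-quartile cut into tissue and degrade the silhouette; the
  `fraction` option exists for such cases but changing it trades
  against the over-cropping failure mode.
- Multi-frame, color, and compressed exotic DICOM transfer syntaxes
  beyond what pydicom decodes are rejected, not coerced.
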