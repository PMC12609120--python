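# Methods

## Scope and model

`eoquant` quantifies endocrine objects (EOs) in 2D bright-field pancreas
sections immunolabeled with chromogens (DAB for insulin, Warp Red for
glucagon) over a hematoxylin counterstain. An EO is any contiguous
hormone-positive structure, from a single endocrine cell to a whole
islet. The pipeline assumes:

- stains mix additively in optical-density space (Beer–Lambert), so a
  pixel's OD vector is a non-negative combination of the stain vectors;
- one endocrine cell occupies roughly 170 μm² of section area, which
  motivates both the minimum object size and the size-bin unit;
- hormone positivity of an object is an area criterion (> 40 μm² of
  labeled area per hormone), not an intensity criterion, which filters
  sub-cellular staining artifacts.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| minimum object area | 170 | μm² | smallest detectable EO (≈ 1 cell); also the bin unit |
| positivity threshold | 40 | μm² | per-hormone labeled-area cutoff; objects with neither hormone above it are excluded |
| bin rule | ⌊log₂(area/170)⌋ | — | bins 0–9 reported; larger clamped to 9 with a warning |
| size classes | 0–3 / 4–6 / 7–9 | bins | small / medium / large |
| microns per pixel | 0.5 | μm/px | ×20 scan resolution |
| OD stabiliser ε | 1 | intensity | avoids log(0); shifts OD < 0.003 at 8-bit depth |
| OD floor | 0.10 | OD | below it a pixel is background, not stain |
| chromogen OD threshold | 0.15 | OD | projected-OD cutoff for hormone positivity per pixel |
| endotype cutoff | 13 | years | age at diagnosis: T1DE1 < 13 ≤ T1DE2 |
| risk rule | ≥ 3 of 4 | — | GRS ≥ 50th pct, insulitis, HLA-I hyperexpression, IA2A⁺ |
| age brackets | 0–1, 2–6, 7–12, 13–17, ≥18 | years | cohort grouping default |

Stain vectors default to the Ruifrok–Johnston optical-density matrices
(hematoxylin and DAB from the H-DAB matrix; the Fast Red vector stands
in for Warp Red, a fellow alkaline-phosphatase red chromogen). Real
archival slides vary in staining intensity, so both vectors and
thresholds are overridable through the YAML stain-model file; no
automatic re-optimisation is performed.

Bin boundaries follow the formula exactly: bin 0 is [170, 340) μm², bin
6 is [10 880, 21 760) μm². Published descriptions of these intervals
sometimes round the upper bounds differently; the formula is
authoritative here.

### Decisions where the design was open

- **Exclusion rule.** An object is *retained* iff at least one hormone
  area is strictly greater than 40 μm²; per-hormone positivity uses the
  same strict inequality, so retention and classification can never
  disagree.
- **Pixel-in-polygon rule.** A pixel belongs to an annotation iff its
  centre lies inside the polygon (even-odd rule): deterministic and
  convergent under refinement.
- **Connectivity.** 8-connectivity for components: chromogen blobs are
  compact and diagonal bridges match visual contiguity.
- **Border objects** are retained but flagged (`touches_border`), so a
  downstream analysis can drop them without re-segmentation.
- **Tie-breaks.** Equal stain projections fall to hematoxylin — the
  conservative direction that never invents hormone-positive area.
- **Matching.** The pairing score weights the centroid term and the four
  bounding-box coordinate differences equally, and assignment is greedy
  in ascending score with a gate at 2× the 95th percentile of
  nearest-neighbour centroid distances. Greedy is deterministic and
  auditable; a globally optimal assignment changes nothing on
  well-separated objects. R² is computed on areas, and the
  bin-difference filter uses unclamped bins so very large discrepancies
  cannot hide in the top bin.
- **Confidence intervals** on group means are t-intervals on donor-level
  values; the Tukey-vs-Dunnett post-hoc choice is an explicit argument,
  never inferred from the data.
- **Degenerate inputs.** All-tied two-group comparisons report p = 1;
  groups with fewer than 3 donors cause tests to be skipped and flagged;
  an empty age bracket leaves a gap in the pancreas-weight fold-change
  series (the next fold is taken against the last non-empty bracket and
  flagged), never an interpolation.

## The synthetic generator

`render_section` draws each EO as a superellipse perturbed by
low-frequency radial noise (harmonics 2–5), area-calibrated to its
target; `shape_irregularity` scales both the superellipse exponent and
the noise, mimicking the observation that larger objects are less
circular and solid. Mixed objects place insulin in the core and glucagon
in a mantle — an arbitrary but documented layout; classification depends
only on areas, never on layout. Concentration maps are pushed through
I = I₀·10^(−Σ cₛvₛ), quantised to 8 bits with mild Gaussian intensity
noise (σ = 1). The ground-truth table is computed from the rendered
masks themselves (connected components of the hormone union), so
overlapping blobs merge in the ground truth exactly as a detector sees
them, and recovery can be asserted pixel-exactly.

`sample_cohort` draws, per section and per (bin, class) cell, a Poisson
count with mean density × tissue area and object areas uniform within
the bin's boundaries — the simplest distributions consistent with
per-bin summaries. The shipped profiles encode the qualitative
non-diabetic and T1D structure: ND totals ≈ 8 EO/mm² with count shares
≈ 54.5/36.8/8.7 % (InsOnly/InsGluc/GlucOnly) and ~96 % of insulin-only
objects small; T1D totals ≈ 4 EO/mm² with shares ≈ 5.8/12.3/81.9 % and
*no* small insulin-only objects. Absolute per-bin densities are this
package's own realistic choice; they are generator parameters, not
measurements. Donor metadata (diagnosis age, duration, autoantibody and
histology flags) are simulated with plausible couplings for exercising
the endotype and risk rules.

What the generator does **not** emulate: nuclei and tissue texture,
immune-cell staining, section folds/tears, stain fading and batch
variation, spatial clustering (lobularity) of EOs, or the segmentation
errors of a learned tissue classifier. Passing tests therefore
demonstrate that the measurement and statistics layers are correct given
a segmentation, not that segmentation of real archival tissue is solved.

## Verification strategy and problem sizes

The test suite verifies each stage against an independent oracle: the
rendered ground truth for detection and areas (50 sections of 300×300 px
with four disjoint interior blobs each — exact equality is required);
closed forms and a 0.1°-step projection scan for morphology; hand
computations for the two-stage aggregation and Benjamini-Hochberg
step-up; and simulation for the statistics (cohorts of 20 donors/group
for effect recovery, 200 replicate null cohorts of 6 donors/group for
family-level type-I control). These sizes keep the full suite under a
minute while leaving the Monte-Carlo checks well-powered; all
simulations are seeded and deterministic.

## Known limitations

- Winner-take-all pixel assignment under-counts genuinely dual-stained
  pixels; strongly overlapping chromogens are attributed to the stronger
  projection only.
- Stain vectors are fixed per run; no Macenko-style per-slide estimation.
- Marching-squares boundaries slightly overestimate perimeter on
  pixelated objects, so the circularity of a rasterized circle plateaus
  near 0.9 rather than 1; closed-form morphology on analytic polygons is
  exact.
- The acinar compartment is summarised only as tissue minus endocrine
  area; ducts and vessels are not segmented.
- Greedy matching can, in principle, differ from a globally optimal
  assignment when objects are denser than their localisation error.
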