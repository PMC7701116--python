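# Methods

This note documents the data model, the algorithms behind the built-in
modules, the synthetic phantoms the tests run on, and the numerical and
design choices a maintainer would want to know. It states no result the
test suite or `scripts/acceptance.py` does not itself compute.

## Data model

The atomic unit is a NIfTI-1 volume plus a UTF-8 JSON sidecar. In
memory this is a `ScanVolume`: an array of at least 3 dimensions
(x, y, z, optionally time and echo), a 4×4 voxel-to-world affine in mm,
RAS+ orientation, and the sidecar dict. ROIs are 3D uint8 masks with
their own affine; any nonzero voxel counts as inside. Affines are kept
exactly as read — no array reorientation happens on import; geometry is
reconciled downstream by reslicing through composed affines.

A project's database is a flat table with one row per image. The
uniqueness key is (subject, timepoint, sequence_name, type): a session
can hold one image per sequence name and kind. Registering a colliding
key is an error rather than auto-suffixing, so that pipeline output
names are deterministic. Persistence is a TSV with a fixed header and
relative paths; file names are regenerated from tags
(`<subject>_<timepoint>_<sequence>.nii.gz`), which is what allows
`rename_tag_value` to keep files and rows consistent atomically (the
rename is simulated first; any key collision aborts before disk is
touched). The group tag is stored verbatim and never used for grouping
or filtering defaults.

NIfTI writing is deterministic: volumes are serialized in memory and
gzip-compressed with a fixed mtime, so identical arrays yield
byte-identical `.nii.gz` files. This is what makes "single-mode and
multi-worker runs produce byte-identical outputs" a testable property
rather than an approximation.

## Conversion

DICOM support covers classic single-frame series. Slices are grouped by
SeriesInstanceUID (mixed series are an error), sorted by the projection
of ImagePositionPatient on the slice normal (row × column direction
cosines), with the sort direction disambiguated by InstanceNumber when
present so acquisition order survives a round trip regardless of the
affine's handedness. Spacing outliers beyond 1e-3 of the median step
abort conversion with the offending gaps listed. The affine is built in
LPS from ImageOrientationPatient / PixelSpacing / positions, then
flipped to RAS. Rescale slope/intercept are applied (CT data therefore
arrives in Hounsfield units).

Metadata extraction is table-driven: YAML rules map a DICOM tag to a
sidecar key with an optional multiplicative unit conversion. The shipped
default uses BIDS-compatible key names but keeps EchoTime and
RepetitionTime in **milliseconds** (the DICOM native unit); a user
mapping can set `unit_conversion: 0.001` to get seconds. Absent source
attributes are omitted from the sidecar, never null-stuffed. Additional
dialects (vendor raw formats) can be registered as reader plug-ins that
return array + affine + metadata; none beyond DICOM and NIfTI are
implemented here.

## Pipeline engine

Iteration unit: one job per (subject, timepoint) session, carrying all
selector-matched entries of that session (modules may declare
`per-subject` arity instead, producing one job per subject for
longitudinal computations). A selector named `X` may be scoped with an
optional string parameter `X_timepoint` that resolves it against one
fixed timepoint of the same subject — this is how every visit can be
resliced onto the first visit's grid inside a per-session pipeline.

Output naming is `<primary input sequence>_<extension>`, with the
extension string a module parameter; output rows are created with
status `virtual` at `add_module` time, so downstream modules can bind
to them before anything is computed. Since a module can only consume
entries that exist at its insertion point, the job dependency graph
(edge where one job's output entry is another's input) is acyclic by
construction; this is still verified and property-tested.

Execution writes every output into `Tmp/jobs/<job-id>/` and, only on
success, promotes files into `Derived_data` / `ROI_data`, appends the
provenance record to each output sidecar, and flips the database row
from virtual to derived/roi. A failed job therefore leaves no partial
files outside `Tmp`, and all its transitive descendants are marked
skipped. Multi mode uses a process pool: a job becomes eligible when
every parent is done, with at most `workers` running; workers receive a
picklable payload and re-import the module from its source (package
module or file path), so external module files work under
multiprocessing. The engine adds no nondeterminism to outputs — only to
scheduling order; modules that need randomness receive a per-job seed
derived from the run seed and the job id.

Compliance colors: a module is red when its selectors match nothing
(and modules consuming its would-be outputs go red in turn when a saved
pipeline is re-bound to a database lacking the tags), orange when its
outputs already exist on disk **and** their sidecar history references
the same module id (parameter changes do not clear orange; they are
visible in history), green otherwise. Orange jobs are skipped unless
`overwrite` is passed. Saved pipelines store only the module sequence,
parameters and insertion filters (JSON, format-versioned) — never jobs,
which are database-specific and regenerated on load against the whole
current database (the user re-filters per module if needed).

A deletion step for pruning intermediates delegates to the project
store's `delete_entries` as a library call rather than running as an
engine job: provenance records require nonempty outputs, and deleting
database rows from inside a worker would race the scheduler.

## Built-in algorithms and their parameters

- **Smoothing** — Gaussian filter, 2D (per-slice) or 3D. The size
  parameter is the standard deviation σ in mm (converted per axis by
  voxel size) or in voxels via a unit flag; σ rather than variance for
  usability. Reflection borders; float output. Defaults: 3D, σ = 2 mm.
- **Threshold** — strict inequality (`>` for above, `<` for below);
  mask output is uint8, clipped output zeroes the complement.
- **ROI masking** — the mask is resampled to the scan grid with
  nearest-neighbour interpolation (masks must stay binary); fill is 0
  or NaN; idempotent.
- **Reslicing** — each output voxel samples the input at the world
  point given by composing the reference affine with the inverse input
  affine (`scipy.ndimage.affine_transform`); nearest or trilinear;
  out-of-field is NaN for float output, 0 for nearest/integer; exact at
  grid points for identity reslices; extra dimensions are processed
  frame by frame; the output affine is the reference affine, bitwise.
- **Brain extraction** — a deliberately simple intensity/morphology
  procedure (Otsu threshold → largest 26-connected component →
  morphological closing with an ellipsoidal element of radius 2 mm in
  voxel units → hole fill → largest component), guaranteeing a single
  component without internal holes. It is a stand-in with a documented
  contract, not a published skull-stripping algorithm; parameters are
  exposed.
- **CT preparation** — optional isotropic resampling, clamping to the
  soft-tissue window (default 0–100 HU), Gaussian filtering (default
  σ = 1 mm), threshold above zero, largest component, hole fill. The
  returned clipped scan is the clamped image; the mask branch instead
  zeroes voxels *outside the open window* before smoothing and
  intersects the final mask with the window, so skull (≈1000 HU) and
  air (−1000 HU) can never enter the brain ROI even through smoothing
  bleed at the boundary.
- **Entropy map** — per-voxel Shannon entropy (bits) of the local
  histogram: bins over the global finite intensity range, square (2D,
  default) or cubic (3D) window of side 2r+1. Defaults r = 3, 32 bins —
  this package's convention, stated here because no canonical values
  exist. Outside-image or non-finite neighbours are excluded, so border
  voxels use smaller neighbourhoods; values lie in [0, log₂ bins].
  Implementation is one box-filter pass per bin, tested against a
  naive per-voxel recomputation to 1e-10.
- **Region growth (active-contour style)** — from a seed, boundary
  candidates (26-neighbourhood) join when |I − mean(region)| ≤
  k·std(region) and they touch the region through at least m of their
  26 neighbours; iterate to fixpoint or `max_iter`. Defaults k = 2.5,
  m = 2, 500 iterations. The smoothness count uses the 26-neighbourhood
  rather than face neighbours: requiring m ≥ 2 face neighbours freezes
  any convex growth front (a voxel ahead of a flat front touches it
  through exactly one face), whereas the 26-count still blocks
  single-voxel tendrils. With a fresh single-voxel region the standard
  deviation is zero, so the first shell admits only exactly-equal
  intensities; the smoothness term is waived for that first shell.
  This, too, is a documented stand-in rather than a published contour
  model.
- **Reports** — the statistics CSV has one row per (subject, timepoint,
  scan, roi) with mean/std/median/min/max/voxel count/volume; numbers
  are exactly those of the statistics API. Run as an engine module it
  emits one fragment per session (keeping the one-job-per-session
  accounting) and `merge_stats_csv` concatenates fragments into the
  cohort table deterministically. The HTML report embeds mid-slice PNG
  thumbnails as base64 with ROI contours; passing a fixed timestamp
  makes the file reproducible.

## Statistics

Standard deviation is the population form (N), fixed and documented.
NaN voxels are excluded from moments but included in the voxel count
and volume (volume = count × |det A₃ₓ₃|). Cross-scan value pairing
reslices both scans (trilinear) onto the ROI grid and drops pairs with
NaN on either side; world-point sampling interpolates trilinearly
through each scan's own inverse affine and returns NaN out of field.
Longitudinal comparison reslices every visit onto the first visit's
grid and reports per-timepoint statistics plus pairwise mean absolute
differences. Voxel indices are 0-based; world coordinates mm RAS+.

## Synthetic data

The generators are first-class, seeded code; the same spec always
produces byte-identical files. The default cohort emulates a small
preclinical study — 2 subjects × 3 timepoints × 10 MR sequences, with
one brain ROI per session — and the clinical scenario is one CT patient
with 3 visits. Phantoms: a bright ellipsoid brain with a thin bright
shell (skull) separated by a dark gap (the shell is kept smaller than
the brain so the largest bright component is the brain); a Hounsfield
head (air −1000, skull ≈1000, interior ≈40 ± 5 HU); an index ramp; a
two-value checkerboard (whose 3×3 interior entropy is the closed-form
−(4/9·log₂(4/9) + 5/9·log₂(5/9)) ≈ 0.9911 bits); and a 4D gamma-variate
bolus. Ground truth (masks, series, parameters) is returned with each
volume and also stored under `truth/`, outside the database.

What these phantoms do *not* emulate: MR physics (coil profiles, bias
fields, partial volume), anatomy, motion, or realistic CT noise
spectra. Passing tests therefore demonstrate the correctness of the
*mechanics* — geometry, scheduling, provenance, statistics — and the
stated contracts of the segmentation stand-ins on separable phantoms,
not segmentation quality on real data.

The DICOM writer emits one single-frame file per slice with geometry
tags derived from the volume's affine; over 50 random rigid
orientations and spacings the conversion recovers the affine to better
than 1e-4 (measured ≈2e-6, dominated by the 10-decimal string encoding
of DICOM attributes).

## Problem sizes and scenario choices

The replayed scenarios use deliberately small volumes so that whole-
cohort runs remain quick on a single CPU while exercising the full
machinery: 12×12×10 voxels for the preclinical cohort (60 scans, 24
jobs), 24×24×18 for the CT patient, and 8×8×6 for the scheduler stress
run — 45 subjects with 110 sessions spread unevenly (2 or 3 visits
each), 990 scans, and an 18-module chain giving 1980 jobs, executed in
both single and multi(4) modes and compared byte for byte. Algorithmic
verification never depends on volume size: the oracle suites
(brute-force filtering, naive entropy, voxel-loop statistics, geometry
recovery) run on randomly sized instances up to 16³.

## Known limitations

Single-frame DICOM only (no enhanced multi-frame, no DICOM-RT);
no vendor raw-format readers (plug-in hook only); no cluster executor —
parallelism is a local process pool; no concurrent multi-writer locking
on a project; brain extraction and region growth are simplified
stand-ins as described; the per-session iteration model assumes tags
identify at most one image per (session, sequence, kind).
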