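# voxpipe

A headless, scriptable store and pipeline engine for cohort-scale
medical-image studies. voxpipe manages a tag-driven database of
subjects × timepoints × sequences over canonical **NIfTI + JSON
sidecar** pairs, converts DICOM/NIfTI sources into that form, and
builds **dependency-aware processing pipelines** from small,
discoverable modules — with full per-file provenance.

It is aimed at imaging scientists (preclinical MR, clinical CT/MR) who
need to apply the *same* multi-step processing to every visit of every
subject in a heterogeneous cohort, reproducibly, from Python scripts or
a shell.

## The model

**Project.** A project is one directory containing five fixed
sub-folders (`Raw_data`, `Derived_data`, `ROI_data`, `Tmp`,
`Saved_Pipelines`) plus a flat tag database (`voxpipe_database.tsv`).
Every image is one row: type (Scan/ROI), subject, timepoint, sequence
name, group, relative path, filename, status. All paths are relative,
so a project directory is movable between machines; the database alone
describes the project. Statuses map to display colors: raw = blue,
derived = green, ROI = pink, virtual = yellow.

**Pipelines, modules, jobs.** A *module* is a declared computation
(parameter schema + run function) found by scanning `module_*.py`
files; 12 ship with the package (Gaussian smoothing, strict
thresholding, ROI masking, reslicing onto a reference grid, isotropic
resampling, brain extraction, CT window/filter/extract preparation,
local entropy mapping, seeded region growth, CSV statistics export,
HTML reporting, 4D time averaging). Adding a module to a pipeline under
a database filter expands it into *jobs* — one per (subject, timepoint)
session matching the module's selectors — and declares each job's
outputs as *virtual* database rows (`<input>_<extension>`), which later
modules can already consume. That construction makes the job graph a
DAG by design. Execution stages outputs in `Tmp` and promotes them only
on success, appending a provenance record (module id, parameters,
input/output files, timestamp) to each output's JSON sidecar. `single`
mode runs jobs in module order; `multi` mode schedules them over a
process pool respecting dependencies — both produce byte-identical
outputs.

Key quantitative primitives, in standard notation: within a binary ROI
M and image I, first-order statistics use the population form
σ² = (1/N)Σ(Iᵢ−μ)², and the ROI volume is N·|det A₃ₓ₃| mm³ for voxel-
to-world affine A. The local entropy map is the Shannon entropy
H(x) = −Σ_b p_b log₂ p_b of the intensity histogram (b bins over the
global range) in a (2r+1)-sided window around each voxel, bounded by
log₂(bins).

## Worked example

`examples/03_preclinical_pipeline.py` builds a synthetic cohort
(2 subjects × 3 timepoints × 10 MR sequences), chains brain extraction →
ROI masking → smoothing → statistics export, and runs it on 4 workers:

```
pipeline of 4 modules expanded into 24 jobs
execution report: {'done': 24, 'failed': 0, 'skipped': 0}
cohort statistics table (6 sessions):
subject,timepoint,scan,roi,mean,std,median,min,max,n_voxels,volume_mm3
S01,T0,T2w_masked_smooth,T2w_brain,33.43168623631615,12.237425452149932,34.20404791493037,13.226846268024364,59.03280170087782,264,264.0
S01,T1,T2w_masked_smooth,T2w_brain,33.41887085305449,12.214214273877126,34.16876705016372,13.2495727838167,58.93623900613792,264,264.0
...
```

24 jobs = 4 modules × 6 sessions: every visit of every subject is
processed identically. Each CSV row is one session's smoothed,
brain-masked T2w statistics; volumes are in mm³ (here 1 mm isotropic
voxels, so volume equals the voxel count). The other examples cover
project/database editing, DICOM conversion, the CT entropy pipeline and
provenance tracing; each prints the numbers it computes and what they
mean.

A thin CLI wraps the same library:

```bash
voxpipe init myproj
voxpipe fixtures make myproj --subjects 2 --timepoints 3
voxpipe pipeline new myproj smooth --module '{"id": "Module_Smooth", "params": {"sequence": "T2w"}}'
voxpipe pipeline run myproj myproj/Saved_Pipelines/smooth.json --mode multi --workers 4
voxpipe db list myproj --json
```

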