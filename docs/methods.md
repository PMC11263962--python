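# Methods

## Model and assumptions

`tomopick` treats particle picking as dark-blob detection at a single known
scale. The assumptions are:

* the reconstruction renders protein density *darker* than the surround
  (`--invert` negates the volume when the convention is opposite);
* particles are roughly spherical with a user-supplied radius *r* (Å),
  converted to voxels as `round(r / pixel_size)`, minimum 1;
* neighboring particle centers are at least 2*r* apart;
* contamination (gold fiducials, ice, hot pixels) is far higher-contrast
  than particles, so it is separable by a global statistical threshold;
* the sample occupies a finite slab around the tomogram mid-plane.

The missing wedge is not modeled anywhere; z-elongation of real tomograms
is only probed synthetically (see below).

## Pipeline and numerical choices

Stage order: background subtraction → contamination mask → detection
low-pass → local-minima extraction → mask/boundary/slab rejection →
projection-statistics filtering. All smoothing is `scipy.ndimage`
Gaussian filtering with replicate-edge boundaries (constant-zero padding
would create dark rims at volume faces that read as spurious minima).

**Mask.** Threshold is two-sided (`|v − μ| > k·σ`) by default: dense gold
and thick ice are dark under the same convention that makes particles dark,
while Fresnel fringes flanking them are bright; `--mask-one-sided` keeps
only the dark tail. Component cleaning uses 26-connectivity (diagonal
contact merges; fewer fragments to clean). The minimum component size
(default 125 voxels = 5³) is a voxel count, not Å. Closing uses a Euclidean
ball of radius 2 voxels, computed on a zero-padded copy so it is exactly the
mathematical closing (extensive and idempotent); unpadded closing erodes
border voxels. Dilation radius is given in Å and converted by pixel size.

**Detection.** A candidate is a voxel *strictly* smaller than every other
voxel in a centered cubic window; ties (plateaus) produce no candidate at
either voxel, which keeps the definition and its oracle unambiguous —
plateaus are practically nonexistent in heavily low-passed float data.
Since `h = 4r` and `h = 2r` are even, the window uses the odd side
`2⌊h/2⌋+1`. The 2r mode's iterative pruning is realized as greedy
darkest-first suppression: candidates sorted by ascending density (ties by
position) are kept unless strictly closer than 2*r* (Euclidean — overlap is
a Euclidean notion) to an already-kept candidate; a pair at exactly 2*r*
survives. Candidates within half a filtering-subvolume side (~1.5*r*) of a
volume face are rejected (`rejected_boundary`) so every surviving candidate
supports the full (3*r*)³ statistics window; the slab restriction keeps
`|z − nz/2| ≤ width/2`, with a default width that covers any volume.

**Filtering.** The acceptance inequality
`fg_std > proj_mean + k_f·proj_std` compares a dispersion against a
location-plus-dispersion threshold; it is implemented literally, but the
input volume (the background-subtracted tomogram, so ice-thickness
gradients do not shift projection means) is standardized to a global
z-score first. For featureless regions `proj_mean ≈ 0` and the rule
degrades to `fg_std > k_f·proj_std`; a negative `k_f` (the dNTPase preset
uses −0.1) means "accept everything by threshold, rely on the other
criteria". The background criterion (`bg_std < fg_std`) is enabled by
default: it is what removes membrane-flanking candidates in crowded
volumes, and for clean in-vitro data it is nearly free (isolated particles
have flat backgrounds). The (3*r*) subvolume side is rounded up to odd so
the candidate voxel is the exact center; the projection is the *mean* along
z, making statistics invariant to depth rounding. All standard deviations
are population (ddof = 0).

**Evaluation.** Predictions and truths are matched greedily by ascending
pair distance, one-to-one, within a threshold that defaults to the particle
radius in voxels; ties are broken by prediction then truth index, so
scoring is deterministic. Greedy matching can in principle fall short of
the maximum bipartite matching; the test suite checks it attains the
optimum (computed by optimal assignment) on its fixtures. The degenerate
empty-vs-empty case scores (1, 1, 1) with a warning.

## Parameters

| parameter | units | default | role |
|---|---|---|---|
| `radius_angstrom` | Å | per dataset (55–100) | the single scale prior |
| `mode` | — | `2r` | minima window regime (`4r` is stricter, cheaper) |
| `lowpass_sigma_factor` | ×r voxels | 0.5 | detection smoothing scale |
| `background_sigma_angstrom` | Å | 200 | background-removal blur |
| `mask_threshold_k` | ×σ | per dataset (0.75–2.5) | contamination threshold |
| `mask_min_component_voxels` | voxels | 125 | speck cleaning |
| `mask_closing_radius_voxels` | voxels | 2 | hole filling |
| `mask_dilation_angstrom` | Å | 70–100 | guard zone around artifacts |
| `detection_width_slices` | slices | full depth (32 for thin ice) | mid-plane slab |
| `filter_k` | ×proj_std | per dataset (−0.1–2.0) | acceptance threshold |
| `use_background_criterion` | — | on | membrane/edge rejection |

The five dataset presets bundle the published operating points; the
threshold parameters are per-dataset by design (chosen once per dataset on
a few tomograms, then fixed) — the intrinsic-statistics formulation is what
makes a single value transfer across the tomograms of one collection.

## Synthetic phantoms

The generator (`tomopick.synth`) emulates what the picker assumes: dark
cosine-tapered spheres (`depth·0.5(1+cos(πd/r))`, so low-passed minima are
well-defined and sub-voxel placement effects are mild) on a flat
background, i.i.d. Gaussian noise, very dark fiducial-like blobs, an
optional dark membrane-like sheet (normal along y, cosine-tapered
cross-section, optional sinusoidal corrugation), and a slab constraint.
Everything is a pure function of the `PhantomSpec`, including its seed.

Placement clearances are part of the model: a particle whose low-passed
support overlaps another dark feature's skirt has no size-scale minimum of
its own (its minimum slides into the deeper valley), so centers must clear
fiducials by `fid_r + 2r + 2` and the membrane mid-surface by
`2r + thickness/2 + 4` voxels. Closer placements are genuinely
unresolvable by a density-minimum method — membrane-proximal targets are a
known limitation, not a test artifact.

Two specs ship with the package. `easy_invitro` (96³ voxels at 10 Å, 20
particles of r = 6 voxels, depth −1, noise σ 0.3, 2 fiducials at depth −12)
emulates a clean in-vitro field of high-contrast particles; its measured
post-low-pass SNR is ~15. `insitu_like` (112×112×96, 30 particles, noise σ
0.35, plus a corrugated dark sheet of amplitude −1.3 and thickness 12
voxels) emulates a crowded cellular volume. Their preset operating points
were chosen from the foreground/background statistic distributions the
brute-force oracles compute on these phantoms: `filter_k = 1.2` for the
easy spec (true spheres and noise dips separate cleanly around k ≈ 1.2),
and for the membrane spec `background_sigma = 100 Å` (at the phantom's
coarse 10 Å pixel the 200 Å default leaves a positive subtraction halo
around the sheet that inflates `proj_mean` near it),
`lowpass_sigma_factor = 0.7` and `filter_k = 0.3`.

What the phantoms do **not** model: CTF, dose and tilt geometry, the
missing wedge (an optional `z_smear_sigma` applies an anisotropic Gaussian
along z to probe elongation robustness), structured cellular background,
and particle shape variability. Passing phantom tests therefore
demonstrates the correctness of the algorithmic chain and its behavior
under noise, crowding, contamination and membranes — not end-to-end
performance on real reconstructions, where the per-dataset thresholds must
be tuned as described above.

## Problem sizes

Tests and the acceptance script run on 64³–112³ phantoms and random
volumes up to 32³ (oracle cross-checks), sizes at which the brute-force
oracles stay exact and the whole suite completes in a couple of minutes on
one CPU. The pipeline itself is O(N) in voxels with small constants
(Gaussian filters, one minimum filter, per-candidate 2D statistics) and is
routinely applicable to full 512×512×256 reconstructions.

## Known limitations

* Lattice-packed or membrane-attached targets defeat the local-minimum
  assumption (the deeper valley wins).
* Strong z-elongation from the missing wedge shifts minima along z; the
  slab restriction mitigates but does not remove this.
* A single radius per run: heterogeneous mixtures need multiple passes.
* The acceptance inequality mixes units by construction (see above); the
  global standardization makes its behavior predictable, but `filter_k`
  values are only comparable between volumes standardized the same way.
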