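# Methods

## The segmentation model

The pipeline assumes a confocal acquisition geometry in which lateral (xy)
resolution is several-fold better than axial (z) resolution — the reference
voxel is 0.691 × 0.691 × 1.75 µm. Every image-processing step before
thresholding is therefore strictly 2D and slice-wise: de-noising, the
derivative maps and the mask never couple z-neighbours. This is a deliberate
trade: lateral contacts between nuclei can be resolved by in-plane gradients,
while axial contacts cannot and are deferred to volume-based post-processing.

### De-noising chain

Gaussian blur (σ = 0.5 px, 5×5 truncated kernel) → optional 3×3 median →
optional Lucy–Richardson deconvolution against a Gaussian PSF → optional
Perona–Malik diffusion, in that fixed order, all with replicated borders.
The diffusion is the explicit 4-neighbour scheme
I ← I + λ Σ g(|ΔI|)·ΔI with g(s) = exp(−(s/κ)²) and λ = 0.25 (the stability
bound for 2D). κ (default 10 intensity units, 4 iterations) separates
gradients to preserve (nuclear edges, ≫ κ) from fluctuations to remove
(≪ κ). The benchmark preset uses only Gaussian + median (no diffusion) with
derivative scale σ_g = 1.1 px; the real-stack default keeps diffusion and
σ_g = 1.5 px.

### Mask and thresholding

Each derivative map is rescaled to [0, 1] by its per-slice maximum (slice-wise
rather than global, so that the weights α, β, ε remain comparable under depth
attenuation). The mask m = ½[1 + tanh(δ − γS)], S = αĜ + βL̂ + εĤ, is strictly
decreasing in S and bounded in (0, 1); at the default weights
(α = β = ε = γ = δ = 1) a flat region (S = 0) gets m ≈ 0.881 while a pixel
where all three maps peak gets m ≈ 0.018.

Otsu's threshold is computed independently per slice on a 256-bin histogram
of that slice's range. Two degeneracy rules apply: a constant slice is all
background, and a slice whose Otsu split separates the two classes by fewer
than 4 background standard deviations is also all background. The second rule
is needed because Otsu always returns a split even for a unimodal
background-only histogram; empirically the separation score is 2–3 for pure
noise and 8–10 for slices containing nuclei, independent of SNR in the range
3–10, so the guard is scale-free and not a tuning knob. It matters only for
stacks with object-free slices (synthetic boxes, image borders); densely
populated tissue stacks never trigger it.

Connected components default to face (6-)connectivity. The mask's lateral
cuts between touching nuclei are one pixel wide; 26-connectivity steps
diagonally across such a line and re-fuses what the mask separated, which
measurably degrades detection in dense scenes. 26-connectivity remains
available for data where objects are large relative to the pixel pitch.

Objects under 10 voxels are discarded as noise. The whole DS path is
deterministic.

### Post-processing of fused objects

Objects with volume above FOV = mean + n·std (population statistics over the
segmented objects) are candidates for splitting. The default n = 0 reflects
densely packed tissue, where examining more objects costs time but not
correctness: an object whose axis profiles are unimodal (mnp = 1) is returned
unchanged by both splitters, so the examination is split-neutral. Raise n on
sparse data to save compute.

Axis profiles are voxel counts per integer coordinate along x, y, z. Profiles
binned finer than 1 µm (the lateral axes) are smoothed with a centred
window-3 moving average before peak finding; the z profile (1.75 µm bins) is
left raw, since a window-3 average there spans 5.25 µm — the size of a whole
nucleus — and erases exactly the fusion-direction peaks being sought. A peak
must exceed 0.2 × the profile maximum and be separated from the nearest
higher accepted peak by a valley below 0.8 × the lower of the two heights.
mnp, the maximum peak count over the three axes, estimates the number of
fused nuclei. Known failure mode: planar arrangements (2×2 sheets) project to
two peaks per axis and yield mnp = 2 for four nuclei; the AIC search below is
the mitigation.

K-means splitting runs with k = mnp on voxel coordinates in µm (clustering in
index space would understate axial distances by dz/dx ≈ 2.5), k-means++ with
10 restarts, then re-examines each child recursively (depth ≤ 3).

GMM splitting fits full-covariance mixtures for k = 1 … k_max and selects the
k minimising AIC = 2p − 2 log L. The search starts at the mnp estimate and
extends past mnp + 1 while AIC still improves, bounded by one component per
40 voxels (≈ a third of a typical nucleus) and 15 overall — deeply fused
chains hide peaks from the profiles, so mnp alone under-counts there. Two
numerical safeguards: covariances are floored at (dz/2)² ≈ 0.77 µm², because
voxel-centre coordinates are lattice-quantised and unregularised EM collapses
components onto single z-planes (which makes AIC prefer spurious splits of
single nuclei); and children under 10 voxels are merged into their nearest
sibling so the children always partition the parent exactly. Both splitters
take an explicit seed; fixed seed ⇒ identical output.

## Baselines

*Watershed.* Two flavours. `watershed_split` is the modern variant:
anisotropy-aware Euclidean distance transform (sampled in µm), Gaussian-
smoothed (σ = 1 voxel), flooded from its regional maxima — it splits convex
fusions cleanly. The benchmark baseline (`ds+watershed`) is the classic
intensity-flooding variant: inverted de-noised intensity, seeded from every
26-connected local maximum inside each object's mask and applied to *every*
object. Residual noise leaves several maxima per nucleus, so this flavour
over-segments — near-perfect sensitivity with precision ≈ 0.6, flat in
density — which is precisely the textbook failure mode the comparison
exhibits. Gating it by the FOV threshold or smoothing its seeds would hide
that phenomenon, so the baseline does neither.

*LoG.* Scale-normalised −s²∇²G responses over a small scale ladder
(2–4 µm, 4 scales), local maxima in (scale, z, y, x) above 0.15 × the peak
response, overlap-suppressed at 4 µm. The kernel is isotropic in voxels
(converted via the lateral pitch), as in stock blob detectors; under
anisotropic sampling it is therefore elongated in physical z. This is
intentional: the baseline represents off-the-shelf usage, and its weakness on
elongated, size-heterogeneous nuclei is part of what the benchmark measures.
(An anisotropy-corrected LoG on these clean synthetic blobs would outperform
everything — unrepresentative of practice on real tissue.)

## The synthetic world

Nuclei are prolate ellipsoids, semi-axes (4, 2, 2) µm with ±15% independent
uniform jitter — a 8 × 4 × 4 µm nucleus, typical of zebrafish PSM tissue.
Placement is random sequential addition of *hard* ellipsoids: a candidate is
rejected if its centre lies closer to an accepted nucleus than 90% of the sum
of the two directional radii along the centre line (plus an absolute 3 µm
floor). Nuclei are impenetrable organelles; allowing deep interpenetration
(as a small isotropic centre gap would) fills in the waists between fused
nuclei and destroys the very voxel-profile valleys that post-processing
relies on. The 10% tolerance mimics slight deformation of touching nuclei.
This geometry keeps the full benchmark density range 1–4.5 × 10⁻³ µm⁻³
placeable (nuclear volume fraction 13–60%).

Orientations follow a von Mises–Fisher law about +z whose concentration is
solved in closed form so that the ensemble nematic order parameter — the
largest eigenvalue of Q = (3/2N) Σ uuᵀ − I/2 — matches the requested
alignment target (0 = isotropic, 1 = perfectly aligned).

Intensities are gamma-distributed: inside nuclei shape = SNR² (so
mean/std = SNR exactly), mean 100; background shape 4, mean 25 — Otsu-
separable but noisy, on a 16-bit scale. Voxels inside several nuclei take the
maximum of independent draws (fluorescence saturates at contacts; no seams).

**What a green benchmark does and does not establish.** The generator
reproduces density, anisotropy, packing, orientation order and first-order
intensity statistics. It does *not* simulate PSF blurring, depth attenuation,
chromatin texture, or optical cross-talk. Consequences worth knowing:

* Contacts between rendered nuclei have geometric pinches but no dim
  PSF-blurred seam. Mechanisms that act on such seams — e.g. noise
  destroying saddle points, which in real data makes low SNR costly at high
  density — are absent. In this world, low SNR actually *helps* slightly at
  the highest densities: the broader nuclear gamma raises the Otsu threshold,
  erodes objects, and eroded objects separate more easily. A benchmark result
  on SNR ordering therefore does not transfer to real optics.
* Slices far from any nucleus contain only noise; the Otsu guard handles
  them, but single isolated nuclei occupying ≲ 1% of a slice's area can fall
  below Otsu's bimodality resolution and be missed. Real dense tissue does
  not approach this regime.

## Evaluation conventions

Matching is a global minimum-cost one-to-one assignment on the bipartite
truth × detection graph with all pairs beyond 2 µm (half a typical nuclear
radius) excluded from the problem itself; leaving a point unmatched costs one
radius, so every admissible match is taken and the matched set has minimum
total distance. Degenerate denominators (no truths / no detections) yield
flagged reports rather than exceptions. In the two-channel mode only
sensitivity is defined (unmatched dense detections are typically real nuclei
without a sparse label) and precision is reported as NaN.

Physical coordinates put voxel centres at (i + 0.5)·pitch; centroids are
means of voxel centres, reported (x, y, z) in µm. Sub-voxel conventions are
applied identically to truth and detections, so they cancel in the matching.

## Reproducibility

Every stochastic path (placement, rendering, K-means, GMM, sweeps) takes an
explicit integer seed; sweep drivers derive per-condition seeds with
`numpy.random.SeedSequence`, so results are independent of evaluation order.
Scene manifests record all parameters and the seed; regenerating from a
manifest is bit-identical.
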