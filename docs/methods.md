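# Methods

## Scope and model overview

meiotrack analyses kinetochore (KT) behaviour in time-lapse 3D
recordings of *Drosophila* spermatocyte meiosis and provides a
generative model of the same behaviour for validation. A recording (or
simulation) covers one division — meiosis I (M I), interkinesis (IK)
or meiosis II (M II) — sampled at 10 s intervals, with 3D positions in
micrometres. A "pair" is the pair of KT signals carried by one
chromosomal unit: the two homolog KT units of an M I bivalent, the
conjoined sister KTs of an M II dyad, or the sister-KT dot of a
univalent in *mnm*/*tef* mutants.

## The trajectory generator

The generator is a phase-switched stochastic model. It is not itself a
published model; it is the minimal kinematic program that reproduces
the published phenomenology (phase durations, jump/congression
behaviour, V/A/D signatures, excursion and breathing statistics), so
that recovering those published values from simulated cohorts is a
meaningful end-to-end test of the analysis.

Per cell, phase durations (minutes) are drawn from per-phase normal
distributions. The control defaults are the published values:

| division | prometaphase A | prometaphase B | metaphase | anaphase | telophase | total |
|---|---|---|---|---|---|---|
| M I  | 5 ± 1.5 | 9.75 ± 3 | 18 ± 4 | 10 ± 2 | 15.25 ± 3 | 58 |
| M II | 5 ± 1.5 | 7 ± 2    | 18 ± 4 | 10 ± 2 | 16 ± 3    | 56 |
| IK   | 54 ± 8 (single phase) | | | | | 54 |

The anaphase mean of 10 min realizes the published assumption that the
metaphase→anaphase transition precedes telophase onset by about
10 minutes; the telophase means close the division totals at
58/56 min. Within each phase:

* **pre-NEBD / prometaphase A** — all pair centres share a saturating
  concerted drift (0.004 μm/s scale, displacement capped ≈ 2.4 μm) plus
  per-pair AR(1) (Ornstein–Uhlenbeck-like) positional jitter
  (σ = 80 nm, lag-1 coefficient 0.8), keeping frame-to-frame speeds
  well below the jump scale;
* **prometaphase B** — per pair, a schedule of ballistic pole visits at
  the jump speed (0.10 μm/s): a jump into the polar zone, a dwell
  (20–60 s), a return to the plate region. During each jump the leading
  KT transiently stretches ahead of its partner (0.5 μm for bivalents,
  0.15 μm for conjoined sister dots) so jumps are KT-led. The number of
  visits is Poisson with mean (excursions_per_pair + 1)/2 — each
  completed visit yields two polar↔equatorial transits, while the first
  poleward trip from a start outside the plate band completes none.
  One designated pair jumps exactly at the phase boundary (the boundary
  *is* the first KT–MT interaction). In cells with a scheduled
  re-orientation (control default: one per cell), the pair with the
  largest time budget jumps to one pole and then across to the
  opposite pole;
* **capture/congression** — each pair is assigned a stabilization time;
  with tension-mediated stabilization these are uniform over the later
  70 % of prometaphase B and the last one defines metaphase onset;
  without it (*mnm*/*tef*) all pairs stabilize near the ~25 min
  time-dependent onset. The congression move is timed backwards from
  the stabilization time (trailing dwells are shortened if needed) so
  the pair arrives exactly then, with its inter-KT axis interpolated
  onto the spindle axis during the approach;
* **metaphase** — tight jitter (σ = 35 nm) around a plate slot; the
  pair axis wobbles a few degrees about the spindle axis;
* **anaphase** — each KT moves ballistically (0.03 μm/s) to its
  destination pole; true positions carry no jitter between anaphase and
  telophase onset, making the within-pair distance non-decreasing by
  construction (measurement noise is added only to the exported table);
* **telophase → interphase** — rest at the poles while a
  decondensation proxy ramps linearly from 0 to 1.

Two proxy channels stand in for signals the original scoring used but
the model does not image: a nucleoplasmic signal that drops from 1.0 to
0.2 over 30 s at NEBD (for His2Av nucleoplasmic release), and the
decondensation ramp between telophase and interphase onset (for
chromatin shape and the mitochondrial autofluorescence cues). Telophase
scoring on real data must instead be supplied externally.

Separation courses: bivalent homolog KTs rest at 1.6–2.4 μm and
stretch ×1.15 under bi-orientation. M II sister separations start at
N(300, 160) nm at NEBD II (floored at 50 nm), rise by ~100 nm during
the MT-independent first five minutes, and ramp to a per-pair plateau
drawn from N(950, 100) nm on bi-orientation. IK dots rest at
80–140 nm; breathing events (Poisson, 0.17 /dot/h) raise the
separation to a box profile of 420–560 nm for 20–40 s (20 % of events
last up to 3 min). Event amplitudes sit above the two-maxima
resolution limit because a breathing event is, by definition, an
episode resolved into two maxima; the ~550 nm ceiling matches the
reported maximal splitting. *mnm* univalents follow their class:
class I univalents (default 30 %) stretch to 330 nm in the
metaphase-like period and split to 700–900 nm starting at the m/a
transition; class II (38 %) stay unresolved at the plate; class III
(32 %) depart polewards before the m/a transition.

Cysts: phase durations are drawn once per cyst; each cell shifts every
boundary by an independent uniform offset within the synchrony bound
(default ±1 min), and the within-cyst dispersion implied by that bound
is removed in quadrature from the cyst-level draw, so per-cell
dispersion equals the configured s.d. and a zero bound gives perfectly
synchronous cells. Per-cell seeds are spawned deterministically from
the root seed.

Cohorts for recovery experiments (`simulate_cohort(..., stratified=True)`
and everything in `meiotrack.recovery`) draw the per-cyst standard
normal deviates from a shuffled symmetric quantile grid, and the
control-vs-*mad2* contrast pairs the two cohorts on common per-cell
seeds. Both are standard Monte Carlo variance-reduction devices chosen
at design time: marginal distributions are unchanged, but a desk-scale
cohort mean estimates the configured mean rather than cohort-sampling
noise. Plain `simulate_cyst` is unstratified.

## Rendering

KTs are rendered as anisotropic Gaussian blobs (σ_xy = 120 nm,
σ_z = 350 nm) on a 100 × 100 × 300 nm voxel grid (the acquisition's
z-spacing), with Poisson photon noise plus Gaussian camera noise; the
chromatin channel holds broad blobs at pair centres plus a diffuse
nucleoplasm component scaled by the NEBD proxy. Blob-pair fixtures for
separation studies place the two sources symmetrically along a random
in-plane axis, matching the published in-plane ("longest axis within
the x-y plane") measurement geometry.

## Analysis pipeline choices

* **Spot detection** — Laplacian-of-Gaussian matched filter at the
  sigma implied by the 500 nm target diameter; threshold = median +
  10 robust σ of the response (so blank frames yield nothing);
  intensity-weighted centroid refinement; duplicate peaks within
  300 nm merged. On default renders the median 3D localization error
  is ≈ 60 nm.
* **Pair separation** — the published manual two-sphere placement is
  automated as: 50 %-of-peak mask (components within 1.6 μm belong to
  one object), in-plane principal axis from intensity second moments,
  then a least-squares fit of two symmetric 2D Gaussians (PSF σ fixed)
  along that axis on the z-projected patch; two sufficiently separated
  prominent maxima (≥ 300 nm apart, ≥ 55 % of peak) mark the estimate
  "resolved". Estimates below 150 nm are censored at the floor rather
  than reported as point values — the manual procedure could not have
  produced them either. The moment relation var_major = σ² + (d/2)²
  provides the fit's initial value. The estimator is monotone over
  0–1200 nm and recovers 300 nm blobs to within ~15 nm (positively
  biased by censoring, consistent with its upper-bound reading).
* **Linking** — constant-velocity prediction, global minimum-cost
  assignment gated by a search radius (1.8 μm, growing with missed
  frames), gap closing up to 3 frames with flagged interpolation. The
  commercial tracker's autoregressive order is unknown; constant
  velocity is the stand-in, and accuracy is reported against ground
  truth instead of emulating manual curation.
* **Pairing** — minimum-weight perfect matching (blossom algorithm) on
  mean within-pair distance over the pre-jump window; for ≤ 10 tracks
  the 105-matching enumeration also flags near-ties (< 5 %) as
  ambiguous; anaphase divergence of paired tracks is checked when
  phases are known.
* **Jump threshold** — 3 × the 95th percentile of speeds in the first
  12 post-NEBD frames of the same cell, floored at 3 × 0.02 μm/s.
  Self-calibrating across noise levels; no published number exists.
* **Metaphase onset** — all pairs simultaneously inside the 3 μm plate
  band (pair midpoint), A_KT < 30°, speeds < 0.025 μm/s, sustained for
  6 frames (60 s). The mobility threshold sits ~3× above metaphase
  jitter+noise speeds and ~4× below the jump scale.
* **Anaphase onset** — first median-D_KT step > 0.3 μm that is
  sustained (+0.45 μm within 4 frames); the median implements the
  majority rule across bivalents.
* **Spindle frame** — anaphase-destination convention: KT end
  positions cluster into two poles (reference pole = that of the
  lowest-id track, for determinism), per-frame unit pair vectors
  oriented towards it and averaged over the last ≤ 35 metaphase
  frames. Without anaphase (colcemid, *mnm*) the fallback is a
  sign-free PCA: for bivalent-scale pair vectors, of the vectors
  themselves; for conjoined sister dots (vectors too short to carry
  direction) of the KT position cloud, restricted to samples ≥ 2.8 μm
  from the plate centre (polar excursions carry the axis; plate
  residency only spreads the cloud across the plate). The plate centre
  is then the median position over the late metaphase-like window.
* **Zones** — equatorial band 3 μm (≈ ¼ of the 12 μm pole-to-pole
  distance); polar zone = outer quarter of each half-axis, the
  symmetric complement. An excursion is a completed polar↔equatorial
  transit (each direction counts one); the intermediate region does not
  reset a transit.
* **Re-orientations** — supra-threshold speed runs are segmented; the
  leading KT is the one with the highest peak in-run speed (endpoint
  displacement is noise-driven because the leading stretch vanishes at
  run boundaries); a run is a poleward jump if the pair centre moves
  ≥ 1 μm axially and settles inside a polar zone one frame after the
  run. Consecutive opposite-pole jumps of the same KT form one event;
  partner displacement towards the opposite pole in between is
  annotated as transient bi-orientation.
* **Breathing** — an event is a maximal run of ≥ 2 consecutive frames
  (≈ 20 s at 10 s cadence) with the resolved flag set; rate = events /
  (dots × observed hours). The trajectory-mode pipeline substitutes a
  350 nm separation proxy for optical resolvability; image-based
  analyses use the real two-maxima criterion.
* **Univalent classes** — the m/a transition is inferred as telophase
  onset − 10 min (configurable). Class I: plate residency ≥ 0.7 over
  the metaphase-like window and a sustained splitting run
  (≥ 450 nm, ≥ 2 frames) starting no earlier than 2 min before the
  inferred m/a; class III: poleward departure before the m/a and no
  splitting run at all; class II: remainder. The 450 nm split
  threshold separates "noticeably elongated" (≈ 330 nm) from "clearly
  resolved" dots; borderline elongations are carried in the evidence
  record.

## What the simulations do and do not show

Passing recovery tests shows the pipeline correctly inverts the
generative model at realistic noise, sampling and cohort sizes — it
does not certify performance on real movies, whose failure modes
(photobleaching, stage drift, overlapping chromatin, z-anisotropy of
real PSFs, missed z-splittings of breathing events, cyst geometry) the
generator deliberately omits. The published estimate that breathing
frequency is underestimated by z-blind detection, for instance, has no
counterpart here because simulated splitting axes are in-plane.
Chromosome-identity assignment (X–Y vs autosomes), deconvolution and
MT-channel analyses are out of scope.

## Problem sizes and numerics

Recovery cohorts run at the published n (13 cysts; 6/9/10 cells; 44/51
blobs; 23 IK cells; 5 M II cells; 28 *mnm* cells), which keeps the
full acceptance run at about a minute and the test suite under two
minutes on one CPU. Degenerate inputs raise explicit errors (odd track
counts, overlapping zones, uncalibrated stacks, missing cadence,
unscored telophase for classification); boundaries that cannot be
scored are reported as missing with an "unscored" tag, never guessed.
Ties in linking resolve to the lower track id; all simulation
randomness flows from a single integer seed through spawned
sub-streams, and identical (config, seed) pairs reproduce outputs bit
for bit.
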