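# Methods

`mmgait` re-creates, at desk scale, a millimeter-wave radar gait-analysis
system: a 60 GHz FMCW sensor watches people walk, the echo is processed into
sparse 5D point clouds, and two parallel branches — a micro-Doppler
spectrogram classifier and a point-cloud-to-skeleton regressor — are fused
into one of five walking-posture classes: W1 normal, W2 stooped, W3 limp,
W4 walker, W5 cane.  Because no public dataset of this kind exists, the
package includes a synthetic gait/radar simulator that stands in for both
the human-subject study and the radar hardware; every quantitative claim in
the test suite is made against data this simulator generates.

## Radar model

The waveform configuration mirrors a TI IWR6843ISK-ODS short-range profile:
start frequency 60.75 GHz, centre 63.008 GHz, valid sweep bandwidth
B = 1780.393 MHz, 3 TX x 4 RX TDM-MIMO, 96 complex ADC samples per chirp at
2.95 Msps, 288 chirps per 55 ms frame, 15 dB CFAR thresholds.  Closed
forms:

- range resolution `dR = c / 2B = 0.084 m`; max range
  `Rmax = 96 * dR = 8.083 m` (the ADC window `Tc = 96 / Fs = 32.5 us`
  defines the chirp slope `S = B / Tc`);
- beat frequency to range `d = f_if c / 2S`; chirp-pair phase to velocity
  `v = w lambda / 4 pi Tc`; antenna-pair phase to angle
  `theta = asin(w lambda / 2 pi d)`.

The chirp repetition interval is taken as idle + ADC-start + sampled ramp
(30 + 25 + 32.5 us = 87.5 us); with the 3x TDM factor this gives
Dmax = 4.53 m/s and dD = 0.094 m/s, within 2 % of the datasheet's
+-4.450 / 0.093 m/s, whose exact ramp timing is not recoverable from the
published parameters (those two published rows are also carried verbatim as
configured constants).  The alternative reading — frame period divided by
chirp count — would cap unambiguous velocities at 2.1 m/s, below brisk
walking plus limb swing, and is rejected for that reason.

The sensor is mounted 2 m high, pitched 15 degrees down; a single rigid
transform maps the antenna frame to a world frame with x lateral, y depth,
z up, floor at z = 0.  The virtual array is modelled as a uniform planar
half-wavelength aperture, 4 elements in azimuth by 3 in elevation; the real
device's nonuniform layout is out of scope.

## Gait simulator

The kinematic model is a rigid-segment 25-joint chain (Kinect V2 joint set)
driven by phase-offset sinusoids, not a biomechanical simulator: its job is
to produce class-discriminable radar signatures with exactly controllable
gait parameters.  Segment lengths are fixed fractions of standing height;
subject heights are drawn from the emulated study population
(170 +- 5.55 cm).  Per frame, the pelvis advances along the walk path
(paths: lateral crossing, toward/away walk, or free wandering, with
rate-limited turnarounds at the walk-area edge), thighs swing
+-0.35 rad at the stride frequency (cadence / 2), knees flex during swing,
arms counter-swing, and the pelvis sways laterally and bobs vertically.
Class effects: W2 pitches the trunk by `stoop_pitch` (default 0.35 rad) and
damps arm swing; W3 scales one leg's swing amplitude by `limp_asymmetry`
(recovered to within a few percent as a step-length ratio) and doubles
lateral sway; W4 pins both arms forward and attaches a 4-point rolling
walker frame; W5 suppresses one arm's swing and attaches a 2-point cane
from that hand to the floor.  Class-typical speeds/cadences (1.25 m/s /
1.9 steps/s normal, down to 0.55 m/s / 1.3 steps/s with a walker) follow
common gait-laboratory ranges, with +-15 % per-subject variation.  Bone
lengths are constant by construction; walking speed and cadence are
independent dials (the model is not dynamically self-consistent — no
ground-contact constraint).

Reflection centres: one scatterer per joint, one per limb/torso segment
midpoint, plus the device anchors; torso reflectivity 1.0, limb midpoints
0.45, joints of the extremities 0.18, device metal 0.8.  Amplitudes follow
1/r^2 on the IF signal (the "range effect" the spectrogram stage later
compensates).

Two simulation routes exist.  The echo route synthesizes the deramped IF
signal per chirp and virtual antenna (beat phase, Doppler phase across the
TDM slow time, planar-array spatial phase, complex Gaussian noise) and is
used to validate the DSP chain oracle-style.  The fast route emulates a
detector's output directly: each scatterer is dropped with probability 0.35
(sparsity, as real clouds show), survivors get anisotropic position jitter
— 2 cm along the line of sight, 6 cm across it, and 4/3 of that on the
elevation-like tangent, reflecting precise ranging versus coarse angular
resolution from the small aperture — Doppler noise of 0.04 m/s, and 1/r^2
intensity.  All experiments at scale use the fast route.

What the generator does not emulate: multipath and ghost targets,
occlusion/self-shadowing, RCS fluctuation and clothing, soft tissue
articulation, irregular cadence, and real Kinect tracking error (the
ground-truth skeletons are exact).  Passing tests therefore demonstrate
that the pipeline recovers what this model encodes, not field performance.

## Signal processing

Range FFT then Doppler FFT (per TX de-multiplexed), Hann on both axes;
approaching targets map to positive velocities.  MTI nulls the zero-Doppler
bin +-1 by default (Hann leakage puts 25 % of a static return in the
adjacent bins; DC-only nulling is available behind the same interface).
Detection is 2-D cell-averaging CFAR with 2 guard and 4 training cells per
side (the window follows common CA-CFAR practice; only the 15 dB threshold
is specified by the emulated device), whose false-alarm rate obeys
`Pfa = (1 + T/N)^-N` — verified by Monte Carlo at a measurable 6 dB
threshold, since at 15 dB over 144 training cells Pfa ~ 4e-13.  Angles come
from zero-padded FFTs over the azimuth and elevation apertures with
per-TX-slot Doppler compensation.  DBSCAN (eps 0.3 m, min 5 points;
defaults are engineering choices) separates subjects; a constant-velocity
Kalman filter per cluster centroid tracks them (gate 0.8 m, confirm after
3 consecutive hits, drop after 5 consecutive misses — initiation and
termination counts are engineering choices).  The chain is deterministic
given its inputs.

## Micro-Doppler branch

Each tracked point deposits its range-compensated intensity
(`I * (r / 1 m)^2`) into the Doppler bin of its frame column; 2 s windows
(about 36 frames, covering at least one gait cycle) slide at 1-frame
stride by default and are normalized to unit maximum, making the branch
invariant to absolute reflected power.  Windows are resampled to 64 x 64
and log-compressed (`log(1 + 100 v) / log(101)`) so the limb micro-Doppler
wings are not drowned by the torso line.

The classifier is four blocks of [3x3 conv -> leaky ReLU (slope 0.01) ->
2x2 max pool -> dropout 5 %] with depths 32/64/128/256, flattened into a
single dense softmax layer over the five classes (~408 k parameters).
Training: Adam at 1e-3, batch 32, cross-entropy, subject-held-out
validation split, early stopping on validation loss with the best weights
restored.  Label-preserving augmentation — velocity-axis flip (walking
toward vs away mirrors the axis), time flip, and circular shifts of up to
6 time / 2 velocity bins (a window starts at an arbitrary gait phase) — is
applied on the fly; it is the main defence against overfitting to the
small number of simulated subjects.  Classification experiments use the
toward/away walk, where micro-Doppler is informative (at broadside radial
velocities vanish).

## Pose branch

Frames are canonicalized to a fixed 64-point x 5-channel tensor: points
more than 3 m from the frame centroid are dropped as scatter outliers, the
rest sorted by (intensity desc, range asc, x asc), truncated or zero-padded,
and the xyz channels centred on the cloud centroid.  The regressor — 1-D
convolutions over the point axis with 16 and 32 channels, batch norm and
dropout 0.3/0.4, then 512-unit and 57-unit dense layers — predicts the 19
joints relative to that centroid (translation-normalization stabilizes
training); an auxiliary 6-unit sigmoid head scores the per-hand wrist
candidates.  Kinect-style ground truth is paired by nearest timestamp
(tolerance: half a frame period) and a constant x mounting offset is
removed by least squares between cloud-centroid x and the spine-mid
trajectory.  The 25 -> 19 reduction collapses each hand's four recorded
candidates (wrist, hand, hand tip, thumb) to one wrist — highest confidence
when scores are available, else the canonical wrist.  Loss is MSE on the 57
coordinates (+0.1 x BCE on the confidence head), Adam at 1e-3.

On held-out synthetic lateral walks the regressor reaches ~5 cm average
MAE per axis versus a ~9 cm predict-the-mean baseline, with the horizontal
(x) axis worst and the wrists the hardest joints — the orderings the
radar's geometry dictates.  Depth (y) beats x but lands near, not below,
the vertical axis: the regressor's z error is set by the learnable rigid
vertical body structure rather than by measurement noise, which is where
this generator's noise model stops mirroring the real system.

## Fusion

The skeleton branch summarizes a window of skeletons into eight features —
mean trunk pitch, left/right step-length ratio (side-agnostic), per-arm
swing amplitude, gait-cycle period (autocorrelation of foot excursion),
walking speed, lateral sway, and the fraction of low leading points (the
signature of a walker frame or planted cane) — scored by a multinomial
logistic (softmax) layer.  Because the pipeline feeds this branch
pose-*estimated* skeletons, whose features are noisier and flatter than
the ground truth (estimated trunk pitch shrinks toward the mean posture,
frame-to-frame jitter fakes step asymmetry), the classifier is trained on
both domains — ground-truth and pose-estimated skeleton features of the
same windows — with moderate regularization (C = 1) so its probabilities
stay calibrated; an overconfident skeleton branch would otherwise overturn
correct micro-Doppler decisions on atypical windows.  The final prediction is the convex combination
`Wp = w * p_doppler + (1 - w) * p_skeleton` with w = 0.5 by default, argmax
ties broken toward the micro-Doppler branch.  Probability-level late fusion
is the central interpretive decision: the source system's combination
operator is not defined beyond "sum", and a convex combination is its
minimal probabilistic reading.  The full pipeline (tracked clouds ->
per-track spectrograms and skeletons -> fused per-window labels) supports
multi-subject scenes and within-walk activity transitions.

## Problem sizes and numerical choices

Experiments are sized for a single CPU: the recognition study simulates 8
subjects per class for 8 s each (about 220 windows per class at a 4-frame
stride, two subjects per class held out), trains at most 20 epochs with
patience 4; the pose study uses 10 subjects x 6 s (about 1100 frames,
2 subjects held out), at most 40 epochs with patience 6.  The networks run
in float32 on a small numpy layer stack (im2col convolutions over BLAS,
bit-reproducible for a fixed seed).  Degenerate inputs are contracts, not
crashes: empty frames give all-zero tensors, an all-zero spectrogram is
returned unnormalized, a frozen skeleton window warns and returns finite
features, equal-magnitude FFT peaks resolve to the lowest bin index by
argmax convention.

## Known limitations

Simulated classes are cleaner than real gait (the ~95 % held-out accuracies
say nothing about clinical data); the parametric walker cannot express
pathologies beyond its dials; tracking is centroid-based and will merge
subjects closer than the DBSCAN radius; the elevation aperture model is a
uniform-array idealization; and the published headline accuracies cannot be
reproduced because the underlying human-subject dataset is not public.
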