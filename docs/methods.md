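# Methods

This note records the models behind each module, the defaults and why they
were chosen, and what the synthetic data do and do not emulate.

## Tightrope trajectory model

A particle on a tightrope of length L (µm) performs a discrete-time Gaussian
random walk: per frame of duration Δt the true position gains a step of
variance 2·D·Δt, reflected at the bead anchors [0, L].  Reflection is the
right boundary for bead-anchored DNA — an absorbing end would conflate
photobleaching/unbinding with boundary loss.  Reported positions add
independent Gaussian localization noise (default σ = 16 nm, the precision of
Gaussian-fit localization on the imaging platform being emulated) and are
clipped to the tightrope.  An optional per-frame detachment rate produces
absent frames; a rate of ln(1/0.8)/120 s⁻¹ reproduces ~80% retention after
two minutes.

Defaults: D = 0.1 µm² s⁻¹ (the dsDNA search-mode regime), Δt = 0.05 s
(40 frames per 2 s ⇒ 20 fps), σ = 16 nm.

### Two-state (search/recognition) switching

A diffusing particle within a capture radius (default 20 nm) of a marked
site becomes captured with per-frame probability 1 − exp(−k_pause·Δt); a
captured particle sits exactly at the site and is released with probability
1 − exp(−k_release·Δt), resuming diffusion from the site.  A point site is
never hit exactly by a discrete-step walk, so capture needs a finite radius;
20 nm is comparable to the localization precision.  The capture and release
rates are not measured quantities: the defaults (k_pause = 0.5 s⁻¹,
k_release = 0.1 s⁻¹) are tuned so that the gapped-tightrope scenario sits
near a 25% stationary captured fraction, which at 16-nm noise yields ~20%
static windows (see below).  They are tuned, not measured.

### Kymograph rendering and localization

Each frame column is the PSF (Gaussian, default σ = 125 nm) integrated over
50-nm pixels, scaled to a photon budget, with Poisson noise on signal plus
background.  Localization fits a Gaussian plus constant offset by
least squares in a ±4σ window around the brightest pixel; a fit is rejected
when the amplitude fails to clear k = 3 times the robust background noise
(1.4826·MAD), when the optimizer diverges, or when the center leaves the
image.  The k = 3 rule is a design choice, not a measured threshold.  At
~100 detected photons/frame over a background of 2 counts/pixel the static-
emitter scatter is ≈ 16–18 nm, the regime the trajectory noise default
emulates.  Pixel centers sit at (i + ½)·pixel size.

## MSD, D and α

`compute_msd` is the exact time average over all ordered frame pairs at each
lag; pairs with an absent endpoint are excluded.  `fit_diffusion` regresses
log MSD on log t (α = slope, D = e^intercept/2, R² on that regression) and
also reports D with α fixed at 1 (line through the origin).  Which of the
two D estimates corresponds to a given published value is often ambiguous,
so both are exposed.

Numerical choices:

* Default fit range: the first 25% of lags (≥ 4 usable lags required;
  lags with non-positive MSD or fewer than 5 pairs are dropped).  Long lags
  of a time-averaged MSD are few-pair, strongly correlated noise.
* Finite single trajectories bias the log-log α estimate downward by a few
  hundredths (e.g. ensemble mean α ≈ 0.94–0.95 for 300-frame unbiased walks
  fitted over 25% of lags).  Restricting to the first 10% of lags reduces
  the bias to ≈ 0.02; the ensemble-recovery test uses that range.  This is a
  property of the estimator, not of the walk.
* The 2σ² localization-noise floor appears as a constant MSD offset; it is
  absorbed by fitted intercepts, never subtracted from the data.

Mobility classification is the fixed rule: mobile iff D > 5×10⁻⁴ µm² s⁻¹
and R² > 0.8.

## Sliding-window D_int and static events

Within each 40-frame window (stepped by 1 frame; overlapping windows
maximize boundary resolution), the within-window MSD over lags 1..10 is fit
with a straight line in lag time; D_int = max(slope/2, 0), and the window is
static when D_int < 1×10⁻⁴ µm² s⁻¹.  The slope-with-intercept estimator is
chosen over MSD/2t because a paused particle with localization noise has a
*flat* MSD at 2σ²: the intercept absorbs the floor and the slope is
centered on zero, whereas a point estimate would be biased up by the floor.
Windows containing absent frames are skipped.

A variance analysis of the slope estimator shows that at σ = 16 nm and
Δt = 0.05 s its sampling sd for a fully paused window is ≈ 1×10⁻⁴ µm² s⁻¹ —
the threshold sits about 1σ above the noise-floor center, so only ~80–85% of
truly paused windows are called static at that precision (at σ = 8 nm the
sensitivity is ≳ 99%).  This is intrinsic to thresholding at the noise
floor.  Consequences: (i) the fraction of static windows in the tuned
gapped scenario lands near 20% although the stationary captured fraction is
25%; (ii) the test that compares window occupancy against an independent
Markov-chain stationary distribution runs the generator at σ = 8 nm so it
isolates the kinetics bookkeeping from threshold sensitivity.

Runs of ≥ 20 consecutive static windows (≈ 1 s of agreement) become events;
runs separated by < half a window are merged first.  The minimum-run default
suppresses single-window false positives and is a design choice.  Event
position is the mean reported position over the run's frames; with pauses of
seconds, that mean is accurate to a few nm.  Known limitation: segments
confined near a reflecting boundary can mimic binding and produce
occasional label-free detections; the event tests therefore match events
against the simulator's hidden state labels.

## AFM position distributions and specificity

The deposition generator places each complex independently on one of N
binding sites (one per bp); a site marked specific carries probability
weight S relative to 1 for a nonspecific site, so S = 1 is exactly uniform.
Positions are reported as % of length from the *closest* end (folded to
0–50%, so a substrate contributes two end sites and one site per internal
feature).  Volumes are log-normal (median 1000 nm³, σ_log 0.25 — chosen to
bracket reported oligomer volumes; only means ± SE are published) and
heights Gaussian (1.41 ± 0.30 nm).

The specificity estimator generalizes the fractional-occupancy formula
S = N·A_SP/A_NSP + 1.  Raw counts in the specific bins include the baseline
nonspecific occupancy of the sites those bins cover, which biases the plain
ratio upward (to ≈ S + 1 even for an infinitesimally narrow region, and
much worse for finite bins); the historical peak-area method measures the
specific peak *above* the background.  The default therefore subtracts the
expected baseline:

    S = 1 + (N / n_sp) · ((1 − f)·A_SP − f·A_NSP) / A_NSP,

where f is the fraction of binding sites inside the specific bins and n_sp
the number of specific sites.  This reduces to the plain formula as f → 0
with n_sp = 1, is unbiased for all S ≥ 1, and is floored at 1 (S < 1 is
outside the preferential-binding model).  The uncorrected value is retained
as `eq1_value`.  The standard error is a seeded bootstrap (1000 multinomial
resamples of the histogram).  N defaults to the substrate length in bp;
published S values depend on the (usually unstated) choice of N and of the
specific-region width, so cross-study comparisons should fix both.

Histogram defaults: 2.5% bins (20 bins over 0–50%); the end region is the
first bin unless an explicit end radius in bp is given.

Volume → molecular weight uses the linear calibration V = 1.45·M_r − 21.59
(V in nm³, M_r in kDa); copy number is the rounded ratio of implied mass to
monomer mass, with the unrounded ratio also returned.

## Spacing mixtures

Nearest-neighbor distances are collected per tightrope; each unordered
mutual pair contributes once by default (`dedupe=False` gives per-particle
distances, the quantity the 1D Poisson law Exp(2·rate) describes).  Peaks
are located with a Gaussian mixture fitted by EM (20 seeded restarts);
k is chosen by BIC over 1..4 when not given.  Components narrower than the
16-nm imaging resolution are degenerate spikes and trigger a refit with one
fewer component.  R² compares the mixture density with a Freedman–Diaconis
histogram; the mixture's EM log-likelihood trace is recorded and is
non-decreasing by construction.

## Anisotropy isotherms

The law-of-mass-action fit treats total protein as free protein, valid for
probe concentrations ≪ K_d (the ~1 nM probe regime); an optional
depletion-corrected quadratic mass balance is provided for completeness and
is off by default.  Starting values come from the data (P_free at the lowest
concentration, P_bound at the highest, K_d at half-amplitude); K_d is
bounded by 10× the largest concentration.  Fits are unweighted least
squares; the reported K_d uncertainty is the SE of the fit (not a replicate
SD) and is labeled as such.  A titration whose fitted response span over the
measured range stays below 3× the residual sd is flagged "no detectable
binding" — the span criterion, rather than the raw amplitude, prevents a
flat curve fitted with a huge K_d and huge amplitude from escaping the flag.

## What the generators do not emulate

No photophysics (blinking, bleaching), no 2D/3D motion or flow, no motion
blur within a frame, no multi-particle interactions or collisions, no AFM
position-measurement error (deposited positions are exact site positions),
and no probe depletion in titrations unless requested.  Passing tests
therefore validate the estimators under idealized noise models; on real
data, drift, blinking and tracking errors add variance the tests do not
probe.

## Problem sizes

The validation suite uses ensembles chosen to make Monte-Carlo error small
relative to each tolerance while keeping runs quick: 200 trajectories of
300–500 frames for D/α recovery, 50×500 frames for the static-window
false-positive bound, 60×6000 frames against the Markov oracle, 20,000
deposited complexes per specificity round trip (on a 1000-bp substrate with
10 marked sites — denser sites shrink the estimator's variance at S = 1,
where a single site on a 2-kb substrate would need far larger samples), and
200 noisy titrations for K_d recovery.
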