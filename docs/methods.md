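# Methods

This note records the models, conventions and numerical choices behind
`specfx`, and what the synthetic generators do and do not emulate.

## Fingerprint construction

Chromatograms are two-column traces (minutes, detector response) on a
strictly increasing grid. Peak detection uses topographic prominence
(`scipy.signal.find_peaks`); the default prominence threshold of 10
intensity units sits well above the simulator's noise floor (σ = 0.3) and
well below its smallest peak heights (≥ 30). A peak's bounds are its
flanking valleys, defined as the lowest trace sample between the apex and
its neighbouring apexes (or the trace ends). This global-minimum definition
coincides with the nearest-local-minimum definition on noiseless traces but
is robust to single-sample noise dips beside an apex, which would otherwise
truncate the integration window. The area is the trapezoid integral over
the bounded window after subtracting the straight chord between the bound
points — a local linear baseline that is exact for an isolated peak on a
linear drift.

Cross-batch matching pools all apexes, sorts them by retention time, and
sweeps greedily: a cluster absorbs a peak when its rt lies within the
tolerance (default 0.3 min, typical HPLC retention repeatability) of the
cluster's running median; a cluster keeps at most one peak per batch, the
nearer one winning and the displaced peak seeding a new cluster. Pooled
sorting makes the result independent of batch order. Only clusters with a
member in every batch become common peaks (labelled X1…Xn by consensus rt).

Similarity is the uncentred cosine (congruence) coefficient between a
batch's common-peak area vector and the reference fingerprint (column mean
by default; median available). Cosine on peak vectors is the documented
convention of fingerprint-evaluation software for herbal preparations; the
centred (Pearson) variant and a whole-trace cosine after resampling are
offered because the commercial tool's exact algorithm is unpublished, and
neither option is asserted to be that tool's.

## Quantification

Calibration is ordinary least squares of area on concentration (mg/mL),
r being the Pearson correlation. Content conversion inverts the curve and
applies the preparation's dilution factor: 0.1 g of freeze-dried powder
made up to 10 mL gives content = 100 × concentration; both mass and volume
are parameters. Concentrations outside the fitted linear range warn rather
than fail, because a packaged content matrix cannot be audited for range
compliance after the fact. All RSDs use the sample (n−1) standard
deviation, matching pharmacopoeial practice. Box statistics use
linear-interpolation (type-7) quartiles with Tukey 1.5·IQR whiskers clipped
to the data; ranking ties break by compound label so the chain is
deterministic.

## Bioassay statistics

The inhibition rate maps the model-group tension to 0% and the pre-agonist
control tone to 100%: `100·(T_model − T_drug)/(T_model − T_control)`. The
formula is an assumption of this package (the emulated assay does not print
one); it reproduces the worked group-mean example to 0.05 points and is
invariant to rescaling all tensions. Rates above 100% are legitimate — the
tissue relaxed below its control tone. When per-animal tensions exist, each
animal's own control and model stages anchor its rate (the cumulative
protocol measures all stages on the same preparation) and the group rate is
the mean ± SEM over animals; this per-animal averaging generally differs
from the group-mean rate, which explains printed rates not reproducible
from group means alone.

Pairwise comparisons use Welch's test reconstructed from summaries
(t = Δm/√(SEM₁²+SEM₂²), Welch–Satterthwaite df), with no multiplicity
correction, mirroring the two footnote comparisons of the emulated table;
one-way ANOVA from summaries (SDs recovered as SEM·√n) covers the stated
omnibus method. Markers use strict thresholds: p < 0.05 single, p < 0.01
double.

## Screening

GRA follows Deng's formulation with two-level (global) Δmin/Δmax and
resolution coefficient ρ = 0.5 by default — the canonical settings in the
spectrum–effect literature. Series are z-scored (sample sd) before the
difference sequences; with that normalisation the grades are invariant to
positive affine maps of any column, so areas and calibrated contents give
identical grades. Grades are unweighted means of the relational
coefficients; ranks break ties by peak label.

PLS1 is fitted by NIPALS on autoscaled X and y (for a univariate response
the inner loop converges in a single pass): w = X′y/‖X′y‖, t = Xw,
p = X′t/(t′t), q = y′t/(t′t), deflating both blocks per component.
Coefficients B = W(P′W)⁻¹q are reported on the standardised scale (the
sign criterion reads these) and mapped back to original units for
prediction. VIP_j = √(p·Σ_a SSY_a w_ja² / Σ_a SSY_a) with
SSY_a = q_a²(t_a·t_a); ΣVIP² = p holds by construction. The default of two
components is conventional for n ≈ 15 batches; a leave-one-out RMSE helper
(`loo_rmse`) supports choosing otherwise. Degenerate cases (constant
response, zero residual covariance, constant predictor columns) raise with
explicit messages.

The selection rule intersects grade > 0.8, VIP > 1 and coefficient > 0.
Because near-misses matter in practice (a constituent failing one criterion
narrowly may still be pharmacologically interesting), the report also lists
peaks meeting exactly two criteria rather than silently dropping them.

The effect vector for the packaged tables defaults to the mean of the 25
and 35 mg/mL inhibition columns, configurable to either single column: the
emulated study names "the inhibition rate" without fixing a dose. The
published grades are kept as a fixture for side-by-side comparison only;
they are not a recomputation target, since the original run's ρ,
normalisation detail and effect column are unknown and five of its twenty
peaks have no printed quantitative series.

## Synthetic generators

Peaks are pure Gaussians, so the area has the closed form h·σ·√(2π) used by
the detection oracle tests; exponentially modified Gaussians (tailing) are
a possible extension, not modelled. Area variation is mean-preserving
lognormal (areas stay positive), rt jitter Gaussian, baseline a linear
drift plus white noise. The default batch design — 15 batches, 20 common
peaks, 10% area CV, 0.05 min jitter, 0–3 batch-unique peaks placed ≥ 1 min
from every common apex — mirrors the emulated study's design; the
variability magnitudes are generator settings chosen as typical for
replicate decoctions, not estimates of any real preparation's variability.

The bioassay generator draws per-animal tensions as stage mean ×
lognormal(CV) with an Emax-style hyperbola
T(C) = T_model − (T_model − T_floor)·C/(C + IC50); defaults (control
0.45 g, model 1.25 g, floor 0.30 g, IC50 12 mg/mL, n = 6, CV 0.12) sit in
the range of the emulated assay's printed tensions and doses. With zero
noise the dose response is exactly monotone and per-animal and summary
inhibition rates coincide — both are test invariants.

The spectrum–effect generator plants a known active subset:
y = Σ coef·zscore(X_col) + N(0, σ). X columns are independent lognormals.
Real batch matrices are more favourable to screening in one respect —
constituents co-vary through shared raw-material quality, raising the
active columns' correlation with the effect — and less favourable in
others (measurement error in y, nonlinearity). Passing recovery tests on
this generator therefore shows the screening machinery is correct, not that
15 real batches suffice to identify 3 actives among 20 peaks; with
independent columns at n = 15 the chance correlation of an inactive column
(≈ 1/√14) rivals each active's true correlation (1/√3 for three equal
drivers), an identifiability limit documented by the recovery-rate test.

## Determinism and I/O

Every generator takes a mandatory seed and draws from a single
`numpy.random.Generator`; identical config + seed reproduces outputs
bitwise, and the pipeline's CSV outputs are byte-identical across reruns of
the same config. CSVs are RFC 4180, UTF-8, "." decimal, always with a
header row, and round-trippable by the package's own readers. Logging goes
to stderr; results to files or stdout.
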