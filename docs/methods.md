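# Methods

This note documents the models, parameter choices and numerical decisions
behind `lbdens`, and what the synthetic-data generators do and do not
emulate.

## Reweighting and the free-energy landscape

Accelerated MD adds a boost ΔV(r) ≥ 0 to the potential wherever it falls
below a threshold, so the sampled density is p·exp(−ΔV/k_BT). Three
estimators undo the bias:

* **exponential** — w_i ∝ exp(ΔV_i/k_BT), exact but high-variance when
  ΔV spans many k_BT; an `OverflowError` is raised (with a pointer to the
  cumulant estimator) when the exponent range exceeds what double
  precision supports.
* **maclaurin** — the exponential truncated at a chosen series order
  (default 10); lower variance, biased for large ΔV.
* **cumulant2** — the per-bin second-order cumulant correction
  ln p(bin) += ⟨βΔV⟩ + var(βΔV)/2, implemented as per-frame weights
  exp(⟨βΔV⟩_b + var_b/2)/N for every frame of bin *b* so that the same
  function signature (frame weights in, weights out) serves all three
  estimators. The binning used for the correction (default 0.1 Å) should
  match the PMF binning. This is the default estimator because it is the
  recommended mode of the standard reweighting toolchain for protein-scale
  boosts.

The PMF is −k_BT ln p over a 2D histogram of the collective variables
(default bin width 0.1 Å, a compromise between CV resolution and bin
occupancy at 10⁴–10⁶ frames), shifted so the occupied minimum is zero.
Empty bins are NaN — "unvisited", never "zero energy". k_B is fixed at
1.9858775×10⁻³ kcal/mol/K throughout. Temperature defaults to 298 K for
populations and PMFs and is overridable everywhere (simulation thermostats
are often set elsewhere, e.g. 310 K; the two uses are deliberately
decoupled and the default follows the population-evaluation convention).

Wells are local minima of the PMF under 8-neighbor connectivity among
occupied bins, restricted to an energy ceiling (`max_energy`, a user
decision — how far above the global minimum a basin still counts as a
conformational state). Equal-energy plateaus collapse to their lowest
flat-index bin, and minima closer than `min_separation` merge keeping the
deeper — both deterministic tie-breaks. Member frames of a well are those
inside the **closed** square of half-width 0.1 Å (side 0.2 Å) around the
well bottom.

## Well clustering and Boltzmann averaging

Well-member frames are k-means clustered (k = 5, squared-Euclidean, 10
seeded restarts; k is reduced with a warning when fewer frames exist).
Cluster fractions are measured against all frames of the well; clusters
under 5% are dropped as insignificant. Per-well observables are the
cluster-weighted average Σ w_i x_i; by default the surviving-cluster
weights are renormalized so the result is a convex combination (a flag
restores the literal truncated sum). Well populations follow
π_i = exp(−E_i/k_BT)/Σ_j exp(−E_j/k_BT); the negative exponent is the
physically required sign (lower energy ⇒ larger population). An audit-only
`literal_sign` flag evaluates the positive-exponent variant. The Boltzmann
average is Σ π_i x̄_i.

## Trajectory observables

* **Hydrogen bond (ideal)**: donor–acceptor heavy-atom distance ≤ 3.5 Å
  and donor–H–acceptor angle ≥ 135°. The ideal cutoffs are a field
  convention; the **relaxed** criterion loosens them by +0.4 Å and −20°.
  Prevalence is the fraction of frames in which *any* selected
  donor/acceptor pair qualifies.
* **Salt bridge**: any side-chain N (NZ, NH1/2, NE, ND1, NE2) to
  side-chain carboxylate O (OE1/2, OD1/2) distance ≤ 4.0 Å (default; the
  cutoff is a convention, exposed as a parameter).
* **Helicity**: a residue is helical in a frame when φ ∈ [−100°, −30°]
  and ψ ∈ [−80°, −5°] and it belongs to a run of ≥ 3 consecutive such
  residues; this dihedral window deliberately avoids a full
  secondary-structure assignment algorithm. Helix extension counts
  contiguously helical residues immediately N-terminal to a reference
  terminus, averaged over frames.
* **Segment RMSD**: least-squares superposition on a fit range, RMSD over
  the backbone (N, CA, C, O) of an evaluation range, in Å. Residue ranges
  are 1-based inclusive (PPARγ2 isoform numbering in the intended
  application).

Trajectory containers are `mdtraj.Trajectory` objects; multi-model PDB is
the interchange format.

## ¹⁹F deconvolution

The lineshape is a phased Lorentzian — the absorptive Lorentzian with a
bounded admixture (|φ| ≤ π/50 rad) of its dispersive counterpart to absorb
small phasing error. A Voigt extension would be straightforward but is not
currently exposed. Models with k = 0…max_peaks peaks plus a constant
baseline are fit by bounded trust-region least squares; peak k+1 is seeded
at the largest smoothed maximum of the k-peak residual, so the whole
procedure is deterministic. BIC = n ln(RSS/n) + p ln n with p = 4k + 1
selects k. Two numerical guards matter: the noise σ used for reporting is
estimated from the outer 10% flanks of the spectrum, and RSS is floored at
n·(10⁻¹⁰·max|y|)² — on noiseless synthetic spectra the likelihood would
otherwise diverge and BIC would keep adding peaks to fit double-precision
residue.

## CEST

Exchange is modeled with the two-site Bloch–McConnell equations under
ideal continuous-wave saturation (default ν₁ = 25 Hz; shaped-pulse
envelopes are out of scope, and any power-equivalent field can be passed
in). The 6-dimensional magnetization evolves as an affine linear system
solved by a 7×7 matrix exponential per (offset, duration) condition;
reported intensities are M_z of the major state normalized to its
equilibrium value. k_ex is fit by 1-parameter least squares with R₁ fixed
(default 2.4 s⁻¹, the measured longitudinal rate of the trifluoromethyl
probe on the apo receptor), initialized from a log-spaced scan so the fit
cannot stall in a flat region. The 95% CI is the profile-likelihood
(F-criterion) interval RSS(k) ≤ RSS_min(1 + F₀.₉₅;₁,ₙ₋₁/(n−1)); a profile
with no k_ex sensitivity (all conditions far off resonance) is flagged
with a warning and an interval spanning the search range.

## Binding

The quadratic (tight-binding) anisotropy model is exact for one receptor,
one labeled probe; no free-ligand approximation is made. Initial values:
A_f = min A, A_b = max A, K_d at the half-maximal R_t; K_d is bounded in
(0, 10·max R_t]. ROUT outlier removal: a soft-L1 robust fit whose scale is
re-estimated from the residual MAD over a few iterations (a gross outlier
must not inflate its own scale and mask itself), residual t-statistics
against the RSDR (68.27th percentile of |residuals|, corrected by
N/(N−K)), and a Benjamini–Hochberg-style FDR detection at Q (default 1%)
restricted to the largest residuals, then an ordinary refit on survivors.
Fold changes are ratios of arithmetic-mean K_d values. The summary t test
uses the pooled-variance unpaired two-tailed form computed directly from
(mean, SD, n) triples, reporting t and the 95% CI on the difference
magnitude.

## HDX-MS

%D = 100·(centroid − undeut)/(fulldeut − undeut), clipped to
[0, 100 + 5]. Back-exchange correction divides by recovery × D-content
(defaults 0.70 × 0.80). Consolidation weights each covering peptide by
1/(effective length) — effective length excludes the peptide's first two
residues and prolines, which contribute no observable amide deuterium.
The reciprocal is the simplest monotone implementation of
"shorter peptides weigh more" and is a documented assumption; any
monotone-decreasing weight would preserve the convexity guarantee.
Differential comparisons are per-peptide, per-timepoint unpaired t tests
on replicate %D (no multiplicity correction by default; a
Benjamini–Hochberg option exists).

## Synthetic data: what it does and does not emulate

The generators produce inputs whose ground truth is known exactly:

* **Landscapes** are Gaussian mixtures whose component weights are
  exp(−depth/k_BT), so well occupancies obey the Boltzmann relation by
  construction. The boost follows the aMD functional form
  ΔV(E) = (E_b−E)²/(α+E_b−E) with defaults E_b = 8, α = 4.8 kcal/mol
  (maximum boost 5 kcal/mol, chosen so exponential reweighting stays
  well-conditioned; real boost parameters derive from prior cMD averages
  and are system-specific). Boosted ensembles are drawn by inverse-CDF
  sampling of the biased density on a 0.02 Å grid with uniform in-cell
  jitter; each frame records the exact ΔV at its own coordinates. The
  piecewise-constant sampling bias is far below the 0.1 Å analysis
  binning.
* **Peptide trajectories** are ideal geometric constructions: backbones
  built from exact dihedrals (α-helix −57°/−47°, extended −135°/135°) via
  internal-coordinate chaining, amide hydrogens placed opposite the
  preceding carbonyl. Scheduled donor/acceptor pairs position a free
  NZ–HZ1 group and an OE1 atom at 2.9 Å/165° when bonded and 6.0 Å when
  not — unambiguously inside the ideal criterion and outside the relaxed
  one, so every prevalence equals its schedule exactly. Nothing about
  force-field dynamics, sterics or solvent is simulated.
* **Spectra** are exact phased-Lorentzian sums plus white noise;
  **CEST profiles** come from the same Bloch–McConnell forward model the
  fitting stage uses; **titrations** evaluate the quadratic model with
  Gaussian noise and optionally planted outliers displaced by 10× the
  noise SD (0.05 anisotropy units when noiseless) and flagged in the
  returned ground truth; **HDX datasets** observe a residue-level truth
  through peptide averaging, scaled by recovery × D-content.

Consequently, passing tests demonstrate that the *analysis* stages invert
their specified forward models — not that real aMD converges, that real
spectra are Lorentzian, or that real back-exchange is uniform at 70%.
Residue consolidation in particular can never resolve uptake variation
finer than the peptide coverage: the closed-loop recovery tests use truths
that are constant within covered segments, which is the regime in which
residue averaging is informative.

Study conditions fixed for the recovery tests (and the acceptance script):
two wells 1 kcal/mol apart at 10⁵ frames; ¹⁹F spectra at a 470 MHz
fluorine observe frequency with 72/28 doublets at 5× width separation and
SNR 50; CEST at p_B = 0.1, Δν = 200 Hz, R₂ = 30 s⁻¹, k_ex = 2 s⁻¹;
titrations of a 50 nM probe with A_f = 0.05, A_b = 0.35 (a realistic
anisotropy span for a fluorescein-labeled peptide binding a ~30 kDa
domain), a 12-point 2-fold series from 5 µM spanning K_d = 100 nM, and
noise SD 0.002–0.005 anisotropy units; HDX at timepoints 10/60/300 s with
triplicates. These sizes keep the full suite and the acceptance script in
the minutes range on a single CPU while leaving all sampling-based checks
comfortably inside their 3-standard-error tolerances.

## Known limitations

* The cumulant2 estimator inherits the binning of its correction; very
  sparse bins fall back toward plain histogram statistics.
* BIC model selection assumes homoscedastic Gaussian noise; strongly
  heteroscedastic baselines would need a weighted variant.
* The CEST CI is a profile-likelihood interval with R₁ fixed; R₁
  misspecification propagates directly into k_ex.
* ROUT's FDR control is approximate for the very small n (≈12) of a
  titration; the false-positive control test characterizes its practical
  behavior rather than guaranteeing the nominal rate.
* Helicity uses a dihedral window, not a hydrogen-bond-based assignment;
  3₁₀/π helices at window edges may be classified differently than DSSP
  would.
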