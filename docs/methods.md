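# Methods

## Probe selection model

The design target is a capture oligo that hybridises with one species and
with no related species. On an existing alignment (building the MSA is out
of scope — any aligner's output in aligned FASTA or Clustal is accepted),
every window of `window_length` columns is scored per nontarget species by
position-wise mismatch count against the target row, and the probe is the
window maximising the minimum count over nontargets — a maximin criterion:
the binding energy gap to the *closest* nontarget limits assay selectivity,
so that is what is optimised. Ties break by higher mean mismatch, then by
leftmost column; both choices are deterministic, making selection invariant
under permutation of the candidate list.

Comparison policy:

* `ambiguity_mode` — `strict` (default): symbols match only if identical.
  `iupac_overlap`: symbols match if their IUPAC base sets intersect.
  Strict is the default so that counts over plain A/C/G/T panels are never
  silently altered by degenerate codes.
* `gap_mode` — a nontarget gap opposite a target base counts as a mismatch
  by default (a gap cannot hybridise, so this is conservative for
  specificity); `exclude` drops the column, and the per-species percent
  then uses the number of compared columns as denominator.
* Windows where the **target** row contains a gap cannot be synthesised as
  an oligo; they are emitted with `valid=False` and the reason recorded
  rather than silently skipped, so a scan is auditable.
* An optional multi-target mode treats additional conspecific rows as
  co-targets: a window is valid only where all target-flagged rows are
  identical (intraspecies conservation), and co-targets are excluded from
  the nontarget profile.

`window_length` defaults to 31 (the length of the published box-turtle
cytb probe) and is exposed over 10–60; positions are 1-based in all
user-facing output and 0-based internally.

The derived panel: the probe carries a 5′ thiol + six-carbon spacer
annotation (`HS-S-(CH2)6`, the gold-coupling chemistry); the
reverse-complementary target is computed with the IUPAC-complete
complement table; k-mismatch variants substitute k seeded positions drawn
without replacement, using transversion partners (A↔C, G↔T) because
purine↔pyrimidine swaps destabilise a duplex more reliably per edit; the
noncomplementary control is a seeded shuffle of the RC accepted once its
mismatch fraction reaches 40% of the length (configurable), failing
explicitly after 1000 attempts.

## Voltammetry analytics

**Peak extraction.** DPV hybridisation signals are a redox peak on a
drifting baseline. The default baseline is the chord: the straight line
joining the trace values at the peak-window edges. It is parameter-free
and exactly absorbs any linear baseline component (adding a + b·E to the
trace leaves Ip unchanged — a property the tests exercise with random
slopes). A `flat` mode (median of the 10% of window points nearest the
edges) is available for sloppy window placement. A non-positive corrected
maximum is reported with a `no_peak` flag rather than raised, since blank
traces are a normal input.

**Replicate statistics.** RSD = σ·100/μ. σ defaults to the sample
standard deviation (ddof = 1), with ddof = 0 available; the choice is
recorded wherever results are reported, because the two differ noticeably
at n = 4. Values are reported at full precision plus a 3-significant-figure
convenience rounding.

**Calibration.** Peak current is regressed on log₁₀(concentration) by
ordinary least squares; R² is the squared Pearson correlation. The linear
range is the longest *contiguous* run of concentration-sorted points with
R² ≥ 0.99 (ties by higher R², at least 4 points). Contiguity is deliberate:
calibration ranges are reported as spans, and unrestricted subset search
would overfit. An exhaustive enumeration oracle checks the search on small
series, including the boundary property that no admissible extension of
the returned run is refused.

**Limit of detection.** LOD is the concentration whose fitted signal
exceeds the blank mean by k·σ_blank, k = 3.3 by default (the common
3.3σ/slope convention) with k = 3 available:
LOD = C_ref · 10^(k·σ_blank/|slope|), where C_ref is the concentration at
which the fitted line equals the blank mean — supplied directly or derived
from the fitted intercept and blank mean. The rule and inversion
convention are recorded in run manifests, since the LOD arithmetic is the
least standardised step of this pipeline.

**Surface area.** For a reversible diffusion-controlled couple at 25 °C,
Ip = 2.69×10⁵ n^{3/2} A D^{1/2} C v^{1/2} (Ip in amperes, D in cm²/s, C in
mol/cm³, v in V/s). The estimator fits Ip on √v and divides the slope by
the remaining factors; currents are handled in μA at the API surface and
converted internally. A non-positive slope is rejected as a non-diffusive
response. Default constants in the CLI (n = 1, D = 6.7×10⁻⁶ cm²/s,
C = 2×10⁻⁶ mol/cm³) correspond to 2 mM ferrocyanide in KCl, a standard
characterisation couple.

## Synthetic data: what it emulates and what it does not

`generate_msa` plants exact per-species mismatch counts inside a chosen
window of an otherwise conserved alignment, with i.i.d. background
substitutions outside it (default 5% per site) and optional gaps
(nontargets only, outside the window unless the stress flag is set, so
ground-truth counts stay exact). Planted positions are anchored at the
window's first and last columns; any shifted window then loses at least
one planted mismatch from every species, which makes the planted window
the strictly best window in the zero-background limit — the guarantee the
recovery tests rely on. Defaults plant 6- and 14-mismatch species
(19%/45% of a 31-mer), the divergence extremes of a real cytb barcode
panel. Substitutions are uniform over the three alternative bases, with
no transition/transversion bias and no phylogenetic correlation between
species: passing tests validate the scanner and selector, not the realism
of molecular evolution.

`generate_dpv` builds current(E) = linear baseline + A(C)·Gaussian(E; Ep,
width) + i.i.d. Gaussian noise, with the amplitude A(C) piecewise: a floor
(1 μA) below 10⁻¹¹ M, 80 + 6·log₁₀(C) μA across 10⁻¹¹–5×10⁻⁶ M, and a
44 μA plateau above. The plateau sits ~4 μA below the log-linear limb's
value at the range top: a high-dose rolloff, as saturating hybridisation
calibrations show once probe sites fill. A plateau at or above the
extrapolated line would make the end of the linear range statistically
invisible to an R²-based search — the saturated limb must deviate for the
planted range to be identifiable at all. Peak defaults (Ep = −0.25 V,
σ = 40 mV, sweep −0.5–0 V, noise 0.05 μA) emulate a methylene-blue
reduction peak. Not emulated: peak-shape change with concentration,
electrode drift, correlated noise.

Calibration sweeps in the tests use 12 concentrations — the decades
10⁻¹⁵…10⁻⁶ M plus 5×10⁻⁶ and 10⁻⁵ M — a 10-decade design with the linear
span 10⁻¹¹–5×10⁻⁶ M sampled at both endpoints. `generate_calibration`
runs the full loop (trace → chord peak → series) and estimates blank noise
from 10 floor-level traces. `generate_scan_rate_series` draws Ip from the
forward Randles–Ševčík relation over 0.04–0.15 V/s.

All generators are pure functions of spec + seed (numpy `default_rng`),
hence bit-reproducible; CLI runs write a JSON manifest with parameters,
input digests and seed, and identical invocations produce byte-identical
outputs apart from the manifest timestamp.

## Numerical and design notes

* Mismatch counting requires equal lengths and raises otherwise;
  alignment is the caller's job. Zero-length percent is an error.
* U→T transliteration on input is a warning, not an error (a common
  supplier-sheet artefact); any other non-IUPAC character is rejected
  with its 1-based position.
* Percent rendering uses round-half-away-from-zero (so 14/31 → 45%,
  6/31 → 19%), matching the reporting convention of barcode divergence
  tables.
* Replicate summaries quoted at printed precision can be internally
  inconsistent (a printed σ need not equal σ recomputed from printed
  replicate values, since the underlying replicates were unrounded); the
  package therefore reports full precision alongside rounded values, and
  tests assert the RSD identity on summary values separately from the
  statistics recomputed from raw replicates.
* Test problem sizes (alignments up to 10×220, 12-point calibrations,
  12-point scan-rate series, 60-seed Monte-Carlo) were chosen as the
  smallest sizes at which the oracles are exhaustive or the statistics
  stable; the whole suite runs in seconds.

## Known limitations

* No thermodynamics: Tm, ΔG, secondary structure and cross-hybridisation
  energetics are outside scope; mismatch count is the only selectivity
  proxy, and an online BLAST specificity check of a designed probe is left
  to the user (the panel FASTA is ready for submission).
* No MSA construction, primer design or phylogenetics.
* The electrochemistry covers peak/calibration/surface-area arithmetic
  only — no impedance-circuit fitting or mechanism modelling.
* The LOD depends on a blank-noise estimate and an anchoring convention;
  comparing LODs across instruments requires matching both.
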