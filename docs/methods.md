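# Methods

This note documents the models implemented in `npbind`, the numerical
choices behind them, what the synthetic-data generators do and do not
emulate, and the package's known limitations.

## Quenching titration fits

A titration is a per-temperature series of quencher concentrations [Q]
(µM, exactly one zero row defining F₀, at least three distinct nonzero
concentrations) and fluorescence intensities F (arbitrary units, all
positive). Three linearizations are fitted by unweighted ordinary least
squares on the transformed variables:

| plot          | transform                         | parameters                         |
|---------------|-----------------------------------|------------------------------------|
| Stern–Volmer  | F₀/F vs [Q]                       | slope K_SV (µM⁻¹), intercept       |
| Lehrer        | F₀/(F₀−F) vs 1/[Q]                | θ = 1/intercept, K_SV = intercept/slope |
| Hill double-log | log₁₀[(F₀−F)/F] vs log₁₀[Q]     | n = slope, K_a = 10^intercept, K_d = 1/K_a |

Conventions and edge handling:

- K_SV and K_a are in µM⁻¹ (reciprocal of the concentration unit of
  [Q]); K_d in µM. K_d·K_a ≡ 1 by construction.
- The Stern–Volmer intercept is estimated, not forced to 1 — departure
  from 1 is itself a diagnostic for external quenching.
- Points with F > F₀ (enhancement artifacts) are excluded with a
  warning, not an error; the Lehrer and double-log transforms also drop
  F = F₀ and [Q] = 0 points, whose transforms are undefined. Excluded
  counts are reported per fit (`points_used`, `n_excluded`).
- Fewer than 3 usable points raises a `FitError` naming the cause; a
  titration with no quenching at all returns slope 0 flagged degenerate.
- A non-positive Lehrer intercept makes θ non-physical; it is returned
  with a warning rather than silently clipped.
- No weighting is applied to the transformed points. This is the
  field's standard practice for these plots, but it makes the
  parameters noise-sensitive: the transforms (reciprocals, logarithms,
  exponentiated intercepts) amplify fluorescence noise, and with ~7
  titration points and noise of 1 % of F₀ the fitted constants
  generically carry errors of 5–30 % (see Limitations).

**Mechanism classification.** After rounding K_SV to 10 significant
digits, a strictly decreasing K_SV(T) series is classified `static`,
strictly increasing `dynamic`, anything else (including ties)
`indeterminate`. At least two temperatures are required.

## Thermodynamics

- **Enthalpy.** Default `pair_extremes` applies the two-point van't
  Hoff formula ΔH = R·ln(K₂/K₁)/(1/T₁ − 1/T₂) to the lowest/highest
  temperatures; `regression` uses −R × slope of ln K on 1/T over all
  points. The two differ on imperfect data (≈ −37.5 vs −38.7 kJ/mol on
  a typical published-style K_SV table); both are exposed and the mode
  is recorded in the result metadata.
- **Entropy.** `gibbs_identity` (default when a ΔG anchor is supplied)
  computes ΔS = (ΔH − ΔG)/T from one known (T, ΔG) pair.
  `vant_hoff_intercept` computes ΔS = R × intercept of ln K on 1/T.
  The intercept route is *unit-dependent*: rescaling K by a factor c
  shifts ΔS by R·ln c, so the units of K are recorded and a warning is
  emitted. With K_SV in µM⁻¹ the intercept entropy of a typical binding
  series is large and negative even when the Gibbs-identity entropy is
  large and positive — the two answer different questions unless K is
  expressed in the (unknown) units the anchor assumed. Both modes are
  kept; neither is silently preferred.
- **Gibbs energies.** ΔG(T) = ΔH − T·ΔS at every requested
  temperature, reported in both J/mol and kJ/mol; the identity holds
  exactly at every stored temperature by construction. ΔG < 0 is
  flagged spontaneous.
- **Force classification** follows the Ross–Subramanian sign rules with
  a configurable tolerance ε (default 0, strict signs): ΔH < −ε and
  ΔS > +ε → electrostatic; both > +ε → hydrophobic; both < −ε → van der
  Waals/H-bond; anything within ε or the remaining pattern →
  indeterminate. The classification is invariant under positive
  rescaling of both arguments.
- R is fixed at 8.314 J·mol⁻¹·K⁻¹.

## Enzyme activity and purification

The initial rate of a product-formation time course is the OLS slope of
fluorescence on time over a window (default: the whole trace), divided
by a calibration factor (fluorescence units per µmol·ml⁻¹ of product).
The calibration is instrument-specific and therefore a required input;
the generator fabricates a known one. Relative activity is
100 × rate/control. Replicate summaries use the sample (n−1) standard
deviation, matching triplicate reporting conventions.

Purification tables derive, per step: total protein = volume ×
concentration; specific activity = total activity / total protein;
fold = specific activity relative to the first (crude) step; yield =
100 × total activity relative to crude. The crude step has fold 1 and
yield 100 identically; fold and yield are invariant to rescaling all
activities. Raw values are kept at full precision with 2-decimal
display rounding.

## Spectra

- Spectra carry their kind: UV–Vis absorbance (bands are maxima) or
  FTIR transmittance (bands are dips/minima). Any strictly monotone
  abscissa direction is accepted and normalized to ascending.
- **Peak position** is the window extremum after a centered moving
  average (default width 3); ties on the smoothed plateau resolve to
  the rawest extremum so an isolated spike reports its own abscissa.
  Peak metrics are invariant to ordinate rescaling and
  abscissa-direction reversal.
- **FWHM** is measured at half the baseline-subtracted band height
  (window minimum as baseline for peaks, maximum for dips), with
  half-height crossings located by linear interpolation. On noise-free
  Gaussians the error is within two grid spacings.
- **Shift series** report per-spectrum position/width and deltas versus
  the first spectrum, plus monotone-increase flags for red shift and
  broadening — the qualitative signatures of corona formation. Only the
  direction of broadening is asserted anywhere; no literature magnitude
  exists to compare against.
- **Baseline** correction is a two-point straight line through the
  region endpoints, subtracted for absorbance (endpoints → 0) or
  divided out for transmittance (endpoints → 1). Rubber-band
  correction is out of scope.
- **Amide-I assignment.** Local extrema in 1600–1700 cm⁻¹ after
  baseline correction are assigned by position: β-sheet [1620, 1641),
  transition [1641, 1648), α-helix [1648, 1660], else unassigned. The
  α/β anchors (~1650, ~1630–1635 cm⁻¹) are standard; the window
  boundaries are configuration values chosen so that a β-band relaxed
  to ~1646 cm⁻¹ lands in an explicit *transition* class instead of
  being silently mis-assigned. `amide_bands` applies **no smoothing by
  default**: neighbouring sub-bands can sit ~5 cm⁻¹ apart, and at
  1–2 cm⁻¹ sampling a width-3 moving average merges marginally resolved
  pairs into one extremum.
- **Band shifts** pair free and bound bands by nearest position within
  a tolerance (default 20 cm⁻¹, greedy in order of proximity); the
  shift is bound − free, and unmatched bands are listed with a null
  shift.

## Nanoparticle model

- **FCC construction.** The 4-atom basis (0,0,0), (½,½,0), (½,0,½),
  (0,½,½) is replicated over integer cells to cover a ball of the
  requested radius. Silver's conventional cell edge a = 4.0857 Å is the
  default, exposed as a parameter. The origin sits on a lattice atom by
  default; interstitial centering (quarter-body-diagonal offset) is a
  flag.
- **Sphere and cap.** Atoms at distance ≤ r are kept (boundary
  inclusive). A cap keeps atoms with z ≥ r − h; in count-targeted mode
  the smallest h whose cap holds at least the requested number of atoms
  is found by bisection (count is a monotone step function of h), all
  atoms tied on the boundary plane are kept, and the achieved count is
  reported — FCC z-planes hold tens of atoms, so a 277-atom target on a
  30 Å silver sphere yields a 362-atom cap (the first plane past the
  target).
- **PDBQT export** writes one fixed-width ATOM record per atom with the
  partial charge as given and the AutoDock atom type equal to the
  element symbol, no torsion tree (rigid receptor), plus an AD4-style
  `atom_par` line carrying R_ii and ε for the metal. Metal partial
  charges default to 0.000: Gasteiger charges are undefined for a bare
  metal cluster. Coordinates round-trip through the format at its
  10⁻³ Å precision.
- **K_i conversion.** K_i = exp(ΔG/(R·T)) with R = 1.98720 × 10⁻³
  kcal·mol⁻¹·K⁻¹ and T = 298.15 K by default.
- **Contact footprint.** Per residue, the minimum atom–atom distance to
  the particle (k-d tree query); residues at or below the cutoff
  (default 3.5 Å) are returned ascending by residue number. The result
  is invariant under rigid transforms applied jointly to both clouds.

## Synthetic data

Generators are deterministic under a fixed seed
(`numpy.random.default_rng`) and exist so that every analysis can be
tested as a noise-free round trip (recovery to 10⁻⁸ relative) and under
controlled noise.

- Titrations: `static_hill` F = F₀/(1 + K_a·Qⁿ) and `lehrer`
  F = F₀(1−θ) + F₀θ/(1 + K_SV·Q); additive Gaussian noise with sd =
  noise_sd × F₀. Default design: Q = 0–60 µM in 10 µM steps,
  F₀ = 1000.
- Temperature series: K(T) = exp(−ΔH/RT + ΔS/R) feeds the titration
  model per temperature (defaults 298–313 K in 5 K steps); the
  ground-truth K(T) is returned alongside.
- Time courses: F(t) = F_start + rate·calibration·t over 20 min
  (21 points), absolute Gaussian noise; default rate 0.594
  µmol·ml⁻¹·min⁻¹ — a typical uninhibited reference rate.
- Spectra: sums of Gaussians on a regular grid over a constant or
  tilted baseline; absorbance bands add, transmittance bands subtract
  (dips). Defaults: UV–Vis 300–800 nm with a 405 nm plasmon band;
  FTIR 1500–1800 cm⁻¹. The generator's default FTIR step is 2 cm⁻¹
  (a typical instrument resolution); the shipped synthetic amide
  fixtures use a 1 cm⁻¹ grid and band σ = 2 cm⁻¹ so that the canonical
  band centers (1635/1646/1651 cm⁻¹) are representable grid points and
  the closely spaced 1646/1651 pair is resolvable by direct extremum
  detection — band *deconvolution* is deliberately out of scope.

What the generators do **not** emulate: inner-filter effects,
instrument drift or wavelength-dependent response, scattering
backgrounds, heteroscedastic detector noise, non-linear assay phases,
or overlapping amide sub-bands requiring second-derivative/deconvolution
analysis. Passing round-trip tests therefore demonstrates correctness
of the transforms and fits, not robustness to every artifact of real
instruments.

## Pipeline

`run_full` executes the configured stages (binding, activity,
purification, spectra, nanoparticle model); missing sections are
skipped with a notice, per-temperature fit failures are recorded
without aborting the run, and unknown configuration keys raise a
validation error naming the key. Reports are JSON-serializable
dataclasses validated against a published schema
(`pipeline.REPORT_SCHEMA`) on every construction; the provenance block
records configuration, seed and library versions but no timestamps, so
reruns are byte-identical. Every excluded data point is logged through
the `npbind` logger with a warning.

Problem sizes throughout the shipped tests and demo are the study-scale
designs themselves (7-point titrations at 4 temperatures, ~500-point
spectra, a 6 603-atom 30 Å nanoparticle sphere), which the package
processes in seconds.

## Known limitations

- The unweighted transformed-variable fits are the field's convention,
  not the statistically efficient estimator; at 1 % fluorescence noise
  and 7 points per titration, recovered constants commonly deviate by
  more than 5 %, and the Hill intercept (exponentiated) and Lehrer
  double-reciprocal parameters are the most sensitive. Users needing
  tight uncertainties at realistic noise should average replicate
  titrations or fit the untransformed isotherm (out of scope here).
- The intercept-mode entropy is only meaningful relative to a stated
  standard state (units of K); the package surfaces rather than
  resolves this ambiguity.
- Nothing in the docking-adjacent code runs a docking engine; the
  package prepares inputs (PDBQT, parameter line, grid-box stanza) and
  post-processes outputs (energies, footprints) only.
- Secondary-structure analysis is positional band assignment, not
  quantitative fraction estimation.
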