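# Methods

This note documents the models behind `letfilm`, the parameters that
matter, the numerical choices, and what the synthetic data does and does
not emulate.

## Media and composite quantities

Film compositions are stored as **atomic** fractions (the hydrogen content
of these polymers, 56–58%, is only possible as an atom count, not by
mass); mass fractions follow from standard atomic weights,
wᵢ = fᵢAᵢ/Σⱼ fⱼAⱼ.  The effective atomic number uses the Mayneord power
law Z_eff = (Σᵢ αᵢ Zᵢᵐ)^(1/m) with electron-fraction weights
αᵢ = fᵢZᵢ/Σⱼ fⱼZⱼ and exponent m = 2.94 (photoelectric regime; the
exponent is an argument for users preferring another convention).  With
these conventions the bundled compositions give Z_eff = 7.51 (EBT3
active), 7.67 (MD-V3 active), 6.71 (EBT3 overall), 6.63 (MD-V3 overall),
within 1% of the manufacturer-derived values.

Mean excitation energies come from Bragg additivity,
ln I = Σ wᵢ(Zᵢ/Aᵢ) ln Iᵢ / Σ wᵢ(Zᵢ/Aᵢ), over elemental in-compound
I-values (ICRU-37/Seltzer–Berger set; e.g. H 19.2 eV, O 106 eV, giving
75.3 eV for water).  Compounds with a standard recommended value (water
75 eV, PMMA 74 eV) carry an `I_override`.  Active-layer density is not
published; both films default to 1.20 g/cm³ (typical manufacturer value)
and the density is configurable — every headline ratio in the analysis is
density-independent.

## Stopping powers

The collision mass stopping power is the Bethe formula with the Møller
close-collision term for identical particles:

    S/ρ = k (Z/A) β⁻² [ ln( τ²(τ+2) / 2(I/m_ec²)² ) + F(τ) − δ ]
    F(τ) = 1 − β² + [ τ²/8 − (2τ+1) ln 2 ] / (τ+1)²

with τ the kinetic energy in units of m_ec² and k = 2π r_e² m_ec² N_A.
The restricted stopping power L_Δ counts only transfers below Δ, replacing
F by

    G(τ,η) = −1 − β² + ln[4(1−η)η] + (1−η)⁻¹
             + (1−β²)[ τ²η²/2 + (2τ+1) ln(1−η) ],   η = min(Δ/E, ½),

which reduces *exactly* to F at η = ½ (the maximum transfer between
identical particles is E/2), so L_Δ(E) = S(E) whenever Δ ≥ E/2 — this is
asserted to 1e-12 relative in the tests.

The density-effect correction δ uses the Sternheimer–Peierls general
parameter rules computed from I and the plasma energy
ħω_p = 28.8159 √(ρ⟨Z/A⟩) eV (non-conductor branch; m = 3).  A
single-oscillator dispersion model was considered and rejected: its sharp
activation threshold underestimates δ near 1–2 MeV by enough to matter at
the few-percent level.

Shell corrections are omitted; radiative losses are excluded everywhere
(LET is a collision quantity).  The validity window is 1 keV–10 MeV, the
lower end matching the Δ = 1 keV floor below which electron cross sections
are not trusted.  Against the bundled reference water table (ICRU-37/ESTAR
transcription) the analytic backend agrees within 0.9% over
10 keV–2 MeV; the test bound is 3%, leaving room for the transcription
precision and the omitted shell terms.  A tabulated backend can be loaded
from a two/three-column text fixture for users who need table-grade
accuracy in other media.  Table lookup interpolates log-log linearly
(stopping power is near power-law over any small interval).

## Spectra and LET averages

Fluence spectra are histograms of Φ(E), the electron fluence differential
in energy per unit absorbed dose (cm⁻² keV⁻¹ Gy⁻¹), on half-open bins with
midpoint representative energies — the convention of Monte Carlo fluence
tallies.  Φ is treated as *fluence* (not energy fluence): the ICRU
spectrum averages are only dimensionally consistent as fluence-weighted
means.  Rebinning conserves the bin content Φ·ΔE exactly by interpolating
the cumulative integral; per-bin uncertainties are treated as uncorrelated
(appropriate for tally noise, not for systematic transport errors).

The two averages are evaluated as discrete sums over bin midpoints with a
track-end term S(Δ)Φ(Δ)Δ (and S²(Δ)Φ(Δ)Δ in the dose-average numerator)
accounting for electrons that slow below Δ; Φ(Δ) is read as the fluence
density of the lowest bin — the simplest unbiased estimate for histogram
data.  The dose-average denominator is exactly the track-average
numerator, so L_D ≥ L_T is a Cauchy–Schwarz identity of the discrete
scheme; it is asserted over 1000 random spectra.  Midpoint summation is
refinement-stable: splitting every bin ×10 moves either average by < 0.2%
whenever the stopping power is smooth across each bin (tested).  Results
convert to keV/µm via L·ρ·0.1.

Uncertainties use a parametric bootstrap (Φᵢ ~ Normal truncated at zero,
default 1000 replicates, mandatory seed) rather than first-order
propagation, because the estimators are ratios; for small relative noise
both agree, and the bootstrap remains exact as noise grows.

The derived cross statistics round the way the headline numbers are
quoted: beam-to-beam ratios to the nearest integer, percent excesses to
integer percent, dose/track ratios below 100 keV to one decimal.

## Beam quality

μ = ln2/HVL defines the attenuation coefficient; the effective energy is
the unique solution of μ/ρ_Al(E) = μ/ρ on a bundled aluminium attenuation
grid (NIST/XCOM total-with-coherent transcription, 5–1500 keV,
ρ_Al = 2.699 g/cm³), inverted by monotone log-log interpolation.  The
study-beam registry reproduces the published beam table; the ⁶⁰Co entry
carries no HVL and stores 1044.7 keV — the mean of the two gamma lines —
verbatim as its equivalent energy.  Effective energies derived from the
registry HVLs land within ~2% of the published equivalent energies, inside
the 3% validation band (grid coarseness near 13 keV dominates).

## Relative efficiency

RE = D_Co60(netOD)/D_Q(netOD) at matched netOD.  Curves are inverted by
Brent root-finding on the monotone shape-preserving (PCHIP) forward
interpolant — never extrapolating, since RE is only defined where both
curves respond.  Noise-level monotonicity violations up to 3 combined
sigmas are tolerated on input (a running maximum regularises the
interpolant); larger violations are validation errors.  RE uncertainty
propagates the two inversion uncertainties in quadrature on the log scale.

The published analysis reports a single weight-averaged RE per beam
without defining the weights; here it is the inverse-variance weighted
mean across the netOD evaluation levels (equal weights when no sigmas are
given), which reduces to the level-independence the data show.  Default
levels are the red-channel values 0.053/0.176/0.510 (EBT3) and
0.009/0.023/0.095 (MD-V3).

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *statistical shape* of photon-generated
electron fluence in film — a Gaussian photoelectron peak at the beam's
effective energy; a Compton continuum rising toward the edge
T_max = 2E²/(m_ec²+2E) with a degraded-primary low-energy tail ~E^-1.15;
K-shell lines at 1.07/1.56/2.47/2.82 keV (Na/Al/S/Cl) with amplitudes tied
to the medium's content of those elements; and a secondary-electron
power-law tail on [1 keV, E_max/2].  The SE index is 2 for the softest
beam (free-electron close-collision transfer) and decreases to 1.2 for
⁶⁰Co, reflecting the harder, further-reaching transfer spectra of fast
primaries; this also orders the SE-axis LET across beams.  Amplitudes are
calibrated so that (i) the ⁶⁰Co SE/TEF fraction lies in ~0.4–0.9 between
1 and 10 keV, (ii) x-ray SE fractions at 1 keV stay below 0.30, and (iii)
both LET averages decrease strictly with effective energy, ⁶⁰Co lowest.
Spectra are normalized so the CEMA of the total fluence — computed by
fine-grid quadrature, independently of the binned estimator — is 1 Gy/Gy;
noise is truncated-normal per bin, with SE and non-SE noise drawn
separately so TEF ≥ SE bin-wise even after noise.

Dose–response curves are netOD(D) = a(1 − e^(−b·s_Q·D)) with per-film
shape (a, b) = (0.8, 0.08 Gy⁻¹) for EBT3 and (0.3, 0.05 Gy⁻¹) for MD-V3
on 24 log-spaced doses over 0.1–25 Gy, a range that covers every default
netOD level for all sensitivity scales in the study.  Because the scale
s_Q multiplies the dose, the ground-truth RE of beam Q is exactly s_Q at
every level.  The study fixture assigns s_Q = 1 + 3u²/(u²+0.12), u the
min-max normalized dose-average LET of that film's total fluence — a
monotone map producing the flat → rapid-rise → slow-rise RE(LET) shape.
Default noise is 0.5% per bin/point: the level of high-statistics tallies
and careful densitometry, and one that makes the fixture's design
contract (scale recovery within 2%) a ≥4σ margin rather than a borderline
statement.

The generator makes **no transport claim**: no angular or depth
distributions, no spectrum of the actual x-ray tubes, no film-scanner
physics.  Passing tests demonstrate that the *analysis* is correct and
stable under realistic statistical structure — not that the synthetic
spectra match any specific measured fluence.

## Determinism and problem sizes

All randomness flows from explicit seeds (`numpy` `SeedSequence`, split
deterministically per stage); regenerating a fixture or rerunning the
pipeline with the same seed is byte-identical.  Default problem sizes —
120 spectrum bins, 200-point stopping-power grids, 1000 bootstrap
replicates (200 in the batch pipeline), 100-replicate recovery studies —
were chosen so the full test suite and a complete study analysis each run
in seconds on a single core while keeping every quoted tolerance
comfortably resolved.

## Known limitations

* The analytic stopping power omits shell corrections; below ~5 keV its
  accuracy degrades (use the tabulated backend where that matters).
* Bragg additivity ignores chemical-binding effects beyond the
  in-compound I-values.
* The effective-energy inversion is only as good as the attenuation grid
  (~0.5% transcription accuracy; log-log interpolation between decade
  points dominates the ~2% deviation near 13 keV).
* Published LET tables for the study beams derive from unpublished
  transport simulations; the package reproduces their *ratio structure*
  from the printed grid and the full computation on synthetic spectra, not
  the absolute printed values from first principles.
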