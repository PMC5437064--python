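# Methods

This note documents the models behind `curtainkit`, the parameter
choices that matter, what the synthetic-data generator does and does not
emulate, and the numerical conventions used throughout.

## Substrate model

The λ substrate is a linear coordinate system of 48,502 bp with origin
at the *cosL* end.  All coordinates are 0-based, half-open
`[start, end)` intervals in bp; kb values in reports are `bp / 1000`
rounded to 0.1 kb.  The default map carries the three engineered
insertion-site centers (A = 21,300, B = 33,500, C = 45,300 bp), a 16-kb
dispensable segment between gene products J and N, and a 1.6-kb
dispensable segment between Rz and *cosR*.  Feature overlap is checked
within a feature kind only, because cassettes and site centers
legitimately sit inside dispensable segments.

Cassette insertion replaces native sequence centered on the target site
and shifts downstream coordinates by the net length change.  The result
must stay within 38–53 kb (78–105% of wild type), the range packagable
into phage capsids; the check is monotone by construction (an interval
test).  Exact cassette sequences are out of scope — cassettes are
modeled symbolically by insert/replaced lengths and marker labels.  A
replacement with `marker=None` denotes restoration of native sequence,
which makes insertion invertible (round-trip identity).

The nicking cassette places three top-strand nicks spaced by one
7-bp recognition sequence plus a 13/12-bp spacer (20 + 19 bp), so the
segment between the first and last nick — the single-stranded stretch
liberated by heating — is 39 nt.  Nick placement relative to the
recognition sequence is configurable; the default puts the first nick
at the site-A center.  Strand-fragment prediction treats the bottom
strand as intact; `mock` mode (perfectly complementary, fully
re-ligated oligo) restores one full-length top strand, while `flap` and
`gap` modes leave the top strand split into the two fragments flanking
the insert: 21,300 and 27,163 nt for the default site-A cassette.  Note
the exact downstream fragment (27.2 kb) differs from the gel-estimated
26.7 kb by ~0.5 kb; both are carried in the tests because a denaturing
gel estimate rounds, while the model is exact.

Duplex digestion takes sorted cut positions and a set of abolished
sites and returns successive differences over the surviving boundaries;
fragment totals are conserved exactly.  The site-A diagnostic layout
places three NcoI cuts delimiting 2.0-kb and 0.8-kb fragments that meet
at the flap-proximal site inside the cassette; abolishing that site
merges them into one 2.8-kb fragment.  Recognition-site scanning
rejects ambiguity codes (deterministic counts) and reports motif
occurrences on the given strand plus reverse-complement occurrences as
bottom-strand sites, counting overlaps; a palindromic motif yields one
site per position.

## Synthetic data

Presets bundle the measured conditions each generator emulates.  The
key shared parameters: 50-ms frame interval; 13-µm tether spanning the
48.5-kb substrate (~80% of B-form contour, 0.268 µm/kb); 0.2667-µm
pixels (16-µm EMCCD pixels at 60×); PSF σ = 1.2 px; 2,000
photons/frame with background 100 counts/px and 2-count read noise
(typical quantum-dot imaging values — the study's actual photon budget
is unreported, so these are declared defaults, not inferences); 30-nm
localization noise added to trajectories.

**Binding positions** are i.i.d. draws from a mixture of site Gaussians
and a uniform background over [0, 48.5] kb, with out-of-range draws
redrawn.  Site centers and widths are the printed fitted values
(e.g. LacI site A 21.7 ± 1.0 kb; flap peak 21.2 ± 1.4 kb).  Those
printed widths already include the scatter of tether anchors across the
~1–1.5-µm chromium barrier, so measured-parameter presets carry the
width as a single Gaussian sd; a uniform anchor-jitter term
(`SiteComponent.jitter_kb`) is available for components specified from
design coordinates instead.  Adding jitter on top of a printed width
would double-count the broadening (and is infeasible for site A, whose
printed 1.0-kb sd is below the jitter of a 1.25-µm barrier alone).

For the PCNA presets the site weights are not printed; they are
parameterized by the measured fold enrichment in the 5-kb window
covering the cassette (2.7-fold for the flap, 1.5-fold for (CAG)₁₃
relative to uniform homoduplex loading), solved in closed form
(`site_weight_for_fold`), giving weights of 0.213 and 0.063.

**Trajectories** are discrete Brownian walks with per-step displacement
~ Normal(0, 2DΔt), folded into [0, tether] by the method of images
(exact reflection).  Site interactions: `reflecting` mirrors any step
across the site coordinate; `trapping` pins the particle at the site
once reached.  Localization noise is added after the dynamics.

**Dwell times** are exponential with mean t½/ln 2; values beyond the
observation window (600 s, matching a 10-minute acquisition) are
returned censored at the window.

**Rendered stacks** integrate a symmetric Gaussian PSF over pixels
(erf differences; pixel centers at integer coordinates), scale to the
photon rate, add constant background, then Poisson-sample and add
Gaussian read noise, quantized to uint16.  Photobleaching and
quantum-dot blinking are not modeled.

**Behavior fixtures** realize exact category counts (flap: 36 blocked /
2 captured / 2 bypass of 40; (CAG)₁₃: 11 captured / 23 blocked /
2 bypass of 36; homoduplex: 40 bypass) as deterministic parametric
paths — linear crossings, triangular approach-and-reverse, stationary
records with a small ripple — so classification percentages are exact,
mirroring how scored molecule tallies are reported.  The (CAG)₁₃
blocked/bypass split beyond the printed 11/36 stationary count is not
printed and is a fixture choice.

What the generator does *not* emulate: flow-extension hydrodynamics and
tension gradients along the DNA, fluorophore photophysics, drift,
multi-channel registration, non-exponential dwell mixtures, and
sequence-dependent sliding friction.  Tests passing on this generator
therefore validate the *analysis* chain (estimator correctness,
calibration, round-trip consistency), not the biological realism of any
particular preset.

## Tracking

Detection thresholds local maxima at the frame median plus k times the
MAD-based robust sigma (1.4826 × MAD), k = 6 by default, with
non-maximum suppression within one PSF radius (3σ).  Localization fits
a symmetric 2D Gaussian plus constant offset by least squares in an
11×11 ROI; failures (no signal, non-convergence, center outside the
ROI) are returned flagged, never dropped.  Linking is greedy nearest
neighbor: candidate pairs within 5 px (default) and at most one missed
frame are assigned in order of increasing displacement, ties broken by
lower track id; gaps are recorded in the frame index, never
interpolated.  Under the default optics the localization error is
~0.05 px RMS and the simulate → render → track round trip recovers
>95% of trajectory points within 2× the 30-nm localization sigma.

## Binding statistics

Positions in µm from the anchor map to kb as
`kb = µm / (13 µm / 48.5 kb)`, assuming every molecule is anchored at
the barrier center (the stated approximation behind histogram
broadening); positions beyond the substrate end + 2 kb are flagged
off-DNA and excluded from histograms.  Peak fits operate on 1-kb-binned
counts with one or two Gaussians plus a constant background term
(histogram fitting, as in curve-fitting-toolbox practice); a raw-sample
MLE (moments / two-component EM) is available as an option.  Samples
under 20 positions fall back to moment estimates; zero-variance samples
return sd = 0 flagged.

The enrichment statistic uses eight contiguous 5-kb windows with the
target window re-centered on the cassette (site A: 18.8–23.8 kb, layout
spanning 3.8–43.8 kb).  A 48.5-kb substrate admits nine full 5-kb
windows; eight is retained as the documented analysis convention, and
the layout is configurable.  Window frequencies are normalized by total
molecule count, so they sum to ≤ 1 (= 1 when the layout tiles the
substrate).  The fold is the ratio of target-window frequencies between
modified and reference substrates; a zero reference count yields an
explicitly undefined fold.  Group comparison uses a two-tailed Welch
t-test (the unequal-variance form is the safer default when only
"two-tailed t test" is specified), with a label-permutation fallback
for zero-variance groups; contingency tables use Pearson χ² without
continuity correction, flagging expected counts below 1.  No
multiple-testing correction is applied: there is a single pre-specified
comparison.  Bootstrap errors are nonparametric (resampling with
replacement, percentile CIs, default B = 1000).

## Dynamics

MSD uses all overlapping displacement pairs — the estimator's index
range forces overlap — and D comes from an OLS line with free intercept
over the first 10 intervals (0.05–0.5 s), D = slope/2.  The free
intercept absorbs the 2σ² static-noise offset; a zero-intercept mode is
provided.  Negative fitted slopes are reported as D = 0 with a flag.
No correction is applied for the correlation of overlapping pairs in
per-molecule errors; molecule-to-molecule spread is the error source,
and population values are reported as mean ± SE over ≥30 molecules.

The salt series models D(c) = D₀ + slope·(c − c₀) with the measured
slope 0.25 µm² s⁻¹ mM⁻¹.  At that per-mM slope, a multi-10-mM span
would push D far beyond what a 13-µm tether at 50-ms frames can
resolve, so the preset probes a narrow span (50.0/50.2/50.4 mM, D =
0.10/0.15/0.20 µm²/s) in which molecules starting mid-tether rarely
reach the ends within the 1200-frame (60-s) record and the line fit is
nearly unbiased; at stationarity on the full tether, confinement
depresses the fitted slope by ~5–10% (measured at 2000
molecules/level), which is why the probe region matters.  The slope is
recovered by inverse-variance-weighted least squares over per-level
mean D, with the SE from the weighted normal equations.

Encounter classification uses a ±1.5-kb tolerance zone about the site
and a 0.25-kb stationarity threshold over the whole record (both
configurable): *captured* = loaded within the zone and stationary;
*bypass* = traversed from beyond one side of the zone to beyond the
other; *blocked* = entered the zone but never crossed; *no-encounter*
otherwise; precedence captured > bypass > blocked.  A 12-case golden
fixture set pins the semantics, including edge cases (start inside the
zone, one-sided excursions).

Dwell fits use the censored-exponential MLE: mean = total observed time
/ uncensored events, t½ = ln 2 × mean, which coincides with the
total-time-on-test estimator; a least-squares fit to the empirical
survival curve is available for comparison.  Records touching movie
boundaries are censored.  CIs are bootstrap percentile intervals over
(time, flag) pairs.

## Reproducibility and problem sizes

Every generator accepts an integer seed or a `numpy` Generator and is
bit-reproducible.  The scenario runner derives named per-stage seeds
from one master seed (SeedSequence keyed by a CRC32 of the stage name,
kept below 2³¹) so stages can be re-run in isolation, and emits
byte-identical JSON reports for identical configurations.

The acceptance script (`scripts/acceptance.py`) recomputes each
headline quantity at these problem sizes, chosen to put Monte-Carlo
error well inside each quantity's uncertainty while completing in
seconds: dwell half-lives as means over 200 replicate samples at the
reported N (63 and 49); the salt slope from 60 molecules × 1200 frames
at each of three concentrations; window enrichments from 40 replicate
experiments of 500 molecules per substrate, averaging window
frequencies before taking the ratio (a single-replicate ratio is noisy,
~15% SD, and carries a small positive Jensen bias from the reciprocal
of the reference count); peak centers from 10,000 site-component draws
(flap) and one 558-molecule draw (LacI site A).

## Known limitations

- Cassette and flap-oligo sequences are symbolic; digest layouts model
  the informative diagnostic bands, not a genome-wide site list.
- The wild-type λ genome FASTA is not bundled; recognition-site
  scanning is validated against a brute-force oracle on synthetic
  sequences, and whether a both-strand or top-strand count is wanted is
  left to the caller (both are reported).
- The linking stage is greedy, not globally optimal; dense fields of
  crossing particles can swap identities.
- The survival fit assumes a single exponential; mixtures will fit but
  the half-life then summarizes, rather than describes, the kinetics.
- Confined-diffusion bias on MSD line fits is characterized but not
  corrected; estimates at large √(DΔt)/L are conservative.
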