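# curtainkit

Simulation and analysis toolkit for single-molecule DNA-curtain
experiments on engineered bacteriophage-λ DNA substrates.

DNA curtains image hundreds of individual λ-DNA molecules (48.5 kb,
stretched to ~13 µm between microfabricated chromium features) by TIRF
microscopy, and follow fluorescently labeled proteins — Lac repressor
bound to engineered operator cassettes, or PCNA sliding clamps loaded at
5′-ssDNA flaps and (CAG)₁₃ triplet-repeat structures — as they bind,
diffuse, and dissociate.  `curtainkit` re-implements the computational
layer of such a study as a tested, reusable package for people who build
or analyze these experiments:

- **`curtainkit.substrate`** — the linear λ substrate as a coordinate
  system (origin at *cosL*, 0-based half-open bp intervals): insertion
  sites A/B/C at 21.3/33.5/45.3 kb, dispensable segments, cassette
  insertion with the 38–53 kb phage-packaging bound, nicking-cassette
  geometry (three nicks, 39 nt excised), recognition-site scanning on
  both strands, and in-silico duplex/strand digests.
- **`curtainkit.simulate`** — synthetic experiments via named presets:
  binding-position mixtures (site Gaussians + uniform background), 1D
  Brownian sliding with reflecting tether ends and reflecting/trapping
  site encounters, right-censored exponential dwell times, and rendered
  16-bit TIFF stacks (pixel-integrated Gaussian PSF, Poisson + read
  noise, 50-ms frames).
- **`curtainkit.tracking`** — spot detection (median + k·MAD robust
  threshold), sub-pixel symmetric 2D-Gaussian localization, greedy
  nearest-neighbor linking with gap closing, kymograph extraction.
- **`curtainkit.binding`** — µm→kb mapping through the tether geometry,
  1/2-Gaussian peak fits to 1-kb-binned histograms, bootstrap errors,
  the eight-window 5-kb enrichment statistic with Welch *t* and Pearson
  χ² tests.
- **`curtainkit.dynamics`** — mean-squared-displacement analysis

      MSD(nΔt) = 1/(N−n) Σᵢ (yᵢ₊ₙ − yᵢ)² ,  MSD(Δt) = 2DΔt,

  with D from an OLS line through the first 10 intervals (free
  intercept absorbs localization noise), salt-dependence slope of D,
  bypass/blocked/captured encounter classification, and censored-MLE
  exponential dwell fits (t½ = ln 2 × total time / events).
- **`curtainkit.pipeline` / `curtainkit.cli`** — scenario orchestration
  (simulate → track → analyze) with per-stage seeds derived from one
  master seed and byte-reproducible JSON reports; `curtainkit` console
  entry point.

## Worked example

Simulate the Lac-repressor site-A experiment at its reported sample size
(N = 558) and fit the binding peak:

```python
from curtainkit.pipeline import ScenarioConfig, run_scenario

report = run_scenario(ScenarioConfig(preset="LacI_siteA", seed=1))
print(report["peak_fit"])
# {'centers_kb': [21.843652], 'sds_kb': [1.080001], 'weights': [1.0], 'ok': True}
```

The fitted center (21.8 kb) and width (1.1 kb) recover the preset's
operator peak at 21.7 ± 1.0 kb within sampling error at N = 558.
Similarly, the flap-loading experiment against its homoduplex control:

```python
report = run_scenario(
    ScenarioConfig(preset="yPCNA_flap", seed=1,
                   reference_preset="yPCNA_homoduplex")
)
print(report["enrichment"]["fold"])   # 2.913043
```

gives the fold enrichment of clamp loading in the 5-kb window covering
the flap (preset value 2.7; a single 500-molecule draw carries ~15%
counting noise), and the IPTG-dissociation preset:

```python
report = run_scenario(ScenarioConfig(preset="LacI_IPTG_siteB", seed=1))
print(report["survival_fit"])
# {'t_half_s': 19.190662, 'ci_95_s': [15.0279, 23.539942],
#  'n_events': 63, 'n_censored': 0}
```

recovers the 21-s dissociation half-life within its bootstrap CI from a
63-molecule sample.  From the shell, the diagnostic digest of the
flap-modified substrate:

```sh
$ curtainkit substrate digest
fragment_bp,strand,enzyme
19310,duplex,NcoI
2800,duplex,NcoI
26392,duplex,NcoI
```

shows the 2.0 + 0.8 kb cassette fragments merged into one 2.8-kb band
once the flap insert abolishes the flap-proximal NcoI site.

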