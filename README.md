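# toccsl

Single-molecule subunit-stoichiometry analysis built around TOCCSL-style
brightness measurements, with a fully synthetic TIRF data generator so
every stage can be verified against known ground truth.

## What it does

- **`toccsl.synthetic`** — seeded generators for single-fluorophore
  brightness draws (lognormal law), oligomer mixture spots, rendered
  16-bit camera frames (integrated Gaussian PSF, shot + read noise,
  offset/gain), full TOCCSL runs (aperture bleach, Brownian re-entry),
  repeated-run bleach series with or without subunit exchange, and FRAP
  traces.
- **`toccsl.imaging`** — counts-to-photons conversion, matched-filter spot
  detection with robust thresholding and unresolvable-pair rejection,
  integrated 2D Gaussian spot fits yielding the single-spot brightness B,
  and surface-density estimation from prebleach frames.
- **`toccsl.mixture`** — monomer brightness PDF (KDE), autoconvolutions
  rho_n, maximum-likelihood mixture fit of the oligomer fractions alpha_n
  on the simplex (plus an independent least-squares-on-histogram
  cross-check), 50%/100-rep subsample bootstrap SDs, and the average
  oligomeric state sum(n * alpha_n).
- **`toccsl.kinetics`** — one-phase-association FRAP fits
  (I(t)/I0 = mf (1 - exp(-K t))), the apparent-fraction model for partial
  bleaching with/without subunit exchange, active-fluorophore decline, and
  the Friedman + Dunn posthoc exchange test.
- **`toccsl.pipeline` / CLI** — config-driven simulate → detect → fit →
  report orchestration with deterministic, seeded outputs, Spearman
  density/oligomer correlation, and Mann-Whitney condition comparison.

## CLI

```sh
toccsl simulate --out sim --seed 1 --cells 3          # TIFFs + truth + config
toccsl pipeline --config sim/config.yaml              # full analysis
toccsl report --results sim/results                   # plain-text summary
toccsl detect img.tif --out spots.csv                 # detection + fitting only
toccsl fit-mixture --brightness spots.csv --monomer mono.csv --out fit.csv
toccsl frap --trace trace.csv                         # mobile-fraction fit
toccsl exchange --series series.csv                   # Friedman + Dunn posthoc
```

Exit codes: 0 success, 1 config error, 2 data error. Every output CSV
carries a header comment with the config hash and seed; reruns with an
identical config are byte-identical.

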