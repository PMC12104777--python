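# bsd — Bayesian spectral decomposition

Bayesian analysis of neural power spectra. A spectrum is modelled as a
power-law aperiodic component plus one band-limited Gaussian peak per
frequency band; models are inverted with variational Laplace to obtain
Gaussian parameter posteriors and a free-energy approximation of the log
model evidence. Free energies feed Bayes-factor model comparison (does
the spectrum contain an alpha peak?) and parametric empirical Bayes (how
does the peak frequency change with age?) at the group level.

## Features

- **Spectral model** (`bsd.model`): frequency bands, link functions
  (positivity and soft band clipping), default priors, filter response
  modelling, per-condition parameter designs, noise covariance, and
  variance-8 rescaling of input spectra.
- **Inversion** (`bsd.inversion`): variational-Laplace fits
  (Gauss-Newton with Levenberg-Marquardt damping), free energy with an
  accuracy/complexity decomposition, analytic Jacobians, and Gaussian
  Bayesian model reduction. For linear forward models with fixed noise
  precision the results equal the conjugate closed form.
- **Model comparison** (`bsd.comparison`): model spaces over subsets of
  candidate bands, log Bayes factors, family-wise (peak presence)
  evidence averaging, and qualitative evidence labels.
- **Group analysis** (`bsd.peb`): second-level GLM over subject
  posteriors with estimated random-effects precisions, credible bands
  for each parameter over a covariate range, and group-level spectrum
  interpolation.
- **Simulators** (`bsd.simulate`): a 32-subject, two-condition,
  covariate-modulated group design and a single-peak SNR benchmark for
  ROC evaluation — no external data needed.
- **Detection benchmarking** (`bsd.roc`): evidence-based and
  peak-height detection criteria with rank-based ROC/AUC.

## Command line

```sh
bsd simulate --design group --seed 1 --out-dir out/    # spectra.tsv + truth.json
bsd fit out/spectra.tsv --config cfg.yaml --out-dir out/
bsd compare out/spectra.tsv --config cfg.yaml --out-dir out/
bsd peb out/posteriors.json design.tsv --out-dir out/
bsd roc out/spectra.tsv out/truth.json --band beta 12 30
bsd pipeline --seed 1 --out-dir results/               # simulate -> fit -> compare -> peb
```

Spectra tables are TSV/CSV with a `frequency_hz` column plus one column
per series. Configs are YAML (JSON accepted); see
`bsd.pipeline.DEFAULT_CONFIG` for the documented defaults. Exit codes:
2 config errors, 3 data errors, 4 numerical failures.

## Python API sketch

```python
import numpy as np
from bsd import Band, ModelSpec, fit, simulate_group
from bsd.comparison import enumerate_model_space, family_evidence, EvidenceTable
from bsd.model import scale_spectrum

ds = simulate_group(seed=1)                      # 32 subjects x 2 conditions
space = enumerate_model_space(ds.config.bands)   # none / alpha / beta / both
F = np.empty((ds.n_spectra, space.n_models))
ids = []
for i, (label, _k, _c, y) in enumerate(ds.iter_spectra()):
    ys, _ = scale_spectrum(y, ds.grid)
    F[i] = [fit(ys, ds.grid, m).free_energy for m in space.models]
    ids.append(label)
table = EvidenceTable(F=F, subject_ids=ids, model_ids=space.model_ids)
print(family_evidence(table, space).to_dict())
```

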