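# smfspipe

Analysis pipeline for single-molecule AFM force spectroscopy of a
dual-binding-mode receptor–ligand complex (cohesin:dockerin), plus a
synthetic trace generator that emulates the experiment.

In the experiment a Coh:Doc complex is pulled apart through a fusion
construct carrying a *fingerprint domain* (xylanase, ~89 nm contour-length
gain upon unfolding, or iLOV, 36 nm).  Doc binds Coh in one of two
~180°-rotated conformations of similar affinity.  The bound mode is set at
binding time and leaves a mechanical signature: mode A dissociates as a
**double rupture** — an ~8 nm contour sub-step (unraveling of the
N-terminal Ca-loop/helix-1 segment, 19 residues × 0.4 nm/aa = 7.6 nm)
followed by the final rupture — while mode B dissociates as a **single
rupture**.  Counting single vs double events therefore measures the
binding-mode ratio, once one corrects for *fingerprint censoring*: a curve
only enters the analysis if its fingerprint unfolded before the complex
ruptured, which preferentially discards the mechanically weaker event
class.

The pipeline implements, end to end:

* **WLC contour-length transformation** — each (force, extension) point
  with F > 0 maps to the contour length Lc solving the Marko–Siggia
  relation F = (kBT/p)[1/(4(1−x/Lc)²) − ¼ + x/Lc] at fixed persistence
  length p = 0.4 nm; a 1 nm-bandwidth KDE over these values turns a
  sawtooth trace into a barrier diagram whose local maxima are the
  unfolding barriers, and whose consecutive differences are the
  contour-length increments used for fingerprint screening (89/36/57 nm)
  and double detection (final increment in 8 ± 4 nm).
* **Bell–Evans rupture kinetics** — rupture-force distributions under a
  force ramp, with analytic most-probable force
  F* = (kBT/Δx)·ln(rΔx/(k₀kBT)) and exact inverse-CDF sampling, used both
  to simulate barriers and to calibrate them to reported peak forces.
* **Censoring-corrected counting statistics** — exact Clopper–Pearson
  intervals on class probabilities; the overlap probability
  P(F_fingerprint < F_rupture) estimated pairwise with an
  inverse-probability-weighted fingerprint marginal; the corrected ratio
  (n_double/o_double)/(n_single/o_single) with a seeded bootstrap; and the
  fingerprint-biasing comparison (conditional unfolding-force modes and a
  two-sample KS test) that distinguishes preset binding modes from
  competing pathways.

## Worked example

```python
from smfspipe import PipelineConfig, run_pipeline

report, records = run_pipeline(PipelineConfig(), n_simulate=300, seed=11)
g = report.groups["all"]
print(report.n_classified, report.rejected_by_reason)
print(g.counts.n_single, g.counts.n_double, g.counts.ci_double)
c = g.correction
print(c.observed_ratio, c.corrected_ratio, c.bootstrap_interval)
```

prints (default configuration: 50/50 binding modes, xylanase fingerprint,
800 nm/s, 5 pN force noise):

```
167 {'no_fingerprint': 96, 'early_double': 37}
75 92 (0.4723..., 0.6276...)
1.2266... 0.7514... (0.5337..., 1.0605...)
```

Of 300 simulated curves, 167 classify (75 single, 92 double); 96 are
rejected because the complex ruptured before the fingerprint unfolded
(censoring) and 37 because the 8 nm sub-step fired before the fingerprint
(early doubles, excluded from counting).  The double fraction is 0.55 with
a 95% Clopper–Pearson interval (0.47, 0.63).  The raw doubles/singles
ratio 1.23 overstates the doubles because censoring discards singles more
often; inflating each class count by its estimated survival probability
(here 0.45 for singles, 0.74 for doubles) gives the corrected ratio 0.75
with bootstrap interval (0.53, 1.06) — consistent with the configured
latent odds (≈ 0.65 apparent at these defaults) and, at realistic sample
sizes, recovering them closely.

The same workflow runs from the shell:

```bash
smfspipe simulate --n 500 --seed 1 --out-dir curves/
smfspipe analyze --in-dir curves/ --out results.csv
smfspipe stats --classified results.csv --seed 1 --out summary.json
smfspipe all --n 500 --seed 1 --out-dir run/     # everything at once
```

Curves are two-column TSV files (piezo nm, force pN) with `#` metadata
headers; the manifest, per-curve classifications and summaries are
CSV/JSON.  A YAML config (see `PipelineConfig.to_dict()` for the full
schema) overrides any default; unknown keys are rejected.

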