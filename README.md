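# ncd — nanocluster co-organization dynamics from two-color SMLM

Single-molecule localization microscopy (PALM/STORM) turns a fluorescence
movie into a list of molecular coordinates. For membrane signaling
proteins — Ras GTPases, their effectors, raft markers — the scientific
questions are spatial and dynamic: does a protein self-cluster at the
plasma membrane, do two proteins mix inside the same nanoclusters, is one
species enriched inside (or at the rim of) the nanodomains of another,
and how do clusters assemble and disperse over time?

`ncd` is a tested, reusable implementation of the point-pattern statistics
used to answer those questions from two-color localization tables
(ThunderSTORM-style CSV):

- **Preprocessing** — photoblinking correction by spatiotemporal grouping
  ("maximum off frames" / "maximum grouping distance"), ROI cropping, and
  slicing of live acquisitions into fixed-duration windows (e.g. 12,000
  frames at 50 fps → 48 windows of 5 s).
- **Pair-correlation statistics** — univariate g(r) (g ≡ 1 under complete
  spatial randomness), bivariate g₁₂(r), Monte Carlo **random-labeling
  envelopes** (19 simulations ≙ a one-sided 95% band), and the **extent of
  mixing** EOM(r) = (g₁₂(r) − 1) / (ḡ₁₂ᴿᴸ(r) − 1), which is 0 for
  non-interacting species and +1 for perfect mixing.
- **Coordinate-based colocalization (CBC)** — per-molecule Spearman
  correlation of own- vs other-species radial density profiles over 50
  rings (20–1000 nm), with nearest-neighbor weighting, a positional
  randomization null, and the kurtosis summary of the CBC histogram.
- **Nanodomain enrichment** — single-linkage clustering at a distance
  threshold d_th (default 80 nm), size classes (monomers … 5-mers and
  larger), domain polygons, and in/out density fold enrichment of a second
  species.
- **Cluster-state dynamics** — per-window (density, g(0–100)) features for
  a cluster ROI, cross-species synchrony (Pearson), a 3-state Gaussian
  mixture on the density–clustering map, and the row-stochastic Markov
  transition matrix between states across 5-s windows.
- **Synthetic data** — generators with known ground truth (Poisson
  backgrounds, Thomas nanoclusters, tunable mixing, peripheral and
  domain enrichment, blinking movies, Markov-driven assembly) for
  calibration and recovery testing.

## Worked example

Generate a clustered two-species pattern whose labels are assigned by
exact random labeling (the perfect-mixing limit), then measure
self-clustering and mixing:

```python
from ncd import (RadialBins, Window, bpcf, eom, mean_eom_short,
                 mean_g_short, pcf, rl_envelope)
from ncd.synthetic import gen_random_label_mix

a, b = gen_random_label_mix(mixing_fraction=1.0,
                            window=Window.square(5000.0), seed=7)
bins = RadialBins.linear(r_max=200.0, width=10.0)
print(f"species A: {a.n} molecules, density {a.density:.1f} per um^2")
print(f"self-clustering g(0-100) of A = {mean_g_short(pcf(a, bins, 'periodic')):.2f}")
env = rl_envelope(a, b, bins, n_sims=19, seed=7, edge_correction="periodic")
curve = eom(bpcf(a, b, bins, "periodic"), env)
print(f"short-range EOM = {mean_eom_short(curve):.3f}")
```

prints

```
species A: 485 molecules, density 19.4 per um^2
self-clustering g(0-100) of A = 21.86
short-range EOM = 0.965
```

g(0–100) ≫ 1 says the species is strongly self-clustered below 100 nm;
the EOM near +1 says the two labels are statistically indistinguishable
within those clusters — exactly what random labeling should give. Two
independently clustered species would instead give EOM ≈ 0.

## Command line

Each stage is also exposed as a subcommand of `ncd`
(`preprocess`, `paircorr`, `cbc`, `domains`, `dynamics`, `states`,
`simulate`), and `ncd run --config analysis.yaml` orchestrates the whole
pipeline, writing `curves.csv`, `cbc.csv`, `domains.json`, `traj.csv`,
`states.json` and a `manifest.json` that records the seed, a config hash
and every default that filled an omitted field. Fixed seed → byte-identical
outputs.

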