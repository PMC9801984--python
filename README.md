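# declinesim

A simulation-study toolkit for evaluating how well genomic methods detect
*recent* population declines (starting up to ~120 years before present) from
contemporary and temporally sampled (museum-style) genotype data.

The package provides every stage of the study as tested, reusable code:

- **demography** — life histories (annual `G1`, overlapping-generations `G2`
  with mean generation time ~3 y), exponential decline trajectories at a
  per-year rate λ, optional 10-fold ancestral size changes at 10,000
  generations, and enumeration of the full factorial study grid
  (18 scenarios × 5 replicates × 3 sampling schemes × 3 sample sizes ×
  3 data types = 2,430 dataset specifications).
- **forward_sim** — an individual-based forward-time simulator: yearly
  reproduction by drawing one male and one female parent with replacement
  among all breeding-age individuals, age-specific mortality, full pedigree
  recording, and pedigree-conditioned transmission of chromosome segments
  with Poisson recombination, recorded as tskit node/edge tables.
- **coalescent** — completion of the uncoalesced founder ancestry with a
  backward-time coalescent (msprime) at the historic size, including the
  ancestral size change, followed by mutation dropping at 1e-8 /bp/gen and
  genotype extraction for the recorded checkpoint samples
  (0/30/60/90/120 ybp).
- **datasets** — temporal sampling schemes (contemporary-only, two-sample,
  serial), WGS vs RAD-like subsetting (random non-overlapping 150-bp loci),
  dataset-wide minor-allele-frequency filtering, and VCF / folded-SFS text
  export with round-trip readers.
- **sfs / sfs_fit** — folded site-frequency spectra, singleton-error
  injection, a deterministic expected-SFS engine for piecewise
  constant/exponential size histories (stable lineage-weight recursion plus
  analytic coalescent-intensity integrals), and composite-likelihood fitting
  of four demographic models (constant; recent exponential change; ancient
  instantaneous change; both) with bounded multi-start truncated-Newton
  optimization, AIC model selection, and stable/declining/expanding
  classification.
- **ld** — two LD-based Ne estimators: an unlinked-pair Burrows-r² estimator
  with the Waples small-sample correction and delete-one-locus jackknife
  CIs, and a recombination-binned LD trajectory (Haldane map, hc = 0.05,
  400 bins) inverted per bin via E[r²] ≈ 1/(3 + 4Nc) with SNP-resampling
  CIs.
- **evaluation** — decline-detection criteria (AIC pathway and
  disjoint-95%-CI pathway), power, mean absolute percentage error, log10
  ratio bias, and the aggregation rules (subset scenarios, exclusion of the
  unlinked-LD method at n = 50, infinite-estimate counting).
- **pipeline / cli / study** — an end-to-end orchestrated pipeline with a
  seeded run manifest, tiny test fixtures, and scaled-down replications of
  the study's headline power experiments.

## Command-line interface

All stages run from a single YAML configuration (see
`tests/test_pipeline.py::TINY_CONFIG` for a minimal example):

```bash
declinesim run      --config config.yaml --out runs/demo        # all stages
declinesim simulate --config config.yaml --out runs/demo        # just simulations
declinesim infer    --config config.yaml --out runs/demo --method sfs
declinesim evaluate --config config.yaml --out runs/demo --strict
declinesim fixture  --preset decline_tiny --out fixtures/       # tiny VCF+SFS
```

Outputs land under the run directory: cached simulations (`sims/`), optional
VCF/SFS exports (`datasets/`), an estimates table (`estimates.csv`),
power/MAPE/infinite-count reports (`report_*.csv`), and a `manifest.json`
recording the config hash and seeds; re-runs with the same manifest skip
completed stages and reproduce results bit-for-bit.

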