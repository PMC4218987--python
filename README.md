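# repliprof

Sort-seq DNA replication profiling in Python: simulate S-phase-sorted
sequencing data from an explicit origin-firing / fork-progression model,
run the fragment-level processing and denoising cascade, quantify
profile sharpness, and score peak-based origin prediction with an
arbitrary-precision binomial enrichment statistic.

## What it does

DNA abundance in a FACS-sorted asynchronous S-phase population reflects
replication timing: early-replicating loci are present in up to two
copies per cell, late loci in one.  Sequencing that population, counting
reads per restriction fragment (DpnII/GATC), and normalizing against a
G1/G2 control yields a *replication profile* whose local maxima mark
active origins.

The package covers the full loop:

- **`repliprof.synthetic`** — ground-truth simulator.  Replication time
  is the arrival-time minimum `t(x) = min_i(T_i + |x - x_i| / v)` over
  origins with firing times `T_i` and fork velocity `v`; origins reached
  by a foreign fork before firing are passively replicated (dormant).
  Population abundance `A(x) = 2 - t(x)/T_S` feeds Poisson or
  negative-binomial fragment counts with a configurable length bias.
  A stochastic per-cell mode with firing efficiencies is included.
- **`repliprof.processing`** — in-silico digestion, 5'-position read
  counting, strict filters (fragments < 150 bp; pervasive-zero rows;
  blacklist; experiments < 100,000 reads), per-chromosome copy-number
  correction, smoothed fragment-length-bias removal, division by the
  mean G1/G2 control signal, and per-experiment z-scoring.
- **`repliprof.denoise`** — rank-k SVD reconstruction (k = 50 by
  default, capped at matrix rank) and per-chromosome Savitzky–Golay
  smoothing; replicate columns average into one profile per strain.
- **`repliprof.metrics`** — prominence-thresholded extrema with
  alternation enforcement and sub-fragment quadratic position
  refinement, activation-height tables at reference positions,
  sharpness summaries (difference histograms and 25/50/75 percentiles at
  reference extrema), length-weighted autocorrelation with half-decay
  lag, and Pearson correlation matrices across strains.
- **`repliprof.prediction`** — 5-kb peak/origin matching, genome window
  coverage fraction, and the upper binomial tail
  `P(X >= K) = sum C(N,i) p^i (1-p)^(N-i)` computed so that values near
  1e-100 keep at least six significant digits (incomplete-beta in
  doubles with an mpmath fallback); results as `{N, K, d, p,
  log10_p_value}`.
- **`repliprof.pipeline` / `repliprof.cli`** — reproducible end-to-end
  runs with YAML configs, three presets (`wildtype`, `slow-fork` with
  `v / 4`, `scaled` with `T x 2, v / 2`), JSON manifests, and
  deterministic seeding throughout.

The central qualitative result reproduced by the simulator + pipeline:
slowing forks activates dormant origins and *sharpens* the profile
(more maxima, faster autocorrelation decay, higher peaks and deeper
valleys), whereas proportional slowdown (`T x 2, v / 2`) leaves the
normalized profile unchanged — the scaling phenotype.

## CLI

```bash
# simulate a dataset (FASTA + BED + TSV counts + ground-truth bedGraph)
repliprof simulate --preset wildtype --seed 1 --out runs/wt

# process counts into profiles, metrics and prediction reports
repliprof process --counts runs/wt/counts.tsv --fragments runs/wt/fragments.tsv \
    --origins runs/wt/origins.bed --genome runs/wt/genome.fa --out runs/wt/proc

# shape metrics / origin prediction for one profile
repliprof metrics --profile runs/wt/proc/profile_wildtype.bedgraph
repliprof predict --profile runs/wt/proc/profile_wildtype.bedgraph \
    --origins runs/wt/origins.bed --genome runs/wt/genome.fa

# run two presets on shared ground truth and contrast them
repliprof compare --seed 1 --presets wildtype,slow-fork --out runs/contrast
```

Exit codes: 0 success, 2 configuration error, 3 stage failure.

## Acceptance

Acceptance is property-based and lives in `tests/test_acceptance.py`
(binomial-tail oracle equivalence, per-base coverage oracle, strict
filter semantics, signal-conditioning identities, normalization
contracts, parameter recovery on simulation, and the slow-fork
sharpening vs. proportional-scaling phenotype contrast).  The report
script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes a quick end-to-end sanity battery and writes the (empty)
target report; there are no reproducible numeric targets because the
original study's headline counts derive from its real sequencing data.
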