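# qmnase

Quantifiable MNase-seq: statistical detection of nucleosome repositioning
in promoter windows, with input-subtracted sigma-threshold ChIP-seq
binding-site calling.

## What it does

MNase-seq reads out nucleosome positions: chromatin digested with
micrococcal nuclease protects ~150 bp mononucleosome footprints whose
fragment centres mark where nucleosomes sit. `qmnase` turns two MNase-seq
samples (e.g. proliferating myoblasts vs differentiated myotubes) into
per-base-pair statistics of nucleosome *repositioning* at promoters:

1. **Coverage engine** — fragments are size-filtered to the
   mononucleosome range (130–200 bp) and each fragment contributes a
   3 bp footprint at its centre; coverage is genome-size normalized and
   written as bedgraph.
2. **Promoter frame** — every gene's −3000..+999 bp window around the
   TSS is extracted into a common strand-aware coordinate frame and
   sum-normalized, so each promoter profile is a probability
   distribution of nucleosome occupancy.
3. **Per-bp paired t-test** — for a group of co-regulated genes, the
   myotube−control difference at each of the 4000 offsets is tested
   across genes with a paired t-test (α = 0.05; optional
   Benjamini–Hochberg).
4. **Region calling and classification** — significant same-sign runs
   are merged (gaps ≤ 25 bp, width ≥ 10 bp) and classified by a
   mass-conservation rule: an adjacent loss/gain lobe pair carrying
   comparable displaced signal is a nucleosome **shift** (downstream or
   upstream); unpaired gains are **build-up**, unpaired losses **loss**.
5. **Profile regression** — differential lobes are summarized by
   two-Lorentzian least-squares fits (signed amplitudes, centres,
   half-widths) or an integral-preserving penalized spline; a spectral
   diagnostic reports the dominant spatial frequency.
6. **ChIP binding** — input-subtracted binding values per promoter;
   sites are called where the signal exceeds the window mean by ≥ 4
   standard deviations (seed) and extended to the surrounding ≥ 1 σ run,
   then validated across replicates and intersected with the
   differential regions.
7. **Synthetic data** — a generator with planted, ground-truth shifts,
   build-ups and losses on shared per-gene nucleosome architectures, used
   for calibration and end-to-end validation.

## Worked example

Simulate the packaged demo experiment (12 skeletal-muscle genes, five
planted promoter perturbations), run the per-bp paired test, and call
and classify regions:

```python
import numpy as np
from qmnase.dynamics import (per_bp_paired_test, call_regions,
                             classify_regions, regions_to_frame)
from qmnase.simulate import demo_spec, simulate_group_profiles

spec = demo_spec()
ctrl, myo = simulate_group_profiles(spec, "skeletal", 12,
                                    np.random.default_rng(7))
res = per_bp_paired_test(ctrl, myo, group="skeletal")
regions = classify_regions(call_regions(res))
print(regions_to_frame(regions).query("width >= 90").to_string(index=False))
print("significant offsets:", int(res.mask.sum()), "of", res.mask.size)
```

Output:

```
label  start   end  width direction   classification  mean_delta
    D  -2526 -2405    122      loss downstream_shift   -0.000380
    E  -2383 -2262    122      gain downstream_shift    0.000367
    G  -2141 -1953    189      gain          buildup    0.000593
    O   -598  -474    125      loss downstream_shift   -0.000337
    P   -457  -360     98      gain downstream_shift    0.000329
    S    -41   139    181      loss             loss   -0.000302
    W    561   704    144      loss downstream_shift   -0.000364
    X    712   827    116      gain downstream_shift    0.000381
significant offsets: 1021 of 4000
```

The eight wide regions are exactly the five planted effects: three
downstream shifts (loss/gain lobe pairs D+E at −2500..−2400, O+P at
−650..−400, W+X at +600..+700, each displaced by the planted 120 bp),
one occupancy build-up (G, planted at −2150..−1950) and one loss (S,
planted at −50..+100).

The same analysis is available from the command line; `qmnase run
--out-dir out --seed 7` executes the full simulate → coverage → diff →
regions → fit → correlate → chip-call pipeline and writes ten TSV
tables plus a manifest with content hashes.

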