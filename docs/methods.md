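# Methods

This note records the statistical model implemented by `qmnase`, the
default parameters and why they have the values they do, and the known
limitations. Promoter coordinates throughout are TSS-relative offsets
in the window −3000..+999 (4000 bp, inclusive); minus-strand genes are
mapped into this frame by reversing the genomic window, so "downstream"
always means toward the gene body.

## Coverage model

- **Fragment size filter**: 130–200 bp inclusive, the mononucleosome
  protection range for the packaged fragment-length mixture
  (0.95·N(165, 10²) mono + 0.05·N(330, 20²) di). Dinucleosome
  fragments are excluded because their centres fall between
  nucleosomes.
- **Centre counting**: each fragment contributes coverage 1 at the
  three bases {c−1, c, c+1} around its centre c = ⌊(start+end)/2⌋
  (half-open BED intervals). A 3 bp footprint keeps the positional
  resolution of centre counting while avoiding single-base sparsity.
  The ±1 bp convention at even/odd lengths is immaterial to every
  downstream statistic.
- **Genome normalization**: tracks are scaled to 1× coverage using the
  mouse (mm10) effective genome size 2,652,783,500 bp, making tracks
  from different sequencing depths comparable.
- **Promoter normalization**: each gene's 4000-bp window is divided by
  its sum, so profiles are occupancy distributions and the
  myotube−control difference (Δ) sums to 0 by construction. This
  removes per-gene depth and MNase-efficiency differences, at the cost
  of the renormalization coupling discussed under *Classification*.

## Per-bp paired statistics

For a gene group, Δ at each offset is tested across genes with a
two-sided paired t-test (the pairing is per gene: both conditions share
that gene's promoter architecture). Defaults:

- **α = 0.05, uncorrected.** The per-offset test is reported at the
  nominal level; with 4000 dependent tests per window this trades
  false positives for sensitivity, which is why isolated significant
  bases are never interpreted alone — region calling (below) requires
  coherent runs. Benjamini–Hochberg across the window is available
  (`bh=True`).
- Zero-variance offsets: all-zero differences give p = 1; identical
  non-zero differences are flagged degenerate-significant rather than
  reporting an infinite t statistic.
- Calibration: on null synthetic data (identical architectures, no
  planted effect) the empirical rejection rate is ≈ 0.05
  (`scripts/acceptance.py`, target t3).

## Region calling

Significant offsets sharing the sign of the mean Δ are merged into
regions when separated by **gaps ≤ 25 bp**; regions narrower than
**10 bp** are dropped. The gap bridges the single-base dropouts
expected of an unsmoothed per-bp mask at α = 0.05; the minimum width
keeps the narrowest biologically meaningful differential intervals
(~16 bp) while discarding isolated noise. Regions are labelled A, B, …
in genomic order. Each region carries two summaries: `mean_delta`, the
mean Δ over its *significant* offsets (sign-consistent with the
direction call — a full-span mean could be flipped by opposite-sign
noise inside bridged gaps), and `delta_mass`, the sum of same-sign Δ
over the full span (sub-threshold bases inside bridged gaps carry real
displaced signal; opposite-sign noise is excluded).

## Region classification

A repositioned nucleosome produces a characteristic **loss lobe at its
old position and a gain lobe at its new position, carrying comparable
occupancy mass** (sum normalization conserves the displaced signal).
The classifier exploits exactly this:

1. **Lobe clustering** — same-direction regions separated by
   ≤ `cluster_gap` = 30 bp are treated as one lobe (per-bp masks
   fragment a single physical lobe where it dips under threshold).
2. **Candidate pairs** — an adjacent loss-lobe/gain-lobe pair is a
   shift candidate if the gap between the lobes is
   ≤ `pairing_distance` = 300 bp (a displaced nucleosome's lobes are
   contiguous or nearly so; 300 bp ≳ one spacing unit) **and** the
   larger lobe mass is ≤ `mass_ratio` = 1.5 × the smaller (mass
   conservation; lobe mass is the summed `delta_mass` of members).
3. **Matching** — candidates are accepted greedily, ordered by gap then
   mass imbalance; matched pairs become `downstream_shift` (loss first)
   or `upstream_shift` (gain first); unmatched gains are `buildup`,
   unmatched losses `loss`.

The mass gate is essential, not cosmetic. Under per-promoter sum
normalization, a strong occupancy *loss* induces a coherent
compensating *gain* at the aligned neighbouring nucleosomes — a
renormalization echo whose mass is roughly 1/2.5 of the loss. Naive
adjacency pairing misreads that echo as a shift; requiring the lobes to
balance within 1.5× (true shift lobes balance within ~1.4×, echoes sit
near 2.5×) separates the two cases.

## Profile regression

- **Two-Lorentzian fit**: a differential lobe pair is summarized by
  y = b + Σᵢ Aᵢ / (1 + ((x−cᵢ)/γᵢ)²) with signed amplitudes, fitted by
  least squares from multiple data-driven starts (coarse extrema of the
  binned signal), with a nested-model guarantee that the two-component
  RSS never exceeds the single-component RSS. Heavy-tailed Lorentzians
  fit occupancy-difference lobes better than Gaussians because jittered
  nucleosome positions mix widths.
- **Constrained spline**: a cubic P-spline (B-spline basis, second-
  difference penalty, λ chosen by generalized cross-validation) with a
  linear equality constraint preserving the integral of the data — a
  smoothed Δ-profile still sums to ~0, as the statistic requires.
- **Spectral diagnostic**: the dominant non-DC frequency of a profile
  via the real FFT, with power below 10⁻²⁰ of the signal energy treated
  as numerically negligible (rounding noise must not produce a
  "dominant" frequency on constant input).

## ChIP binding

- **Binding value**: IP minus input, both as sum-normalized promoter
  profiles, so the statistic is depth-free and sums to 0 per window.
- **4σ caller**: sites are seeded where the binding value exceeds the
  window mean by ≥ 4 standard deviations (population SD, ddof = 0,
  over the 4000 window values) and extended to the surrounding run
  above mean + 1σ. The rule is affine-invariant. The one-sided
  Gaussian confidence of the 4σ threshold is 100·Φ(4) = 99.9968 %;
  the commonly quoted "99.8 %" for 4σ understates it (99.8 % already
  holds just below 3σ) — the implementation computes the exact value.
- **Replicate validation**: a site is kept only if it overlaps (≥ 1 bp)
  a site called independently in the other replicate of the same gene
  and condition; replicate-inconsistent noise excursions are discarded.
- Downstream reports: per-group site census (each gene counted once),
  control→myotube site retention, Δ-content under sites, and
  site-vs-differential-region overlap with signed distances.

## Gene groups

Four a-priori promoter groups are packaged: skeletal-muscle-specific
(12 genes), muscle-common (9), heart-specific (6), and a non-muscle
control set of **26 unique genes** (fibroblast, endothelial and
neuronal markers). Curation note: endothelial marker lists often
include both *Cd31* and *Pecam1*, which are aliases of the same gene;
the packaged config keeps *Pecam1* so gene identifiers are unique and
the group size is 26.

## Synthetic data

The generator is the package's ground-truth instrument, built around a
**paired design**: each gene draws one nucleosome architecture
(centres at ~190 bp mean spacing, 15 bp spacing jitter, occupancy
bell-width 30 bp) that is shared by both conditions, and only the
condition-specific perturbation differs. An unpaired generator would
bury planted effects in inter-gene architecture variance — the pairing
is what gives the per-bp paired t-test its power, in simulation as in
a real differentiation experiment.

- **Anchoring**: within each perturbation window the nucleosome nearest
  the window midpoint is pinned to it (10 bp cross-gene jitter) in the
  shared architecture. Co-regulated promoters share positioned
  nucleosomes at their regulatory elements; without that alignment each
  gene's change lands at a different offset and the group-level per-bp
  statistic washes out.
- **Planted perturbations** (demo spec, skeletal group): downstream
  shifts of the anchored nucleosome by **δ = 120 bp** at −2500..−2400,
  −650..−400 and +600..+700; a 3× occupancy build-up at −2150..−1950; a
  0.85 occupancy loss at −50..+100. δ = 120 keeps the move local
  (< one spacing unit) while separating the loss and gain lobes; at
  δ ≈ 80 the lobes overlap by more than half a lobe width and partially
  cancel. Window widths are 100–250 bp so exactly one positioned
  nucleosome sits inside (window half-width < spacing − 3·jitter);
  wider windows let a second, unanchored nucleosome straddle the edge
  and smear the planted signature.
- **Fragments**: lengths from the mono/di mixture above, centres from
  the perturbed occupancy distribution, mapped to genomic coordinates
  per strand; ChIP adds box-shaped enrichments over a uniform input
  with independent replicates.
- **Null generator**: per-gene occupancy curves plus i.i.d. Gaussian
  noise in both conditions (equal means), truncated at zero and
  sum-normalized — the calibration substrate for target t3.

## Numerical and engineering choices

- Coverage tracks are run-length encoded (start, end, value) and
  round-trip bedgraph text exactly (floats serialized with round-trip
  precision); dense expansion is exact, not interpolated.
- All stochastic code takes an explicit `numpy` `Generator`; the
  pipeline derives per-stage seeds from the run seed, and same-seed
  runs are byte-identical (manifest records SHA-256 of every table).
- The pipeline writes a manifest (parameters, seed, versions, table
  hashes) on success and a partial, stage-named manifest on failure.

## Limitations

- The synthetic generator models promoter windows only — no genome-wide
  background, GC/mappability bias, or MNase sequence preference.
- Per-bp tests at adjacent offsets are strongly dependent (a fragment
  spans 3 bp of centre coverage and a nucleosome ~150 bp); nominal-α
  calibration holds per offset, not family-wise, by design.
- The classifier's mass gate assumes sum-normalized profiles; on
  unnormalized data lobe masses need not balance and the shift call
  degrades to adjacency pairing.
- Real-data ingestion starts from fragment BED files; alignment and
  duplicate handling are upstream of this package.
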