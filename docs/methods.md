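# Methods

## The statistical problem

MEG/EEG functional-connectivity contrasts between two cortical regions of
interest (ROIs) are usually run on the ROI-averaged time series. When the
underlying effect occupies only part of an ROI — or different parts in
different subjects — averaging dilutes it. The test implemented here
subdivides each ROI into N (and M) sub-ROIs, estimates time–frequency
coherence for every cross-ROI sub-ROI pair, and aggregates pair-level
cluster statistics into a single permutation-tested quantity, retaining
spectral, temporal and spatial specificity while controlling the
family-wise error rate (FWER) non-parametrically.

## The test

For subjects s = 1..S, conditions C1, C2, and each sub-ROI pair (i, j):

1. **Coherence.** Morlet-wavelet coefficients X_e(f, t) per epoch e give
   magnitude coherence across epochs,
   Coh(f,t) = |Σ_e X_e conj(Y_e)| / sqrt(Σ_e |X_e|² Σ_e |Y_e|²) ∈ [0, 1].
2. **Pair-level cluster statistics.** The per-subject condition
   difference of coherence is tested pointwise with a paired t-test
   (df = S−1). Points with |t| above the two-sided parametric threshold
   (97.5th t percentile by default) are grouped into 4-connected
   components of the TF plane; each cluster's **mass** is the sum of its
   t-values (sign = direction of the difference). Cluster p-values come
   from the sign-flip permutation distribution of the maximum absolute
   cluster mass (max-statistic FWER over time and frequency, both signs
   jointly). In a paired design, swapping a subject's condition labels
   flips the sign of its difference map, so relabelings are sign
   vectors ε ∈ {±1}^S.
3. **Aggregation.** Per direction (C1>C2 / C2>C1), the N×M *original
   connectivity matrix* holds, for each pair, the mass of its
   largest-|mass| significant cluster (p < α, default 0.05), else 0.
   The *original total connectivity* is A = Σ_ij |a_ij|.
4. **Outer permutation.** The whole inner procedure is recomputed under
   condition relabelings to build the null distribution of A per
   direction; p = (k+1)/(n_p+1) with k the number of null totals
   tying-or-exceeding the observed A, Bonferroni-corrected by 2 for the
   two directions.

### Nested-permutation strategy

Inner and outer nulls share **one** set of relabelings. Per pair, the
t-maps of all relabelings are computed in a single batch (sign flips
leave the per-subject mean square invariant, so only flipped means are
recomputed), and all relabelings' TF planes are clustered in one
connected-component pass. Every relabeling's clusters — the identity
included — are ranked against the max-|mass| set of **all** relabelings:
p_c = #{max ≥ |m|} / n_total. This symmetric convention preserves
exchangeability exactly (an asymmetric variant that leaves the identity
out of the ranking set is measurably anticonservative), and for the
observed labeling it is algebraically identical to the usual
(k+1)/(n_p+1) formula, because a labeling's own maximum always
ties-or-exceeds each of its clusters. Cost is O(n_p · N · M) t-maps
instead of O(n_p²).

With 2^S ≤ n_p all 2^S relabelings are enumerated; the test is then
exact and fully deterministic (at the default S = 8 and n_p ≥ 256:
256 relabelings, smallest attainable p = 1/256 ≈ 0.0039). Otherwise
n_p relabelings are sampled uniformly with replacement.

### Tie handling

Outer exceedance counts ties (k = #{null ≥ A}). With a continuous null
this is indistinguishable from strict exceedance; in the fully
degenerate case (identical conditions, all totals zero) it yields p = 1,
where strict counting would produce a spurious p = 1/(n_p+1).

## The conventional comparator

Sub-ROI series are averaged (unweighted mean) within each ROI, a single
coherence map per subject/condition is computed, and one cluster test —
same forming threshold, connectivity, null conventions — decides at
level 0.05 on the minimum cluster p. Power differences against the
nested test are therefore attributable to sub-ROI aggregation alone.

## Synthetic data generator

Emulates a two-ROI, two-condition epoched study at the sub-ROI level
(one series per sub-ROI; forward/inverse modelling and anatomy are
deliberately bypassed — the statistical structure the test addresses,
TF-coherent bursts in some sub-ROIs and noise elsewhere, is preserved).

- **Signal** (condition 1, active sub-ROIs of both ROIs): Hann-windowed
  equal-weight sum of sinusoids, q0·(1/F)·Σ_{f∈Ω} w(τ)·sin(2πfτ) with
  τ = t − t_on, Ω = {15…20} Hz, window 200–400 ms, exactly zero outside.
  The same waveform is injected in every active sub-ROI and epoch
  (maximal inter-ROI coherence; phase-lagged variants are configurable
  through the burst helper).
- **Noise**: per-sub-ROI 1/f (power-law exponent 1) Gaussian processes
  plus a shared 1/f component with mixing weight 0.2, giving the weak
  baseline inter-regional coherence of resting recordings
  (magnitude-squared ≈ (w²/(1+w²))² ≈ 0.04). Variance normalization is
  analytic, not empirical. Condition 1 noise is β·R1 + R2 (independent
  draws R1, R2); condition 2 is β·R1′ + R2′ from the same law, so with
  signal scale 0 the conditions are exchangeable by construction.
- **SNR** (dB) = 20·log10(S/N): S = mean |signal| over all channels
  within the signal window, N = mean |condition-2 noise| over all
  channels and times. Because S is linear in the signal scale α_sig,
  a target SNR can be realized exactly by solving for α_sig.
- **Spatial layouts**: *continuous* (sub-ROIs {0,1,2} of both ROIs),
  *scattered* ({0,3,6}, pairwise non-adjacent), *variable* (ROI1's
  triple drawn once per dataset and shared by all subjects; ROI2's
  triples per-subject, non-adjacent, pairwise distinct across subjects).

The canonical study conditions are the defaults: 8 subjects, 9
sub-ROIs per ROI, 50 epochs per condition, −250…750 ms at 600 Hz,
α_sig ~ U(0.04, 0.1) and β ~ U(0, 1) when not fixed. The background
noise amplitude (noise_scale = 0.03, abstract units) was chosen once so
this α_sig range maps onto realized SNRs of roughly −2…6 dB, bracketing
the 2–3.4 dB regime the simulations treat as their illustrative working
points.

### What the generator does *not* emulate

Recorded resting-state MEG (spatially structured, artifact-laden,
non-Gaussian), sensor physics, and — importantly — source leakage
(point spread), which in real source estimates smears activation into
neighbouring sub-ROIs. Consequences for interpreting the simulations:

- Because the burst is identical in every epoch and subject, the
  between-subject variance of the coherence excess is tiny and the
  paired t-statistics are very large for any consistent effect: in the
  continuous and scattered layouts both methods retain full power far
  below 0 dB (verified to −25 dB at small replicate counts). On real
  noise the dilution penalty of ROI averaging produces the published
  sensitivity gap; here it never materializes for these layouts.
- In the subject-variable layout each cross pair is active in only ~1/3
  of subjects; the paired t saturates below the forming threshold as
  SNR grows, capping the nested test's sensitivity around 60–75%
  (0.73 measured at 30 replicates at 6 dB) regardless of SNR. With
  source leakage, activation would effectively cover more sub-ROIs per
  subject, lifting this ceiling. The ROI-averaging comparator is
  layout-invariant here (every subject's ROI mean carries 3/9 bursts of
  identical waveform), so it does not degrade for scattered/variable
  layouts the way it does on real noise.

Passing simulation tests therefore validate the statistical machinery
(calibration, exactness, FWER control, ordinal power behaviour where
the noise model supports it), not point reproduction of real-data power
curves.

## Numerical and design choices

- **TF estimator**: Morlet wavelets, 7 cycles; default grid 8–45 Hz
  step 1 Hz, decimation to 100 Hz; the "reduced" profile (power sweeps,
  desk-scale runs) uses 10–30 Hz step 2 Hz, decimation 8, n_p = 500.
  Epochs shorter than the longest wavelet are zero-padded symmetrically
  and cropped back after the transform.
- **Edge handling**: TF samples within 2 wavelet standard deviations
  (σ_t = n_cycles/(2πf_min)) of the epoch edges are excluded from all
  statistics.
- **Degenerate points**: zero difference-variance gives t = 0 (counted);
  zero coherence denominators give coherence 0 (counted).
- **Two thresholds, deliberately separate**: the parametric
  cluster-forming threshold on |t| (two-sided level 0.05 → 97.5th t
  percentile) and the cluster-selection threshold α on permutation
  cluster p-values (0.05). Both configurable.
- **Per-pair aggregation**: the largest-|mass| significant cluster per
  direction (a pair contributes one value); summing all significant
  masses is available as an option.
- **Multiple same-direction clusters / no clusters**: no suprathreshold
  points → empty cluster list → zero matrix entry → A may be 0, in
  which case the raw p is exactly 1.
- **Reproducibility**: one master seed; per-(subject, stream) and
  per-(grid point, replicate) RNG streams derived via SeedSequence spawn
  keys. Identical (seed, config, data) re-runs are bit-identical.
- **Monte-Carlo power**: replicates are paired (both methods consume the
  same dataset and, with exhaustive relabelings, the same labeling set);
  sensitivities carry Clopper–Pearson 95% intervals; failed replicates
  are recorded with their error, not dropped. Default problem sizes:
  30 replicates per grid point and the reduced analysis profile for
  sweeps; 100 replicates with the full profile for final figures.

## Known limitations

- The coherence estimator is fixed to across-epoch magnitude coherence
  on Morlet coefficients (the front-end is pluggable); PLV/wPLI-style
  metrics are out of scope.
- Cluster connectivity is 4-neighbour on the TF plane; no TFCE.
- The variance-stabilizing arctanh transform is off by default (paired
  t-tests are applied to coherence directly); enable `fisher_z` to use
  it.
- Exchangeability of conditions is assumed, as in any permutation test;
  unbalanced designs and multi-condition (ANOVA-style) contrasts are not
  supported.
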