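# Methods

## Scope and model of the experiment

`lrrmap` treats a repeat protein as an ordered chain of design units: the
repeats `1..R`, optionally interrupted by one *loopout* pseudo-unit (a
non-repeat insertion that occupies a single slot in the ordering and
counts as one unit for all design arithmetic). Terminal caps are appended
to every construct but are not design units. Unit indexing is 1-based and
windows are inclusive on both ends, matching the field's "LRRs 6–10"
naming. Sequences are optional throughout: the design and statistics never
look at amino acids, only assembly and FASTA export do.

In the packaged demo the loopout sits between repeats 27 and 28. That
placement is an assumption reconstructed from refinement-round construct
naming (the final 5-unit window of the C-terminal region is `l/o-31`,
which fixes the loopout five ordinals from the end); it is a config field,
not a constant.

## Entropy-guided sub-segmentation

For a region of `L` units tiled by all `L − n + 1` stride-1 windows of
length `n`, the inclusion fraction of unit `i` is
`P_i = min(i, n, L−i+1, L−n+1)/(L−n+1)` (exact rationals internally), and
the experiment is scored by `entropy = −Σ P_i log₂ P_i`. The `P_i` are
used exactly as defined — inclusion fractions summing to `n`, not a
probability distribution. Entropy-argmax ties break toward the larger `n`
(larger sub-segments keep repeats in a more native-like environment).
Admissibility at tolerance `t` (default 0.9) means
`entropy(n) ≥ t · max_n entropy`, compared with a relative epsilon of
1e-9 so lengths sitting exactly on the threshold are kept. Profiles cover
`n = 1..L` even though the extremes are rarely useful; filtering is the
caller's concern. Refinement rounds select the **largest** admissible
length by default (folding trumps a small entropy gain); the rule and an
explicit per-round `n` override are exposed.

## Partitioning and branch-and-bound pruning

The initial coarse partition covers the `R` repeats with `k` segments of
length `s`; the excess `k·s − R` is spread over the `k − 1` junctions as
evenly as possible, larger overlaps to earlier junctions on ties. Overlap
hedges against misfolding of repeats abutting a non-native cap junction.
(The run configuration exposes `k_initial` and `segment_length`; the
junction overlap — 4 for the 31/3×13 demo — is derived, not set.)

Pruning uses the same misfolding concern in reverse: a non-binding
construct is only trusted in its core, i.e. the window minus
`edge_margin` units at each end (default 2 — the value that reconciles a
4-unit junction overlap with retaining units two-from-the-edge of a
negative segment). Positive windows minus the union of trusted negative
cores, returned as maximal contiguous runs, are the next round's candidate
regions. Inconclusive calls contribute no evidence in either direction:
a weak ribosome-display signal cannot distinguish non-binding from
misfolding on the ribosome. This pruning rule is a reconstruction of the
worked decision sequence the method is modeled on, not a quoted
algorithm; the margin is configurable.

## Simulator

The generator emulates competed/uncompeted ribosome-display qPCR readouts:

* specific binding `s = β · max_p overlap(construct, p)/|p|`, zeroed when
  the best contiguous overlap is below `min_contig` (default 3 units) —
  too small an interface gives no detectable binding;
* bound material `s + b` uncompeted and `leak·s + b` competed
  (defaults `b = 0.05`, `leak = 0.05`, `β = 1`); competition is a
  multiplicative survival fraction rather than mass-action titration,
  which keeps the parameters identifiable at desk scale;
* `Cq = c0 − log₂(bound) + batch_offset + N(0, σ)` with `c0 = 20`,
  σ default 0.25 cycles, i.e. perfect doubling per cycle; amplification
  efficiency deviations are out of scope;
* dose-response: bound `(1 − level·(1 − leak))·s + b` for competitor
  levels in [0, 1].

Closed form under σ = 0: `ΔCq = log₂((s+b)/(leak·s+b))`, zero iff
`s = 0`, strictly increasing in `s`; a full binder gives
`log₂(1.05/0.10) ≈ 3.39` cycles. All randomness flows from one
`numpy` generator seeded per run; regeneration is bit-identical.

What the generator does **not** model: translation efficiency, ribosome
kinetics, gel-band imaging (a `band_intensities` helper returns a column
proportional to 2^(−Cq) instead), amplification-efficiency variation, or
construct-specific misfolding (an s-independent background is the only
noise floor). Passing recovery tests therefore demonstrate that the
design→analysis loop is self-consistent under additive batch effects and
Gaussian cycle noise — not that real panning data meet those assumptions.
Demo noise levels (σ = 0.25 cycles, ±0 batch offsets, 3 replicates) were
chosen once as typical of replicate qPCR spread.

## Statistics

1. **Batch normalization**: each batch is shifted to the global average
   Cq (`Cq − batch mean + grand mean`), preserving all within-batch
   differences exactly; day-to-day additive offsets cancel.
2. **ΔCq**: competed − uncompeted, paired by (replicate, batch); with
   balanced data the mean of paired differences equals the difference of
   condition means. The reported uncertainty is the propagated
   `sqrt(sd_c² + sd_u²)` of the per-condition Cq spreads.
3. **Outlier fence**: constructs whose propagated sd exceeds
   `Q3 + 1.5·IQR` of the round's sds are excluded. The fence is one-sided
   (low variance is not a defect) and `k = 1.5` is the conventional
   multiplier; with fewer than four usable constructs quartiles are
   meaningless and nothing is flagged.
4. **ANOVA + Tukey HSD**: single-factor ANOVA on the replicate-level ΔCq
   values (replicate-level, not summary means — the only choice that
   makes the ANOVA well-posed), then Tukey HSD on all pairs via the
   studentized range with the Tukey–Kramer adjustment for unequal group
   sizes, significant at α (default 0.1). Degenerate inputs (all
   observations identical) report an undefined F and no significant
   pairs; all-constant but distinct groups report F = ∞ and unambiguous
   pairs.

## Hotspot calling

A construct is *significant* when its mean ΔCq is positive **and** it is
Tukey-significantly greater than at least one other construct in the
round — the round's own low-signal constructs act as the internal
non-binder baseline. This is a decision rule of this package: the source
workflow picks "greatest signal-to-noise" constructs informally, and a
rule phrased against ground-truth non-binders would be circular at
analysis time. With a single construct there is no baseline and a ΔCq
floor (default 1.0 cycle) is used instead. Per-unit support counts
significant and tested constructs containing each unit; hotspots are
maximal contiguous runs with support ≥ `min_support` (default 1 — dense
tilings may warrant more). Ties for a region's top construct break by
largest ΔCq mean, then smallest span, then lowest start unit. Resolution
is the repeat unit; no residue-level claims are made.

Because every window partially overlapping a paratope can reach
significance, called intervals are typically the paratope padded by
`n − min_contig`-ish units on each side (the demo calls 4–11 and 21–l/o
for planted 6–10 and 22–26); the top construct, not the interval edge,
is the best point estimate of the paratope.

## Problem sizes and numerical choices

The recovery and false-positive properties are tested at 200 seeds with
σ = 0.25 and 3 replicates — enough for rate estimates with Monte-Carlo
standard errors around 2 percentage points while keeping the suite quick.
Tukey p-values use the exact studentized-range distribution (the dominant
runtime cost of a replay). Entropy arithmetic is exact-rational for the
fractions and float for the logs, with a 1e-9 relative epsilon at the
admissibility threshold; sample standard deviations use ddof = 1 and are
defined as 0 for singleton samples.

## Known limitations

* The binding model is phenomenological; it cannot calibrate absolute
  affinities or competitor concentrations.
* Hotspots separated by fewer units than the window length minus
  `min_contig` can merge into one interval at `min_support = 1`.
* Verdicting of coarse rounds reuses the refinement significance rule;
  with `k = 2` segments both binding, no pair separates and the round
  returns no positives — supply explicit calls in that regime.
* The Tukey fence assumes the round has mostly well-behaved replicate
  variances; with ≤ 3 constructs no outlier screening occurs.
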