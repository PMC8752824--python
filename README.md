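# lrrmap

Entropy-informed segmentation design and binding-hotspot mapping for
modular repeat proteins.

Many plant immune receptors are leucine-rich-repeat (LRR) proteins whose
stacked 20–30 aa repeats form an extended ligand-binding surface. They are
notoriously hard to express heterologously, so their paratopes are often
mapped with cell-free ribosome-display (RD) panning of receptor
*sub-segments*: contiguous runs of repeats flanked by the native N- and
C-terminal caps, assayed against immobilized target with and without excess
soluble competitor. `lrrmap` is the desk-side toolkit for that workflow: it
designs maximally informative sub-segmentation experiments, plans
branch-and-bound refinement rounds, simulates the qPCR readout against a
planted ground-truth paratope, and analyzes competed/uncompeted Cq data to
call hotspot intervals. It is aimed at protein engineers planning tiling
libraries and at anyone analyzing ΔCq panning data.

## The design statistic

Tiling a region of `L` units with all `L − n + 1` windows of length `n`
includes unit `i` in a fraction

    P_i = min(i, n, L − i + 1, L − n + 1) / (L − n + 1)

of the tested constructs, and the information content of the experiment is
scored as

    entropy(L, n) = −Σ_{i=1..L} P_i · log₂ P_i   [bits]

(the `P_i` are inclusion fractions, not a normalized distribution). Lengths
within a tolerance (default 90%) of the maximal entropy are *admissible*;
taking the largest admissible `n` trades a sliver of information for
larger, better-folding constructs. For an 11-unit region the maximum is at
`n = 3` with admissible lengths {2, 3, 4, 5}; for a 12-unit region the
maximum is at `n = 4` with admissible lengths {3, 4, 5}.

Downstream, competed-minus-uncompeted quantification cycles
(ΔCq = Cq_competed − Cq_uncompeted; positive for specific, competable
binding) are batch-normalized, screened for outlying replicate variance
(Tukey fence), and compared across constructs with one-way ANOVA plus
Tukey HSD. Units covered by significantly binding constructs accumulate
support; maximal contiguous support runs are the called hotspots.

## Worked example

The packaged demo models a 31-repeat receptor (LeEIX2-like: terminal caps
plus a loopout pseudo-unit between repeats 27 and 28) with planted
paratopes at repeats 6–10 and 22–26:

```
$ lrrmap run-demo --out-dir demo_run
rounds: initial, initial/refine-1-11, initial/refine-21-31
hotspot 4-11 (top construct LRR6-10)
hotspot 21-l/o (top construct LRR22-26)
2 hotspot interval(s); artifacts in demo_run
```

The pipeline partitions the 31 repeats into three 13-repeat segments
sharing 4 repeats per junction (1–13, 10–22, 19–31), simulates the panning
round, calls segments 1 and 3 positive, prunes the trusted core of the
negative middle segment to leave candidate regions 1–11 (11 units) and
21–31 (12 units including the loopout), tiles each with 5-unit windows
(7 and 8 constructs), and analyzes the simulated qPCR table. Both planted
paratopes are recovered: each called interval contains its true 5-repeat
paratope, padded by the partially overlapping windows that also reach
significance, and the top construct per interval is the full-overlap
window. In `demo_run/results.json` a non-binder such as `LRR1-5` shows a
ΔCq mean near 0 while binders sit near `log₂(1.05/0.10) ≈ 3.39` cycles;
the single-factor ANOVA across the 15 refinement constructs gives
F ≈ 39.5, p ≈ 2e-15.

Individual steps are also exposed (`design-entropy`, `plan`,
`generate-constructs`, `simulate`, `analyze-qpcr`, `infer-hotspots`); see
`lrrmap --help`.

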