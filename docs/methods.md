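# Methods

Algorithmic contracts and design rationale, module by module. Coordinates
are 1-based inclusive throughout; all randomness flows through explicit
integer seeds (NumPy `default_rng`).

## Sequence handling (`seqio`)

Families are analysed on the residue numbering of a designated reference
sequence. `set_reference` maps each alignment column to the reference
position (gap-in-reference columns are marked), and `degap_to_reference`
deletes insertion columns so the aligned length equals the reference's
ungapped length. Residue content of retained columns is never altered.

Diverse-subset selection is greedy maximin (farthest-point) on pairwise
identity distance (1 − fractional identity over mutually non-gap, non-X
positions; pairs with no comparable position get distance 1). Selection
starts from the most distant pair (or a supplied seed id), then repeatedly
adds the record whose minimum distance to the chosen set is maximal. Ties
break on the lexicographically smallest identifier, which makes the result
invariant to input order. Greedy maximin carries the standard
2-approximation guarantee relative to the optimal subset; the test suite
verifies this bound against exhaustive enumeration on 8-sequence fixtures.

## Topology (`topology`)

**Profile.** Per-position consensus hydropathy is the mean Kyte–Doolittle
value over non-gap, non-X residues of each column, smoothed with a centred
moving average (default window 19) whose window shrinks symmetrically at
the termini. Positions with <50% coverage are flagged, not dropped.

**Segmentation (`segment_tmds`).** Maximal runs with smoothed hydropathy ≥
threshold (default 1.5) become helices. Runs shorter than `min_tm` (15) are
discarded; runs longer than `max_tm` (28) are split recursively at the
interior smoothed-hydropathy minimum, excluding `min_tm`-sized margins at
both ends (leftmost position on ties). Every emitted segment therefore has
length in `[min_tm, max_tm]`. An optional `merge_gap` fuses runs separated
by sub-threshold dips of at most that many positions before splitting:
brief dips occur inside genuine helices, and a fused over-long run is
recovered by the splitting rule while a fragmented one is lost.

**Boundary refinement (`refine_boundaries`).** Threshold crossing of a
smoothed profile biases edges toward the helix interior next to strongly
hydrophilic loops and toward the loop after a run split. Each edge is
re-placed by a direction-constrained two-level change-point fit (minimum
summed squared error around the two segment means) on the *unsmoothed*
consensus profile, searched within half a smoothing window of the crude
edge: start edges must step up, end edges must step down, and searches are
clamped by the neighbouring helices' current edges. Passes over start and
end edges alternate until no edge moves (at most four rounds). Moves that
would push a helix outside `[min_tm, max_tm]` are reverted, and refined
helices never overlap: a degenerate overlap truncates the previous end, so
refinement is always one-to-one with its input.

**Pipeline (`predict_topology`).** Threshold runs are first collected down
to `run_min = max(5, min_tm − 10)` residues: a window-19 smoother turns an
18-residue helix into a triangular peak whose above-threshold run is
narrower than the helix, so genuine helices can surface as short runs.
After refinement, sub-`min_tm` segments are pruned one at a time — least
helix-like first, judged by mean raw hydropathy over the refined span —
and the remaining crude runs re-refined, because a spurious remnant clamps
its neighbours' search windows and genuine helices can refine short only
while it is present. Surviving segments are renumbered and oriented.

**Orientation (`orient`).** The positive-inside rule: count the
reference's K+R residues over all loops (termini included) under both
candidate orientations and place the richer loop set on the cytoplasmic
side; exact ties default to a cytoplasmic N-terminus. A C-terminal
dilysine signal (KKxx or KxKxx) overrides the tally and forces the
C-terminus cytoplasmic, since an ER-retrieval signal must face the cytosol.

## Conservation (`conservation`)

Information content per position, `ic = log2(20) − H(freq)` in bits, with
gaps and X excluded from the denominator — the convention of standard
sequence logos computed on a reference-degapped alignment. No small-sample
correction by default at family sizes of 25–30 (available behind a flag).
Conserved-position calls use either an ic cutoff or a class-frequency
cutoff (default 0.8) with D/E, K/R and N/Q merged, because acidic and
basic pairs are functionally interchangeable in the catalytic motifs.
Logo letter heights are `freq × ic`, so each column's stack height equals
its information content.

## Motifs (`motifs`)

A PROSITE-like grammar: residue classes `[DE]`, wildcard `x`, bounded
repeats `x{4,14}`, optional elements `?`, C-terminal anchor `$`, and
top-level alternatives `|`. Scanning enumerates every admissible (start,
width) pair, so it is exactly equivalent to brute-force enumeration (the
test suite checks this against an independent regex oracle). Hits are
assigned to loops by their start position; hits overlapping any helix are
labelled `TMD-embedded`. Luminal loops are numbered EL1… from the
N-terminus, cytoplasmic loops CL1…, matching the field convention.

The shipped library covers the shared GT-C catalytic motifs (an EL1
acidic pair `[DE]x?[DE]`, EL2 arginine-anchored motifs, a conserved EL3
basic position realized as a conserved-position call rather than a string
pattern, the `Rx{4,14}P` motif of the C-terminal cluster, and the dilysine
signal) plus a registry of expected helix counts and organizations per
family.

## Family model (`model`)

**Organization string.** Helices are partitioned at inter-helix luminal
loops of at least 40 residues (large loops are 40+; short inter-helix
loops are <15, so the landmark is unambiguous); termini are not partition
points. This yields `1-8-4` for the 13-helix architecture, `1-6-4` for 11,
and `1-6-5` / `1-6-7` for the 12/14-helix variants with extra C-terminal
helices. Parts always sum to the helix count.

**Asymmetry test.** Statistic: pooled mean information content over
luminal-loop positions minus the same over cytoplasmic-loop positions
(helix positions excluded, termini included). The null redistributes the
observed side labels over loops uniformly at random — whole loops, not
positions, because within-loop conservation is autocorrelated — and the
one-sided p-value carries the +1 correction. The test conditions on the
observed loop-size layout: it asks whether conservation is higher on the
luminal side *given* where the loops are and how large they are. Under
families whose loop sizes themselves differ systematically by side, the
label-permutation null is not exact; the calibration check therefore uses
fully exchangeable null families (no planted motifs, no positive-inside
bias, side-balanced K/R frequency, side-balanced loop-size ranges, no
dilysine), where the empirical type-I rate at α = 0.05 falls inside the
exact binomial 95% interval over 500 replicates.

**Report.** `build_report` cross-checks observed vs expected helix count,
motif membrane sides (a dilysine hit must be cytoplasmic), and expected
motifs that were not found; it embeds the full configuration for re-run
reproducibility.

## Mass spectrometry (`massspec`)

Tryptic digestion cleaves after K/R except before P; peptides at 0 missed
cleavages tile the parent exactly. Monoisotopic masses: residue masses +
water (18.010565) + fixed modifications + hexoses (162.052824 each,
attached to Trp, mass-only). Cys carbamidomethylation (+57.021464) is a
fixed modification by default — the standard state of Cys in in-gel
digests, and required to reproduce the reference ion values — and can be
disabled. `m/z = (M + z × 1.007276)/z`. The matching tolerance for printed
reference ions is ±0.02, covering the difference between observed
centroids and theoretical monoisotopic values.

## Synthetic families (`synth`)

The generator reproduces the statistical structure the pipeline relies on,
with exact ground truth:

* helices of 18–25 residues drawn from a hydrophobic alphabet
  (I/L/V/F/A/M, mean Kyte–Doolittle ≈ 3.5);
* loop backgrounds that are polar-enriched rather than uniform: hydrophobic
  residues are strongly downweighted and no two consecutive hydrophobic
  residues are emitted within a loop. Loops of real polytopic membrane
  proteins are polar-enriched, and a chance hydrophobic cluster abutting a
  helix makes that boundary unrecoverable from hydropathy for any method —
  uniform loop composition would make boundary identifiability a property
  of the noise draw rather than of the algorithm;
* polar helix-capping belts (4-residue flank regions) at both ends of
  every loop, emulating the charged/polar belts of real membrane proteins;
* cytoplasmic loops boosted in K/R (positive-inside bias), luminal loops
  set to a target total K+R frequency (default 0.03);
* near-invariant planted motif instances and large conserved areas in the
  luminal loops (the catalytic motifs and conserved domains), substituted
  at a much lower rate (default 0.02) than the background (default 0.3);
  substitutions are drawn from region-appropriate distributions so noise
  does not destroy segmentability;
* an optional C-terminal dilysine signal for the 12/14-helix variants.

Families are gapless by construction (ground-truth coordinates are
trivial; degapping is exercised by hand-written fixtures), and the first
record is the unmutated template, serving as the reference. The
DPAGT1-like control (`control_family`) flips every planted motif to the
opposite membrane side; flipping twice is an exact involution.
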