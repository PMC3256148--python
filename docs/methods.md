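# Methods

## Model and scope

The package treats a classical plant-genomics problem: a draft assembly
exists only as scaffolds, and a selfed RIL population genotyped at
PCR markers (SSR/InDel/SV length polymorphisms, scored A/B/H/missing)
is used to (i) build a bin-based genetic map, (ii) anchor and orient
the scaffolds into pseudochromosomes, (iii) estimate the cM/Mb
landscape, and (iv) flag segregation distortion. All coordinates are
0-based, half-open; calls are encoded A=0, B=1, H=2, missing=−1 with A
the assembly parent.

## Inbred-line two-point statistics

For markers scored in `n` common individuals as opposite homozygotes,
with `k` discordant, the observed discordance is `R = k/n`. Among fully
inbred selfed lines `R` relates to the meiotic recombination fraction by
the Haldane–Waddington fixed point `R = 2r/(1+2r)`, inverted as
`r = R/(2−2R)` (clamped to [0, 0.5]). Linkage support is the binomial
log-likelihood ratio against independence,
`LOD = k·log10(2R) + (n−k)·log10(2(1−R))` with `0·log10 0 := 0`, which
equals `n·log10 2` at complete cosegregation. Heterozygous and missing
calls are excluded pairwise; residual F8 heterozygosity is (1/2)^7 ≈
0.78% per locus, so the fully-inbred approximation is adequate and the
default policy converts H to missing before mapping.

A small caveat quantified by the exact selfing chain in
`melonmap.theory`: at generation 8 the discordance is slightly below
its fixation limit (e.g. 0.1626 vs 0.1667 at r = 0.1), so the estimator
carries a ~2–3% downward bias relative to the infinite-generation
formula. This is visible as a mild map-length shortfall and is left
uncorrected, matching standard practice of treating RILs as fixed.

## Map construction pipeline

1. **Grouping.** Single-linkage transitive closure over pairs with
   LOD ≥ 10 and r̂ ≤ 0.45 (the r-guard blocks chance long-range joins).
   Groups below `min_group_size` (default 2) go to a residual pool.
2. **Singleton cleaning.** A singleton is an isolated call that differs
   from both immediate neighbours while those agree — an apparent
   double crossover in a tiny interval, almost always a scoring error.
   Cleaning sets it to missing, never touches terminal markers, and
   runs as a single pass (flags computed before application, no
   cascade). It runs twice per group: first along bp order within each
   scaffold, then along the provisional map order.
3. **Bins.** Markers with zero pairwise discordance merge into bin
   signatures; the consensus takes the non-missing call wherever any
   member has one, and a conflict (opposite homozygotes) always blocks
   the merge. Merging is greedy in the deterministic (scaffold, bp, id)
   order, so the result is invariant to input row order.
4. **Ordering.** Bins are ordered to minimise the sum of adjacent r̂
   (open-path TSP). Up to 9 bins the search is exhaustive and therefore
   exactly optimal; above that, nearest-neighbour seeding from every
   start plus full 2-opt. The path direction is canonicalised (end
   holding the smallest marker id first). Exact search for small
   instances was preferred over running the heuristic everywhere
   because small groups are cheap to solve optimally and the heuristic
   has no optimality guarantee.
5. **Distances.** Haldane map function `d = −50·ln(1−2r̂)` cM,
   accumulated from 0. Haldane matches the simulator's no-interference
   crossover model, so map-length recovery is unbiased in expectation
   up to the F8 effect above. Adjacent r̂ = 0.5 raises an error.
6. **Residual placement.** Unplaced markers attach to the bin with the
   highest LOD ≥ 4 (ties toward smaller r̂; unresolved ties stay
   unplaced).

## Anchoring and landscape

Scaffolds take the LG holding the majority of their mapped markers
(exact ties are conflicts and stay unanchored; two LGs with ≥2 markers
each flag a chimera), are ordered by median marker cM, and oriented by
the sign of the Kendall concordance between within-scaffold bp and map
cM — one marker, one bin, or an exact tie leaves the scaffold
unoriented, mirroring the fact that orientation in low-recombination
regions is genuinely undetermined by a map of this resolution.
Pseudochromosomes are emitted as AGP 2.1 with a fixed 100 bp N-gap
between components (configurable; the gap length is a bookkeeping
convention, not an estimate), orientation `?` preserved for unoriented
components. Genetic positions are interpolated linearly between marker
anchors and clamped beyond the terminal markers (unanchored tails thus
read rate 0); per-1-Mb windows classify as suppressed below 1.0 cM/Mb
and hot at or above it (suppression is defined strictly "less than"),
with a short terminal window normalised by its true length.

## Simulator

Chromosomes are tiled by Dirichlet-partitioned scaffolds with random
true orientation and presented shuffled. Markers sit on a jittered grid
(emulating deliberately even marker spacing along scaffolds). Meioses
draw Poisson(L Morgans) crossovers uniform on the genetic scale, mapped
to bp through an optional monotone recombination profile; the default
watermelon-scale profile puts 10% of the genetic length in the middle
40% of the chromosome (pericentromeric suppression, end rates ≈3.4×
average). Genotyping flips homozygous calls with probability ε
(heterozygotes flip to a random homozygote) and masks calls with
probability m.

Viability selection at a distortion locus weights the disfavoured
homozygote by 1−s each generation. Selection acts at the population
level: a non-viable offspring is replaced by an offspring of a
uniformly random line from the parent generation, so population
genotype frequencies follow the selfing transition reweighted by
viability — exactly the Markov chain in `melonmap.theory`, which the
simulation tests use as oracle. The alternative (strictly per-line
redraws) silently cancels selection once a line is fixed and produces
much weaker skew (allele frequency ≈0.59 instead of ≈0.88 at s = 0.3
by F8); the population-level mechanism is the one that actually
produces segregation-distortion regions of the strength observed in
wide crosses.

Study-scale defaults follow the reference map: 11 chromosomes with the
published per-LG marker counts, scaffold counts and genetic lengths,
physical sizes rescaled to a 353 Mb genome; n = 103 F8 lines;
genotyping error 0.005 and missingness 0.05 for end-to-end checks.
What the simulator does **not** model: sequencing reads and assembly
errors, gel band-size confusions (errors are symmetric flips), crossover
interference, and real marker-density heterogeneity; passing tests
demonstrate algorithmic correctness under the stated genetic model, not
robustness to assembly artefacts.

## Numerical and policy choices

* SSR units restricted to primitive 2–6 bp motifs (homopolymers
  excluded); tracts may end in a partial unit; overlapping tracts
  resolve to the longer (ties: smaller unit). InDel bounds 5–10 bp and
  SV bounds 120–1400 bp are inclusive.
* Locus uniqueness is an exact-occurrence count over both strands
  (deterministic, conservative); the false-priming screen checks every
  13–15 bp primer substring rather than sampling windows.
* Chi-square tests use no continuity correction by default (a Yates
  option exists) and no multiple-testing correction, matching the raw
  P < 0.05 convention for segregation screens; SDR runs are strictly
  adjacent by default with an optional gap tolerance.
* Scaffolds sharing a single bin have no recoverable internal order;
  they keep their deterministic tie-break order and stay unoriented.

## Known limitations

* **Strict-run SDR calling has a non-trivial null rate at high marker
  density.** With ~950 markers over ~800 cM and n = 103, adjacent
  markers are ~0.84 cM apart (R ≈ 0.017), so the skew statistics of
  neighbouring loci are correlated ≈0.97 and a single chance
  allele-frequency excursion can span ten or more adjacent loci.
  Simulated null genomes show ≈0.4 such runs per map — far more than an
  independence calculation (~(0.05)¹⁰ scale) would suggest. Detected
  SDRs should therefore be read together with their skew magnitude, not
  as family-wise-error-controlled calls. Detection power for a real
  selected locus (s = 0.3) is effectively 100%.
* Map lengths run ~4–8% short of truth: finite-generation bias (above)
  plus singleton cleaning, which cannot distinguish a genuine double
  crossover within two marker intervals from a scoring error and
  removes both.
* Orientation accuracy is only meaningful for scaffolds spanning ≥2
  distinct cM positions; below that the map carries no orientation
  information and the package says so (`?`) rather than guessing.
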