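# Methods

## Scope and data model

The package analyses a fixed six-line allopolyploid design: progenitors
`aar` (A subgenome donor) and `ath` (T subgenome donor), hybrid `f1`,
resynthesized allotetraploids `a733`/`a738`, natural allotetraploid `asu`.
Analysis *samples* are (line, subgenome) pairs — ten in total, since each
progenitor carries one subgenome. All statistics run on a single
`SiteMatrix`: the cytosines shared by every sample after replicate merging,
the ≥3-read coverage filter, and restriction to homology blocks ≥1 kb with
alignment score ≥1,000. T-subgenome positions are lifted onto A-subgenome
coordinates through the (gapless) homology blocks, so a matrix row is one
conserved cytosine with ten count pairs; cross-subgenome and
line-versus-progenitor comparisons then share one window universe, which is
what makes the set arithmetic of the trajectory classes well defined.

Coordinates: cytosine positions are 1-based (as in the input reports);
every interval — gene, block, window, DMR — is 0-based half-open. A
cytosine at `pos` is in `[s, e)` iff `s ≤ pos − 1 < e`. Strands are never
collapsed into CpG dyads; the conserved-cytosine logic operates per strand.

## DMR statistics

Windows are fixed genomic tiles `[k·step, k·step + window)` with
`window = step = 100 bp` by default; a step smaller than the window gives
overlapping tiles, but the default tiling avoids double counting in the
downstream set arithmetic, and window-level calls are never merged into
larger regions. Counts are pooled over a window's cytosines of one context
(weighted methylation), giving one 2×2 table per window and comparison.

* Fisher's exact test is two-sided: p sums hypergeometric point
  probabilities ≤ that of the observed table (relative tie tolerance
  1 + 1e-7, as in scipy/R). The implementation is vectorised over windows
  via a shared log-gamma lookup table; it is verified in the tests against
  `scipy.stats.fisher_exact` and an exact integer-arithmetic enumeration of
  every table with total ≤ 50. Tables with a zero margin return p = 1.
* Benjamini–Hochberg adjustment runs within each (comparison × context)
  family, through `statsmodels.stats.multitest.multipletests`.
* A window is a DMR iff q < 0.05 and |Δm| ≥ {0.5 CG, 0.3 CHG, 0.1 CHH},
  and only windows with ≥{4, 4, 16} cytosines of the context are tested.
  `hyper` means focal above reference; for A-vs-T comparisons the A sample
  is focal, for line-vs-progenitor comparisons the allotetraploid is focal.

`DMRCaller` and `TrajectoryClassifier` follow the scikit-learn estimator
protocol (`fit`, `get_params`, fitted attributes with trailing underscores)
so parameter scans compose with standard tooling; the module-level
functions are thin wrappers.

## Trajectory classes

"Decreased to a similar level" is operationalised as: in `asu` the window
is not a DMR **and** |Δ| is below the context cutoff. "Consistently
present in F1, Allo733 or Allo738" is computed both per line and as the
all-three intersection, and both are reported, since either reading is
defensible. Labels use the precedence both > convergent > conserved >
persistent_hyper > other; convergent and persistent_hyper are mutually
exclusive by construction (one requires, the other forbids, significance in
`asu`). A-vs-T hypo-DMRs are oriented as A below T. When the classifier is
run with an explicit `delta_cutoff`, the hyper flags are re-thresholded at
that cutoff so that scanning the cutoff is self-consistent (and empirically
monotone on well-separated data).

## Association

Gene–DMR links use half-open intersection of the DMR with the gene body
extended by the 2-kb flank; `flank=0` reduces exactly to body overlap.
Expression ratios are log₂ of replicate-mean TPM with a +1 pseudocount
(zeros occur; no published rule, so the guard is explicit and
configurable). Group comparisons use Mann–Whitney U — exact enumeration
when the pooled sample is ≤20 and tie-free, otherwise the tie-corrected
normal approximation. Per-gene methylation–expression correlation defaults
to Pearson on the five line-level values (Spearman optional); genes with
fewer than three complete pairs or zero variance are flagged undefined
rather than forced to a number. The homolog-pair methylation threshold
reuses the CG effect cutoff 0.5. "Upregulated" defaults to a positive
focal/parent log₂ ratio with a two-sided two-sample test on log-TPM across
replicates at p < 0.05 (a two-group ANOVA is the same test); both threshold
and test are arguments, since no exact definition is published.

## LTR clock

K = −¾·ln(1 − 4d/3) requires d < 0.75 (saturation is an error, not a
clamp); t = K/2r with r = 7×10⁻⁹ per site per generation, one generation
per year. Divergence d may be supplied directly or computed from two
aligned LTR sequences as the mismatch fraction over non-gap columns.

## Synthetic cohort: what it emulates, and what it does not

The generator writes the exact formats the readers consume. Its stated
world: one chromosome per subgenome, colinear, with identical cytosine
positions — every cytosine is conserved and lifts trivially. Per 100-bp
tile it places 6 CG, 5 CHG and 17 CHH cytosines (uniform offsets, random
strand). Null windows draw one methylation level per context from Beta
distributions (CG(0.6, 1.8), CHG(0.5, 4.5), CHH(0.8, 15)) shared by all
samples; planted windows (default CG) follow the class profiles with low
level 0.15 and effect 0.6 — comfortably above the 0.5 CG call cutoff, as
in the well-separated bimodal CG methylation typical of plant genomes.

Key numerical choices:

* **Site noise** `clip(μ + N(0, 0.05))` is frozen per cytosine across
  replicates, samples and the two homologous chromosomes. It models a
  sequence-context effect; sharing it across samples is what makes the
  zero-effect cohort an *exact* null for the FDR-control check. Real
  between-sample biological variation is therefore *not* emulated, and the
  FDR test establishes control under exchangeable samples only.
* **Coverage** is negative-binomial per cytosine and replicate (mean 20,
  dispersion 5; Poisson as dispersion → ∞), emulating overdispersed WGBS
  depth; counts are binomial given depth.
* **Placement**: planted windows sit on a sparse lattice (≥45 tiles =
  4.5 kb apart) so one gene plus its 2-kb flanks can never reach two
  planted windows; real DMR density is of the same order (~1 per 9 kb).
  Planting beyond capacity is an error.
* **"Both" windows** are only realisable when the parental difference
  saturates at 1.0 (a window cannot be A-over-T by ≥0.5 in F1 *and* below
  the progenitor by ≥0.5 unless the parents differ by ≥1.0), so none are
  planted by default; the published convergent∩conserved overlap is a
  gene-level, not window-level, statement. A sixth class `hyper`
  (methylation gained in `asu` versus the progenitor) supplies
  hyper-DMR-linked genes for the expression checks.
* **Expression**: one homolog-paired gene sits on each planted window
  (body = the window, so gene-level methylation equals window methylation);
  baselines are log-normal (mean 4, sd 1.5 log₂ units; homolog partners
  correlated, sd 0.5), replicate noise sd 0.25 log₂. Methylation represses:
  each line's copy is shifted by −1·(μ − 0.15)/0.6 log₂ units (clipped to
  [−1, 0]), so a line that lost its progenitor's methylation sits +1 log₂
  above it. Genes off planted windows are symmetric around ratio 0.
* **Determinism**: a master `SeedSequence` spawns child streams for
  placement, counts and expression, so stages regenerate independently and
  byte-identically.

A green synthetic test therefore establishes: correct arithmetic and
thresholds, FDR control under exchangeability, and recovery of planted
effects at realistic depth. It does not establish robustness to
between-sample biological variance, mappability artefacts, context
mis-annotation, or non-colinear homology — none of which the generator
emulates.

## Degenerate inputs

Windows with zero pooled coverage in either sample are excluded and
flagged, not scored. Empty site intersections raise with per-line
diagnostics; an empty conserved-region result warns. Fractions with zero
denominators are NaN/flagged. Percentages are rounded half-even to one
decimal, matching how the source counts are printed.

## Known limitations

Adjacent significant windows are not merged into larger DMRs (counts are
window-level). The liftover supports gapless, same-orientation blocks only
— sufficient for the colinear synthetic world, not for real rearranged
genomes. Whether the ≥3-read rule applies per replicate or post-merge is
not documented upstream; it is applied post-merge, per line. GO enrichment,
clustering/heatmap rendering and everything upstream of the cytosine
reports (alignment, methylation extraction, repeat annotation) are out of
scope.
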