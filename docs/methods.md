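# Methods

`picoevo` implements a comparative-genomics pipeline for marine
picocyanobacteria (*Prochlorococcus*, *Synechococcus*, *Cyanobium*): given a
phyletic pattern (strains × gene-family copy counts over CLOGs — clusters of
likely orthologous genes), a rooted core-protein tree, per-strain genome
annotations and single-copy core-protein alignments, it quantifies how gene
content and protein sequences have diverged across the radiation, on an
absolute time scale when a chronogram is available.

## Pan-genome structure (`pangenome`)

A CLOG is **core** in a taxonomic group when present in ≥ 90% of the group's
strains (`core_fraction=0.9`; groups under `min_group_size=3` genomes are
skipped), **unique** when present in exactly one strain overall, and
**accessory** otherwise. A strict mode (`core_fraction=1.0`) implements the
all-strains reading; both are exposed because the two definitions give
different core counts on real data and the right choice depends on how
tolerant the analysis should be of assembly/annotation dropouts.

Rarefaction integrates genomes in uniformly random orders (default 1,000
permutations; an `exhaustive` mode enumerates all N! orders for small N) and
reports median/quartiles of pan and core sizes at each depth. The asymptotic
core size is the `omega` of the exponential-decay fit

    core(n) = kappa · exp(−n/tau) + omega,

by nonlinear least squares on the median core curve with starting values
(first − last, N/3, last). A flat curve short-circuits to `kappa = 0`. The
fitted `omega` is only meaningful when no accessory family sits near the
core-definition boundary (a family at ~90% prevalence drifts in and out of
the core along the curve and inflates the apparent asymptote).

## Gene gain/loss reconstruction (`gainloss`)

Each family evolves independently as a two-state CTMC on the fixed rooted
tree: gain rate `alpha` (absent → present) and loss rate `beta` per unit
branch length, transition probabilities in closed form. Among-family rate
variation uses a K-category discrete gamma (default K = 4; category medians
renormalized to mean 1) applied as a multiplier shared by both rates — a
shared multiplier keeps the gain/loss balance identifiable while letting
fast families be fast in both directions.

Copy numbers are binarized: every downstream analysis here consumes
presence/absence, and duplication dynamics are out of scope.

**Ascertainment.** Families absent from every genome cannot be observed, so
the likelihood is conditioned on presence in ≥ 1 tip. Without this
correction the gain-rate MLE is biased downward (absent-everywhere patterns
would be "explained" by a low gain rate).

**Root prior** defaults to the model's stationary distribution; a fixed
prior is available for sensitivity analyses.

Fitting maximizes the summed per-family log-likelihood (Felsenstein
pruning, vectorized over families, per-family rescaling for numerical
range) over (log alpha, log beta[, log shape]) with Nelder–Mead.
Marginal ancestral presence posteriors come from the standard up–down pass.
States are binarized only where max(p, 1−p) ≥ `cutoff` (default 0.9);
otherwise the node is *ambiguous* for that family. A branch event is a gain
(parent absent ∧ child present) or loss (reverse), with tips at their
observed states; branches touching an ambiguous state contribute no event.
This makes the default event counts deliberately conservative: deep events
whose placement the data cannot pin down are left uncounted rather than
resolved by parsimony. For recovery assessments against simulation truth we
therefore use `cutoff=0.5` (the best state call per node); at 0.9 the
correlation between inferred and true per-branch gains drops not because
placements are wrong but because deep placements are abstained from.

**Fixed genes.** A family is fixed at an internal node when present in every
descendant leaf and absent from every other strain (at the root the second
condition is vacuous). Terminal branches are excluded: a strain-private
family cannot be called fixed.

## Time calibration and rates (`chronology`)

The recommended input is a chronogram (branch durations in My). When only a
substitutions/site tree exists, a simplified relative-time scaler is
provided: relative node depth = mean node-to-descendant-leaf path length,
parent ≥ child enforced by upward max-propagation, then one positive scale
factor chosen by least squares against calibration midpoints and clipped
into the intersection of the per-calibration feasible intervals (midpoint
least squares as fallback when intervals conflict). This is deliberately
*not* a relative-rate dating framework; it is exact for clock-like trees
and adequate for rate regressions, which only need branch durations.
Reference calibrations for this group place the *Cyanobium*/marine
*Synechococcus* ancestor at 582–878 My and the SC 5.1 radiation at
252–486 My.

Per-branch substitution counts are branch length × total alignment residues
(kept real-valued). Rates are through-origin OLS slopes of per-branch counts
on branch durations, separately for internal and terminal branches; no
intercept because a zero-duration branch must carry zero expected events.
R² is computed about zero, as appropriate without an intercept. Fixation
rates pair each internal branch with the count fixed at its child node.

*Known limitation:* event counts are Poisson-like (variance ∝ duration),
so homoscedastic OLS standard errors undercover — simulation puts 95% CI
coverage near 70–80% on skewed branch-length distributions, and
heteroscedasticity-robust SEs do not fully repair it at these sample sizes.
Slopes themselves are unbiased (verified by simulation); treat the reported
SE/p as descriptive.

## Genomic islands and the sharing network (`islands`)

Windows of 10,000 bp slide at 100 bp steps along each genome (wrapping on
circular genomes); a window qualifies when nucleotides of *gained* CDS,
clipped to the window, exceed 50% of all coding nucleotides in the window
(zero-coding windows never qualify). Maximal runs of consecutive qualifying
windows are merged, the genes overlapping each region are trimmed inward so
the island starts and ends with full-length gained genes, and islands with
< 2 genes are dropped. Because a qualifying run extends up to a window
length beyond the enriched locus, trimming additionally applies the same
> 50% rule locally at region boundaries: a boundary block of gained genes is
removed when the non-gained gap separating it from the island core carries
at least as many coding nucleotides as the block. Without this, a scattered
gained singleton in the flank drags interleaving ancestral genes into the
island.

Islands from different strains are linked when the Jaccard similarity of
their CLOG sets is ≥ 0.1 (sharing ≥ 10% of pooled gene content); edges carry
the similarity and the patristic distance between strains on the core tree.
Modules are Louvain communities (edge weights = similarity) with the
resolution parameter multiplying the null-model term — higher resolution,
more and smaller modules — at the default resolution 0.2.

## Tree-space comparison (`treespace`)

The gene-content tree is neighbor joining on the Jaccard distance between
family presence sets (default over all families; a `non_core` scope drops
universally present families, which compress all distances equally without
reordering them). Bootstrap supports resample pattern columns. Topology
comparison reports Robinson–Foulds distance and per-clade monophyly.

For each clade-base node, *external* length is the mean node-to-descendant-
leaf path and *internal* length is the parent edge; the paired comparison of
external/internal ratios between the two trees uses the Wilcoxon
signed-rank test (the standard paired rank test; exact null for ≤ 25 pairs,
normal approximation with continuity correction above). A larger ratio in
the gene-content tree than in the core tree means gene content keeps
churning within clades after core sequences have settled.

## Clade-specific variants (`variants`)

A column is *specific* to a strain set when all set strains share one
residue and no other strain carries it. Columns containing a gap are
excluded by default (`exclude_column`); the `gap_as_state` policy lets a gap
satisfy "any other amino acid" outside the set but never be the set residue.
Node-fixed variants apply the definition with the leaf set below each
non-root internal node. Per-protein counts are normalized by alignment
length (gap columns included — the normalization is per comparable column,
and the single-copy core alignments used here are gap-poor), proteins are
ranked per set by density (rank 1 = densest, average ranks on ties), and a
protein is a candidate for the focal set when its focal rank is < 0.33 ×
the median rank over background sets (single-strain sets excluded: their
"specific" variants are ordinary private substitutions).

## Sequence statistics (`seqstats`)

ANI follows the fragment-based protocol: 1,020-bp consecutive fragments of
the query (tail dropped), each locally aligned to the subject on both
strands; hits with identity > 30% over ≥ 70% of the fragment are retained;
ANI = mean retained identity, conserved DNA = fraction of the query covered
by hits above 90% identity; both directions computed, mean reported (the
max-symmetrization convention applies to AAI only). The aligner is
injectable; the default is a local pairwise aligner at match +1, mismatch
−1, gap open −5, extend −2 (BLOSUM62, −11/−1 for proteins). No claim of
BLAST-identical scores is made — only method-faithful behavior on
controlled inputs. GC3 counts G+C at third codon positions, ambiguous bases
excluded from numerator and denominator.

## Synthetic data (`simulate`)

The generator states a desk-scale world mirroring the statistical structure
of a picocyanobacterial radiation; all defaults are fixed once:

- **Tree**: 16 strains in 4 clades, coalescences within clades at 5–40% of
  the root age, among clades at 50–100%, root at 1,000 My (bracketing the
  582–878 My reference calibration for the deepest within-dataset split).
  Companion substitutions tree: duration × 2.5 × 10⁻⁴ subs/site/My (≈ 0.25
  root-to-tip, typical of core-protein divergence across the radiation) × a
  lognormal per-branch multiplier (σ = 0.3, mean 1; σ = 0 gives a strict
  clock).
- **Gene content**: 1,000 root families; per-family loss rate 10⁻³/My
  (root-family survival ≈ 0.37 per lineage over the tree height); gains
  appear as *fresh* families at 0.5/branch/My. Gains are irreversible per
  family, so each gained family is attributable to exactly one branch and
  per-branch truth is unambiguous. The emitted pattern contains only
  families present in ≥ 1 tip, matching the ascertainment the inference
  corrects for.
- **Genomes**: 900-bp CDS, 100-bp intergenic gaps (degenerate distributions
  by default so span arithmetic is exact). 90% of terminal-branch gains go
  into planted contiguous islands of 5–10 genes (at least 3 per strain,
  more as needed to absorb the quota), the rest are interleaved singletons —
  recently gained genes cluster in island loci; leaving most gains scattered
  would itself create chance >50%-enriched regions and contradict the
  stated world.
- **Alignments**: 20 families of ~250 aa evolving under a symmetric
  20-state replacement process on the substitutions tree; 5 columns per
  family per target set are overwritten with set-specific residues. Truth
  is the definition scan of the *final* alignments, so chance-arising
  specific columns are included in the truth rather than appearing as false
  positives.
- **CTMC pattern** (`simulate_ctmc_pattern`): a fixed family set evolving
  under exactly the reconstruction model, with per-branch endpoint-state
  event truth — the correctly-specified world for parameter/event recovery
  checks. By contrast the fresh-family generator is intentionally
  *misspecified* relative to the recurrent-gain CTMC (each family is
  gained once); fitted gain rates on that world are not interpretable as
  the generator's gain intensity.

What the generator does **not** emulate: nucleotide composition (GC skew),
recombination, rate heterogeneity among families beyond one multiplier,
horizontal sharing of the *same* gained family between strains (gains are
irreversible, so generator islands never overlap in content across strains
and island-network edges only arise on real or hand-built data), and indels
in core alignments (gap policies are exercised on hand-built fixtures). A
green test on generator output therefore establishes correctness of the
algorithms on a world with known truth — not faithfulness of any real
dataset to that world.

Determinism: one global seed; each stage draws from an independently
spawned substream, so emissions are bit-reproducible given (config, seed).

## Numerical choices

- Pruning uses per-family rescaling (log accumulators), exact to ≤ 1e-9
  against enumeration on small trees.
- Discrete-gamma categories use equal-mass category medians renormalized to
  mean exactly 1.
- Degenerate patterns (all families everywhere, or none anywhere) are
  rejected as rate-unidentifiable rather than fitted.
- NJ trees come from the Saitou–Nei Q-criterion (scikit-bio); additive
  matrices are reconstructed exactly (path error < 1e-9). A basal
  trifurcation is rooted deterministically on its first child for
  representation only.
- Louvain module ids are renumbered by smallest member for stability; the
  assignment is deterministic given the seed.
- Average ranks on density ties keep the rank-ratio screen invariant to
  protein order.
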