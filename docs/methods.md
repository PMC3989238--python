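# Methods

## The problem

Mitochondrial protein-coding genes are a standard marker for anthozoan
phylogeny, but the two data views they offer disagree: nucleotide
alignments support a monophyletic hard-coral clade, while amino-acid
alignments pull one sub-clade (the "Robust" corals) away from its sister
and nest the skeleton-less corallimorpharians inside the corals (the
"naked coral" arrangement). The Robust-coral genomes carry a distinctive
compositional signature — elevated A+T, strong T-enrichment and
C-depletion at all codon positions, constrained codon usage, and
proteomes enriched for the amino acids encoded by A+T-rich codons
(F, Y, M, I, N, K) at the expense of the G+C-rich set (G, A, R, P).
Under a stationary, homogeneous substitution model such a clade-local
composition shift is systematic error waiting to happen.

This package implements the full diagnostic battery for that situation:
composition and codon-usage statistics, alphabet reductions that hide
the shift from the model (RY coding; six- and four-class amino-acid
recoding; residue masking), composition-only distance trees (base-
frequency distances), composition-robust distances (LogDet/paralinear),
a likelihood engine over arbitrary alphabets with discrete-gamma rates,
fast-site exclusion, RELL-based KH/SH topology tests, the Goldman
parametric-bootstrap adequacy test, and a non-stationary simulator that
reproduces the compositional signature on a known tree so that every
claim can be tested against ground truth.

## Likelihood engine

Felsenstein pruning over pattern-compressed alignments, vectorised
across discrete-gamma categories. Models are reversible GTR-type
matrices (2, 4 or 6 states) or the empirical JTT matrix (20 states),
with optional +G (equal-probability categories represented by their
conditional means; 5 categories by default), +I (an extra rate-zero
mixture class; gamma rates are rescaled by 1/(1-p_inv) so the mixture
mean stays 1) and +F (alignment-wide empirical frequencies). The rate
matrix is normalised to mean rate 1, so branch lengths are expected
substitutions per site. Transition matrices come from the symmetrised
eigendecomposition; per-node rescaling guards against underflow and is
triggered lazily.

Branch lengths are optimised coordinate-wise with bounded Brent steps
(lnL never decreases; sweeps stop below a 1e-6 tolerance by default).
Substitution parameters (free GTR exchangeabilities, gamma shape,
invariant proportion) are fitted by Nelder-Mead on transformed
coordinates, alternating with branch-length sweeps. Tree search is
greedy NNI with re-optimisation, intended for the package's synthetic
datasets (up to ~30 taxa), not for production-scale genomics.

The engine is validated against exhaustive enumeration over all
internal-state assignments on 5-taxon trees for all five alphabets
(agreement to 1e-8), which is the package's ground truth for every
downstream likelihood quantity.

## Composition statistics

Per-taxon base frequencies are computed per codon position with gaps and
missing symbols excluded from denominators. Skews are (A-T)/(A+T) and
(G-C)/(G+C), NaN-flagged on empty denominators. FYMINK/GARP is the
ratio of summed A+T-rich to G+C-rich amino-acid proportions. Wright's
effective number of codons derives its synonymous family-size classes
from the bound genetic code (so the coelenterate mitochondrial code's
two-codon tryptophan family is handled correctly); a size class with no
estimable family borrows the mean of the nearest available classes, and
the result is clipped to [20, number of sense codons]. CAI uses
count-weighted geometric means over multi-codon families with
self-referential weights by default (w = count / family maximum, floored
at 0.01 for unobserved reference codons); an external reference-weight
table can override this, and because the reference set behind published
"default" CAI values is tool-specific, absolute CAI values are treated
as internally comparable only. Group summaries are means of per-taxon
statistics (a mean of ratios), matching the convention of reporting
averages across species.

## Distances

The base-frequencies (BF) distance is half the L1 distance between
frequency vectors — the printed form of the formula it implements lacks
absolute-value bars and would be identically zero, so the absolute-value
(total variation) reading is used. It is a metric; trees built from it
reflect composition alone and serve as a positive control for
compositional structure. LogDet/paralinear distances are computed from
pairwise joint-count matrices over shared non-missing sites; singular
joint matrices are flagged infinite and pairs with fewer than k shared
sites are flagged undefined, never silently imputed. Neighbor joining
(the standard minimum-evolution heuristic) builds trees, flooring
negative branch lengths at zero; OLS branch lengths on a fixed topology
are available via non-negative least squares. Quartet analyses sample
one taxon per group with replacement and score the three groupings by
the four-point condition (distances) or maximised likelihood (ML);
exact ties count as unresolved.

## Topology tests and model adequacy

KH and SH use RELL resampling of per-site log-likelihood vectors
(shared index draws across topologies, seeded, bit-reproducible).
KH is two-sided on the centred resampled lnL difference; SH centres
each topology's replicates and compares to the observed gap from the
best topology. Site-lnL matrices can be written and read in a
Consel-compatible plain-text layout so external AU testing remains
possible.

The Goldman test compares the fitted model's lnL to the unconstrained
multinomial lnL of the site-pattern frequencies. The observed gap is
calibrated by simulating n_sim = 200 datasets under the fitted model
and refitting each with the identical bounded schedule (branch lengths
and, by default, the gamma shape; topology fixed). The p-value uses the
add-one convention (1 + #{delta* >= delta_obs}) / (n_sim + 1), so it is
never zero. Because the identical fitting procedure is applied to the
observed data and every replicate, the Monte Carlo p-value is calibrated
even though each individual fit stops short of full convergence; the
calibration is itself verified empirically (100 seeded tests under the
true model; rejection rate at 5% inside the exact binomial interval).

## The synthetic generator

The generator evolves in-frame codons on a labelled tree whose unrooted
backbone is ((robust, complex), corallimorph, outgroup) — coral
monophyly is true by construction. Each codon draws one discrete-gamma
rate shared by its three positions; each position evolves under a
GTR-type process whose equilibrium depends on the branch's clade class
(branch-local equilibria in the spirit of non-stationary GC-content
models, not per-branch joint matrices). Codons that would become stops
under the bound code (table 4 by default) are resampled with bounded
retries, which slightly renormalises achievable composition — real
coding sequence faces the same constraint. All randomness flows through
one seeded generator; replicate seeds are derived by fixed offsets.

The `robust_like` preset encodes the study conditions:

- Background per-position equilibria give ~62% A+T.
- The robust-like clade's equilibria move probability from C to T and
  from G to A — the two strand faces of unrepaired cytosine
  deamination. Increments are chosen so the *observed* leaf composition
  at the preset depths shows the emulated signature (about +5% T at
  first and +4% T at second codon positions; overall A+T near 72%
  against the 62% background; FYMINK/GARP ≈ 2.6 versus ≈ 1.6): because
  composition relaxes toward a new equilibrium at roughly one unit per
  substitution, and the coding positions evolve slowly, the equilibrium
  increments must substantially exceed the observed shifts.
- Codon positions have strongly unequal rates (0.3 : 0.2 : 2.5),
  emulating purifying selection: the true backbone signal is carried
  mostly by silent third positions, which is exactly why the translated
  (amino-acid) view of the same data is information-poor about the
  backbone while retaining the full compositional artifact.
- The outgroup is A+T-enriched in the same within-class way, mirroring
  the real outgroups (octocorals are themselves A+T-rich relative to
  the complex corals); this shared derived composition is what a
  stationary model misreads as shared ancestry.
- The robust-like clade's branch rates are multiplied by 2 and it
  carries a deeper shared stem than the other coral clades. The deep
  clades are sampled as ladders — successive divergences subdividing
  their stems — which mirrors dense real-world taxon sampling and is
  what keeps distance- and recoding-based analyses out of the
  long-branch-attraction regime that would otherwise dominate every
  method (binary RY characters are the most fragile state space in that
  regime; see the design-history notes below).
- Among-site rate variation beyond the position-rate structure is mild
  (gamma shape 8). Strong extra rate variation makes LogDet-class
  distances non-additive and would confound the experiment's question —
  what does *composition* do to each method — with a second, separate
  violation.
- Exchangeabilities are equal (no transition bias). With a
  transition-biased matrix, the C-depleted shifted equilibrium sharply
  raises the transversion share of the normalised rate, so
  purine/pyrimidine-collapsed branch lengths inflate clade- and
  position-specifically — an induced heterotachy that misleads even a
  correctly specified two-state analysis and has nothing to do with the
  compositional question.

Preset design history, briefly: the generator's free parameters (depths,
rates, exchangeabilities) were explored systematically before freezing.
Three regimes had to be avoided: deep naked stems (every method,
especially two-state RY, collapses into long-branch attraction
regardless of composition), strong gamma rate variation (LogDet loses
additivity), and near-polytomy backbones (all methods degrade into
noise). The frozen preset sits in the window where the stationary
amino-acid analysis is measurably misled by the compositional
convergence while the recoded and composition-robust analyses of the
identical data are not, and where the stationary control is recovered
cleanly by all methods.

What the generator does not emulate: indels and alignment error,
selection (dN/dS) structure, within-clade compositional gradients,
tRNA-import-driven codon choice, heterotachy. Passing tests therefore
demonstrate the pipeline's behaviour under clade-local compositional
non-stationarity specifically, not under every failure mode of real
mitochondrial data.

## The recovery experiment

Each replicate simulates a dataset under the preset, derives the
nucleotide, RY-recoded, translated and reduced-alphabet views, and asks
each method which backbone it prefers: the generating arrangement
("monophyly"), the shifted clade displaced with corallimorphs joining
complex corals ("naked_coral"), or anything else. Distance methods build
an NJ tree and classify its splits; the LogDet method computes
distances per codon position and averages them, because the positions
evolve under visibly different processes and LogDet is consistent only
within a homogeneous site class — and it uses the slowly evolving
first and second positions only, since LogDet degrades badly on
saturated, rate-heterogeneous classes (the standard practice of pairing
LogDet with slow or filtered data). On those positions the
compositional shift is precisely the signal LogDet corrects and naive
distances misread. ML methods score the
two named candidate topologies with distance-initialised branch lengths,
a gamma shape fitted once and reused, and bounded likelihood refinement
of the backbone edges — every candidate and every method gets the
identical treatment, so the comparison isolates the data view
(amino acids vs RY vs LogDet), which is the question. Scoring two fixed
candidates rather than searching all of tree space mirrors how competing
published topologies are actually compared, and keeps 50-replicate runs
on one CPU affordable.

## Numerical choices and edge cases

- Coordinates: 0-based half-open internally, 1-based inclusive in all
  messages; joins by taxon label, never row order.
- '?' and 'X' are missing; missing counts as gap for column filters;
  codon-alignment filters operate on whole triples to preserve frame.
- Fast-site exclusion uses a strict `>` threshold (the boundary
  convention differs between published descriptions; only boundary
  sites are affected).
- Residue "exclusion" masks cells to '?' by default; a column-dropping
  variant exists for sensitivity analysis but removes most columns.
- Quartet and NNI ties break toward "unresolved" and "no move"
  respectively; stochastic steps take explicit seeds.
- Problem sizes in tests and the acceptance script (4-16 taxa, 50-4,000
  codons, 50 replicates, 200 bootstrap simulations) are chosen so the
  full battery runs on a single CPU in well under an hour while keeping
  every Monte Carlo check at interpretable resolution.

## Known limitations

- The likelihood engine targets correctness and small-problem speed;
  it does not implement analytic derivatives or SPR search.
- LogDet behaviour under strong among-site rate variation is a known
  theoretical gap (not specific to this implementation); the partitioned
  variant addresses process heterogeneity across codon positions only.
- CAI absolute values depend on the reference-weight convention.
- The Goldman test holds the topology fixed during refits.
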