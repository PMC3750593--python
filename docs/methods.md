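# Methods

This note documents the models implemented in `lowdense`, the defaults
and their rationale, the numerical choices made where the methodology
leaves room, and what the simulation-based tests do and do not show.

## Setting and assumptions

The package targets a two-tier genotyping design: a reference set of
progeny-tested sires genotyped at high density (HD) and phased, and
selection candidates genotyped with a low-density (LD) panel. Two
structural assumptions run through the imputation model:

1. the sire of every LD candidate is HD-genotyped and phased, and
2. dams are not genotyped; maternal information enters only through the
   phased haplotype library and the pedigree.

Genotypes are allele-1 dosages in {0, 1, 2} with allele 1 the minor
allele (matrices are recoded on load); positions are megabases.

## Marker QC

Markers are retained when they jointly pass: call rate ≥ 95%,
parent-progeny Mendelian conflict rate ≤ 2%, MAF ≥ 3% and HWE
p ≥ 1e-4. The HWE test is a chi-square goodness of fit with 1 df on
genotype counts — at a cutoff of 1e-4 the exact test changes nothing
material and the chi-square is fully vectorizable. The conflict rate is
opposite-homozygote pairs divided by genotyped parent-offspring pairs
with both calls present at the marker; with no genotyped pairs the
filter is skipped with a warning rather than silently passing
everything. Both normalizations are exposed as thresholds on the QC
entry points.

## LD-based position approximation

Markers without physical positions would otherwise be unusable for
imputation. Two markers belong to the same equivalence class when a
chain of markers connects them with |r| > 0.4 (genotype correlation,
pairwise-complete) between adjacent links and MAF > 0.15 for every
interior link. The low-MAF restriction exists because rare markers
correlate weakly and unreliably; the |r| threshold keeps classes from
spanning chromosomes.

The chain relation is not transitive where low-MAF markers sit at chain
ends, so the implementation makes the assignment single-valued: classes
are connected components of the |r| > 0.4 graph restricted to high-MAF
markers, and each low-MAF marker contributes exactly one edge, to its
strongest admissible neighbour (ties to the lowest marker index). This
reproduces the chain rule exactly for high-MAF markers and resolves the
ambiguity deterministically; the test suite checks both properties
against independent brute-force implementations.

A class maps to a chromosome when strictly more than 95% of its
known-position members agree; otherwise it stays unassigned (a mixed
class is evidence of a spurious edge, not of a real cross-chromosome
block). Each marker needing a position — unknown position, or a known
position contradicting the class call (a *remapped* marker) — receives
the known position of its best-|r| partner among originally-placed
markers on the class chromosome. Approximated and remapped positions
carry weight u = 0.8 in panel scores (remapped markers are "estimated"
too; a flag restores full weight for the alternative reading).
Absolute correlation is used throughout: under minor-allele coding the
sign of LD is arbitrary, and a perfectly negatively correlated partner
is exactly as informative as a positive one.

## Panel design

The distance between markers on the same chromosome blends physical
distance and LD below a window κ:

    d(m′, m″) = λ·|Δloc| + (1 − λ)·κ·(1 − 0.99·|r|),  λ = min(1, |Δloc|/κ)

with κ = 5 Mb, so co-located markers in weak LD still count as distant
and may both enter the panel; markers on different chromosomes are
infinitely distant. Scores default to MAF·u (read as a product: an
exponent u would *reward* uncertain positions); alternatives provided
are uniform scores, the additive-variance score 2·MAF(1 − MAF)·ā² and
an optional short-chromosome boost ((1 − λL)·L_m + λL·max L)/L_m.

Selection is greedy on Score × min-distance-to-panel. Candidates on a
chromosome without any selected marker have infinite min-distance and
outrank every finite objective; among them the best score wins. This
makes initialization emergent — the first picks are the top scorer of
each chromosome — without a separate seeding rule. All ties break
toward the lowest marker index, so the procedure is deterministic.
Min-distances are maintained incrementally; tests verify equality with
naive recomputation and with an exhaustive per-step argmax. The naive
equally-spaced design is the exact κ = 0 limit (d = |Δloc|) with
uniform scores and assembly-placed candidates only, which repeatedly
picks the centre of the largest gap.

## Imputation

Per candidate and chromosome:

1. **Origin tracing.** At each panel marker the sire haplotype that
   transmitted the paternal allele is identified where the offspring is
   homozygous and the sire heterozygous (`Which` ∈ {0, 1}); everything
   else is undetermined. An offspring homozygous for an allele the sire
   lacks is a Mendelian conflict: the marker's call is dropped
   (neutralized) and counted, rather than aborting the individual.
2. **Extension.** Equal flanking origins fill the gap; unequal origins
   put the crossover at the interval midpoint (a marker exactly at the
   midpoint takes the right-hand origin — a half-open convention chosen
   once for determinism). Beyond the outermost determined marker the
   nearest origin extends to the chromosome end. A chromosome with no
   determined marker falls back to the sire haplotype with fewest
   conflicts against the observed panel genotypes (tie: paternal).
3. **Maternal derivation.** At panel markers, maternal = dosage −
   paternal where that is a valid allele; infeasible differences are
   derivation conflicts (neutralized and counted).
4. **Library imputation.** For each panel marker m in position order,
   every library haplotype h is scored against the partial maternal
   haplotype i:

       Score_{i,m}(h) = (1 + a_{i,h}) · Σ_{k=0..4} c_{h,i}^m(k) · 0.75^k

   where c(k) is the number of other panel markers on the chromosome
   with exactly k conflicting markers between them and m (endpoints
   excluded; a `half-open` variant counting a conflict at the target
   marker itself is provided because the depth convention is a genuine
   free choice — both are implemented and oracle-tested). Conflicts are
   markers where i is known and h differs. The depth-damped sum makes
   the score robust to sporadic phasing errors; the (1 + a) factor
   favours relatives of the dam, who share long true haplotypes rather
   than chance matches. a is the tabular-method additive relationship
   between the candidate's dam and the haplotype carrier; library
   members absent from the pedigree get a = 0 and still compete through
   the +1 term.

   The winning haplotype (ties: larger a, lower carrier id, paternal
   haplotype first) is copied over the largest window around m bounded
   exclusively by its nearest conflicting panel markers (or chromosome
   ends), writing only still-missing positions — earlier fills are
   never overwritten, so the outcome does not depend on later, lower-
   confidence choices. Residual gaps are filled from the globally
   best-scoring haplotype and flagged as fallback.

Every allele carries provenance (observed / origin-traced / library /
fallback), written to VCF output as FORMAT/PV. The whole procedure is
deterministic: identical inputs give bit-identical output.

Scoring is vectorized: with x the conflict indicator over the P panel
markers of a chromosome and t its exclusive running sum, the conflict
depth between m < m~ is t[m~] − t[m] − x[m], giving all P² depths per
haplotype from one cumulative sum. Scores depend only on the fixed
partial haplotype i, so the score matrix is computed once per candidate
and chromosome.

## GBLUP with heterogeneous residual variances

DGV solve the mixed model y = 1μ + g + e with Var(g) = σ²_g·G and
Var(e) = σ²_e·diag(w_i), where y are deregressed EBV (dEBV = EBV/r²;
precomputed deregressed proofs pass through) and

    w_i = C + (1 − r²_i)/r²_i,  C = 0.25.

C is the fraction of additive variance not captured by the markers; the
weight grouping C + (1 − r²)/r² (not (C + 1 − r²)/r²) follows the
deregression-weight structure, and a flag offers the alternative. G is
VanRaden method 1, (M − 2p)(M − 2p)′ / 2Σp(1 − p), with frequencies
from the genotyped set unless supplied; a ridge of 1e-6 × mean(diag G)
guarantees invertibility with finite marker counts. The solver uses the
mixed-model equations, so individuals without records receive DGV
through G. The variance ratio σ²_e/σ²_g must be supplied (no silent
estimation); a one-dimensional profile-REML helper exists for
convenience. Tests verify the MME solution against an independent
closed-form GLS solve (V = ZGZ′ + ratio·D) to ~1e-12, the shrinkage
limit, permutation equivariance, and that substituting the pedigree
A-matrix reproduces pedigree BLUP.

## Accuracy estimation

The imputation error rate is the share of masked genotypes not restored
exactly on the 0/1/2 scale, with breakdowns by position class (assembly
vs approximated) and chromosome. The r² accuracy enters every marker
twice, as coded and with dosages reflected (g → 2 − g in both vectors),
making it exactly invariant to per-marker allele coding.

The naive DGV accuracy cor(DGV,EBV)/r_Val assumes EBV prediction errors
of training and validation animals are uncorrelated. In a joint
pedigree evaluation they are not, and the ratio is biased upward —
increasingly so for low-reliability traits. The regression correction
fits, across traits,

    cor(DGV,EBV)_t = a0 + a1·r_t^Val + a2·r_t^Train + e_t

by OLS and evaluates it at r^Val = 1, where EBV coincide with TBV and
the error contribution vanishes: per trait,
ĉor(DGV,TBV)_t = cor(DGV,EBV)_t − â1(r_t^Val − 1); for a random trait,
â0 + â1 + â2·mean(r^Train). The per-trait form assumes the residual
e_t does not depend on r^Val. A single-trait variant drops a2, for
designs where replicates (training/validation/omitted splits with
varying validation reliability) replace traits. r^Val and r^Train are
means of per-individual accuracies √r²; a flag averages reliabilities
instead. Collinear predictors (e.g. constant training reliability
across traits) are rejected with diagnostics rather than silently
dropped.

## Simulation generator

The generator produces the assumed structure: founders in linkage
equilibrium (allele frequencies uniform on (0.1, 0.5)), LD built by
random mating in a closed population (drift LD — the dominant source in
livestock with small effective size), then a three-generation study
design: HD grandsires and sires sampled from the pool, dams bred from
grandsire × pool matings (recorded with unknown dam), and LD candidates
from sire × dam matings. Meiosis is Haldane: Poisson crossover counts
at 1 cM/Mb, uniform positions, no interference. Defaults — 2
chromosomes × 1000 markers on 100 Mb, 80 founders, 20 burn-in
generations, 50 sires × 2 dams × 2 offspring, 50 grandsires — define
the study conditions used by the monotonicity tests. The
position-recovery test uses a denser, longer-drift configuration (600
markers/chromosome at 0.167 Mb spacing, 100 founders, 150 generations)
because chain construction needs chip-like adjacent-marker LD; real
60k-chip spacing is ~4× denser still.

TBV are sums of standard-normal effects at random QTL, scaled to unit
variance. EBV are a deliberate shrinkage construction,
EBV = r²·TBV + r·√(1 − r²)·e with e standard normal, giving
cor(EBV, TBV) = r by design — a test harness, not a claim about BLUP.
With the family-error switch on, a share (default 0.5) of e is a
component shared between a sire and his offspring, reproducing the
correlated prediction errors of a joint evaluation; this is what makes
the naive accuracy ratio overestimate in the tests, mirroring the
mechanism the regression approach corrects.

What the simulations do **not** emulate: genotyping and phasing errors
(the library is truth-phased, so library-related error rates are
optimistic), mutation, selection during burn-in, X-chromosome
inheritance (dosages are treated autosomally throughout, males not
special-cased), and realistic marker ascertainment. Absolute error
rates at desk scale are therefore higher than chip-scale practice —
the populations are small and LD far weaker than on a 48k-marker
genome — and the tests assert directions and invariants, not absolute
levels.

## Numerical choices and degenerate inputs

* Correlations are pairwise-complete; undefined correlations (constant
  vectors, < 2 shared observations) are NaN and treated as "no signal"
  (0) by callers.
* All-missing markers have undefined MAF and are flagged; monomorphic
  markers fall to the MAF filter; an all-monomorphic GRM input is an
  error.
* Zero-reliability trait records are excluded with a warning.
* Ties everywhere break deterministically (lowest index / larger
  relationship / paternal first), so every pipeline stage is
  reproducible bit for bit.
* Offspring with zero called panel genotypes impute as all-fallback
  with a warning; an empty haplotype library is an error.

## Known limitations

* Phasing of the reference set is out of scope: the library must arrive
  phased (VCF "|" genotypes); unphased heterozygotes exclude an
  individual from the library (or raise, where a library is required).
* The simple deregression EBV/r² does not remove parent-average
  contributions; studies with precomputed deregressed proofs should
  pass them through.
* Population-HMM imputation (Beagle-style) is intentionally not
  reimplemented; the library method is designed for the
  genotyped-sire / ungenotyped-dam structure and degrades when the
  library contains no relatives of the dam.
* The accuracy regression extrapolates linearly to r^Val = 1; with few
  traits or a narrow reliability range the extrapolation variance is
  substantial, and no bootstrap intervals are provided.
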