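# Methods

## Repeat census

A locus is a *maximal perfect tandem repeat*: an interval periodic with
period k (its unit length, 1–4) that cannot be extended by one base in
either direction.  The scanner run-length-encodes the self-match
`s[i] == s[i+k]` for each k; every maximal True-run is a maximal periodicity
tract, and the locus keeps only whole units phased at the tract start.  A
tract whose leading unit is non-primitive (e.g. "AA", "ATAT") is exactly the
tract already reported at a smaller period and is skipped — this is what
makes a poly-A tract a homopolymer rather than an "AA" dinucleotide repeat,
and assigns every interval a unique unit length for rate denominators.
Partially overlapping loci with different units are all reported.  Runs of N
split sequences into independent scan segments.

Defaults: homopolymers ≥ 3 bp, microsatellites ≥ 3 units.  Observed
mutability extends down to 4 bp runs and 3-unit microsatellites, so the
census reaches one length class below that; both thresholds are arguments.
Tetranucleotides are censused but excluded from rate curves by default
(too sparse for stable rates).

Motif classes collapse a unit over strand and rotation — a tandem tract has
no intrinsic phase or strand.  The canonical representative is the lexically
smallest string among all rotations of the unit and of its reverse
complement; labels are written `rep/complement(rep)`, with dinucleotide
classes displayed under their traditional names (GT/CA, GA/CT, AT/TA).
Under this collapse some historically separate trinucleotide labels merge
(e.g. AAT/TTA and ATT/TAA are one rotation class); the census keeps the
collapsed class because rate denominators must not double-count.

Nearest-neighbour distances are non-negative end-to-start gaps; touching or
overlapping loci are at distance 0, and a chromosome with a single locus
yields NaN (dropped from ECDFs).

## Mutation classification

Substitutions collapse over strands into six classes; transition iff both
bases are purines or both pyrimidines.  Indels are left-aligned (shift left
while the preceding base equals the last base of the inserted/deleted
sequence, rotating the sequence accordingly) before assignment, because a
caller may report an indel anywhere inside a repeat.  An indel is assigned
to a locus when (a) the breakpoint touches the locus interval (gap 0 —
slippage acts within the run), and (b) the inserted/deleted sequence is a
whole number of locus units up to rotation.  Among several qualifying loci
the longest wins, then the leftmost.  Multi-unit indels count as one event
with a signed `units_changed`.

Two study-design filters: indels at repeats require ≥ 3 reads spanning the
whole repeat in both endpoint and ancestor (callability of slippage calls);
variants identical across ≥ 3 lineages are removed everywhere, as such
recurrence marks mutations that arose in the shared ancestor before
passaging.  Note that in the scaled-up synthetic conditions (below) hot
long repeats genuinely recur across lineages, so applying the shared filter
there removes real events and makes long-repeat rates conservative; the
recovery analyses therefore run on unfiltered synthetic calls, and the
narrative drivers report how many records the filter took.

The boundary-shift detector asks whether a substitution at the junction of
two repeats (gap ≤ 1 bp) is equivalent to a double slippage: the ±20 bp
context is re-decomposed into maximal repeats before and after the
substitution at relaxed thresholds (≥ 2 bp / 2 units, so a census-size run
contracting below threshold stays visible), and the flag is set iff exactly
one junction partner gained one unit, the other lost one, and nothing else
changed.

## Rates and fits

Rates are events per opportunity; opportunity is callable bp (or censused
repeats) × generations × lineages.  Defaults: g = 170 generations per
lineage and callable genome G = 1.216×10⁷ bp, the value consistent with the
packaged per-lineage event counts and their printed per-bp rates (solving
rate = events/(g·G) across lineages gives 1.214–1.218×10⁷); both are
arguments everywhere.  Event-count CIs are exact Poisson (Garwood,
chi-square quantiles); fluctuation CIs are handled separately (below).

The rate-by-length curve uses run length in bp for homopolymers and unit
count otherwise.  The exponential regime is fitted by OLS of log₁₀(rate) on
length over 3–8 units (zero-rate lengths excluded and reported;
fold-per-unit = 10^slope), the linear regime by OLS of rate on length for
≥ 9 units with R².  A regime with fewer than 3 (exp) or 2 (lin) informative
lengths is marked unavailable, never extrapolated.  Lengths whose tract is
≥ 14 bp are flagged: spanning-read coverage collapses there, so their rates
are underestimates.

Report rounding follows the field's tables (two significant figures for
rates, integer folds, one-decimal percentages); all stored values are
unrounded.

## Bias, proximity and spectrum statistics

Insertion/deletion bias per class is Pearson χ² against a 50:50 split,
df = 1, *without* Yates correction — the convention under which the
printed p-values for the C/G (10:28 → p = 3.5×10⁻³) and AT/TA
(71:42 → p = 6.4×10⁻³) counts reproduce exactly.  Classes with n < 5 are
computed but flagged low-n.  Proximity uses the two-sample KS statistic
over the pooled support with the asymptotic Smirnov p
(effective n = n₁n₂/(n₁+n₂)); repeat censuses give thousands of distances,
where the asymptotic p is accurate.  Spectrum comparison between strains is
a Monte-Carlo Fisher-type exact test on the 2×k table: p is the probability
mass of margins-fixed tables whose hypergeometric likelihood does not
exceed the observed one, estimated from 10⁵ multivariate-hypergeometric
draws (seed mandatory); the χ² p is reported alongside.  On 2×2 tables the
MC p converges to the closed-form Fisher value (tested at tolerance 0.01).

## Fluctuation analysis

The mutant-count distribution uses the Lea–Coulson/MSS recursion.  P0:
m̂ = −ln f₀ with a Clopper–Pearson CI on f₀ propagated through −ln;
undefined when no culture has zero mutants (the code then points to the
MLE).  MSS-MLE: bounded derivative-free maximisation of the count
log-likelihood over ln m, m ∈ [10⁻⁶, 10³], relative tolerance 10⁻⁶; counts
above k_cap = 10⁴ (jackpots) are lumped into a tail category with
probability 1 − Σp_k.  The CI uses the Stewart normal approximation
σ_ln m = 1.225·m̂^(−0.315)/√C.  The per-cell-division rate is m/n_final
(divisions ≈ n_final when n_final ≫ n_initial).  Plating efficiency and
phenotypic lag are not modelled.

The forward simulator draws mutations as Binomial(divisions, rate) with
mutation times uniform over divisions and grows each mutant clone
stochastically to a Geometric(s/n_final) final size (s the population size
at mutation) — the asynchronous exponential-growth model whose count law
the MSS recursion describes; at m = 1 the simulated distribution matches
the recursion to total-variation distance < 0.01.  A synchronous
whole-culture doubling model is available as `model="synchronous"` for
comparison, but its mutant clones are exact powers of two and its count law
deviates visibly from the recursion (e.g. p₂ = e⁻¹(m/4 + m²/8) ≈ 0.138
vs 0.107), so it is not the default.

## Synthetic study conditions

The generator's defaults are the study conditions: 16 lineages, 170
generations, substitution rate 4.8×10⁻⁹ per bp per generation, slippage
fold 4 per unit, deletion biases A/T 0.93, C/G 0.74, AT/TA 0.37,
GT/CA 0.65, detection dropout (probability 0.5) for repeats ≥ 14 bp, on a
1 Mb genome.  The absolute per-repeat slippage rates of a real genome
(≈10⁻⁹ at 3 units) would give essentially zero events at 1 Mb, so the base
rate is scaled to 7.5×10⁻⁷ at L = 3 with a geometric census (≈3-fold fewer
loci per extra unit; ~40,000 embedded loci, ~15% of the genome).  These
sizes were chosen so that (i) each length bin in 3–8 units expects tens of
events, giving the exponential fit a ~3% standard error, and (ii) the
per-locus per-experiment event expectation stays ≤ 0.13 even at L = 8, so
that at most a few percent of locus-lineage pairs see more than one event —
multiple hits collapse into one net endpoint call and would otherwise bias
rates down and break the binomial sampling of the deletion fraction.  The
rate law rises exponentially to 8 units and continues linearly beyond
(slope equal to the last exponential step), mirroring the observed
exponential-to-linear crossover; a law that kept doubling would make
insertion-biased loci ratchet to divergence within an experiment.

Embedded loci are placed with flanking bases chosen to break their
periodicity (left flank ≠ last unit base, right flank ≠ first), so each is
maximal and the census recovers it at exact coordinates; a repair pass
rewrites any background base that happened to form a census-size repeat
overlapping or within 1 bp of an embedded locus.  A configurable fraction
of loci (default 0.1) is placed as close pairs (gap ≤ 3 bp) so proximity
structure exists; an optional `proximal_boost` multiplies slippage rates at
loci with a neighbour ≤ 3 bp away (default 1.0 — no effect — because the
study conditions quantify no boost; the proximity property tests switch it
on explicitly).  Lineage streams derive from the master seed by fixed
offsets; every output is bit-reproducible from (seed, config).

What the generator does *not* emulate: read-level errors and alignment
(detection enters only through the parametric dropout and span counts),
selection between bottlenecks (accumulation is neutral; the bottleneck
interval is metadata), transition-biased substitution spectra (alternative
bases are uniform), de-novo repeat birth by substitution, diploidy and
structural variation.  Passing recovery tests therefore validate the
estimators and bookkeeping, not variant calling itself.

## Verification design

Every operation with a closed-form or enumerable answer is checked against
an independent oracle implemented in the test suite: a character-by-character
brute-force repeat finder (exact set equality on random sequences), an
explicit sup-over-support KS statistic, the normal-tail closed form for
χ²₁ p-values, all-pairs nearest distances, closed-form OLS R², and
scipy's Fisher exact test for the 2×2 Monte-Carlo case.  The end-to-end
check simulates the full study conditions over 20 fixed seeds and requires
each of (a) the true substitution rate inside the recovered exact Poisson
CI, (b) fold-per-unit within 15% of 4, (c) the configured A/T deletion
bias inside the exact binomial CI of the recovered fraction, to hold in
≥ 90% of seeds.  The three checks are assessed per criterion (not as a
triple conjunction per seed): each is an interval with ~95% coverage, and
demanding their conjunction seed-by-seed at 90% would require per-check
coverage the intervals do not claim.

## Known limitations

- Boundary-shift detection is conservative: contexts where the substitution
  simultaneously creates an unrelated ≥ 2 bp repeat in the window can be
  missed; junction pairs must already be census loci.
- The indel-assignment rule (touching locus, rotation-compatible unit) can
  accept a malformed call that a slippage process would not produce; such
  calls do not arise from the simulator or from left-aligned caller output.
- At scaled-up synthetic rates, net endpoint calls under-count multiple
  hits at the hottest loci (a few percent at L = 8); the real study's rates
  are far below the regime where this matters.
- The MSS CI is a normal approximation on ln m; for very few cultures
  (< 10) it is optimistic.
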