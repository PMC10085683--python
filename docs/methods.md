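# Methods

This note documents the models and procedures implemented in `chromonema`,
the parameter choices that matter, and what the synthetic-data tests do and
do not demonstrate.

## Contact probability P(s)

All intra-chromosomal contact pairs are binned by genomic separation
`s = |pos_a − pos_b|` on a logarithmic grid (default 100 kb – 1 Gb, 10 bins
per decade, half-open bins).  The probability in a bin is the observed pair
count divided by the number of possible locus pairs at separations in the
same bin, where loci are non-overlapping 100 kb tiles and counts are pooled
over chromosomes.  Positions are 0-based throughout.  Bins without possible
pairs are *undefined* (NaN), never zero — note that with 100 kb tiles the
narrow bins just above 100 kb contain no tile-pair separation at all and
are therefore undefined by construction.  Curves can be normalized to equal
exactly 1 at the bin containing 100 kb; normalization is idempotent.
Log-log derivatives use central differences at bin midpoints with one-sided
differences at the ends; they are exact for power laws sampled on the grid.

Inter-chromosomal pairs are parsed and flagged but excluded from P(s); all
downstream analyses are intra-chromosomal.

## Regional turn-length estimation

Chromosomes are divided into non-overlapping 5 Mb regions (a terminal
remainder shorter than 5 Mb is merged into the last full region).  A pair
is attributed to a region if at least one endpoint falls inside it or if it
spans the region entirely; each qualifying pair is counted once.  The
contact-distance histogram of each region (log-spaced bins, 40 per decade,
from 100 kb) is fitted with

    counts(s) = A·exp(−s/λ) + B·exp(−(s−μ)²/(2σ²))

and μ is reported as the region's helical turn length.

Numerical choices:

* **Attribution ramp.** The attribution rule gives a pair at separation s a
  qualifying measure proportional to `region_size + s` (either endpoint
  inside, or spanning).  The density is divided by this known factor before
  fitting; without the correction the Gaussian centre is biased upward by
  ~0.7 Mb at the default signal shape and, worse, bump-free data acquire a
  spurious boundary Gaussian.
* **Weighting.** Least squares on densities with Poisson weights,
  σ_i = √(counts+1)/bin width.
* **Initialisation** (deterministic): λ₀ from the log-slope of the first
  decade of bins; μ₀ at the smoothed-density argmax beyond 10 Mb; σ₀ = 5 Mb.
* **Bounds.** μ ∈ [10, 60] Mb by default (configurable); σ ∈ [0.5, 20] Mb.
* **Detection.** A Gaussian is accepted when the fit converged, the Gaussian
  integral is ≥ 5 % of the total fitted integral, *and* μ is not pinned at a
  bound — an optimizer pushing the centre onto the boundary is patching the
  exponential, not detecting a bump.  Regions failing detection, regions
  with fewer than 1000 qualifying pairs and regions overlapping a supplied
  mask (centromeres, NORs) are flagged `no_signal`.  A region whose μ
  exceeds (or falls below) both neighbours by more than 1.5× is flagged
  `abrupt_peak` — on real assemblies such spikes usually mark reference
  errors.  Flags annotate; they never alter fitted values.

## Helical path geometry

One path monomer represents `m·l0` bp (monomer size × mean major-loop
size).  Given a per-monomer turn length l_i (piecewise-constant lookup of
the region containing the monomer's genomic midpoint):

    n_i = l_i/m/l0,   Δz = H/n_i,   Δθ = 360°/n_i,
    (d·n_i)² = (2π r_i)² + H²

with turn height H = 400 nm and monomer spacing d = 50 nm by default.
θ is stored cumulatively (unwrapped) so the number of turns — the number of
cycles of cos θ — is exactly total θ/360°.  Each monomer covers one
inter-monomer interval, so a constant-l profile of length L yields exactly
L/l turns and a z-extent of (L/l)·H.  Turn counting uses the 1 Mb-monomer,
l0 = 1 parameterization.  A turn too short for the pitch (d·n_i < H) has no
real radius and is rejected with the offending region named.  Handedness is
right-handed by default and configurable; the data constrain relative, not
absolute, handedness.

Physical predictions are plain arithmetic on the path: chromosome length =
turns × per-turn height (the height range is an input, e.g. 380–450 nm);
packing density = volume/DNA.

**SCE classifier.**  A helical ~400 nm chromonema permits only two kinds of
sister-chromatid-exchange segments: sub-turn exchanges about one chromonema
thick and possibly narrower than the chromatid, and exchanges of one or
more full turns spanning the whole chromatid width.  The classifier uses a
thickness band of 300–550 nm (the observed transition range) and a 10 %
full-width tolerance: height below 300 nm → `violation_too_short`; full
width → `multiturn_consistent`; height within the band and incomplete
width → `subturn_consistent`; taller than the band yet narrow →
`violation_tall_narrow` (geometrically impossible on a helix).

## Bottle-brush polymer model

Beads-on-a-string homopolymer, one bead = 200 bp (nucleosome + linker,
10 nm); a 1 kb/bead coarsening is used for desk-scale runs.  Major loops
(mean 3 Mb) and nested minor loops (mean 500 kb) have exponential lengths
truncated at one monomer, the last loop truncated at the chain end.  Five
forces:

1. harmonic bonds, rest 10 nm; spring constant kBT/wiggle² with wiggle
   1 nm (the thermal-standard-deviation convention);
2. harmonic angle force, 1 kBT/rad², straight rest angle;
3. soft repulsion `U(r) = E·(1 − 3x² + 2x³)`, x = r/10 nm: barrier
   E = 1.5 kBT at zero separation (2.5 kBT in the wide-cylinder variants),
   smooth to zero with zero slope at the cutoff, monotone in between — the
   finite barrier allows strand crossing;
4. harmonic tether (4 kBT/nm²) pinning each major-loop base to its anchor
   on the helical path; anchors are equally separated along the path (50 nm
   default spacing; 20 and 100 nm variants);
5. optional cylindrical confinement: harmonic radial wall (10 kBT/nm²) at
   the radius granting 11³ nm³ per monomer, or an explicit radius
   (e.g. 650 nm).

**Loop closure.**  Only three internal forces are stated for the chain, but
side-by-side nested loops need a mechanical realization: consecutive loop
anchors (minor-loop bases, with the flanking major bases) are connected by
harmonic bridging bonds identical to chain bonds.  This is the package's
design choice; it makes minor loops emanate from a secondary backbone the
way major loops emanate from the path.

**Dynamics.**  Langevin integration with the BAOAB splitting (exact
Ornstein–Uhlenbeck noise), internal units kBT = 1, nm, bead mass 1.
Temperature enters only through the kBT scaling of the stated constants.
The time step (0.08) resolves the stiffest harmonic mode (tether, ω = 2)
with dt·ω ≈ 0.16; friction 0.1 is chosen for fast configurational mixing —
equilibrium distributions, not kinetics, are the object of study.
Repulsion pairs come from a cell-list neighbour search with a 4 nm Verlet
skin, rebuilt every 20 steps.  Runs are single-threaded and bitwise
deterministic for a fixed seed.

**Equilibration.**  The run proceeds in blocks (1500 steps by default);
after each block the model contact probability of the current conformation
is computed and the run stops when consecutive curves agree within
max |Δlog₁₀ P| < 0.05 over bins with at least 50 observed contacts (sparser
bins fluctuate by counting noise alone), or when the block budget is
exhausted (reported in the summary).

**Initial conformation.**  Major-loop bases sit exactly on the analytic
helical path; loop interiors start as closed random bridges around their
anchors with an outward radial bias (50 nm at the loop apex), so loops
emerge radially and bonds start near their rest length.  The half-helical
variant keeps |x| of every anchor (handedness reversal each half turn),
leaving y and z unchanged.

**Small comparison model.**  The helical/half-helical discrimination runs
a 10 Mb region with 2 Mb turn length, 100 nm turn height, 100 kb major and
10 kb minor loops on a 100 nm-radius path without confinement, at 1 kb per
bead (10 000 beads), 8 blocks of 1500 steps, three replicate seeds with
resampled loop architectures.  These sizes keep a replicate around a minute
on one CPU while reproducing the contrast: the helical model's P(s) passes
through a marked minimum and peaks at the turn length; the half-helical
model decays without an equivalent single full-turn peak.

## Model contact read-out

Contacts are bead pairs within 51 nm (centre to centre; a bead radius for
the contact rule is not defined, so the threshold is used as given), found
with a k-d tree that agrees exactly with the all-pairs check.  Pairs are
grouped by |i−j|·bp_per_monomer; separations below one monomer are
excluded.  Replicates are pooled at the count level (observed and possible
pairs summed) before the curve is normalized to 1 at the bin containing
100 kb; when the monomer size exceeds 100 kb, the smallest-separation bin
is used with a warning.  Peak detection smooths log P with a 3-bin binomial
kernel, treats measured zeros as a value below the smallest positive bin
(not as missing data), requires a candidate maximum to rise ≥ 0.1 log₁₀
above the lowest preceding point (a genuine full-turn peak sits behind a
marked minimum; noise wiggles on a monotone decay do not), searches up to
half the modelled span, takes the largest-separation qualifying maximum
and refines it by quadratic interpolation in log-log space.

## Synthetic data: what it emulates, what it does not

`generate_helical_pairs` draws the left endpoint uniformly and the
separation from `(1−w)·Exp(λ) + w·Normal(T(pos), σ)` with defaults
w = 0.3, σ = 5 Mb, λ = 5 Mb — a shape that reproduces the observed
metaphase P(s): exponential short-range decay plus a helical bump.
Off-chromosome draws are rejected and redrawn (clipping would distort the
bump near ends); consequently regions within one turn length of a
chromosome end carry a truncated bump and are excluded from recovery
assertions.  `generate_interphase_pairs` draws a truncated power law with
no bump.  `generate_ideal_helix_conformation` places beads exactly on the
analytic path plus isotropic Gaussian blur standing in for stochastic loop
placement.

These generators validate estimator correctness (parameter recovery, flag
behaviour, end-to-end closure from pairs to turn counts).  They do **not**
emulate restriction-site bias, duplicates, trans-contact noise, coverage
variation along real assemblies, centromere/NOR contact suppression or
assembly errors, so passing tests demonstrate statistical soundness of the
method, not robustness to every artefact of real Hi-C libraries.

## Known limitations

* Loops are static; no loop-extrusion kinetics, no sister-chromatid
  cohesion, no explicit topoisomerase chemistry beyond the crossing-
  permissive truncation.
* The interphase comparison curve is taken as given; `ratio_curve` accepts
  any curve on the same grid.
* The denominator of P(s) pools locus pairs over chromosomes; per-
  chromosome denominators would differ slightly for genomes with very
  uneven chromosome sizes.
* Turn lengths inside centromeres and NORs are masked, not modelled.
* The 400 nm model turn height versus the ~450 nm cytological pitch is an
  unresolved tension in the underlying data; both enter only as parameters
  (`turn_height`, and the height range of the length extrapolation).
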