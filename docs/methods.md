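# Methods

## The assay being modelled

In a multiplexed end-joining fidelity assay, a hairpin substrate carrying a
degenerate four-base 5'-overhang is ligated in a single pot, so every one of
the 256 overhangs competes for every possible partner. Sequencing the
ligation products (top- and bottom-strand consensus per molecule) reveals,
for each junction, which two overhangs were joined. Because strand
designation of a product is arbitrary, each product is counted in both
orientations, giving a symmetric 256 x 256 ordered-count matrix whose total
is twice the number of products. All statistics in this package are defined
on that matrix:

- **Normalised ligation frequency** of overhang *o*:
  `freq(o) = 256 * rowsum(o) / total`, so uniform usage gives 1.0 and the
  profile sums to 256. The assay's source publication does not pin down its
  normalisation; mean-1 makes deficits such as the TNNA family directly
  readable as "x-fold below average".
- **Fidelity**: overall, the fraction of ordered events on Watson-Crick
  cells (`bottom == revcomp(top)`); per overhang, the Watson-Crick cell
  divided by the row sum. Zero-event overhangs are reported as missing
  (NaN), never 0, so they cannot bias bin means. A palindromic overhang's
  correct partner is itself; its diagonal cell receives 2 per self-ligation
  so product-level and event-level fractions coincide.
- **GC stratification**: bins 0/25/50/75/100% GC with populations
  16/64/96/64/16; per-bin mean and median. Adjacent bins are compared with
  a two-sided Mann-Whitney rank test (the choice of test is a package
  decision; the source does not name one).
- **Mismatch spectrum**: mismatches of every ordered pair are enumerated
  with count weights and labelled `top:bottom` at 1-based top-strand
  positions N1..N4; edge aggregates positions 1 and 4 (equivalently,
  position 1 of each counted orientation), middle aggregates 2 and 3.
  Frequencies are normalised within each position class. Because both
  orientations are counted, T:G and G:T appear as separate labels of one
  underlying unordered type.
- **Mismatch-count distribution** over 0..4 mismatches per product; its
  0 class equals the overall fidelity by construction, and among 2-mismatch
  products the edge-involvement fraction is reported separately.
- **Cross-sample comparison**: Pearson correlation of two 256-value
  frequency profiles; undefined (NaN) under zero variance.

## Generative ligase model

The simulator treats one ligation event as a single draw from a multinomial
over unordered overhang pairs — a propensity-weighted competition rather
than explicit annealing kinetics, which is the minimal model that still has
closed-form expectations for every statistic above. The ordered-pair
propensity is

    propensity(a, b) = w_a * w_b * exp(alpha * gc_pairs(a, b))
                       * prod_m [ tol(type_m, class_m) * exp(beta * gc_pairs(a, b)) ]

with:

- `w_o > 0` — per-overhang weight (default 1): intrinsic sequence
  preference of the ligase, independent of the partner.
- `alpha` (dimensionless, default 0) — log-scale annealing boost per
  correctly paired G:C position; positive values reproduce the observed
  enrichment of GC-rich overhangs among products.
- `tol(type, class)` in [0, 1] — mismatch tolerance keyed by unordered
  base-pair type (G:T and T:G are one type) times position class
  (edge/middle), the granularity at which positional mismatch profiles are
  reported. Unlisted types are 0, so the default model is
  Watson-Crick-only. With a single nonzero `tol(G:T, edge) = t`, the
  count ratio of a one-edge-G:T cell to its Watson-Crick cell estimates `t`
  directly; this is the parameter-recovery check.
- `beta` (default 0) — optional annealing-mismatch coupling multiplying
  each mismatch factor by `exp(beta * gc_pairs)`.

The `beta` term exists because the pure product form cannot reproduce one
empirical hallmark of end-joining: fidelity falling with GC content. Under
the product form, per-overhang fidelity is a within-row ratio, absolute
annealing strength cancels, and a mismatch at a G/C position *loses* one
annealed G:C pair — so expected fidelity weakly *rises* with GC for any
uniform tolerance. Physically, a GC-rich duplex stays annealed long enough
for a mismatched end to be sealed while an AT-rich mismatched duplex falls
apart first; `beta > 0` encodes exactly that, and with `3*beta > alpha` the
expected per-overhang fidelity decreases monotonically across GC bins. At
`beta = 0` the model is the plain product form.

Model presets (`uniform`, `gc-biased-strict`, `permissive`) sketch
qualitative regimes for testing and demonstrations; they are **not** fitted
to any measured enzyme.

Sampling is a `numpy.random.Generator` multinomial over the 32,896
unordered pairs (upper triangle), reproducible per seed; each draw
increments both ordered orientations.

## Synthetic reads and extraction

`emit_reads` writes, per product, a top and bottom strand with the layout
`left_const | overhang | right_anchor | control hexamer | rest of constant
region`, each 5'->3' on its own strand. The anchors are fixed 20-mer
package constants; the emulation is structural (anchor / N4 / constant /
N6-control), not a reproduction of the real substrate sequence. The
control hexamer is drawn independently of the overhang — uniformly by
default, or with a per-base composition skew to exercise the synthesis-bias
correction. Uniform per-base substitution errors model residual consensus
error.

Extraction locates both anchors by exact match (consensus reads are
high-accuracy; a corrupted anchor marks an unusable read), takes the four
bases between them as the overhang, and classifies failures as
`anchor-missing`, `wrong-gap-length` or `non-ACGT` — counted and logged,
never silently dropped. An optional fuzzy mode allows one substitution per
anchor. At zero error rate the chain sample -> emit -> extract -> tabulate
reproduces the sampled matrix exactly; the failure fraction is
nondecreasing in the error rate.

The synthesis-bias correction estimates per-position base frequencies from
the pooled control hexamers (positions treated independently), computes the
expected relative abundance of each overhang as the product of its four
per-base frequencies against the uniform 1/4 baseline (overhang positions
1-4 mapped to control positions 1-4), divides observed frequency by it and
renormalises to mean 1. It is skipped with a warning when tallies are
absent or a position has no observations. Raw (uncorrected) frequencies
are the default output.

## Kinetics

For defined-oligo timecourses (fraction product vs minutes), the initial
velocity is the ordinary-least-squares slope over the leading points with
conversion at or below a cap (default 25%); the first point above the cap
and everything after it are excluded, so late points never perturb the
fit. Exactly collinear retained points give stderr 0 (the two-point case
is defined the same way). Replicates are averaged arithmetically; the
reported error combines per-fit slope standard errors in quadrature
(`sqrt(sum se_i^2)/n`), and the plain SD of replicate slopes is emitted
alongside, since "replicate error" can reasonably mean either. Velocities
convert to nM/min through the substrate concentration and enter unit-free
fold ratios.

## Numerical and design notes

- Sequences are strictly ACGT; lowercase is normalised with a warning, U
  and IUPAC ambiguity codes are rejected. Positions are 1-based within the
  overhang; there are no genome coordinates anywhere.
- All pairing logic is backed by precomputed 256 x 256 tables (mismatch
  masks per position, mismatch counts, annealed-G:C counts); a scalar
  per-pair implementation is kept alongside and the two are cross-checked
  in tests, as is Biopython's reverse complement.
- Counts CSVs are accepted in long form (`top_overhang,bottom_overhang,
  count`) or wide 256 x 256 form, autodetected; non-symmetric tables are
  flagged and folded only on explicit request. Malformed rows are reported
  with their row number.
- Statistics are scale-invariant and invariant under top/bottom
  relabelling (property-tested); expected-profile statistics agree with
  the model's closed forms to machine precision, and sampled ones converge
  at the binomial rate (the oracle-equivalence tests assert 3 binomial
  standard errors at 10^6 events).
- Problem sizes in the test-suite and the acceptance script: exhaustive
  enumeration over all 65,536 ordered pairs; 10^6 sampled events for
  convergence and parameter-recovery checks; 10^4 events for read-level
  round trips. These sizes put sampling noise well below the asserted
  tolerances while keeping runs to seconds.

## What the simulator does not capture

No polymerase or sequencing error structure beyond uniform substitutions;
no hairpin/secondary-structure effects, adenylated-intermediate kinetics,
or nearest-neighbour thermodynamics (annealing strength is GC-pair count
only); overhangs are always four bases (no 3' overhangs or blunt ends).
Passing tests therefore demonstrate correctness of the counting and
statistics machinery and self-consistency of the generative model — not
that any preset reproduces a particular enzyme. Statistics on real count
tables (when supplied as CSV) exercise the same code paths with none of
these caveats.
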