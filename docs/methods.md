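# Methods

## The decision model

A fuzzy soft set over a universe of `m` alternatives and `n` parameters is an
`m × n` matrix `D = (d_ij)` of membership degrees in `[0, 1]`: `d_ij` is the
degree to which alternative `x_i` satisfies parameter `e_j`.  The package
treats the `m` alternatives as a Dempster–Shafer frame of discernment
`Θ = {x_1, …, x_m}` (mutually exclusive and exhaustive) and each parameter as
one item of evidence about which alternative is best.

### Grey relational uncertainty of a parameter

The evidential method needs to know how much each parameter actually
discriminates.  Grey relational analysis supplies that: each membership is
compared with its *row mean* `d̄_i` (the alternative's average level over all
parameters), giving deviations `Δd_ij = |d_ij − d̄_i|`.  Within each parameter
column these are rescaled by the column extremes `a = min_i Δd_ij`,
`b = max_i Δd_ij` into grey mean relational degrees

    r_ij = (a + ρ·b) / (Δd_ij + ρ·b),   ρ ∈ (0, 1),

which lie in `(0, 1]` and equal 1 exactly where the column deviation is
minimal.  The q-order uncertainty degree of parameter `e_j` is

    DOI(e_j) = (1/m) (Σ_i r_ij^q)^(1/q).

Interpretation: if every alternative sits close to its own mean under `e_j`,
all `r_ij` approach 1 and `DOI` approaches its maximum `m^(1/q − 1)`
(`m^(−1/2)` at `q = 2`) — the parameter tells the alternatives apart poorly
and its evidence should be heavily discounted.  Because `r_ij ∈ (0, 1]`, the
computed `DOI` always lies in `(0, m^(−1/2)]` for `q = 2`; this bound is a
derived consequence of the construction and is enforced as a property test,
with the upper end rescaled into `(0, 1]` mass space by the construction
below.

### From uncertainty to mass functions

Column normalisation (`information structure image`)
`d̃_ij = d_ij / Σ_i d_ij` turns each parameter into a distribution over
alternatives.  Parameter `e_j`'s mass function then assigns

    m_j({x_i}) = d̃_ij · (1 − DOI(e_j)),    m_j(Θ) = DOI(e_j):

the discriminating share of the parameter's unit mass is split over the
singletons in proportion to support, and the uncertain share stays on the
whole frame as ignorance.  Since the image columns sum to one, each `m_j` is
a valid basic probability assignment; this identity (`m_j(Θ) = DOI(e_j)` to
1e-9) is asserted in the tests.

### Combination and decision

Dempster's rule combines two mass functions by intersecting focal sets,
discarding the conflicting product mass `K` and renormalising by
`1/(1 − K)`; `K = 1` means non-combinable evidence and raises an error.  The
n-ary combination is implemented as a left fold of the pairwise rule, which
for Dempster's rule is algebraically identical to the single-normalisation
n-ary formula and independent of input order (asserted over permutations).
Alternatives are ranked by combined singleton mass — equal to the belief
`Bel({x_i})` because the pipeline's focal sets are singletons plus Θ — and
every argmax is reported as optimal.  Although the pipeline only produces
singleton + Θ masses, the mass-function type and the combination rule handle
arbitrary non-empty focal sets, and the test suite exercises that general
path against a power-set enumeration oracle.

### The mean potentiality baseline

The level-soft-set baseline thresholds `D` at the *mean potentiality* `m_p`
(the grand mean of all memberships) rounded to `ρ` significant figures, where
`ρ` is the maximum number of significant decimal digits among the
memberships *as written* in the source file.  Choice values are the row sums
of the thresholded indicator.  A unique maximum decides immediately
(stage 4).  Otherwise the table is re-thresholded at the rounded mean
per-parameter spread `α` (stage 8), and a remaining tie goes to the tied
alternative with the smallest per-alternative spread `β_i` (stage 9); if the
spreads tie too, all minimal-spread alternatives are returned.  Before any of
this, a *normal parameter reduction* is attempted: the smallest parameter
subset whose per-alternative membership sums are constant across alternatives
is dropped, since it shifts every choice value equally.

### The performance measure

Both methods' chosen optima are scored by
`Υ = 1/S + Σ_i v_i` with `S = Σ_{i<j} |v_i − v_j|` over the optimum's
membership row `v`.  The double-sum form of this measure is ambiguous between
ordered and unordered index pairs; the unordered reading is implemented
because it is the one consistent with the worked-example values the test
suite pins (the ordered reading scales `S` by two).  `Υ` is undefined when
the optimum's memberships all coincide (`S = 0`); that case raises an error.

## Tunable parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| `rho` | distinguishing coefficient of the grey degrees | 0.5 | in (0, 1); larger compresses the spread of `r_ij` |
| `q` | order of the uncertainty norm | 2 | ≥ 1; higher orders weight large relational degrees more |
| `sig_figs` | significant figures for `m_p` and `α` rounding | from the data | override needed for sets built in memory |
| `max_reduction_size` | cap on the dispensable-subset search | 3 | the search is combinatorial in this cap |

Both defaults `ρ = 0.5`, `q = 2` are the conventional strong-distinguishing
choice for grey relational analysis and are what the bundled examples use.

## Numerical choices

- **Degenerate grey column** (`b = 0`: every alternative exactly at its row
  mean): `r` is 0/0 by the formula; the whole column is set to 1, the
  continuous limit as the deviations vanish uniformly.  A single-alternative
  table therefore has `DOI = 1` everywhere and produces only vacuous
  evidence.
- **Zero-support parameter** (a column of zeros): column normalisation raises
  an error naming the parameter rather than inventing a uniform fill — a
  parameter no alternative satisfies carries no evidence, and silently
  redistributing it would fabricate some.
- **Significant figures** are counted on the decimal text as written (digits
  after leading zeros; written trailing zeros count), captured at parse time.
  Rounding is half away from zero, routed through a 12-digit decimal string
  so binary float noise (0.6259999…) cannot flip the rounding.
- **Level thresholding** uses `membership ≥ t` with a 1e-9 absolute slack:
  thresholds arise from decimal rounding and memberships from text, so only
  representation noise needs absorbing.
- **Tolerances**: mass functions must sum to 1 within 1e-9; ranking ties are
  grouped at 1e-12; comparisons against 4-decimal reference values use
  1.5e-4.
- **Tie handling**: `gds` reports all argmax alternatives as jointly optimal;
  the baseline's stage-9 spread tie-break is restricted to the alternatives
  still tied at stage 8.  The method comparison requires unique optima and
  raises otherwise, since `Υ` evaluates a single chosen object.

## The synthetic generator

`synth_fss(m, n, seed, decimals)` draws memberships independently and
uniformly on `[0, 1]`, written to a fixed number of decimal places through
their text form so that the recorded precision and the stored values agree
exactly.  It emulates only the *shape* of a decision table — independent
uniform entries — not features of real elicitation data such as correlated
parameters, skewed membership distributions, or systematically missing
support.  Property tests on generated tables therefore establish structural
invariants (normalisation, bounds, monotonicity, round-trips, order
independence), not decision quality on any real domain; the worked-example
tables are the fidelity anchor.

## Known limitations

- Dempster's rule is the only combination rule; highly conflicting evidence
  is renormalised away rather than redistributed (no Yager or PCR variants),
  and total conflict is a hard error.
- The grey reference is always the row mean; reference-sequence variants
  against an ideal alternative are out of scope.
- The normal-parameter-reduction search is exhaustive up to the subset-size
  cap and will miss larger dispensable sets.
- Crisp soft sets are handled as the {0, 1} special case of fuzzy soft sets;
  no intuitionistic or interval-valued extensions.
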