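# Methods

This note documents the models, parameter choices and numerical conventions
behind `olisim`, and what the synthetic-data generator does and does not
emulate.

## Hairpin phenotype: a single-stem two-state model

Full secondary-structure prediction is intentionally out of scope. The
selection phenotype is reduced to the question the protocol actually asks —
*can the 3′ terminus pair with an internal tract and prime?* — answered by a
single perfect-complementarity stem:

- `find_self_priming_stem` returns the longest 3′-terminal suffix whose
  reverse complement occurs internally, with the partner tract ending at
  least one base before the suffix starts. Ties at a given length take the
  5′-most partner. Only perfect Watson–Crick pairing is considered (no G·T
  wobble, no bulges): the founding molecule was designed as a perfect
  duplex, and the simplest model consistent with that design keeps the
  genotype→phenotype map transparent. For the shipped ancestor the maximal
  stem is 9 bp (suffix 99–107 paired with 9–17); it contains the designed
  8-bp duplex (100–107 vs 9–16) plus one additional complementary position.
- Stability is two-state: `dG(T) = (L−1)(ΔH_stack − T·ΔS_stack) + ΔG_loop`
  with defaults ΔH_stack = −8.0 kcal/mol, ΔS_stack = −0.0227 kcal/(mol·K),
  ΔG_loop = +3.5 kcal/mol. These are calibration constants, not measured
  nearest-neighbour parameters: they are chosen so the ancestral stem has
  dG < 0 over 45–55 °C and dG > 0 at ≥ 65 °C, with its midpoint at 60.0 °C,
  matching the designed behaviour of the founder (stable folding at the
  starting temperature, loss of folding well below the final 70 °C).
  All are configurable via `ThermoParams`.
- Fold probability is the Boltzmann fraction `1/(1+exp(dG/RT))`, which is
  monotonically non-increasing in temperature for every sequence (property
  tested). `min_stem = 6` by default: shorter duplexes are treated as unable
  to hold a priming geometry.

Extension appends the reverse complement of the prefix 5′ of the partner
tract. For the ancestor this appends `CACTGCTT` (8 nt), producing the 115-nt
product whose last 20 nt are exactly the reverse complement of the forward
primer. The extended product's own best stem has its partner at position 1,
so re-extension is a no-op.

## Primer geometry

The printed reverse primer differs from the ancestral 5′ end at two internal
positions. Those two substitutions remove the internal bottom-strand BsaI
site (`GAGACC`) from every primer-incorporated amplicon, so an amplicon's
only cleavable sites are the two at the extended 3′ end — inside the
forward-primer footprint. This geometry is why digestion escape is
expensive: killing both sites needs one substitution in `CCTTC` and one in
`GGTCTC`, which already puts two mismatches into the forward footprint.
`escape_possible_with_k` enumerates all ≤ k point substitutions exhaustively
(k ≤ 2) and confirms no single or double mutant escapes digestion while
keeping both footprints within one mismatch.

Two consequences are adopted consistently:

- Pipeline primer filtering (`filter_by_primers`) expects amplicon reads:
  one primer verbatim at the 5′ end and the reverse complement of the other
  at the 3′ end, in either orientation, exact by default.
  `extended_amplicon()` constructs the ancestral amplicon.
- The simulator tracks insert (molecule) sequences, not primer-incorporated
  amplicons. Its primer-viability check therefore compares a molecule's 5′
  end to the ancestral 5′ footprint and its 3′ end to the reverse complement
  of the forward primer; a mutation in either footprint (default tolerance 0
  mismatches, configurable to 1) demotes the lineage from exponential to
  linear growth. This reproduces the mechanism — footprint mutations cost a
  primer — without simulating strand-level primer incorporation.

## The simulator

One transfer is: self-priming (per-copy Bernoulli at the transfer's
temperature) → primer-limited PCR → restriction digestion → bottleneck.

- **PCR.** Per cycle, every extended-lineage copy duplicates and every
  unextended founder gains one linear copy (the protocol states linear
  increase without mechanism; +1 copy per founder per cycle is the simplest
  faithful form). Every new strand passes through the mutation model and
  consumes one primer from a shared pool of `2 × primer_copies` (the two
  primer species are pooled; the protocol notes one primer is limiting, and
  the pooled budget preserves the stated capacity bound
  `total ≤ founding + 2 × primer_copies`). When demand exceeds the remaining
  pool, successful strands are drawn by multivariate hypergeometric
  allocation, producing the plateau.
- **Mutation.** Per new strand: substitutions Binomial(L, 0.008) with a
  uniform (configurable) spectrum, indels Binomial(L, 0.0008) of 1–3 bases —
  the combined 8.8/kb sits mid-range of the polymerase's stated 1–16/kb.
  Mutations apply only to newly synthesized strands.
- **Digestion** maps every copy through three-prime-mode `digest_trim`;
  copies whose sites mutated away survive uncut and stay extended.
- **Bottleneck** is an exact multivariate hypergeometric sample (identity
  when the population is already at or below the bottleneck size). Copy
  counts are integers throughout, so extinctions are exact events.
- **Sequencing** samples reads with replacement proportional to copy counts,
  with an optional uniform per-base error (default 0). Reads are the
  digested molecule sequences; primer ends are not added, so pipeline runs
  on simulated reads skip the primer gate (`--skip-primer-filter`).
- **Regimes.** Control holds 55 °C; sudden steps to 70 °C at transfer 2;
  intermediate steps +3 °C at transfers 3, 5, 7, 9, 11; slow steps +1.5 °C
  every transfer. The exact step placement for sudden/intermediate is an
  assumption (only the totals and step counts are fixed by the protocol) and
  is config-overridable.
- **Determinism.** All randomness flows from one `SeedSequence`; replicates
  use spawned child streams, so identical configs give bit-identical output.

Defaults are the protocol's stated conditions: 30 000 founding copies
(the stated molecule count is used as printed; 0.05 pmol would physically be
~3×10¹⁰ molecules — the discrepancy is noted, not reconciled), 5×10⁶ copies
of each primer, 40 cycles, 10⁵ bottleneck, 56 replicates, 11 transfers
sampled at 1, 3, 7, 11. Tests and examples use `scaled_config` — founding
600, 2.5×10⁴ primers per primer, bottleneck 500, 30 cycles — which preserves
the ~100× bottleneck-to-capacity ratio (and hence the shape of the growth
curves and the strength of drift at the bottleneck) at desk-scale runtimes;
the statistical checks state these sizes explicitly.

### What the generator does not emulate

Cooperation (molecules priming each other), recombination and
concatemerization are absent by design; these are precisely the processes
the wet protocol could not repress. Sequencing is error-free by default and
has no homopolymer bias. Primer incorporation is not tracked strand by
strand (see above). Consequently, passing simulation tests shows the
selection/mutation/drift machinery behaves as specified — it does not show
that real populations, where cooperation and genome-length evolution were
prominent, would reproduce the same trajectories. One measured divergence is
documented below.

## Pipeline conventions

- Coordinates are 0-based half-open; restriction cut positions are
  between-base top-strand indices. For a recognition site on the top strand
  at i the cut is `i + |rec| + cut_top`; for a bottom-strand site at
  top-start j it is `j − cut_top`. Cuts implied beyond either end are
  dropped; cuts at the boundary (position 0 or L) cleave nothing.
- `digest_trim` default mode applies the single 3′-most cut located in the
  3′ half — the digestion step's purpose is removing the extension. Applying
  it twice equals applying it once for pipeline-realistic inputs (the
  recognition site driving the cut is retained upstream of it).
  `all_cuts_keep_longest` also honours the founder's 5′-end bottom-strand
  site, reproducing the regex-trimming reading in which that site is cut
  too; it is not the default because it destroys the forward footprint
  region of every unextended molecule.
- Dereplication canonicalizes each read to the lexicographic minimum of
  itself and its reverse complement (the published pipeline merges
  orientations without naming a canonical strand), sorts by descending
  count, ties lexicographically.
- Clustering merges sequences at unit-cost global edit distance ≤ d
  (substitution = 1, each gap base = 1; backed by edlib and checked against
  a brute-force DP oracle) under single linkage, with pairs whose
  shorter/longer length ratio < 0.87 never merged. The 97% identity
  parameter only tunes the shared-k-mer candidate prefilter (the stand-in
  for the original BLAST pass); enforcing it as a hard post-merge bound
  would contradict the 1–30 mismatch sweep, since 30 mismatches on a
  ~100-mer is far below 97% identity. The prefilter's k is chosen by the
  q-gram pigeonhole bound `k ≤ (m − d + 1)/(d + 1)` (m = shortest sequence),
  guaranteeing — and property-testing — that every true pair is examined;
  if no k ≥ 3 satisfies the bound, all length-compatible pairs are checked.
- Genealogy assignment scores children against the previous sampled
  transfer with local affine-gap alignment (match +5, mismatch −4; a
  length-L gap costs 20 + (L−1)·1). The gap penalties are the published
  ones; match/mismatch are standard DNA scores chosen to be compatible with
  them, and assignments on the simulated suite are insensitive to their
  exact values. Ties are broken uniformly at random under a seeded
  generator. Edge distances are positional Hamming for equal lengths and
  optimal global-alignment mismatch+gap columns (edit distance) otherwise.
  Transfer-1 vertices receive no ancestors.
- Extinction tables report scaled cumulative extinctions truncated (not
  rounded) to three decimals — this reproduces every printed value of the
  published summary, including 230/257 → 0.894 and 249/257 → 0.968. The
  validator flags printed interval extinctions that contradict the count
  differences; the published intermediate-treatment transfer-7 row is such a
  case (1305 − 113 = 1192, printed 1194) and is reported, not reconciled.
- Relative slope: the log-signal slope over the best window of ≥ 5 cycles,
  divided by the mean standard slope. A literal "window strictly inside the
  10–90% band of the plateau" is unsatisfiable even for a pure doubling
  standard (which spends log₂9 ≈ 3.2 cycles there), so candidate windows
  are all ≥ 5-cycle runs *overlapping* the band, ranked by R² (ties prefer
  longer, then earlier). Windows below R² = 0.99 raise a quality error.
  A standard scored against itself gives exactly 1.
- Fold fraction: the qPCR estimate of self-primed starting copies (threshold
  crossing inverted through a standard line of known pre-extended inputs,
  threshold at 50% of the smallest standard plateau so linear growth of
  unextended molecules contributes little) divided by the known total,
  clamped at 1.

## A measured divergence from the wet experiment

In the wet experiment the rising-temperature treatments ended with *higher*
relative slopes than the control. Under this model the direction reverses
(measured at desk scale: control ≈ 0.67 vs sudden ≈ 0.32 mean final-transfer
relative slope): within a transfer, fitness is essentially the probability
of folding at that transfer's temperature, the control sits at 55 °C where
the ancestral stem already folds four times in five, and no stem reachable
by point mutation in eleven transfers folds comparably well at 70 °C. The
wet-lab direction plausibly rests on mechanisms outside this model's scope —
cooperation, recombination/concatemerization, and the evolution of short
super-hairpin genomes with faster per-cycle replication (relative slopes
above 1 in the wet data already imply faster-than-standard amplification,
which no purely fold-limited model produces). The corresponding directional
check is kept in the acceptance suite and reports the measured values; it is
expected to fail under this model, and that failure is informative about the
model boundary, not about the machinery (which the remaining checks cover).

## Known limitations

- The two-state single-stem phenotype cannot represent alternative folds,
  wobble pairs or bulged stems; molecules that would fold via imperfect
  duplexes are scored as non-folders.
- Linear growth of unextended molecules is a modelling convention (+1
  copy/founder/cycle); real single-primer amplification kinetics differ.
- The exhaustive escape checker is limited to k ≤ 2 (enumeration grows as
  (3L choose k)); the headline claim only needs k ≤ 2.
- Genealogy inference assumes the true parent is present in the previous
  sampled transfer; sparse sampling of deep lineages will mis-assign through
  closest surviving relatives, as in the published analysis.
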