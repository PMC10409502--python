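# Methods

## The design problem

An ARTi guide must satisfy two requirements that ordinary shRNA design
trades off: maximal knockdown efficacy and *zero* transcriptome targets.
Because the target site is synthetic and engineered into the transcript of
interest, the design space is unconstrained by any gene — the only job is
to find 22-mers that look like the best-performing natural guides while
their seed region matches nothing that exists.

The package encodes this as a degenerate base-composition matrix,
`TTCGWWWNNAHHWWCATCCGGN`:

| positions | code | rationale |
|---|---|---|
| 1–4 | `TTCG` fixed | 5′ T is favoured for RISC loading; `TCG` is among the rarest seed-start triplets in low-off-target seed sets |
| 5–7 | `W` (A/T) | keeps the guide 5′ end thermodynamically loose, preserving 5′→3′ duplex asymmetry |
| 8–9 | `N` | unconstrained |
| 10 | `A` fixed | efficacy-associated |
| 11–12 | `H` (A/C/T) | efficacy-associated, G excluded |
| 13–14 | `W` | asymmetry, as 5–7 |
| 15–21 | `CATCCGG` fixed | efficacy-associated 3′ half; the G at position 20 means the passenger strand starts with C and cannot be RISC-loaded |
| 22 | `N` | unconstrained (position 22 is not part of the mature seed-pairing region) |

The matrix expands to 2⁵·4³·3² = 18,432 candidates, enumerated in
lexicographic order for reproducibility.

## Scoring

The published workflow ranks candidates with an external linear-model
predictor (DSIR, threshold > 105). Those coefficients are not ours to
re-implement, so the scorer is a *pluggable callable*; the default is a
position-frequency-matrix log-odds score

    S(g) = Σₚ log((f[p, g[p]] + c) / (0.25 + c)),   c = 0.01

against the PFM of the six validated guides. The score is additive per
position, zero under a uniform PFM, and uniquely maximal at the consensus
of an indicator PFM. The `score_threshold` config field carries the
"score > X" semantics of whatever scorer is plugged in; with the default
scorer no threshold is applied unless set. The pseudocount keeps the score
finite when a base has zero observed frequency; 0.01 is small enough not
to perturb the ranking of frequent bases.

## Off-target screening

Orientation convention: a guide silences transcripts that *contain the
reverse complement* of its seed region, so the k-mer index built over
transcript sense strands is queried with `revcomp(seed)`. Whether a
published screen also checked the guide-strand text is unknowable from the
sequences alone, so `--both-orientations` additionally queries the
guide-strand text; the default is complement-only.

* **Extended-seed elimination (k = 13, guide positions 2–14).** Exact
  membership; any hit eliminates the candidate. Overlapping occurrences
  are counted; windows containing N are skipped, so an ambiguous base in a
  transcript can never create a "perfect match" (conservative in the
  direction of keeping candidates, matching the exact-match semantics).
* **Seed off-target burden (k = 7, positions 2–8).** Raw complement-hit
  count over a 3′-UTR set, normalised per indexed sequence. This is a
  hit-count analogue of published seed-potential scores, deliberately
  unweighted (per-site context weights are a property of the external
  tool, not of this package) and labelled accordingly.
* **Percentiles.** Ascending mean-rank: `100·(rank − 0.5)/n`, ties share
  the mean rank; "top 1 %" means percentile ≤ 1. The convention makes a
  unique minimum in a universe of 1000 land at 0.05.

No transcriptome is bundled; the index is build-agnostic and takes any
FASTA (cDNA or UTR set).

## Construct grammar

A miR-E 97-mer is `flank5(18) + sense(22) + loop(19) + guide(22) +
flank3(16)`. The sense strand is `revcomp(guide)` with position 1 replaced
by C. That substitution is not documented in the format description; it
was derived by decomposing all six validated 97-mers against the canonical
flank/loop strings, is consistent across all six, and is guarded by
bit-exact golden tests. `parse_97mer` is the exact inverse and reports
which fixed segment mismatches (flank5/loop/flank3/sense) on failure.

CDS cassettes prepend the fewest `A` bases needed to reach a multiple of 3
(two 22-nt sites → pad `A`, 45 nt), matching the published in-frame
insertion; padding uses `A` only and is prepended. In-frame stop codons
(TAA/TAG/TGA, frame 1) are reported as a warning, not an error — the
published cassette is verified stop-free by the test suite. UTR cassettes
are plain concatenations.

## Assay quantification

Knockdown efficiency from two-colour flow events: with
`r = mean(GFP | mCherry⁺) / mean(GFP | mCherry⁻)`,

    raw_kd        = 1 − r
    normalized_kd = 1 − r / r_control

where the control table comes from a neutral hairpin (Ren.713).
"Normalised to" is interpreted as a ratio of residual expressions (the raw
value is always reported alongside, so a difference-of-efficiencies
convention is recoverable). `r > 1` is reported as negative knockdown and
flagged, not rejected. Marker positivity must be supplied as a boolean
column — no auto-gating.

DE filter: a gene is up if log₂FC ≥ 2 and −log₁₀ p ≥ 5, down if
log₂FC ≤ −2 with the same significance cut. A literal reading of
"≤ 2 (down)" would count unchanged genes as down-regulated; the symmetric
reading is the default and the literal variant is available via
`DEFilterConfig(literal_down=True)`.

Tumor volume follows the caliper formula `length · diameter² · π/6` (mm³).

## Synthetic fixtures

Generators exist so that every stage has an input with *exact* ground
truth: transcriptomes with planted motifs at recorded positions, seed
universes whose 5′-triplet mixture is planted (the uniform remainder
excludes the listed triplets, so the expected planted fraction equals the
mixture exactly), flow-event tables with lognormal noise around a known
residual expression (unit-mean noise, so the estimator is unbiased for the
planted residual), and DE tables with exact planted up/down counts.
Backgrounds are i.i.d. at a stated GC content — sufficient for exact-match
screens, but not a model of real transcriptome composition: real 3′-UTRs
have strong dinucleotide and repeat structure, so passing tests demonstrate
the correctness of the operations, not the empirical hit rates one would
measure on a real transcriptome. All generators are bit-reproducible under
a fixed integer seed; the suite's default is 20230808.

Test and fixture sizes (synthetic transcriptomes of tens of records ×
hundreds of nt, 10⁴-event flow tables, 10³–10⁴-seed universes) were chosen
as the smallest sizes at which binomial/Monte-Carlo tolerances (3 standard
errors) are meaningfully tight.

## Known limitations

* Exact k-mer matching only — no alignment-based or wobble/mismatch
  off-target search, no miRNA-style context scoring or conservation.
* The default efficacy scorer ranks by similarity to a six-guide pool; it
  is a stand-in interface, not a validated efficacy predictor, and scores
  are not comparable across PFMs.
* Genome-scale statistics (e.g. seed-triplet fractions of a real
  low-off-target seed universe, transcriptome-wide elimination rates)
  require external data; the package provides the operations and verifies
  them on planted mixtures only.
* Cloning logistics (vector maps, restriction sites, Gibson arms) are out
  of scope; the output stops at the 97-mer oligo and cassette sequences.
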