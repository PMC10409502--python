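# arti

Design of synthetic, ultra-potent, off-target-free shRNAmir guides for
**artificial RNA interference (ARTi)**.

Conventional RNAi target validation designs a new hairpin for every gene,
and every new hairpin brings its own knockdown efficacy and its own
seed-mediated off-target spectrum. ARTi inverts the workflow: a synthetic
guide with **no target anywhere in the transcriptome** is designed and
validated once, and any gene of interest is made repressible by engineering
the guide's 22-nt target site into its transcript (in-frame before the stop
codon, or into the 3′-UTR). Expressing the hairpin in engineered versus
wild-type cells then gives full, built-in control over on- and off-target
effects.

This package implements the computational side of that workflow:

- **Candidate enumeration** from a 22-position degenerate base-composition
  matrix, `TTCGWWWNNAHHWWCATCCGGN` (IUPAC: W = A/T, H = A/C/T,
  N = A/C/G/T), which encodes efficacy biases at fixed positions, a
  low-off-target `TTCG` seed start, A/T biasing at positions 5–7 and 13–14
  to preserve 5′→3′ duplex asymmetry, and a fixed G at guide position 20 so
  the passenger strand cannot be RISC-loaded. The matrix expands to
  2⁵·4³·3² = 18,432 concrete guides.
- **Efficacy scoring** via a pluggable scorer (default: position-frequency
  matrix log-odds, `Σₚ log((fₚ,ᵦ + c)/(0.25 + c))` with pseudocount
  c = 0.01); external predictors such as DSIR drop in as a callable.
- **Seed-level off-target screening** against any transcriptome FASTA: a
  k-mer index over transcript sense strands is queried with the reverse
  complement of the guide's *extended seed* (positions 2–14); any perfect
  13-mer match eliminates the candidate. A 7-mer variant scores seed
  (positions 2–8) complement burden across 3′-UTR sets and percentile-ranks
  seed universes.
- **Construct assembly**: miR-E 97-mer cloning oligos
  (5′ flank · sense · loop · guide · 3′ flank, with the sense strand being
  the reverse complement of the guide carrying a C at position 1), in-frame
  CDS target-site cassettes (A-padded to a multiple of 3, stop-codon
  checked) and 3′-UTR cassettes.
- **Assay quantification**: reporter knockdown efficiency
  (1 − mean GFP(mCherry⁺)/mean GFP(mCherry⁻), normalised to a neutral
  control hairpin), de-regulated-gene counts from DE tables
  (|log₂FC| ≥ 2 and −log₁₀ p ≥ 5), and caliper tumor volume
  (length · diameter² · π/6).
- **Synthetic fixtures** with exact ground truth (planted seed matches,
  planted triplet mixtures, simulated flow events) so the whole pipeline is
  testable without downloads.

## Worked example

```python
from arti import design_guides, assemble_97mer

res = design_guides()           # built-in matrix, empty off-target screen
print(f"{res.n_candidates} candidates, {len(res.survivors)} survivors")
for rec, con in zip(res.selected[:2], res.constructs[:2]):
    print(rec.guide.bases, f"score={rec.efficacy_score:.2f}")
    print("  target site:", rec.target_site.bases)
    print("  97-mer:", con.oligo.bases)
```

prints

```
18432 candidates, 18432 survivors
TTCGAATAAAACATCATCCGGA score=25.92
  target site: TCCGGATGATGTTTTATTCGAA
  97-mer: TGCTGTTGACAGTGAGCGCCCGGATGATGTTTTATTCGAATAGTGAAGCCACAGATGTATTCGAATAAAACATCATCCGGATGCCTACTGCCTCGGA
TTCGAATAAAATATCATCCGGA score=25.92
  target site: TCCGGATGATATTTTATTCGAA
  97-mer: TGCTGTTGACAGTGAGCGCCCGGATGATATTTTATTCGAATAGTGAAGCCACAGATGTATTCGAATAAAATATCATCCGGATGCCTACTGCCTCGGA
```

The guide is the 22-nt small RNA loaded into RISC; the target site is its
reverse complement, ready for cassette insertion; the 97-mer is the
single-stranded oligo to order and clone into a miR-E expression vector.
With a transcriptome supplied, any candidate whose extended seed has a
perfect match is eliminated before selection:

```sh
arti design --transcriptome cdna.fa --n-select 6 --out design_out/
arti validate design_out/oligos_97mer.fa --out check/
```

The same CLI exposes `screen`, `assemble`, `cassette`, `simulate` and
`quantify` subcommands; every run writes a `run_manifest.json` with the
parameters and input digests.

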