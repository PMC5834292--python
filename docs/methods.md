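# Methods

## Somatic variant calling

Calling operates on per-site pileup observations (one record per read base:
allele, base quality, mapping quality, read length, mismatch count) for a
tumor and a matched normal. Two read-level hygiene filters are applied
before any counting, mirroring what a BWA + Picard exome pipeline leaves
behind: reads with mapping quality < 30 are removed, and so are reads whose
mismatch count exceeds 5 % of the read length (we read the mismatch rule as
a per-read fraction of read length; a per-site "fraction of reads with
mismatches" reading is possible but does not match how per-read alignment
records are filtered in practice). Bases with Phred quality < 15 are then
excluded from all allele counts — the base-quality criterion is an
observation filter, not a per-site summary, because quality is a property
of the individual base call.

For every non-reference allele observed in the filtered tumor pileup, six
criteria decide the call, with the stated boundary semantics:

| criterion      | default | bound      |
| -------------- | ------- | ---------- |
| base quality   | 15      | inclusive (bases ≥ 15 are counted) |
| depth          | 10      | inclusive, applied to tumor **and** normal |
| variant depth  | 4       | inclusive  |
| tumor VAF      | 0.10    | inclusive  |
| normal VAF     | 0.02    | strict (<) |
| Fisher p       | 0.05    | strict (<) |

The depth criterion's sample is not fully specified by convention; we apply
it to both samples, since a shallow normal cannot support the normal-VAF
or Fisher criteria. When no germline control exists (established cell
lines), calls are variants against the reference, not strictly somatic;
the caller itself is unchanged.

The Fisher exact test is one-sided for alt enrichment in tumor (the
somatic-caller convention; two-sided is selectable via
`CallingParams(fisher_alternative="two-sided")`). It is computed by exact
big-integer hypergeometric summation — the only floating-point rounding is
the final division — and is cross-checked in the tests against both a
brute-force table-enumeration oracle (exact rational arithmetic) and
`scipy.stats.fisher_exact`.

Multi-allelic sites emit one record per alt allele in lexicographic order;
indel alleles are carried as VCF-style strings and trimmed/left-shifted by
shared-prefix/suffix normalization. Coordinates are 1-based VCF throughout.

## Neoepitope screening

Missense mutations are derived from CDS-level single-nucleotide changes via
standard-code translation (synonymous and stop-gain changes are classified
and excluded; frameshift/indel-derived neoepitopes are out of scope — the
enumeration rule covers amino-acid substitutions only). For a substitution
at protein position p, every window of length L ∈ {8, 9, 10, 11} of the
mutant protein containing position p is emitted with its wild-type
counterpart; the number of windows is Σ_L [min(p, n−L+1) − max(1, p−L+1) +
1]⁺ (38 for an interior position), verified against brute force.

The screening order is fixed: IC50 ≤ 500 nM (the conventional binder
definition, inclusive per "or lower"), then mutant RNA evidence ≥ 1 read
(mutant-allele-specific reads, not locus coverage), then tier assignment
with the priming tier at IC50 ≤ 50 nM. Wild-type IC50 and the
cross-reactivity flag are computed for every survivor.

Cross-reactivity risk is `high` iff the substitution offset is an HLA
anchor position **and** the wild-type analog binds. Anchors default to
{2, 9} for both HLA-A\*02:01 and HLA-A\*24:02 (both alleles use the
canonical P2/PΩ anchors) and are configurable per allele; the "wild type
also binds" condition is operationalized as wt IC50 ≤ 500 nM — the same
binder definition as the discovery filter — rather than a mutant/wild-type
ratio, which keeps the criterion threshold-compatible with the rest of the
pipeline (a ratio mode can be composed from the annotated columns).

Affinity predictions are pluggable: a tab-delimited table
(`peptide, hla_allele, ic50_nm`, the essential columns of
binding-predictor output) or the built-in toy position-weight-matrix
predictor. The toy PWM assigns each position a residue score, with anchor
columns (2 and C-terminal) strongly favoring the allele's canonical
residues, and maps the summed score S to IC50 = scale·exp(−S), scaled so
the consensus peptide scores exactly 1 nM. It is deterministic and
rank-sensible but **not** a trained affinity model; it exists so the
pipeline runs hermetically, and any conclusion about real peptides requires
a real predictor through the table interface.

## TCR repertoire decomposition

Amplicon reads are modeled as single merged sequences of the form adapter +
V + junction insert + J + constant-region tail. V and J assignment uses
local alignment (match +2, mismatch −3, gap −5; Biopython's
`PairwiseAligner`) of the read against every germline segment of a chain;
an assignment is accepted when the score reaches 80 % of the segment's
perfect score, which rejects random sequence while tolerating scattered
errors, and ties break to the lexicographically smaller segment name. When
the chain is unknown both are tried and the higher combined V+J score wins.

CDR3 delimitation follows the IMGT convention: from the first base of the
V segment's conserved 2nd-CYS codon through the last base of the J
segment's conserved F/W (of the F/W-G-X-G motif), both inclusive, located
on the read by mapping the germline anchor coordinates through the local
alignments. A junction whose span is not a multiple of 3, or whose
translation contains a stop, is kept but marked non-productive.

Clonotype identity is (chain, V, J, CDR3 nucleotide sequence); amino-acid
collapse is available but not the default, since nucleotide identity is
what distinguishes convergent rearrangements. Because a per-base error
rate of ε leaves a fraction ≈ 1 − (1−ε)^|CDR3| of a clonotype's reads with
corrupted CDR3s, aggregation by default absorbs satellites — clonotypes
with the same chain/V/J/length within one mismatch of a clonotype at least
5× larger (child ≤ 0.2 × parent reads) — into their parent, the standard
repertoire-tool treatment of sequencing-error inflation. Reads with ≥ 2
CDR3 errors (≈ 1 % at ε = 0.005 and a 27–30 nt CDR3) remain as rare
singletons; this bounds the frequency bias well below the ±0.02 recovery
tolerance used in the tests. Frequencies are fractions of assigned reads
per chain (pie-chart semantics; reads, not cells).

The dominant pair is the top-frequency clonotype of each chain; the
repertoire is called "dominated" when both top frequencies reach 0.5. The
0.5 threshold is a package choice — qualitative dominance has no standard
numeric definition — and is configurable.

## Synthetic data generators

All generators are pure functions of (spec, seed) via
`numpy.random.default_rng`; identical seeds give byte-identical files.

**Pileups.** Depths are Poisson around the configured means (default 100);
tumor reads at a planted site carry the alt allele with probability VAF
(default 0.20), and every base is then miscalled with probability ε
(default 0.01) to a uniformly chosen other base. Base qualities are drawn
bimodally (Q37/Q12) with miscalled bases enriched for low quality (25 %
high-quality vs 95 % for correct calls), reflecting that Phred quality
tracks error probability; this is what makes the base-quality criterion an
effective error filter, exactly as in real data. Mapping qualities are 60
with a 3 % low-MAPQ (20) fraction; per-read mismatch counts are
Poisson(1). The model has uniform substitution errors only — no indel
errors, strand bias, GC/coverage structure or mapping artifacts — so
passing recovery tests demonstrates the criteria's filtering logic, not
performance on real exomes.

**Proteome.** Random CDS (ATG + uniform sense codons + TAA), protein
lengths uniform on [100, 400]; planted changes are uniform single-base
substitutions redrawn until missense. Mutant RNA read counts are
zero-inflated (25 % zeros, else 1 + Poisson(30)) to exercise the
expression filter. A specified peptide can be embedded around the planted
substitution (choosing a wild-type/mutant codon pair one nucleotide apart)
for fixture tests.

**Repertoire reads.** A clone mixture (default 0.7/0.2/0.1 over three
clones, 10,000 reads, ε = 0.005) where each clone has one TRA and one TRB
rearrangement over the in-repo synthetic germline set (4 V and 4 J per
chain, structurally valid anchors, deterministic sequences — labeled
synthetic stand-ins, not IMGT alleles). Each read picks a clone, then a
chain uniformly, and copies the template with substitution errors. Read
ids carry the truth labels.

## Numerical and design notes

- VAF boundary comparisons are plain float comparisons; counts like 10/100
  and 1000/10000 round to exactly the same double as the 0.10 literal, so
  the inclusive bounds behave exactly at the printed precision.
- The Fisher p is exact; the oracle agreement tolerance of 1e-12 over all
  tables with row margins ≤ 30 is limited only by the final float division.
- Simulation sizes in the default test run (hundreds of sites/reads for
  unit tests, the full 1,000-site and 10,000-read conditions in the
  acceptance-style tests) were chosen to make binomial sampling noise small
  relative to the asserted tolerances.
- Degenerate inputs: empty pileups are no-calls; an empty clonotype list is
  an error for dominance; a missing affinity prediction raises rather than
  silently dropping a candidate.

## Known limitations

- The caller handles indel alleles as opaque strings from the pileup; it
  does not realign or left-shift against a reference genome beyond
  prefix/suffix trimming.
- The toy PWM is not an affinity model; IC50 values are only meaningful
  relative to its own scale.
- V/J assignment is exhaustive pairwise alignment, adequate for germline
  sets of tens of segments; a full IMGT reference would want a seeded
  aligner.
- Bulk dominance pairs TRA with TRB statistically, not physically; true
  chain pairing requires single-cell data.
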