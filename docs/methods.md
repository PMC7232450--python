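# Methods

## Model and definitions

`syndinuc` scores the representation of a dinucleotide *j* at a frame
position *h* of a coding sequence against the null hypothesis of **equal
synonymous codon usage**. The unit of synonymous variation is the amino
acid for the two within-codon positions (`pos1` = codon nucleotides 1–2,
`pos2` = 2–3) and the *ordered* amino-acid pair for the bridge position
(codon nucleotide 3 plus the next codon's nucleotide 1); order matters
because the bridge dinucleotide is direction-dependent.

For a unit *i*, the expected proportion *e<sub>i,j,h</sub>* is the fraction
of its equally weighted synonymous codons realising *j* at *h*. At the
bridge it factorises exactly as P(third nucleotide of *a*) × P(first
nucleotide of *b*) under uniform codon usage, which equals the fraction over
all synonymous codon pairs; the test suite asserts this identity against
brute-force pair enumeration. The statistic is the abundance-weighted mean
of observed/expected ratios,

SDU<sub>j,h</sub> = Σ<sub>i</sub> n<sub>i</sub> (o<sub>i,j,h</sub>/e<sub>i,j,h</sub>) / N,

its maximum is Σ n<sub>i</sub>/e<sub>i</sub>/N (every synonymous slot uses
*j*), and RSDU = SDU/SDU<sub>max</sub> ∈ [0,1]. RDA is the odds ratio
f(XY)/(f(X)f(Y)); RSCU(c) = count(c)·m/Σ counts over the m synonyms of c's
amino acid.

### Unit inclusion

Units with *e* = 0 cannot carry the dinucleotide synonymously; they are
excluded from both the weighted sum and N. Including them would force
SDU < 1 under the null itself, destroying the interpretation of 1 as null
agreement. Units with *e* = 1 contribute a ratio of exactly 1 and are
included by default; `include_e1_units=False` drops them (this changes the
weighting of informative cells whose unit set mixes *e* = 1 and fractional
*e* units, and makes some cells undefined). The default was chosen because
it keeps every non-informative cell at exactly 1 and every informative cell
centred on 1, and the two conventions coincide wherever all contributing
units have fractional *e*.

A cell with *no* contributing unit in a given sequence is reported as
missing (None), never as 0. Cells where every reachable *e* equals 1 are
*non-informative*: emitted with value 1 and an explicit flag, never silently
dropped. Informativeness is a property of the (dinucleotide, position) pair
— "some unit has 0 < e < 1" — which under the standard code yields 37
informative cells of 48, with 11 of 16 dinucleotides non-informative at
pos1 (only Arg, Ser, Leu vary there).

### RDA frame-position mode

The classical RDA is defined genome-wide. The per-position variant here
uses the dinucleotide frequency at that frame position as numerator and
*slot-specific* mononucleotide marginals as denominator (codon slots 1×2 for
pos1, 2×3 for pos2, 3×next-1 for the bridge). Slot-specific marginals are
the only choice for which slot-independent composition gives RDA = 1
exactly; a whole-sequence mode (`pos=None`) is also provided.

## Input handling

FASTA records (via Biopython) are validated per record: length divisible by
3, no internal stops (strict default; a lenient flag truncates at the first
internal stop instead), one trailing stop permitted and trimmed. DNA/RNA
and case are normalized to uppercase RNA; all reported dinucleotides use U.
Codons containing IUPAC ambiguity codes are kept in frame but masked out of
every count, together with the two bridge pairs touching them — no
resolution by guessing. Records are analysed independently; the pooled mode
concatenates records with a masked NNN spacer codon, so pooled counts are
exactly the summed per-record counts and bridge pairs never span records.
Stop-adjacent bridge pairs do not arise: stops are trimmed or rejected
before pairing.

## Monte-Carlo null

The error distribution of SDU/RSDU for a concrete sequence is obtained by
redrawing every codon independently and uniformly from its amino acid's
synonymous set (the aa sequence is fixed), recomputing the metric, and
repeating `n_iter` times (default 1000). The resampling deliberately
preserves neither GC content nor codon counts — equal synonymous usage is
the hypothesis being sampled. Under it E[SDU] = 1 exactly for every
informative cell.

Significance uses the min–max envelope of the resamples by default
("under"/"within"/"over"); a two-sided quantile rule (default 2.5–97.5%) is
available as a more robust option. The range rule's nominal coverage for a
null-distributed observation is ≈ 1 − 2/(n_iter+1), which the suite checks
empirically.

Determinism: one seeded `numpy` Generator; multi-record runs derive a
per-record substream from (seed, CRC32(record id)), so results do not
depend on record order. The production path is vectorised — a single
uniform matrix of codon choices mapped through small integer lookup tables
— and is asserted bit-identical to the scalar resample-then-recompute route
for the same seed, so the fast path is not a separate model.

## Synthetic data

`random_protein` draws i.i.d. amino acids, by default **uniform over the 20
residues** — a deliberate neutral choice, configurable to any weighting
(e.g. an empirical viral composition). `random_cds` attaches codons drawn
uniformly among synonyms, i.e. generates exactly under the null. The
length-vs-error experiment simulates one protein per length on the ladder
700–7000 residues in steps of 700 (10% of the longest), computes the
CpG-bridge null with 1000 resamples each, and reports its sd; this full
scale runs in a few seconds, and the acceptance script measures the single
length 5,667 aa (~17,000 nt), where the sd comes out just below 0.05 under
the uniform composition. What the generator does *not* emulate: amino-acid
autocorrelation, codon-usage bias, GC heterogeneity and selection on
dinucleotides in real genomes — so passing calibration tests demonstrates
correctness of the machinery under the stated null, not that real sequences
are null-distributed.

## Numerical choices

All computation is double precision; published-value comparisons in the
optional integration suite use 2-decimal rounding, matching the precision
those values are reported at. Summary statistics of a null distribution are
always recomputed from the stored samples; sd is the sample standard
deviation (ddof = 1). Uniform synonym choice uses floor(u·m) on one uniform
per site, clipped defensively at m−1. Degenerate inputs: single-codon
sequences have no bridge pairs; all-Met/Trp proteins make many cells
undefined — both are reported as missing values rather than numbers.

## Known limitations

- Single CDSs only: no ORF discovery, GenBank parsing or genome annotation.
- The null conditions on the amino-acid sequence; metrics confound
  mutational and selective causes of synonymous skew by design.
- RSDU's null expectation varies between cells (that is its purpose), so
  only its relative magnitudes are comparable.
- Alternative NCBI translation tables are supported by injection
  (`GeneticCode.from_ncbi_table`), but the informative-cell structure then
  differs from the 37/48 of the standard code.
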