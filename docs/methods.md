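# Methods

This note documents the models, conventions and design choices behind
`kdrkit`: what each stage assumes, which parameters matter, what the
synthetic-data generator does and does not emulate, and where the design was
genuinely open.

## Gene model and mutation sites

The unit of analysis is a codon-level mutation site on the coding strand of
the house fly voltage-sensitive sodium channel (VSSC, *para*-like). A site is
defined by its codon number (house fly *para* numbering, taken from the
mutation name), wild and mutant codons differing at exactly one position (the
*variable position*), and a guide anchor sequence used to locate the codon in
a sequenced fragment. The packaged model carries the four canonical sites:

| site   | wild → mutant codon | variable position | guide (coding strand)  | codon offset |
|--------|---------------------|-------------------|------------------------|--------------|
| M918T  | ATG → ACG           | 2                 | `AATTTACTCATTTCGATTAC` | 0            |
| T929I  | ACA → ATA           | 2                 | `GGTGCATTGGGTAATCTGAT` | 0            |
| L1014F | CTT → TTT           | 1                 | `ACGGTCGTGATCGGCAATT`  | −1           |
| L1014H | CTT → CAT           | 2                 | `CGGTCGTGATCGGCAATCA`  | 0            |

`codon offset` is the codon start relative to the end (exclusive) of the
guide match. The L1014F offset of −1 is forced by the published primer and
guide sequences themselves: the allele-specific primer kdr2
(`GTCGTGATCGGCAATT`) must discriminate with its 3′-terminal base on the
codon-1014 variable position, and the reverse-complement of kdr3
(`CTTGTGGTAAGTTGACG`) begins with the susceptible codon `CTT` — so the
18-mer context `ACGGTCGTGATCGGCAAT` abuts codon 1014 directly and the L1014F
guide's final `T` *is* the resistant variant base. Anchor matching therefore
masks codon positions when counting mismatches, so a guide that spells one
allelic variant anchors sequences of every genotype.

The wild/mutant codons for M918T and T929I are conventions: only the amino
acid substitutions are fixed by the mutation names, and the single-base-change
invariant forces `ATG→ACG` and (among synonymous options) we chose
`ACA→ATA`. L1014F and L1014H are forced exactly (`CTT→TTT`, `CTT→CAT`) by
the amino acids under the standard code.

Both codon-1014 tests are modeled as *independent* sites. On the packaged
synthetic reference the L1014H test is given its own locus (guide immediately
5′ of its own test codon) rather than overlapping the L1014F codon; this
keeps the four assays orthogonal and the generator-truth round trip exact,
at the cost of not representing L1014F/L1014H compound heterozygotes as a
single physical codon. Real data with an apparent compound signal at codon
1014 would be reported as two independent RS calls.

## Sequence-based genotyping

Inputs are base-called consensus sequences (gDNA or cDNA) in which
heterozygous positions carry IUPAC ambiguity codes; chromatogram (AB1)
processing is out of scope — a C/T double peak is assumed to have been
base-called as `Y`. Parsing is case-insensitive and accepts `U` for `T`.

Anchor search scans both strands with at most `max_mismatches` (default 1)
IUPAC-compatible mismatches outside the codon footprint. The best placement
minimizes (masked mismatches, then raw mismatches); a residual tie is an
explicit ambiguity error rather than an arbitrary pick — silent wrong-locus
calls are worse than a loud failure. Reverse-strand matches report
coordinates on the forward query; internally coordinates are 0-based
half-open, CSV output is 1-based.

The genotype rule at the extracted codon: variable base equal to the wild
base → SS; equal to the mutant base → RR; equal to the IUPAC code whose
expansion is *exactly* {wild, mutant} → RS; anything else — a third allele, a
wider ambiguity (e.g. `H`), a mismatching non-variable position, a truncated
codon, a missing anchor — is INDETERMINATE. This is deliberately
conservative: a triple-ambiguity code is never promoted to RS.

Input form is inferred from anchor spacing: the M918/T929 block and the
codon-1014 block are contiguous on cDNA but separated by a large intron
(~1700 bp by default) on gDNA. Spacing within 100 bp of the reference
spacing → cDNA; at least the reference spacing plus 90% of the intron →
gDNA; otherwise unknown.

## In-silico PASA

Allele-specific PCR is simulated purely mechanically: a primer primes at a
footprint if its 3′-terminal base(s) (default: 1) match the template exactly
and internal mismatches do not exceed a cap (default: 0). Thermodynamics,
annealing temperatures and secondary structure are not modeled; the
3′-terminal rule is the textbook PASA discrimination mechanism and suffices
to reproduce the assay logic. The primer table labels kdr2 "reverse" and
kdr3 "forward", but valid products require each reaction pair to contain
opposite-facing primers; the simulator trusts geometry over labels and logs
the discrepancy.

Amplicons are end-to-end inclusive lengths between a forward-priming and a
facing reverse-priming site within a maximum product length (default
1000 bp). Band interpretation matches measured sizes to the nominal expected
sizes (480 control / 200 susceptible / 280 resistant) within a fractional
tolerance (default ±10%, configurable — gel sizing is approximate):
control + 200 → SS, control + 280 → RR, all three → RS, and *no control band
means a failed assay*, hence INDETERMINATE regardless of other bands.

Geometry of the packaged reference: with the published primers, the
susceptible product (kdr1→kdr3) and resistant product (kdr2→kdr4) both pivot
on the codon-1014 base, so their footprints overlap by 32 bp and the control
product is structurally 200 + 280 − 32 = 448 bp. The three nominal sizes
(480/280/200) would require adjacent, non-overlapping inner amplicons, which
no single-base allele-specific design can achieve. The packaged reference
therefore keeps the allele-informative bands exact (200 and 280 bp) and
yields a 448-bp control, which the nominal 480-bp class absorbs within the
±10% tolerance. The K1/K2 sequencing amplicon measures exactly 448 bp.

## Population statistics

* Allele frequency uses the standard 2N denominator.
* The packaged survey's "% kdr alleles" column divides by a *fixed* 32 allele
  copies (a nominal 16 flies/site) for every location, regardless of N; the
  module exposes `denominator_alleles` so both conventions are available,
  with 2N the default in summaries and 32 used in the reproduce-published
  mode. The fixed-32 convention is reproduced, not endorsed. One cell of the
  published column (Hili, printed 15.6) is inconsistent with its own printed
  counts (which give 18.8 under any consistent convention) and is treated as
  a typo.
* The HWE test uses no Yates continuity correction and df = 1 (three genotype
  classes − 1 − one estimated allele frequency); both choices are verified by
  exact reproduction of the published per-location chi-squares (max
  |error| < 1e−4 across all 19 rows). Monomorphic populations report χ² = 0
  with an undefined p-value and are excluded from deviation counts.
* No multiple-testing correction is applied across locations by default (an
  optional Bonferroni flag exists), matching how such surveys are reported.
* Display percentages round half-up to one decimal; CSV numeric columns keep
  full precision. The aggregate heterozygote share of the packaged survey is
  102/279 = 36.56%, which the source table prints as 36.5 (truncated); the
  package reports the exact fraction.

## Bottle bioassay

Mortality series live on the 0–120 min grid at 15-min steps; series must be
monotone with death counts within [0, n]. Bottles are pooled (sum of dead /
sum of exposed) rather than averaged per bottle, matching aggregate-mortality
reading of bottle-bioassay guidelines. Control mortality is handled with
Abbott's correction, clamped to [0, 1]; control mortality above 10%
invalidates the run (standard practice — the correction becomes unreliable),
and any nonzero control correction is logged.

The diagnostic dose is the smallest dose at which every susceptible-strain
bottle reaches 100% kill within the window; the diagnostic time is the
earliest grid time at which that dose achieves it in all bottles. Field runs
are susceptible iff pooled corrected mortality at the diagnostic time reaches
the threshold, default 100% (every susceptible reference row shows complete
kill at the diagnostic time); softer CDC-style thresholds (90%/97%) are
available via the `threshold` parameter but off by default.

## Synthetic-data generator

The generator defines the study conditions and makes every stage testable:

* **Genotypes** are drawn per individual with P(RR) = p² + Fpq,
  P(RS) = 2pq(1−F), P(SS) = q² + Fpq. F is an inbreeding-style *testing
  device* for HWE-deviating fixtures, not an inference claim. Defaults
  (N = 16, p = 0.34375) mirror the packaged survey's headline location.
* **Sequences** are rendered from a deterministic, explicitly non-biological
  700-bp synthetic cDNA reference built from a fixed internal seed, with
  every guide and primer footprint embedded at the geometry described above;
  candidate random fillers are rejected until all anchors are unique and all
  primer site counts are exact on wild, heterozygous and mutant renderings.
  gDNA renderings insert a 1700-bp intron (GT…AG) between the 918/929 and
  1014 regions; heterozygotes become IUPAC codes in consensus sequences and
  are phased arbitrarily in haplotype pairs (phase is irrelevant to PASA).
* **Bioassays** use a logistic-in-time cumulative kill probability with two
  interpretable parameters (midpoint, slope) per resistance status, a
  full-kill time that guarantees monotone completion (60 min susceptible,
  90 min resistant), deterministic expected-curve mode by default and
  per-insect sampled death times in stochastic mode. The susceptible
  calibration ladder (1.0, 2.0, 4.5, 9.0 µg/ml) is engineered so the
  diagnostic resolves to 4.5 µg/ml at 60 min.
* **Worked-example tables** (the 19-location genotype survey and the
  16-location bioassay outcomes) are packaged verbatim as module constants
  and written to CSV on demand, alongside a six-fly demonstration FASTA
  covering all genotype classes.

What the generator does **not** emulate — and hence what passing tests do not
show about real data: sequencing error, chimeras and low-quality base calls;
chromatogram peak shapes; the real genomic coordinates and inter-primer
distances of the VSSC gene (the packaged geometry is a reconstruction);
linkage between sites (sites are simulated independently); multi-generation
selection dynamics; and between-bottle heterogeneity beyond binomial noise.

## Numerical choices and problem sizes

Determinism: all simulations take explicit integer seeds (NumPy
`default_rng`); identical seeds give byte-identical outputs. Chi-square
p-values come from `scipy.stats.chi2.sf`. Oracle-equivalence tests compare
the codon classifier against full IUPAC-expansion enumeration (all 15³
codons per site) and the HWE statistic against a from-first-principles
implementation at 1e−9. Monte-Carlo checks use 2,000 replicates at
p = 0.3, N = 100 for the HWE type-I error (accepted band 0.03–0.08 — the χ²
approximation is only approximate at moderate N), 10,000 replicates of
N = 16 for the allele-count expectation, and 500 stochastic replicates for
resistant-classification recovery; these sizes give stable verdicts while
keeping the default suite fast.

## Known limitations

* INDETERMINATE is the only escape hatch for messy codons; there is no
  quality-weighted or probabilistic calling.
* The PASA simulator's binary priming rule ignores partial extension and
  primer-dimer artifacts; gel tolerance is a single symmetric fraction.
* The HWE test is the asymptotic chi-square, not an exact test — small or
  skewed samples (several survey locations have N < 10) inherit its known
  anticonservatism/conservatism; the published survey used the same
  statistic, which is why it reproduces exactly.
* Bioassay classification at the 100% threshold is knife-edged by design; a
  single surviving fly flips a location to resistant, exactly as in the
  underlying field protocol.
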