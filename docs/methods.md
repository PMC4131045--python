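# Methods

This note documents the models and procedures implemented in `retrocensus`,
the parameter choices that matter, what the synthetic-data generator does and
does not emulate, and the numerical decisions taken where the design was
genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Reference library

Classification rests on the reverse-transcriptase (RT) domain, the most
conserved protein region of LTR retroelements. A `ReferenceLibrary` holds
amino-acid domains tagged `id|family|type|domain_kind` in protein FASTA,
plus a catalogue mapping each of eleven element types (Kobel, Hydra3.1,
Hydra1.1, Mtanga, Amn-san, Cer, Gmr, Mag, MuERV, SnRV, XEN1) to its family
and an average element length (AEL, bp) used by the census. GAG/POL/ENV/CHR
entries support a minimal element-integrity screen; ENV references exist
only for Retroviridae (the envelope gene distinguishes retroviruses) and a
chromo-domain reference only for the chromovirus-like Amn-san.

The bundled library is **synthetic**: one random peptide (240–300 aa,
background amino-acid frequencies) per type, deterministic from a fixed
seed. Random peptides are mutually unrelated, so planted queries have an
unambiguous truth label; nothing in the bundled sequences carries biological
signal, and conclusions about real genomes require a curated RT library in
the same format.

## Synthetic data

`generate_genome` plants copies of parameterized elements
(LTR–inner–LTR; the inner region optionally carries an RT-coding ORF
≥ 450 bp) into i.i.d. background at a stated GC content (default 0.40,
a typical vertebrate value). The element's two LTRs match at a configurable
identity; each planted copy is independently mutated at a per-site
substitution rate. Placement is uniform without overlap; `min_gap` can
enforce a minimum background distance between copies, because copies of one
master share near-identical LTRs and two copies planted within the
detector's element window present a cross-element repeat pair that a
direct-repeat detector may legitimately report instead of either planted
pair (adjacent/nested element resolution is out of scope). Truth records
(BED-like, 0-based half-open) are exact.

Substitutions inside a planted ORF are applied under a purifying-selection
rule: a mutation that would create an in-frame stop or destroy the start
codon is reverted. Active, recently proliferated copies keep intact reading
frames in real genomes; without this rule, any appreciable divergence would
sever the ≥ 450 bp ORFs that the genomic-ORF counting method depends on,
and the generator could not represent "diverged but countable" copies.

Reads are single-end, forward-strand, fixed length, drawn from elements
proportional to abundances with uniform per-base substitution error. Count
matrices are negative binomial with variance μ + αμ² (α = 0 gives Poisson)
and per-sample library-size factors. Not emulated: indels, paired ends,
read-quality models, reverse-strand transcription, positional coverage
bias, GC bias, isoforms/splicing, and genome-scale repeat background other
than the planted copies. Passing tests therefore demonstrate correctness of
the algorithms under substitution-only divergence and idealized sampling,
not performance on real sequencing data.

## De novo LTR detection

The detector implements a seed-and-extend contract over direct repeats:
exact 20-mer seed pairs at separations within
[min_element − 2·max_ltr, max_element]; ungapped extension (right, then
left) accepted step-by-step while the running repeat identity stays
≥ 70 %; each direction trimmed back to its maximum of a +1/−1 match score
(first maximum — the shortest extent — wins, making boundaries
deterministic); repeat length filtered to [30, 2000] bp and element span to
[min_element, max_element]; overlapping candidates merged keeping the
highest-similarity, then longest, then leftmost one. K-mers occurring more
than 200 times per contig are skipped as low-complexity. The element-span
window defaults to [1000, 12000] bp, bracketing the catalogued AELs
(4000–10000 bp); it is a detector parameter, not a biological claim.

Ungapped extension is a deliberate simplification matched to the
substitution-only generator; it also keeps the detector equivalent to an
exhaustive repeat-pair oracle that the tests run on small instances. The
max-score trim means a repeat boundary can overshoot the true element edge
by a few bases when flanking background happens to match; tests therefore
compare coordinates with a ±10 bp tolerance. Detection sensitivity is
bounded by seed survival: with pairwise LTR identity p and LTR length L,
roughly L·(1−p) mismatch gaps must include one run of ≥ 20 matching
positions (probability ≈ p²⁰ each). The sensitivity conditions used in
tests (500 bp LTRs, master LTR identity 0.90, copy divergence 0.005) keep
the expected number of surviving seeds around five, compatible with the
≥ 95 % recovery requirement; short (≈ 300 bp) LTR pairs near 85 % identity
sit at the detection floor of a 20 bp exact seed, for this detector as for
any detector honoring the same seed contract.

## Alignment, e-values and classification

Peptide alignment is optimal Smith–Waterman with affine gaps (BLOSUM62;
gap of length L costs 11 + L; X scores zero against everything; delegated
to Biopython's C `PairwiseAligner`, with an independent pure-Python DP as
the test oracle). Significance follows Karlin–Altschul statistics with the
standard gapped-BLOSUM62 constants K = 0.041, λ = 0.267: bit score
S' = (λS − ln K)/ln 2 and E = m·n·2^(−S') over query length m and summed RT
database length n. These constants approximate, not reproduce, NCBI BLAST's
edge-corrected statistics; the operative thresholds (E ≤ 10⁻⁴⁰ for genome
searches, 10⁻³⁰ for transcriptome searches, both configurable) sit so far
from the random-score regime that the approximation does not affect
assignments on the scales exercised here.

Genomic ORFs are maximal start-to-stop regions (both strands, three
frames, ≥ 450 bp including start and stop codons, standard genetic code).
Nucleotide queries (candidate inner regions, transcripts) are classified
blastx-style through all six-frame stop-to-stop segments ≥ 50 aa, best
qualifying hit per query; ties break by coverage, then lexicographic type
name, keeping results deterministic. Each query yields at most one
assignment — one count per ORF or candidate.

Near-duplicate peptides can be collapsed by greedy longest-first clustering
at 80 % identity (identity = maximal matched residues in a global alignment
divided by the shorter length; fragments < 120 aa discarded first).
Placement sanity trees are neighbor-joining over distances
d(a,b) = 1 − score(a,b)/min(self(a), self(b)), with lowest-index
tie-breaking; NJ recovers additive topologies exactly and is a light-weight
stand-in, not a substitute for maximum-likelihood phylogenetics.

## Census arithmetic

AAE rounds the dual-count mean half-up (134.5 → 135); the genome-fraction
percent uses the exact, unrounded mean: 100 · mean · AEL / G. Totals are
always recomputed from rows. The default genome size G = 1.45569 × 10⁹ bp
is a calibration: it is the value (stated to six significant digits)
consistent with all per-type genome-fraction percentages of the reference
census that the package reproduces, and it is configurable per assembly.

## Relatedness

R = ln Σ coverage·score over ordered pairs, self-pairs excluded — self-hits
carry no proliferation signal and would otherwise dominate the sum. The
natural logarithm and the raw (not bit) alignment score are used; both
choices only shift R by a constant factor/offset and are configurable in
spirit (the statistic is meaningful on a relative scale). Using ordered
rather than unordered pairs adds ln 2. Monotonicity holds by construction:
adding a copy adds non-negative terms. R is undefined (reported missing)
for fewer than two copies.

## Expression

The read counter is a deliberately simplified stand-in for a short-read
mapper: exact seed (15-mer) plus ungapped diagonal extension, a hit
requiring ≥ 30 matching bases, both orientations tried. What matters for
the census of multi-copy families is the counting **policy**: each read
increments every one of its up-to-20 best-matching elements (a fractional
1/n-per-hit mode is available behind a flag). Users with externally
produced counts can enter the pipeline at the count-matrix stage.

Size factors are the median-of-ratios estimator over elements with a
positive geometric mean across samples; only the normalization is
implemented, not dispersion estimation or a differential-expression model.
NRC_rel divides each element's NRC by its arithmetic mean across samples,
so every expressed element's profile averages exactly 1 (asserted on every
run); all-zero elements are flagged and reported as zeros.

The per-element battery always fits Box–Cox by maximum likelihood on the
grid λ ∈ [−2, 2] step 0.01 (λ = 0 is the log; non-positive values are
shifted by 1 − min with the shift recorded), then gates on Shapiro–Wilk
(residuals) and Levene (mean-centered) at α: one-way ANOVA if both pass,
Kruskal–Wallis otherwise, with the full decision trail in the result.
Constant data short-circuits to F = 0, p = 1. P-values are reported raw;
an optional Benjamini–Hochberg column is off by default, since per-element
significance with no correction is the reported convention this pipeline
mirrors. Stage profiles renormalize each stage's per-type NRC to shares
summing to one; all-zero stages are emitted as zero rows with a warning.

## Determinism and problem sizes

Every stochastic routine takes an explicit seed; pipeline runs echo a
manifest (version, seed, input checksums) and re-running a config
byte-identically reproduces all TSV outputs. The test suite and the
acceptance script size their simulations to run comfortably on one CPU —
synthetic genomes of 0.1–0.3 Mb, 2000-element count matrices, 2000-replicate
null calibrations, 200-replicate power runs — sizes at which the measured
quantities (recovery rates, size-factor errors, type-I error) are stable
across seeds.

## Known limitations

- The bundled reference library is synthetic; real-genome use requires a
  curated RT/GAG/POL/ENV library in the same FASTA dialect.
- Ungapped detection and counting: indel-diverged repeats and indel
  sequencing errors are outside the model.
- No TSD/PBS/PPT signals, no nested- or adjacent-element resolution; a
  tandem cluster of same-family copies can present cross-element repeat
  pairs that win the overlap merge.
- Karlin–Altschul constants are fixed approximations; absolute e-values
  should not be compared against other search engines, only thresholded.
- The battery's adaptive test choice (normality/variance gates) is applied
  per element without multiplicity adjustment by default.
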