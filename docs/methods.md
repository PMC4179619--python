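# Methods

## Problem and model

Mature miRNAs are not single sequences: small RNA-seq libraries contain,
for each annotated miRNA, a cloud of isoforms (isomiRs) that differ at
the 5′ or 3′ end. Two generative mechanisms are distinguished by one
criterion: a **templated** isomiR pairs perfectly with its precursor
hairpin (imprecise Drosha/Dicer cleavage shifted the cut site), while a
**non-templated** isomiR carries added bases not present in the
precursor (post-transcriptional nucleotidyl-transferase activity,
chiefly adenylation and uridylation).

Rather than aligning reads leniently and interpreting mismatches,
isomirkit inverts the problem: it *enumerates* the full admissible
variant space up front and then requires exact, full-length, zero-
mismatch matches. For a mature of length L the variant space is

    1 canonical
  + Σ_{k=1..3} 4^k  5′ extensions   (= 84)
  + Σ_{k=1..3} 4^k  3′ extensions   (= 84)
  + max(0, L − min_len) 3′-trimmed forms,

i.e. `169 + max(0, L − 18)` variants with the defaults. Because every
1–3 nt extension is present regardless of templated status, exact
matching against this database recovers non-templated reads that a
genome or hairpin aligner would discard, and a hash lookup on the read
sequence is *mathematically equivalent* to zero-mismatch best-hit
alignment of short reads against the database — no external aligner is
needed (a parser for legacy bowtie `.map` output is kept for
interoperability with pre-computed alignments).

### Classification rules

Each extension is compared position-wise, outward from the mature
boundary, against up to 3 flanking hairpin bases on every locus carrying
the mature (miRNAs encoded at several loci are templated if *any*
precursor explains the addition — the union rule). Positions beyond a
hairpin's terminus cannot be templated on that hairpin. For a
non-templated variant the **iso-group** (A/C/G/U, reported in RNA
letters) is the added base at the first position where every flank has
failed, given that all inner positions matched on the same flank; this
"first non-templated nucleotide" rule classifies a mixed tail like
`-TA` over flank `TCA` as an A-form (the leading T is precursor-
encoded). **Pure** forms are non-templated tails of one repeated base
(`-A/-AA/-AAA`), the signature of a single enzymatic activity; all
other non-templated tails are **mixed**. A mature absent from every
hairpin is kept, with every extension non-templated, since public
mature/hairpin sets are not always consistent; 5′-trimmed and
internally-edited variants, and simultaneous 5′+3′ modifications, are
out of scope by design.

### Tie-breaking

Sequence-identical database entries are real (paralogous loci; a
trimmed form of a long miRNA equalling a shorter miRNA's canonical
sequence). Zero-mismatch alignment cannot rank them, so a deterministic
priority resolves every collision: canonical < trim3 < templated ext3 <
templated ext5 < non-templated ext3 < non-templated ext5, then fewer
modified bases, then lexicographic variant id. The rule prefers the
simplest biological explanation and makes assignment tables
byte-reproducible; it is a convention, not an inference, and ties are
reported (`resolution=tie_broken`, `n_candidates`).

## Adapter trimming

Inserts shorter than the read length run into the 3′ sequencing
adapter. The trimmer scans read positions left to right and cuts at the
first position whose suffix aligns to a prefix of the adapter with at
most `floor(max_err_rate × overlap)` mismatches (`max_err_rate=0.1`),
requiring `min_overlap=5`; a terminal overlap shorter than
`min_overlap` must match an adapter prefix exactly. Cutting to length 0
(adapter-only reads) and leaving a read untouched (no adapter found)
are both valid outcomes. Qualities are truncated in lockstep; no
quality filtering is performed. Reads shorter than `min_len=18` after
trimming are removed before assignment — shorter exact matches are
unreliable and the database contains nothing below 18 nt.

One boundary case is worth stating precisely: trimming is idempotent
*except* when a trimmed read happens to end in an exact adapter prefix
shorter than `min_overlap`; re-applying the trimmer then removes that
remnant too. The single-pass behaviour is kept because it preserves the
insert exactly for reads of the form `insert + adapter`, which is what
quantification needs; the property test asserts the guarantee in this
form (any extra bases removed by a second pass are themselves
recognized as pure adapter).

## Quantification and comparison

Raw counts per variant per sample are RPM-normalized
(`rpm = count × 1e6 / library_size`); the default denominator is total
assigned reads, so per-sample RPM sums to exactly 1e6, with an option
to divide by the post-trimming read count instead. Summaries follow the
standard reporting structure: per-class detected species and read
totals (classes canonical, trim3, ext5-T/NT, ext3-T/NT); per-miRNA
composition restricted to robustly covered miRNAs (pooled total
strictly > 100 reads) with threshold counts per class and a flag for
miRNAs whose prevalent form is a 3′ non-templated variant; and the
A/C/G/U iso-group distribution of 3′ additions, non-templated side
optionally restricted to pure forms, templated side grouped by first
added base for contrast.

Two-sample comparison uses plain log2 fold changes on RPM
(`log2fc = log2(rpm_b / rpm_a)`) over features with raw count > 100 in
at least one sample, flagging |log2fc| > 1; no pseudocount is added,
and a variant-level zero on one side yields a signed infinity that is
flagged rather than dropped. No replicate-aware test and no
multiple-testing correction is applied — the comparison is a
fold-change screen between one pair of samples. `level` selects
canonical-only counts (default), per-parent aggregates, or individual
variants.

Iso-group enrichment uses Fisher's exact conditional test, implemented
by direct hypergeometric enumeration with exact integer weights
(`C(r1,x)·C(r2,c1−x)` compared as integers, two-sided p = sum of
probabilities ≤ the observed table's, odds ratio `ad/bc` with the
infinite convention when `bc = 0`). Exact integer comparison avoids
floating-point tie ambiguity; the test suite cross-checks against
`scipy.stats.fisher_exact` and an independent vectorized hypergeometric
tail summation over every 2×2 table with margins ≤ 30.

## Synthetic data generator

The generator emulates the structure of a real small-RNA sequencing
experiment, not any particular dataset. A toy reference embeds random
matures (default 22 nt, the modal miRNA length) in random hairpins with
8–15 nt flanks, verified collision-free (each mature occurs exactly
once in exactly one hairpin, unless paralog duplication is requested).
Libraries are drawn from a read-share mixture chosen to reflect
typical bulk small-RNA composition: canonical 60%, 3′ modifications 30%
(templated ≈ 2× non-templated; among non-templated, pure A-tails 5% and
pure U-tails 2% of all miRNA reads, so adenylation dominates), 3′
trimming 9.5%, 5′ modifications 0.5%. Reads are `variant + adapter`
truncated to 50 nt. Decoy classes reproduce the multi-modal
post-trimming length profile: adapter-only reads (mode 0), 6–17 nt
degradation fragments peaked at 10 nt, 34 nt tRNA-like fragments, and
unclipped random 50-mers — defaults 10% / 12% / 10% / 8% of all reads,
leaving 60% miRNA-derived.

Substitution errors are applied per base at a configurable rate from a
dedicated random stream, so the ground-truth table (intended, pre-error
counts per variant) is invariant to the error rate at a fixed seed.
Indels and quality/ligation-bias models are deliberately absent: the
assigner is exact, so any insert error simply unaligns the read, and an
indel would model nothing further.

What passing round-trip tests show — and what they do not: an
error-free library built from database sequences is recovered *exactly*
(the assigner loses nothing by construction), and at a 1% substitution
rate the unassigned fraction matches the analytic no-error probability.
A read is recoverable iff its insert is error-free, so P(assigned) ≈
(1−e)^L per read of insert length L: errors within the compared adapter
bases fall under the trimmer's 10% mismatch budget (P ≥ 3 errors in ~28
compared bases at e = 0.01 is ≈ 3·10⁻⁶) and so do not cost reads. These
tests validate the pipeline's bookkeeping, not its behaviour on real
libraries, which additionally contain sequences outside the enumerated
variant space, non-uniform error profiles, and ligation biases the
generator does not model. One known leak at positive error rates: a
substitution inside the *added tail* of an extension read converts it
into a different enumerated extension, so small spurious counts can
appear on variants with zero intended reads; recovery assertions are
therefore made on variants with positive truth, under mixtures whose
sampled pools are pairwise length-distinct.

## Numerical and design choices

- Sequences are canonicalized to DNA (U→T) internally; iso-groups are
  reported in RNA letters to match field nomenclature.
- Exports are byte-stable: fixed column sets, fixed sort order
  (mirna_id, then canonical < trim3 < ext5 < ext3, then n_mod, then
  added tail lexicographic).
- "Detected" means ≥ 1 read by default; a strict "more than one read"
  variant is available via `detected_min=2`.
- `min_len=18` and `max_ext=3` are exposed but default to the values
  that define the variant space above; changing them changes the
  cardinality closed form accordingly.
- Problem sizes in tests and in `scripts/acceptance.py` (5–8 loci,
  10,000–20,000 reads per library) are chosen so the full suite runs in
  well under a minute while every count of interest is in the hundreds
  to thousands; all randomness is seed-derived.

## Known limitations

- No mismatch-tolerant alignment: sequencing errors cost sensitivity
  rather than specificity, by design.
- Internal (editing/SNP) variants and combined 5′+3′ modifications are
  not enumerated and therefore invisible.
- The fold-change comparison has no replication model; it screens, it
  does not test.
- The tie-break priority is a convention; reads in duplicate-sequence
  groups are attributed, not disambiguated.
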