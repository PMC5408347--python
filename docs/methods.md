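# Methods

`srnaproc` re-implements, as a tested library, the computational workflow
used to characterise small-RNA processing changes in ER-stressed cells:
classify reads into RNA classes by perfect matching, decompose miRNA-class
reads into isomiRs with non-templated 3' additions (NTA), profile
tRNA-derived stress-induced fragments (tiRNAs), and compare conditions with
median-of-ratios-normalised counts. This note records the models,
conventions and numerical choices behind each stage, what the bundled
read generator does and does not emulate, and the known limitations.

## Conventions

All sequences are normalised to the uppercase DNA alphabet (U→T) on load;
reports map T back to U for tail-type labels. All coordinates are 0-based
half-open internally; GFF3 (1-based closed) and the tRNA structure TSV are
converted at the file boundary. The tRNA structure input is a bespoke
six-column TSV (`gene_id, isotype, anticodon, anticodon_start, loop_start,
loop_end`) rather than a parse of tRNAscan-SE output; isotypes are named
`AminoAcid-Anticodon` (e.g. `Gly-GCC`).

## Preprocessing

Adapter clipping is exact-match: a read is cut at the leftmost occurrence of
an adapter prefix of at least `min_overlap` bases (default 5), including
prefixes running off the read's 3' end. The default adapter is the Illumina
TruSeq small-RNA 3' adapter; unclipped reads are kept by default
(configurable to discard). Quality handling is reduced to trimming trailing
bases below Phred `quality_cutoff` (default Q20, FASTQ only). Reads shorter
than 15 nt after clipping are removed — below that, exact placement is too
ambiguous — and N-containing reads are dropped because zero-mismatch
matching cannot place them. Identical sequences are collapsed with
multiplicities; every stage preserves `total_raw = total_kept + discarded`.

A caveat on clipping: with partial-overlap suffix matching the operation is
not strictly idempotent — clipping can expose a new, shorter 3' suffix that
itself matches an adapter prefix running off the new end. At
`min_overlap = len(adapter)` idempotence holds exactly, which is how the
property is tested. In the pipeline the clipper runs once per read.

## Classification

Exact substring search against the reference sequences stands in for a
zero-mismatch short-read aligner; for this use the two are equivalent, and
the index (a dictionary over all reference substrings in the 15–35 nt read
window, with a linear-scan fallback outside it) is dependency-free and
exhaustively verifiable against a naive scan. Reads matching several classes
resolve to the first match in a fixed hierarchy (default miRNA > tRNA >
rRNA > snoRNA > snRNA > piRNA > mRNA > repeat) and contribute their full
count to that class only — no fractional splitting. Reverse-complement
matching is off by default (small-RNA libraries are stranded).

One deliberate extension: membership in the miRNA class is granted to any
read the isomiR caller accepts (below), not only to exact precursor
substrings. A non-templated tail is by definition not a perfect match, yet
such reads are miRNA-derived; excluding them would understate the miRNA
class by the tailing rate (~20%) and empty the NTA denominators. Stored
hits remain exact matches only.

Composition tables report per-class counts and fractions over *assigned*
reads, overall and in the 18/22/32-nt strata; the unassigned count is
carried with an undefined fraction. Length histograms cover 15–35 nt; on a
modal tie the smallest length is reported and the tie flagged. Cross-
condition class ratios divide assigned-read fractions (stress/control);
classes absent from the control are flagged infinite.

## isomiR calling

A read is an isomiR of a mature locus when its 5' end starts within ±2 nt
of the annotated mature 5' end ("less than 3 nt apart" ⇒ |shift5| ≤ 2), its
templated body matches the precursor with zero internal mismatches, and at
most 3 terminal 3' bases remain uncovered — the non-templated tail.

The decomposition is templated-priority: from each candidate start the body
is the *maximal* exact extension into the precursor (through the downstream
context), so a 3' base matching the next template base is always counted as
templated extension, never as a tail. This is deterministic and
conservative; the alternative (calling ambiguous bases as tails) would
overstate NTA rates by the template's base composition (~25% of tails).
Among valid candidate starts, the call with the longest templated match
wins; ties prefer the smallest |shift5|, then upstream over downstream
shifts. The caller is tested for exact agreement with a brute-force
enumeration of every (start, templated-length) decomposition.

Categories are mutually exclusive with precedence nta > shift5 > shift3 >
canonical (a tailed read counts as NTA regardless of end shifts); the full
three-component call is retained so other tabulations remain possible.
Tails are typed by base for homopolymers (mono = 1 nt, multi = 2–3 nt);
mixed-base tails are pooled under "mixed" and excluded from single-base
fractions (reported NTA totals are available with and without them).

Per-miRNA counts sum all isomiRs of a locus; loci sharing an identical
mature sequence each receive the full count. Genome-wide (global and
per-arm) NTA fractions instead count each read once, attributed to the
lexicographically smallest matching mature id, to avoid double counting.
NTA fractions are of the total miRNA-class read count in scope, so the
untailed complement closes the budget.

### Comparative statistics

The global control-vs-stress NTA comparison is a two-sided two-proportion
score (z) test on pooled tailed/total counts per tail type. The per-miRNA
comparison is a Wilcoxon signed-rank over miRNAs with ≥500 reads in both
conditions (the abundance filter used for per-miRNA scatter comparisons),
skipped with a warning below 10 eligible miRNAs. These are documented
choices, not claimed identical to the unnamed tests behind published
significance floors. Read-length shifts are tested with a count-weighted
two-sided Mann–Whitney U; the arm bias of a tail type is the ratio of 3p-
to 5p-arm mono-tail fractions; the coupling between per-miRNA NTA change
and expression change is a Spearman rank correlation (≥10 pairs required).
The 5'-isomiR summary flags miRNAs whose 5'-shifted fraction exceeds a
threshold (default 0.2, configurable).

## tiRNA analysis

Reads resolving to the tRNA class are pooled per isotype: a read whose tRNA
hits all fall in genes of a single isotype is kept (the longest gene is the
canonical coordinate frame; hits on shorter paralogs keep their own
offsets — no realignment); reads hitting two or more isotypes cannot be
attributed and are excluded into a discard ledger. The upstream Methods
wording about excluding "unambiguously mapped reads" is treated as a typo
for "ambiguously"; a flag can invert the behaviour.

Per isotype the profile records total and 32-nt counts (the focal tiRNA
length; an exploratory 30–35 window is configurable), per-position
coverage, 5'/3' terminus spectra, and the dominant fragment. Half
classification: a fragment is a five_prime_half if it starts within 2 nt of
the tRNA 5' end and ends inside the anticodon loop, a three_prime_half if
it ends within 3 nt of the 3' end (accommodating CCA) and starts inside the
loop, else internal; the tolerances are package choices since none are
published. The cleavage offset is the signed distance of the loop-side
boundary from the anticodon-loop midpoint. The phased fraction at a length
is the count share of fragments carrying the modal terminus — the 3'
terminus for 5' halves and vice versa (for internal dominants the larger of
the two is reported). No numeric threshold defines "precisely phased"; the
fraction itself is reported, and 0.5 is the documented default where a
boolean call is needed. Per-isotype log2 fold changes use median-of-ratios
size factors and a 0.5 pseudocount.

## Normalization and differential abundance

Size factors are median-of-ratios: over features with nonzero counts in all
samples, the median per sample of count/(feature geometric mean), rescaled
to geometric mean 1. RPM is reads per million mapped.

The differential test is deliberately simplified and labeled as such in
every output header: the full NB-GLM machinery with dispersion shrinkage,
outlier filtering and fold-change moderation that a dedicated DE package
provides is out of scope here, since it is an off-the-shelf step rather
than this package's contribution. With one sample per group, conditioning
on the feature total makes the control count binomial with probability
s_ctrl/(s_ctrl+s_stress) under the null — an exact two-sided binomial test.
With replicates, a Wald test on the log2 ratio of group means uses a
negative-binomial variance (μ + αμ²) with a method-of-moments common
dispersion (median over features of (var−mean)/mean², clipped at 0).
P-values are Benjamini–Hochberg adjusted across features. Log ratios use a
0.5 pseudocount throughout. Calibration (type-I ≤ nominal on null
simulations; power on planted four-fold changes) is asserted in the test
suite at reduced problem sizes (200 replicates of 200-feature null
matrices; 50 replicates for power at a 100k-read depth), which keeps the
default suite fast while pinning both error rates.

## The synthetic-read generator

The generator is first-class, tested code: it emits toy references and
reads whose statistical structure matches the study conditions, plus a
per-read truth table against which every downstream stage is validated.

References: hairpin precursors (60–90 nt) with embedded 5p/3p mature arms
(canonical lengths 21–23, mode 22); tRNAs of 76 nt (73 + CCA) with the
anticodon at positions 32–34 inside a [30, 37) loop, except the Asp-GTC
gene at 65 nt so that a 32-nt three-prime half starts inside the loop;
four 300-nt decoys per background class. The base immediately downstream
of a mature end is 'A' at a controlled rate (default 0.25) so
templated-ambiguity cases occur at a known frequency.

Reads: class drawn from the condition's composition (control: miRNA 9.0%,
tRNA 7.5%; stress: miRNA 4.7%, tRNA 13%; remainder spread over
backgrounds). miRNA reads draw a precursor from a log-normal abundance
model (shape 1.0; no published abundance distribution exists, so a heavy
right tail typical of small-RNA libraries is used), an arm (50/50), a 5'
shift (90% canonical), and a tail from the condition's table (control
mono-A/U/C 8.4/5.2/6.6%, stress 5.6/6.5/5.0%, mono-G 0.3%, 2–3 nt and
mixed tails totalling ~1%). Mono-U is 2.7× more frequent on the 3p arm and
mono-C biased 2× to the 5p arm, implemented as arm multipliers that leave
the library-wide fraction at its nominal value. Tail-type-specific body
lengths put C on 21-nt and A/U on 22-nt pre-modified bodies, with the
A-on-22 share rising from 45% to 55% under stress. Under stress, per-locus
mono-C rates are coupled inversely to the locus's expression fold change
(normalised so the library-wide rate stays on target), planting the
negative correlation between mono-cytidylation change and expression
change.

Tails are non-templated by construction: if a sampled body length puts the
cut where the next template base equals the tail base, the body length is
re-drawn (up to 6 times, then the cut is shifted by up to 2 nt).
Separately, a configurable fraction of untailed reads (default 0.1) is
planted as templated +1 extensions — reads a non-greedy caller would
misread as tailed — recorded as templated in the truth table so the
templated-priority rule is exercised measurably.

tRNA reads concentrate phased anticodon-loop cleavage in five target
isotypes (Gly-GCC, Gly-CCC, Glu-CTC, Asp-GTC, Val-CAC; 60% of tRNA reads
in control, doubled under stress) emitting 32-nt halves at rate 0.8 —
five-prime halves except Asp-GTC, which yields three-prime halves — with a
5% one-nt slide jitter; other isotypes emit phased halves at 0.2 (raised
under stress, emulating broader stress cleavage so the five targets carry
~86% of control and ~76% of stress 32-nt reads) and random 18–31 nt
fragments otherwise.

No sequencing errors are simulated by default: the pipeline maps with zero
mismatches, so errored reads would simply vanish; an optional uniform
substitution rate exists to exercise the rejection path. A fixed seed
yields byte-identical FASTQ, reference files and truth tables; control and
stress libraries built from the same seed share references, abundances and
fold changes.

### What the generator does not emulate

Ligation/sequence bias, realistic quality strings, internal editing,
genomic multi-mapping beyond the provided references, and the unattributed
18-nt read peak seen in real libraries. Passing recovery tests therefore
demonstrates the pipeline's correctness on data satisfying its model
assumptions, not robustness to real-library artefacts.

One quantitative interaction worth knowing: because reference sequences are
fixed, each locus deterministically forbids ~1/4 of cut positions per tail
base (the next template base matches), so the realized pre-modified length
distribution is a few points flatter at its mode than the nominal table
(E[P(22)] ≈ 0.41 for a 0.45 parameter). Modal lengths and the direction of
the control→stress shift are unaffected; tests assert those.

## Orchestration and determinism

`run_all` executes preprocess → classify → isomiR → tiRNA → quant per
condition and the cross-condition comparisons, writing TSVs (fractions at
six decimals) and a JSON manifest (version, seed, parameters, input
checksums). Any stage failure aborts with the stage name. Reruns under one
seed are byte-identical; output tables are sorted deterministically.

## Limitations

* Exact matching cannot use reads with sequencing errors; abundances are
  therefore conditional on error-free reads.
* The simplified DE test has no dispersion shrinkage: at very low counts it
  is conservative, and single-sample designs test technical (counting)
  variation only.
* Half-classification tolerances (2 nt at the 5' end, 3 nt at the 3' end)
  are heuristics; unusual tRNA geometries may need adjustment.
* The substring index holds all reference substrings in the read-length
  window in memory — appropriate for curated small-RNA references, not for
  genome-scale sequence sets.
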