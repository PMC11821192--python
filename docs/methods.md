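# Methods

## Parental-origin model

The pipeline assumes the derived line is inbred: informative sites are
fixed differences only. After an inclusive QUAL ≥ 20 filter (the
conventional variant-calling cutoff; configurable), a site is DONOR when
all three genotypes are homozygous and the line matches the donor but not
the recipient, RECIPIENT in the symmetric case, UNINFORMATIVE when the
parents agree or any genotype is heterozygous or missing, and CONFLICT when
the line is homozygous for an allele absent from both parents. Treating
het/missing as uninformative is deliberately conservative: residual
heterozygosity, collapsed repeats and genotyping errors all present as
hets, and discarding them avoids phasing without biasing block calls
(het/missing noise can only shrink a block's support, never create donor
evidence). Multiallelic VCF records are split into one biallelic site per
alternate allele; a sample homozygous for a different alternate is coded as
a distinct state so a line-private allele surfaces as CONFLICT rather than
being miscoded. Indels are anchored at the VCF POS base for all positional
logic.

## Region classification

Each variant gets exactly one of seven classes. Within a gene body the
precedence is 5′/3′ UTR over exon over intron, which keeps the three
retained categories (5′ UTR, exon, 3′ UTR) disjoint in the summary table —
UTRs are sub-intervals of terminal exons in most annotations, so without
the precedence rule the UTR rows would be empty. Outside gene bodies,
positions within `flank_window` (default 5000 bp, the conventional
annotator default) of a gene are UPSTREAM or DOWNSTREAM relative to that
gene's strand; the nearest gene wins when flanks overlap, ties broken by
smaller start coordinate. Everything else, including sites on chromosomes
absent from the annotation (warned once per chromosome), is INTERGENIC.
Only UTR/exon sites feed the region table and gene-origin calls; block
detection intentionally uses **all** informative sites genome-wide, since
intergenic fixed differences carry the same ancestry signal and roughly
10-fold more of them exist.

## Block delineation

Donor blocks are maximal runs of DONOR sites per chromosome. A run
tolerates up to `max_gap_sites` (default 2) consecutive non-donor
informative sites in its interior — enough to absorb isolated genotyping
errors without merging distant blocks — and must contain at least
`min_support_sites` (default 5) donor sites. Uninformative sites are
transparent. Block bounds are the first and last supporting variants, so
the reported span is measured variant-to-variant, not gene-to-gene; the
true introgression boundary lies between the outermost donor site and the
next informative non-donor site, giving a boundary uncertainty of one
inter-site spacing. Because maximal qualifying runs are provably disjoint
(the union of two overlapping qualifying runs still qualifies), the greedy
left-to-right scan is exact; the test suite checks it against brute-force
enumeration of all maximal runs on random instances.

Gene origin is DONOR/RECIPIENT when only one parent's sites occur in the
gene's retained regions, NON_POLYMORPHIC with no retained site, and
CONFLICT with both — conflicted genes are counted separately rather than
folded into either parent's total. The inheritance fraction is
100·donor/(donor+recipient), reported to one decimal; NON_POLYMORPHIC and
CONFLICT genes are excluded from the denominator because they carry no
(unambiguous) ancestry signal.

## CAPS marker analysis

Primer matching counts mismatches under a strict 3′ anchor (defaults:
anchor 3, max 2 mismatches) — a transparent rule that reproduces
"amplifies the near neighbours, rejects distant homologues" behaviour
without a melting-temperature model, which would add parameters the
fragment predictions never use. Every orientation-valid forward/reverse
site pair below the product-size cap is reported as an amplicon; zero or
multiple products are returned as such. Recognition patterns are IUPAC
strings scanned on both strands via regex with lookahead (overlapping
occurrences included); a minus-strand match at plus-position *i* cuts the
plus strand at *i* + (pattern length − cut offset), and palindromic
patterns therefore deduplicate to one cut per locus. Digests are linear
only; fragments always sum to the amplicon length. An enzyme discriminates
two alleles when the fragment-length multisets differ; fragments below a
20 bp gel-resolution floor are flagged in reports as likely invisible on
agarose.

The enzyme table is data, not code (`data/enzymes.tsv`, editable, loadable
from any path). It ships RsaI = GT^AC, the canonical recognition site;
some sources conflate RsaI with the GATC site of MboI/Sau3AI, so the table
carries both enzymes under their correct patterns and the discrimination
search is agnostic to which enzyme ends up discriminating.

## Nodule genotyping and statistics

Call rules: no control band → FAILED; control without target → NODX_MINUS;
a target band is classified by digest pattern (CUT → inoculant-type allele
only, UNCUT → indigenous allele only, BOTH → mixed infection). A target
band with pattern NA (or vice versa) is a malformed record and raises.
FAILED nodules stay in the counts but leave percentage denominators —
occupancy describes genotyped nodules. Percentages are rounded half-up to
integers, matching how such tables are reported (2 of 64 → 3%).

Kruskal–Wallis (tie-corrected, χ² reference on k−1 df) and Welch's *t* on
ln(x + offset) wrap `scipy.stats`; the all-identical degenerate case
returns H = 0, p = 1 rather than an error, and the ln offset defaults to 0
with an explicit option (e.g. 1) for zero counts, since there is no single
convention for transforming zeros. The Welch–Satterthwaite df is computed
explicitly and returned alongside t and p.

## Synthetic data

Each generator consumes one seeded `numpy` Generator in a fixed field
order (trio: per-chromosome reference, gene models, per-chromosome
variants), so a fixed seed yields byte-identical files.

**Trio.** Defaults: three 1 Mb chromosomes, variant density 1.7×10⁻³/bp
(~5,000 variants — a toy-genome rescaling of the density at which fixed
differences between distant cultivars occur), SNV:indel ratio 29:1 (the
genome-wide ratio observed in such comparisons), 90% of sites
donor/recipient-discordant, QUAL ~ Gamma(4, 20) (mean 80, a few percent
below the 20 cutoff). Genes are non-overlapping and single-transcript with
2–4 exons and explicit UTR intervals inside the terminal exons — the
simplest structure exercising all seven region classes. The line equals
the donor inside planted blocks and the recipient outside, before noise;
`het_fraction`/`missing_fraction` are per-site probabilities that one
randomly chosen sample of the trio is set to het/missing. The generator
does **not** model read-level errors, linked selection, recombination
interference or real pea chromosome content, so passing recovery tests
demonstrate the algorithm's correctness under clean fixed-difference
signal plus genotype noise — not performance on real resequencing data.

**Marker templates.** Two alleles of default length 1106 with the target
primer pair embedded near the ends and, when planting, a concrete
realisation of the enzyme's site mid-template, destroyed in allele B by one
substitution at the most constrained pattern position; the remaining k−1
differences are placed outside primer footprints and the planted site. The
random background is rejection-sampled until each allele amplifies as
exactly one product covering the planted site and (for k = 1) the planted
enzyme is the table's sole discriminator — the pair is a clean positive
control by construction, not probabilistically. At k = 24 the extra
substitutions may create additional discriminating enzymes; the guarantee
is that the planted enzyme is always recovered.

**Assays.** Category proportions per group are realised either exactly
(largest-remainder rounding of n·p, ties by declaration order) or
multinomially. Emitted band/digest fields are the deterministic image of
the category under the call rules, so calling inverts generation with zero
error — the round-trip validates the call rules' consistency, not assay
noise robustness.

## Problem sizes and tolerances

The recovery acceptance property runs 20 seeds of the 3×1 Mb / ~5,000
variant configuration with two planted blocks (300 kb and 250 kb) at 5%
het + 5% missing noise, asserting ≥95% truth-base coverage and ≤1%
background per seed; observed values are ~99.5% and 0% (false donor
evidence cannot arise under this noise model). The acceptance script runs
5 replicates of the same configuration, 30 marker seeds and 400 assay
records — sizes chosen to characterise the pipeline tightly while keeping
a full from-scratch rerun in seconds. Floating-point expectations in tests
use absolute tolerances of 5×10⁻⁴ on hand-derived statistics; percent
identity and inheritance fractions are exact at their reporting precision.

## Known limitations

- Block boundary precision is limited to one informative-site spacing;
  very small introgressions (< `min_support_sites` variants) are invisible.
- The primer model ignores thermodynamics; specificity conclusions are
  sequence-identity statements only.
- Circular templates and partial digests are unsupported.
- Occupancy statistics treat nodules as independent; plant-level clustering
  is not modelled.
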