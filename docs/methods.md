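# Methods

## The model

A retroduplicated gene ("retrogene") is a gene copy created when an mRNA of
a multi-exon parent is spliced, reverse-transcribed, and integrated into
the genome by retrotransposon machinery. When the integrating element is an
LTR retrotransposon, the new copy sits between the element's two long
terminal repeats, which are identical at the moment of insertion and then
diverge neutrally. This yields four testable predictions that the pipeline
operationalizes:

1. the retrocopy's span is contained in a full-length element (or, after
   recombination/deletion, in merged partial LTR fragments);
2. a parental gene exists elsewhere in the genome whose spliced CDS covers
   the retrocopy CDS almost completely while carrying *more* exons
   (intron loss);
3. the insertion carries a 3′ poly(A) remnant and short flanking direct
   repeats (target-site duplications at the element boundary);
4. the element's LTR pair, and the retrocopy/parent synonymous divergence,
   date the insertion and the duplication respectively.

The pipeline stages are: full-length and partial candidate detection →
class II TE-conflict removal → parental verification → multi-gene-element
discrimination → orphan filtering → retro/ambiguous/normal partition →
signature scanning → clocks → report. Every filter reports
`in = out + rejected`.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| `parent_min_coverage` | 0.95 | fraction of candidate CDS | parent must explain (nearly) the whole retrocopy; lower values admit domain-sharing paralogs |
| `te_conflict_fraction` | 0.5 | fraction of gene span | "overlaps a DNA transposon/Helitron" needs a fraction; 0.5 avoids rejection by incidental 1-bp overlaps while still catching mis-predicted elements |
| `normal_ltr_overlap` | 0.8 | fraction of gene span | genes >80% covered by LTR-order repeats are too entangled with elements to serve as the clean comparison ("normal") class |
| exon-dominance ratio | 1.5 | fold | a single exon >1.5× every neighbor exon marks the merged-exon structure typical of retrocopies |
| `min_orf_nt` | 900 | nt | gag/pol ORFs are kilobases long; 900 nt (300 codons) separates them cleanly from chance ORFs in random DNA (P ≈ 10⁻⁶ per position) |
| poly(A) run | ≥10 A, ≤1 mismatch | nt | long enough that a 200-nt downstream window is hit with probability <1% under a uniform base model |
| direct repeats | 4–20 nt, ≥90% id (exact <10 nt), offset ≤5 nt | nt | typical TSD lengths; the tight mirrored-offset window keeps the null false-positive rate near zero |
| `signature_window` | 200 | nt | poly(A) remnants sit immediately downstream of the CDS |
| `r_intergenic` | 1.3 × 10⁻⁸ | subs/site/yr | neutral intergenic clock applied to LTR pairs (intergenic DNA evolves faster than coding) |
| `r_synonymous` | 6.96 × 10⁻⁹ | subs/syn-site/yr | synonymous-site clock applied to Ks of gene pairs |
| `ks_cluster_cutoff` | 0.1 | Ks | pairs within Ks 0.1 (≈7 MY at the synonymous rate) are treated as one duplication event; application-dependent and exposed in the config |

Strand is ignored for containment (a retrocopy may insert in either
orientation relative to its element); "fully contained" means the whole
gene span, not just the CDS.

## Clocks and numerics

* **K2P.** `K = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q)` over ungapped columns of
  a global alignment with free end gaps (LTR boundaries are approximate).
  Non-positive log arguments raise a saturation error ("age not
  estimable") rather than returning a number.
* **NG86.** Synonymous site counts per codon use the fraction of the three
  single-nucleotide neighbors that are synonymous; changes creating a stop
  codon count as nonsynonymous, so sites per codon always total 3 (the
  same convention Biopython uses, which the test suite cross-checks).
  Differences average over all mutational orderings between a codon pair,
  excluding pathways that pass through a stop codon (all pathways are used
  if every one is blocked). Each class receives the Jukes–Cantor
  correction `d = −¾ ln(1 − 4p/3)`. Codon columns containing a gap are
  skipped; stop-containing columns raise unless `skip_stops=True`, which
  the pipeline sets because mutated retrocopies can carry chance stops.
* **Alignment scores.** Local (parent search) and global (LTR pairs)
  alignments use match +2, mismatch −3, gap open −5, gap extend −2. Query
  coverage is aligned query bases / query length; identity is matches /
  aligned columns. Parent ranking is score, then identity, then
  lexicographic id, making the choice order-independent.
* **Multi-gene ties.** Within the discrimination rules, ties break by
  longer CDS, then smaller genomic start. With ≥3 genes in an element,
  "neighboring genes" means all co-resident genes. Mutual >1.5-fold
  dominance is arithmetically impossible, so at most one gene can satisfy
  rule 2.
* **Degenerate inputs.** Zero-length intervals are rejected at
  construction; an empty gene file yields an all-zero report and success;
  genes at contig edges have signature windows truncated to the available
  side; elements with a single LTR child are excluded from the full-length
  set (they may still appear as repeat fragments).

## The synthetic genome generator

The generator emulates exactly the structures the analysis assumes, on a
uniform-composition random background (2 × 300 kb by default):

* 12 multi-exon parent genes (2–8 exons, 300–500 codons, canonical GT–AG
  introns, both strands), family-labelled `CNL-G2` so family-restricted
  parent search is exercised;
* 20 retro events: the parent CDS, optionally diverged at 0.02/site
  (transition:transversion 2:1), inserted with a 15-nt poly(A) tract
  between a freshly duplicated 500-nt LTR pair with 8-nt target-site
  duplications. Each LTR then accumulates substitutions independently at
  `r_intergenic × age`, so the expected pairwise LTR distance is `2rt`;
  planted ages cycle 0.2–1.8 MY (LTR divergence ≤ ~4.7%). About 30% of
  retrocopies keep one intron (intron retention), matching the observation
  that roughly a third of real retro-NLRs are still multi-exon; 28% of
  full-length elements carry a 3-kb pol-like ORF (the literature reports
  ~72% non-autonomous); 20% of events are emitted as decayed elements
  (LTR fragments only) to exercise the partial pass;
* decoys with known expected verdicts: retro-like genes annotated as
  DNA/hAT or RC/Helitron (TE conflict), parentless 3-exon genes inside
  elements (orphans), two-gene elements constructed to exercise each
  discrimination branch, solo LTRs, and scattered background class II /
  LINE repeats.

Everything derives from one `numpy` `default_rng(seed)`, so outputs are
byte-identical across runs.

What the generator does **not** model — and hence what passing tests do
not show about real data: indels and alignment ambiguity, GC/composition
skew, nested element insertions, gene-family paralogy gradients (parents
are mutually unrelated random CDS, so parent assignment is unambiguous by
construction), segmental duplications that mimic retrocopies, and
annotation noise in the input gene models. Recovery being exact here means
the *logic* is right, not that real-genome precision/recall would be 1.

## Problem sizes

Default validation runs use 600-kb genomes with ~20 planted events, which
make detection exhaustive rather than sampled. Age-recovery regressions
use 20 elements with 5-kb LTR pairs (ages 0.2–3.0 MY): at these lengths
the binomial sampling noise of K gives individual age errors of a few
percent and a regression slope within a few percent of 1. With 500-nt LTRs
(the detection default) a 1-MY age has ~0.28 MY standard error, which is
why dating accuracy is asserted via the 5-kb regression and not per
element.

## Design choices where the design was open

* The representative transcript is the longest-CDS one (ties: smallest
  start); the source procedure did not state its choice.
* The TE-conflict trigger is restricted to DNA and RC (Helitron) orders;
  LINE overlaps do not reject a candidate — LINE-mediated retroduplication
  is a real mechanism, and LINE evidence instead feeds the signature scan.
* Partial-pass containment uses the *merged* union of LTR-order fragments
  (book-ended fragments join), requiring fragment material strictly on
  both sides of the gene, rather than any single fragment.
* Single-exon candidates with no parent survive only with a poly(A) or
  direct-repeat signature; unconditional retention would admit any gene
  that happens to sit in an element, unconditional rejection would discard
  genuine retrocopies whose parent was lost.
* The direct-repeat scan anchors on the *element* span when the candidate
  has one (TSDs form at the element boundary, not the gene's), and on the
  gene span otherwise.
* K2P (not a richer model) is used for LTR pairs, and NG86 (not ML) for
  Ka/Ks: with the short, recently diverged sequences involved, the model
  differences are far below the clock-rate uncertainty, and both have
  closed forms that can be verified exactly against enumeration oracles.

## Known limitations

* No codon-aware alignment: Ka/Ks is computed only when candidate and
  parent CDS have equal, frame-compatible lengths (always true for the
  generator's substitution-only divergence; real indel-bearing pairs would
  need PRANK-style codon alignment first).
* Genome-wide retrogene scans outside any LTR/repeat context are out of
  scope, as are gag/pol domain annotation (ORF length is the autonomy
  proxy), nested-element graph resolution, and Bayesian divergence dating.
* Ages beyond LTR saturation (K2P domain violations) are reported as not
  estimable rather than extrapolated.
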