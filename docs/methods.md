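# Methods

## Scope and model

`fleshmark` treats flesh colour as a two-haplotype-group problem at a single
gene: every allele belongs to the red-flesh group (Rf; skin subtypes GsRf,
RsRf) or the white-flesh group (Wf; subtypes WsWf, RsWf). A site is
*diagnostic* when all Rf alleles share one state and all Wf alleles share a
different one; *subtype-specific* when one Wf subtype's alleles share a state
that differs from the single state shared by everything else; otherwise
*nondiagnostic*. Markers are useful exactly insofar as they interrogate
diagnostic sites, so classification, design and genotyping all hang off this
definition. The pipeline assumes a diploid, selfing-tolerant crop: accessions
carry one or two alleles, and heterozygotes are expected among commercial F1
cultivars.

Coordinates are 1-based inclusive on a reference allele (by convention the
first Rf allele by sorted id). Reported positions are anchor-relative with no
zero: the anchor base is +1 and the base 5′ of it is −1. The ATG is the default
anchor; the TSS is available by flag. This matches how marker positions are
quoted in breeding practice ("the 35th nucleotide upstream of the ATG") and
avoids the ambiguity of zero-based conventions.

## Alignment and variant calling

Each allele is globally aligned to the reference with affine gap scores
(match +2, mismatch −3; a gap of length L scores −8 − L). With these scores a
substitution (swing 5) is always cheaper than a 1-nt gap pair (9), so isolated
differences are called as SNPs. Alignment is delegated to Biopython's
`PairwiseAligner`; the first reported alignment is taken and all indel events
are subsequently left-normalized (VCF-style), so reported positions are
independent of the aligner's internal tie-breaking.

Gap runs are merged into single InDel events keyed by (normalized position,
operation, sequence). Microsatellite loci are detected on the reference only:
maximal tandem runs of a primitive unit of 1–6 nt, at least 4 full repeats and
8 nt total (safely below the smallest locus of interest, (TC)₁₃); the canonical
unit is the lexicographically smallest rotation, and overlapping candidates are
resolved longest-first, then leftmost, then shortest unit. Any indel whose
footprint lies inside a detected locus and whose sequence is whole repeats of
the locus unit is re-expressed as repeat-count variation (the per-allele state
is an integer count); an indel that straddles a locus boundary or is not
unit-periodic is kept as an InDel and flagged ambiguous rather than silently
counted either way. Deletions that remain InDels blank out the carrier's state
at the sites they cover; N bases are likewise missing states, excluded from the
specificity vote and never called as SNPs.

Coding effects are annotated from the gene model (CDS = exonic bases from the
ATG): intronic/promoter/UTR variants are noncoding, exonic SNPs are translated
codon-wise (synonymous/nonsynonymous), and length variants are frameshift
unless their length is a multiple of 3. Adjacent substitution columns are
counted as separate SNPs (per-site accounting); the summary matrix counts
variants by region class (Promoter/Exon/Intron, with exon_i/intron_i collapsed)
× kind × specificity class, with a Total row that must equal the column sums.
Nondiagnostic and ambiguous variants are excluded from the matrix.

## Phylogeny

The group-structure check uses p-distance (mismatches / compared columns) over
reference-projected columns, excluding gap/N columns pairwise; insertions
relative to the reference are not columns and do not contribute. Trees are
built by neighbor joining (scikit-bio), taxa sorted by id first so the result
is independent of input order, negative branch lengths clamped to zero with a
warning. The reported result is not the tree itself but whether some internal
edge bipartitions the leaves exactly into the Rf and Wf sets — the only claim
the distances are asked to support. No substitution model is fitted and no
bootstrap is computed; p-distance need not be additive, so the triangle
inequality is checked only opportunistically in tests.

## Marker design

Two modes:

* **Codominant length markers** (ID-P, SSR-P). Both primers are taken from the
  reference in windows containing no polymorphic position (the mask is built
  from the variant calls of the widest panel supplied, so primers also avoid
  the private SNPs of validation accessions — the in-silico analogue of
  checking candidate primers against all available sequence). Candidates are
  ranked by |Tm − 60 °C|, then |GC − 50%|, then leftmost position; the chosen
  pair must produce exactly one amplicon on every panel allele, and the
  majority Rf-class and Wf-class product sizes must differ by exactly the
  target's length difference.
* **Dominant allele-specific pairs** (PS-P, WD/AD-P). For each group, primers
  are built on a representative allele of that group with the 3′ terminus on a
  diagnostic site (for InDel anchors, candidate termini step across the
  junction). A candidate pair is accepted only if exact in-silico PCR yields
  one product on every own-group allele and none on any other-group allele.
  The discriminating contract is therefore verified, not assumed.

Tm defaults to the Wallace rule 2(A+T) + 4(G+C) — adequate for ranking short
primers around the 62 °C annealing used in validation protocols — with the
nearest-neighbor thermodynamic model available by flag. The Tm window
(55–65 °C), length 18–24 nt, product 100–1200 bp and a ≤4-nt mononucleotide-run
limit are enforced; the GC bounds (20–80%) are deliberately acceptance-only,
because anchored allele-specific primers have no positional freedom and on an
AT-rich template a tight GC filter rejects every candidate at the anchor while
contributing nothing to specificity (the ranking still prefers 50%).
Primer uniqueness is checked only within the supplied allele sequences
(single-gene scope), not genome-wide.

## Virtual PCR and genotype calls

A primer binds where the template matches its 3′-terminal 3 bases exactly and
differs at ≤2 positions elsewhere (N counts as mismatch); both strands are
scanned. These two parameters are an explicit stand-in for annealing
stringency, not a thermodynamic model, and are configurable. Every convergent
forward/reverse site pair within the size range yields an amplicon whose size
is the distance between the primers' 5′ ends, inclusive. An accession's band
set is the union of its alleles' band sets.

Length markers call Rf/Wf/Het/fail by matching bands to expected class sizes
within ±2 nt (agarose-resolution tolerance; a marker whose expected class sizes
fall within twice this tolerance of each other is flagged non-discriminating
and its calls failed). Allele-specific markers call by which group's pair
amplified. Phenotype prediction defaults to the dominant rule (any Rf allele →
red), because heterozygous red-fleshed F1 cultivars exist in real panels; the
recessive alternative (red only for Rf/Rf) is selectable rather than
adjudicated, since the trait's inheritance is genuinely unsettled.
Concordance counts accessions as concordant/discordant/uncallable, with
pink/segregating phenotypes in a separate bucket; fractions are NA when nothing
is callable.

## Synthetic panels: what they emulate and what they do not

The generator builds a ~3.5 kb gene — 1 kb promoter, 7 exons, 6 introns, 20-nt
5′UTR — with an implant table of per-(region, kind, specificity) counts whose
default reproduces the published polymorphism table of the motivating study
(28/3/3 diagnostic SNPs/InDels/SSRs, 6/7/3 WsWf-specific, 9/1/1 RsWf-specific,
promoter diagnostic row 16/2/1). Mandatory features are fixed: the 14-nt Wf
insertion at ATG −35 (with a 20-nt 5′UTR this falls 15 nt upstream of the TSS,
reconciling the "−35 from ATG" and "immediately upstream of the TSS"
descriptions of the same event), the (TC) microsatellite in intron 2 with 13
repeats on Rf and 68 on Wf, a CAT InDel in intron 5, both exonic diagnostic
SNPs in exon 6 (the design anchor for WD/AD-P), and diagnostic SNPs inside the
promoter window −979..−818. Exonic SNPs are installed at synonymous
third-codon positions and exonic InDels kept in-frame by default, mirroring the
observed protein-level conservation between colour groups. Dashes in count
tables are read as zero.

Placement is collision-free by construction: a registry keeps implanted
footprints, reserved conserved flanks around the marker-bearing features, and
pre-existing repeat runs apart (10 nt default spacing; private SNPs, being
isolated substitutions, need only 4 nt). Repeat blocks are installed with
flanking bases that break the periodicity, insertions are drawn already in
left-normal form, and a validation pass re-detects every installed locus and
re-normalizes every InDel on the final reference — if anything is ambiguous the
whole layout is rejected and rebuilt from a deterministically derived fresh
seed (same seed → same panel, always). Each accession's second allele carries 3
private nondiagnostic SNPs (within-line allele divergence of inbred, not
doubled-haploid, material); all implanted and private variants are written to a
truth table with their normalized anchor-relative positions, and the test suite
requires the caller to reproduce that table *exactly* — position, kind, region
and specificity — across ≥20 seeds.

Two panels are generated per experiment: a 4-line discovery panel (one
homozygous accession per subtype, 8 alleles — the shape of a cloned-and-
sequenced study panel) and a 9–10-accession validation panel with inbred lines,
breeding lines and three heterozygous cultivars. The optional homoplasy
accession is a white-flesh homozygote whose intron-2 microsatellite keeps the
Rf repeat count: every marker reads it correctly except SSR-P, reproducing the
empirical failure mode of repeat-count markers for this trait.

What the generator does **not** emulate: sequencing error, recombination
within the gene, realistic mutation-rate heterogeneity, more than one
microsatellite mutation process, population structure beyond the four
subtypes, or any off-target genome for primers to mis-prime on. Passing tests
therefore demonstrate the pipeline's internal correctness and its behaviour
under the stated polymorphism structure — not robustness to raw-data noise or
genome-scale primer specificity.

## Numerical and policy choices

* Problem sizes in the tests and the acceptance script (a 3.5 kb gene, 8-allele
  discovery panels, 20-seed batches) were chosen so a full run takes well under
  a minute per seed on one CPU while every feature of interest — the longest
  repeat expansion included — still fits with conserved flanks.
* The anthocyanin formulas are implemented exactly as printed in their source,
  including the unconventional multiplication by the optical path length and
  the absence of a molar extinction coefficient; `compute_tac_standard`
  provides the conventional ε-normalized form for users who want absolute
  concentrations. Negative relative content is reported with a warning, not
  clipped.
* Degenerate inputs: empty FASTA → empty panel with a warning; a panel with a
  single distinct sequence → zero variants; <3 taxa → phylogeny error; design
  failures are returned as records (the suite always attempts all four
  markers), while stage-level errors in the CLI exit nonzero naming the stage.
* The gene model parser enforces the 7-exon/6-intron structure by default
  (`strict_structure=False` lifts it for other genes); features must tile the
  post-promoter span exactly, and the promoter must end immediately before the
  TSS.

## Known limitations

The mismatch binding model has no temperature dependence, so marker
transferability to other PCR programs is out of scope. p-distance trees are a
structural check only. Adjacent substitution columns are always counted as
separate SNPs; merging multi-nucleotide substitutions into single events is a
defensible alternative convention that is not implemented. Each allele-specific
marker always gets its own forward and reverse primer per group (a shared
common primer between the two pairs is never emitted). Primer specificity is
verified only against the supplied alleles, not a genome.
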