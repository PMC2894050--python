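# Methods

This note documents the models, conventions and numerical choices behind
`l1prom`, in the spirit of a methods appendix: what each stage computes,
which knobs matter, what the synthetic data does and does not emulate, and
where genuinely open design points were decided.

## Coordinates and formats

All internal coordinates are 0-based half-open on the forward strand;
conversion happens only at format boundaries (BED passes through unchanged,
GFF3's 1-based inclusive spans become `(start−1, end)`). Lower-case and N
bases are accepted on input and upper-cased; N never counts toward GC
content, CpG statistics or motif matches. Promoter-relative positions are
defined on the element's own strand: minus-strand UTRs are
reverse-complemented on extraction, so "upstream of the ATG" always means
5′ on the element.

## Monomer segmentation

Monomer copies are found by repeated best local alignment
(match +1, mismatch −1, gap open −2, gap extend −1) of each subfamily
template against the UTR, hard-masking each accepted subject span and
realigning until the best alignment falls below the acceptance floor
(identity ≥ 0.70 over ≥ 150 bp). Because tandem monomers do not nest,
masking is lossless and the iteration enumerates all acceptable copies.
Candidates from all templates are then chained greedily by score into a
non-overlapping set; hits more than 50 bp apart are split into separate
arrays and only the ATG-proximal array is kept. Monomer 1 is the
ATG-proximal copy, numbering away from the ATG — the convention that makes
"CpG islands in monomers 2–3" and a YY1 peak ~330 bp upstream of the ATG
mutually consistent with a short (~25–45 bp) non-monomeric spacer. All
thresholds are exposed in `SegmentationParams`. Local alignment may trim a
few mismatching bases at copy edges, so hit spans can deviate from exact
monomer boundaries by single bases; motif-to-monomer assignment is
unaffected because the planted motifs sit mid-monomer.

Subfamily is the template with the highest mean identity across a
promoter's hits, ties broken by total score and then the fixed priority
T_F > G_F > A. Elements classifying as F or unclassified are carried
through reporting but excluded from motif and island summaries.

## CpG islands

A 100-bp window slides in 1-bp steps; a window is marked when its GC
fraction strictly exceeds 0.50 and its Gardiner–Garden O/E
(N<sub>CpG</sub>·L/(N<sub>C</sub>·N<sub>G</sub>), CpGs counted fully inside
the window) strictly exceeds 0.60. Windows containing any N are never
marked, so masked sequence cannot seed an island. Marked windows that
overlap or abut merge into candidate spans; spans longer than 200 bp whose
*span-level* recomputed GC and O/E again pass are reported. Span-level
re-validation makes every reported island self-certifying; it can be
disabled (`revalidate=False`) for strict plain-dialect emulation. Note a
subtlety the tests encode: with merging and re-validation, raising a
threshold does not monotonically reduce the island *count* (a failing
merged span can split into passing fragments); what is monotone is the
marked-window set, and in the plain dialect the base coverage of calls.

Transition counting compares two pre-aligned equal-length monomers: at each
consensus CpG, observed T at the C position is a CpG→TpG transition and
observed A at the G position a CpG→CpA transition; other substitutions
count only as mismatches, and gap columns are excluded.

## Motif scanning and YY1 classification

Consensus patterns — YY1 `GGTCGCCATCTTGGT`, RUNX3 `TGCATTTCCATCTGAGGTA`,
and both printed E2F variants `SSCGGC` and `TTTSSCGC` (kept as separate
named motifs rather than silently choosing one) — are scanned by IUPAC-aware
mismatch counting; divergence is the mismatching fraction of pattern
positions, substitutions only (no indels inside a 15-mer, matching a
percent-of-positions rule). Every window at or below the scan cutoff
(default 0.40, generous enough to find degenerate sites) is a candidate;
overlaps keep the lower-divergence hit, ties leftmost; scanning is
forward-strand only since promoters are extracted strand-aware. A promoter
with ≥ 2 monomers is *intact* iff at least one YY1 occurrence in its two
ATG-proximal monomers diverges ≤ 20% (strictly greater than 20% ⇒
mutated; a minimal monomer with no hit contributes divergence 1.0), and
*potentially active* iff it has ≥ 2 monomers and intact YY1. At the 0.40
scan cutoff, random ~1-kb promoters yield background windows near the
cutoff; these cannot perturb classification, which only compares against
the 0.20 boundary (a spurious ≤ 0.20 window is a ~10⁻⁵-per-promoter event).

PFM columns tally counts over aligned equal-length occurrences; information
content uses a 0.25-per-base pseudocount,
`info[j] = 2 + Σ_b f_bj log2 f_bj`, so unanimous columns approach (never
reach) 2 bits as occurrences accumulate. A minimal matplotlib logo renderer
is included.

## Gene neighborhoods

A gene neighbors an element when their edge-to-edge gap is at most 100 kb
(0 for any overlap; the edge is inclusive). Orientation is sense iff gene
and element strands agree; the side is relative to the element's 5′ end,
with overlapping genes resolved by midpoint. Distance bins are half-open
[0,5), [5,10), [10,20), [20,50), [50,100] kb with a closed top edge, so
they partition [0, 100 kb]. *Intergenic* means no gene-body overlap and no
gene within the window; genic is its complement, and the two sub-states
(overlap vs proximity) are distinguishable from the neighbor records.
"20-kb surrounding composition" is read symmetrically as 10 kb per side,
excluding the element body, clipped at chromosome ends (`flank=` to
change).

## Statistics and reporting

Pearson correlation takes its two-tailed p from t = r√((n−2)/(1−r²)) with
n−2 df; t-tests are one-sample or Welch two-sample (both provided because
composition comparisons can be read either way); the chi-square test for
trend is the Cochran–Armitage statistic on (counts, totals, scores) with 1
df. The score variable is an explicit argument — defaulting to chromosome
rank by size, name-ordered on ties — because per-chromosome trend tests are
not well defined without one. Percentages round half-away-from-zero, the
convention that reproduces the survey's printed percentages from its
printed counts (e.g. 48/290 → 17, 100/124 → 81). No multiple-testing
correction is applied, matching the source analysis. Reference agreement
for all four tests was checked once against R 4.3.3 (`cor.test`, `t.test`,
`prop.trend.test`) and frozen as fixtures in the test suite.

## The synthetic genome

The generator emulates the statistical structure the analysis assumes,
not real L1 sequence. Subfamily monomer templates (204/208/200/206 bp for
T_F/G_F/A/F) are random GC-rich sequences with the YY1 consensus planted at
offset 100 and an instantiated E2F site exactly 70 bp downstream of it; the
CpG-rich variant has > 65% GC and ≥ 16 CpGs, and the CpG-poor variant
applies a C→T or G→A transition at every CpG outside the planted motifs
(motif-internal CpGs are exempt so that divergence plans stay exact). An
element is `[monomer]×n + spacer + ATG + 300-bp ORF stub` with monomer 1
ATG-proximal; island-flagged elements use the rich variant for monomers 2–3
and the poor variant elsewhere, and the spacer is sized so the monomer-2
YY1 midpoint falls 324–341 bp upstream of the ATG (realized per-element in
332–338, keeping the modal 10-bp histogram bin stable). YY1 divergence is
planted as an exact mismatch count inside the motif (mutated elements draw
4–6/15 per minimal monomer, intact 0–3/15); a 2% background substitution
rate outside motifs avoids touching or creating CpGs so island status
survives mutation. Islands are only assigned to elements with ≥ 3 monomers
so the planted rich span (≥ 2 monomer lengths) clears the > 200 bp filter
with margin.

All planted fractions (subfamily mix 60/8/32%, mutated-YY1 13%, islands
8.5%, genic elements 36%, antisense neighbors 77%, 87% of neighbor genes
beyond 20 kb) use largest-remainder quotas, so realized truth-table
frequencies match configuration exactly; monomer counts are 2 + Poisson
draws around per-subfamily means 4.1/5.6/4.26 (T_F/G_F/A). Genic and
intergenic elements are placed on disjoint chromosome groups — gene-rich
chromosomes with 40%-GC background and gene-free AT-rich (61.3% AT)
chromosomes — so neighborhood labels are realized exactly at desk-scale
densities; `near_gene` truth is nevertheless re-derived from the final
layout, and `gene_density = 0` produces a gene-free genome. Neighbor genes
are planted at exact edge distances drawn from the configured bin quotas
(genes may overlap each other, as real annotations do, but never an L1).
Minus-strand elements are written reverse-complemented with truth stored in
forward coordinates.

What the generator does **not** emulate: real T_F/G_F/A consensus
sequences, ORF content, target-site duplications, retrotransposition
dynamics, exon/intron structure, or chromosome-length variation. Passing
recovery tests therefore demonstrate that the pipeline's operations are
correct under the stated model — not that the thresholds are optimal for
real genomes.

## Problem sizes and determinism

The default study conditions are a 3-Mb genome (6 × 500 kb) with 200
elements; recovery cohorts in the tests use n = 100–200 with fixed seeds.
Genome-scale headline numbers from the original survey (1,464 elements,
subfamily counts 875/473/116, 124 islands, r = 0.588, χ² = 6.688, island
lengths 202–885 bp) depend on a full mouse assembly and a curated L1
database and are treated as descriptive context; the pipeline reports the
same *kinds* of quantities at desk scale. The paper-printed island length
range is a sanity band only: synthetic islands (two rich monomers plus
margins) average ~500 bp. Everything is single-threaded; a fixed seed gives
byte-identical outputs, which the test suite verifies by hashing whole
output trees.

## Known limitations

- Segmentation assumes tandem, non-nested monomer arrays; greedy chaining
  is exact for that structure but not for pathological overlapping
  candidates.
- Transition summaries compare only monomer copies whose aligned span
  length equals the template length (gapless comparison); indel-shifted
  copies are skipped.
- The per-chromosome "ratio" percentages of the original survey are of
  unstated definition; the package reports count-per-Mb and labels it as
  such.
- TRANSFAC matrix scoring is replaced by consensus mismatch scanning; the
  > 20% divergence classification rule is itself consensus-based, so the
  classification is faithful even though matrix scores are not reproduced.
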