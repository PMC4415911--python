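# Methods

This note documents the models, rules and conventions implemented in
`hcpanel`, the defaults chosen where the underlying study protocol left a
choice open, and what the synthetic tests do and do not demonstrate.

## Consequence classification from HGVS

The classifier consumes only the cDNA and protein HGVS strings produced by
an upstream annotator; it never consults a reference sequence, so it
validates form, not sequence content. Priority order:

1. A protein-level frameshift annotation (`fs`) wins outright — including
   over the splice window. A deletion spanning a splice acceptor but
   annotated `p.A1823Gfs*9` is a frameshift: the annotator has already
   resolved the downstream effect at the protein level, and protein-level
   evidence is treated as authoritative throughout.
2. Splicing: any change whose nearest affected position is within
   `splice_window` bases of an exon/intron boundary (default 2, symmetric
   across donor and acceptor — the canonical GT/AG dinucleotides).
3. Indels: frameshift when the affected reference span is not a multiple
   of 3. Two conventions matter here:
   - A single-base deletion/duplication whose first shifted codon is a
     stop is written by HGVS as a bare `p.X#*`. Mechanistically the stop
     arises from the shifted frame, so these are classified
     `frameshift_indel`, not `nonsense`. `nonsense` is reserved for
     substitution stop-gains.
   - A duplication of in-frame length whose protein annotation is a plain
     residue insertion (`p.X#_Y#ins...` rather than `p....dup`) is treated
     as frame-disrupting. This annotation-consistency convention mirrors
     how coordinate-based annotators resolve ambiguous duplication
     junctions, and it is what reproduces published class totals on real
     annotated tables.
   - For `delins`, the replaced reference span (not the net length
     change) feeds the frame rule; in practice annotators tag
     frame-disrupting delins with `fs` anyway.
4. Substitutions: stop-gain → nonsense; amino-acid exchange → missense;
   unchanged residue or `p.=` → synonymous; anything else (e.g. `p.?` deep
   intronic) → other.

## Candidate filter

Retention requires all four criteria (evaluated without short-circuiting,
so the retained set is independent of evaluation order):

| criterion | rule | default |
|---|---|---|
| region | exonic, or within the splice window | `splice_window = 2` bp |
| class | indel, nonsense, missense or splicing | — |
| frequency | 1000G MAF absent or ≤ `maf_max` | `maf_max = 0.01` |
| inheritance | genotype consistent with gene's mode | — |

MAF semantics: an absent annotation and an observed frequency of 0 both
mean "not seen in the reference panel" and both pass; the criterion
excludes only variants *observed* above the threshold. The criterion is
applied identically to SNVs and indels.

Inheritance: dominant (or unknown) genes accept any germline genotype.
Recessive genes require homozygosity, compound heterozygosity (≥ 2
filter-class variants in the same gene and sample), or a lone *strong
candidate*. A strong candidate is an unambiguously disruptive allele: a
canonical splice change or any protein-truncating change — substitution
stop-gains and frameshifts alike. (Restricting the clause to substitution
stop-gains would be inconsistent: a frameshift with an immediate stop is
at least as disruptive as a nonsense substitution.) Strong candidates are
retained as `retained_needs_curation` and resolve to `retained` only when
a curation entry with database or literature evidence matches the
gene + cDNA change; without one they are surfaced, not silently kept.

The QC pre-filter (quality ≥ 20, neighbor distance ≥ 5, depth ≥ 4)
reflects thresholds defined for SNV calling; by default indel calls bypass
it (`qc_indels = false` extends it to indels when the upstream caller
emits comparable metrics).

## Pathogenicity

Truncating classes (frameshift indel, in-frame indel, nonsense, splicing)
are deleterious by class; prediction columns attached to such variants are
ignored. Missense deleteriousness needs both in-silico features —
prediction (SIFT damaging OR PolyPhen-2 possibly/probably damaging;
"possibly damaging" counts as damaging by default, a conservative mapping
exposed as configuration) and conservation (PhyloP OR LRT conserved) — and
curation evidence. An absent tool call counts as not-damaging within its
OR, but each feature requires at least one tool with a call. Both feature
functions are monotone: upgrading any single tool call can never revoke a
damaging verdict.

## Pedigrees

Eligibility follows the three enrolment rules (age ≤ 35 with ≥ 1 affected
blood relative; 35 < age ≤ 50 with ≥ 2 affected in the same lineage;
age > 50 with ≥ 3). "Same lineage" is the paternal or maternal side of the
pedigree; when an explicit lineage column is absent it is derived by graph
connectivity from each parent (blocking paths through the proband and the
other parent), with siblings and own descendants as *nuclear*. Nuclear
relatives share both bloodlines and count toward either side's total.
Probands with multiple diagnosis ages (bilateral disease) store all ages;
the first enters age-based rules.

Segregation for a variant is `carriers/tested` over genotyped members
(proband included). *Complete* segregation requires every **affected**
tested member to carry the variant: an unaffected tested non-carrier is
the expected genotype and does not break completeness, which is how a 5/6
family can segregate completely while another 5/6 family (affected
non-carrier) does not.

Syndrome criteria (HBOCS, LFS, LS) are consumed as per-family input flags;
the package deliberately does not re-encode clinical guideline texts.

## MSI / EMAST / IHC

Marker panels are fixed name lists (NCI: BAT25, BAT26, D2S123, D5S346,
D17S250; extra dinucleotide: D18S64, D18S69; EMAST: MYCL1, D20S82, D20S85,
L17835, D8S321, D9S242, D19S394). Per panel, failed markers drop from
numerator and denominator; zero unstable markers → MSS; otherwise MSI-L
below `msi_low_fraction` and MSI-H at or above it. The 0.30 default places
2-of-7 unstable (0.286) in MSI-L and 3-of-7 (0.43) in MSI-H, matching how
extended-panel instability is graded in the EMAST literature; whether the
historical cut is a count or a fraction is not recoverable from the study
protocol, so the fraction form is exposed as configuration. EMAST
positivity is ≥ 1 unstable tetranucleotide marker. IHC change is
categorized from the normal−tumor staining difference, with marked loss at
≥ `ihc_loss_delta` (default 2) steps.

## Cohort summary

Percentages are rounded half-up to one decimal (the convention that
reproduces every published fraction: 18/99 → 18.2, 7/34 → 20.6,
18/88 → 20.5, 6/19 → 31.6). A carrier contributes to every gene-category
count it belongs to (categories overlap for multi-gene carriers);
`multi_gene_carriers` counts each such proband once. The onset-age
comparison defaults to the classical pooled-variance two-sample *t*-test
(the unnamed "t-test" of 2012-era clinical reporting), with Welch
selectable; identical constant groups return (t = 0, P = 1) rather than
NaN. Published onset-age means are not reproduced as checks because the
underlying per-relative ages are not fully recoverable from the printed
tables; the operation is instead verified against a textbook
pooled-variance oracle.

## Synthetic cohorts

The generator emulates input *structure*, not population genetics: no
linkage, haplotypes, mutation-rate or penetrance models. Defaults (one
choice, stated here, applied throughout the test suite):

- 10 families per cohort, 50 background variants per proband (scaled to
  5 × 30 in the fast recovery tests — the separation property is
  size-independent since every variant's fate is determined by
  construction);
- background MAF mixture with 70% mass uniform on (0.01, 0.5] (so the
  frequency criterion does visible work) and the remainder uniform on
  [0, 0.01], split 40% synonymous / 30% deep-intronic / 30%
  benign-profile missense;
- a default spike plan covering all five filter-accepted classes across
  dominant genes plus one recessive splice spike, heterozygous, with
  generated curation entries where the rules require them;
- marker instability rates per MMR status: deficient ≈ (mono 0.01,
  di 0.15–0.25, EMAST 0.5), proficient ≈ 0.005–0.02 everywhere,
  reproducing the dinucleotide + tetranucleotide signature of MSH3 loss;
- per-family random streams spawned from `(seed, family_index)`, so
  cohorts are reproducible under partial regeneration.

By construction every spiked variant satisfies all four criteria and the
pathogenicity rules, and every background variant violates at least one —
so perfect recovery (sensitivity = specificity = 1.0 over 20 seeds) shows
the pipeline implements its own rules exactly; it does **not** show
real-data performance, where annotation errors, borderline frequencies and
curation gaps blur the separation. The adversarial mode
(`n_adversarial > 0`) constructs curated, damaging-profile background
missense variants and verifies the false-positive count equals the
constructed overlap exactly.

## Degenerate inputs and numerical conventions

- Coordinates are 1-based inclusive `[start, end]`; the optional VCF
  reader converts at the boundary.
- Unparseable HGVS raises a `ParseError` echoing the offending token; in
  the batch pipeline such rows fall through to class `other` and are
  excluded with a recorded reason rather than aborting the cohort.
- Empty marker panels after dropping failed calls, missense variants
  without prediction profiles, groups of size < 2 in the t-test, and
  pedigrees with zero or multiple probands are all hard errors.
- Every variant entering the pipeline leaves it exactly once — as a
  deleterious call or with one machine-readable exclusion reason.

## Known limitations

- The HGVS dialect covers annotated panel-table output (substitution,
  del, dup, ins, delins, intronic offsets, ranges), not the full grammar
  (no inversions, alleles-in-cis, mosaic or RNA-level descriptions).
- Classification trusts the upstream annotator's protein calls; the
  package cannot detect annotator errors without a reference sequence.
- Syndrome-criteria flags are inputs; the package does not evaluate NCCN
  guideline logic.
- The curation gate models "reported in a locus database or publication"
  as a lookup table; it does not grade evidence strength.
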