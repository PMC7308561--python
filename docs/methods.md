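# Methods

`plastdeg` quantifies plastome degradation in parasitic plants. This note
documents the models and procedures the package implements, the parameters
that matter, what the synthetic-data generator does and does not emulate, and
the numerical choices behind the defaults.

## The quadripartite model and inverted-repeat detection

A canonical angiosperm plastome is a circular molecule of roughly 120–160 kb
laid out as LSC + IRb + SSC + IRa, where IRa is the exact reverse complement
of IRb and the large single-copy region (LSC) is by definition the longer of
the two inter-repeat arcs. The four junctions are named JLB (LSC/IRb), JSB
(IRb/SSC), JSA (SSC/IRa) and JLA (IRa/LSC). IR expansion and contraction move
these junctions into or away from particular genes, which is one of the
structural signatures of plastome degradation.

The detector defines the IR pair as the *maximal-length pair of circularly
disjoint intervals whose sequences are exact reverse complements of each
other*. Matching is exact: the clades this pipeline targets have repeats of
at least ~12 kb, so mismatch tolerance buys nothing at the boundary
resolution being reported, and exactness makes the optimum well defined. The
search runs a binary search over candidate repeat lengths (existence of a
valid disjoint pair is monotone in length, since trimming one base preserves
disjointness) with a double 64-bit polynomial rolling hash over the doubled
sequence, so origin-spanning repeats are found on circular inputs; the
winning pair is verified by direct string comparison, making hash collisions
harmless. Ties at the maximal length are broken toward the pair whose
flanking single-copy arcs are most unequal (the canonical long-LSC /
short-SSC layout), then toward the smallest start coordinate. Complexity is
O(n log n) hash probes; a 150 kb genome takes a few seconds in pure Python.

`min_ir_length` defaults to 1,000 bp — far below any real plastome IR in the
target clade, far above chance reverse-complement repeats in a 160 kb genome.
Sequences with no qualifying pair raise `NoIRFound` and are reported as
IR-lacking rather than force-partitioned.

Partitioning assigns the longer arc to LSC, labels the repeat copy that
follows LSC as IRb, and records `linear_offset`, the rotation taking the
input linearization to the canonical LSC-first frame. All reported
coordinates are post-rotation. Region metrics (sizes, GC) and junction
contexts are invariant to the input rotation and to strand flips — both are
property-tested.

GC content is computed over unambiguous A/C/G/T only; IUPAC ambiguity codes
are excluded from numerator and denominator and are never coerced to N. The
coding region is the interval *union* of all non-pseudo-flagged features
(overlaps counted once); non-coding is its complement, so coding + noncoding
always equals the genome size. Published "coding region" accountings differ
in whether introns and pseudogenes are counted; our definition is stated here
precisely so residual differences from other software are interpretable, and
it is deliberately not tuned to match any external tool.

## Gene status calling

Each gene of an autotrophic reference (the role a non-parasitic relative
plays in a degradation study) is classified in each target plastome as
**functional (F)**, **pseudogene (P)** or **deleted (D)**:

1. **Locate.** The spliced reference gene is searched against both strands of
   the target by Smith-Waterman local alignment with BLAST-like scores
   (match +2, mismatch −3, first gap base −5, each further base −2). On
   targets where the full quadratic fill would be slow, an edit-distance
   infix search (edlib) first narrows the genome to a handful of candidate
   windows; scoring and all reported evidence come from the Smith-Waterman
   refinement inside those windows. Circular targets are extended by a
   query-length prefix so origin-spanning genes are found.
2. **Deletion test.** The gene is deleted when the best hit fails any of:
   reference coverage ≥ 0.30, identity ≥ 60%, aligned span ≥ 30 bp, and
   Karlin-Altschul E-value ≤ 1e-4. The coverage/identity pair separates a
   trackable pseudogene remnant from "gone"; the span and E-value gates
   exclude chance-level local hits, which for short genes (tRNAs especially)
   can otherwise reach 0.3 coverage at 70–80% identity on random sequence.
   The λ ≈ 0.42, K ≈ 0.2 statistics were calibrated on random-sequence
   simulations under this exact scoring scheme (the published BLAST constants
   assume costlier gaps). Every deleted call is equivalent to the explicit
   `verify_absence` confirmation search, mirroring the local-BLAST
   verification step a curator would run.
3. **Frame analysis** (protein-coding genes only). The *full* reference CDS
   is re-aligned against the located window with a query-global, free
   target-end-gap alignment under the same scores — local alignment trims
   mismatching gene ends, which would hide substitutions near the terminal
   codon. Indels are read off this alignment; the gene is frameshifted when
   the *net* indel length within the CDS is not ≡ 0 (mod 3), so a
   compensating +1/−1 pair restores frame (individual indel positions are
   still reported as evidence). The located target segment is then translated
   in the reference frame from its start; any stop codon strictly before the
   reference's terminal codon is premature — no "90% length" leniency,
   because the rule is categorical. One frameshift or premature stop makes
   the gene a pseudogene.
4. **RNA genes.** tRNA/rRNA genes have no reading frame and can only be F or
   D, unless the target annotation itself flags every copy pseudo.

IR-duplicated genes resolve naturally to the *less degraded* copy: the best
local hit is the intact copy, and in annotation-based inventories a gene is
counted pseudo only when every copy is flagged. The gene inventory
deduplicates by gene symbol (tRNAs keep their anticodon suffix, e.g.
`trnV-UAC`, because losses are tracked at that resolution) and satisfies the
identities functional = protein-coding + tRNA + rRNA and total = functional +
pseudogenes by construction; deleted counts are relative to the reference
panel size.

Known limitation: a real partial remnant of a very short gene (aligned span
below ~30 bp) is indistinguishable from chance under this scoring and will be
called deleted; and a gene whose 3′ end is genuinely missing but which passes
the presence thresholds is frame-analysed including its decayed tail, which
can surface stop evidence — both behaviors are deliberate and documented
rather than special-cased.

## Event mapping on the phylogeny

Degradation is modelled as an ordered irreversible process F → P → D (the
Dollo assumption for gene loss: a pseudogenized gene does not regain
function, a deleted gene does not return). Given a rooted input tree — tree
inference is out of scope — and the species × gene F/P/D matrix, ancestral
states are reconstructed per gene by Sankoff dynamic programming over
{F, P, D} with step costs F→P = 1, P→D = 1, F→D = 2 and infinite cost for
any reversal; the root is fixed to F because the reference lineage is
autotrophic. Events are emitted on branches where parent and child states
differ. Because the costs are additive along the chain, delaying a
transformation is always cost-neutral; ties are resolved by DELTRAN (choose
the least-derived state compatible with the minimum, pushing events toward
the tips), which is deterministic and stated in the output metadata. Genes
are independent, so the total cost is the sum of per-gene minima. A P→D
completion on a descendant branch counts as its own event, which is how a
"pseudogenized deep, physically lost late" history is represented.

The mapper is property-tested against exhaustive enumeration of all 3^k
ancestral assignments on trees of up to 6 tips, including the check that the
DELTRAN assignment is always one of the enumerated optima.

## The synthetic-data generator

The generator is the test bed for every pipeline stage. It emulates:

- the circular quadripartite layout with IRa = revcomp(IRb) exactly;
- the empirical GC gradient IR > LSC > SSC (defaults 43% / 36% / 31%,
  per-base i.i.d. background at the region target);
- a panel of protein-coding/tRNA/rRNA genes on both strands, with real
  plastid symbols (ndhA–K, infA, matK, rps/rpl, trn with anticodon suffixes,
  the four rRNAs), IR-resident genes that are implicitly duplicated, and a
  gene spanning the JLB junction (the rps19 situation);
- planted degradation events placed on the branches of a clade tree:
  whole-gene deletions (both IR copies when duplicated), 1-bp frameshift
  indels, and premature-stop codon rewrites, composed along root-to-tip
  paths with irreversibility enforced at generation time.

Protein genes are built as a start codon, random sense codons and a stop, so
the reference panel is frame-clean by construction. Planted repeats are made
*maximal*: after assembly the bases flanking each junction are adjusted so no
chance complementarity extends the repeat past the planted boundary —
without this, one in ~four genomes would detect an IR one base longer than
planted. IR-copy edits are mirrored under reverse complement (a mirrored
insertion lands one base past the mirror point, complemented), so the repeat
pair stays exact and the truth region lengths stay consistent. Everything is
deterministic under the spec seed.

The default spec is study-scale: six tips (an autotrophic reference plus five
ingroup species), ~149 kb genomes (LSC 84 kb, IR 25 kb, SSC 15 kb), a
28-gene panel, and an event pattern echoing hemiparasitic clades — deep
shared ndh degradation, lineage-specific tRNA loss, and a pseudogenization
completed into a physical loss on a terminal branch. Routine tests use a
~6.4 kb toy version with the same qualitative structure, and the
100-replicate recovery properties run on randomized ~4–6 kb clades with 5–10
genes and up to 10 events; these sizes were chosen so the property suite
exercises every code path in minutes while the study-scale configuration is
still run end to end in targeted tests and the acceptance script.

What the generator does **not** emulate — and hence what passing tests do not
show about real data: nucleotide substitution along branches (targets differ
from the reference only by the planted events, so alignment identity is
near-100%, far cleaner than diverged real plastomes), sequencing or assembly
error, introns in the planted genes, partial gene remnants, annotation
errors, and IR boundary micro-shifts between closely related genomes.
Real-data behavior of the thresholds (coverage/identity/E-value) therefore
rests on their stated rationale, not on these tests.

## Bundled survey tables

`plastdeg/data/` ships two small TSVs with published region metrics and gene
content for 31 Santalales plastomes (facultative and obligate hemiparasites
plus the autotrophic reference *Erythropalum scandens*). They serve as
validation fixtures: every row satisfies LSC + SSC + 2·IR = total,
coding + noncoding = total, and the gene-count identities exactly, and the
five newly deposited species' printed dimensions drive the full-scale
partition-recovery checks.

## Numerical and degenerate-input choices

- Coordinates are 0-based half-open everywhere internally; GenBank's 1-based
  inclusive (and join()) forms are converted at the reader boundary.
  Origin-crossing features are stored as multiple intervals.
- Equal-length inter-repeat arcs (LSC = SSC) are resolved deterministically
  (first arc in scan order becomes LSC); zero-length arcs are tolerated.
- GC of a slice with no unambiguous bases raises `UndefinedGC` rather than
  returning a number.
- A junction is *inside* a gene iff one feature covers the bases on both
  sides of the boundary; otherwise the nearest covered bases upstream and
  downstream name the flanking spacer, with coordinate-then-name
  tie-breaking. A junction in an intron therefore reports the gene as both
  flanks rather than as containing it.
- Reference genes shorter than 12 bp are rejected (no meaningful local
  alignment seed).
- The reference species' matrix column is all-F by construction and is not
  re-aligned against itself.
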