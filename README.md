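# plastdeg

**Quantifying plastome degradation in parasitic plants.**

When a plant lineage shifts from autotrophy toward parasitism, its
chloroplast genome (plastome) degrades: the genome shrinks, the inverted
repeats expand or contract, and genes — the *ndh* family first — are
pseudogenized and eventually deleted outright. Comparative studies of
hemiparasitic clades such as the sandalwood order track this process by
partitioning each plastome into its quadripartite structure, tallying region
sizes and GC content, classifying every gene against an autotrophic
reference, and mapping the resulting loss/pseudogenization events onto a
phylogeny. `plastdeg` implements that entire comparative workflow as tested,
reusable software, for researchers in organelle comparative genomics and
parasitic-plant evolution.

## What it computes

A plastome is modelled as a circle LSC + IRb + SSC + IRa with
IRa = revcomp(IRb), so that

```
|LSC| + |SSC| + 2·|IR| = genome size
```

- **quadripartite** — finds the maximal pair of disjoint reverse-complement
  intervals (binary search over repeat length with a double rolling hash,
  verified exactly), rotates to the canonical LSC-first frame, and reports
  per-region size/GC, the coding/non-coding split (interval union of
  non-pseudo features), and the gene context of the four junctions
  JLB/JSB/JSA/JLA.
- **gene_status** — classifies each reference gene per target as
  **F**unctional / **P**seudogene / **D**eleted. A gene is deleted when its
  best local hit (Smith-Waterman, match +2 / mismatch −3 / gap −5,−2, edlib
  infix pre-screen on large targets) fails coverage ≥ 0.30, identity ≥ 60%,
  span ≥ 30 bp, or E ≤ 1e-4; a protein-coding gene is a pseudogene when the
  net indel length in its CDS is not ≡ 0 (mod 3) or a stop codon appears
  strictly before the reference's terminal codon.
- **phylo_events** — reconstructs per-gene ancestral states on a rooted
  input tree under irreversible Sankoff parsimony over {F, P, D} with costs
  F→P = 1, P→D = 1, F→D = 2, reversals forbidden, root fixed F, DELTRAN
  tie-breaking; emits per-branch events and an annotated Newick.
- **simulate** — generates annotated plastomes with planted quadripartite
  structure, IR-duplicated and junction-spanning genes, and degradation
  events placed on a clade tree, with full ground truth for every stage.

See `docs/methods.md` for the models, parameter rationale, and limitations.

## Worked example

Generate a small synthetic clade (six ~6.4 kb plastomes, one autotrophic
reference `REF` and five ingroup species with planted events) and run the
three analysis stages:

```python
from plastdeg import (
    RunConfig, simulate, detect_inverted_repeats, partition_quadripartite,
    region_metrics, junction_context, build_degradation_matrix,
    reconstruct_events,
)

clade = simulate.generate_clade(simulate.toy_spec(seed=1))
cfg = RunConfig(min_ir_length=200)

ref = clade.reference
part = partition_quadripartite(
    ref, detect_inverted_repeats(ref.sequence, cfg.min_ir_length)
)
m = region_metrics(ref, part)
print("sizes:", m.sizes)
print("JLB context:", junction_context(ref, part)["JLB"])

targets = [rec for name, rec in clade.records.items() if name != "REF"]
matrix = build_degradation_matrix(ref, targets, cfg)
print(matrix.table.to_string())

events = reconstruct_events(clade.tree, matrix)
print("total parsimony cost:", events.total_cost)
```

prints

```
sizes: {'whole': 6400, 'lsc': 3400, 'ir': 950, 'ssc': 1100, 'coding': 3596, 'noncoding': 2804}
JLB context: rps19
    rbcL matK infA ndhC trnV-UAC rps19 rrn16 ndhB trnN-GUU ndhF ccsA trnL-UAG
REF    F    F    F    F        F     F     F    F        F    F    F        F
sp1    F    F    F    P        D     F     F    F        F    F    F        F
sp2    F    P    F    P        F     F     F    P        F    F    F        F
sp3    F    F    F    P        F     F     F    P        F    F    F        F
sp4    F    F    F    P        F     F     F    F        F    D    P        F
sp5    F    F    F    D        F     F     F    F        F    D    P        F
total parsimony cost: 9
```

Reading the output: the partition recovers the planted 3400/950/1100 layout
(3400 + 1100 + 2·950 = 6400), and the LSC/IRb junction falls inside the
planted junction-spanning gene *rps19*. The matrix shows the planted
degradation pattern — e.g. *ndhC* pseudogenized across the whole ingroup and
physically lost in sp5 — and the event mapper places each event on the
correct branch: `ingroup ndhC F->P`, `clade45 ndhF F->D`, `sp5 ndhC P->D`,
and so on, for a total parsimony cost of 9.

The same workflow is available from the shell:

```bash
plastdeg simulate --out sim --seed 1
plastdeg partition sim/clade.fasta --out part --min-ir-length 200
plastdeg status --reference sim/REF.gb sim/sp*.gb --out status --min-ir-length 200
plastdeg events --tree sim/clade.nwk --matrix status/matrix.tsv --out events
```

Real studies substitute GenBank flat files of annotated plastomes (e.g.
downloaded once from NCBI) for the simulated inputs; `read_genbank` accepts
multi-record flat files and a lifeform mapping
(`FH`/`OH`/`Autotroph`). The package also bundles the published region and
gene-content survey of 31 Santalales plastomes
(`load_survey_regions()`, `load_survey_gene_content()`), which the test
suite uses to validate the partition and inventory arithmetic.

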