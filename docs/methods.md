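# Methods

`barcode_diet` implements a clone-library DNA-barcoding workflow for
predator gut contents: COI clone sequences from individual guts are
collapsed into operational taxonomic units (OTUs), each OTU is identified
against a local reference barcode library by a two-criterion rule, and the
resulting OTU × sample table is summarized into size-class diet statistics.
This note records the models, the parameters that matter, and the design
choices taken where the procedure is genuinely open.

## The identification model

Each OTU is tested against two independent lines of evidence:

1. **Identity criterion.** The best-hit percent identity of the OTU's
   representative sequence against the reference library must reach the
   species threshold (default **98%**). The 2% allowance absorbs
   intraspecific variation plus PCR/sequencing error at the COI barcode
   locus. Identity is computed from an optimal global alignment over
   *informative columns only*: any column containing a gap or an `N` in
   either sequence is excluded from both numerator and denominator. Barcode
   fragments at this locus are length-conserved, so low-divergence pairs
   align without gaps and the identity denominator is effectively the
   fragment length (658 for full Folmer fragments).

2. **Tree criterion.** The query must cluster *conclusively* with
   references of a single species on a bootstrapped neighbor-joining tree
   built over the query, its top `n_reference_hits` (default 10) reference
   hits, and `n_outgroups` (default 3) outgroups drawn from the nearest
   families outside the best hit's family. Conclusive clustering is
   operationalized as: reading the tree as rooted on the first outgroup's
   pendant edge, some clade containing the query (i) has bootstrap support
   ≥ `min_support` (default 50%), (ii) contains no outgroup leaf, and
   (iii) contains reference leaves that all carry the same name at the
   candidate rank. Ranks are tested most-specific-first
   (species → genus → family → order); the most specific rank achieved by
   any qualifying clade is the *clade-conclusive rank*. Clades containing a
   designated outgroup are skipped because the outgroups are a rooting
   device, not candidate relatives; without this exclusion the top clade
   would trivially certify order-level membership whenever outgroups come
   from the same order.

The decision rule combines the two criteria:

| identity vs threshold | clade-conclusive rank | call |
|---|---|---|
| ≥ 98% | species | species (best hit's name) |
| ≥ 98% | genus / family / order | that rank ("tree inconclusive at species") |
| < 98% | species | genus (species calls need both criteria) |
| < 98% | genus / family / order | that rank |
| any | unresolved | unresolved |

Two additional conventions: when the top identity is tied across references
of *different* species at or above the threshold, the call is demoted to
genus (the criteria jointly fail at species); and genus-level calls are
labeled "\<Genus\> sp.", numbered ("Asellus sp. 1", "Asellus sp. 2") when
several distinct OTUs land in one genus.

Raising the identity threshold can only demote calls (species → genus);
this rank-monotonicity is property-tested.

## Sequence primitives

**Alignment.** A Needleman–Wunsch/Gotoh global aligner with affine gaps:
match +1, mismatch −1, gap open 5, gap extend 2 (a gap run of length *L*
costs `open + (L−1)·extend`; end gaps are penalized). Traceback ties prefer
diagonal, then up, then left, making output deterministic. The DP fill is
JIT-compiled when numba is importable and falls back to pure Python
otherwise; both paths are exercised by an exhaustive-enumeration oracle for
short sequences and cross-checked against Biopython's `PairwiseAligner`
under the same scoring.

**Best hit.** An exhaustive identity scan of the whole reference library
replaces a heuristic database search. At barcode scale (≤ a few hundred
references of ~658 bp) the exact scan is fast and removes a class of
seed-and-extend failure modes. Ties are broken lexicographically by
accession.

**Dereplication.** Greedy centroid clustering in descending
clone-abundance order (ties by sequence string): each unique sequence joins
the first centroid at ≥ 98% identity, else founds a new OTU. Clone counts
are conserved exactly (property-tested). The 98% default matches the
species-delimitation threshold so that within-species clone noise collapses
while congeners stay apart. When only a published count table is available
(no deposited sequences), OTUs are built directly from its rows and the
decision rule is applied to the published identity values and clade ranks
("fixture mode").

## Distances, trees, supports

**K2P distance** `d = −½·ln(1−2P−Q) − ¼·ln(1−2Q)` over informative
columns, with *P*, *Q* the observed transition/transversion proportions; a
nonpositive log argument raises a saturation error naming the pair. The
p-distance is available as an alternative NJ input via configuration. K2P
was the era-standard barcoding distance and is the default; the choice is a
documented assumption, not an inference from the source analyses.

**Neighbor joining** is the standard Saitou–Nei agglomeration: minimize
the Q-matrix, join, update distances. Ties take the smallest `(i, j)` index
pair of the current working matrix (platform-independent); negative branch
lengths are clamped to zero with the clamped total recorded on the tree.
On additive matrices the implementation recovers topology and path lengths
exactly (tested to 1e−9 against an independent path-distance oracle on
random trees of 4–12 leaves, and against scikit-bio's NJ on random
matrices).

**Bootstrap.** Alignment columns are resampled with replacement (seeded,
default 1000 replicates), the NJ tree is rebuilt per replicate, and each
internal bipartition of the full-alignment tree is scored by the percentage
of replicates containing it. Site-pattern classes per sequence pair are
precomputed once so each replicate only re-counts classes over resampled
columns.

**Multiple alignment for tree input** is a star alignment anchored on the
best-hit reference: every sequence is pairwise-aligned to the anchor and
insertions are merged by per-position maximum. This is appropriate for
near-equal-length barcode fragments and is *not* a general progressive MSA;
with indel-free input it is an identity pass-through.

## Diet statistics

Predators are binned by total length into half-open size classes
I `[0, 100)` mm, II `[100, 200)` mm, III `[200, ∞)` mm. PCR success is
reported over non-empty guts only. Composition is **presence-based**: clone
libraries give presence/absence evidence, so each OTU counts once per
scope regardless of clone multiplicity; percentages are computed on exact
fractions and rounded only for display. The size-class overlap partitions
observed OTUs into seven disjoint cells by presence pattern. The predator's
own (self-DNA) OTU is retained by default so published-style totals
reproduce; `--exclude-self` recomputes everything without it, which can
only decrease richness counts (tested).

The packaged fixtures keep published values verbatim, including one record
whose printed total length is smaller than its body length (loaded with a
warning, not an error) and a count matrix whose cell total (269)
undercounts the sequenced clones (308) because extra clones from two deeply
sequenced guts were never tabulated; the loader validates the per-size-class
clone subtotals (85/142/81, total 308) from the predator records and
deliberately reconciles neither matrix marginal.

## Synthetic data

The generator evolves a random 658-bp ancestor down a known taxonomy under
the exact finite-time K2P transition probabilities (multiple hits modeled,
so the K2P estimator is consistent for generated data; verified within 5%
at d = 0.10 over 200 replicates). `ts_tv_ratio` is the expected
transitions-per-transversion ratio R (default 2.0; κ = 2R). Branch
divergences default to 0.05 (species), 0.10 (genus), 0.18 (family)
expected substitutions/site, placing conspecific queries above the 98%
identity band and congeners in the mid-80s–low-90s, the regime where the
decision rule has to discriminate. Within-species clone noise defaults to
0.005. The default taxonomy shape is one order of 3 families × 2 genera ×
2 species (12 references): deep enough for genus/family structure and
family-level outgroups, shallow enough that no pair approaches K2P
saturation.

Gut libraries mirror the study design: 30 samples, 10 clones each, 1–4 prey
species per gut with dominance-weighted multiplicities; optional self-DNA
contamination from a designated predator species. No indel process is
simulated by default and no PCR bias, chimeras, or secondary predation are
modeled — so passing recovery tests demonstrates correctness of the
clustering/placement/decision machinery under clean amplicons, not
robustness to those artifacts in real libraries.

For recovery experiments the bootstrap is run at 100 replicates per OTU
(supports for the relevant cherries are near-unanimous at default
divergences, so 100 replicates resolves the ≥50% support question with
ample margin) and two to five libraries of ~300 clones are scored per run;
end-to-end species-level accuracy at default settings is ≥90% across
seeds (observed: 100% on the seeds exercised by the tests).

## Known limitations

- The star MSA assumes near-length-conserved fragments; data with long
  indels needs a true progressive MSA upstream.
- Clade support uses bipartition frequencies of the reference topology
  only; no branch-length or likelihood-based placement.
- The exhaustive best-hit scan is quadratic in total sequence length and
  meant for curated local libraries, not GenBank-scale search.
- Fixture mode trusts the published identity values and identification
  levels; it cannot re-derive clade ranks from trees that were never
  deposited.
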