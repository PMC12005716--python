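# Methods

This note documents the models, parameters and numerical choices behind
`karyolg`, and what the simulation-based validation does and does not
establish.

## Linkage-group model

A linkage group is a set of orthologs inferred to have shared one
chromosome in the common ancestor of the sampled genomes. The working
signal is pure co-occurrence: for each universal single-copy ortholog we
record the vector of chromosome assignments, one slot per genome, in a
fixed (sorted) genome order. Under macrosynteny conservation, orthologs
of one ancestral group have identical vectors up to noise from
inter-chromosomal translocation.

**Clustering.** Exact-vector identity classes with at least
`min_support` members (default 5) become linkage groups. Remaining
orthologs attach to the unique group whose consensus differs in at most
`floor(epsilon * G)` slots (`epsilon` default 0.05 over `G` genomes);
with seven genomes this floor is 0, so every mismatching ortholog lands
in the *noise set* — by construction these are exactly the translocated
genes, and they feed the rate estimator rather than being discarded.
Groups are renumbered 1..L by descending member count, ties broken on
the consensus vector, so numbering is invariant to input row order.
Exact-vector clustering (rather than graph community detection) was
chosen because the target signal is vector-structured and the decision
is then fully auditable; a variant that masks chromosome pairs failing
the homology test before clustering is available through the homology
tables.

The choice of `min_support` should scale with group size: coincidental
classes arise when several genes move from one group to the same target
chromosome in the same lineage. With ~236 genes per group the default 5
is safe; analyses with hundreds of genes per group and heavy
translocation (e.g. the rate-recovery validation at 500 genes/group) use
a support threshold of 20.

**Homology testing.** For a genome pair, each chromosome pair (n_a, n_b
assigned orthologs of N total, s shared) gets the hypergeometric upper
tail `P[X >= s]`, BH-corrected across all chromosome pairs of that
genome pair (`alpha` default 0.05). The statistic depends only on the
contingency counts, so it is invariant to gene relabelling.

## Ancestral reconstruction and event calls

Each tip genome is summarised by its fused sets — the partition of
linkage groups by shared consensus chromosome — which expand to binary
characters over all C(L, 2) unordered group pairs. Characters are
reconstructed independently by Fitch parsimony (down-pass intersections/
unions, up-pass resolution), with residual ambiguity at the root
resolved to the unfused state: absent other evidence we prefer not to
posit an ancestral fusion. A Dollo mode (single gain, losses free)
treats fusion as irreversible and is available as a toggle; both modes
are provided because the reconstruction criterion in this kind of study
is a genuine modelling choice, and they differ exactly where fusion
homoplasy exists.

A node's chromosomes are the connected components of its fused-pair
graph (components absorb intransitive pair reconstructions), so 1n is
the component count. Branch events are read off parent/child partitions:
fissions first (parent components straddling child components), then
fusions over the fragments; a multi-way merge is reported as one event
with `n - 1` pairwise steps, matching how multi-chromosome fusions are
described as a unit. The synapomorphy flag on a fusion requires every
underlying pair-character to be 1 in all tips below the branch and 0 in
every other tip; on terminal branches the same rule marks
autapomorphies.

**Duplication vs fission.** A second chromosome carrying a group is a
*duplicate copy* when the fraction of the group's placed orthologs
present in two copies, split one per chromosome, reaches
`dup_threshold` (default 0.5); otherwise it is treated as a fission
fragment. Zero informative orthologs defaults to FISSION with a
warning. Duplicate copies are only observable at tips (internal
reconstruction runs on fusion characters alone), so duplications are
called on terminal branches — which matches the one duplication in the
bundled scenario.

Tip karyotype states ignore (chromosome, group) occupancy cells below
`max(2, 0.05 x group placements)`: single translocated genes are noise,
not karyotype structure. An intra-group fission (one group split through
its middle with no duplication) is not representable at linkage-group
resolution; the event-partition merges such fragments, a documented
limitation.

**Mixing.** For a fused chromosome the mixing index is the observed
number of adjacent gene pairs with different group labels divided by its
exact expectation under random permutation,
`E = (n-1) (1 - sum n_i (n_i - 1) / (n (n-1)))`. The index averages 1
under random order, approaches 0 for preserved blocks, and exceeds 1 for
over-dispersed alternation; chromosomes at or above 0.5 are flagged
"well mixed". The flag is descriptive only and never feeds inference.

## Translocation rate

For a genome pair, `c` is the fraction of universal single-copy
orthologs whose chromosome in either genome violates their group's
consensus there; noise-set orthologs are first attached to their unique
best-matching group (no unique match counts as violating). The rate is
`r = c / t` with `t` the time since the pair's common ancestor, read
from the dated input tree as half the patristic distance — the stated
divergence-time normalization taken literally; because both lineages
accumulate changes over `t`, `r` estimates the two-lineage rate, and
outputs always report `c`, `t` and `r` separately so a per-lineage
convention can be applied downstream.

## The simulator and the bundled scenario

The generator builds an ancestor of `n_lgs` chromosomes with
`genes_per_lg` genes each and evolves it in preorder along a dated tree.
Scripted events are written in linkage-group coordinates and resolved to
the chromosome currently carrying the group; background events are drawn
per branch as Poisson(rate x branch length). Every applied event is
recorded fully resolved with its own RNG seed, so ledger replay is
byte-exact; per-branch seeds are hashes of (global seed, child label),
so editing one branch's script never perturbs another branch.

Event semantics: FUSION concatenates two chromosomes and then shuffles a
fraction π of positions among themselves (π = 0 pure block
concatenation, π = 1 full interleave; the expected mixing index is
non-decreasing in π). FISSION splits at a gene index. DUPLICATION copies
a chromosome's genes onto a new chromosome as second paralog copies; a
`fraction` < 1 copies a random subset, modelling partial duplication
(default 1.0). TRANSLOCATION moves k random genes to random other
chromosomes; SHUFFLE permutes order. Gene loss is not simulated: the
ortholog set of interest is universal and single-copy, and loss would
only shrink it.

The bundled `chiton_radiation` scenario is the study condition for all
recovery results: 20 linkage groups x 236 genes (4720 orthologs, the
scale of a universal single-copy set over seven genomes), seven tips
(two conchiferans, five chitons), and the event route that reproduces
every reported haploid count — three stem fusions (the three-way 4+16+18
plus 7+10 and 8+9; chiton ancestor 16), one further stem fusion for
Chitonida s.l. (15), no change to Chitonida s.s., three Deshayesiella
fusions one of which is four-way (1n = 11), two Callochiton fusions
(13), the Liolophura fusion (π = 0.05, hence not well mixed) followed by
a 0.6-fraction duplication, three genus-stem fusions (10) and two
different fusions per congener (8 and 8). Groups 19 and 20 are touched
by no event and serve as the conserved-group control. The duplication
fraction must be partial: a full duplication leaves the two affected
groups with no single-copy members and they would be unrecoverable from
single-copy vectors; 0.6 represents substantial but incomplete paralog
retention. Background translocation runs at 0.05 events/My (k = 1),
i.e. an expected ~27 moved genes (≈0.6%) per root-to-tip lineage — under
the 1%-noise regime the recovery claims are stated for.

Tree calibration: the *Acanthochitona* split at 23 My and crown
Polyplacophora near 280 Mya are fossil-anchored; the root (crown
Mollusca) sits at 540 Mya and the remaining internal ages are scenario
choices on that scale. Chromosome lengths, gene spacing and bitscores
are synthetic conveniences (even spacing, copy-1 pairs scoring above
paralog pairs); they carry no biological claim.

**What passing does and does not show.** The simulator reproduces the
processed form of a real multi-genome comparison — single-copy ortholog
placements on chromosomes under fusion/fission/duplication/translocation
— so recovery results validate the inference logic end to end. It does
not emulate assembly error, fragmented scaffolds, annotation noise,
ortholog misassignment, gene loss, or rate variation among lineages;
performance on real assemblies depends on those upstream steps.

## Validation problem sizes

The test suite runs the full 4720-gene scenario once (shared fixture),
a 600-gene variant for replay/determinism checks, 100 seeded
classifier trials at 2% translocation noise, a 5000-gene two-tip
rate-recovery simulation, and exhaustive brute-force oracles
(hypergeometric tails by enumeration at N ≤ 25, parsimony by exhaustive
labeling at ≤ 6 tips, mixing expectation by permutation enumeration).
The acceptance script re-runs the full scenario and measures the four
headline quantities; all sizes complete in well under a minute each on
one CPU.

## Known limitations

* Dollo and Fitch disagree under fusion homoplasy; no attempt is made to
  pick the "right" criterion automatically.
* Duplications are only detectable on terminal branches (copy evidence
  lives in tip genomes).
* Intra-group fission is invisible at linkage-group resolution.
* Mapping inferred group numbers onto any published numbering is a user
  supplied lookup (here recovered from simulator truth by majority
  membership); inferred ids rank by size only.
* The MBH route assumes precomputed similarity tables; no aligner is run.
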