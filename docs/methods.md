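# Methods

## Scope and data model

`fignet` detects hybridization from three independent lines of evidence —
site-pattern asymmetry (D-statistics), gene-tree concordance-factor
asymmetry with network γ fitting, and cophylogenetic host switching — and
cross-matches them. All statistics consume either a biallelic genotype
matrix (taxa × sites, derived-allele counts, VCF-backed) or a collection of
rooted per-window gene trees (Newick). Branch lengths on species trees and
networks are in coalescent units (1 unit = 2N generations); tips are
contemporaneous (ultrametric), which the simulator validates.

## Coalescent simulation on species networks

Gene trees are simulated under the multispecies coalescent on a species
tree plus zero or more *hybridization pulses*. Each pulse is an
instantaneous event at a fixed time: looking backwards, every lineage
present on the recipient branch at that time traces into the donor branch
independently with probability γ (the inheritance probability). This
matches the interpretation of γ as the fraction of the recipient genome
contributed by the donor, and deliberately excludes continuous migration.
Within each branch, k lineages coalesce at rate k(k−1)/2 per unit time;
above the root coalescence continues until one lineage remains.

Mutations follow the infinite-sites model at rate θ/2 per unit branch
length: each mutation is one biallelic site whose derived allele is carried
by the leaves under the mutated edge. There is no back-mutation and no
sequence-level (multi-hit) mode. When an outgroup is declared, edges whose
subtree contains the outgroup carry no mutations, so the outgroup is fixed
ancestral and the matrix is outgroup-polarized by construction — the
synthetic analogue of polarizing genotype calls on an outgroup species.
Each locus occupies one genomic window (default 10 kb) so the window
machinery and the jackknife blocks align with loci. Missingness is applied
per genotype as an independent Bernoulli mask.

Defaults: one haploid sample per species (one accession per species is the
standard design for this kind of resequencing panel); θ defaults to 1 per
coalescent unit and is raised to ~4 in the validation studies so a 10-kb
window carries a realistic few dozen SNPs. No recombination within a locus;
no demographic size changes. Organelle loci are simulated as a single
non-recombining genealogy in which each pulse either captures the *whole*
organelle lineage pool into the donor (probability `capture_prob`) or
leaves it — organelle capture is all-or-nothing per lineage history, unlike
the per-lineage nuclear routing.

Reproducibility: all randomness derives from counter-based Philox streams
keyed by (master seed, stream id, locus index), so the same seed is
bit-identical and locus i does not change when `n_loci` does.

## Windows and window trees

Site filter: a site is kept when its missing fraction across all samples is
at most 40%. Windows: non-overlapping base-pair windows (the trailing
partial window is retained and left to the SNP-count filter — the cleanest
reading of a fixed-grid design) or fixed-SNP-count windows of `size` SNP
ordinals every `step` ordinals (step ≥ size leaves a gap of step−size
SNPs). Windows with fewer than 50 SNPs are dropped. Coordinates are 1-based
inclusive internally; the BED export converts to 0-based half-open
explicitly.

Per-window trees use pairwise allele-sharing distances (mean |f_i − f_j|
over pairwise-complete sites, which is the Hamming fraction for haploids),
Jukes–Cantor corrected (−(3/4)·ln(1 − 4p/3), capped just below the p = 3/4
saturation), neighbor joining (scikit-bio), negative branch lengths clamped
to zero, rooted on the outgroup. Pairs sharing fewer than 10 sites are
undefined; taxa causing undefined pairs are dropped from that window
(most-undefined-first), and windows with fewer than four usable taxa are
skipped. A distance method replaces per-window maximum likelihood because
every downstream statistic consumes topologies only; externally computed
Newick gene trees can be substituted without code changes.

## Concordance factors and the greedy consensus

A clade's CF is the fraction of gene trees supporting it. Clades are
canonicalized to the split side not containing a reference taxon (the
outgroup in pipeline use). Gene trees with missing taxa count toward a
clade only when the bipartition's smaller side is fully present and the
restricted split is still informative; the denominator is therefore
per-clade. The species tree is the greedy consensus: clades sorted by CF
(ties broken on the lexicographic form of the clade, deterministically) and
accepted when compatible (disjoint-or-nested) with everything accepted so
far; the output can be non-binary. Bootstrap 95% percentile intervals over
gene-tree resampling quantify CF uncertainty; they stand in for Bayesian
concordance credibility intervals while preserving the downstream
non-overlap logic, and the interfaces accept per-window tree samples so a
Bayesian backend could be slotted in.

## D-statistics

Group derived-allele frequencies p1, p2, p3 are means over non-missing
member taxa (member species are sample replications). With the outgroup
fixed ancestral, per-site weights are abba = (1−p1)·p2·p3 and
baba = p1·(1−p2)·p3; with one haploid member per group these reduce to the
classical pattern counts. D = (Σabba − Σbaba)/(Σabba + Σbaba). The standard
error is a weighted delete-one jackknife over genomic windows with weights
proportional to each block's informative mass (abba+baba), following the
standard weighted-jackknife variance formula, because windows differ widely
in information content. Significance defaults to |Z| ≥ 3; an optional
Benjamini–Hochberg adjustment across a scan exists but is off by default
(per-test reporting is the field's convention for these scans). Sign
convention: D > 0 implicates gene flow between P2 and P3, D < 0 between P1
and P3.

Test enumeration: at a chosen grouping level (species, section, subgenus,
main clade), each monophyletic group is a unit (non-monophyletic groups are
excluded and reported); a test ((A,B),C) is emitted for every unit pair
{A,B} and outward unit C such that MRCA(A,B) excludes C — i.e. every
four-taxon arrangement concordant with the rooted species tree. An optional
toggle emits alternative arrangements for branches whose CF falls below a
threshold (for topologically unstable regions); it is off by default since
no principled threshold exists.

## Quartet CFs, the minor-topology test, and γ fitting

For a species *tree*, the internal path length t (coalescent units)
separating a quartet's two pairs gives expected CFs
(1 − (2/3)e^(−t), (1/3)e^(−t), (1/3)e^(−t)) — standard coalescent theory,
validated here against both the package's own simulator and msprime. The
equality of the two minor topologies is the ILS null; it is tested with an
exact two-sided binomial test on the minor counts (exact rather than χ²
because minor counts can be small), with an optional BH correction across
branches and a CI-overlap report for the two minor CFs.

A single reticulation (donor → recipient, inheritance γ) predicts quartet
CFs that are the γ-mixture of two parental trees: the base tree and the
base tree with the recipient clade regrafted as sister to the donor. Both
parental trees' internal-edge lengths are free parameters shared where the
clades coincide; γ and the lengths maximize the multinomial log
pseudolikelihood Σ_q Σ_k n_qk log CF_model (L-BFGS-B, bounded, best of 10
multi-starts by default). Candidates where the two parental trees induce
identical quartet systems are rejected as unidentifiable. Model selection
follows the hmax rule: the reticulation is kept only if it lowers the
negative log pseudolikelihood by more than δ. δ = 1.5 by default,
calibrated as the 95th percentile of the null drop on reticulation-free
five-taxon simulations (5,000 loci, 100 replicates) — i.e. ≈5% false
selection. Scope is deliberately one reticulation over user-nominated or
small enumerable candidate edge pairs; full network topology search is out
of scope.

## Cophylogenetic reconciliation

Host and associate trees must be binary; host node times come from branch
lengths (topological rank order as fallback). The reconciliation optimum is
computed by exact dynamic programming over associate nodes × host edges:
cospeciation at a host node, duplication on an edge, host switch from an
edge to any *time-overlapping* edge (open-interval intersection — an
explicit approximation to zoned timing rules), and losses charged per host
node passed. Multi-host associate tips (from failure to diverge) are placed
by a coverage recursion charging one failure-to-diverge per spanned host
split and losses for missed sides. The associate root may enter at any host
edge at no charge. All co-optimal histories are enumerable up to a cap;
identity is the full event history (placements, pairings, switch landing
edges). At the package's target scale (≤ ~24 tips) the exact DP replaces
genetic-algorithm search, so GA-style tuning parameters are configuration
no-ops. Correctness is checked against a brute-force enumerator that
explicitly places every associate node on every host edge.

Cost schemes: cospeciation/duplication/loss/failure-to-diverge ∈ [0,1],
switch ∈ [0,2]. Scheme selection scans a grid, requires both permutation
tests significant (α = 0.05 — the conventional level, as no other is
canonical), then takes the lowest observed cost, breaking ties by fewest
switches then the lexicographic cost tuple. Permutation tests: random tip
mapping (shuffle the tip map) and random associate topology (uniform
labelled binary topology via uniform edge insertion), p = (1 + #{null ≤
observed})/(N+1) — the add-one convention avoids p = 0.

## Cophylogeny simulator

Forward in time along the host tree. At each host split a lineage on that
edge cospeciates (default probability 0.85), misses one daughter (a
sorting loss, 0.10), or fails to diverge (0.05 — persists on both
daughters, creating multi-host tips). Along branches, duplication
(0.02/lineage/unit) and switching (0.10/lineage/unit) are Poisson;
switch targets are uniform among contemporaneous host edges
(distance-weighted preference is out of scope). Defaults were chosen once
to produce mostly-codivergent associate trees with a few switches per
15-tip history — the regime the reconciliation stage is designed to read —
and are not fitted to any dataset. Under this event set a lineage cannot go
globally extinct (a loss keeps it on the sister side), so the degenerate
failure mode is a history with fewer than two surviving lineages, which is
retried with a derived seed and errors out after 20 attempts. The event log
is ground truth: every cospeciation, duplication, loss, failure to diverge,
and switch (with donor and recipient host clades) is recorded.

## Integration

Significant D results map to unordered clade pairs via the sign rule;
minor-topology verdicts and γ fits attach to the same canonical pair key,
deduplicated across taxonomic levels. A host switch matches a
hybridization event when its donor and recipient intersect-or-nest one in
each of the event's two clades (either orientation); a switch inside a
single clade never matches. This operationalizes a verbal matching
criterion in an auditable, refinement-monotone way. Geographic clustering
of an organelle tree is scored by the Fitch parsimony score of the tip
region character against tip-label permutations (lower = more clustered);
the permutation null makes the visual claim testable.

## Validation studies and problem sizes

`fignet.studies` packages each validation as a function; the acceptance
script and `tests/test_acceptance.py` run them at these sizes (chosen to
give stable verdicts in a few minutes on one CPU):

- D null calibration: 100 replicates × 1,600 loci (θ = 4, ≈ 47k sites per
  replicate), internal branch 0.5; checks mean D ≈ 0 and |Z| ≥ 3 rate ≤ 2%.
- D power: 60 replicates with a γ = 0.3 pulse; power ≥ 95% with positive D.
- Quartet CFs: 30,000 loci at t ∈ {0, 0.5, 1, 2}; majors within 3 binomial
  SEs of theory, minors equal within 3 SEs.
- Minor-topology test: 100 null + 50 alternative replicates at 2,000 loci.
- γ recovery: 25 replicates × 5,000 loci per γ ∈ {0.1, 0.25, 0.4};
  |bias| ≤ 0.05, ≥ 90% of estimates within ±0.1.
- Species tree: 100 random 15-taxon trees (internal ≥ 0.5 units), 1,000
  gene trees each; recovery ≥ 95%.
- Reconciliation: DP = brute force (cost and optimum count) on random 3–5
  tip pairs over a 20-scheme grid, exactly.
- Cophylogeny: 40 planted-switch replicates (recovery ≥ 90%), congruent
  pair p ≤ 0.01 at 199 permutations, random-pair p uniform (KS).
- Event matching: 25 coupled and 25 decoupled joint simulations.

## What the simulations do and do not show

The generator reproduces the statistical structure the methods rely on —
MSC gene-tree discordance, pulse-like introgression, infinite-sites
biallelic SNPs aligned to windows, organelle capture, event-logged
cophylogenies — but not sequencing error, alignment or genotype-calling
artifacts, recombination within windows, repeat content, demographic size
changes, or selection. Passing tests therefore demonstrate that the
estimators are correct and calibrated under their model assumptions, not
that any particular empirical dataset satisfies those assumptions. The
study system's published headline quantities depend on the original
resequencing data and are intentionally not encoded anywhere in this
package.

## Known limitations

- Level-1, pulse-style hybridization only; one reticulation per fit.
- The quartet-CF path-length formula treats each quartet's internal path as
  a single exponential race, exact for species trees with one sample per
  taxon, and the mixture model is exact only when the recipient clade
  contributes a single lineage at the pulse.
- The reconciliation DP charges switches a flat cost and ignores intra-edge
  event ordering; timing feasibility is interval overlap, not full zone
  logic.
- NJ window trees are a consistency-grade stand-in for per-window ML; at
  very low per-window signal they will be noisier than ML trees.
- `read_vcf` loads genotypes into memory; it targets desk-scale matrices
  (millions of sites × tens of taxa), not population-scale cohorts.
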