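# Methods

This note documents the models, numerical choices and limitations of
`rdrpscout`, in the order the pipeline runs them.

## ORF extraction under alternative genetic codes

ORFs are maximal stop-free codon runs between consecutive stop codons,
with no start-codon requirement, because transcriptome assemblies are
frequently fragmentary and viral polyproteins need not begin at an AUG
within a contig. Both strands and all three frames are scanned; the
paper trail for real screens does not fix strandedness, and
negative-sense virus contigs are routinely deposited in either
orientation, so scanning both is the safe default (this assumption is
flagged here deliberately). Three code tables are used: 1 (standard), 4
(UGA→Trp) and 6 (UAA/UAG→Gln), covering the reassignments that
otherwise fragment RdRp ORFs of viruses in ciliates and similar hosts.
The minimum length of 60 nt is measured on complete codons only, so 60
nt means 20 aa; terminal partial codons are discarded. Codons
containing N translate to X, which is score-neutral in profile search
and never counts as an identity in alignments.

Cross-table duplicates are removed per contig: every pair of
hit-bearing ORFs from the same accession is globally aligned with
match 1, mismatch 0 and free gaps — a parameter-free scheme whose
optimal score is the longest common subsequence — and when identities
divided by the shorter length equal 1 the shorter ORF is dropped.
Exact length ties drop the higher code table, then the larger
strand/frame key, making the operation deterministic and idempotent.

## Profile HMMs

A profile has match states for alignment columns with gap fraction
< 50%. Emissions use one unit of background-proportional pseudocount
mass per column; for a single-row seed this leaves half the probability
mass on the pseudocount, which is the intended behaviour for
one-sequence families (heavily smoothed but usable). Insert emissions
are tied to the background. Transition counts along each row receive
Dirichlet-style priors (M→{M,I,D}: 1.8/0.1/0.1; I→{M,I}: 0.3/0.1;
D→{M,D}: 0.3/0.1); inserts adjacent to deletes are attributed to the
neighbouring match-to-match path since an I↔D transition is not
modelled. The background is the seed's residue frequencies blended 1:1
with the Robinson–Robinson table, which keeps profiles from families
with biased composition from drifting too far from a realistic null.
Seed rows are not phylogenetically weighted; an overrepresented genus
therefore pulls the profile toward itself, a known bias of count-based
profile construction that users should counter by curating seed
diversity.

Scoring is local Viterbi in base-2 log-odds: uniform entry into any
match state (probability 1/M), free exit after any match state, and an
i.i.d. background null over exactly the residues the alignment
consumes. There is no length-modelled null and no MSV/bias filter —
this is a deliberate departure from HMMER's plan7 pipeline in favour of
a small, fully testable model whose Viterbi and Forward scores are
verified against exhaustive path enumeration (to 1e-9 bits on all
profiles with M ≤ 3 and sequences of length ≤ 5). Forward sums odds
ratios over all local paths and is always ≥ Viterbi. The kernels are
numba-compiled; a 350-residue sequence against a 400-state profile
scores in well under a millisecond.

### Calibration

Significance uses the extreme-value (Gumbel) law expected for optimal
local alignment scores. Decoys drawn i.i.d. from the profile background
are Viterbi-scored and a Gumbel is fitted by maximum likelihood
(`scipy.stats.gumbel_r.fit`); `P(S ≥ s) = 1 − exp(−e^{−λ(s−μ)})`. With
10,000 calibration decoys the empirical fraction of fresh decoys with
p < 0.01 lands within [0.005, 0.02], and p-values on independent decoys
are uniform to a KS statistic < 0.05 at n = 5,000. Defaults: 5,000
decoys of length 350 per profile inside the pipeline (calibration
accuracy at the 1e-6 threshold is dominated by the Gumbel slope, not
the decoy count); 10,000 in the standalone calibration command.
Because score distributions depend mildly on sequence length, p-values
for ORFs much shorter than the calibration length are slightly
conservative. E-values are p-values times the number of ORFs scanned in
the same code-table pass, so a constant p-value threshold corresponds
to a database-size-adjusted E-value threshold, matching per-table
searches.

The numbers produced by this calibration are not interchangeable with
HMMER E-values: the pseudocounts, null model and fitting procedure all
differ. A cross-check test therefore compares engines at the level that
is comparable — both must accept held-out family members and reject
background decoys at P ≤ 1e-6 — and they agree exactly on that.

## Classification

IDscore = bit score ÷ alignment length in amino acids, computed on the
single best-scoring local alignment per (ORF, profile). The alignment
span (not a wider envelope) is used as the length. Sorting: best
IDscore < 0.25 → unclassified; a second significant profile less than
20% below the best → ambiguous; otherwise classified, with "exactly 20%
lower" classifying and "exactly 0.25" not unclassified. The margin test
uses a relative-epsilon guard so that score pairs that are exactly at
the boundary in real arithmetic (e.g. 0.50/0.40) classify despite
floating-point rounding. Ties in IDscore break by bit score, then
profile name. Classified ORFs are trimmed to the matched span; this
"core" is the unit for clustering, motif analysis and host summaries.

## Clustering and diversity

Greedy representative clustering processes sequences longest-first
(ties by id) and joins the first cluster whose representative matches
at ≥ threshold identity, founding a new cluster otherwise — the
definition of incremental identity clustering, implemented directly
rather than through word-filter heuristics, so results are exact and
order-deterministic; the brute-force transcription of the same rule
over a full pairwise matrix is the test oracle. Identity is LCS over
the shorter length, as in deduplication. Cluster-increase statistics
filter both sets to a length cutoff (default 400 aa, the typical
full-length RdRp core) before counting. Alignment diversity reports
mean pairwise identity (excluding doubly-gapped columns) and per-column
Shannon entropies in nats over residue frequencies.

## Motif C, co-occurrence, hosts

Motif C is read at an annotated profile column ("anchor") through the
stored Viterbi match map of the core's best hit, which makes the
location reproducible instead of manual. Cores whose hit does not cover
the anchor fall back to a pattern scan: X-D-X with the first residue in
{G,S,A,I,N,H} and the third in {D,N,E,Q}, preferring the occurrence
nearest 70% of the core length (where the triplet sits in full-length
cores); the wider first-residue set admits rarer variants. The
13-residue window (5+3+5, '-'-padded at edges) feeds the positional
census.

Co-occurrence counts best×second-best profile pairs over classified
records with at least two significant hits and normalises each row by
its maximum, so every nonzero row peaks at exactly 1.0 and the diagonal
is structurally zero.

Host categories are decided by ordered keyword tests on exact
semicolon-delimited lineage tokens (case-sensitive, so "Fungi" never
matches inside another name): no Eukaryota → metagenomic; then Fungi,
Viridiplantae, Arthropoda, Vertebrata; Metazoa without the last two →
invertebrates; remaining Eukaryota → protists. The seven categories
partition all inputs. Folding non-eukaryotic and unannotated lineages
into "metagenomic" approximates annotation-based grouping and is the
known coarsening of this rule set. Host summaries count each exact
duplicate core once per family group.

## Intron detection

Candidates are all GT..AG substrings within a length window (default
40–2,000 nt, generously bracketing the 98–132 nt introns that motivate
the module). Each is annotated with its AU fraction, a junction
log-odds score against a fixed plant-like consensus PWM (donor
AG|GTAAGT, acceptor TTTTGCAG|G; consensus bases 0.7, the invariant
GT/AG 0.97, uniform background), and the change in longest-ORF length
its excision causes (computed under code table 1 and verified to match
re-running ORF extraction on the spliced sequence).

Selection maximises the longest ORF over subsets of non-overlapping
candidates, with ties broken towards fewer introns, then higher summed
junction score, then genome order — so intron-free input returns the
empty subset. Two eligibility filters apply to selection (reporting is
unfiltered): junction score ≥ 24 bits (a perfect consensus scores 27.1;
random GT..AG pairs essentially never reach 24), and AU fraction at
least 0.10 above the whole-contig AU fraction. The AU filter encodes
the defining observation about these introns — roughly 68% AU against a
56% genome — and is what prevents a failure mode of a pure longest-ORF
objective: a chance near-consensus donor inside an upstream gene can
pair with a genuine acceptor and fuse two coding regions into an ORF
longer than the true polymerase; such chimeric excisions span ordinary
~50% AU sequence and fail the filter. Subset search is exhaustive for
≤ 15 eligible candidates and beam search (width 50, candidates in
genome order) above that; the two agree whenever both run. ORF-breaking
candidates are reported but never selected, since selection only ever
improves the longest ORF.

The stop–start motif scan expands a degenerate consensus (both
`(X/Y)` groups and IUPAC letters; U≡T) and reports windows with at most
a configurable number of mismatches (degenerate positions match their
alternatives at zero cost) by 1-based end coordinate. DNA is used
internally throughout; reports render motifs in the RNA alphabet.

## Synthetic data generator

The generator is first-class, tested code and defines the study
conditions for every end-to-end check.

*Families.* An ancestral core (default 400 aa) is drawn from the
Robinson–Robinson background, a motif-C triplet from
{GDD, SDD, GDN, IDD, ADN, ADD} is planted at 70% of its length, and the
triplet ±2 columns are held invariant. Members substitute each free
site independently with probability 1 − e^{−d} (default divergence
d = 0.3 expected substitutions/site, a realistic within-family level
that leaves members ~75% identical to the ancestor), replacement
uniform over the other 19 residues. No indels are simulated —
substitution-only evolution keeps members trivially aligned so every
oracle stays simple; consequently the generator does not probe
insert/delete state estimation, and passing tests say nothing about
indel-rich real alignments. The seed alignment covers the first half of
the members; the second half is held out for recovery measurements.
Divergence high enough to push mean pairwise identity below 0.15 is
recorded as a warning in the returned truth.

*Contigs.* Each member is reverse-translated with uniform synonymous
codon choice under a code table drawn from {1,4,6}; table-4 members are
forced to contain at least one TGA-Trp codon (and table-6 members a
TAA/TAG-Gln) so the code-table machinery is genuinely exercised — the
ancestor always carries ≥2 Trp to make that possible. The coding region
is bracketed by in-frame stops, wrapped in random UTR-like flanks
(60–300 nt), fragmented to a random 60–200 aa window with probability
0.3, and reverse-complemented with probability 0.5. Decoys (default
200, 400–1,500 nt) are random transcripts with 10% low-complexity and
10% GC-extreme cases to stress calibration. Lineages cycle through
fixtures covering all seven host categories. The default preset — five
families × 20 members plus 200 decoys — is the condition under which
the package promises ≥95% held-out recovery, zero classified decoys and
≤1% fragment misassignment.

*Spliced genomes.* Layout leader–N–ORF2–ORF3–L with an instantiated
stop–start consensus before ORF2, ORF3 and L. Introns (default lengths
132/98/131 nt, AU target 0.68 versus ~0.56 intergenic background) carry
exact consensus donor/acceptor context; insertion sites are chosen
where the L coding sequence already reads AG|…|G so the exonic PWM
positions are consensus too, and a 12-nt all-frame stop block inside
each intron guarantees the unspliced L ORF is broken regardless of
intron length modulo 3. An AU target below the background is allowed
but recorded as a warning, since the AU-excess filter then loses its
discriminating power.

All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; no global state.

## Problem sizes and determinism

The acceptance suite runs the full pipeline on the default preset
(~28,000 ORFs against 5 profiles, ~90 s total on one CPU), 500 random
DP-oracle instances, 200 clustering-oracle trials, a 10,000-decoy
calibration with 5,000 fresh decoys, and 50 three-intron genomes plus
15 intron-free genomes. The acceptance script uses 20 three-intron and
10 intron-free genomes. These sizes are the package's own choice of a
desk-scale experiment; all quantities are recomputed at run time. The
pipeline is byte-deterministic: re-running with the same seed
reproduces every output file exactly (artifact paths are stored
relative to the run directory for that reason).

## Known limitations

- Substitution-only synthetic evolution (no indels, no phylogenetic
  correlation between members); real families violate both.
- The i.i.d. null without length correction makes p-values mildly
  length-dependent; mitigated, not removed, by calibrating at a typical
  ORF length.
- No ribosomal-frameshift handling and no Met-initiated ORF calling.
- The splice PWM is a fixed minimal consensus; organisms with divergent
  splice signals need a different PWM (exposed as module constants).
- Greedy clustering is exact but quadratic; it is meant for thousands,
  not millions, of cores.
- Classification fractions on real databases depend on the database
  snapshot and profile set; the pipeline reports them but makes no
  claim that they reproduce any particular published split.
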