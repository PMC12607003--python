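# Methods

`spacerlink` implements the computational core of a CRISPR-based
virus–host linking analysis for virome datasets: detecting repeat–spacer
CRISPR arrays on host and viral scaffolds, matching spacers to viral
protospacers under strict retention criteria, summarizing the resulting
bipartite networks, measuring spacer conservation across datasets,
curating auxiliary metabolic gene (AMG) calls, and screening viral
genomes for compact type V effector candidates, genome size classes, and
direct terminal repeats (DTRs). Every stage is exercised against a
seeded synthetic community whose ground truth is known by construction.

## CRISPR array detection

Arrays are modelled as R(S₁R)(S₂R)…(SₙR): n+1 near-identical direct
repeats interleaved with n unique spacers. Detection follows the
CRT/MINCED family of algorithms:

1. **Seeding.** Exact k-mers (k = minimum repeat length, default 23 bp)
   recurring at gaps compatible with one repeat–spacer period
   (`[min_repeat + min_spacer, max_repeat + max_spacer]`) are chained;
   chains with ≥ `min_repeats` occurrences (default 3) become candidates.
2. **Extension.** The shared seed is extended one column at a time in
   both directions. An extension column is accepted only when it is
   *unanimous* across all repeat copies. The configured per-repeat
   mismatch-fraction bound (default 0.2 vs the per-column majority
   consensus, ties broken A<C<G<T) is enforced as a final validation of
   the extended repeats. We chose strict extension over budget-gated
   extension deliberately: with a mismatch budget, random flanking
   columns are absorbed until the budget is spent, which blurs repeat
   boundaries; unanimity keeps boundary calls exact whenever repeat
   copies are exact, at the cost of not extending across point mutations
   near repeat edges.
3. **Validation.** After full extension, every spacer must lie within
   `[min_spacer_len, max_spacer_len]` (defaults 25–60 bp; the minimum
   mirrors a MINCED run with the minimum spacer length raised to 25).
   A violating spacer rejects the entire candidate — the repeat is never
   truncated to rescue the spacers, matching MINCED's filter semantics.
4. **Resolution.** Overlapping candidates are resolved greedily by more
   repeats, then longer span, then smaller start.

Spacer sets are dereplicated at 100% identity with equal length required
(optionally reverse-complement aware), keeping the first-seen identifier.
Whether clustering at 100% identity should also collapse proper
substrings is ambiguous in common practice; because downstream
conservation analysis requires exact length matches, dereplication here
never collapses a shorter sequence into a longer one.

## Spacer→protospacer matching

The matcher replaces a `blastn -task blastn-short` search with an exact,
enumerable definition so that results can be verified against a
brute-force oracle. A spacer of length L may align to a target gaplessly
along any diagonal; end-trimmed contiguous windows down to
⌈`min_query_coverage`·L⌉ are allowed (no internal gaps). Per (diagonal,
strand) the longest window with ≤ `max_mismatches` mismatches is
reported, ties broken by fewer mismatches, then leftmost; one report is
kept per (spacer, target, start, strand).

Retention criteria (defaults): at most 1 mismatch, no gaps, query
coverage ≥ 0.90, E-value ≤ 1e-4, both strands searched. A base aligned
to N is always a mismatch — N forgives nothing, mirroring megablast's
conservative treatment of ambiguous bases.

Significance uses Karlin–Altschul ungapped statistics with
blastn-short-like scoring (match +1, mismatch −3; λ = 1.374, K = 0.711):

    S' = (λ·S − ln K) / ln 2        (bit score)
    E  = m · n · 2^(−S')            (m = spacer length, n = database length)

For near-exact matches of ≥ 23 nt this criterion is essentially never
binding; it exists so the full retention rule is reproducible without an
external aligner. In viral-element mode, targets shorter than 10 kbp are
excluded from linking.

The engine is implemented with vectorized per-diagonal mismatch totals
plus an exact necessary-condition filter (total diagonal mismatches ≤
`max_mismatches` + trimmable columns), with candidate diagonals and
target-edge overhangs resolved exactly in scalar code.

## Virus–host networks

A link is a distinct (host MAG, viral node) pair; its weight counts
*distinct spacers* of that MAG matching that node (not alignment
positions — "targeted 20 times" is read as 20 spacers of one host's
complement). Viral scaffolds binned into a vMAG aggregate to one node,
and a spacer hitting several member scaffolds of one vMAG counts once.
Hyper-targeted elements are links with ≥ 20 distinct spacer hits.

Cross-phylum calls require the linked hosts to span ≥ 2 distinct phyla
after dropping non-compliant hosts: a supporting host must carry its
array-bearing scaffold(s) on ≥ 10,000 bp and have contamination
≤ 5.00% (both boundaries inclusive). Hosts without a phylum label are
excluded with a warning rather than an error.

Cross-site targeting matrices count, for each ordered (source, target)
dataset pair, source spacers with ≥ 1 retained match into the target's
viral elements, reported as a percent of the source complement at one
decimal.

## Spacer conservation

Sharing between two dereplicated spacer complements requires exact,
equal-length identity; reverse complements count, and a spacer matching
in both orientations counts once. The reported percentage is
2·shared/(n_A + n_B) — each shared spacer counted once per dataset. The
alternative literal reading shared/(n_A + n_B) is exposed via
`convention="single"`; the default is the convention that reproduces the
published pairwise percentages exactly. Multi-copy detection collapses
reverse complements and reports sequences occurring ≥ 2 times in an
undereplicated set.

## AMG curation

Three rules filter putative AMGs in a VIBRANT-style annotation table
(v-scores in [0, 1]; 1 = fully virus-like annotation):

1. `END_OF_SCAFFOLD` — the AMG is the first or last gene on its scaffold
   (gene ordinal, not bp distance).
2. `HIGH_VSCORE` — the AMG's own KEGG or Pfam v-score is ≥ 1.
3. `HOSTLIKE_FLANKS` — **all** KEGG-scored genes among the ≤ 4 genes
   upstream and ≤ 4 downstream have v-scores < 0.25, with at least one
   scored flank present. The quantifier is genuinely ambiguous in the
   underlying rule statement; "any" would discard AMGs adjacent to a
   single host-like gene, which contradicts the retention of curated
   AMGs in mixed neighborhoods, so "all" (an entirely host-like
   neighborhood) is the default and both quantifier and threshold are
   arguments. Genes without a KEGG v-score are ignored by rule 3.

Verdicts are independent of row order; a gap in a scaffold's gene index
is an error because flanking context would be undefined. Category
summaries report counts and proportions over kept AMGs only.

## Effector mining, genome size, DTRs

The effector screen takes the 10 kbp regions directly upstream and
downstream of each viral CRISPR array (clipped at scaffold bounds), calls
ORFs, keeps those 300–800 aa inclusive, and scans the proteins for RuvC
motifs. The ORF caller is minimal by design: both strands, bacterial
code (table 11), starts ATG/GTG/TTG (translated as Met), one ORF per
stop-delimited frame segment (first start codon to stop), stop codon
required. It is not a gene finder — no RBS model, no coding statistics —
which is sufficient for screening windows for large ORFs.

RuvC motifs are residue-class regular expressions with one anchored
catalytic residue each, constrained to thirds of the protein:

| motif | default pattern | catalytic anchor | span |
|---|---|---|---|
| RuvC-I | `[ILMVF]x{1,2}[TS]xD` | D | N-terminal third |
| RuvC-II | `Ex{2,3}[GA]` | E | central third |
| RuvC-III | `[DN]xD` | terminal D | C-terminal third |

These are deliberately permissive defaults validated only via
planted-motif tests; no formal community definition of the motifs
exists, and the patterns are configuration, not doctrine. A candidate is
"complete" when all three motifs occur with strictly increasing anchor
positions. Per-element candidate counts dereplicate at exact protein
identity.

Genome size classes: standard < 200 kbp ≤ jumbo < 500 kbp ≤ megaphage.
DTR detection returns the longest k ≥ `min_len` (default 20 bp) with
prefix(k) = suffix(k), computed exactly as the longest border of the
sequence via the KMP failure function (linear time; a 50 kbp random
sequence yields 0 with overwhelming probability).

## The synthetic community generator

The generator emits host scaffolds carrying planted arrays whose spacers
are copied (with controlled mismatch counts) from viral scaffolds,
orphan spacers with no target, viral scaffolds from a log-normal length
law plus explicit jumbo/megaphage-scale lengths, exact DTRs on selected
viruses, viral arrays with nearby reverse-translated RuvC-motif ORFs,
VIBRANT-style gene tables with one planted AMG curation scenario per
scaffold, and CheckM-style MAG metadata.

Design choices that matter for interpreting test results:

* **Background composition** is i.i.d. uniform A/C/G/T, which maximizes
  the distinguishability of planted repeats at the tested lengths. Real
  genomes have skewed composition, repeats, and shared k-mer content;
  passing tests demonstrate algorithmic correctness on the planted
  structure, not false-positive rates on real sequence.
* **Determinism.** Each scaffold draws from an RNG stream seeded by the
  root seed plus a CRC32 of the scaffold id, so adding scaffolds never
  perturbs earlier ones; identical config + seed gives byte-identical
  files.
* **Placement** of arrays, DTRs, protospacers and ORFs is uniform with
  rejection sampling against previously planted features (1,000 retries,
  then an error naming both features).
* **Central mismatches.** Mismatches on planted spacers are confined to
  the window every ≥ 90%-coverage end-trimmed alignment must contain
  (positions [L−⌈0.9L⌉, ⌈0.9L⌉)). Without this, an edge mismatch could be
  trimmed away and a 2-mismatch plant would be recovered as a 1-mismatch
  alignment, making the recorded mismatch count inconsistent with the
  matcher's view.
* **Boundary guard.** The single host base on each side of a planted
  array is set to differ from the corresponding spacer-adjacent base, so
  a chance-unanimous flanking column can never extend a detected repeat
  past the planted boundary. This makes exact boundary recovery a
  deterministic guarantee rather than a high-probability event.
* **Effector genes** reverse-translate a motif-bearing protein template
  (filler residues chosen so they cannot form any default motif) with one
  fixed codon per residue, prefixed by a stop codon so the ORF caller
  starts exactly at the planted ATG. Codon usage is not realistic and is
  not meant to be.
* **AMG scenarios** cycle kept / end-of-scaffold / high-v-score /
  host-like-flanks, one per viral scaffold, so rule outcomes cannot
  interact. Host-like flank scores are drawn from [0, 0.24] so 3-decimal
  rounding cannot land on the 0.25 threshold.

Defaults describe a small but structurally complete community: 12 hosts
of 60 kbp, 20 viruses (log-normal median 30 kbp, σ = 0.4, floor 12 kbp,
first two records at 250 kbp and 520 kbp to cover the jumbo and
megaphage classes), 1–2 arrays per host, 3–8 spacers per array of
25–50 bp, repeats 23–40 bp, 70% of spacers copied from viruses with
mismatch counts distributed 0.7/0.2/0.1 over {0, 1, 2}, DTRs of 100 and
250 bp, 20% of viruses carrying an array with an 80% chance of a planted
450 aa effector ORF. Tests and the acceptance script scale some of these
down (e.g. 8 hosts × 40 kbp, 10 viruses without the megaphage records
for linking runs) — problem sizes chosen to keep each stage's behaviour
fully observable while the whole suite stays quick to run.

## Numerical conventions

* Internal coordinates are 0-based half-open; all written reports are
  1-based inclusive.
* Printed percentages round half-up (not banker's), which matches human
  reporting convention; internal fractions are unrounded floats.
* Shared-spacer and targeting percentages round at 2 and 1 decimals
  respectively, as in their table conventions.

## Known limitations

* The array detector seeds on exact k-mers, so arrays whose repeat
  copies share no exact 23-mer (heavily mutated repeats) are missed;
  strict extension also stops at point mutations near repeat edges.
  Both are acceptable for ground-truthed evaluation and conservative on
  real data.
* The matcher is an exhaustive scan suitable for desk-scale inputs
  (megabases), not a seeded heuristic for terabase databases.
* The effector screen is window ∧ length ∧ motif only; it deliberately
  omits HMM/BLASTp homology confirmation and phylogenetic placement, so
  its candidates are screening hypotheses, not classifications.
* AMG curation consumes an existing annotation table; it does not
  predict AMGs or assign v-scores.
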