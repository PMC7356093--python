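# Methods

`straindiff` compares two complete assemblies of near-identical bacterial
strains and characterises their differences, with emphasis on insertion-
sequence (IS) elements. This note records the models, the parameters that
matter, the numerical conventions, and what the synthetic benchmark does and
does not demonstrate.

## Whole-genome diff

**Model.** The two genomes are assumed to be colinear (no large
rearrangements) and nearly identical, differing by point substitutions,
one-letter indels, and multi-base inserted runs ("long inserts", ≥ 2 bp;
the configurable `long_insert_min` separates them from one-letter indels).
Under those assumptions a whole-genome alignment can be scaffolded by
*anchors*: k-mers occurring exactly once in each genome and shared between
them. Uniqueness-in-both is the load-bearing choice — a dispersed element
present in tens of copies contributes no anchors, so repeats can never
mis-anchor the chain; the alignment inside repeat copies is simply inherited
from their being identical in both genomes.

- `k` (default **21 bp**): long enough that a random 200 kb–5 Mb genome is
  dominated by unique k-mers, short enough that anchors re-start within a few
  bases after every variant. Validated k ≥ 15.
- **Chaining** maximises the number of anchors in a subset strictly
  increasing in both genomes (weighted longest-increasing-subsequence over
  maximal runs of consecutive same-offset anchors). Among equal-cardinality
  chains the one minimising total |offset| drift wins, then the earliest
  predecessor — the chain is a pure function of the input. Run-merging makes
  the DP quadratic in the number of *runs* (a few hundred for a 200 kb pair),
  not anchors. Merging assumes collinear same-diagonal runs do not interleave
  with other diagonals closer than k, which holds whenever duplicated context
  at a variant is shorter than k (target-site duplications are 2–10 bp).
- **Chain coverage floor** (default **0.5**): if the chain anchors less than
  half of either genome the inputs are not a near-identical pair and the diff
  aborts rather than emit nonsense.
- **Gap classification.** Segments between consecutive chain blocks are
  aligned by global Needleman–Wunsch with match +1, mismatch −1, linear gap
  −2, end gaps penalised, and a deterministic traceback (diagonal, then
  consume-A, then consume-B). The edit transcript is decomposed into runs:
  each maximal gap run is one insert (1 bp → indel, ≥ 2 bp → long insert),
  each mismatch column one substitution. `N` never matches anything,
  including another `N`, and never anchors.
- **Hamming shortcut.** Equal-length gap pairs with at most
  `substitution_ceiling` (default **2**) mismatches are emitted directly as
  substitutions. Two is the largest provably safe ceiling under this scoring:
  d substitutions score L − 2d while any gapped alignment of equal-length
  segments scores at most L − 5, so d ≤ 2 can never be beaten by an indel
  pair, whereas d = 3 sometimes is. The shortcut is therefore exactly
  equivalent to the full DP (and is tested against it).
- **Left normalisation.** An inserted or deleted run inside repeated context
  is only defined up to shifts; both the differ and the simulator's truth
  tables shift every indel maximally left, making "exact coordinate
  recovery" a well-posed criterion (the same convention as VCF indel
  normalisation).
- **Reporting.** `aligned_identity` is matches over all aligned columns
  (anchored bases + gap-alignment columns, gap columns counted), in percent.
  Variants carry 1-based positions in both genomes; an insertion's position
  in the non-carrier genome is the base immediately before the insertion
  point (0 = before the first base). Applying the variant list to genome A
  reconstructs genome B exactly — a property tested on every synthetic pair
  and on fuzzed random pairs.
- **Circular replicons** (off by default): genome B is rotated so the first
  anchor aligns the origins, the offset is reported, and the diff proceeds
  linearly. Variants spanning the cut point are not specially handled.

Because anchoring-and-chaining is one of several reasonable whole-genome
alignment strategies, coordinate-level agreement with any *other* aligner is
not guaranteed, only event-level agreement; all exactness claims are against
the package's own conventions.

## Insert typing

Differential long inserts are clustered by **single linkage**: two inserts
share a type iff connected through pairs at ≥ `identity_threshold` (default
**90%**). Each pair is globally aligned in both orientations (elements insert
on either strand) and the better orientation is kept.

The *linkage* statistic counts every alignment column, gaps included. The
conventional gap-excluded identity, 100 × (1 − *p*-distance), is reported per
type (as the realised within-type minimum) but is deliberately not used for
linkage: when a short insert is globally aligned to an unrelated long one,
the aligner scatters the short sequence onto its best-matching positions and
the gap-excluded figure approaches the per-column match probability of that
best embedding (~89% for a random 378 bp/853 bp pair under this scoring) —
uncomfortably close to any threshold one would choose. Counting gap columns
sends unrelated length-mismatched pairs to ~40% while leaving genuinely
related pairs (same length, percent-level divergence) essentially unchanged.

Types are numbered by decreasing member count, then first occurrence; the
partition itself is invariant to input order.

## Transposon identification and census

**Terminal repeats.** An element is recognised by its terminal inverted
repeat (TIR): the longest exact prefix equal to the reverse complement of the
suffix, reported when ≥ `min_tir_len` (default **10 bp** — long enough that
exact genome-wide matches of both ends within a length window are non-random
in megabase genomes, short enough for typical IS-element TIRs). Insertion
duplicates the target site, so a leftmost-normalised called insert usually
carries its TSD as a prefix and the element body sits at a shifted placement.
The detector enumerates every placement reachable by rotating the run against
its flanks (bounded by `max_tsd_len`, default 16 bp) and, at each placement,
the candidate TSDs: a run prefix matching the right flank, a left-flank
suffix matching the right flank (the presentation at a differential element
locus, where the insert sits between two target copies), or none
(`min_dr_len` default **3 bp**). The candidate with the longest TIR wins;
ties prefer TSD-bearing, least-shifted placements.

A single copy can present a *chance-extended* inverted repeat — the exact
TIR extended a base or two into that copy's private TSD or into the shared
core. The family-level TIR is therefore decided by **majority vote over the
members' detected TIR strings** (`element_type_from_members`); only the
repeat identical across the family survives the vote. A type with no
detected TIR is not a transposon; both detections (TSD and flanking direct
repeat) are evaluated and the one supported by the sequence is reported.

**Census.** All copies of a type are found by exact string match of the TIR
(left ends) and its reverse complement (right ends), pairing ends whose span
falls within `length_window` (default 0.3×–1.05× the consensus length) and
accepting candidates greedily shortest-span first without overlap — the
greedy rule prevents nested or adjacent occurrences from producing chimeric
calls and is compared against a naive quadratic oracle in the tests. A
TIR-bounded element reads identically from both strands at its ends, so
strand is assigned from the interior by a shared-k-mer vote against the
consensus (ties to '+'). Copies are full-length iff within
`full_length_tolerance` (default **10 bp**) of the type's longest observed
copy. Exact matching is a deliberate scope decision; a mismatch-tolerant scan
is out of scope, so a copy diverged *inside the voted repeat region* would be
missed — with exact implanted copies, census recall and precision are both
100% by construction, and that invariant is tested.

**Excision scars.** For each differential element locus, the empty
orthologous site is inspected: a tandem duplication of the target
(`dr` immediately repeated) is the signature of an element that excised; a
single target copy is an ordinary pre-insertion site. The cut point within a
tandem repeat is ambiguous, so scar positions are left-normalised the same
way indels are. A pre-existing tandem duplication of a target site is locally
indistinguishable from a scar; the simulator refuses to implant elements at
such sites so the synthetic truth stays unambiguous (a ~(1/4)^dr per-site
coincidence in real data remains a caveat of the method itself).

## Annotation impact

Region calls use closed intervals (an event touching a CDS boundary counts as
CDS), then a strand-aware **promoter window** upstream of the CDS start
(default **150 bp** — promoters are rarely annotated in bacterial
deposits, so the window length is an explicit, reported choice), then
intergenic. Long inserts and element copies inside a CDS are
`gene_disrupted`; indels whose length is not a multiple of three are
`frameshift`; substitutions are translated in-frame with NCBI translation
table 11 into `synonymous` / `missense` / `nonsense`. Gene-panel rows compare
CDS and promoter sequences between strains by global alignment with gaps
counted as differences, so `differs` is true iff any base changed; an
unresolvable locus tag flags the row `missing` rather than aborting. Partial
codons at CDS ends are truncated before translation.

## Neighbor joining and bootstrap

Canonical Saitou–Nei agglomeration on a validated symmetric matrix of
*p*-distances (mismatched columns / compared columns, gap-containing columns
excluded from both counts; zero comparable columns is an error). Q-criterion
ties break on the lexicographically smallest pair of cluster labels (a
cluster is labelled by its smallest leaf), so the tree is deterministic.
Negative pendant lengths are clamped to zero with the deficit moved to the
sister branch, preserving their sum; on an additive matrix the generating
topology and branch lengths are recovered exactly (tested to 1e−9 for 4–10
leaves, and cross-checked against an independent implementation).

Bootstrap support resamples alignment columns with replacement (seeded
generator, seed exposed on the CLI), rebuilds the tree per replicate, and
annotates each internal edge with the percentage of replicates containing the
same bipartition. The multiple alignment behind the bootstrap is a **star
alignment** anchored on the longest member — adequate for families at
percent-level divergence, not for deeply diverged sets. Degenerate case: if
every pairwise distance is zero the topology carries no signal and supports
are reported as 100 by convention.

## The synthetic benchmark

`simulate` draws an i.i.d. ancestor at the requested GC content (default
**0.40**, a realistic figure for the motivating organisms) with
non-overlapping CDS features (start/stop codons enforced, internal in-frame
stops removed, so translation-based checks are meaningful), then implants,
via one master seed with per-stage substreams:

- an element library — default three types: 853 bp and 782 bp transposon-like
  elements with 24/26 bp TIRs and 4/6 bp TSDs, and a 378 bp repeat-less type,
  mirroring the length classes of the motivating comparison;
- shared dispersed copies placed before the strains split (default 30 + 12),
  identical in both strains;
- per-strain differential inserts (default 8 + 8, the second transposon type
  confined to strain B), each with TSD, random orientation, and per-copy core
  divergence (default **0.005/bp**, TIRs untouched — within-type identity
  then realises ≈ 98–99%, matching the >97% regime the method assumes);
  one insert is placed inside a gene interior and recorded as the disrupted
  locus;
- one-letter indels (default 4), substitutions (default 1), and optional
  excision scars (element in strain A, tandem TSD in strain B);
- every event placed ≥ 50 bp from every other and from gene bodies
  (except the designated disruption), so each inter-anchor gap contains one
  event and exact recovery is well-defined.

The default genome is **200 kb** — large enough to hold the full event
complement at realistic density while a complete pipeline run stays in
seconds; `full_scale_config` keeps the same event structure at larger
genome sizes. The generator emulates the *event structure* of a real strain
pair, not sequencing: there are no assembly errors, no homopolymer artifacts,
no rearrangements, and intergenic sequence is i.i.d. rather than genomic.
Passing the benchmark therefore demonstrates the pipeline's correctness on
its stated model — colinear genomes differing by clean insertions and point
events — not robustness to mis-assembly, and the 11 bp scale of the smallest
real inserts is represented by the one-letter/long-insert dichotomy rather
than by a dedicated element type.

## Known limitations

- No rearrangement (inversion/translocation) calling; low chain coverage is
  an error, not a call.
- Exact-match census only; diverged copies whose ends differ from the voted
  family repeat are not counted.
- Pairwise (not progressive) alignment drives typing; the star alignment
  behind the bootstrap assumes high within-family identity.
- Coordinate conventions are internally consistent and round-trip exactly,
  but agreement with other aligners' coordinates is count-level only.
- The substitution-carrier label is conventional (the B-side genome);
  symmetry of diff(A,B)/diff(B,A) is over the event set, not that label.
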