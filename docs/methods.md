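# Methods

This note records the model implemented by `fernmir`, the parameter defaults,
the coordinate conventions, and the deliberate resolutions of ambiguities —
in enough detail to re-derive every number the package reports.

## Preprocessing (`fernmir.preprocess`)

Reads flow through five stages, each producing a `StageLog` that must satisfy
`n_in == n_kept + n_removed` (read-count conservation is asserted):

1. **Adapter trimming** — the 3' adapter is located by its leftmost prefix
   match (≥ 6 nt overlap, ≤ 1 mismatch by default). A read that begins with
   the adapter has an empty insert and is counted as removed.
2. **Collapsing** — identical sequences are merged into `UniqueTag`s with
   summed counts, ordered by descending count then lexicographic sequence.
   Collapsing is idempotent and order-invariant.
3. **Length filter** — inclusive bounds, default 15–40 nt. (Some vendor
   pipelines use 15–45; the bound is a parameter, and the package default is
   the stricter one since nothing downstream uses tags over 24 nt.)
4. **Contaminant removal** — a tag is removed when it occurs as an exact
   substring of any contaminant sequence (rRNA/tRNA/snoRNA databases);
   `mode="near"` additionally allows one mismatch. The removing database
   entry is recorded as the reason.
5. **RPM normalisation** — reads per million with the **post-contaminant
   total** as denominator, so RPM values reflect the analysed library.

The length histogram is read-weighted (not tag-weighted); its 21-nt and 24-nt
modes are the miRNA and heterochromatic-siRNA signatures of plant libraries.

## Conserved miRNA identification (`fernmir.identify`)

**Alignment.** Tags of 20–24 nt are placed ungapped on each mature reference
with 5'/3' end offsets of at most ±3 nt, ≥ 15 nt overlap and ≤ 2 mismatches.
The best placement minimises `(mismatches, |offset5|+|offset3|)`, with ties
broken toward `offset5 = 0`, then `offset3 = 0`; across references, the
reference id breaks exact ties deterministically.

**Families.** References map to canonical families through a synonym map
(miR157→miR156, miR165→miR166, miR530 and miR1030 → miR530/1030). In merged
mode, the miR156/529 and miR159/319 superfamilies are collapsed, taking the
23 split families in the packaged table to 21.

**Bona fide criteria.** A family is accepted when it has (1) ≥ 10 reads of
20–22 nt, (2) 5' homogeneity ≥ 0.75 — the read-weighted fraction of tags
sharing the modal 5' start, taken as the minimum over arms with data, because
each processed strand must independently show consistent DCL1 cleavage — and
(3) a most-abundant variant within 2 mismatches and 1 nt of length of a
high-confidence reference. A family failing (1) is rescued when both duplex
arms (5p and 3p) are observed with near-identical matches to their reference
arms; when hairpin precursors are supplied, the two arms must additionally
co-locate on one hairpin with ~2-nt 3'-overhang duplex geometry (±1 nt).

**Naming.** Accepted variants are named `pmi-miR<family>_v<k>` by descending
read count (ties lexicographic); merged families use their first number as
the stem (miR530/1030 → `pmi-miR530_v1`).

**5'-terminal nucleotide.** A 5' uridine marks AGO1 loading; families whose
variants are majority 5'-A are flagged as candidates for AGO2/AGO4-type
sorting. In the packaged table, 35 of 57 variants (61%) begin with U,
spanning 18 of 23 families.

**Similarity statistics.** Sequence similarity is summarised by the ungapped
Karlin–Altschul E-value `E = K · m · n · exp(−λS)`, where `S` is the best
ungapped local score over all diagonals (Kadane's algorithm; +1/−3 scoring),
`K = 0.711`, and λ is the unique positive root of
`Σ pᵢpⱼ exp(λ sᵢⱼ) = 1`, solved with Brent's method to `|f(λ)| < 1e−9`
(λ ≈ 1.374 for +1/−3 with uniform base frequencies; +1/−1 gives λ = ln 3
analytically, used as a test oracle). The stringent reassessment keeps a
candidate iff its best E-value against the reference set is **below 0.01 and**
its abundance is ≥ 1 RPM; a candidate failing either bound is discarded with
the binding reason recorded.

## Target prediction (`fernmir.targets`)

A miRNA (5'→3') pairs antiparallel to a transcript window: miRNA position
`k` (1-based) pairs the `k`-th base from the window's 3' end. Penalties:
Watson–Crick 0, G:U wobble 0.5 (G–T/T–G on the DNA representation), mismatch
1, gap 2, all doubled at miRNA positions 2–13 (the core that guides AGO
slicing). Sites with expectation E ≤ 3.0 are reported (4.0 for miR168, which
conventionally tolerates a weaker duplex on AGO1 mRNA). `allow_one_bulge`
also evaluates windows one nt shorter/longer with a single gap; a gap column
in the miRNA string is attributed to the *next* miRNA position for core
weighting.

By default overlapping qualifying windows are merged to the best-scoring
placement (`merge_overlapping=True`); with merging disabled the scanner
returns exactly one site per qualifying window, which is the form used by the
brute-force oracle tests. Results are sorted by `(E, start)`.

Region classification uses 0-based half-open CDS coordinates: a site entirely
5' of the CDS is 5'UTR, entirely 3' is 3'UTR, anything touching the CDS —
including straddling a boundary — is CDS; transcripts without CDS annotation
give "unknown".

Cross-species site co-location aligns two homologous transcripts with a
hand-rolled Needleman–Wunsch (match +1, mismatch −1, gap −2) whose traceback
prefers diagonal, then up, then left — the tie-break order is part of the
contract so aligned strings are reproducible — and declares two sites
co-located when the Jaccard overlap of their alignment-column sets is ≥ 0.5.

## TAS3 phasing (`fernmir.tas3`)

A TAS3 candidate needs two non-overlapping miR390 sites with an inter-site
gap of 30–400 nt; the better site must score E ≤ 3.0 and the other E ≤ 4.0.
The cleaved site is the more extensively paired one (lower E); ties default
to the 3' site, the seed-plant convention, and `override` can force a side.
Cleavage follows the 10/11 rule: for a site `[s, e)` the cut coordinate is
`c = e − 10`. The 21-nt phasing register runs from `c` toward the other site
(3'-ward from a cleaved 5' site, 5'-ward from a cleaved 3' site), emitting
only full in-bounds windows; every window satisfies `(start − c) mod 21 = 0`.
tasiRNAs are the (+)-strand 21-mers of those windows and are scanned against
ARF transcripts with the same expectation scorer.

## Origin mapping (`fernmir.phylo`)

The character model is Dollo parsimony: each family is gained exactly once,
at the MRCA of the taxa that carry it (the unique loss-minimising single-gain
node), and lost any number of times below. Losses are counted as maximal
all-absent subtrees under the origin; a property test verifies equality with
exhaustive minimisation over all candidate gain nodes. On the packaged
23-family matrix and eight-taxon cladogram this yields 14 embryophyte-,
3 moss+vascular-, 1 tracheophyte- and 5 euphyllophyte-node origins, and
column censuses give 14/15/10 families shared between ferns and liverworts/
mosses/lycophytes.

## Synthetic generators (`fernmir.simulate`)

All generators draw from `numpy.random.default_rng(seed)`; one integer seed
fully determines the output, and manifests record the planted truth.

- **Hairpins** — star = revcomp(mature[:−2]) + 2 fixed nucleotides, giving
  both strands the canonical 2-nt 3' overhang; arms are seed-independent,
  the loop is not.
- **Libraries** — multinomial family abundances; per-read end jitter
  *truncates* (5' +1 / 3' −1) so every read remains an exact hairpin
  substring and manifest offsets are exact; substitution errors and
  contaminant windows (19–24 nt) are optional. The planted jitter probability
  is recoverable from the measured 5' homogeneity to within 3σ.
- **Target sites** — a perfect complement is mutated to an exact requested
  expectation by subset-sum over half-unit penalty options (at most one per
  position; positions 9–12 protected so the cleavage region stays
  unambiguous), then embedded in rejection-sampled flanks verified to contain
  no other qualifying site; decoy transcripts are verified clean at E ≤ 3.0.
  Requested expectations must be multiples of 0.5 — the penalty grammar
  cannot produce anything else.
- **TAS3** — two constructed miR390 sites a configurable gap apart, the
  cleavable one built to pair better, with the phasing register computed from
  the construction and optionally an "ARF" decoy embedding the complement of
  a chosen in-phase tasiRNA.

## Scope and limitations

- Raw-library-scale numbers (tens of millions of reads) are out of scope;
  correctness at that scale is covered by conservation and oracle properties
  rather than re-execution.
- Target-site accessibility energy (UPE) requires RNA folding and is not
  computed; the site record carries an optional field for it.
- The expectation scorer evaluates at most one bulge per site; multi-gap
  duplexes are not searched.
- Precursor discovery (hairpin folding, MFE screening) is not implemented;
  precursor evidence enters only through user-supplied hairpin sequences in
  duplex detection and through the synthetic generators.
- The cladogram is fixed and polytomy-free; Dollo parsimony on trees with
  polytomies is untested.
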