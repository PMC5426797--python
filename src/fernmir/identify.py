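"""Conserved miRNA identification from collapsed small-RNA tags.

Tags are aligned ungapped to mature reference miRNAs allowing up to three
nucleotides of length variation at either end and up to two internal mismatches,
grouped into canonical families (miR157 -> miR156, miR165 -> miR166,
miR530/miR1030 -> miR530/1030), and accepted as bona fide when the family

1. carries at least 10 reads of 20-22 nt,
2. shows consistent 5' processing of the mature strand, and
3. matches a high-confidence reference closely (<= 2 mismatches, <= 1 nt length
   difference);

families failing criterion 1 are rescued when both duplex strands (5p and 3p
arms) are observed, the signature of genuine hairpin processing.

Sequence similarity to the reference set is summarised by an ungapped
Karlin-Altschul E-value (E = K*m*n*exp(-lambda*S)), the short-sequence analogue
of the BLASTN statistic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from scipy.optimize import brentq

from .io_formats import ReferenceMiRNA
from .preprocess import UniqueTag

DEFAULT_SYNONYMS = {"157": "156", "165": "166", "1030": "530/1030", "530": "530/1030"}
MERGE_SUPERFAMILIES = {"156": "156/529", "529": "156/529", "159": "159/319", "319": "159/319"}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class MiRNAAlignment:
    """An ungapped placement of a tag on a mature reference miRNA.

    offset5/offset3 are the tag's 5'/3' end positions minus the reference's
    (positive = tag extends past or starts inside the reference 5'/3' end).
    """

    tag: UniqueTag
    reference: ReferenceMiRNA
    offset5: int
    offset3: int
    mismatches: int

    @property
    def rank_key(self) -> tuple:
        return (
            self.mismatches,
            abs(self.offset5) + abs(self.offset3),
            abs(self.offset5),
            abs(self.offset3),
            self.offset5,
            self.offset3,
        )


def align_to_reference(
    tag: UniqueTag,
    reference: ReferenceMiRNA,
    max_mismatch: int = 2,
    max_end_offset: int = 3,
    min_overlap: int = 15,
) -> Optional[MiRNAAlignment]:
    """Best bounded-offset ungapped placement of a tag against one reference.

    Best = lexicographic minimum of (mismatches, |offset5| + |offset3|), ties
    broken toward offset5 = 0 then offset3 = 0; None when no placement satisfies
    the offset/mismatch/overlap bounds.
    """
    t, r = tag.sequence, reference.sequence
    best: Optional[MiRNAAlignment] = None
    for d in range(-max_end_offset, max_end_offset + 1):
        # d = offset5: position of the tag's first base in reference coordinates.
        offset3 = d + len(t) - len(r)
        if abs(offset3) > max_end_offset:
            continue
        lo = max(0, d)
        hi = min(len(r), d + len(t))
        overlap = hi - lo
        if overlap < min_overlap:
            continue
        mm = sum(1 for i in range(lo, hi) if t[i - d] != r[i])
        if mm > max_mismatch:
            continue
        cand = MiRNAAlignment(tag, reference, d, offset3, mm)
        if best is None or cand.rank_key < best.rank_key:
            best = cand
    return best


def best_alignment(
    tag: UniqueTag,
    references: Sequence[ReferenceMiRNA],
    max_mismatch: int = 2,
    max_end_offset: int = 3,
) -> Optional[MiRNAAlignment]:
    """Best alignment across a reference set; reference id breaks exact ties."""
    best = None
    for ref in references:
        aln = align_to_reference(tag, ref, max_mismatch, max_end_offset)
        if aln is None:
            continue
        if best is None or (aln.rank_key, aln.reference.id) < (best.rank_key, best.reference.id):
            best = aln
    return best


def canonical_family(
    reference: ReferenceMiRNA,
    synonym_map: Optional[dict[str, str]] = None,
    merge_mode: str = "split",
) -> str:
    """Canonical family name for a reference, e.g. ath-miR157a-5p -> miR156."""
    syn = DEFAULT_SYNONYMS if synonym_map is None else synonym_map
    num = reference.family_number
    if num not in syn and f"miR{num}" not in _KNOWN_FAMILIES:
        warnings.warn(f"family miR{num} not in synonym map; passing through unchanged")
    num = syn.get(num, num)
    if merge_mode == "merged":
        num = MERGE_SUPERFAMILIES.get(num, num)
    elif merge_mode != "split":
        raise ValueError(f"merge_mode must be 'split' or 'merged', got {merge_mode!r}")
    return f"miR{num}"


def merge_family_label(family: str) -> str:
    """Map a canonical family label to its merged superfamily
    (miR156 -> miR156/529, miR159 -> miR159/319; others unchanged)."""
    num = family.replace("miR", "", 1)
    return f"miR{MERGE_SUPERFAMILIES.get(num, num)}"


_KNOWN_FAMILIES = {
    f"miR{n}"
    for n in (
        "156 159 160 162 166 167 168 169 171 172 319 390 395 396 403 408 477 "
        "529 535 536 1024 1083"
    ).split()
} | {"miR530/1030"}


def five_prime_homogeneity(alignments: Iterable[MiRNAAlignment]) -> float:
    """Read-weighted fraction of tags sharing the modal 5' start, per arm.

    The family value is the minimum over arms with data: each processed strand
    must independently show consistent 5' cleavage.
    """
    by_arm: dict[str, dict[int, int]] = {}
    for aln in alignments:
        arm = aln.reference.arm
        by_arm.setdefault(arm, {})
        by_arm[arm][aln.offset5] = by_arm[arm].get(aln.offset5, 0) + aln.tag.count
    if not by_arm:
        raise ValueError("five_prime_homogeneity needs at least one alignment")
    values = []
    for counts in by_arm.values():
        total = sum(counts.values())
        values.append(max(counts.values()) / total)
    return min(values)


def duplex_geometry_ok(
    five_seq: str, three_seq: str, overhang: int = 2, tol: int = 1, max_mismatch: int = 2
) -> bool:
    """Check miRNA/miRNA* duplex geometry: the arms pair antiparallel leaving a
    ~2-nt 3' overhang on each strand (tolerance +-1 nt)."""
    for o in range(max(0, overhang - tol), overhang + tol + 1):
        a = five_seq[: len(five_seq) - o] if o else five_seq
        b = revcomp(three_seq[: len(three_seq) - o] if o else three_seq)
        span = min(len(a), len(b))
        if span < 15:
            continue
        mm = sum(1 for x, y in zip(a[:span], b[:span]) if x != y)
        if mm <= max_mismatch:
            return True
    return False


@dataclass
class CandidateVariant:
    given_name: str
    sequence: str
    length_nt: int
    total_reads: int
    best_reference: ReferenceMiRNA
    similarity_evalue: float
    alignment: MiRNAAlignment = field(repr=False)
    rpm: float = 0.0


@dataclass
class FamilyCall:
    family: str
    variants: list[CandidateVariant]
    reads_20_22: int
    five_prime_homogeneity: float
    has_duplex: bool
    bona_fide: bool = False
    rescue_used: bool = False
    failure_reasons: list[str] = field(default_factory=list)

    @property
    def total_reads(self) -> int:
        return sum(v.total_reads for v in self.variants)


def detect_duplex(
    variants: Sequence[CandidateVariant],
    precursors: Optional[dict[str, str]] = None,
) -> bool:
    """True when both hairpin arms (5p and 3p) are observed among the variants.

    With precursor sequences supplied (keyed by family), additionally require the
    two arms to co-locate on one hairpin with duplex overhang geometry.
    """
    five = [v for v in variants if v.best_reference.arm == "5p"]
    three = [v for v in variants if v.best_reference.arm == "3p"]
    if not (five and three):
        return False
    if precursors is None:
        return True
    for v5 in five:
        for v3 in three:
            for hp in precursors.values():
                hp = hp.upper().replace("U", "T")
                if v5.sequence in hp and v3.sequence in hp:
                    if duplex_geometry_ok(v5.sequence, v3.sequence):
                        return True
    return False


def bona_fide_filter(
    call: FamilyCall,
    min_reads: int = 10,
    len_window: tuple[int, int] = (20, 22),
    min_homogeneity: float = 0.75,
    max_ref_mismatch: int = 2,
    max_ref_len_diff: int = 1,
) -> FamilyCall:
    """Apply the three acceptance criteria, with miRNA/miRNA* duplex rescue.

    The similarity criterion ("identical or very similar") is evaluated on the
    family's most abundant variant: <= 2 mismatches and <= 1 nt length difference
    to its best high-confidence reference.
    """
    reasons = []
    top = call.variants[0]
    aln = top.alignment
    len_diff = abs(len(top.sequence) - len(aln.reference.sequence))
    similar = aln.mismatches <= max_ref_mismatch and len_diff <= max_ref_len_diff

    if call.reads_20_22 < min_reads:
        reasons.append(f"reads_{len_window[0]}_{len_window[1]}={call.reads_20_22}<{min_reads}")
    if call.five_prime_homogeneity < min_homogeneity:
        reasons.append(
            f"five_prime_homogeneity={call.five_prime_homogeneity:.3f}<{min_homogeneity}"
        )
    if not aln.reference.high_confidence:
        reasons.append("reference_not_high_confidence")
    if not similar:
        reasons.append("not_similar_to_reference")

    call.rescue_used = False
    if not reasons:
        call.bona_fide = True
        call.failure_reasons = []
        return call

    # Duplex rescue: both strands observed, each nearly identical to its reference arm.
    if call.has_duplex:
        arms_ok = all(
            v.alignment.mismatches <= max_ref_mismatch for v in call.variants
        )
        if arms_ok:
            call.bona_fide = True
            call.rescue_used = True
            call.failure_reasons = []
            return call
        reasons.append("duplex_arms_not_near_identical")

    call.bona_fide = False
    call.failure_reasons = reasons
    return call


def name_variants(call: FamilyCall, species_prefix: str = "pmi") -> FamilyCall:
    """Assign ``pmi-miR<family>_v<k>`` names by descending read count
    (ties: lexicographic sequence)."""
    call.variants.sort(key=lambda v: (-v.total_reads, v.sequence))
    stem = call.family.replace("miR", "", 1).split("/")[0]
    for k, v in enumerate(call.variants, start=1):
        v.given_name = f"{species_prefix}-miR{stem}_v{k}"
    return call


@dataclass
class TerminalNtSummary:
    base_counts: dict[str, int]  # 5'-base (U/A/G/C) -> number of variants
    n_variants: int
    families_with_u: set[str]
    families_majority_a: set[str]

    @property
    def n_u_variants(self) -> int:
        return self.base_counts.get("U", 0)


def terminal_nt_summary(variants: Iterable[tuple[str, str]]) -> TerminalNtSummary:
    """5'-terminal nucleotide statistics over (family, sequence) pairs.

    A 5' uridine marks AGO1-loaded miRNAs; a 5' adenine majority marks families
    handled by AGO2/AGO4-type complexes.
    """
    base_counts: dict[str, int] = {}
    fam_bases: dict[str, list[str]] = {}
    n = 0
    for family, seq in variants:
        base = seq[0].upper().replace("T", "U")
        base_counts[base] = base_counts.get(base, 0) + 1
        fam_bases.setdefault(family, []).append(base)
        n += 1
    families_with_u = {f for f, bases in fam_bases.items() if "U" in bases}
    families_majority_a = {
        f for f, bases in fam_bases.items() if bases.count("A") * 2 > len(bases)
    }
    return TerminalNtSummary(base_counts, n, families_with_u, families_majority_a)


# ---------------------------------------------------------------------------
# Karlin-Altschul statistics for short ungapped similarity search


def solve_karlin_lambda(
    match_score: float,
    mismatch_score: float,
    base_freqs: Optional[Sequence[float]] = None,
) -> float:
    """Unique positive root of sum_ij p_i p_j exp(lambda * s_ij) = 1.

    Requires a negative expected pair score and a positive maximum score.
    """
    p = [0.25] * 4 if base_freqs is None else list(base_freqs)
    if abs(sum(p) - 1.0) > 1e-9:
        raise ValueError("base frequencies must sum to 1")
    p_match = sum(x * x for x in p)
    p_mis = 1.0 - p_match
    expected = p_match * match_score + p_mis * mismatch_score
    if expected >= 0:
        raise ValueError("expected pair score must be negative for a finite lambda")
    if match_score <= 0:
        raise ValueError("maximum pair score must be positive")

    def f(lam: float) -> float:
        return p_match * math.exp(lam * match_score) + p_mis * math.exp(lam * mismatch_score) - 1.0

    hi = 1.0
    while f(hi) < 0:
        hi *= 2.0
    lam = brentq(f, 1e-12, hi, xtol=1e-14)
    assert abs(f(lam)) < 1e-9
    return float(lam)


@dataclass
class SimilarityScore:
    raw_score: float
    lam: float
    K: float
    search_space: float
    evalue: float


def best_ungapped_score(
    query: str, subject: str, match_score: float = 1.0, mismatch_score: float = -3.0
) -> float:
    """Best ungapped local alignment score over all diagonals (Kadane per diagonal)."""
    if not query or not subject:
        raise ValueError("empty sequence")
    q, s = query.upper(), subject.upper()
    best = 0.0
    for d in range(-(len(q) - 1), len(s)):
        run = 0.0
        for i in range(len(q)):
            j = i + d
            if not 0 <= j < len(s):
                continue
            run += match_score if q[i] == s[j] else mismatch_score
            if run < 0:
                run = 0.0
            best = max(best, run)
    return best


def similarity_evalue(
    query: str,
    subject: str,
    match_score: float = 1.0,
    mismatch_score: float = -3.0,
    K: float = 0.711,
    search_space: Optional[float] = None,
    lam: Optional[float] = None,
) -> SimilarityScore:
    """Karlin-Altschul E-value of the best ungapped local alignment."""
    if lam is None:
        lam = solve_karlin_lambda(match_score, mismatch_score)
    S = best_ungapped_score(query, subject, match_score, mismatch_score)
    mn = float(len(query) * len(subject)) if search_space is None else search_space
    E = K * mn * math.exp(-lam * S)
    return SimilarityScore(S, lam, K, mn, E)


@dataclass
class Discard:
    item: object
    reason: str


def reassess_stringent(
    candidates: Sequence,
    reference_db: Sequence[ReferenceMiRNA],
    rpm_min: float = 1.0,
    evalue_max: float = 0.01,
    **evalue_kwargs,
) -> tuple[list, list[Discard]]:
    """Stringent cross-species reassessment of candidate miRNAs.

    Keep a candidate iff its best E-value against the reference set is below
    ``evalue_max`` (close similarity) AND its abundance is at least ``rpm_min``
    reads per million.  Candidates must expose ``sequence`` and ``rpm``.
    """
    kept, discarded = [], []
    db_len = sum(len(r.sequence) for r in reference_db)
    for cand in candidates:
        best_e = min(
            similarity_evalue(
                cand.sequence,
                r.sequence,
                search_space=len(cand.sequence) * db_len,
                **evalue_kwargs,
            ).evalue
            for r in reference_db
        )
        if best_e >= evalue_max:
            discarded.append(Discard(cand, f"low_similarity_evalue={best_e:.3g}"))
        elif cand.rpm < rpm_min:
            discarded.append(Discard(cand, f"low_abundance_rpm={cand.rpm:.3g}"))
        else:
            kept.append(cand)
    return kept, discarded


# ---------------------------------------------------------------------------
# Family aggregation pipeline


def identify_families(
    tags: Sequence[UniqueTag],
    references: Sequence[ReferenceMiRNA],
    merge_mode: str = "split",
    max_mismatch: int = 2,
    max_end_offset: int = 3,
    select_len: tuple[int, int] = (20, 24),
    min_reads: int = 10,
    min_homogeneity: float = 0.75,
    precursors: Optional[dict[str, str]] = None,
    species_prefix: str = "pmi",
) -> list[FamilyCall]:
    """Full identification pass: select 20-24 nt tags, align, group into canonical
    families, apply the bona fide criteria with duplex rescue, and name variants."""
    selected = [t for t in tags if select_len[0] <= len(t.sequence) <= select_len[1]]
    grouped: dict[str, list[MiRNAAlignment]] = {}
    for tag in selected:
        aln = best_alignment(tag, references, max_mismatch, max_end_offset)
        if aln is None:
            continue
        fam = canonical_family(aln.reference, merge_mode=merge_mode)
        grouped.setdefault(fam, []).append(aln)

    db_len = sum(len(r.sequence) for r in references)
    calls = []
    for fam in sorted(grouped):
        alns = grouped[fam]
        variants = [
            CandidateVariant(
                given_name="",
                sequence=a.tag.sequence,
                length_nt=len(a.tag.sequence),
                total_reads=a.tag.count,
                best_reference=a.reference,
                similarity_evalue=similarity_evalue(
                    a.tag.sequence,
                    a.reference.sequence,
                    search_space=len(a.tag.sequence) * db_len,
                ).evalue,
                alignment=a,
                rpm=a.tag.rpm,
            )
            for a in alns
        ]
        reads_20_22 = sum(
            a.tag.count for a in alns if 20 <= len(a.tag.sequence) <= 22
        )
        call = FamilyCall(
            family=fam,
            variants=variants,
            reads_20_22=reads_20_22,
            five_prime_homogeneity=five_prime_homogeneity(alns),
            has_duplex=detect_duplex(variants, precursors),
        )
        name_variants(call, species_prefix)
        bona_fide_filter(call, min_reads=min_reads, min_homogeneity=min_homogeneity)
        calls.append(call)
    return calls
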