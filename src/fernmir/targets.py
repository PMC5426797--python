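"""Plant miRNA target prediction by position-weighted complementarity scoring.

A miRNA (5'->3') is paired antiparallel against a transcript window, and each
position contributes a penalty: Watson-Crick pair 0, G:U wobble 0.5, mismatch 1,
gap 2; penalties at miRNA positions 2-13 (the 5' "core" that guides cleavage)
are doubled.  The summed penalty is the expectation E: 0 for a perfect
complement, and sites with E below a threshold (conventionally 3.0, relaxed to
4.0 for some miRNAs) are reported.  The target-accessibility energy term used by
web platforms requires RNA folding and is out of scope; the site record reserves
an optional field for it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .io_formats import Transcript

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ScoringParams:
    mismatch_penalty: float = 1.0
    gu_penalty: float = 0.5
    gap_penalty: float = 2.0
    core_range: tuple[int, int] = (2, 13)  # 1-based miRNA positions, inclusive
    core_multiplier: float = 2.0
    max_expectation: float = 3.0

    def position_multiplier(self, mirna_pos: int) -> float:
        lo, hi = self.core_range
        return self.core_multiplier if lo <= mirna_pos <= hi else 1.0


def pair_class(mirna_base: str, target_base: str) -> str:
    """Classify one antiparallel pair: 'wc', 'gu' or 'mm' (DNA alphabet;
    G:U wobble is G-T / T-G on the DNA representation)."""
    if target_base == mirna_base.translate(_COMPLEMENT):
        return "wc"
    if (mirna_base, target_base) in (("G", "T"), ("T", "G")):
        return "gu"
    return "mm"


def expectation_score(
    mirna_seq: str,
    site_seq: str,
    alignment: Optional[tuple[str, str]] = None,
    params: Optional[ScoringParams] = None,
) -> float:
    """Expectation E of a miRNA paired antiparallel to a site.

    Without an explicit alignment the pairing is ungapped and the sequences must
    have equal length; miRNA position k (1-based from its 5' end) pairs the k-th
    base from the site's 3' end.  ``alignment`` supplies gapped aligned strings
    (miRNA written 5'->3', site written 3'->5', '-' for gaps); a gap column in
    the miRNA string is attributed to the next miRNA position for core weighting.
    """
    p = params or ScoringParams()
    if alignment is None:
        if len(mirna_seq) != len(site_seq):
            raise ValueError("ungapped pairing requires equal lengths")
        alignment = (mirna_seq.upper(), site_seq.upper()[::-1])
    m_aln, s_aln = (a.upper() for a in alignment)
    if len(m_aln) != len(s_aln):
        raise ValueError("aligned strings differ in length")
    if m_aln.replace("-", "") != mirna_seq.upper():
        raise ValueError("alignment inconsistent with miRNA sequence")

    E = 0.0
    consumed = 0  # miRNA bases consumed so far
    L = len(mirna_seq)
    for mb, sb in zip(m_aln, s_aln):
        if mb == "-" and sb == "-":
            raise ValueError("double-gap column in alignment")
        if mb == "-" or sb == "-":
            pos = min(consumed + 1, L)
            E += p.gap_penalty * p.position_multiplier(pos)
            if mb != "-":
                consumed += 1
            continue
        consumed += 1
        cls = pair_class(mb, sb)
        if cls == "gu":
            E += p.gu_penalty * p.position_multiplier(consumed)
        elif cls == "mm":
            E += p.mismatch_penalty * p.position_multiplier(consumed)
    return E


def pairing_string(mirna_seq: str, site_seq: str) -> str:
    """Per-position pairing marks along the miRNA (5'->3'): '|' Watson-Crick,
    'o' G:U wobble, ' ' mismatch."""
    marks = []
    rev = site_seq.upper()[::-1]
    for mb, sb in zip(mirna_seq.upper(), rev):
        cls = pair_class(mb, sb)
        marks.append({"wc": "|", "gu": "o", "mm": " "}[cls])
    return "".join(marks)


@dataclass
class TargetSite:
    mirna_name: str
    transcript_id: str
    start: int  # 0-based half-open on the transcript, sense strand
    end: int
    expectation: float
    pairing: str
    region: str = "unknown"
    upe: Optional[float] = None  # accessibility energy; not computed here

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


def _bulge_expectations(mirna: str, window: str, params: ScoringParams) -> float:
    """Best E over single-gap placements of a window one nt shorter/longer
    than the miRNA (one bulged base on either strand)."""
    L = len(mirna)
    rev = window[::-1]
    best = float("inf")
    if len(window) == L - 1:
        # one miRNA base unpaired: gap in the site string
        for g in range(L):
            s_aln = rev[:g] + "-" + rev[g:]
            best = min(best, expectation_score(mirna, window, (mirna, s_aln), params))
    elif len(window) == L + 1:
        # one bulged target base: gap in the miRNA string
        for g in range(L + 1):
            m_aln = mirna[:g] + "-" + mirna[g:]
            best = min(best, expectation_score(mirna, window, (m_aln, rev), params))
    else:
        raise ValueError("bulge windows must differ from the miRNA length by 1")
    return best


def scan_transcript(
    mirna_name: str,
    mirna_seq: str,
    transcript: Transcript,
    params: Optional[ScoringParams] = None,
    max_expectation: Optional[float] = None,
    allow_one_bulge: bool = False,
    merge_overlapping: bool = True,
) -> list[TargetSite]:
    """Scan every window of a transcript for miRNA complementarity sites.

    Reports sites with E <= threshold sorted by (E, start); by default
    overlapping reported sites are merged to the best-scoring placement
    (``merge_overlapping=False`` returns one site per qualifying window).
    """
    p = params or ScoringParams()
    threshold = p.max_expectation if max_expectation is None else max_expectation
    mirna = mirna_seq.upper().replace("U", "T")
    seq = transcript.sequence.upper().replace("U", "T")
    L = len(mirna)
    if len(seq) < L:
        return []

    candidates: list[TargetSite] = []
    for start in range(len(seq) - L + 1):
        window = seq[start : start + L]
        E = expectation_score(mirna, window, params=p)
        end = start + L
        if allow_one_bulge:
            for wlen in (L - 1, L + 1):
                if start + wlen <= len(seq) and wlen >= 1:
                    Eb = _bulge_expectations(mirna, seq[start : start + wlen], p)
                    if Eb < E:
                        E, end = Eb, start + wlen
        if E <= threshold:
            candidates.append(
                TargetSite(
                    mirna_name,
                    transcript.id,
                    start,
                    end,
                    E,
                    pairing_string(mirna, seq[start : start + L]),
                )
            )

    candidates.sort(key=lambda s: (s.expectation, s.start))
    if not merge_overlapping:
        return candidates
    reported: list[TargetSite] = []
    for site in candidates:
        if all(site.end <= r.start or site.start >= r.end for r in reported):
            reported.append(site)
    reported.sort(key=lambda s: (s.expectation, s.start))
    return reported


def classify_region(site: TargetSite, transcript: Transcript) -> str:
    """5'UTR / CDS / 3'UTR by interval position relative to the CDS
    (a site straddling a boundary counts as CDS); 'unknown' without a CDS."""
    if transcript.cds is None:
        return "unknown"
    cds_start, cds_end = transcript.cds
    if site.end <= cds_start:
        return "5'UTR"
    if site.start >= cds_end:
        return "3'UTR"
    return "CDS"


def annotate_regions(sites: Sequence[TargetSite], transcripts: dict[str, Transcript]) -> None:
    for s in sites:
        s.region = classify_region(s, transcripts[s.transcript_id])


@dataclass
class GlobalAlignment:
    score: float
    aligned_a: str
    aligned_b: str

    def columns_for_a(self, interval: tuple[int, int]) -> set[int]:
        """Alignment columns covered by a [start, end) interval of sequence a."""
        cols, pos = set(), 0
        for col, ch in enumerate(self.aligned_a):
            if ch != "-":
                if interval[0] <= pos < interval[1]:
                    cols.add(col)
                pos += 1
        return cols

    def columns_for_b(self, interval: tuple[int, int]) -> set[int]:
        cols, pos = set(), 0
        for col, ch in enumerate(self.aligned_b):
            if ch != "-":
                if interval[0] <= pos < interval[1]:
                    cols.add(col)
                pos += 1
        return cols


def global_align(
    seq_a: str, seq_b: str, match: float = 1.0, mismatch: float = -1.0, gap: float = -2.0
) -> GlobalAlignment:
    """Needleman-Wunsch global alignment with deterministic tie-breaking
    (diagonal preferred, then up = gap in seq_b, then left = gap in seq_a)."""
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    a, b = seq_a.upper(), seq_b.upper()
    n, m = len(a), len(b)
    score = [[0.0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        score[i][0] = i * gap
    for j in range(1, m + 1):
        score[0][j] = j * gap
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            diag = score[i - 1][j - 1] + (match if a[i - 1] == b[j - 1] else mismatch)
            up = score[i - 1][j] + gap
            left = score[i][j - 1] + gap
            score[i][j] = max(diag, up, left)
    # traceback with the documented preference order
    out_a, out_b = [], []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and score[i][j] == score[i - 1][j - 1] + (
            match if a[i - 1] == b[j - 1] else mismatch
        ):
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i, j = i - 1, j - 1
        elif i > 0 and score[i][j] == score[i - 1][j] + gap:
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
    return GlobalAlignment(score[n][m], "".join(reversed(out_a)), "".join(reversed(out_b)))


def site_colocated(
    alignment: GlobalAlignment,
    site_a: tuple[int, int],
    site_b: tuple[int, int],
    min_overlap_frac: float = 0.5,
) -> bool:
    """Do two sites on homologous transcripts occupy the same aligned region?

    Both intervals are mapped to alignment columns and compared by Jaccard
    overlap of the column sets.
    """
    cols_a = alignment.columns_for_a(site_a)
    cols_b = alignment.columns_for_b(site_b)
    union = cols_a | cols_b
    if not union:
        return False
    return len(cols_a & cols_b) / len(union) >= min_overlap_frac
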