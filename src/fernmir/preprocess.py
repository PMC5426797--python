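"""Small-RNA library preprocessing: adapter trimming, length filtering, collapsing
to unique tags, contaminant removal and length-distribution profiling.

Every stage conserves reads (input = kept + removed) and appends one entry to a
stage log, so pipelines can assert read accounting end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .io_formats import SmallRNARead


@dataclass
class UniqueTag:
    """A distinct small-RNA sequence with its summed read count.

    ``rpm`` (reads per million) is computed against the library total that survives
    contaminant filtering, the denominator used for low-abundance cutoffs.
    """

    sequence: str
    count: int
    rpm: float = 0.0


@dataclass
class StageLog:
    stage: str
    n_in: int
    n_kept: int
    n_removed: int

    def __post_init__(self) -> None:
        if self.n_in != self.n_kept + self.n_removed:
            raise ValueError(
                f"stage {self.stage}: {self.n_in} != {self.n_kept} + {self.n_removed}"
            )


@dataclass
class TrimResult:
    read: Optional[SmallRNARead]  # None when the adapter leaves an empty insert
    adapter_found: bool


def trim_adapter(
    read: SmallRNARead, adapter3: str, min_overlap: int = 6, max_mismatch: int = 1
) -> TrimResult:
    """Truncate a read at the leftmost match of a 3' adapter prefix.

    A match is a prefix of ``adapter3`` of length >= ``min_overlap`` (or the full
    remaining read suffix, if shorter spans reach the read end) aligned at some
    position with <= ``max_mismatch`` mismatches.  Unmatched reads are returned
    whole with ``adapter_found=False``.
    """
    if min_overlap < 4 or len(adapter3) < min_overlap:
        raise ValueError("require adapter3 length >= min_overlap >= 4")
    seq = read.sequence
    ad = adapter3.upper()
    for pos in range(0, len(seq)):
        span = min(len(ad), len(seq) - pos)
        if span < min_overlap:
            break
        mm = sum(1 for a, b in zip(seq[pos : pos + span], ad[:span]) if a != b)
        if mm <= max_mismatch:
            trimmed_seq = seq[:pos]
            if not trimmed_seq:
                return TrimResult(None, True)  # adapter at position 0: empty insert
            qual = read.quality[:pos] if read.quality else None
            return TrimResult(SmallRNARead(trimmed_seq, read.count, qual), True)
    return TrimResult(read, False)


def length_filter(
    tags: Iterable[UniqueTag], min_len: int = 15, max_len: int = 40
) -> tuple[list[UniqueTag], list[UniqueTag]]:
    """Keep tags with min_len <= length <= max_len; returns (kept, removed)."""
    if min_len > max_len:
        raise ValueError("min_len > max_len")
    kept, removed = [], []
    for t in tags:
        (kept if min_len <= len(t.sequence) <= max_len else removed).append(t)
    return kept, removed


def collapse(reads: Iterable[SmallRNARead | UniqueTag]) -> list[UniqueTag]:
    """Collapse reads to unique tags, counts summed.

    Order is deterministic: descending count, then lexicographic sequence; the
    operation is idempotent and invariant to input permutation.
    """
    counts: dict[str, int] = {}
    for r in reads:
        counts[r.sequence] = counts.get(r.sequence, 0) + r.count
    return [
        UniqueTag(seq, n)
        for seq, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


@dataclass
class RemovedTag:
    tag: UniqueTag
    reason: str


def filter_contaminants(
    tags: Iterable[UniqueTag],
    contaminant_db: list[tuple[str, str]],
    mode: str = "exact",
) -> tuple[list[UniqueTag], list[RemovedTag]]:
    """Remove tags matching contaminant sequences (rRNA/tRNA/sn(o)RNA/repeats stand-in).

    mode="exact": tag occurs as an exact substring of a contaminant sequence.
    mode="near": tag matches some same-length contaminant window with <= 1 mismatch.
    """
    if mode not in ("exact", "near"):
        raise ValueError(f"unknown contaminant matching mode: {mode!r}")
    db = [(cid, seq.upper().replace("U", "T")) for cid, seq in contaminant_db]
    kept: list[UniqueTag] = []
    removed: list[RemovedTag] = []
    for tag in tags:
        hit: Optional[str] = None
        for cid, cseq in db:
            if mode == "exact":
                if tag.sequence in cseq:
                    hit = cid
                    break
            else:
                L = len(tag.sequence)
                for i in range(0, len(cseq) - L + 1):
                    mm = sum(1 for a, b in zip(tag.sequence, cseq[i : i + L]) if a != b)
                    if mm <= 1:
                        hit = cid
                        break
                if hit:
                    break
        if hit is None:
            kept.append(tag)
        else:
            removed.append(RemovedTag(tag, hit))
    return kept, removed


def assign_rpm(tags: list[UniqueTag]) -> list[UniqueTag]:
    """Set rpm = count * 1e6 / total over the given (post-filter) tag set."""
    total = sum(t.count for t in tags)
    for t in tags:
        t.rpm = t.count * 1e6 / total if total else 0.0
    return tags


@dataclass
class LengthHistogram:
    counts: dict[int, int]  # full range, read-weighted
    display_range: tuple[int, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def percentages(self) -> dict[int, float]:
        tot = self.total
        return {L: 100.0 * n / tot for L, n in self.counts.items()} if tot else {}

    @property
    def mode(self) -> int:
        return max(self.counts, key=lambda L: (self.counts[L], -L))

    def second_mode(self) -> int:
        ranked = sorted(self.counts, key=lambda L: (-self.counts[L], L))
        return ranked[1] if len(ranked) > 1 else ranked[0]

    def display_counts(self) -> dict[int, int]:
        lo, hi = self.display_range
        return {L: self.counts.get(L, 0) for L in range(lo, hi + 1)}


def length_histogram(
    tags: Iterable[UniqueTag], display_range: tuple[int, int] = (18, 25)
) -> LengthHistogram:
    counts: dict[int, int] = {}
    for t in tags:
        counts[len(t.sequence)] = counts.get(len(t.sequence), 0) + t.count
    return LengthHistogram(counts, display_range)


@dataclass
class PreprocessResult:
    tags: list[UniqueTag]
    removed_short_long: list[UniqueTag]
    removed_contaminant: list[RemovedTag]
    histogram: LengthHistogram
    stage_logs: list[StageLog] = field(default_factory=list)


def run_preprocess(
    reads: list[SmallRNARead],
    adapter3: Optional[str] = None,
    min_len: int = 15,
    max_len: int = 40,
    contaminant_db: Optional[list[tuple[str, str]]] = None,
    contaminant_mode: str = "exact",
    min_overlap: int = 6,
    max_mismatch: int = 1,
) -> PreprocessResult:
    """The documented stage order: trim -> collapse -> length filter -> contaminants."""
    logs: list[StageLog] = []
    n0 = sum(r.count for r in reads)

    if adapter3:
        trimmed = []
        n_empty = 0
        for r in reads:
            res = trim_adapter(r, adapter3, min_overlap, max_mismatch)
            if res.read is None:
                n_empty += r.count
            else:
                trimmed.append(res.read)
        logs.append(StageLog("adapter_trim", n0, n0 - n_empty, n_empty))
        reads = trimmed

    tags = collapse(reads)
    n1 = sum(t.count for t in tags)
    logs.append(StageLog("collapse", n1, n1, 0))

    tags, too_short_long = length_filter(tags, min_len, max_len)
    n_removed = sum(t.count for t in too_short_long)
    logs.append(StageLog("length_filter", n1, n1 - n_removed, n_removed))

    removed_contam: list[RemovedTag] = []
    if contaminant_db:
        n2 = sum(t.count for t in tags)
        tags, removed_contam = filter_contaminants(tags, contaminant_db, contaminant_mode)
        n_rm = sum(rt.tag.count for rt in removed_contam)
        logs.append(StageLog("contaminant_filter", n2, n2 - n_rm, n_rm))

    assign_rpm(tags)
    return PreprocessResult(tags, too_short_long, removed_contam, length_histogram(tags), logs)
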