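"""TAS3 tasiRNA phasing analysis.

A TAS3 non-coding transcript carries two miR390 complementarity sites
("two-hit trigger").  Cleavage at one site — inferred as the more extensively
paired one — sets a 21-nt register between the two sites, and the phased
21-mers (tasiRNAs) produced from the (+) strand can themselves target ARF3/4
transcription-factor mRNAs.

Coordinates follow the canonical slicing rule: the RNA is cut opposite the
boundary between miRNA positions 10 and 11.  A site [s, e) places miRNA
position 1 against transcript position e-1, so the cut is at c = e - 10.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .io_formats import Transcript
from .targets import ScoringParams, TargetSite, scan_transcript


@dataclass
class Tas3Candidate:
    transcript_id: str
    site5: TargetSite  # 5'-most miR390 site
    site3: TargetSite  # 3'-most miR390 site
    cleavable: str  # "site5" or "site3"
    cleavage_pos: int  # 5' end of the 3' cleavage fragment (0-based)
    phase_windows: list[tuple[int, int]] = field(default_factory=list)
    tasirna_seqs: list[str] = field(default_factory=list)


def find_dual_sites(
    mir390_seq: str,
    transcript: Transcript,
    maxE_primary: float = 3.0,
    maxE_secondary: float = 4.0,
    gap_range: tuple[int, int] = (30, 400),
    params: Optional[ScoringParams] = None,
    mirna_name: str = "miR390",
) -> Optional[Tas3Candidate]:
    """Find the best pair of non-overlapping miR390 sites on one transcript.

    The better (lower-E) site must score <= maxE_primary, the other
    <= maxE_secondary, and their separation (inter-site gap between intervals)
    must fall within ``gap_range``.  Returns None when no qualifying pair exists.
    """
    sites = scan_transcript(
        mirna_name, mir390_seq, transcript, params=params, max_expectation=maxE_secondary
    )
    best_pair: Optional[tuple[TargetSite, TargetSite]] = None
    best_key: Optional[tuple[float, float]] = None
    for i, a in enumerate(sites):
        for b in sites[i + 1 :]:
            first, second = (a, b) if a.start <= b.start else (b, a)
            if first.end > second.start:
                continue
            gap = second.start - first.end
            if not gap_range[0] <= gap <= gap_range[1]:
                continue
            lowE, highE = sorted((first.expectation, second.expectation))
            if lowE > maxE_primary or highE > maxE_secondary:
                continue
            key = (lowE + highE, lowE)
            if best_key is None or key < best_key:
                best_key = key
                best_pair = (first, second)
    if best_pair is None:
        return None
    site5, site3 = best_pair
    cleavable = infer_cleavable(site5, site3)
    cpos = cleavage_position(site5 if cleavable == "site5" else site3)
    return Tas3Candidate(transcript.id, site5, site3, cleavable, cpos)


def infer_cleavable(site5: TargetSite, site3: TargetSite, override: Optional[str] = None) -> str:
    """Choose the cleaved site: the one with the more extensive pairing
    (lower expectation); ties default to the 3' site, the seed-plant convention.
    ``override`` forces a side."""
    if override is not None:
        if override not in ("site5", "site3"):
            raise ValueError("override must be 'site5' or 'site3'")
        return override
    return "site5" if site5.expectation < site3.expectation else "site3"


def cleavage_position(site: TargetSite) -> int:
    """Transcript coordinate of the 10/11 cut for a site [s, e): c = e - 10."""
    if site.end - site.start < 11:
        raise ValueError("site shorter than 11 nt has no 10/11 boundary")
    return site.end - 10


def phase_register(
    candidate: Tas3Candidate,
    transcript: Transcript,
    n_max: int = 20,
    phase: int = 21,
) -> Tas3Candidate:
    """Lay the 21-nt phasing register between the two miR390 sites.

    From a cleaved 5' site the register runs 3'-ward: windows
    [c + 21k, c + 21(k+1)) while fully 5' of the 3' site; from a cleaved 3' site
    it runs 5'-ward from c while fully 3' of the 5' site.  tasiRNA sequences are
    the (+)-strand 21-mers of those windows.
    """
    c = candidate.cleavage_pos
    windows: list[tuple[int, int]] = []
    if candidate.cleavable == "site5":
        k = 0
        while len(windows) < n_max:
            w = (c + phase * k, c + phase * (k + 1))
            if w[1] > candidate.site3.start:
                break
            windows.append(w)
            k += 1
    else:
        k = 0
        while len(windows) < n_max:
            w = (c - phase * (k + 1), c - phase * k)
            if w[0] < candidate.site5.end:
                break
            windows.append(w)
            k += 1
        windows.reverse()
    seq = transcript.sequence.upper().replace("U", "T")
    candidate.phase_windows = windows
    candidate.tasirna_seqs = [seq[s:e] for s, e in windows]
    return candidate


def tasirna_targets(
    tasirna_seqs: Sequence[str],
    transcripts: Sequence[Transcript],
    params: Optional[ScoringParams] = None,
    max_expectation: Optional[float] = None,
) -> list[tuple[int, TargetSite]]:
    """Scan candidate tasiRNAs against transcripts (e.g. ARF mRNAs).

    Delegates to the target scanner; results are (source window index, site).
    """
    hits: list[tuple[int, TargetSite]] = []
    for idx, tasi in enumerate(tasirna_seqs):
        for tx in transcripts:
            for site in scan_transcript(
                f"tasiRNA_w{idx}", tasi, tx, params=params, max_expectation=max_expectation
            ):
                hits.append((idx, site))
    return hits
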