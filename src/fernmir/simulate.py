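"""Ground-truth synthetic data generators.

Every stage of the pipeline is testable without external downloads: small-RNA
libraries with planted miRNA families (hairpin-derived mature/star reads with
configurable 5'/3' end jitter, sequencing error and contaminant spike-ins),
transcriptomes with target sites constructed to an exact expectation score by
inverting the penalty grammar, and TAS3-like transcripts with two miR390 sites
and a known phasing register.  A single integer seed makes each generator fully
reproducible; manifests record the planted truth the pipeline must recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .io_formats import SmallRNARead, Transcript
from .targets import ScoringParams, revcomp

_BASES = "ACGT"


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_BASES), size=length))


# ---------------------------------------------------------------------------
# Hairpin precursors


def make_precursor(
    mature: str,
    mature_arm: str = "5p",
    loop_len: int = 15,
    seed: int = 0,
) -> tuple[str, dict[str, tuple[int, int]]]:
    """Build a hairpin around a mature sequence with proper duplex geometry.

    The star strand is the reverse complement of the mature sequence arranged so
    both strands carry a 2-nt 3' overhang (the DCL1 processing signature):
    star = revcomp(mature[:-2]) + 2 fixed overhang nucleotides.  The loop varies
    with the seed; the arms do not.
    """
    if not 20 <= len(mature) <= 24:
        raise ValueError("mature length must be 20-24 nt")
    if mature_arm not in ("5p", "3p"):
        raise ValueError("mature_arm must be '5p' or '3p'")
    mature = mature.upper().replace("U", "T")
    star = revcomp(mature[:-2]) + "CC"
    rng = np.random.default_rng(seed)
    loop = _random_seq(rng, loop_len)
    if mature_arm == "5p":
        hairpin = mature + loop + star
        coords = {
            "5p": (0, len(mature)),
            "3p": (len(mature) + loop_len, len(mature) + loop_len + len(star)),
        }
    else:
        hairpin = star + loop + mature
        coords = {
            "5p": (0, len(star)),
            "3p": (len(star) + loop_len, len(star) + loop_len + len(mature)),
        }
    return hairpin, coords


# ---------------------------------------------------------------------------
# sRNA library simulation


@dataclass
class FamilySpec:
    """One planted miRNA family: mature strand, abundance weight, end jitter and
    the mature:star read ratio."""

    name: str
    mature: str
    star: Optional[str] = None  # derived from the hairpin when None
    abundance: float = 1.0
    end_jitter_prob: float = 0.0  # per-read probability of a +-1 nt 5' shift
    jitter3_prob: float = 0.0
    arm_ratio: float = 0.9  # fraction of family reads from the mature strand


@dataclass
class LibrarySpec:
    families: list[FamilySpec]
    n_reads: int
    seed: int
    contaminant_fraction: float = 0.0
    error_rate: float = 0.0


@dataclass
class ReadProvenance:
    origin: str  # family name or "contaminant:<id>"
    arm: str  # "mature", "star" or ""
    offset5: int = 0
    offset3: int = 0
    n_errors: int = 0


@dataclass
class Manifest:
    reads: list[ReadProvenance] = field(default_factory=list)
    precursors: dict[str, str] = field(default_factory=dict)
    arm_coords: dict[str, dict[str, tuple[int, int]]] = field(default_factory=dict)
    sites: list["PlantedSite"] = field(default_factory=list)

    def family_read_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for p in self.reads:
            counts[p.origin] = counts.get(p.origin, 0) + 1
        return counts

    def contaminant_read_count(self) -> int:
        return sum(1 for p in self.reads if p.origin.startswith("contaminant:"))


def simulate_library(
    spec: LibrarySpec,
    contaminants: Optional[list[tuple[str, str]]] = None,
) -> tuple[list[SmallRNARead], Manifest]:
    """Draw a read library from a planted-family specification.

    Reads are substrings of per-family hairpins (mature or star arm, ends
    jittered within +-1 nt), with uniform substitution errors and contaminant
    reads drawn as random windows of the supplied contaminant sequences.
    """
    if not spec.families or all(f.abundance <= 0 for f in spec.families):
        raise ValueError("library spec needs at least one family with positive abundance")
    if spec.contaminant_fraction > 0 and not contaminants:
        raise ValueError("contaminant_fraction > 0 requires contaminant sequences")

    rng = np.random.default_rng(spec.seed)
    manifest = Manifest()
    arms: dict[str, dict[str, str]] = {}
    for fam in spec.families:
        hairpin, coords = make_precursor(fam.mature, seed=spec.seed)
        manifest.precursors[fam.name] = hairpin
        manifest.arm_coords[fam.name] = coords
        star = fam.star if fam.star is not None else hairpin[slice(*coords["3p"])]
        arms[fam.name] = {"mature": fam.mature.upper().replace("U", "T"), "star": star}

    n_contam = int(round(spec.n_reads * spec.contaminant_fraction))
    n_fam_total = spec.n_reads - n_contam
    weights = np.array([f.abundance for f in spec.families], dtype=float)
    weights /= weights.sum()
    fam_counts = rng.multinomial(n_fam_total, weights)

    reads: list[SmallRNARead] = []
    for fam, n in zip(spec.families, fam_counts):
        hairpin = manifest.precursors[fam.name]
        coords = manifest.arm_coords[fam.name]
        for _ in range(int(n)):
            use_mature = rng.random() < fam.arm_ratio
            arm_name = "mature" if use_mature else "star"
            base = arms[fam.name][arm_name]
            # locate the arm on the hairpin to jitter its ends; jitter truncates
            # (5' +1 / 3' -1) so reads always stay within the hairpin
            start = hairpin.index(base) if base in hairpin else -1
            o5 = 1 if rng.random() < fam.end_jitter_prob else 0
            o3 = -1 if rng.random() < fam.jitter3_prob else 0
            if start >= 0:
                end = start + len(base)
                seq = list(hairpin[start + o5 : end + o3 or None])
            else:
                seq = list(base[o5 : len(base) + o3 or None])
            n_err = 0
            if spec.error_rate > 0:
                for i in range(len(seq)):
                    if rng.random() < spec.error_rate:
                        seq[i] = rng.choice([b for b in _BASES if b != seq[i]])
                        n_err += 1
            seq_s = "".join(seq)
            reads.append(SmallRNARead(seq_s, 1, "I" * len(seq_s)))
            manifest.reads.append(ReadProvenance(fam.name, arm_name, o5, o3, n_err))

    for _ in range(n_contam):
        cid, cseq = contaminants[int(rng.integers(len(contaminants)))]
        cseq = cseq.upper().replace("U", "T")
        L = int(rng.integers(19, 25))
        L = min(L, len(cseq))
        start = int(rng.integers(0, len(cseq) - L + 1))
        sub = cseq[start : start + L]
        reads.append(SmallRNARead(sub, 1, "I" * len(sub)))
        manifest.reads.append(ReadProvenance(f"contaminant:{cid}", ""))

    return reads, manifest


def write_fastq(path, reads: Sequence[SmallRNARead]) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(reads):
            fh.write(f"@read_{i}\n{r.sequence}\n+\n{r.quality or 'I' * len(r.sequence)}\n")


# ---------------------------------------------------------------------------
# Target transcriptomes with sites of constructed expectation


@dataclass
class SiteSpec:
    mirna_name: str
    expectation: float
    region: str = "unknown"  # "5'UTR", "CDS", "3'UTR" or "unknown"


@dataclass
class PlantedSite:
    mirna_name: str
    transcript_id: str
    start: int
    end: int
    expectation: float
    region: str


def _mutate_to_expectation(
    mirna: str,
    requested: float,
    params: ScoringParams,
    rng: np.random.Generator,
    protected: tuple[int, int] = (9, 12),
) -> str:
    """Build a site window whose expectation against ``mirna`` is exactly
    ``requested``, by mutating a perfect complement.

    Uses a subset-sum over per-position penalty options (G:U where the miRNA has
    G or T, mismatch anywhere; core positions doubled); positions inside the
    cleavage-critical 10/11 region are protected by default so downstream
    slicing logic stays unambiguous.  Raises when the requested value is not a
    sum of available penalties.
    """
    L = len(mirna)
    target_half = round(requested * 2)
    if abs(requested * 2 - target_half) > 1e-9 or requested < 0:
        raise ValueError(f"expectation {requested} not a multiple of 0.5")

    options: list[tuple[int, list[int]]] = []  # (position, list of half-unit penalties)
    for pos in range(1, L + 1):
        if protected[0] <= pos <= protected[1]:
            continue
        mult = params.position_multiplier(pos)
        opts = [int(round(params.mismatch_penalty * mult * 2))]
        if mirna[pos - 1] in "GT":
            opts.append(int(round(params.gu_penalty * mult * 2)))
        options.append((pos, opts))

    # DP subset-sum: choose at most one penalty per position.
    reachable: list[Optional[tuple[int, int]]] = [None] * (target_half + 1)
    reachable[0] = (-1, 0)  # (option index used to get here, penalty chosen)
    for idx, (_pos, opts) in enumerate(options):
        for total in range(target_half, -1, -1):
            if reachable[total] is None:
                continue
            for pen in opts:
                if total + pen <= target_half and reachable[total + pen] is None:
                    reachable[total + pen] = (idx, pen)
    if reachable[target_half] is None:
        raise ValueError(
            f"expectation {requested} unreachable with the penalty grammar for this miRNA"
        )

    # Trace back which (position, penalty) pairs were used.
    choices: list[tuple[int, int]] = []
    total = target_half
    while total > 0:
        idx, pen = reachable[total]
        choices.append((options[idx][0], pen))
        total -= pen

    site = list(revcomp(mirna))  # perfect complement, 5'->3'
    comp = dict(zip("ACGT", "TGCA"))
    for pos, pen in choices:
        mult = params.position_multiplier(pos)
        mbase = mirna[pos - 1]
        site_idx = L - pos  # miRNA position pos pairs site index L - pos
        if pen == int(round(params.gu_penalty * mult * 2)) and mbase in "GT":
            site[site_idx] = "T" if mbase == "G" else "G"
        else:
            wc = comp[mbase]
            wobble = {"G": "T", "T": "G"}.get(mbase, "")
            site[site_idx] = rng.choice(
                [b for b in _BASES if b != wc and b != wobble]
            )
    return "".join(site)


def make_target_transcriptome(
    mirnas: dict[str, str],
    site_specs: Sequence[SiteSpec],
    n_decoys: int = 0,
    seed: int = 0,
    params: Optional[ScoringParams] = None,
    flank: int = 40,
    decoy_len: int = 120,
    decoy_threshold: float = 3.0,
) -> tuple[list[Transcript], Manifest]:
    """One transcript per site spec (plus clean decoys), with a manifest of the
    planted intervals and their constructed expectation scores."""
    p = params or ScoringParams()
    rng = np.random.default_rng(seed)
    manifest = Manifest()
    transcripts: list[Transcript] = []

    from .targets import scan_transcript  # local import to avoid cycles at load

    for i, spec in enumerate(site_specs):
        mirna = mirnas[spec.mirna_name].upper().replace("U", "T")
        window = _mutate_to_expectation(mirna, spec.expectation, p, rng)
        tid = f"planted_{i}_{spec.mirna_name}"
        for _attempt in range(50):
            f5 = _random_seq(rng, flank)
            f3 = _random_seq(rng, flank)
            seq = f5 + window + f3
            start, end = flank, flank + len(window)
            if spec.region == "5'UTR":
                cds = (end + 3, len(seq) - 3)
            elif spec.region == "3'UTR":
                cds = (3, start - 3)
            elif spec.region == "CDS":
                cds = (3, len(seq) - 3)
            else:
                cds = None
            tx = Transcript(tid, seq, cds)
            hits = scan_transcript(
                spec.mirna_name, mirna, tx, params=p,
                max_expectation=max(decoy_threshold, spec.expectation),
            )
            if [h.interval for h in hits] == [(start, end)] and hits[0].expectation == spec.expectation:
                transcripts.append(tx)
                manifest.sites.append(
                    PlantedSite(spec.mirna_name, tid, start, end, spec.expectation, spec.region)
                )
                break
        else:
            raise RuntimeError(f"could not isolate planted site for {spec.mirna_name}")

    for d in range(n_decoys):
        for _attempt in range(200):
            seq = _random_seq(rng, decoy_len)
            tx = Transcript(f"decoy_{d}", seq)
            clean = all(
                not scan_transcript(name, m, tx, params=p, max_expectation=decoy_threshold)
                for name, m in mirnas.items()
            )
            if clean:
                transcripts.append(tx)
                break
        else:
            raise RuntimeError("could not draw a clean decoy transcript")

    return transcripts, manifest


# ---------------------------------------------------------------------------
# TAS3-like transcripts


@dataclass
class Tas3Manifest:
    transcript: Transcript
    site5: tuple[int, int]
    site3: tuple[int, int]
    cleavable: str
    cleavage_pos: int
    phase_windows: list[tuple[int, int]]
    planted_tasirnas: dict[int, str]  # window index -> 21-mer
    arf: Optional[Transcript] = None
    arf_site: Optional[tuple[int, int]] = None


def make_tas3(
    mir390: str,
    gap: int = 126,
    cleavable_side: str = "site5",
    in_phase_windows: Sequence[int] = (0,),
    seed: int = 0,
    params: Optional[ScoringParams] = None,
    cleavable_E: float = 0.5,
    other_E: float = 2.5,
    flank: int = 30,
    make_arf: bool = True,
) -> Tas3Manifest:
    """Build a TAS3-like transcript: two miR390 sites ``gap`` nt apart, the
    cleavable one constructed to pair better (lower E), and an optional decoy
    "ARF" transcript embedding the complement of the first requested in-phase
    tasiRNA window."""
    if gap < 21:
        raise ValueError("inter-site gap must be >= 21 nt")
    if cleavable_side not in ("site5", "site3"):
        raise ValueError("cleavable_side must be 'site5' or 'site3'")
    p = params or ScoringParams()
    rng = np.random.default_rng(seed)
    mir = mir390.upper().replace("U", "T")
    L = len(mir)

    E5, E3 = (cleavable_E, other_E) if cleavable_side == "site5" else (other_E, cleavable_E)
    w5 = _mutate_to_expectation(mir, E5, p, rng)
    w3 = _mutate_to_expectation(mir, E3, p, rng)
    mid = _random_seq(rng, gap)
    seq = _random_seq(rng, flank) + w5 + mid + w3 + _random_seq(rng, flank)
    site5 = (flank, flank + L)
    site3 = (flank + L + gap, flank + 2 * L + gap)

    if cleavable_side == "site5":
        c = site5[1] - 10
        windows = []
        k = 0
        while c + 21 * (k + 1) <= site3[0]:
            windows.append((c + 21 * k, c + 21 * (k + 1)))
            k += 1
    else:
        c = site3[1] - 10
        windows = []
        k = 0
        while c - 21 * (k + 1) >= site5[1]:
            windows.append((c - 21 * (k + 1), c - 21 * k))
            k += 1
        windows.reverse()

    tx = Transcript("tas3_synthetic", seq)
    planted = {
        idx: seq[windows[idx][0] : windows[idx][1]]
        for idx in in_phase_windows
        if 0 <= idx < len(windows)
    }

    arf = arf_site = None
    if make_arf and planted:
        first = sorted(planted)[0]
        tasi = planted[first]
        a5 = _random_seq(rng, flank)
        a3 = _random_seq(rng, flank)
        arf_seq = a5 + revcomp(tasi) + a3
        arf = Transcript("arf_synthetic", arf_seq)
        arf_site = (flank, flank + len(tasi))

    return Tas3Manifest(tx, site5, site3, cleavable_side, c, windows, planted, arf, arf_site)
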