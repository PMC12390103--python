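"""Promoter and intrinsic-terminator detection.

Two independent detectors per signal class support the downstream two-tool
confidence rule: a signal seen by both detectors is called high confidence,
by one detector low confidence.

Promoters: canonical sigma-70 architecture, a -35 box (consensus TTGACA)
and a -10 box (consensus TATAAT) separated by a 15–19 nt spacer.  Method
``pwm`` scores both boxes against position-weight matrices (log-odds bits
over the scanned region's base composition) with a spacer-length penalty;
method ``consensus`` is a degenerate string match with a per-box mismatch
budget.  The TSS is placed a fixed offset (default 7 nt) downstream of the
-10 box 3' end.

Terminators: a stem-loop followed by a U-tract.  Method ``energy`` scores
base-pair stacking (G·C=3, A·T=2, G·U=1) minus a loop-length penalty plus
a U-tract bonus; method ``pattern`` demands perfect Watson–Crick stems and
at least four consecutive T shortly after the stem.

All scanning happens on the window sequence read 5'→3' on the requested
strand and coordinates are mapped back to the genome afterwards, which
makes the scanners exactly strand-symmetric.  Windows containing N at a
motif position are skipped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from .seqio import GenomeRecord, GenomicInterval, extract

__all__ = [
    "PromoterHit",
    "TerminatorHit",
    "BOX35_CONSENSUS",
    "BOX10_CONSENSUS",
    "build_pwm",
    "load_pwm",
    "scan_promoters_pwm",
    "scan_promoters_consensus",
    "scan_terminators_energy",
    "scan_terminators_pattern",
]

BOX35_CONSENSUS = "TTGACA"
BOX10_CONSENSUS = "TATAAT"
SPACER_RANGE = (15, 19)
_BASES = "ACGT"
_PAIR_WEIGHT = {
    ("G", "C"): 3.0, ("C", "G"): 3.0,
    ("A", "T"): 2.0, ("T", "A"): 2.0,
    ("G", "T"): 1.0, ("T", "G"): 1.0,
}
_WC = {("G", "C"), ("C", "G"), ("A", "T"), ("T", "A")}


@dataclass(frozen=True)
class PromoterHit:
    box35: GenomicInterval
    box10: GenomicInterval
    tss: int
    strand: int
    score: float
    method: str  # "pwm" | "consensus"


@dataclass(frozen=True)
class TerminatorHit:
    stem5: GenomicInterval
    loop: GenomicInterval
    stem3: GenomicInterval
    u_tract: GenomicInterval | None
    strand: int
    score: float
    method: str  # "energy" | "pattern"

    @property
    def end3(self) -> int:
        """Genome position of the released transcript's 3' end: the last
        U-tract position when present, else the stem3 end."""
        tail = self.u_tract if self.u_tract is not None else self.stem3
        return tail.three_prime

    @property
    def span(self) -> GenomicInterval:
        parts = [self.stem5, self.loop, self.stem3] + ([self.u_tract] if self.u_tract else [])
        return GenomicInterval(min(p.low for p in parts), max(p.high for p in parts), self.strand)


def build_pwm(consensus: str, background: dict[str, float], p_consensus: float = 0.7) -> np.ndarray:
    """Log-odds matrix (positions x ACGT, bits) for a consensus motif.

    Each position gives probability ``p_consensus`` to the consensus base
    and the remainder uniformly to the other three, scored against the
    supplied background composition.
    """
    p_other = (1.0 - p_consensus) / 3.0
    mat = np.empty((len(consensus), 4))
    for i, c in enumerate(consensus):
        for j, b in enumerate(_BASES):
            p = p_consensus if b == c else p_other
            mat[i, j] = math.log2(p / max(background[b], 1e-9))
    return mat


def load_pwm(path: str | Path) -> np.ndarray:
    """Read a PWM from a tab-separated table: one row per motif position,
    columns A, C, G, T (weights in bits).  A leading '#' header is allowed."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            vals = line.split("\t")
            if len(vals) != 4:
                raise ValueError(f"PWM rows need 4 columns (A,C,G,T), got {len(vals)}")
            rows.append([float(v) for v in vals])
    return np.array(rows)


def _composition(seq: str) -> dict[str, float]:
    n = max(1, sum(seq.count(b) for b in _BASES))
    comp = {b: seq.count(b) / n for b in _BASES}
    # guard zero-frequency bases so log-odds stay finite
    return {b: max(f, 0.01) for b, f in comp.items()}


def _local_to_genome(region: GenomicInterval, a0: int, b0: int) -> GenomicInterval:
    """Map a 0-based local span [a0, b0] on the region's strand back to
    genome coordinates."""
    if region.strand == 1:
        return GenomicInterval(region.low + a0, region.low + b0, 1)
    return GenomicInterval(region.high - b0, region.high - a0, -1)


def _genome_pos(region: GenomicInterval, p0: int) -> int:
    return region.low + p0 if region.strand == 1 else region.high - p0


def _promoter_placements(n: int, spacer_range: tuple[int, int]) -> Iterator[tuple[int, int, int]]:
    lo, hi = spacer_range
    for i in range(n):
        for sp in range(lo, hi + 1):
            j = i + 6 + sp
            if j + 6 <= n:
                yield i, sp, j


def _score_pwm(mat: np.ndarray, word: str) -> float | None:
    total = 0.0
    for i, c in enumerate(word):
        k = _BASES.find(c)
        if k < 0:
            return None  # N or other ambiguity: placement excluded
        total += mat[i, k]
    return float(total)


def scan_promoters_pwm(
    genome: GenomeRecord,
    region: GenomicInterval,
    threshold: float = 12.0,
    box35_pwm: np.ndarray | None = None,
    box10_pwm: np.ndarray | None = None,
    tss_offset: int = 7,
    spacer_range: tuple[int, int] = SPACER_RANGE,
) -> list[PromoterHit]:
    """PWM promoter scan of ``region`` on its strand.

    Score = PWM(-35) + PWM(-10) + spacer penalty (0 at spacer 17, -0.5 bits
    per nt of deviation).  Hits with score >= ``threshold`` whose TSS falls
    inside the region are returned, sorted by position.
    """
    seq = extract(genome, region)
    n = len(seq)
    if n < 6 + spacer_range[0] + 6:
        return []
    if box35_pwm is None or box10_pwm is None:
        bg = _composition(seq)
        box35_pwm = box35_pwm if box35_pwm is not None else build_pwm(BOX35_CONSENSUS, bg)
        box10_pwm = box10_pwm if box10_pwm is not None else build_pwm(BOX10_CONSENSUS, bg)
    hits: list[PromoterHit] = []
    for i, sp, j in _promoter_placements(n, spacer_range):
        tss_local = j + 5 + tss_offset
        if tss_local >= n:
            continue
        s35 = _score_pwm(box35_pwm, seq[i : i + 6])
        s10 = _score_pwm(box10_pwm, seq[j : j + 6])
        if s35 is None or s10 is None:
            continue
        score = s35 + s10 - 0.5 * abs(sp - 17)
        if score >= threshold:
            hits.append(
                PromoterHit(
                    box35=_local_to_genome(region, i, i + 5),
                    box10=_local_to_genome(region, j, j + 5),
                    tss=_genome_pos(region, tss_local),
                    strand=region.strand,
                    score=score,
                    method="pwm",
                )
            )
    return hits


def scan_promoters_consensus(
    genome: GenomeRecord,
    region: GenomicInterval,
    max_mismatches: int = 1,
    tss_offset: int = 7,
    spacer_range: tuple[int, int] = SPACER_RANGE,
) -> list[PromoterHit]:
    """Degenerate-consensus promoter scan: TTGACA/TATAAT with at most
    ``max_mismatches`` per box.  Score = -(total mismatches)."""
    seq = extract(genome, region)
    n = len(seq)
    hits: list[PromoterHit] = []
    for i, sp, j in _promoter_placements(n, spacer_range):
        tss_local = j + 5 + tss_offset
        if tss_local >= n:
            continue
        w35, w10 = seq[i : i + 6], seq[j : j + 6]
        if "N" in w35 or "N" in w10:
            continue
        mm35 = sum(a != b for a, b in zip(w35, BOX35_CONSENSUS))
        mm10 = sum(a != b for a, b in zip(w10, BOX10_CONSENSUS))
        if mm35 <= max_mismatches and mm10 <= max_mismatches:
            hits.append(
                PromoterHit(
                    box35=_local_to_genome(region, i, i + 5),
                    box10=_local_to_genome(region, j, j + 5),
                    tss=_genome_pos(region, tss_local),
                    strand=region.strand,
                    score=-(mm35 + mm10),
                    method="consensus",
                )
            )
    return hits


def _u_tract_run(seq: str, start: int, window: int = 8) -> tuple[int, int]:
    """(count, last_offset) of a 5'-anchored T run in ``seq[start:start+window]``
    allowing one single-base interruption.  ``last_offset`` is the 0-based
    offset (from ``start``) of the last counted T, -1 when none."""
    count = 0
    last = -1
    interruptions = 0
    for k in range(min(window, len(seq) - start)):
        c = seq[start + k]
        if c == "T":
            count += 1
            last = k
        else:
            interruptions += 1
            if interruptions > 1:
                break
    return count, last


def _reduce_local_maxima(hits: list[tuple[float, int, int, "TerminatorHit"]]) -> list[TerminatorHit]:
    """Keep highest-scoring hits among mutually overlapping spans (local
    coordinates), deterministically."""
    hits.sort(key=lambda t: (-t[0], t[1], t[2]))
    taken: list[tuple[int, int]] = []
    kept: list[tuple[int, TerminatorHit]] = []
    for score, a, b, hit in hits:
        if any(a <= tb and ta <= b for ta, tb in taken):
            continue
        taken.append((a, b))
        kept.append((a, hit))
    kept.sort(key=lambda t: t[0])
    return [h for _, h in kept]


def scan_terminators_energy(
    genome: GenomeRecord,
    region: GenomicInterval,
    min_score: float = 18.0,
    stem_range: tuple[int, int] = (4, 20),
    loop_range: tuple[int, int] = (3, 10),
) -> list[TerminatorHit]:
    """Stacking-energy terminator scan (G·U pairs allowed).

    Score = sum of pair weights (G·C=3, A·T=2, G·U=1) - loop penalty
    (1 per nt beyond 4) + U-tract bonus (1 per T of the 5'-anchored run,
    one interruption allowed, in the 8 nt after the stem).  Hits need at
    least 3 such T and score >= ``min_score``; overlapping hits are reduced
    to local maxima.
    """
    seq = extract(genome, region)
    n = len(seq)
    raw: list[tuple[float, int, int, TerminatorHit]] = []
    for i in range(n):
        for k in range(stem_range[0], stem_range[1] + 1):
            for l in range(loop_range[0], loop_range[1] + 1):
                e = i + 2 * k + l - 1  # stem3 end, 0-based
                if e >= n:
                    break
                ucount, ulast = _u_tract_run(seq, e + 1)
                if ucount < 3:
                    continue
                pair_score = 0.0
                ok = True
                for m in range(k):
                    pair = (seq[i + m], seq[e - m])
                    w = _PAIR_WEIGHT.get(pair)
                    if w is None:
                        ok = False
                        break
                    pair_score += w
                if not ok:
                    continue
                score = pair_score - max(0, l - 4) + ucount
                if score < min_score:
                    continue
                stem5 = _local_to_genome(region, i, i + k - 1)
                loop = _local_to_genome(region, i + k, i + k + l - 1)
                stem3 = _local_to_genome(region, i + k + l, e)
                utract = _local_to_genome(region, e + 1, e + 1 + ulast)
                raw.append(
                    (score, i, e + 1 + ulast,
                     TerminatorHit(stem5, loop, stem3, utract, region.strand, score, "energy"))
                )
    return _reduce_local_maxima(raw)


def scan_terminators_pattern(
    genome: GenomeRecord,
    region: GenomicInterval,
    stem_range: tuple[int, int] = (6, 20),
    loop_range: tuple[int, int] = (3, 8),
) -> list[TerminatorHit]:
    """Strict-pattern terminator scan: perfect Watson–Crick stems of length
    >= 6, loop 3–8, and >= 4 consecutive T starting within 5 nt after the
    stem.  Score = stem length."""
    seq = extract(genome, region)
    n = len(seq)
    raw: list[tuple[float, int, int, TerminatorHit]] = []
    for i in range(n):
        for k in range(stem_range[0], stem_range[1] + 1):
            for l in range(loop_range[0], loop_range[1] + 1):
                e = i + 2 * k + l - 1
                if e >= n:
                    break
                # a run of >=4 consecutive T must start within 5 nt after the stem
                t_start = None
                for off in range(1, 6):
                    p = e + off
                    if p + 4 > n:
                        break
                    if seq[p : p + 4] == "TTTT":
                        t_start = p
                        break
                if t_start is None:
                    continue
                if not all((seq[i + m], seq[e - m]) in _WC for m in range(k)):
                    continue
                t_end = t_start
                while t_end + 1 < n and seq[t_end + 1] == "T":
                    t_end += 1
                stem5 = _local_to_genome(region, i, i + k - 1)
                loop = _local_to_genome(region, i + k, i + k + l - 1)
                stem3 = _local_to_genome(region, i + k + l, e)
                utract = _local_to_genome(region, t_start, t_end)
                raw.append(
                    (float(k), i, t_end,
                     TerminatorHit(stem5, loop, stem3, utract, region.strand, float(k), "pattern"))
                )
    return _reduce_local_maxima(raw)
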