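"""Step A of the screen: small-ORF discovery and toxin candidate filters.

Candidate type I toxins are small (default 30–90 aa) open reading frames
with at least one predicted transmembrane segment.  Optional filters remove
homologs of known non-toxin proteins (local alignment against a curated
exclusion set, or an imported tabular hit file) and ORFs that sit within
100 bp of a same-strand annotated gene, which are likely operon members
rather than independently regulated toxin genes.

Transmembrane segments are called with a Kyte–Doolittle sliding-window
hydropathy rule (window 19, mean >= 1.6), a self-contained surrogate with a
documented contract; it is not a reimplementation of any HMM-based
topology predictor and its per-protein segment counts are a soft check
against published tables, not an exact one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .seqio import (
    FormatError,
    GeneAnnotation,
    GenomeRecord,
    GenomicInterval,
    START_CODONS,
    STOP_CODONS,
    reverse_complement,
    translate_orf,
)

__all__ = [
    "OrfRecord",
    "TmSegmentation",
    "HomologyHit",
    "KYTE_DOOLITTLE",
    "find_orfs",
    "predict_tm_segments",
    "make_aligner",
    "best_local_hit",
    "homology_exclude",
    "import_homology_hits",
    "operon_flag",
]

# Kyte & Doolittle hydropathy scale.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


@dataclass(frozen=True)
class OrfRecord:
    """A candidate toxin ORF (start codon through stop codon, inclusive)."""

    interval: GenomicInterval
    aa_sequence: str
    start_codon: str
    genome_id: str
    order_index: int = 0

    @property
    def aa_length(self) -> int:
        return len(self.aa_sequence)


@dataclass(frozen=True)
class TmSegmentation:
    """Predicted transmembrane segments, 1-based on the protein."""

    segments: tuple[tuple[int, int], ...]

    @property
    def count(self) -> int:
        return len(self.segments)


@dataclass(frozen=True)
class HomologyHit:
    query_id: str
    subject_id: str
    score: float
    identity_fraction: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.score):
            raise ValueError("alignment score must be finite")
        if not 0.0 <= self.identity_fraction <= 1.0:
            raise ValueError("identity_fraction must lie in [0, 1]")


def find_orfs(
    genome: GenomeRecord,
    min_aa: int = 30,
    max_aa: int = 90,
    all_starts: bool = False,
    start_codons: Sequence[str] = START_CODONS,
) -> list[OrfRecord]:
    """Six-frame ORF scan over both strands.

    An ORF runs from a permitted start codon to the first in-frame stop.
    By default only the longest ORF per stop codon is reported (the first
    start after the previous in-frame stop); ``all_starts=True`` reports
    every start choice.  ORFs whose span contains N are skipped.  Records
    are sorted by low coordinate and given 1-based ``order_index`` ranks.
    """
    if min_aa < 1 or max_aa < min_aa:
        raise ValueError("need 1 <= min_aa <= max_aa")
    L = len(genome)
    out: list[OrfRecord] = []
    for strand in (1, -1):
        s = genome.sequence if strand == 1 else reverse_complement(genome.sequence)
        for frame in range(3):
            starts: list[int] = []  # 0-based start offsets since last stop
            for i in range(frame, L - 2, 3):
                codon = s[i : i + 3]
                if codon in STOP_CODONS:
                    chosen = starts if all_starts else starts[:1]
                    for a in chosen:
                        n_codons = (i + 3 - a) // 3
                        aa_len = n_codons - 1
                        if not (min_aa <= aa_len <= max_aa):
                            continue
                        nt = s[a : i + 3]
                        if "N" in nt:
                            continue
                        # map local (strand-oriented) 1-based [a+1, i+3]
                        if strand == 1:
                            iv = GenomicInterval(a + 1, i + 3, 1)
                        else:
                            iv = GenomicInterval(L - (i + 3) + 1, L - (a + 1) + 1, -1)
                        out.append(
                            OrfRecord(iv, translate_orf(nt), nt[:3], genome.identifier)
                        )
                    starts = []
                elif codon in start_codons:
                    starts.append(i)
    out.sort(key=lambda r: (r.interval.low, r.interval.high, -r.interval.strand))
    return [
        OrfRecord(r.interval, r.aa_sequence, r.start_codon, r.genome_id, k + 1)
        for k, r in enumerate(out)
    ]


def predict_tm_segments(
    aa_sequence: str,
    window: int = 19,
    threshold: float = 1.6,
    min_gap: int = 5,
) -> TmSegmentation:
    """Hydropathy-based transmembrane segment prediction.

    Every residue whose centered ``window``-mean Kyte–Doolittle hydropathy
    is at least ``threshold`` is marked; maximal runs of marked residues,
    expanded to the window extent and merged when separated by fewer than
    ``min_gap`` residues, become segments.  Sequences shorter than the
    window yield zero segments.  Non-standard residues (B, Z, X, ...) are
    scored with hydropathy 0.
    """
    n = len(aa_sequence)
    if n < window:
        return TmSegmentation(())
    half = window // 2
    values = np.array([KYTE_DOOLITTLE.get(a, 0.0) for a in aa_sequence.upper()])
    means = np.convolve(values, np.ones(window) / window, mode="valid")
    marked = means >= threshold  # index i -> center position i + half (0-based)
    segments: list[list[int]] = []
    run_start = None
    for i, m in enumerate(marked):
        if m and run_start is None:
            run_start = i
        elif not m and run_start is not None:
            segments.append([run_start, i - 1])
            run_start = None
    if run_start is not None:
        segments.append([run_start, len(marked) - 1])
    # expand runs of centers to full window extent, in 1-based protein coords
    expanded = [[s + 1, e + window] for s, e in segments]
    merged: list[list[int]] = []
    for seg in expanded:
        if merged and seg[0] - merged[-1][1] - 1 < min_gap:
            merged[-1][1] = max(merged[-1][1], seg[1])
        else:
            merged.append(seg)
    return TmSegmentation(tuple((max(1, s), min(n, e)) for s, e in merged))


def make_aligner(matrix: str = "BLOSUM62", gap_open: float = 11.0, gap_extend: float = 1.0):
    """Local protein aligner; a gap of length k costs ``gap_open + k*gap_extend``."""
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def best_local_hit(query_id: str, query: str, subject_id: str, subject: str, aligner=None) -> HomologyHit:
    """Best Smith–Waterman hit of ``query`` against ``subject``.

    Identity is counted over the aligned span (gap columns included), the
    convention of the de facto tabular hit format.
    """
    if aligner is None:
        aligner = make_aligner()
    alignments = aligner.align(query, subject)
    score = float(aligner.score(query, subject))
    if score <= 0 or len(alignments) == 0:
        return HomologyHit(query_id, subject_id, max(score, 0.0), 0.0)
    aln = alignments[0]
    counts = aln.counts()
    span = counts.identities + counts.mismatches + counts.gaps
    ident = counts.identities / span if span else 0.0
    return HomologyHit(query_id, subject_id, score, ident)


def homology_exclude(
    candidates: Sequence[OrfRecord],
    exclusion_proteins: dict[str, str] | None,
    score_threshold: float = 50.0,
    identity_threshold: float = 0.35,
) -> tuple[list[OrfRecord], list[HomologyHit]]:
    """Drop candidates similar to proteins that are not type I toxins.

    A candidate is dropped when its best local-alignment hit against any
    exclusion protein scores at least ``score_threshold`` with identity at
    least ``identity_threshold`` over the aligned span.  With an empty
    exclusion set all candidates are retained.  Returns the retained
    candidates and a log of the hits that caused drops.
    """
    if not exclusion_proteins:
        return list(candidates), []
    aligner = make_aligner()
    kept: list[OrfRecord] = []
    dropped_hits: list[HomologyHit] = []
    for cand in candidates:
        qid = f"{cand.genome_id}:{cand.interval.low}-{cand.interval.high}"
        best: HomologyHit | None = None
        for sid, prot in exclusion_proteins.items():
            hit = best_local_hit(qid, cand.aa_sequence, sid, prot, aligner)
            if best is None or hit.score > best.score:
                best = hit
        assert best is not None
        if best.score >= score_threshold and best.identity_fraction >= identity_threshold:
            dropped_hits.append(best)
        else:
            kept.append(cand)
    return kept, dropped_hits


def read_protein_fasta(path: str | Path) -> dict[str, str]:
    """Protein FASTA as an {id: sequence} exclusion set."""
    from Bio import SeqIO

    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq or not seq.replace("*", "").isalpha():
            raise FormatError(f"malformed protein record {rec.id!r} in {path}")
        if rec.id in out:
            raise FormatError(f"duplicate protein identifier {rec.id!r} in {path}")
        out[rec.id] = seq.rstrip("*")
    if not out:
        raise FormatError(f"no protein records found in {path}")
    return out


def import_homology_hits(path: str | Path) -> list[HomologyHit]:
    """Parse 12-column tab-separated hits (query, subject, %identity, length,
    mismatches, gap opens, qstart, qend, sstart, send, e-value, bitscore).

    Lines starting with ``#`` are comments.  The bitscore is used as the
    score and %identity is converted to a fraction.
    """
    hits: list[HomologyHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise FormatError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, got {len(fields)}"
                )
            try:
                ident = float(fields[2]) / 100.0
                bitscore = float(fields[11])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            hits.append(HomologyHit(fields[0], fields[1], bitscore, ident))
    return hits


def operon_flag(
    orf: OrfRecord,
    annotations: Sequence[GeneAnnotation],
    max_gap: int = 100,
) -> str:
    """``possible_operon_member`` when a same-strand annotated gene lies
    within ``max_gap`` nucleotides of either ORF end, else ``free_standing``.

    An annotation identical in span and strand to the ORF itself (the ORF's
    own gene entry) is ignored.
    """
    for ann in annotations:
        if ann.interval.strand != orf.interval.strand:
            continue
        if ann.interval.low == orf.interval.low and ann.interval.high == orf.interval.high:
            continue
        if orf.interval.distance_to(ann.interval) < max_gap:
            return "possible_operon_member"
    return "free_standing"
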