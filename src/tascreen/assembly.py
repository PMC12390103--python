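"""Steps B–C of the screen: antisense antitoxin inference, toxin mRNA
modelling, overlap classification, confidence, naming.

For each retained toxin ORF the antisense strand of a window reaching
``pad`` (default 300) nt beyond both ORF ends is scanned for promoters and
terminators.  Promoters upstream of terminators (in antisense transcription
order) imply cis-encoded antisense RNA antitoxins; multiple promoters
sharing a terminator yield antitoxin isoforms.  Each isoform is classified
by which parts of the toxin mRNA it is complementary to: CDS, 5'-UTR,
3'-UTR.  When no promoter or terminator is found for the toxin itself the
toxin mRNA falls back to the bare CDS and classification is CDS-relative:
antitoxin extent beyond the CDS on the toxin's 3' side counts as 3'-UTR,
on the 5' side as 5'-UTR.

Confidence follows the two-tool rule: an element (one promoter or one
terminator, grouped across detection methods when positions agree within a
tolerance) found by both methods is high confidence, by one method low.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .seqio import GenomeRecord, GenomicInterval
from .screen import (
    OrfRecord,
    TmSegmentation,
    find_orfs,
    homology_exclude,
    operon_flag,
    predict_tm_segments,
)
from .signals import (
    PromoterHit,
    TerminatorHit,
    scan_promoters_consensus,
    scan_promoters_pwm,
    scan_terminators_energy,
    scan_terminators_pattern,
)

__all__ = [
    "TranscriptModel",
    "SignalElement",
    "AntitoxinIsoform",
    "TaCandidate",
    "antisense_window",
    "evaluate_confidence",
    "group_promoters",
    "group_terminators",
    "build_antitoxin_isoforms",
    "build_toxin_mrna",
    "classify_overlap",
    "assemble_candidates",
]

CDS = "CDS"
UTR5 = "5′-UTR"
UTR3 = "3′-UTR"


@dataclass(frozen=True)
class TranscriptModel:
    """An inferred RNA: TSS through 3' end, with optional CDS and UTRs."""

    strand: int
    tss: int
    end3: int
    cds: GenomicInterval | None = None
    utr5: GenomicInterval | None = None
    utr3: GenomicInterval | None = None

    def __post_init__(self) -> None:
        if self.strand * (self.end3 - self.tss) < 0:
            raise ValueError("tss -> end3 must run 5'->3' on the transcript strand")

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(min(self.tss, self.end3), max(self.tss, self.end3), self.strand)

    @property
    def length(self) -> int:
        return abs(self.end3 - self.tss) + 1


@dataclass(frozen=True)
class SignalElement:
    """One promoter or terminator, possibly seen by several methods."""

    kind: str  # "promoter" | "terminator"
    position: int  # TSS (promoter) or transcript 3' end (terminator)
    strand: int
    confidence: str  # "high" | "low"
    hits: tuple = ()

    @property
    def methods(self) -> frozenset[str]:
        return frozenset(h.method for h in self.hits)


@dataclass(frozen=True)
class AntitoxinIsoform:
    transcript: TranscriptModel
    isoform_index: int
    overlap_classes: frozenset[str]
    promoter_confidence: str
    terminator_confidence: str


@dataclass(frozen=True)
class TaCandidate:
    """One putative type I TA locus: toxin ORF + antisense antitoxin isoforms."""

    toxin: OrfRecord
    toxin_mrna: TranscriptModel
    isoforms: tuple[AntitoxinIsoform, ...]
    toxin_name: str
    antitoxin_name: str
    overall_confidence: str
    tm: TmSegmentation | None = None
    operon_status: str = "free_standing"


def antisense_window(toxin: GenomicInterval, genome_length: int, pad: int = 300) -> GenomicInterval:
    """The antisense search window: the toxin span padded by ``pad`` on both
    sides, clipped to genome bounds, on the strand opposite the toxin."""
    return GenomicInterval(
        max(1, toxin.low - pad),
        min(genome_length, toxin.high + pad),
        -toxin.strand,
    )


def evaluate_confidence(hits: Sequence) -> str:
    """Two-tool rule for one grouped element: both methods -> high, one -> low."""
    methods = {h.method for h in hits}
    if not methods:
        raise ValueError("no hits for element")
    return "high" if len(methods) >= 2 else "low"


def _group(hits: Sequence, key, kind: str, strand: int, tolerance: int,
           preferred_method: str) -> list[SignalElement]:
    """Single-linkage clustering of hits along ``key`` with ``tolerance``.

    The element position is taken from the best-scoring hit of the
    preferred method when present, else the best remaining hit.
    """
    if not hits:
        return []
    ordered = sorted(hits, key=key)
    clusters: list[list] = [[ordered[0]]]
    for h in ordered[1:]:
        if key(h) - key(clusters[-1][-1]) <= tolerance:
            clusters[-1].append(h)
        else:
            clusters.append([h])
    elements = []
    for cl in clusters:
        pref = [h for h in cl if h.method == preferred_method] or cl
        best = max(pref, key=lambda h: (h.score, -key(h)))
        elements.append(
            SignalElement(kind, key(best), strand, evaluate_confidence(cl), tuple(cl))
        )
    return elements


def group_promoters(hits: Sequence[PromoterHit], tolerance: int = 5) -> list[SignalElement]:
    strand = hits[0].strand if hits else 1
    return _group(hits, lambda h: h.tss, "promoter", strand, tolerance, "pwm")


def group_terminators(hits: Sequence[TerminatorHit], tolerance: int = 5) -> list[SignalElement]:
    strand = hits[0].strand if hits else 1
    return _group(hits, lambda h: h.end3, "terminator", strand, tolerance, "energy")


def build_antitoxin_isoforms(
    promoters: Sequence[SignalElement],
    terminators: Sequence[SignalElement],
    toxin_mrna: TranscriptModel,
    strand: int,
    min_length: int = 40,
) -> list[AntitoxinIsoform]:
    """Pair each antisense TSS with the nearest terminator 3' end downstream
    of it, classify the implied transcript against the toxin mRNA, and
    number isoforms by increasing length (isoform 1 is the shortest, the
    promoter nearest the shared terminator)."""
    raw: list[tuple[TranscriptModel, SignalElement, SignalElement]] = []
    for prom in promoters:
        downstream = [t for t in terminators if strand * (t.position - prom.position) > 0]
        if not downstream:
            continue
        term = min(downstream, key=lambda t: abs(t.position - prom.position))
        transcript = TranscriptModel(strand=strand, tss=prom.position, end3=term.position)
        if transcript.length < min_length:
            continue
        raw.append((transcript, prom, term))
    raw.sort(key=lambda t: (t[0].length, t[0].interval.low))
    isoforms = []
    for idx, (transcript, prom, term) in enumerate(raw, start=1):
        classes = classify_overlap(transcript.interval, toxin_mrna)
        isoforms.append(
            AntitoxinIsoform(transcript, idx, frozenset(classes),
                             prom.confidence, term.confidence)
        )
    return isoforms


def _rank_promoter(elem: SignalElement) -> tuple:
    pwm = [h.score for h in elem.hits if h.method == "pwm"]
    cons = [h.score for h in elem.hits if h.method == "consensus"]
    return (
        0 if elem.confidence == "high" else 1,
        -(max(pwm) if pwm else float("-inf")),
        -(max(cons) if cons else float("-inf")),
    )


def build_toxin_mrna(
    toxin: OrfRecord,
    promoters: Sequence[SignalElement],
    terminators: Sequence[SignalElement],
) -> TranscriptModel:
    """Model the toxin mRNA from same-strand signals around the CDS.

    TSS = the best-ranked promoter TSS upstream of the start codon (high
    confidence first, then PWM score, then proximity); 3' end = the nearest
    terminator end downstream of the stop codon.  Either side falls back to
    the CDS boundary, leaving that UTR empty.
    """
    cds = toxin.interval
    s = cds.strand
    ups = [p for p in promoters if s * (cds.five_prime - p.position) > 0]
    downs = [t for t in terminators if s * (t.position - cds.three_prime) > 0]
    tss = cds.five_prime
    utr5 = None
    if ups:
        best = min(ups, key=lambda p: (_rank_promoter(p), abs(cds.five_prime - p.position)))
        tss = best.position
        utr5 = GenomicInterval(min(tss, cds.five_prime - s), max(tss, cds.five_prime - s), s) \
            if tss != cds.five_prime else None
    end3 = cds.three_prime
    utr3 = None
    if downs:
        term = min(downs, key=lambda t: abs(t.position - cds.three_prime))
        end3 = term.position
        utr3 = GenomicInterval(min(end3, cds.three_prime + s), max(end3, cds.three_prime + s), s) \
            if end3 != cds.three_prime else None
    return TranscriptModel(strand=s, tss=tss, end3=end3, cds=cds, utr5=utr5, utr3=utr3)


def classify_overlap(antitoxin_iv: GenomicInterval, toxin_mrna: TranscriptModel) -> set[str]:
    """Which toxin mRNA regions the antisense antitoxin is complementary to.

    Returns every category the antitoxin interval intersects: ``CDS``,
    ``5'-UTR``, ``3'-UTR``.  When a UTR is modelled its own extent is used;
    in fallback mode (UTR absent) any antitoxin extent beyond the CDS on
    the corresponding side counts as that UTR.  An empty result means the
    pair fails the complementarity requirement.
    """
    cds = toxin_mrna.cds
    if cds is None:
        raise ValueError("toxin mRNA must carry a CDS for classification")
    if antitoxin_iv.strand == cds.strand:
        raise ValueError("antitoxin must lie on the strand opposite the toxin")
    classes: set[str] = set()
    if antitoxin_iv.overlaps(cds):
        classes.add(CDS)
    s = cds.strand
    # 5' side of the CDS on the toxin strand
    utr5 = toxin_mrna.utr5
    if utr5 is not None:
        if antitoxin_iv.overlaps(utr5):
            classes.add(UTR5)
    else:
        beyond5 = antitoxin_iv.low < cds.low if s == 1 else antitoxin_iv.high > cds.high
        if beyond5:
            classes.add(UTR5)
    utr3 = toxin_mrna.utr3
    if utr3 is not None:
        if antitoxin_iv.overlaps(utr3):
            classes.add(UTR3)
    else:
        beyond3 = antitoxin_iv.high > cds.high if s == 1 else antitoxin_iv.low < cds.low
        if beyond3:
            classes.add(UTR3)
    return classes


def _scan_all(genome: GenomeRecord, region: GenomicInterval, config) -> tuple[list, list]:
    """Both promoter methods and both terminator methods over one region."""
    prom = scan_promoters_pwm(
        genome, region, threshold=config.promoter_threshold,
        tss_offset=config.tss_offset,
        spacer_range=(config.spacer_min, config.spacer_max),
    ) + scan_promoters_consensus(
        genome, region, max_mismatches=config.promoter_max_mismatches,
        tss_offset=config.tss_offset,
        spacer_range=(config.spacer_min, config.spacer_max),
    )
    term = scan_terminators_energy(
        genome, region, min_score=config.terminator_min_score,
    ) + scan_terminators_pattern(genome, region)
    return prom, term


def assemble_candidates(
    genome: GenomeRecord,
    config=None,
    annotations: Sequence | None = None,
    exclusion_proteins: dict[str, str] | None = None,
) -> tuple[list[TaCandidate], dict]:
    """Run the full three-step screen on one genome.

    Returns the accepted TA candidates and a stage log mapping stage name
    to ``{"in": n, "kept": n, "dropped": n}`` so candidate counts can be
    audited across every filter.
    """
    from .config import PipelineConfig

    if config is None:
        config = PipelineConfig()
    log: dict[str, dict[str, int]] = {}

    orfs = find_orfs(genome, config.min_aa, config.max_aa, all_starts=config.all_starts)
    log["orf_scan"] = {"in": 0, "kept": len(orfs), "dropped": 0}

    tm_map: dict[int, TmSegmentation] = {}
    tm_kept: list[OrfRecord] = []
    for orf in orfs:
        seg = predict_tm_segments(
            orf.aa_sequence, config.tm_window, config.tm_threshold, config.tm_min_gap
        )
        if seg.count >= 1:
            tm_map[orf.order_index] = seg
            tm_kept.append(orf)
    log["tm_filter"] = {"in": len(orfs), "kept": len(tm_kept), "dropped": len(orfs) - len(tm_kept)}

    hom_kept, _hits = homology_exclude(
        tm_kept, exclusion_proteins,
        config.homology_score_threshold, config.homology_identity_threshold,
    )
    log["homology_filter"] = {
        "in": len(tm_kept), "kept": len(hom_kept), "dropped": len(tm_kept) - len(hom_kept)
    }

    operon_status: dict[int, str] = {}
    op_kept: list[OrfRecord] = []
    for orf in hom_kept:
        status = operon_flag(orf, annotations or [], config.operon_max_gap)
        operon_status[orf.order_index] = status
        if status == "free_standing" or config.keep_operon_flagged:
            op_kept.append(orf)
    log["operon_filter"] = {
        "in": len(hom_kept), "kept": len(op_kept), "dropped": len(hom_kept) - len(op_kept)
    }

    candidates: list[TaCandidate] = []
    for orf in op_kept:
        window = antisense_window(orf.interval, len(genome), config.window_pad)
        anti_prom_hits, anti_term_hits = _scan_all(genome, window, config)
        anti_proms = group_promoters(anti_prom_hits, config.group_tolerance)
        anti_terms = group_terminators(anti_term_hits, config.group_tolerance)
        if not anti_proms or not anti_terms:
            continue
        sense_window = GenomicInterval(window.low, window.high, orf.interval.strand)
        tox_prom_hits, tox_term_hits = _scan_all(genome, sense_window, config)
        toxin_mrna = build_toxin_mrna(
            orf,
            group_promoters(tox_prom_hits, config.group_tolerance),
            group_terminators(tox_term_hits, config.group_tolerance),
        )
        isoforms = [
            iso for iso in build_antitoxin_isoforms(
                anti_proms, anti_terms, toxin_mrna, window.strand,
                config.min_isoform_length,
            )
            if iso.overlap_classes
        ]
        isoforms = [
            AntitoxinIsoform(iso.transcript, k + 1, iso.overlap_classes,
                             iso.promoter_confidence, iso.terminator_confidence)
            for k, iso in enumerate(isoforms)
        ]
        if not isoforms:
            continue
        high = any(
            iso.promoter_confidence == "high" and iso.terminator_confidence == "high"
            for iso in isoforms
        )
        suffix = f"{orf.order_index:04d}"
        candidates.append(
            TaCandidate(
                toxin=orf,
                toxin_mrna=toxin_mrna,
                isoforms=tuple(isoforms),
                toxin_name=f"{config.toxin_prefix}{suffix}",
                antitoxin_name=f"{config.organism_prefix}{suffix}",
                overall_confidence="high" if high else "low",
                tm=tm_map.get(orf.order_index),
                operon_status=operon_status.get(orf.order_index, "free_standing"),
            )
        )
    log["signal_gate"] = {
        "in": len(op_kept), "kept": len(candidates), "dropped": len(op_kept) - len(candidates)
    }
    return candidates, log
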