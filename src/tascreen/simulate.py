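"""Synthetic genomes with planted, truth-annotated type I TA loci.

Every planted locus carries the structure the screen assumes: a small
toxin ORF whose protein has a contiguous hydrophobic stretch (back-
translated from residues sampled in {L,I,V,F,A,M}), and on the opposite
strand within the 300-nt search window a two-box sigma-70 promoter and,
downstream of its implied TSS, a stem-loop terminator with a U-tract.
Promoter and terminator are positioned so the implied antisense transcript
overlaps the toxin CDS with a configured expected class set, cycling
through the three patterns seen in real loci: {CDS, 3'-UTR},
{CDS, 5'-UTR} and {3'-UTR}.

The generator is deterministic under its seed.  Loci are spaced at least
700 nt apart so their search windows never interact.  An in-frame stop
codon is written immediately upstream of each planted start codon so the
longest-ORF-per-stop rule recovers exactly the planted toxin interval.
Where a planted signal must overwrite toxin codons (terminator hairpins
reaching into the CDS 3' end; the -10 box of a 5'-UTR-overlapping
antitoxin's promoter) the locus is re-drawn until the reading frame is
still stop-free and the transmembrane stretch still scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .seqio import GenomeRecord, GenomicInterval, reverse_complement, translate_orf
from .screen import predict_tm_segments
from .signals import BOX10_CONSENSUS, BOX35_CONSENSUS
from .assembly import CDS, UTR3, UTR5

__all__ = ["SimConfig", "TruthRecord", "simulate_genome", "save_simulation"]

_HYDROPHOBIC = "LIVFAM"
_HYDROPHILIC = "KEDNQSRTG"
_CLASS_CYCLE = (
    frozenset({CDS, UTR3}),
    frozenset({CDS, UTR5}),
    frozenset({UTR3}),
)


class SimulationError(ValueError):
    """Raised when a configuration cannot be realised (e.g. genome too short)."""


@dataclass(frozen=True)
class SimConfig:
    genome_length: int = 100_000
    gc_content: float = 0.5
    n_loci: int = 5
    toxin_aa_min: int = 45
    toxin_aa_max: int = 80
    tm_segment_length: int = 24
    promoter_mismatches: int = 0
    spacer: int = 17
    terminator_stem: int = 8
    terminator_loop: int = 4
    u_tract: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.gc_content < 1.0:
            raise SimulationError("gc_content must lie in (0, 1)")
        if self.n_loci < 0:
            raise SimulationError("n_loci must be >= 0")
        if not 45 <= self.toxin_aa_min <= self.toxin_aa_max <= 90:
            raise SimulationError("need 45 <= toxin_aa_min <= toxin_aa_max <= 90")
        if self.tm_segment_length < 19:
            raise SimulationError("tm_segment_length must cover one hydropathy window (>= 19)")
        if not 15 <= self.spacer <= 19:
            raise SimulationError("spacer must lie in [15, 19]")
        if not 4 <= self.terminator_stem <= 20:
            raise SimulationError("terminator_stem must lie in [4, 20]")
        if not 3 <= self.terminator_loop <= 8:
            raise SimulationError("terminator_loop must lie in [3, 8]")
        if self.u_tract < 4:
            raise SimulationError("u_tract must be >= 4")
        if 2 * self.terminator_stem + self.terminator_loop + self.u_tract > 36:
            raise SimulationError(
                "terminator footprint (2*stem + loop + u_tract) must be <= 36 nt "
                "so planted hairpins fit beside the toxin reading frame"
            )


@dataclass(frozen=True)
class TruthRecord:
    locus_id: str
    toxin_iv: GenomicInterval
    antitoxin_iv: GenomicInterval
    expected_classes: frozenset[str]

    def __post_init__(self) -> None:
        if self.antitoxin_iv.strand == self.toxin_iv.strand:
            raise ValueError("planted antitoxin must lie opposite its toxin")


def _codon_choices() -> dict[str, list[str]]:
    from Bio.Data.CodonTable import unambiguous_dna_by_id

    table = unambiguous_dna_by_id[11].forward_table
    rev: dict[str, list[str]] = {}
    for codon, aa in sorted(table.items()):
        rev.setdefault(aa, []).append(codon)
    return rev


_CODONS = _codon_choices()


def _background(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(np.array(list("AGCT")), size=n, p=probs)


def _mutate_box(rng: np.random.Generator, box: str, n_mismatches: int) -> str:
    chars = list(box)
    if n_mismatches:
        for pos in rng.choice(len(chars), size=min(n_mismatches, len(chars)), replace=False):
            options = [b for b in "ACGT" if b != chars[pos]]
            chars[pos] = options[rng.integers(len(options))]
    return "".join(chars)


def _write(seg: list[str], low: int, text: str) -> None:
    """Write ``text`` on the plus strand at 1-based position ``low``."""
    seg[low - 1 : low - 1 + len(text)] = list(text)


def _write_antisense(seg: list[str], low: int, minus_read: str) -> None:
    """Write a string read 5'->3' on the minus strand over [low, low+len-1]."""
    _write(seg, low, reverse_complement(minus_read))


def _plant_locus(
    rng: np.random.Generator, cfg: SimConfig, classes: frozenset[str]
) -> tuple[str, GenomicInterval, GenomicInterval]:
    """One locus segment with the toxin on the plus strand.

    Returns (segment, toxin interval, antitoxin interval), coordinates
    1-based within the segment.
    """
    for _attempt in range(200):
        aa_len = int(rng.integers(cfg.toxin_aa_min, cfg.toxin_aa_max + 1))
        nt_len = 3 * (aa_len + 1)
        ts = 80
        te = ts + nt_len - 1
        seg_len = te + 150
        seg = list(_background(rng, seg_len, cfg.gc_content))

        # toxin ORF: M, then a hydrophobic stretch at codons 3.., hydrophilic rest
        tm_s, tm_e = 3, 3 + cfg.tm_segment_length - 1
        residues = ["M"]
        for k in range(2, aa_len + 1):
            pool = _HYDROPHOBIC if tm_s <= k <= tm_e else _HYDROPHILIC
            residues.append(pool[rng.integers(len(pool))])
        codons = ["ATG"]
        for aa in residues[1:]:
            opts = _CODONS[aa]
            codons.append(opts[rng.integers(len(opts))])
        codons.append("TAA")
        _write(seg, ts, "".join(codons))
        _write(seg, ts - 3, "TAA")  # in-frame guard stop just upstream

        # antisense cassette geometry (antitoxin on the minus strand); the
        # terminator occupies [term_end, term_end + term_len - 1]
        term_len = 2 * cfg.terminator_stem + cfg.terminator_loop + cfg.u_tract
        if classes == frozenset({CDS, UTR3}):
            tss, term_end = te + 50, te - (term_len + 2)
        elif classes == frozenset({CDS, UTR5}):
            tss, term_end = te - 20, ts - 40
        elif classes == frozenset({UTR3}):
            tss, term_end = te + 90, te + 45
        else:
            raise SimulationError(f"unsupported expected class set {set(classes)}")

        # terminator: stem5 + loop + stem3 + U-tract, read on the minus strand,
        # ending (3'-most, lowest genome coordinate) at term_end
        stem5 = "".join("GC"[rng.integers(2)] for _ in range(cfg.terminator_stem))
        terminator = (
            stem5 + "C" * cfg.terminator_loop + reverse_complement(stem5) + "T" * cfg.u_tract
        )
        _write_antisense(seg, term_end, terminator)

        # promoter boxes; the spacer between them keeps the existing sequence
        box10 = _mutate_box(rng, BOX10_CONSENSUS, cfg.promoter_mismatches)
        box35 = _mutate_box(rng, BOX35_CONSENSUS, cfg.promoter_mismatches)
        _write_antisense(seg, tss + 7, box10)
        _write_antisense(seg, tss + 13 + cfg.spacer, box35)

        segment = "".join(seg)
        orf_nt = segment[ts - 1 : te]
        try:
            aa = translate_orf(orf_nt)
        except ValueError:
            continue  # an overwrite broke the frame; redraw
        if predict_tm_segments(aa).count < 1:
            continue
        if segment[ts - 4 : ts - 1] != "TAA":
            continue
        toxin_iv = GenomicInterval(ts, te, 1)
        anti_iv = GenomicInterval(min(tss, term_end), max(tss, term_end), -1)
        return segment, toxin_iv, anti_iv
    raise SimulationError("could not realise a planted locus in 200 attempts")


def simulate_genome(config: SimConfig) -> tuple[GenomeRecord, list[TruthRecord]]:
    """A background genome at the configured GC with ``n_loci`` planted TA loci."""
    rng = np.random.default_rng(config.seed)
    genome = list(_background(rng, config.genome_length, config.gc_content))

    truths: list[TruthRecord] = []
    if config.n_loci:
        seg_max = 80 + 3 * (config.toxin_aa_max + 1) - 1 + 150
        spacing = seg_max + 700
        margin = 400
        slot = (config.genome_length - 2 * margin) // config.n_loci
        if slot < spacing:
            raise SimulationError(
                f"genome_length {config.genome_length} too short for "
                f"{config.n_loci} loci (need >= {margin * 2 + config.n_loci * spacing})"
            )
        for i in range(config.n_loci):
            classes = _CLASS_CYCLE[i % len(_CLASS_CYCLE)]
            segment, tox_rel, anti_rel = _plant_locus(rng, config, classes)
            # jitter within the slot keeps >= 700 nt between neighbouring loci
            jitter = int(rng.integers(0, slot - spacing + 1))
            offset = margin + i * slot + jitter  # 0-based genome offset
            toxin_strand = 1 if rng.integers(2) == 0 else -1
            if toxin_strand == -1:
                L = len(segment)
                segment = reverse_complement(segment)
                tox_rel = GenomicInterval(L - tox_rel.high + 1, L - tox_rel.low + 1, -1)
                anti_rel = GenomicInterval(L - anti_rel.high + 1, L - anti_rel.low + 1, 1)
            genome[offset : offset + len(segment)] = list(segment)
            truths.append(
                TruthRecord(
                    locus_id=f"locus_{i + 1:02d}",
                    toxin_iv=GenomicInterval(
                        tox_rel.low + offset, tox_rel.high + offset, tox_rel.strand
                    ),
                    antitoxin_iv=GenomicInterval(
                        anti_rel.low + offset, anti_rel.high + offset, anti_rel.strand
                    ),
                    expected_classes=classes,
                )
            )
    record = GenomeRecord(f"sim_seed{config.seed}", "".join(genome), "linear")
    return record, truths


def save_simulation(
    out_dir: str | Path, genome: GenomeRecord, truths: list[TruthRecord]
) -> dict[str, Path]:
    """Write genome FASTA plus truth GFF3 and TSV; returns the paths."""
    from .report import write_gff3
    from .seqio import write_fasta

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": out_dir / "genome.fasta",
        "truth_gff3": out_dir / "truth.gff3",
        "truth_tsv": out_dir / "truth.tsv",
    }
    write_fasta(paths["genome"], [genome])
    features = []
    for t in truths:
        features.append(
            (genome.identifier, "tascreen_sim", "CDS", t.toxin_iv, ".",
             {"ID": f"{t.locus_id}_toxin"})
        )
        features.append(
            (genome.identifier, "tascreen_sim", "ncRNA", t.antitoxin_iv, ".",
             {"ID": f"{t.locus_id}_antitoxin",
              "overlap_classes": ",".join(sorted(t.expected_classes))})
        )
    write_gff3(paths["truth_gff3"], features)
    with open(paths["truth_tsv"], "w") as fh:
        fh.write(
            "locus\ttoxin_start\ttoxin_end\ttoxin_strand\t"
            "antitoxin_start\tantitoxin_end\tantitoxin_strand\texpected_classes\n"
        )
        for t in truths:
            ts, te = t.toxin_iv.as_start_end()
            as_, ae = t.antitoxin_iv.as_start_end()
            fh.write(
                f"{t.locus_id}\t{ts}\t{te}\t{t.toxin_iv.strand}\t"
                f"{as_}\t{ae}\t{t.antitoxin_iv.strand}\t"
                f"{', '.join(sorted(t.expected_classes))}\n"
            )
    return paths
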