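"""Report writers and the coordinate-only classification check.

Two tabular dialects mirror the worked-example tables: a toxin table
(Name, GenBank Accession, Start, End, Strand, Length (aa), TM Regions) and
an antitoxin table (Name, Isoform, Start, End, Strand, Length (nt), Toxin
mRNA Complementarity).  Start/End are 5'-first, so Start > End on the
minus strand.  Complementarity categories are joined as e.g.
"CDS, 3′-UTR".  A combined GFF3 links toxin CDS, toxin mRNA and antitoxin
ncRNA features through shared locus identifiers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .assembly import CDS, UTR5, UTR3, TaCandidate, TranscriptModel, classify_overlap
from .fixtures import AntitoxinRow, ToxinRow
from .seqio import FormatError, GenomicInterval

_CLASS_ORDER = (CDS, UTR5, UTR3)

TOXIN_COLUMNS = ["Name", "GenBank Accession", "Start", "End", "Strand",
                 "Length (aa)", "TM Regions"]
ANTITOXIN_COLUMNS = ["Name", "Isoform", "Start", "End", "Strand",
                     "Length (nt)", "Toxin mRNA Complementarity"]


def format_classes(classes: Iterable[str]) -> str:
    cs = set(classes)
    return ", ".join(c for c in _CLASS_ORDER if c in cs)


def write_toxin_table(path: str | Path, candidates: Sequence[TaCandidate]) -> None:
    rows = []
    for cand in candidates:
        start, end = cand.toxin.interval.as_start_end()
        rows.append({
            "Name": cand.toxin_name,
            "GenBank Accession": "-",
            "Start": start,
            "End": end,
            "Strand": cand.toxin.interval.strand,
            "Length (aa)": cand.toxin.aa_length,
            "TM Regions": cand.tm.count if cand.tm else 0,
        })
    pd.DataFrame(rows, columns=TOXIN_COLUMNS).to_csv(path, sep="\t", index=False)


def write_antitoxin_table(path: str | Path, candidates: Sequence[TaCandidate]) -> None:
    rows = []
    for cand in candidates:
        single = len(cand.isoforms) == 1
        for iso in cand.isoforms:
            start, end = iso.transcript.interval.as_start_end()
            rows.append({
                "Name": cand.antitoxin_name,
                "Isoform": "-" if single else str(iso.isoform_index),
                "Start": start,
                "End": end,
                "Strand": iso.transcript.strand,
                "Length (nt)": iso.transcript.length,
                "Toxin mRNA Complementarity": format_classes(iso.overlap_classes),
            })
    pd.DataFrame(rows, columns=ANTITOXIN_COLUMNS).to_csv(path, sep="\t", index=False)


def read_toxin_table(path: str | Path) -> list[ToxinRow]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in TOXIN_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return [
        ToxinRow(
            name=r["Name"],
            accession=r["GenBank Accession"],
            interval=GenomicInterval.from_start_end(int(r["Start"]), int(r["End"]),
                                                    int(r["Strand"])),
            length_aa=int(r["Length (aa)"]),
            tm_regions=int(r["TM Regions"]),
        )
        for _, r in df.iterrows()
    ]


def read_antitoxin_table(path: str | Path) -> list[AntitoxinRow]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ANTITOXIN_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return [
        AntitoxinRow(
            name=r["Name"],
            isoform=r["Isoform"],
            interval=GenomicInterval.from_start_end(int(r["Start"]), int(r["End"]),
                                                    int(r["Strand"])),
            length_nt=int(r["Length (nt)"]),
            complementarity=r["Toxin mRNA Complementarity"],
        )
        for _, r in df.iterrows()
    ]


@dataclass(frozen=True)
class ClassifyRow:
    name: str
    isoform: str
    printed_length: int
    recomputed_length: int
    printed_classes: str
    recomputed_classes: str
    error: str = ""

    @property
    def length_ok(self) -> bool:
        return not self.error and self.printed_length == self.recomputed_length

    @property
    def classes_ok(self) -> bool:
        return not self.error and self.printed_classes == self.recomputed_classes


@dataclass(frozen=True)
class ToxinCheckRow:
    name: str
    printed_length_aa: int
    recomputed_length_aa: int
    error: str = ""

    @property
    def length_ok(self) -> bool:
        return not self.error and self.printed_length_aa == self.recomputed_length_aa


def classify_tables(
    toxins: Sequence[ToxinRow], antitoxins: Sequence[AntitoxinRow]
) -> tuple[list[ToxinCheckRow], list[ClassifyRow]]:
    """Recompute every length and complementarity string from coordinates
    alone and flag rows whose printed values disagree.

    The toxin mRNA is modelled CDS-relatively (no UTR extents are printed
    in the tables), so any antitoxin extent beyond the CDS on the toxin's
    3'/5' side classifies as the corresponding UTR.  Rows that cannot be
    matched or classified carry an error message; processing continues.
    """
    toxin_checks = [
        ToxinCheckRow(t.name, t.length_aa, t.interval.length // 3 - 1)
        for t in toxins
    ]
    by_order = {t.order_number: t for t in toxins}
    rows: list[ClassifyRow] = []
    for a in antitoxins:
        tox = by_order.get(a.order_number)
        if tox is None:
            rows.append(ClassifyRow(a.name, a.isoform, a.length_nt, -1,
                                    a.complementarity, "",
                                    error=f"no toxin row matches {a.name}"))
            continue
        mrna = TranscriptModel(
            strand=tox.interval.strand,
            tss=tox.interval.five_prime,
            end3=tox.interval.three_prime,
            cds=tox.interval,
        )
        try:
            classes = classify_overlap(a.interval, mrna)
        except ValueError as exc:
            rows.append(ClassifyRow(a.name, a.isoform, a.length_nt,
                                    a.interval.length, a.complementarity, "",
                                    error=str(exc)))
            continue
        rows.append(ClassifyRow(
            a.name, a.isoform, a.length_nt, a.interval.length,
            a.complementarity, format_classes(classes),
        ))
    return toxin_checks, rows


def write_gff3(path: str | Path, features: Iterable[tuple]) -> None:
    """Write (seqid, source, type, interval, score, attrs) tuples as GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for seqid, source, ftype, iv, score, attrs in features:
            strand = "+" if iv.strand == 1 else "-"
            attr_str = ";".join(f"{k}={v}" for k, v in attrs.items()) or "."
            fh.write(
                f"{seqid}\t{source}\t{ftype}\t{iv.low}\t{iv.high}\t{score}\t"
                f"{strand}\t.\t{attr_str}\n"
            )


def candidate_features(genome_id: str, candidates: Sequence[TaCandidate]) -> list[tuple]:
    """Combined feature list: toxin CDS + mRNA and antitoxin ncRNAs per locus."""
    feats: list[tuple] = []
    for cand in candidates:
        locus = cand.toxin_name
        feats.append((genome_id, "tascreen", "CDS", cand.toxin.interval, ".",
                      {"ID": f"{locus}_cds", "locus": locus,
                       "tm_regions": cand.tm.count if cand.tm else 0,
                       "operon_flag": cand.operon_status}))
        feats.append((genome_id, "tascreen", "mRNA", cand.toxin_mrna.interval, ".",
                      {"ID": f"{locus}_mrna", "locus": locus}))
        for iso in cand.isoforms:
            feats.append((genome_id, "tascreen", "ncRNA", iso.transcript.interval, ".",
                          {"ID": f"{cand.antitoxin_name}_{iso.isoform_index}",
                           "locus": locus,
                           "overlap": format_classes(iso.overlap_classes),
                           "promoter_confidence": iso.promoter_confidence,
                           "terminator_confidence": iso.terminator_confidence}))
    return feats
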