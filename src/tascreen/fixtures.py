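"""The bundled worked-example coordinate fixture.

Ten putative type I toxin loci and fifteen cognate antisense antitoxin
isoforms from the Microcystis aeruginosa PCC 7806SL chromosome
(CP020771.1), transcribed as coordinate tables.  Only coordinates, strands,
lengths and complementarity labels are bundled — no genome sequence is
required or shipped; every derived quantity (lengths, complementarity
classes) can be recomputed from the coordinates alone, which is what the
classification round-trip checks exercise.

Coordinates use the 5'-first convention of the source tables (Start > End
on the minus strand).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .seqio import GenomicInterval

__all__ = ["ToxinRow", "AntitoxinRow", "table_fixture", "fixture_paths"]


@dataclass(frozen=True)
class ToxinRow:
    name: str
    accession: str
    interval: GenomicInterval
    length_aa: int
    tm_regions: int

    @property
    def order_number(self) -> str:
        return self.name.rsplit("_", 1)[-1]


@dataclass(frozen=True)
class AntitoxinRow:
    name: str
    isoform: str  # "1", "2", ... or "-" for a single unnumbered isoform
    interval: GenomicInterval
    length_nt: int
    complementarity: str  # e.g. "CDS, 3′-UTR"

    @property
    def order_number(self) -> str:
        return self.name.rsplit("_", 1)[-1]


def fixture_paths() -> tuple:
    data = resources.files("tascreen") / "data"
    return (data / "table1_toxins.tsv", data / "table2_antitoxins.tsv")


def table_fixture() -> list[tuple[ToxinRow, list[AntitoxinRow]]]:
    """Fixture as (toxin, [its antitoxin isoforms]) pairs, in genome order."""
    t1_path, t2_path = fixture_paths()
    with resources.as_file(t1_path) as p:
        t1 = pd.read_csv(p, sep="\t")
    with resources.as_file(t2_path) as p:
        t2 = pd.read_csv(p, sep="\t")

    toxins = [
        ToxinRow(
            name=row["Name"],
            accession=row["GenBank Accession"],
            interval=GenomicInterval.from_start_end(int(row["Start"]), int(row["End"]),
                                                    int(row["Strand"])),
            length_aa=int(row["Length (aa)"]),
            tm_regions=int(row["TM Regions"]),
        )
        for _, row in t1.iterrows()
    ]
    antitoxins = [
        AntitoxinRow(
            name=row["Name"],
            isoform=str(row["Isoform"]),
            interval=GenomicInterval.from_start_end(int(row["Start"]), int(row["End"]),
                                                    int(row["Strand"])),
            length_nt=int(row["Length (nt)"]),
            complementarity=row["Toxin mRNA Complementarity"],
        )
        for _, row in t2.iterrows()
    ]
    out = []
    for tox in toxins:
        isoforms = [a for a in antitoxins if a.order_number == tox.order_number]
        out.append((tox, isoforms))
    return out
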