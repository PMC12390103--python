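# tascreen

A de novo screen for **type I toxin–antitoxin (TA) loci** in bacterial
genomes. Type I TA systems pair a small, usually membrane-damaging protein
toxin with a *cis*-encoded antisense RNA antitoxin that base-pairs with the
toxin mRNA and blocks its translation. Because historical screens search
for similarity to known loci, type I systems have mostly been reported
from a few phyla; `tascreen` instead looks only for the sequence-level
hallmarks of the architecture, so it can be pointed at genomes — such as
cyanobacterial chromosomes — where no type I system has been described.
It is aimed at microbiologists and bioinformaticians who want a
reproducible, fully self-contained (no web-tool) implementation of such a
screen, plus a simulator for benchmarking it.

## The screen

Three steps, mirroring how these loci are organised:

1. **Candidate toxins** — six-frame ORF scan (table 11; starts
   ATG/GTG/TTG), size filter 30–90 aa, and a transmembrane requirement:
   at least one maximal run of positions with 19-residue windowed
   Kyte–Doolittle hydropathy mean ≥ 1.6. Optional filters drop homologs
   of a user-supplied non-toxin protein set (Smith–Waterman, BLOSUM62,
   affine gaps) and ORFs within 100 bp of a same-strand annotated gene
   (likely operon members).
2. **Antisense antitoxin genes** — the opposite strand of each toxin
   ± 300 nt is scanned for σ70 promoters (−35 `TTGACA` / −10 `TATAAT`,
   spacer 15–19 nt; a PWM detector and a degenerate-consensus detector)
   and rho-independent terminators (stem-loop + U-tract; a
   stacking-energy detector and a strict-pattern detector). A locus needs
   a promoter upstream of a terminator in antisense orientation.
3. **Overlap and confidence** — each antisense TSS is paired with the
   nearest downstream terminator end; promoters sharing a terminator give
   antitoxin **isoforms**. Each isoform is classified by the toxin mRNA
   regions it is complementary to (`CDS`, `5′-UTR`, `3′-UTR`). Elements
   found by both detection methods are *high* confidence, by one method
   *low* — the two-tool rule.

See `docs/methods.md` for the model, parameter defaults and their
rationale, and known limitations.

## Worked example

Simulate a 20-kb genome with three planted loci, screen it, and check the
report:

```sh
tascreen simulate --out sim --seed 11 --n-loci 3 --genome-length 20000
tascreen scan sim/genome.fasta --out scan_out
```

which prints the per-stage audit:

```
genome=sim_seed11 stage=orf_scan in=0 kept=207 dropped=0
genome=sim_seed11 stage=tm_filter in=207 kept=14 dropped=193
genome=sim_seed11 stage=homology_filter in=14 kept=14 dropped=0
genome=sim_seed11 stage=operon_filter in=14 kept=14 dropped=0
genome=sim_seed11 stage=signal_gate in=14 kept=3 dropped=11
final loci: 3
```

207 small ORFs were found, 14 had a predicted membrane helix, and 3 — the
planted loci — had antisense promoter/terminator support. `scan_out/`
contains a toxin table, an antitoxin table and a combined GFF3:

```
Name      GenBank Accession  Start  End    Strand  Length (aa)  TM Regions
TOX_0063  -                  5321   5491   1       56           1
TOX_0108  -                  10009  9845   -1      54           1
TOX_0148  -                  14061  13864  -1      65           1

Name      Isoform  Start  End    Strand  Length (nt)  Toxin mRNA Complementarity
TIA_0063  -        5541   5461   -1      81           CDS, 3′-UTR
TIA_0108  -        9865   10049  1       185          CDS, 5′-UTR
TIA_0148  -        13774  13820  1       47           3′-UTR
```

Start/End are 5′-first (Start > End on the minus strand). Each antitoxin
lies on the strand opposite its toxin; the last column says which parts
of the toxin mRNA it can base-pair with — e.g. `TIA_0063` covers the 3′
end of the `TOX_0063` coding sequence and its 3′-UTR.

The package bundles a coordinate fixture of a published worked example:
ten putative type I toxins and their eighteen antitoxin isoforms from the
*Microcystis aeruginosa* PCC 7806SL chromosome. `classify` recomputes
every length and complementarity string from the printed coordinates
alone and flags disagreements:

```sh
tascreen classify src/tascreen/data/table1_toxins.tsv \
                  src/tascreen/data/table2_antitoxins.tsv
# -> length disagreements: 0; class disagreements: 0
```

Running the screen end-to-end on the actual PCC 7806SL genome
(CP020771.1, not bundled) is an optional demonstration: it requires
downloading the external sequence, and candidate sets will differ in
detail from published ones because the promoter/terminator detectors here
are self-contained surrogates, not the original web tools.

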