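# Methods

`tascreen` implements a de novo screen for chromosomal type I
toxin–antitoxin (TA) loci: two-gene modules in which a small, usually
membrane-targeting protein toxin is silenced by a cis-encoded antisense
RNA antitoxin that base-pairs with the toxin mRNA. The screen assumes only
sequence-level hallmarks — it uses no homology to known TA families — and
therefore suits genomes from phyla where no type I systems have been
described.

## The screen

The pipeline runs in three steps over a genome FASTA.

**Step A — candidate toxins.** All six reading frames are scanned for ORFs
running from a permitted start codon (ATG/GTG/TTG, translation table 11)
to the first in-frame stop. By default only the longest ORF per stop codon
is reported. Candidates must fall within 30–90 amino acids. The lower
bound is a package choice: only an upper bound is inherent to the screen
(known type I toxins are small, and the size cap is deliberately generous
at 90 aa to admit divergent toxins), while 30 aa suppresses spurious
micro-ORFs yet sits well below the smallest toxin the worked example
reports (39 aa). Each candidate protein must contain at least one
predicted transmembrane segment: a maximal run of positions whose
19-residue windowed mean Kyte–Doolittle hydropathy is ≥ 1.6, runs merged
when separated by fewer than 5 residues. This hydropathy rule is a
self-contained surrogate for HMM-based topology predictors; its contract
is "has a plausible membrane helix", not replication of any external
tool's segment counts, so per-protein counts of 1 vs 2 are a soft
diagnostic only. Two optional filters follow: local-alignment exclusion
against a user-supplied set of known non-toxin proteins (Smith–Waterman,
BLOSUM62, affine gaps costing 11 + k for a gap of length k; drop when
score ≥ 50 and identity over the aligned span ≥ 0.35 — conservative
defaults, deliberately configurable because no validated cutoffs exist
for this step), and an operon-proximity rule that demotes ORFs lying
within 100 bp of a same-strand annotated gene, since such ORFs are likely
co-transcribed operon members rather than independently regulated toxins.
Externally produced homology hits can be imported in the 12-column tabular
format instead of using the built-in aligner.

**Step B — antisense antitoxins.** For each retained toxin the opposite
strand of a window padding the ORF by 300 nt on both sides is scanned for
sigma-70 promoters and rho-independent terminators, each by two
independent detectors so that downstream confidence can follow a two-tool
rule. A promoter is a −35 box (consensus TTGACA) and a −10 box (consensus
TATAAT) separated by a 15–19 nt spacer; the TSS is placed 7 nt downstream
of the −10 box 3′ end (a typical sigma-70 spacing; configurable). The PWM
detector scores both boxes with log-odds matrices built from the consensus
(0.7 probability to the consensus base, 0.1 to each other) against the
scanned window's own base composition, minus 0.5 bits per nt of spacer
deviation from 17; default threshold 12 bits, i.e. within roughly two
mismatches of the perfect consensus (≈ 17.8 bits at uniform composition).
The consensus detector is a degenerate string match allowing one mismatch
per box. A terminator is a stem-loop followed by a U-tract. The energy
detector enumerates stems of 4–20 bp (G·U allowed) with loops of 3–10 nt,
scoring pair stacking (G·C = 3, A·T = 2, G·U = 1) minus a loop penalty
(1 per nt beyond 4) plus a U-tract bonus (1 per T of the 5′-anchored run,
one interruption allowed, in the 8 nt after the stem); hits need ≥ 3 such
T and a score ≥ 18, about six G·C pairs — marginal 5–6 bp mixed stems
score below this and are treated as noise. The pattern detector demands a
perfect Watson–Crick stem of ≥ 6 bp, loop 3–8, and ≥ 4 consecutive T
starting within 5 nt of the stem. Overlapping terminator calls are
reduced to local score maxima. All detectors operate on the window read
5′→3′ on the scanned strand with coordinates mapped back afterwards, which
makes the scan exactly strand-symmetric; windows containing N at a motif
position are skipped rather than imputed.

**Step C — isoforms, overlap, confidence.** Cross-method detections whose
positions (TSS, or terminator 3′ end) agree within 5 nt are grouped into
one element; an element seen by both methods is high confidence, by one
method low. Each antisense TSS is paired with the nearest terminator 3′
end downstream of it; promoters sharing a terminator yield antitoxin
isoforms, numbered by increasing length (the worked example numbers the
shortest isoform first). Transcripts shorter than 40 nt are discarded
(the shortest credible antitoxin in the worked example is 43 nt). The
terminator 3′ end — and hence the antitoxin 3′ end — is the last U-tract
position when present, else the stem 3′ end, matching how intrinsic
termination releases the transcript. The toxin mRNA is modelled from
same-strand signals in the same window: best-ranked promoter upstream of
the start codon and nearest terminator downstream of the stop, either side
falling back to the bare CDS. Each isoform is then classified by which
toxin mRNA regions it is complementary to: CDS, 5′-UTR, 3′-UTR. When a
UTR is modelled its extent is used; in fallback mode any antitoxin extent
beyond the CDS on the corresponding side counts as that UTR. This
CDS-relative fallback reproduces every complementarity label of the
worked-example tables from coordinates alone, which is why it is the
reporting default. Note that under the fallback rule the category set is
never empty for an interval inside the search window, so the effective
locus gate is the presence of an antisense promoter upstream of an
antisense terminator — consistent with the worked example, which accepts
one antitoxin that overlaps only the toxin's 3′-UTR, not its CDS. A locus
is high confidence when at least one isoform has both its promoter and its
terminator supported by both methods.

Names: toxins keep their ORF rank (`TOX_` + genome order number by
default); antitoxins get a configurable organism prefix (default `TIA_`)
plus the cognate toxin's order number, following the convention of naming
the antitoxin after its toxin.

## The synthetic genome generator

`tascreen.simulate` plants truth-annotated loci in an i.i.d. background of
configurable GC (default 0.5 — GC is a knob, not an organism constant).
Each locus contains a toxin ORF of 45–80 aa whose codons 3–26 encode a
24-residue stretch sampled from {L,I,V,F,A,M} (windowed KD mean ≈ 3.2,
comfortably above the 1.6 threshold) back-translated with uniform
synonymous codons, the rest sampled from hydrophilic residues; an in-frame
TAA is written immediately upstream of the start codon so the
longest-ORF-per-stop rule recovers exactly the planted interval. On the
opposite strand the generator writes a perfect (or deliberately
mismatched) two-box promoter with a 17 nt spacer and a stem-loop
terminator (8 bp G/C stem, 4 nt loop, 8 nt U-tract), positioned so the
implied antisense transcript overlaps the toxin CDS with one of the three
class patterns seen in real loci — {CDS, 3′-UTR}, {CDS, 5′-UTR},
{3′-UTR} — cycling per locus. Where a planted element must overwrite toxin
codons (hairpins reaching into the CDS 3′ end; the −10 box of the
5′-UTR-pattern promoter), the locus is re-drawn until the reading frame is
stop-free and the transmembrane stretch still scores. Loci are placed in
equal slots with jitter bounded so neighbouring search windows stay ≥ 700
nt apart; generation is deterministic under the seed.

What the generator does *not* emulate: real intergenic composition,
codon-usage bias, gene-dense neighbourhoods, sequencing artefacts, or
promoters/terminators of intermediate strength. Passing the recovery
checks therefore demonstrates that the pipeline's plumbing — coordinates,
strands, pairing, classification — is correct under the screen's own
assumptions, not that the surrogate detectors match any trained external
predictor on real genomes.

## Numerical and procedural choices

- Coordinates are 1-based inclusive `low/high` + strand internally;
  reports use the 5′-first Start/End convention (Start > End on the minus
  strand), and GFF3 output uses the standard low/high.
- Chromosome topology defaults to linear; circular extraction (intervals
  wrapping the origin) is supported but off by default.
- Degenerate bases: windows containing N are excluded from motif and
  hydropathy scoring; ORFs containing N are skipped.
- Tie-breaks: terminator local-maxima selection orders by score, then
  window position, then stem length; grouped elements take their position
  from the best hit of the preferred method (PWM for promoters, energy for
  terminators). All choices are deterministic, so identical inputs give
  byte-identical reports.
- Problem sizes in the shipped checks (100 random 2-kb genomes for the ORF
  oracle, 50 protein pairs for the alignment oracle, 10 seeds × 5 planted
  loci on 100-kb genomes plus 10 background genomes for recovery) were
  chosen to give stable estimates while keeping a full run in the order of
  minutes on one core.

## Known limitations

- The promoter/terminator detectors are documented surrogates with their
  own thresholds; they do not reproduce the numeric output of trained
  external predictors, and no score cutoffs for such tools are validated
  here. All thresholds are exposed in the configuration.
- The screen only finds cis-overlapping (type I) arrangements; antitoxins
  encoded in trans, without overlap, are out of scope by design.
- Transmembrane prediction has no topology model (inside/outside), no
  signal-peptide discrimination, and scores non-standard residues as
  neutral.
- The homology-exclusion step ships with an empty exclusion set; screening
  against comprehensive protein databases is left to external tools whose
  tabular output can be imported.
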