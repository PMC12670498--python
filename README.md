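# lassokit

Desk-side computation for the discovery and MS validation of bacterial **lasso
peptides** — ribosomally synthesized peptides whose C-terminal tail is threaded
through an N-terminal macrolactam ring, making them mechanically interlocked
rather than merely cyclic.

The package covers three stages that are usually done by hand or spread across
ad-hoc scripts:

1. **Mining** (`lassokit.mining`): scan metagenomic contigs for candidate
   precursor (A) genes that automated cluster detectors miss. Every ORF is
   screened for a leader/core split bearing the lasso motif set — a conserved
   Thr at position −2 relative to the core start, a ring-forming starter
   residue (canonically G/C/S/A, extended with N/Q for noncanonical rings),
   and an Asp/Glu acceptor at ring offset 7–10. Clusters are classified as
   Group I (classical proteobacterial A–B–C architecture) or Group II (split
   peptidase genes B1/B2) and checked for colinearity of the core genes.
2. **Refactoring** (`lassokit.refactor`): plan a heterologous expression
   insert from a prioritized cluster — keep the biosynthetic genes, always
   exclude isopeptidase genes (they cleave the macrolactam), re-orient to the
   plus strand, and replace intergenic regions lacking an apparent
   Shine–Dalgarno motif with an *E. coli* optimized RBS
   (`AGAGGAGAAATTAACC`). The insert is emitted as an annotated GenBank record
   with Gibson-style junction overlaps.
3. **Fragment model and annotation** (`lassokit.massmodel`,
   `lassokit.annotate`): exact monoisotopic mass accounting for the lasso
   topology and its diagnostic MS/MS ions, matched against centroided peak
   lists at ppm tolerance.

A synthetic-data module (`lassokit.synth`) generates contigs with planted
precursors and simulated MS1/MS2 peak lists with controlled noise, so the
whole pipeline is testable without any external data.

## The fragment-mass model

For a core sequence of length *N* with ring size *r* (ring = residues 1..*r*,
isopeptide bond between the α-amine of residue 1 and the side-chain carboxyl
of the Asp/Glu at *r*), with residue masses *m<sub>k</sub>*, water *w* =
18.0105646 Da and proton *p* = 1.00727646 Da:

- neutral peptide mass: M = Σ *m<sub>k</sub>* (ring closure condenses out one
  water, cancelling the terminal water of the linear form);
- tail b ions (ring intact, water deficit carried on the b side):
  neutral(b<sub>i</sub>) = Σ<sub>1..i</sub> − *w*, for *r* ≤ *i* ≤ *N*−1;
- tail y ions: neutral(y<sub>j</sub>) = Σ<sub>last j</sub> + *w*, so that
  b<sub>i</sub> and y<sub>N−i</sub> are exactly complementary:
  neutral(b<sub>i</sub>) + neutral(y<sub>N−i</sub>) = M;
- ring opening: cleaving the backbone amide between ring residues *k* and
  *k*+1 (the isopeptide bond is never opened) yields *r*−1 linearized
  rotations [*k*+1..*r*, 1..*k*], each producing secondary b ions from its
  prefixes;
- interlocked species [(b<sub>i</sub>)\*(y<sub>j</sub>)]: two cleavages inside
  the loop window release an internal stretch, but the b and y fragments stay
  non-covalently associated because the tail is sterically trapped inside the
  ring — neutral = M − Σ(eliminated residues). Their observation is strong
  evidence of a threaded conformation;
- internal (b<sub>x</sub> y<sub>j</sub>) fragments span residues *N*−*j*+1..*x*
  with neutral mass equal to the residue sum;
- m/z = (neutral + *z·p*)/*z* throughout.

## Worked example

```bash
$ lassokit simulate --seed 5 --out sim
wrote contig (6000 bp), truth, ms1/ms2 MGF to sim
planted core NVRLYHLIMDLRVKHKVMWF (ring 10, loop window (15, 19)), [M+2H]2+ m/z 1290.7140

$ lassokit mine --contigs sim/contig.fasta --gff sim/truth.gff3 --out mine_out
synthctg5: 78 ORFs, 127 candidate splits, group_I

$ lassokit refactor --contigs sim/contig.fasta --gff sim/truth.gff3 --out ref_out
synthctg5 (group_I): insert 1142 bp, parts ['synthctg5_A', 'RBS_1', 'synthctg5_B',
'RBS_2', 'synthctg5_C'], excluded 4

$ lassokit annotate --mgf sim/ms2.mgf --core NVRLYHLIMDLRVKHKVMWF \
    --ring-size 10 --loop-window 15 19 --out ann_out
b coverage 1.00, y coverage 0.90, interlocked 10 -> threaded_supported

$ lassokit eic --mgf sim/ms1.mgf --mz 1290.7140 --ppm 5
apex at rt 4.00 min, intensity 1e+06
```

What the numbers mean: the simulated contig hosts a planted precursor gene
whose top-scored leader/core split is reported by `mine` alongside 126 lower-
or equal-scored alternatives across all ORFs; `refactor` assembles the A, B
and C genes with two 16-bp RBS spacers (insert length = Σ gene lengths +
2×16); `annotate` recovers the full tail b series and 9/10 y ions (y1 falls
below the 200 m/z scan floor) plus ten interlocked species, so the topology
call is `threaded_supported`; the extracted ion chromatogram of the 2+
precursor peaks at the planted 4.0-minute elution apex.

The same operations are available as library calls; see the module docstrings
and `docs/methods.md` for the model details and parameter semantics.

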