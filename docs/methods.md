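# Methods

## Scope and model

`lassokit` implements the computation behind a lasso peptide discovery
campaign: precursor-gene mining on contigs, expression-construct refactoring,
and a macrolactam-aware fragment-mass model with spectrum annotation that can
support a threaded (lasso) topology call. It deliberately does **not** run
homology-based cluster detection (antiSMASH-style B/C/D gene calling),
taxonomic placement, or any wet-lab planning beyond junction overlaps; gene
roles other than the precursor are taken from input annotations.

## Mass model

All arithmetic is monoisotopic. Constants are fixed at proton
1.00727646 Da and water 18.0105646 Da; residue masses are the standard
monoisotopic values for the 20 canonical residues (Leu/Ile share a mass and
are never disambiguated). These precisions comfortably support the 4-decimal
m/z values typical of high-resolution instruments. No isotope envelopes,
neutral losses, a/c/x/z ions or intensity predictions are modelled: the
annotation task is identity matching, not spectrum prediction.

Mass conventions, with core length N and ring size r:

- **Lasso neutral mass** M = Σ residues. Ring closure loses one water, which
  exactly cancels the water of the linear peptide's termini.
- **Tail b/y ions.** The ring-closure water deficit is assigned to the
  N-terminal (b-side) moiety: neutral(b_i) = Σ(1..i) − water for r ≤ i ≤ N−1,
  y ions standard. This is the only assignment consistent with both standard
  y-ion masses and the complementarity identity b_i + y_{N−i} = M, which the
  test suite enforces to 1e−9 Da.
- **Ring-opened secondary b ions.** Opening backbone bond k/k+1 (1 ≤ k ≤ r−1;
  the isopeptide bond is chemically not a backbone amide and is never opened)
  yields rotation [k+1..r, 1..k]. Secondary b ions take the same −water
  offset by default, so the full-length rotation prefix reproduces the intact
  ring ion b_r. Because the literature does not fix this convention, a
  `water_offset ∈ {−water, 0}` switch is exposed; calibrate it against an
  observed ring-fragment ladder when real spectra are available. Duplicate
  m/z values across rotations are retained, each with its own label, and the
  annotator reports all co-matching labels.
- **Interlocked [(b_i)*(y_j)] complexes.** Both cleavage-site indices (i for
  the b cut, N−j for the y cut) must fall inside the user-supplied loop
  window, and i + j ≤ N − 1 so at least one residue is eliminated. The loop
  window is a parameter rather than a derived quantity because it depends on
  the steric-lock position, which only structure determination fixes. The
  enumeration is verified exhaustively against a brute-force double loop for
  all geometries with N ≤ 12.
- **Internal (b_x y_j) fragments** span residues N−j+1..x; the complementary
  internal fragment of an interlocked pair (i, j) is (x = N−j, j′ = N−i) and
  is included in the theoretical spectrum by default.

Default product charges {1, 2, 3} bracket the 2+/3+ precursor states typical
of ~2 kDa lasso peptides.

## Mining heuristic

The precursor scan enumerates every leader/core split p of every six-frame
ORF (stop-to-stop segments with an ATG/GTG/TTG start, bacterial code 11,
alternative starts translated as Met, stop codon included in the gene span).
A split qualifies when the protein is 25–90 aa, the leader ≥ 8 aa, the core
starter is in {G, C, S, A, N, Q}, a D/E acceptor exists at offset 7–10, and
≥ 3 tail residues remain. The score

score = 0.4·[Thr at −2] + 0.3·[starter ∈ {G,C,S,A}] + 0.2·[offset ∈ {7,8,9}]
+ 0.1·[leader length ∈ [10, 50]]

is an explicitly heuristic ranking: the weights order the motif evidence
(the Thr(−2) motif is the strongest single conserved feature; canonical
starters and ring sizes next; leader length is a weak prior) and every
weight, set and bound is config-exposed. The size bounds are judgement calls
scaled from known precursor genes, not literature constants. When several
acceptor offsets qualify, the smallest canonical one is reported.

Architecture classification is purely role-set based (Group I: A, B, C
without split B; Group II: A, B1, B2, C) and colinearity considers core
biosynthetic genes only, so an inversely oriented peptidase does not break
it.

## Refactor planner

Group I keeps A, B, C (plus D and/or tailoring genes on request); Group II
keeps A, B1, B2, C plus tailoring genes. Peptidase-role genes are always
excluded, because lasso isopeptidases cleave the macrolactam and would
degrade the product in the expression host. The cluster is re-oriented so the
core genes read on the plus strand (requiring colinearity), preserving gene
order. The native-RBS rule — an exact match of ≥ 4 consecutive bases of
AGGAGG ending 4–14 bp upstream of the downstream start codon — is a
config-exposed stand-in for manual inspection; no thermodynamic model is
implied. Failed junctions receive the 16-bp optimized RBS spacer
AGAGGAGAAATTAACC. `build_insert` emits the concatenated insert, a junction
table with `overlap_len` (default 20, valid 15–40) terminal bases per
adjacent part for Gibson-style assembly, and an annotated GenBank record
whose features round-trip to the plan. The expression vector is abstract
(name only, default pET28a).

## Annotation

Matching is nearest-peak-in-window at a ppm tolerance (default 5 ppm); one
peak may serve several isobaric labels, and no intensity weighting is used —
the scientific claim rests on identities, not scores. Evidence is pooled as
the union of matches across collision energies (default NCE set 15/25/35/45).
MS2 spectra whose selected precursor is further than half the isolation
window (default 2 Da) from any expected charge state are flagged but still
matched. The topology call is `threaded_supported` when at least
`min_interlocked` (default 1) interlocked species match and tail y-ion
coverage is ≥ `min_y_cov` (default 0.5); these thresholds are operating
points, not literature values, and are config-exposed.

## Synthetic data

The generator emulates the study-scale inputs: a 6-kb contig hosting a
reverse-translated precursor gene (fixed most-frequent E. coli codon table,
for determinism) amid dummy biosynthetic genes, decoy ORFs and random
intergenic DNA; and peak lists over a 200–2500 m/z scan range with Gaussian
m/z jitter (default σ = 2 ppm), log-normal intensity spread (CV 0.3),
uniform-m/z/exponential-intensity decoy peaks (0.02 peaks/Th — the simplest
null that exercises the matcher's false-positive bound), and a Gaussian
elution profile (apex 4.0 min, σ 0.2 min on an 8-min gradient). Each planted
gene is preceded by an in-frame stop codon so the six-frame scan recovers
exactly the planted protein.

Random (non-motif) residue positions are drawn from an alphabet excluding
{T, D, E} and the starter set, so a planted precursor is the unique
motif-bearing split of its ORF and recall/rank metrics are well defined
against the truth record. Consequences to keep in mind: synthetic proteins
are compositionally unrealistic, decoy peaks carry no isotope structure or
chemical noise correlations, and chromatography has no tailing or saturation
— so passing round-trip tests demonstrate the correctness of the enumeration
and matching logic, not detection performance on real extracts. The default
validation topology is a 20-residue core with a 10-residue Asn-initiated,
Asp-closed ring and loop window 15–19, mirroring the scale of a ~2.1 kDa
lasso peptide with a noncanonical starter; its ring interior is synthetic.

## Numerical and design choices

- 1-based residue indexing everywhere, matching b/y nomenclature; intervals
  inclusive.
- Theoretical spectra are sorted by m/z with (label, charge) tie-breaks, so
  outputs are byte-deterministic.
- Fragment tables round masses to 5 decimals on emission only; internal
  arithmetic is full double precision.
- The m/z–mass algebra is exactly invertible; tests enforce round trips to
  1e−9 Da for z ≤ 5.
- Codons containing IUPAC ambiguity letters translate to X and are never
  starts or stops; non-IUPAC characters are rejected with their position.
- MGF is the required peak-list format; mzML reading is available through
  the same reader contract.
- Contig length filtering is strictly greater-than (a "> 5 kb" filter keeps
  5001 bp, not 5000 bp).

## Problem sizes

The test suite and acceptance script use 1,000 random topologies for the
complementarity bound, all 705 loop-window geometries with N ≤ 12 for the
interlocked oracle, 100 simulation replicates for recovery rates, and 200
planted contigs for mining recall — sizes chosen so the full run completes
in well under a minute while estimating each rate to about a percent.

## Known limitations

- No homology or HMM detection of B/C/D genes; role annotations are inputs.
- The ring-opened b-ion water convention is a switch, not a resolved fact.
- The loop window (hence the interlocked catalogue) is user-specified.
- No intensity modelling: collision-energy dependence of fragment yields is
  outside the model, so NCE only labels spectra.
- Leu/Ile and other isobaric ambiguities are not resolved.
- The scoring weights for precursor candidates are heuristic; treat scores
  as a ranking, not probabilities.
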