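"""Synthetic fixtures: planted BGC contigs and simulated MS1/MS2 peak lists.

Every stage of the pipeline is testable without downloads: this module
generates (a) precursor proteins with the lasso motif set planted at known
coordinates, (b) contigs embedding a reverse-translated precursor (A) gene
amid dummy biosynthetic genes, decoy ORFs and random intergenic DNA, with a
ground-truth gene table, and (c) centroided MS1 runs and targeted MS2 scans
containing the theoretical fragment peaks of a lasso topology under
ppm-scale m/z jitter, log-normal intensity spread and uniform decoy peaks.

All generators are deterministic under a fixed seed.  Defaults mirror the
validation conditions of a ~2.1 kDa lasso peptide: ring of 10 residues with
an Asn starter and Asp acceptor, 10-residue tail, NCE set {15, 25, 35, 45},
scan range 200-2500 m/z, 8-minute gradient.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import massmodel
from .annotate import Spectrum
from .massmodel import FragmentConfig, LassoTopology
from .mining import Contig, Gene

__all__ = [
    "SynthConfig",
    "FILL_ALPHABET",
    "random_precursor",
    "synth_bgc_contig",
    "simulate_ms2",
    "simulate_ms1_run",
    "write_truth_gff",
    "write_contig_fasta",
]

#: Residues used for random (non-motif) positions.  The set deliberately
#: excludes Thr, Asp/Glu and the ring-starter residues so that a planted
#: precursor is the unique motif-bearing candidate in its ORF.
FILL_ALPHABET = "PVLIMFWYHKR"

#: Most-frequent E. coli codon per amino acid (fixed for determinism).
CODON_TABLE = {
    "A": "GCG", "R": "CGC", "N": "AAC", "D": "GAT", "C": "TGC",
    "Q": "CAG", "E": "GAA", "G": "GGC", "H": "CAT", "I": "ATT",
    "L": "CTG", "K": "AAA", "M": "ATG", "F": "TTT", "P": "CCG",
    "S": "AGC", "T": "ACC", "V": "GTG", "W": "TGG", "Y": "TAT",
}


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of all synthetic generators.

    Sequence layout: ``ring_size``/``tail_len``/``leader_len`` set the planted
    precursor geometry; ``starter`` and ``acceptor`` the ring chemistry;
    ``loop_window`` the interval where interlocking cleavages occur.  MS noise:
    ``mz_jitter_ppm`` (Gaussian sigma of the m/z error), ``intensity_cv``
    (log-normal coefficient of variation), ``decoy_peak_rate`` (uniform decoy
    peaks per Th over the scan range).  Chromatography: Gaussian elution at
    ``rt_apex`` +/- ``rt_sigma`` minutes over an ``rt_end``-minute gradient.
    """

    seed: int = 0
    # precursor / contig
    ring_size: int = 10
    tail_len: int = 10
    loop_window: tuple[int, int] = (15, 19)
    leader_len: int = 20
    starter: str = "N"
    acceptor: str = "D"
    contig_len: int = 6000
    n_decoy_orfs: int = 4
    group: str = "group_I"
    include_peptidase: bool = False
    # MS2
    nces: tuple[float, ...] = (15.0, 25.0, 35.0, 45.0)
    scan_range: tuple[float, float] = (200.0, 2500.0)
    mz_jitter_ppm: float = 2.0
    decoy_peak_rate: float = 0.02  # peaks per Th
    intensity_cv: float = 0.3
    base_intensity: float = 1.0e6
    precursor_z: int = 2
    charges: tuple[int, ...] = (1, 2, 3)
    # MS1 / chromatography
    rt_apex: float = 4.0
    rt_sigma: float = 0.2
    rt_end: float = 8.0
    scan_interval: float = 0.05

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _random_aa(rng: np.random.Generator, n: int, alphabet: str = FILL_ALPHABET) -> str:
    return "".join(rng.choice(list(alphabet), size=n))


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def reverse_translate(protein: str) -> str:
    """Fixed-codon reverse translation (stop codon appended)."""
    return "".join(CODON_TABLE[aa] for aa in protein) + "TAA"


def random_precursor(
    cfg: SynthConfig, rng: np.random.Generator | None = None
) -> tuple[str, LassoTopology, dict]:
    """A precursor protein with the full lasso motif set planted.

    Leader: Met start, conserved Thr at position -2 relative to the core
    start.  Core: configured starter residue, random ring interior, D/E
    acceptor at ``ring_size``, random tail.  The truth record carries every
    planted coordinate.
    """
    rng = cfg.rng() if rng is None else rng
    core_len = cfg.ring_size + cfg.tail_len
    if cfg.ring_size >= core_len or cfg.ring_size < 2:
        raise ValueError("ring_size must satisfy 2 <= ring_size < ring_size + tail_len")
    if cfg.leader_len < 4:
        raise ValueError("leader_len must be >= 4 to place the Met and Thr(-2) motif")
    leader = "M" + _random_aa(rng, cfg.leader_len - 3) + "T" + _random_aa(rng, 1)
    core = (
        cfg.starter
        + _random_aa(rng, cfg.ring_size - 2)
        + cfg.acceptor
        + _random_aa(rng, cfg.tail_len)
    )
    protein = leader + core
    top = LassoTopology(core=core, ring_size=cfg.ring_size, loop_window=cfg.loop_window)
    truth = {
        "protein": protein,
        "core_start": cfg.leader_len + 1,
        "leader": leader,
        "core": core,
        "ring_size": cfg.ring_size,
        "starter": cfg.starter,
        "acceptor_offset": cfg.ring_size,
        "thr_minus2_pos": cfg.leader_len - 1,
    }
    return protein, top, truth


def synth_bgc_contig(
    cfg: SynthConfig, rng: np.random.Generator | None = None
) -> tuple[Contig, list[Gene], dict]:
    """A contig embedding a planted lasso BGC plus decoy ORFs.

    The precursor (A) gene is reverse-translated from :func:`random_precursor`;
    dummy B/C (or B1/B2/C) and decoy genes carry random motif-free proteins.
    Each planted gene is preceded by an in-frame stop codon so the six-frame
    scan recovers exactly the planted protein.  Returns the contig, the
    ground-truth gene table (roles assigned) and a truth record.
    """
    rng = cfg.rng() if rng is None else rng
    protein, top, prec_truth = random_precursor(cfg, rng)
    if cfg.group == "group_I":
        layout = [("A", protein), ("B", None), ("C", None)]
    elif cfg.group == "group_II":
        layout = [("A", protein), ("B1", None), ("B2", None), ("C", None)]
    else:
        raise ValueError(f"unknown group {cfg.group!r}")
    if cfg.include_peptidase:
        layout.append(("peptidase", None))
    for k in range(cfg.n_decoy_orfs):
        layout.append((f"decoy{k}", None))

    segments: list[str] = [_random_dna(rng, 150)]
    genes: list[Gene] = []
    pos = len(segments[0])
    contig_id = f"synthctg{cfg.seed}"
    for role, prot in layout:
        if prot is None:
            n_aa = int(rng.integers(60, 120)) if role.startswith("decoy") else int(
                rng.integers(120, 180)
            )
            prot = "M" + _random_aa(rng, n_aa - 1)
        nt = reverse_translate(prot)
        strand = "-" if role == "peptidase" else "+"
        block = "TAA" + nt
        if strand == "-":
            from Bio.Seq import Seq

            block = str(Seq(block).reverse_complement())
            g_start, g_end = pos + 1, pos + len(nt)
        else:
            g_start, g_end = pos + 4, pos + 3 + len(nt)
        segments.append(block)
        pos += len(block)
        genes.append(
            Gene(
                id=f"{contig_id}_{role}",
                contig_id=contig_id,
                start=g_start,
                end=g_end,
                strand=strand,
                role="other" if role.startswith("decoy") else role,
                protein=prot,
                seq=nt,
            )
        )
        ig = _random_dna(rng, int(rng.integers(40, 80)))
        segments.append(ig)
        pos += len(ig)
    seq = "".join(segments)
    if len(seq) > cfg.contig_len:
        raise ValueError(
            f"contig_len {cfg.contig_len} too small for the planted parts ({len(seq)} bp)"
        )
    seq += _random_dna(rng, cfg.contig_len - len(seq))
    contig = Contig(id=contig_id, seq=seq)
    a_gene = genes[0]
    truth = {
        "contig_id": contig_id,
        "precursor": prec_truth,
        "a_gene": {"start": a_gene.start, "end": a_gene.end, "strand": a_gene.strand},
        "roles": sorted({g.role for g in genes if g.role != "other"}),
        "group": cfg.group,
    }
    return contig, genes, truth


def simulate_ms2(
    top: LassoTopology,
    cfg: SynthConfig,
    rng: np.random.Generator | None = None,
    include_labels: set[str] | None = None,
) -> list[Spectrum]:
    """Targeted MS2 scans (one per NCE) of a lasso topology.

    Peaks are the theoretical fragment ions inside the scan range (optionally
    restricted to ``include_labels``), with Gaussian m/z jitter of sigma
    ``mz_jitter_ppm``, log-normal intensity spread of CV ``intensity_cv``,
    plus Poisson-count uniform decoy peaks with exponential intensities.
    """
    rng = cfg.rng() if rng is None else rng
    ions = massmodel.theoretical_spectrum(
        top, FragmentConfig(charges=cfg.charges)
    )
    lo, hi = cfg.scan_range
    planted = [
        ion
        for ion in ions
        if lo <= ion.mz <= hi
        and (include_labels is None or ion.label in include_labels)
    ]
    sigma_ln = float(np.sqrt(np.log1p(cfg.intensity_cv**2)))
    prec_mz = massmodel.mz_from_mass(top.neutral_mass(), cfg.precursor_z)
    spectra = []
    for idx, nce in enumerate(cfg.nces):
        mzs = [
            ion.mz * (1.0 + rng.normal(0.0, cfg.mz_jitter_ppm * 1e-6))
            for ion in planted
        ]
        intens = [
            cfg.base_intensity * rng.lognormal(0.0, sigma_ln) for _ in planted
        ]
        n_decoy = rng.poisson(cfg.decoy_peak_rate * (hi - lo))
        mzs += list(rng.uniform(lo, hi, size=n_decoy))
        intens += list(rng.exponential(cfg.base_intensity * 0.01, size=n_decoy))
        spectra.append(
            Spectrum(
                scan_id=f"ms2_nce{nce:g}",
                ms_level=2,
                retention_time=cfg.rt_apex,
                mz=np.array(mzs, dtype=float),
                intensity=np.array(intens, dtype=float),
                nce=nce,
                precursor_mz=prec_mz,
                precursor_z=cfg.precursor_z,
            )
        )
    return spectra


def simulate_ms1_run(
    neutral: float,
    charges: tuple[int, ...],
    cfg: SynthConfig,
    rng: np.random.Generator | None = None,
    abundance: float = 1.0e6,
) -> list[Spectrum]:
    """An MS1 scan series with a Gaussian elution of the target ion.

    The target's charge states elute together with apex ``rt_apex`` and width
    ``rt_sigma`` (minutes); each scan additionally carries uniform decoy
    peaks.  Apex intensity scales linearly with ``abundance``.
    """
    if neutral <= 0:
        raise ValueError("neutral mass must be positive")
    rng = cfg.rng() if rng is None else rng
    lo, hi = cfg.scan_range
    times = np.arange(0.0, cfg.rt_end + 1e-9, cfg.scan_interval)
    targets = [massmodel.mz_from_mass(neutral, z) for z in charges]
    spectra = []
    for k, rt in enumerate(times):
        height = abundance * float(
            np.exp(-0.5 * ((rt - cfg.rt_apex) / cfg.rt_sigma) ** 2)
        )
        mzs, intens = [], []
        for mz in targets:
            if lo <= mz <= hi and height > 0:
                mzs.append(mz * (1.0 + rng.normal(0.0, cfg.mz_jitter_ppm * 1e-6)))
                intens.append(height)
        n_decoy = rng.poisson(cfg.decoy_peak_rate * (hi - lo))
        mzs += list(rng.uniform(lo, hi, size=n_decoy))
        intens += list(rng.exponential(abundance * 0.001, size=n_decoy))
        spectra.append(
            Spectrum(
                scan_id=f"ms1_{k}",
                ms_level=1,
                retention_time=float(rt),
                mz=np.array(mzs, dtype=float),
                intensity=np.array(intens, dtype=float),
            )
        )
    return spectra


def write_truth_gff(genes: list[Gene], path) -> None:
    """Write the ground-truth gene table as GFF3 with ``role=`` attributes."""
    lines = ["##gff-version 3"]
    for g in genes:
        lines.append(
            "\t".join(
                [
                    g.contig_id,
                    "lassokit_synth",
                    "CDS",
                    str(g.start),
                    str(g.end),
                    ".",
                    g.strand,
                    "0",
                    f"ID={g.id};role={g.role}",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_contig_fasta(contig: Contig, path) -> None:
    from Bio.Seq import Seq
    from Bio import SeqIO
    from Bio.SeqRecord import SeqRecord

    SeqIO.write([SeqRecord(Seq(contig.seq), id=contig.id, description="")], str(path), "fasta")
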