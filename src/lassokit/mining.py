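"""Lasso precursor (A-gene) mining and BGC prioritization from contigs.

Automated cluster detectors can miss lasso precursor genes whose core peptides
carry noncanonical ring-forming residues; this module re-implements the manual
rescue heuristic: scan every ORF of a contig for a leader/core split bearing
the lasso motif set — a Thr two residues upstream of the core start, a
ring-forming starter residue, and an Asp/Glu acceptor at a plausible ring
offset — then prioritize clusters by gene architecture (Group I: classical
proteobacterial A-B-C; Group II: split peptidase B1/B2) and colinearity of the
core biosynthetic genes.

Role assignment (B vs C vs peptidase) comes from input annotations, not from
homology search; the bespoke part is the precursor heuristic.
"""

from __future__ import annotations

import json
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field, asdict
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "Contig",
    "Gene",
    "PrecursorCandidate",
    "MiningConfig",
    "CORE_ROLES",
    "filter_contigs",
    "find_orfs",
    "score_precursor",
    "classify_architecture",
    "check_colinearity",
    "mine",
    "read_contigs_fasta",
    "read_roles_gff",
    "report_to_table",
]

_DNA_LETTERS = set("ACGTNRYSWKMBDHV")
_START_CODONS = ("ATG", "GTG", "TTG")
_STOP_CODONS = ("TAA", "TAG", "TGA")  # genetic code 11

#: Roles whose genes constitute the core biosynthetic machinery.
CORE_ROLES = frozenset({"A", "B", "B1", "B2", "C"})


@dataclass(frozen=True)
class Contig:
    id: str
    seq: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", self.seq.upper())
        for pos, base in enumerate(self.seq, start=1):
            if base not in _DNA_LETTERS:
                raise ValueError(
                    f"contig {self.id!r}: non-DNA character {base!r} at position {pos}"
                )

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class Gene:
    """A gene on a contig; 1-based inclusive coordinates on the forward strand."""

    id: str
    contig_id: str
    start: int
    end: int
    strand: str
    role: str = "other"
    protein: str = ""
    seq: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.id!r}: start > end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.id!r}: strand must be '+' or '-'")


@dataclass(frozen=True)
class PrecursorCandidate:
    """A scored leader/core split of a precursor protein."""

    protein: str
    core_start: int  # 1-based index into protein
    leader: str
    core: str
    ring_residue: str
    acceptor_offset: int  # 1-based core index of the ring-closing D/E
    has_thr_minus2: bool
    score: float


@dataclass(frozen=True)
class MiningConfig:
    """Heuristic knobs of the precursor scan.

    The starter set is the canonical {G, C, S, A} extended by {N, Q}
    (noncanonical Asn-initiated rings and their nearest neighbour); the
    acceptor offset range 7-10 covers the canonical 7-9 ring sizes widened to
    10.  Length bounds and score weights are heuristic and config-exposed.
    """

    min_contig_len: int = 5000
    min_orf_aa: int = 25
    starter_set: frozenset[str] = frozenset("GCSANQ")
    canonical_starters: frozenset[str] = frozenset("GCSA")
    acceptor_offsets: tuple[int, int] = (7, 10)
    preferred_offsets: frozenset[int] = frozenset({7, 8, 9})
    precursor_len: tuple[int, int] = (25, 90)
    min_leader: int = 8
    min_tail: int = 3
    leader_bonus_range: tuple[int, int] = (10, 50)
    w_thr: float = 0.4
    w_starter: float = 0.3
    w_offset: float = 0.2
    w_leader: float = 0.1


def filter_contigs(contigs: Iterable[Contig], min_len: int) -> list[Contig]:
    """Keep contigs strictly longer than ``min_len`` bp, order preserved."""
    if min_len < 0:
        raise ValueError("min_len must be >= 0")
    return [c for c in contigs if c.length > min_len]


def _translate(nt: str) -> str:
    """Translate an ORF body (start codon included, stop excluded), table 11.

    Alternative starts (GTG/TTG) translate to Met, the bacterial convention;
    codons containing ambiguity codes yield 'X' rather than failing.
    """
    aas = []
    for k in range(0, len(nt) - 2, 3):
        codon = nt[k : k + 3]
        if set(codon) <= set("ACGT"):
            aas.append(str(Seq(codon).translate(table=11)))
        else:
            aas.append("X")
    if aas:
        aas[0] = "M"
    return "".join(aas)


def find_orfs(contig: Contig, min_aa: int = 25, table: int = 11) -> list[Gene]:
    """Six-frame stop-to-stop ORF scan with ATG/GTG/TTG starts.

    Within each stop-to-stop segment the first start codon opens the ORF.  The
    stop codon is included in the gene span; the translated protein excludes
    it.  Coordinates are 1-based inclusive on the forward strand.  Codons
    containing ambiguity codes are neither starts nor stops and translate to X.
    """
    if min_aa < 10:
        raise ValueError("min_aa must be >= 10")
    if table != 11:
        raise ValueError("only the bacterial genetic code (table 11) is supported")
    genes: list[Gene] = []
    length = contig.length
    for strand, oriented in (
        ("+", contig.seq),
        ("-", str(Seq(contig.seq).reverse_complement())),
    ):
        for frame in range(3):
            start_idx: int | None = None
            for k in range(frame, length - 2, 3):
                codon = oriented[k : k + 3]
                if not set(codon) <= set("ACGT"):
                    continue  # ambiguity: neither start nor stop
                if codon in _STOP_CODONS:
                    if start_idx is not None:
                        n_aa = (k - start_idx) // 3
                        if n_aa >= min_aa:
                            body = oriented[start_idx : k + 3]
                            if strand == "+":
                                fwd_start, fwd_end = start_idx + 1, k + 3
                            else:
                                fwd_start, fwd_end = length - (k + 3) + 1, length - start_idx
                            genes.append(
                                Gene(
                                    id=f"{contig.id}_orf{fwd_start}_{strand}",
                                    contig_id=contig.id,
                                    start=fwd_start,
                                    end=fwd_end,
                                    strand=strand,
                                    role="other",
                                    protein=_translate(body[:-3]),
                                    seq=body,
                                )
                            )
                    start_idx = None
                elif start_idx is None and codon in _START_CODONS:
                    start_idx = k
    genes.sort(key=lambda g: (g.start, g.end, g.strand))
    return genes


def score_precursor(
    protein: str, config: MiningConfig | None = None
) -> list[PrecursorCandidate]:
    """Enumerate and score candidate leader/core splits of a protein.

    A split at 1-based position p qualifies when (a) the protein length is
    within the precursor size window, (b) the leader is long enough, (c) the
    core starts with a ring-forming residue, (d) some offset d in the acceptor
    range places a D/E acceptor, and (e) at least ``min_tail`` residues remain
    beyond the acceptor.  The score is a weighted sum of the Thr(-2) motif,
    canonical starter, canonical ring size, and leader-length indicators,
    sorted descending (ties by core_start).
    """
    cfg = config or MiningConfig()
    if len(protein) < 15:
        raise ValueError("protein too short to host a precursor split (< 15 aa)")
    lo_len, hi_len = cfg.precursor_len
    if not lo_len <= len(protein) <= hi_len:
        return []
    d_lo, d_hi = cfg.acceptor_offsets
    candidates = []
    for p in range(cfg.min_leader + 1, len(protein) + 1):
        core = protein[p - 1 :]
        if core[:1] not in cfg.starter_set:
            continue
        offsets = [
            d
            for d in range(d_lo, d_hi + 1)
            if d <= len(core)
            and core[d - 1] in ("D", "E")
            and len(core) - d >= cfg.min_tail
        ]
        if not offsets:
            continue
        preferred = [d for d in offsets if d in cfg.preferred_offsets]
        d = min(preferred) if preferred else min(offsets)
        leader = protein[: p - 1]
        has_thr = p >= 3 and protein[p - 3] == "T"
        lb_lo, lb_hi = cfg.leader_bonus_range
        score = (
            cfg.w_thr * has_thr
            + cfg.w_starter * (core[0] in cfg.canonical_starters)
            + cfg.w_offset * (d in cfg.preferred_offsets)
            + cfg.w_leader * (lb_lo <= len(leader) <= lb_hi)
        )
        candidates.append(
            PrecursorCandidate(
                protein=protein,
                core_start=p,
                leader=leader,
                core=core,
                ring_residue=core[0],
                acceptor_offset=d,
                has_thr_minus2=has_thr,
                score=round(score, 10),
            )
        )
    candidates.sort(key=lambda c: (-c.score, c.core_start))
    return candidates


def classify_architecture(genes: Sequence[Gene]) -> str:
    """Group I (classical A-B-C), Group II (split B1/B2), or unclassified."""
    roles = {g.role for g in genes}
    if {"A", "B", "C"} <= roles and not roles & {"B1", "B2"}:
        return "group_I"
    if {"A", "B1", "B2", "C"} <= roles:
        return "group_II"
    return "unclassified"


def check_colinearity(genes: Sequence[Gene]) -> bool:
    """True iff all core biosynthetic genes share one strand.

    Accessory genes (peptidase, D/transporter, tailoring) are ignored; an
    inversely oriented peptidase does not break colinearity.
    """
    core = [g for g in genes if g.role in CORE_ROLES]
    if len(core) < 2:
        raise ValueError("colinearity needs at least 2 core genes (roles A/B/B1/B2/C)")
    return len({g.strand for g in core}) == 1


def mine(
    contigs: Iterable[Contig],
    annotations: Mapping[str, Sequence[Gene]] | None = None,
    config: MiningConfig | None = None,
) -> dict:
    """End-to-end mining report over a set of contigs.

    Filters contigs by length, scans ORFs, scores precursor candidates, and —
    when role annotations are supplied — classifies the architecture and
    checks colinearity per contig.  The report is a deterministic, JSON-ready
    dict.
    """
    cfg = config or MiningConfig()
    annotations = annotations or {}
    rows = []
    for contig in filter_contigs(contigs, cfg.min_contig_len):
        orfs = find_orfs(contig, min_aa=cfg.min_orf_aa)
        cand_rows = []
        for orf in orfs:
            if len(orf.protein) < 15:
                continue
            for cand in score_precursor(orf.protein, cfg):
                cand_rows.append(
                    {
                        "orf_id": orf.id,
                        "orf_start": orf.start,
                        "orf_end": orf.end,
                        "strand": orf.strand,
                        **{
                            k: v
                            for k, v in asdict(cand).items()
                            if k not in ("protein",)
                        },
                    }
                )
        cand_rows.sort(key=lambda rec: (-rec["score"], rec["orf_start"], rec["core_start"]))
        ann = list(annotations.get(contig.id, []))
        architecture = classify_architecture(ann) if ann else "unclassified"
        colinear = None
        if sum(g.role in CORE_ROLES for g in ann) >= 2:
            colinear = check_colinearity(ann)
        rows.append(
            {
                "contig_id": contig.id,
                "length": contig.length,
                "n_orfs": len(orfs),
                "architecture": architecture,
                "colinear": colinear,
                "candidates": cand_rows,
            }
        )
    return {"contigs": rows}


def report_to_table(report: dict):
    """Flatten a mining report into a candidate DataFrame (one row per split)."""
    import pandas as pd

    flat = []
    for contig in report["contigs"]:
        for cand in contig["candidates"]:
            flat.append(
                {"contig_id": contig["contig_id"], "architecture": contig["architecture"], **cand}
            )
    columns = [
        "contig_id", "architecture", "orf_id", "orf_start", "orf_end", "strand",
        "core_start", "leader", "core", "ring_residue", "acceptor_offset",
        "has_thr_minus2", "score",
    ]
    return pd.DataFrame(flat, columns=columns)


def read_contigs_fasta(path) -> list[Contig]:
    """Read contigs from a FASTA file."""
    return [Contig(id=rec.id, seq=str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def read_roles_gff(path, contigs: Mapping[str, Contig] | None = None) -> dict[str, list[Gene]]:
    """Read gene coordinates and roles from a GFF3 file (attribute ``role=``).

    When the matching contigs are given, gene nucleotide and protein sequences
    are extracted as well.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    out: dict[str, list[Gene]] = {}
    for feat in db.all_features():
        role = feat.attributes.get("role", ["other"])[0]
        gene = Gene(
            id=feat.id,
            contig_id=feat.seqid,
            start=feat.start,
            end=feat.end,
            strand=feat.strand if feat.strand in ("+", "-") else "+",
            role=role,
        )
        if contigs and feat.seqid in contigs:
            nt = contigs[feat.seqid].seq[gene.start - 1 : gene.end]
            if gene.strand == "-":
                nt = str(Seq(nt).reverse_complement())
            gene.seq = nt
            gene.protein = _translate(nt[:-3]) if len(nt) >= 6 else ""
        out.setdefault(feat.seqid, []).append(gene)
    for genes in out.values():
        genes.sort(key=lambda g: (g.start, g.end))
    return out


def write_report(report: dict, out_dir) -> None:
    """Write the mining report as JSON and TSV into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "mining_report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    report_to_table(report).to_csv(out / "mining_candidates.tsv", sep="\t", index=False)
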