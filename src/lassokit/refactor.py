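"""Planning of refactored expression inserts from a prioritized lasso BGC.

A prioritized cluster is turned into a heterologous-expression insert by
keeping the biosynthetic genes (Group I: A, B, C, optionally the D transporter
and tailoring genes; Group II: A, B1, B2, C plus tailoring genes), always
excluding isopeptidase/peptidase genes (they can cleave the macrolactam ring
and degrade the product), re-orienting everything to the plus strand, and
replacing intergenic regions that lack an apparent native ribosome binding
site with an E. coli optimized RBS spacer.  The insert is emitted with
junction overlaps for Gibson-style assembly into an expression vector; the
vector itself is handled abstractly (name only).
"""

from __future__ import annotations

import warnings
from collections.abc import Sequence
from dataclasses import dataclass, field

from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .mining import CORE_ROLES, Gene

__all__ = [
    "DEFAULT_RBS",
    "RefactorOptions",
    "Part",
    "ConstructPlan",
    "InsertBuild",
    "needs_rbs",
    "plan_refactor",
    "build_insert",
    "plan_from_record",
]

#: E. coli optimized ribosome binding site used as intergenic spacer.
DEFAULT_RBS = "AGAGGAGAAATTAACC"

PEPTIDASE_EXCLUSION_REASON = "isopeptidase can cleave the macrolactam ring"


@dataclass(frozen=True)
class RefactorOptions:
    """Options of the construct planner.

    The Shine-Dalgarno detection rule (>=4-base exact match to AGGAGG with its
    3' end 4-14 bp upstream of the downstream start codon) is a heuristic
    stand-in for manual inspection and is fully config-exposed.
    """

    rbs_seq: str = DEFAULT_RBS
    include_transporter: bool = False  # group I: keep the D gene
    include_tailoring: bool = False    # group I: keep tailoring genes
    sd_core: str = "AGGAGG"
    sd_min_match: int = 4
    sd_spacing: tuple[int, int] = (4, 14)
    vector_name: str = "pET28a"


@dataclass(frozen=True)
class Part:
    kind: str  # "gene" | "rbs_spacer"
    name: str
    seq: str
    role: str | None = None


@dataclass
class ConstructPlan:
    parts: list[Part]
    excluded: list[tuple[str, str]]  # (gene id, reason)
    vector_name: str = "pET28a"
    insert_seq: str = ""


@dataclass
class InsertBuild:
    insert_seq: str
    junctions: "object"  # pandas.DataFrame
    record: SeqRecord
    warnings: list[str]


def needs_rbs(
    intergenic: str,
    sd_core: str = "AGGAGG",
    min_match: int = 4,
    spacing: tuple[int, int] = (4, 14),
) -> bool:
    """False iff a Shine-Dalgarno-like motif sits at spacing from the start.

    ``intergenic`` is the region immediately upstream of a start codon, read
    in the gene's direction.  A native RBS is called when an exact match of
    >= ``min_match`` consecutive bases of ``sd_core`` ends 4-14 bp upstream of
    the downstream start (i.e. of the end of ``intergenic``).
    """
    intergenic = intergenic.upper()
    lo, hi = spacing
    motifs = {
        sd_core[a : a + w]
        for w in range(min_match, len(sd_core) + 1)
        for a in range(len(sd_core) - w + 1)
    }
    for motif in motifs:
        pos = intergenic.find(motif)
        while pos != -1:
            gap = len(intergenic) - (pos + len(motif))
            if lo <= gap <= hi:
                return False
            pos = intergenic.find(motif, pos + 1)
    return True


_GROUP_KEEP = {
    "group_I": {"A", "B", "C"},
    "group_II": {"A", "B1", "B2", "C"},
}


def _normalize_orientation(genes: Sequence[Gene], contig_seq: str):
    """Re-orient the cluster so its core genes read on the plus strand."""
    core_strands = {g.strand for g in genes if g.role in CORE_ROLES}
    if len(core_strands) != 1:
        raise ValueError("core genes are not colinear; cannot plan a refactor")
    if core_strands == {"+"}:
        return list(genes), contig_seq
    length = len(contig_seq)
    flipped_seq = str(Seq(contig_seq).reverse_complement())
    flipped = []
    for g in genes:
        flipped.append(
            Gene(
                id=g.id,
                contig_id=g.contig_id,
                start=length - g.end + 1,
                end=length - g.start + 1,
                strand="+" if g.strand == "-" else "-",
                role=g.role,
                protein=g.protein,
            )
        )
    return flipped, flipped_seq


def plan_refactor(
    genes: Sequence[Gene],
    contig_seq: str,
    group: str,
    options: RefactorOptions | None = None,
) -> ConstructPlan:
    """Plan a refactored insert for a classified BGC.

    Keeps the group's biosynthetic genes in original cluster order, re-oriented
    to the plus strand; always excludes peptidase-role genes; inserts the RBS
    spacer before every internal gene whose native upstream intergenic region
    shows no apparent Shine-Dalgarno motif.
    """
    opts = options or RefactorOptions()
    if group not in _GROUP_KEEP:
        raise ValueError(f"group must be one of {sorted(_GROUP_KEEP)}, got {group!r}")
    keep_roles = set(_GROUP_KEEP[group])
    if group == "group_I":
        if opts.include_transporter:
            keep_roles.add("D")
        if opts.include_tailoring:
            keep_roles.add("tailoring")
    else:
        keep_roles.add("tailoring")

    oriented, seq = _normalize_orientation(genes, contig_seq)
    oriented = sorted(oriented, key=lambda g: g.start)
    present = {g.role for g in oriented}
    for role in _GROUP_KEEP[group]:
        if role not in present:
            raise ValueError(f"cannot refactor: required gene role {role!r} is missing")

    kept, excluded = [], []
    for g in oriented:
        if g.role == "peptidase":
            excluded.append((g.id, PEPTIDASE_EXCLUSION_REASON))
        elif g.role in keep_roles:
            kept.append(g)
        else:
            excluded.append((g.id, f"role {g.role!r} not included in the construct"))

    parts: list[Part] = []
    for idx, g in enumerate(kept):
        if idx > 0:
            intergenic = seq[kept[idx - 1].end : g.start - 1]
            if needs_rbs(intergenic, opts.sd_core, opts.sd_min_match, opts.sd_spacing):
                parts.append(Part(kind="rbs_spacer", name=f"RBS_{idx}", seq=opts.rbs_seq))
        gene_seq = seq[g.start - 1 : g.end]
        parts.append(Part(kind="gene", name=g.id, seq=gene_seq, role=g.role))
    return ConstructPlan(parts=parts, excluded=excluded, vector_name=opts.vector_name)


def build_insert(plan: ConstructPlan, overlap_len: int = 20) -> InsertBuild:
    """Assemble the insert sequence, junction report and annotated record.

    The junction report lists, per adjacent part pair, the terminal
    ``overlap_len`` bases on each side (the Gibson-style overlap handles).
    A gene part containing an internal stop codon in its own frame raises a
    warning, not a failure.
    """
    import pandas as pd

    if not 15 <= overlap_len <= 40:
        raise ValueError("overlap_len must be within [15, 40] bp")
    warns: list[str] = []
    seqs = [p.seq for p in plan.parts]
    insert = "".join(seqs)
    plan.insert_seq = insert

    rows = []
    for left, right in zip(plan.parts, plan.parts[1:]):
        rows.append(
            {
                "left_part": left.name,
                "right_part": right.name,
                "left_overlap": left.seq[-overlap_len:],
                "right_overlap": right.seq[:overlap_len],
            }
        )
    junctions = pd.DataFrame(rows, columns=["left_part", "right_part", "left_overlap", "right_overlap"])

    record = SeqRecord(
        Seq(insert),
        id=f"{plan.vector_name}_ins"[:16],
        name="refactored_bgc"[:16],
        description=f"refactored lasso BGC insert for {plan.vector_name}",
        annotations={"molecule_type": "DNA", "topology": "linear"},
    )
    offset = 0
    for p in plan.parts:
        loc = FeatureLocation(offset, offset + len(p.seq), strand=1)
        ftype = "CDS" if p.kind == "gene" else "regulatory"
        quals = {"label": [p.name], "part_kind": [p.kind]}
        if p.role:
            quals["role"] = [p.role]
        record.features.append(SeqFeature(loc, type=ftype, qualifiers=quals))
        if p.kind == "gene":
            aa = str(Seq(p.seq[: len(p.seq) // 3 * 3]).translate(table=11))
            if "*" in aa[:-1]:
                msg = f"gene part {p.name!r} contains an internal stop codon in frame"
                warns.append(msg)
                warnings.warn(msg, stacklevel=2)
        offset += len(p.seq)
    return InsertBuild(insert_seq=insert, junctions=junctions, record=record, warnings=warns)


def plan_from_record(record: SeqRecord) -> list[tuple[str, str, int, int]]:
    """Recover (kind, name, start, end) part tuples from an annotated record.

    Used to round-trip the emitted GenBank insert back into the plan's part
    order and coordinates.
    """
    parts = []
    for feat in record.features:
        kind = feat.qualifiers.get("part_kind", ["gene"])[0]
        name = feat.qualifiers.get("label", ["?"])[0]
        parts.append((kind, name, int(feat.location.start), int(feat.location.end)))
    parts.sort(key=lambda t: t[2])
    return parts
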