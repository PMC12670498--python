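"""Monoisotopic mass accounting and theoretical fragmentation of lasso peptides.

A lasso peptide is a ribosomally synthesized peptide whose N-terminal
macrolactam ring (formed by condensation of the residue-1 alpha-amine with the
side-chain carboxyl of an Asp/Glu at ring position ``r``, losing one water) has
the C-terminal tail threaded through it.  This module provides exact
monoisotopic mass arithmetic for such topologies and enumerates the theoretical
fragment ions that diagnose them under collisional dissociation:

* conventional b/y ions of the linear tail (the ring stays intact, so the b
  series starts at ``b_r``),
* secondary b ions of the ``r - 1`` linearized forms produced by random
  ring-opening cleavages of the macrolactam,
* mechanically "interlocked" [(b_i)*(y_j)] complexes, in which a b and a y
  fragment stay non-covalently associated because the tail is sterically
  trapped inside the ring — strong evidence of a threaded conformation,
* the internal fragments complementary to those complexes.

All masses are monoisotopic; only the monoisotopic peak per ion is produced
(no isotope envelopes, no neutral-loss satellites).
"""

from __future__ import annotations

import enum
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from types import MappingProxyType

__all__ = [
    "PROTON_MASS",
    "WATER_MASS",
    "RESIDUE_MASSES",
    "MassConstants",
    "LassoTopology",
    "IonKind",
    "FragmentIon",
    "FragmentConfig",
    "residue_mass_sum",
    "neutral_mass",
    "mass_from_mz",
    "mz_from_mass",
    "tail_by_ions",
    "enumerate_ring_openings",
    "ring_opened_b_ions",
    "enumerate_interlocked",
    "complementary_internal_pair",
    "internal_by_fragments",
    "theoretical_spectrum",
    "fragments_to_table",
    "write_fragment_table",
]

#: Monoisotopic mass of a proton, Da.
PROTON_MASS = 1.00727646
#: Monoisotopic mass of water, Da (lost on macrolactam closure).
WATER_MASS = 18.0105646

#: Monoisotopic residue (amino-acid minus water) masses, Da, for the 20
#: canonical residues.  Leu/Ile are distinct letters with identical mass; no
#: disambiguation is attempted anywhere in the package.
RESIDUE_MASSES: Mapping[str, float] = MappingProxyType(
    {
        "G": 57.02146372,
        "A": 71.03711379,
        "S": 87.03202841,
        "P": 97.05276385,
        "V": 99.06841392,
        "T": 101.04767847,
        "C": 103.00918448,
        "L": 113.08406398,
        "I": 113.08406398,
        "N": 114.04292744,
        "D": 115.02694302,
        "Q": 128.05857751,
        "K": 128.09496302,
        "E": 129.04259309,
        "M": 131.04048509,
        "H": 137.05891186,
        "F": 147.06841391,
        "R": 156.10111102,
        "Y": 163.06332853,
        "W": 186.07931295,
    }
)


@dataclass(frozen=True)
class MassConstants:
    """Immutable bundle of the mass constants used throughout the model."""

    proton_mass: float = PROTON_MASS
    water_mass: float = WATER_MASS
    residue_masses: Mapping[str, float] = field(default_factory=lambda: RESIDUE_MASSES)

    def __post_init__(self) -> None:
        if set(self.residue_masses) != set(RESIDUE_MASSES):
            raise ValueError("residue_masses must cover exactly the 20 canonical residues")
        if any(m <= 0 for m in self.residue_masses.values()):
            raise ValueError("residue masses must be positive")


def residue_mass_sum(seq: str) -> float:
    """Sum of monoisotopic residue masses of ``seq`` (no termini), Da."""
    if not seq:
        raise ValueError("sequence must be non-empty")
    total = 0.0
    for pos, aa in enumerate(seq, start=1):
        try:
            total += RESIDUE_MASSES[aa]
        except KeyError:
            raise ValueError(
                f"unknown amino-acid letter {aa!r} at position {pos}"
            ) from None
    return total


def neutral_mass(seq: str, form: str = "linear") -> float:
    """Neutral monoisotopic mass of a peptide, Da.

    ``form="linear"`` adds one water for the free termini; ``form="lasso"``
    omits it, because macrolactam ring closure condenses out exactly one water,
    so M(lasso) is simply the residue-mass sum.
    """
    if form not in ("linear", "lasso"):
        raise ValueError(f"form must be 'linear' or 'lasso', got {form!r}")
    if form == "lasso" and len(seq) < 2:
        raise ValueError("a lasso (macrolactam) requires at least 2 residues")
    total = residue_mass_sum(seq)
    return total + WATER_MASS if form == "linear" else total


def mass_from_mz(mz: float, z: int) -> float:
    """Neutral mass from an [M+zH]z+ m/z value."""
    if z < 1:
        raise ValueError(f"charge must be a positive integer, got {z}")
    if mz <= 0:
        raise ValueError("m/z must be positive")
    return z * mz - z * PROTON_MASS


def mz_from_mass(neutral: float, z: int) -> float:
    """m/z of the [M+zH]z+ ion of a neutral mass."""
    if z < 1:
        raise ValueError(f"charge must be a positive integer, got {z}")
    if neutral <= 0:
        raise ValueError("neutral mass must be positive")
    return (neutral + z * PROTON_MASS) / z


@dataclass(frozen=True)
class LassoTopology:
    """Core sequence plus its ring/loop/tail partition.

    Residue indexing is 1-based throughout, matching b/y ion nomenclature.
    The ring comprises residues ``1..ring_size``; the isopeptide bond joins
    the alpha-amine of residue 1 to the side-chain carboxyl of the Asp/Glu at
    ``ring_size`` (the acceptor).  ``loop_window`` is the inclusive 1-based
    residue interval within the tail where interlocking cleavages may occur;
    it depends on the (structure-determined) steric lock position and must be
    supplied by the user when interlocked species are wanted.
    """

    core: str
    ring_size: int
    loop_window: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        residue_mass_sum(self.core)  # validates letters
        n = len(self.core)
        if not 2 <= self.ring_size < n:
            raise ValueError(
                f"ring_size must satisfy 2 <= r < N; got r={self.ring_size}, N={n}"
            )
        if self.core[self.ring_size - 1] not in ("D", "E"):
            raise ValueError(
                "acceptor residue (core position ring_size) must be D or E, "
                f"got {self.core[self.ring_size - 1]!r}"
            )
        if self.loop_window is not None:
            lo, hi = self.loop_window
            if not (self.ring_size < lo <= hi <= n):
                raise ValueError(
                    f"loop_window {self.loop_window} must lie within "
                    f"({self.ring_size}, {n}]"
                )

    @property
    def n(self) -> int:
        return len(self.core)

    @property
    def acceptor_pos(self) -> int:
        return self.ring_size

    @property
    def ring_seq(self) -> str:
        return self.core[: self.ring_size]

    @property
    def tail_seq(self) -> str:
        return self.core[self.ring_size :]

    def neutral_mass(self) -> float:
        """Neutral monoisotopic mass of the mature (ring-closed) peptide."""
        return neutral_mass(self.core, form="lasso")


class IonKind(str, enum.Enum):
    PRECURSOR = "precursor"
    B_TAIL = "b_tail"
    Y_TAIL = "y_tail"
    B_RING_OPENED = "b_ring_opened"
    INTERNAL_BY = "internal_by"
    INTERLOCKED = "interlocked"


@dataclass(frozen=True)
class FragmentIon:
    """One theoretical ion with its neutral mass and [M+zH]z+ m/z."""

    kind: IonKind
    label: str
    z: int
    neutral_mass: float
    mz: float
    i: int | None = None
    j: int | None = None
    opening_site: int | None = None
    rotation_pos: int | None = None


def _make_ion(kind: IonKind, label: str, neutral: float, z: int, **idx: int | None) -> FragmentIon:
    return FragmentIon(
        kind=kind, label=label, z=z, neutral_mass=neutral,
        mz=mz_from_mass(neutral, z), **idx,
    )


def _check_charges(charges: Iterable[int]) -> list[int]:
    zs = sorted(set(charges))
    if not zs:
        raise ValueError("charge set must be non-empty")
    if any(z < 1 for z in zs):
        raise ValueError(f"charges must be positive integers, got {zs}")
    return zs


def tail_by_ions(top: LassoTopology, charges: Iterable[int] = (1, 2, 3)) -> list[FragmentIon]:
    """Conventional b/y ions of the linear tail, ring intact.

    The ring-closure water deficit is carried on the N-terminal (b-side)
    moiety: neutral(b_i) = sum(residues 1..i) - water for r <= i <= N-1, while
    y ions are standard: neutral(y_j) = sum(last j residues) + water for
    1 <= j <= N-r.  This convention is forced by the complementarity identity
    neutral(b_i) + neutral(y_{N-i}) = M(lasso).
    """
    zs = _check_charges(charges)
    n, r = top.n, top.ring_size
    ions: list[FragmentIon] = []
    prefix = residue_mass_sum(top.core[:r])
    for i in range(r, n):
        if i > r:
            prefix += RESIDUE_MASSES[top.core[i - 1]]
        for z in zs:
            ions.append(_make_ion(IonKind.B_TAIL, f"b{i}", prefix - WATER_MASS, z, i=i))
    suffix = 0.0
    for j in range(1, n - r + 1):
        suffix += RESIDUE_MASSES[top.core[n - j]]
        for z in zs:
            ions.append(_make_ion(IonKind.Y_TAIL, f"y{j}", suffix + WATER_MASS, z, j=j))
    return ions


def enumerate_ring_openings(top: LassoTopology) -> list[tuple[int, str]]:
    """Linearized forms of the macrolactam from single backbone cleavages.

    Opening the backbone amide between ring residues k and k+1
    (1 <= k <= r-1) yields the residue order [k+1, ..., r, 1, ..., k]; the
    isopeptide bond itself is never the opened bond, so exactly r-1 distinct
    rotations exist.  Returns (opening_site k, rotated ring sequence) pairs.
    """
    ring = top.ring_seq
    r = top.ring_size
    return [(k, ring[k:] + ring[:k]) for k in range(1, r)]


def ring_opened_b_ions(
    top: LassoTopology,
    charges: Iterable[int] = (1, 2, 3),
    water_offset: float = -WATER_MASS,
) -> list[FragmentIon]:
    """Diagnostic secondary b ions of every ring-opened linear form.

    For each rotation (opening site k) and prefix length m in [1, r-1]:
    neutral = sum(first m residues of the rotation) + ``water_offset``.  The
    default offset of -water makes the full-length prefix reproduce the intact
    ring ion b_r, which is appended once; pass ``water_offset=0.0`` for the
    alternative convention in which the opened form keeps the condensation
    water.  Duplicate m/z values are retained, each under its own label.
    """
    if water_offset not in (-WATER_MASS, 0.0):
        raise ValueError("water_offset must be -WATER_MASS or 0.0")
    zs = _check_charges(charges)
    r = top.ring_size
    ions: list[FragmentIon] = []
    for k, rotation in enumerate_ring_openings(top):
        prefix = 0.0
        for m in range(1, r):
            prefix += RESIDUE_MASSES[rotation[m - 1]]
            for z in zs:
                ions.append(
                    _make_ion(
                        IonKind.B_RING_OPENED,
                        f"ro{k}-b{m}",
                        prefix + water_offset,
                        z,
                        opening_site=k,
                        rotation_pos=m,
                    )
                )
    ring_neutral = residue_mass_sum(top.ring_seq) - WATER_MASS
    for z in zs:
        ions.append(_make_ion(IonKind.B_RING_OPENED, f"b{r}(ring)", ring_neutral, z, i=r))
    return ions


def _interlocked_pairs(top: LassoTopology) -> list[tuple[int, int]]:
    """All (i, j) with both cleavage sites inside the loop window.

    The b cleavage falls after residue i and the y cleavage before residue
    N-j+1 (i.e. after residue N-j); both site indices must lie inside
    ``loop_window`` and i + j <= N - 1 so that at least one residue is
    eliminated between them.
    """
    if top.loop_window is None:
        raise ValueError(
            "loop_window is not set on this topology; configure the loop "
            "residue interval to enumerate interlocked species"
        )
    lo, hi = top.loop_window
    n = top.n
    pairs = []
    for i in range(lo, hi + 1):
        for j in range(1, n - top.ring_size + 1):
            if lo <= n - j <= hi and i + j <= n - 1:
                pairs.append((i, j))
    return pairs


def enumerate_interlocked(
    top: LassoTopology, charges: Iterable[int] = (1, 2, 3)
) -> list[FragmentIon]:
    """Interlocked [(b_i)*(y_j)] complexes diagnostic of threading.

    Two cleavages inside the loop release an internal stretch; the resulting b
    and y fragments remain non-covalently associated because the tail is
    trapped inside the macrolactam ring.  neutral(complex) = sum(residues
    1..i) + sum(last j residues) = M(lasso) - sum(eliminated residues).
    """
    zs = _check_charges(charges)
    n = top.n
    total = top.neutral_mass()
    ions = []
    for i, j in _interlocked_pairs(top):
        eliminated = residue_mass_sum(top.core[i : n - j])
        for z in zs:
            ions.append(
                _make_ion(
                    IonKind.INTERLOCKED,
                    f"[(b{i})*(y{j})]",
                    total - eliminated,
                    z,
                    i=i,
                    j=j,
                )
            )
    return ions


def complementary_internal_pair(top: LassoTopology, i: int, j: int) -> tuple[int, int]:
    """(x, j') indices of the internal fragment complementary to [(b_i)*(y_j)].

    The eliminated stretch of the interlocked pair spans residues i+1..N-j,
    which in internal (b_x y_j') notation is x = N - j, j' = N - i.
    """
    return top.n - j, top.n - i


def internal_by_fragments(
    top: LassoTopology,
    pairs: Sequence[tuple[int, int]],
    charges: Iterable[int] = (1,),
) -> list[FragmentIon]:
    """Internal (b_x y_j) fragments spanning residues N-j+1 .. x.

    neutral = sum of the spanned residues; m/z = (neutral + z*proton)/z.
    """
    zs = _check_charges(charges)
    n = top.n
    ions = []
    for x, j in pairs:
        start = n - j + 1
        if not start <= x <= n - 1:
            raise ValueError(
                f"internal fragment pair (x={x}, j={j}) out of range: "
                f"requires N-j+1 <= x <= N-1 with N={n}"
            )
        span = top.core[start - 1 : x]
        for z in zs:
            ions.append(
                _make_ion(
                    IonKind.INTERNAL_BY,
                    f"(b{x}y{j})",
                    residue_mass_sum(span),
                    z,
                    i=x,
                    j=j,
                )
            )
    return ions


@dataclass(frozen=True)
class FragmentConfig:
    """Knobs of the theoretical-spectrum generator.

    charges: product charge states; the default {1, 2, 3} brackets the 2+ and
    3+ precursors typically observed for ~2 kDa lasso peptides.
    water_offset: convention for ring-opened secondary b ions (see
    :func:`ring_opened_b_ions`).
    include_interlocked / include_internal: interlocked complexes (needs a
    loop_window on the topology) and their complementary internal fragments.
    """

    charges: tuple[int, ...] = (1, 2, 3)
    water_offset: float = -WATER_MASS
    include_interlocked: bool = True
    include_internal: bool = True


def theoretical_spectrum(
    top: LassoTopology, config: FragmentConfig | None = None
) -> list[FragmentIon]:
    """All theoretical ions of a lasso topology, sorted by m/z.

    Aggregates precursor ions, tail b/y ions, ring-opened secondary b ions,
    interlocked complexes (when a loop window is configured) and the internal
    fragments complementary to each interlocked pair.  Deterministic for a
    fixed input; ties in m/z are broken by label.
    """
    cfg = config or FragmentConfig()
    zs = _check_charges(cfg.charges)
    total = top.neutral_mass()
    ions: list[FragmentIon] = [
        _make_ion(IonKind.PRECURSOR, f"[M+{z}H]{z}+", total, z) for z in zs
    ]
    ions += tail_by_ions(top, zs)
    ions += ring_opened_b_ions(top, zs, water_offset=cfg.water_offset)
    if cfg.include_interlocked and top.loop_window is not None:
        ions += enumerate_interlocked(top, zs)
        if cfg.include_internal:
            pairs = sorted(
                {complementary_internal_pair(top, i, j) for i, j in _interlocked_pairs(top)}
            )
            ions += internal_by_fragments(top, pairs, zs)
    ions.sort(key=lambda ion: (ion.mz, ion.label, ion.z))
    return ions


def fragments_to_table(ions: Sequence[FragmentIon]):
    """Fragment list as a DataFrame (label, kind, i, j, opening_site, z, masses)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "label": [ion.label for ion in ions],
            "kind": [ion.kind.value for ion in ions],
            "i": [ion.i for ion in ions],
            "j": [ion.j for ion in ions],
            "opening_site": [ion.opening_site for ion in ions],
            "z": [ion.z for ion in ions],
            "neutral_mass": [round(ion.neutral_mass, 5) for ion in ions],
            "mz": [round(ion.mz, 5) for ion in ions],
        }
    )


def write_fragment_table(ions: Sequence[FragmentIon], path) -> None:
    """Write the fragment table as TSV (m/z to 5 decimals)."""
    fragments_to_table(ions).to_csv(path, sep="\t", index=False)
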