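"""Peak-list I/O, EIC extraction, fragment matching and topology calling.

The computational counterpart of targeted LC-MS/MS validation of a lasso
peptide: extract ion chromatograms at ppm tolerance from MS1 runs, match the
theoretical fragment catalogue of a lasso topology against centroided MS2
peaks pooled across collision energies, and call a threaded topology when
interlocked [(b_i)*(y_j)] species are observed alongside adequate tail-ion
coverage.

MGF is the required interchange format (read and written through pyteomics);
mzML reading is optional behind the same reader contract.
"""

from __future__ import annotations

import json
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import massmodel
from .massmodel import FragmentConfig, FragmentIon, IonKind, LassoTopology

__all__ = [
    "Spectrum",
    "MatchResult",
    "AnnotationReport",
    "AnnotateConfig",
    "ppm_window",
    "extract_eic",
    "match_fragments",
    "annotate_run",
    "classify_topology",
    "read_mgf",
    "write_mgf",
    "read_mzml",
]


@dataclass
class Spectrum:
    """One centroided spectrum; peaks kept sorted by m/z."""

    scan_id: str
    ms_level: int
    retention_time: float  # minutes
    mz: np.ndarray
    intensity: np.ndarray
    nce: float | None = None
    precursor_mz: float | None = None
    precursor_z: int | None = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays must have the same shape")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be >= 0")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]
        if self.ms_level not in (1, 2):
            raise ValueError("ms_level must be 1 or 2")
        if self.ms_level == 2 and self.precursor_mz is None:
            raise ValueError("MS2 spectra require a precursor_mz")


@dataclass(frozen=True)
class MatchResult:
    ion: FragmentIon
    peak_mz: float
    peak_intensity: float
    ppm_error: float


def ppm_window(target_mz: float, tol_ppm: float) -> tuple[float, float]:
    """Inclusive (lo, hi) m/z bounds of a symmetric ppm window."""
    if target_mz <= 0 or tol_ppm <= 0:
        raise ValueError("target_mz and tol_ppm must be positive")
    half = target_mz * tol_ppm * 1e-6
    return target_mz - half, target_mz + half


def extract_eic(
    spectra: Iterable[Spectrum], target_mz: float, tol_ppm: float = 5.0
):
    """Extracted ion chromatogram: per-MS1-scan summed intensity in a ppm window.

    Returns a DataFrame with columns ``rt`` (minutes) and ``intensity``,
    sorted by retention time.
    """
    import pandas as pd

    lo, hi = ppm_window(target_mz, tol_ppm)
    rows = []
    for sp in spectra:
        if sp.ms_level != 1:
            continue
        a = np.searchsorted(sp.mz, lo, side="left")
        b = np.searchsorted(sp.mz, hi, side="right")
        rows.append({"rt": sp.retention_time, "intensity": float(sp.intensity[a:b].sum())})
    if not rows:
        raise ValueError("extract_eic requires at least one MS1 spectrum")
    return pd.DataFrame(rows).sort_values("rt", ignore_index=True)


def match_fragments(
    spectrum: Spectrum,
    theoretical: Sequence[FragmentIon],
    tol_ppm: float = 5.0,
) -> tuple[list[MatchResult], list[FragmentIon]]:
    """Match each theoretical ion to the nearest in-window peak.

    One peak may serve several isobaric labels (shared-peak rule); no
    intensity weighting is applied.  Returns (matches, unmatched ions).
    """
    if not theoretical:
        raise ValueError("theoretical ion list must be non-empty")
    if spectrum.ms_level != 2:
        raise ValueError("match_fragments expects an MS2 spectrum")
    matches, unmatched = [], []
    mzs = spectrum.mz
    for ion in theoretical:
        lo, hi = ppm_window(ion.mz, tol_ppm)
        a = np.searchsorted(mzs, lo, side="left")
        b = np.searchsorted(mzs, hi, side="right")
        if a == b:
            unmatched.append(ion)
            continue
        k = a + int(np.argmin(np.abs(mzs[a:b] - ion.mz)))
        err_ppm = (mzs[k] - ion.mz) / ion.mz * 1e6
        matches.append(
            MatchResult(
                ion=ion,
                peak_mz=float(mzs[k]),
                peak_intensity=float(spectrum.intensity[k]),
                ppm_error=float(err_ppm),
            )
        )
    return matches, unmatched


@dataclass(frozen=True)
class AnnotateConfig:
    """Matching and topology-calling parameters.

    tol_ppm: fragment-match tolerance (default 5 ppm, the EIC convention).
    isolation_window_da: width of the MS2 precursor isolation window used for
    the precursor consistency warning (2 Da default).
    min_interlocked / min_y_cov: evidence thresholds for calling a threaded
    topology.
    """

    tol_ppm: float = 5.0
    isolation_window_da: float = 2.0
    min_interlocked: int = 1
    min_y_cov: float = 0.5
    fragment: FragmentConfig = field(default_factory=FragmentConfig)


@dataclass
class AnnotationReport:
    """Union-over-NCE summary of matched theoretical species."""

    matched_b_tail: list[str]
    matched_y_tail: list[str]
    matched_ring_opened: dict[int, list[str]]  # opening site -> labels
    matched_interlocked: list[str]
    matched_internal: list[str]
    matched_precursor: list[str]
    b_coverage: float
    y_coverage: float
    n_theoretical: int
    n_matched_labels: int
    warnings: list[str]

    @property
    def n_interlocked(self) -> int:
        return len(self.matched_interlocked)

    def to_dict(self) -> dict:
        return {
            "matched_b_tail": self.matched_b_tail,
            "matched_y_tail": self.matched_y_tail,
            "matched_ring_opened": {str(k): v for k, v in self.matched_ring_opened.items()},
            "matched_interlocked": self.matched_interlocked,
            "matched_internal": self.matched_internal,
            "matched_precursor": self.matched_precursor,
            "b_coverage": self.b_coverage,
            "y_coverage": self.y_coverage,
            "n_theoretical": self.n_theoretical,
            "n_matched_labels": self.n_matched_labels,
            "warnings": self.warnings,
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")


def _ion_index_sort(label: str) -> tuple:
    digits = "".join(ch for ch in label if ch.isdigit())
    return (int(digits) if digits else 0, label)


def annotate_run(
    spectra: Iterable[Spectrum],
    top: LassoTopology,
    config: AnnotateConfig | None = None,
) -> AnnotationReport:
    """Annotate a set of targeted MS2 spectra against a lasso topology.

    Matches are pooled across collision energies (union of matched labels);
    coverage fractions count distinct matched indices over the theoretical
    tail series.  Spectra whose selected precursor m/z is inconsistent with
    the topology beyond the isolation window produce a warning but are still
    matched.
    """
    cfg = config or AnnotateConfig()
    ions = massmodel.theoretical_spectrum(top, cfg.fragment)
    ms2 = [sp for sp in spectra if sp.ms_level == 2]
    if not ms2:
        raise ValueError("annotate_run requires at least one MS2 spectrum")
    total = top.neutral_mass()
    expected = {
        z: massmodel.mz_from_mass(total, z) for z in cfg.fragment.charges
    }
    warns: list[str] = []
    matched_labels: set[str] = set()
    label_kind: dict[str, FragmentIon] = {}
    for sp in ms2:
        if sp.precursor_mz is not None:
            off = min(abs(sp.precursor_mz - mz) for mz in expected.values())
            if off > cfg.isolation_window_da / 2:
                warns.append(
                    f"scan {sp.scan_id}: precursor m/z {sp.precursor_mz:.4f} is "
                    f"{off:.3f} Da from any expected charge state (isolation "
                    f"window {cfg.isolation_window_da} Da)"
                )
        matches, _ = match_fragments(sp, ions, cfg.tol_ppm)
        for m in matches:
            matched_labels.add(m.ion.label)
            label_kind.setdefault(m.ion.label, m.ion)

    def labels_of(kind: IonKind) -> list[str]:
        labs = sorted(
            {lab for lab, ion in label_kind.items() if ion.kind == kind},
            key=_ion_index_sort,
        )
        return labs

    n, r = top.n, top.ring_size
    b_idx = {label_kind[lab].i for lab in labels_of(IonKind.B_TAIL)}
    y_idx = {label_kind[lab].j for lab in labels_of(IonKind.Y_TAIL)}
    ring_by_site: dict[int, list[str]] = {}
    for lab in labels_of(IonKind.B_RING_OPENED):
        site = label_kind[lab].opening_site
        ring_by_site.setdefault(-1 if site is None else site, []).append(lab)
    return AnnotationReport(
        matched_b_tail=labels_of(IonKind.B_TAIL),
        matched_y_tail=labels_of(IonKind.Y_TAIL),
        matched_ring_opened=ring_by_site,
        matched_interlocked=labels_of(IonKind.INTERLOCKED),
        matched_internal=labels_of(IonKind.INTERNAL_BY),
        matched_precursor=labels_of(IonKind.PRECURSOR),
        b_coverage=len(b_idx) / (n - r),
        y_coverage=len(y_idx) / (n - r),
        n_theoretical=len({ion.label for ion in ions}),
        n_matched_labels=len(matched_labels),
        warnings=warns,
    )


def classify_topology(report: AnnotationReport, config: AnnotateConfig | None = None) -> str:
    """'threaded_supported' iff enough interlocked species and tail y coverage."""
    cfg = config or AnnotateConfig()
    if report.n_interlocked >= cfg.min_interlocked and report.y_coverage >= cfg.min_y_cov:
        return "threaded_supported"
    return "inconclusive"


# ---------------------------------------------------------------------------
# Peak-list I/O


def write_mgf(spectra: Sequence[Spectrum], path) -> None:
    """Write spectra as MGF.  MS1 scans carry MSLEVEL=1 and no precursor."""
    from pyteomics import mgf

    entries = []
    for sp in spectra:
        params = {
            "title": sp.scan_id,
            "rtinseconds": sp.retention_time * 60.0,
            "mslevel": sp.ms_level,
        }
        if sp.nce is not None:
            params["nce"] = sp.nce
        if sp.ms_level == 2:
            params["pepmass"] = sp.precursor_mz
            if sp.precursor_z:
                params["charge"] = sp.precursor_z
        entries.append(
            {"m/z array": sp.mz, "intensity array": sp.intensity, "params": params}
        )
    mgf.write(entries, output=str(path), file_mode="w")


def read_mgf(path) -> list[Spectrum]:
    """Read spectra from MGF (MSLEVEL param honoured, default 2)."""
    from pyteomics import mgf

    spectra = []
    with mgf.MGF(str(path)) as reader:
        for entry in reader:
            params = entry["params"]
            level = int(params.get("mslevel", 2))
            pepmass = params.get("pepmass")
            prec_mz = float(pepmass[0]) if pepmass and pepmass[0] else None
            charge = params.get("charge")
            prec_z = int(charge[0]) if charge else None
            nce = params.get("nce")
            spectra.append(
                Spectrum(
                    scan_id=str(params.get("title", f"scan{len(spectra)}")),
                    ms_level=level,
                    retention_time=float(params.get("rtinseconds", 0.0)) / 60.0,
                    mz=entry["m/z array"],
                    intensity=entry["intensity array"],
                    nce=float(nce) if nce is not None else None,
                    precursor_mz=prec_mz if level == 2 else None,
                    precursor_z=prec_z,
                )
            )
    return spectra


def read_mzml(path) -> list[Spectrum]:
    """Read spectra from mzML (optional path; same reader contract as MGF)."""
    from pyteomics import mzml

    spectra = []
    with mzml.MzML(str(path)) as reader:
        for entry in reader:
            level = int(entry.get("ms level", 1))
            rt = 0.0
            scan_list = entry.get("scanList", {}).get("scan", [{}])
            if scan_list and "scan start time" in scan_list[0]:
                rt = float(scan_list[0]["scan start time"])
            prec_mz = prec_z = None
            if level == 2:
                sel = entry["precursorList"]["precursor"][0]["selectedIonList"]["selectedIon"][0]
                prec_mz = float(sel["selected ion m/z"])
                if "charge state" in sel:
                    prec_z = int(sel["charge state"])
            spectra.append(
                Spectrum(
                    scan_id=str(entry.get("id", f"scan{len(spectra)}")),
                    ms_level=level,
                    retention_time=rt,
                    mz=entry["m/z array"],
                    intensity=entry["intensity array"],
                    precursor_mz=prec_mz,
                    precursor_z=prec_z,
                )
            )
    return spectra
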