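"""Peptide-centric validation of cross-links by extracted ion chromatograms.

DDA sampling is stochastic: a cross-linked precursor that is genuinely
present may simply never be selected for fragmentation in a given
replicate, so the absence of an XSM is not evidence of absence.  This
module therefore tests each accepted cross-link precursor against the
*complete* MS1 data of every run: extracted ion chromatograms (EICs) of
the first three isotopes are pulled within a ppm m/z window, an ion
mobility window from the mobility library, and a retention-time window
projected through the per-run iRT calibration.  A chromatographic peak is
called when the signal-to-noise ratio and the coelution (minimum pairwise
correlation of the three isotope traces) pass thresholds.

A precursor is *validated* when it passes the XSM-level FDR filter, a peak
is detected in every sample replicate, and no peak is detected in the
cross-linker-free negative controls at the matching iRT/mobility
coordinates.  Rejection reasons are reported with fixed precedence
(fdr, then control, then replicates) for deterministic output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .chem_core import isotope_mz
from .im_library import MobilityLibraryEntry
from .irt_align import IrtModel, predict_rt, to_irt
from .xsm_results import XsmSet, precursor_key

__all__ = [
    "Eic",
    "PeakCall",
    "ValidationRecord",
    "MS1PeakSource",
    "read_ms1_table",
    "read_ms1_mzml",
    "extract_eic",
    "call_peak",
    "validate_precursor",
    "validate_study",
    "upset_counts",
    "match_between_runs",
    "DEFAULT_PPM",
    "DEFAULT_SN_THRESHOLD",
    "DEFAULT_COELUTION_THRESHOLD",
]

logger = logging.getLogger(__name__)

DEFAULT_PPM = 10.0
DEFAULT_SN_THRESHOLD = 3.0
DEFAULT_COELUTION_THRESHOLD = 0.8
N_ISOTOPES = 3
BOUNDARY_FRACTION = 0.05  # peak ends where signal falls to 5% of apex

VERDICTS = (
    "validated",
    "rejected_fdr",
    "rejected_control",
    "rejected_replicates",
    "not_detected",
)


@dataclass
class Eic:
    """Extracted ion chromatogram of one isotope of one precursor in one run."""

    precursor: str
    isotope: int
    run_id: str
    rt: np.ndarray  # minutes, strictly increasing
    intensity: np.ndarray
    ppm: float
    im_window: Tuple[float, float]

    def __post_init__(self) -> None:
        self.rt = np.asarray(self.rt, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if len(self.rt) > 1 and not np.all(np.diff(self.rt) > 0):
            raise ValueError("EIC retention times must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("EIC intensities must be non-negative")


@dataclass(frozen=True)
class PeakCall:
    """Result of chromatographic peak detection on an isotope triplet."""

    apex_rt: float
    boundaries: Tuple[float, float]
    apex_intensity: float
    area: float
    sn: float
    coelution: float
    detected: bool


@dataclass
class ValidationRecord:
    """Final per-precursor validation outcome across all runs."""

    precursor: str
    q_value: float
    per_run_detected: Dict[str, bool] = field(default_factory=dict)
    per_run_peaks: Dict[str, PeakCall] = field(default_factory=dict)
    replicate_detection_count: int = 0
    n_replicates: int = 0
    negative_control_detected: bool = False
    verdict: str = "not_detected"
    consensus_irt: float = float("nan")


class MS1PeakSource:
    """Queryable MS1 peak store for one run: (rt, mz, intensity, 1/K0) rows."""

    def __init__(self, run_id: str, table: pd.DataFrame):
        required = {"rt_min", "mz", "intensity", "inv_k0"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"MS1 table missing columns: {sorted(missing)}")
        self.run_id = run_id
        self._table = table.sort_values(["rt_min", "mz"], kind="mergesort")
        self._rt = self._table["rt_min"].to_numpy(dtype=float)
        self._mz = self._table["mz"].to_numpy(dtype=float)
        self._intensity = self._table["intensity"].to_numpy(dtype=float)
        self._inv_k0 = self._table["inv_k0"].to_numpy(dtype=float)

    def query(
        self,
        mz_lo: float,
        mz_hi: float,
        rt_lo: float,
        rt_hi: float,
        im_lo: float,
        im_hi: float,
    ) -> Tuple[np.ndarray, np.ndarray]:
        """All peaks inside the box, as (rt, intensity) arrays sorted by rt."""
        mask = (
            (self._mz >= mz_lo)
            & (self._mz <= mz_hi)
            & (self._rt >= rt_lo)
            & (self._rt <= rt_hi)
            & (self._inv_k0 >= im_lo)
            & (self._inv_k0 <= im_hi)
        )
        return self._rt[mask], self._intensity[mask]


def read_ms1_table(path: Union[str, Path], run_id: Optional[str] = None) -> MS1PeakSource:
    """Load an MS1 peak table CSV (columns rt_min, mz, intensity, inv_k0)."""
    path = Path(path)
    return MS1PeakSource(run_id or path.stem, pd.read_csv(path))


def read_ms1_mzml(path: Union[str, Path], run_id: Optional[str] = None) -> MS1PeakSource:
    """Load MS1 spectra from an mzML file into a peak source.

    Uses the scan start time per spectrum; an ion-mobility array is used
    when present, otherwise 1/K0 is recorded as 0 (mobility filters then
    must span 0 to match anything).
    """
    from pyteomics import mzml as _pymzml

    path = Path(path)
    rows = {"rt_min": [], "mz": [], "intensity": [], "inv_k0": []}
    with _pymzml.MzML(str(path)) as reader:
        for spec in reader:
            if spec.get("ms level") != 1:
                continue
            rt = float(
                spec["scanList"]["scan"][0].get("scan start time", 0.0)
            )
            mzs = spec["m/z array"]
            ints = spec["intensity array"]
            im = spec.get("mean inverse reduced ion mobility array")
            ims = im if im is not None else np.zeros(len(mzs))
            rows["rt_min"].extend([rt] * len(mzs))
            rows["mz"].extend(mzs.tolist())
            rows["intensity"].extend(ints.tolist())
            rows["inv_k0"].extend(np.asarray(ims).tolist())
    return MS1PeakSource(run_id or path.stem, pd.DataFrame(rows))


def extract_eic(
    source: MS1PeakSource,
    mz: float,
    ppm: float = DEFAULT_PPM,
    rt_window: Tuple[float, float] = (0.0, float("inf")),
    im_center: float = 0.0,
    im_halfwidth: float = float("inf"),
    precursor: str = "",
    isotope: int = 0,
) -> Eic:
    """Extract one isotope trace within m/z (ppm), RT and mobility windows.

    The trace grid is the set of distinct source scan times inside the RT
    window; per grid point the intensities of all matching peaks are
    summed.  An empty trace (no matching peaks) is allowed.
    """
    if ppm <= 0:
        raise ValueError(f"ppm must be positive, got {ppm}")
    if mz <= 0:
        raise ValueError(f"mz must be positive, got {mz}")
    half = mz * ppm * 1e-6
    rts, ints = source.query(
        mz - half, mz + half,
        rt_window[0], rt_window[1],
        im_center - im_halfwidth, im_center + im_halfwidth,
    )
    if len(rts):
        grid, inverse = np.unique(rts, return_inverse=True)
        summed = np.zeros(len(grid))
        np.add.at(summed, inverse, ints)
    else:
        grid, summed = np.array([]), np.array([])
    return Eic(
        precursor=precursor,
        isotope=isotope,
        run_id=source.run_id,
        rt=grid,
        intensity=summed,
        ppm=ppm,
        im_window=(im_center - im_halfwidth, im_center + im_halfwidth),
    )


def _align_traces(eics: Sequence[Eic]) -> Tuple[np.ndarray, np.ndarray]:
    """Intersect the RT grids of the traces; returns (grid, traces[k, t])."""
    common = eics[0].rt
    for e in eics[1:]:
        common = np.intersect1d(common, e.rt)
    traces = np.zeros((len(eics), len(common)))
    for k, e in enumerate(eics):
        idx = np.searchsorted(e.rt, common)
        traces[k] = e.intensity[idx]
    return common, traces


def _peak_boundaries(summed: np.ndarray, apex: int) -> Tuple[int, int]:
    """Descend from the apex to 5% of its height or a local minimum."""
    floor = BOUNDARY_FRACTION * summed[apex]
    left = apex
    while left > 0 and summed[left - 1] > floor and summed[left - 1] <= summed[left]:
        left -= 1
    right = apex
    n = len(summed)
    while (
        right < n - 1
        and summed[right + 1] > floor
        and summed[right + 1] <= summed[right]
    ):
        right += 1
    return left, right


def call_peak(
    eic_triplet: Sequence[Eic],
    sn_threshold: float = DEFAULT_SN_THRESHOLD,
    coelution_threshold: float = DEFAULT_COELUTION_THRESHOLD,
) -> PeakCall:
    """Detect a chromatographic peak on the aligned isotope triplet.

    The apex is the maximum of the summed trace; boundaries descend to 5%
    of the apex or the nearest local minimum.  Noise is the median absolute
    deviation of the off-peak region scaled to an SD (falling back to a
    unit floor when the off-peak region is empty or silent); coelution is
    the minimum pairwise Pearson correlation of the isotope traces within
    the boundaries.  ``detected`` requires S/N and coelution thresholds and
    a non-zero apex.
    """
    grid, traces = _align_traces(list(eic_triplet))
    summed = traces.sum(axis=0)
    if len(grid) == 0 or summed.max() <= 0:
        return PeakCall(
            apex_rt=float("nan"), boundaries=(float("nan"), float("nan")),
            apex_intensity=0.0, area=0.0, sn=0.0, coelution=0.0, detected=False,
        )
    apex = int(np.argmax(summed))
    left, right = _peak_boundaries(summed, apex)
    inside = slice(left, right + 1)
    off_peak = np.concatenate([summed[:left], summed[right + 1:]])
    noise = 1.4826 * float(np.median(np.abs(off_peak - np.median(off_peak)))) if len(off_peak) else 0.0
    if noise <= 0:
        noise = max(float(np.median(off_peak)) if len(off_peak) else 0.0, 1.0)
    sn = float(summed[apex] / noise)
    coelution = 1.0
    for a, b in combinations(range(traces.shape[0]), 2):
        xa, xb = traces[a, inside], traces[b, inside]
        if len(xa) < 2 or np.std(xa) == 0 or np.std(xb) == 0:
            coelution = 0.0
            break
        coelution = min(coelution, float(np.corrcoef(xa, xb)[0, 1]))
    if right > left:
        area = float(np.trapezoid(summed[inside], grid[inside]))
    else:
        area = float(summed[apex])
    detected = bool(sn >= sn_threshold and coelution >= coelution_threshold)
    return PeakCall(
        apex_rt=float(grid[apex]),
        boundaries=(float(grid[left]), float(grid[right])),
        apex_intensity=float(summed[apex]),
        area=area,
        sn=sn,
        coelution=coelution,
        detected=detected,
    )


def _decide_verdict(
    q_value: float,
    alpha: float,
    control_detected: bool,
    replicate_count: int,
    n_replicates: int,
) -> str:
    """The three-criterion conjunction with fixed rejection precedence."""
    if not (q_value <= alpha):
        return "rejected_fdr"
    if control_detected:
        return "rejected_control"
    if replicate_count == n_replicates and n_replicates > 0:
        return "validated"
    if replicate_count > 0:
        return "rejected_replicates"
    return "not_detected"


def validate_precursor(
    key: str,
    mono_mz: float,
    charge: int,
    q_value: float,
    consensus_irt: float,
    replicate_sources: Mapping[str, MS1PeakSource],
    control_sources: Mapping[str, MS1PeakSource],
    library_entry: Optional[MobilityLibraryEntry],
    irt_models: Mapping[str, IrtModel],
    ppm: float = DEFAULT_PPM,
    alpha: float = 0.05,
    sn_threshold: float = DEFAULT_SN_THRESHOLD,
    coelution_threshold: float = DEFAULT_COELUTION_THRESHOLD,
) -> ValidationRecord:
    """Validate one precursor across sample replicates and negative controls.

    Per run, the first three isotope EICs are extracted inside the
    iRT-projected RT window and the library mobility window, then peak
    detection is applied; the verdict follows the three-criterion rule.
    """
    record = ValidationRecord(
        precursor=key, q_value=q_value, consensus_irt=consensus_irt,
        n_replicates=len(replicate_sources),
    )
    if library_entry is None:
        logger.warning("%s: no mobility library entry; cannot validate", key)
        record.verdict = "not_detected"
        return record
    im_half = library_entry.window_width / 2.0
    for run_id, source in {**replicate_sources, **control_sources}.items():
        model = irt_models.get(run_id)
        if model is None:
            logger.warning("%s: no iRT model for run %s", key, run_id)
            record.per_run_detected[run_id] = False
            continue
        rt_pred, rt_half = predict_rt(model, consensus_irt)
        eics = [
            extract_eic(
                source,
                isotope_mz(mono_mz, charge, k),
                ppm=ppm,
                rt_window=(rt_pred - rt_half, rt_pred + rt_half),
                im_center=library_entry.mean_inv_k0,
                im_halfwidth=im_half,
                precursor=key,
                isotope=k,
            )
            for k in range(N_ISOTOPES)
        ]
        peak = call_peak(
            eics, sn_threshold=sn_threshold, coelution_threshold=coelution_threshold
        )
        record.per_run_peaks[run_id] = peak
        record.per_run_detected[run_id] = peak.detected
    record.replicate_detection_count = sum(
        record.per_run_detected.get(r, False) for r in replicate_sources
    )
    record.negative_control_detected = any(
        record.per_run_detected.get(r, False) for r in control_sources
    )
    record.verdict = _decide_verdict(
        q_value, alpha, record.negative_control_detected,
        record.replicate_detection_count, record.n_replicates,
    )
    return record


def validate_study(
    filtered_xsms: XsmSet,
    replicate_sources: Mapping[str, MS1PeakSource],
    control_sources: Mapping[str, MS1PeakSource],
    library: Sequence[MobilityLibraryEntry],
    irt_models: Mapping[str, IrtModel],
    ppm: float = DEFAULT_PPM,
    alpha: float = 0.05,
    sn_threshold: float = DEFAULT_SN_THRESHOLD,
    coelution_threshold: float = DEFAULT_COELUTION_THRESHOLD,
) -> List[ValidationRecord]:
    """Validate every distinct precursor present in the filtered XSM set.

    The per-precursor q-value is the best (lowest) q among its XSMs; the
    consensus iRT is the median of its XSM retention times projected
    through each source run's calibration.  The monoisotopic precursor m/z
    is computed from the identified sequences (theoretical cross-link mass
    at the XSM charge) — measured precursor m/z values carry the search
    engine's mass error and would bias the narrow ppm windows; the median
    measured m/z is used only as a fallback for unparsable sequences.
    """
    lib_by_key = {e.precursor: e for e in library}
    groups: Dict[str, List] = {}
    for rec in filtered_xsms.records:
        key = precursor_key(
            rec.peptide_a, rec.pos_a, rec.peptide_b, rec.pos_b, rec.charge
        )
        groups.setdefault(key, []).append(rec)
    out = []
    for key in sorted(groups):
        members = groups[key]
        irts = [
            to_irt(irt_models[m.run_id], m.rt)
            for m in members
            if m.run_id in irt_models
        ]
        if not irts:
            logger.warning("%s: no XSM from a calibrated run; skipping", key)
            continue
        out.append(
            validate_precursor(
                key=key,
                mono_mz=_theoretical_mz(members[0]),
                charge=members[0].charge,
                q_value=float(min(m.q_value for m in members)),
                consensus_irt=float(np.median(irts)),
                replicate_sources=replicate_sources,
                control_sources=control_sources,
                library_entry=lib_by_key.get(key),
                irt_models=irt_models,
                ppm=ppm,
                alpha=alpha,
                sn_threshold=sn_threshold,
                coelution_threshold=coelution_threshold,
            )
        )
    return out


def _theoretical_mz(rec) -> float:
    """Theoretical precursor m/z from the identified cross-link, falling
    back to the measured value when the sequences cannot be interpreted."""
    from .chem_core import CrossLink, Peptide, crosslink_mass
    from .chem_core import precursor_mz as _precursor_mz

    try:
        xl = CrossLink(
            alpha=Peptide(rec.peptide_a), beta=Peptide(rec.peptide_b),
            link_pos_alpha=rec.pos_a, link_pos_beta=rec.pos_b,
        )
        return _precursor_mz(crosslink_mass(xl), rec.charge)
    except Exception:
        logger.warning(
            "cannot compute theoretical m/z for %s--%s; using measured value",
            rec.peptide_a, rec.peptide_b,
        )
        return float(rec.precursor_mz)


def upset_counts(id_sets: Mapping[str, Iterable]) -> Dict[Tuple[str, ...], int]:
    """Exclusive intersection counts over named identifier sets.

    For every non-empty combination of set names, counts the identifiers
    belonging to *exactly* those sets.  Counts sum to the size of the union.
    Keys are tuples of set names in the mapping's order.
    """
    if not id_sets:
        raise ValueError("need at least one named set")
    names = list(id_sets)
    sets = {n: set(v) for n, v in id_sets.items()}
    membership: Dict[Tuple[str, ...], int] = {}
    union = set().union(*sets.values())
    for element in union:
        combo = tuple(n for n in names if element in sets[n])
        membership[combo] = membership.get(combo, 0) + 1
    return membership


def match_between_runs(
    validated: Sequence[ValidationRecord],
    xsms: XsmSet,
    replicate_runs: Sequence[str],
) -> pd.DataFrame:
    """Classify each (precursor, replicate run) as XSM+peak / peak-only / no-peak.

    "peak-only" marks a transferred identification: the precursor shows a
    confirmed chromatographic peak in a run that produced no XSM for it —
    the match-between-runs rescue that replicate-intersection counting
    misses.  Returns a tidy frame plus the summary columns
    ``fraction_xsm_all_replicates`` (precursors with XSMs in every
    replicate) and ``fraction_rescued`` (precursors recovered in at least
    one run by peak-only transfer).
    """
    xsm_runs: Dict[str, set] = {}
    for rec in xsms.records:
        key = precursor_key(
            rec.peptide_a, rec.pos_a, rec.peptide_b, rec.pos_b, rec.charge
        )
        xsm_runs.setdefault(key, set()).add(rec.run_id)
    rows = []
    for vr in validated:
        runs_with_xsm = xsm_runs.get(vr.precursor, set())
        for run in replicate_runs:
            has_xsm = run in runs_with_xsm
            has_peak = vr.per_run_detected.get(run, False)
            if has_peak and has_xsm:
                status = "xsm_and_peak"
            elif has_peak:
                status = "peak_only"
            else:
                status = "no_peak"
            rows.append(
                {
                    "precursor": vr.precursor,
                    "run_id": run,
                    "has_xsm": has_xsm,
                    "has_peak": has_peak,
                    "status": status,
                }
            )
    df = pd.DataFrame(
        rows, columns=["precursor", "run_id", "has_xsm", "has_peak", "status"]
    )
    if len(validated):
        per_prec = df.groupby("precursor")
        all_xsm = per_prec["has_xsm"].all()
        rescued = per_prec.apply(
            lambda g: bool((g["status"] == "peak_only").any()), include_groups=False
        )
        df.attrs["fraction_xsm_all_replicates"] = float(all_xsm.mean())
        df.attrs["fraction_rescued"] = float(rescued.mean())
    else:
        df.attrs["fraction_xsm_all_replicates"] = 0.0
        df.attrs["fraction_rescued"] = 0.0
    return df
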