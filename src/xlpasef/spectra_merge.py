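"""Merge ion-mobility-resolved DDA MS/MS scans into consensus spectra.

On TIMS-TOF instruments a single eluting precursor is typically fragmented
several times across consecutive PASEF ramps.  These repeat scans share a
precursor m/z, retention time and inverse reduced mobility (1/K0) within
narrow tolerances and carry partially redundant fragment information, so
they are grouped into "compounds", summed, and peak-picked into one
consensus spectrum per compound.  The consensus carries the ion-mobilogram
center (intensity-weighted mean precursor 1/K0), which is annotated in the
MGF scan title for downstream library building.

Grouping is greedy seeded clustering: records are sorted by descending
precursor intensity (ties broken by m/z then scan id); the most intense
unassigned record seeds a cluster and absorbs every unassigned record
within all three tolerances *of the seed* (not transitively).  This is
deterministic and independent of input order.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from pyteomics import mgf as _pymgf

from .chem_core import ISOTOPE_SPACING

__all__ = [
    "SpectrumRecord",
    "ConsensusSpectrum",
    "group_spectra",
    "merge_cluster",
    "merge_run",
    "infer_charge",
    "write_mgf",
    "read_mgf",
    "MgfParseError",
]

logger = logging.getLogger(__name__)

# Default tolerances for combining repeat MS/MS scans of one precursor.
DEFAULT_TOL_RT = 0.75  # minutes
DEFAULT_TOL_MZ = 0.015  # Th, absolute
DEFAULT_TOL_IM = 0.025  # V*s/cm^2
DEFAULT_FRAG_BIN_TOL = 0.02  # Th, fragment peak binning width


class MgfParseError(ValueError):
    """Malformed MGF structure, reported with a line number."""


@dataclass
class SpectrumRecord:
    """One centroided PASEF MS/MS scan with its precursor coordinates."""

    run_id: str
    scan_id: str
    precursor_mz: float
    precursor_charge: int  # 0 = unknown
    rt: float  # minutes
    inv_k0: float  # V*s/cm^2; <= 0 or NaN means mobility-unknown
    peaks: List[Tuple[float, float]]
    precursor_intensity: float = 0.0  # 0 = unknown

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks, key=lambda p: p[0])
        if any(i < 0 for _, i in self.peaks):
            raise ValueError(f"scan {self.scan_id}: negative peak intensity")

    @property
    def mobility_known(self) -> bool:
        return self.inv_k0 > 0 and not np.isnan(self.inv_k0)

    @property
    def weight(self) -> float:
        """Seeding/averaging weight: precursor intensity, falling back to TIC."""
        if self.precursor_intensity > 0:
            return self.precursor_intensity
        return sum(i for _, i in self.peaks)

    def total_intensity(self) -> float:
        return sum(i for _, i in self.peaks)


@dataclass
class ConsensusSpectrum:
    """Summed, peak-picked consensus of one compound's member scans."""

    compound_id: str
    run_id: str
    member_scan_ids: List[str]
    precursor_mz: float
    charge: int
    rt_apex: float
    rt_range: Tuple[float, float]
    inv_k0_center: float
    inv_k0_range: Tuple[float, float]
    peaks: List[Tuple[float, float]]

    def total_intensity(self) -> float:
        return sum(i for _, i in self.peaks)


def _sort_for_seeding(records: Sequence[SpectrumRecord]) -> List[SpectrumRecord]:
    return sorted(
        records, key=lambda r: (-r.weight, r.precursor_mz, r.rt, r.scan_id)
    )


def group_spectra(
    records: Sequence[SpectrumRecord],
    tol_rt: float = DEFAULT_TOL_RT,
    tol_mz: float = DEFAULT_TOL_MZ,
    tol_im: float = DEFAULT_TOL_IM,
) -> List[List[SpectrumRecord]]:
    """Partition scans of one run into compound clusters.

    Every cluster member lies within ``tol_mz`` (absolute Th), ``tol_rt``
    (min) and ``tol_im`` (V*s/cm^2) of the cluster seed.  Records with
    unknown mobility only co-cluster with other mobility-unknown records.
    The partition is a deterministic function of the record set (order
    invariant).
    """
    if min(tol_rt, tol_mz, tol_im) < 0:
        raise ValueError("tolerances must be non-negative")
    pending = _sort_for_seeding(records)
    assigned = [False] * len(pending)
    clusters: List[List[SpectrumRecord]] = []
    for i, seed in enumerate(pending):
        if assigned[i]:
            continue
        members = [seed]
        assigned[i] = True
        for j in range(i + 1, len(pending)):
            if assigned[j]:
                continue
            cand = pending[j]
            if cand.mobility_known != seed.mobility_known:
                continue
            if abs(cand.precursor_mz - seed.precursor_mz) > tol_mz:
                continue
            if abs(cand.rt - seed.rt) > tol_rt:
                continue
            if seed.mobility_known and abs(cand.inv_k0 - seed.inv_k0) > tol_im:
                continue
            members.append(cand)
            assigned[j] = True
        clusters.append(members)
    return clusters


def _bin_peaks(
    peaks: Sequence[Tuple[float, float]], tol: float
) -> List[Tuple[float, float]]:
    """Merge m/z-sorted peaks closer than ``tol`` to their neighbour.

    Groups are formed by gaps: a new picked peak starts whenever the next
    m/z is more than ``tol`` above the previous one.  Picked m/z is the
    intensity-weighted mean; intensity is the sum (conserved).
    """
    if not peaks:
        return []
    ordered = sorted(peaks, key=lambda p: p[0])
    picked: List[Tuple[float, float]] = []
    group_mz = [ordered[0][0]]
    group_int = [ordered[0][1]]
    prev_mz = ordered[0][0]
    for mz, inten in ordered[1:]:
        if mz - prev_mz > tol:
            picked.append(_weighted_peak(group_mz, group_int))
            group_mz, group_int = [], []
        group_mz.append(mz)
        group_int.append(inten)
        prev_mz = mz
    picked.append(_weighted_peak(group_mz, group_int))
    return picked


def _weighted_peak(mzs: List[float], intensities: List[float]) -> Tuple[float, float]:
    total = sum(intensities)
    if total > 0:
        center = sum(m * i for m, i in zip(mzs, intensities)) / total
    else:
        center = sum(mzs) / len(mzs)
    return (center, total)


def merge_cluster(
    cluster: Sequence[SpectrumRecord],
    frag_bin_tol: float = DEFAULT_FRAG_BIN_TOL,
    compound_id: Optional[str] = None,
) -> ConsensusSpectrum:
    """Sum and peak-pick one compound cluster into a consensus spectrum."""
    if not cluster:
        raise ValueError("cannot merge an empty cluster")
    members = _sort_for_seeding(cluster)
    weights = np.array([m.weight for m in members], dtype=float)
    if weights.sum() <= 0:
        weights = np.ones(len(members))
    mzs = np.array([m.precursor_mz for m in members])
    rts = np.array([m.rt for m in members])
    prec_mz = float(np.average(mzs, weights=weights))
    # rt apex: scan of the most intense precursor; if no member reports a
    # precursor intensity, the median RT is the better apex estimate.
    if any(m.precursor_intensity > 0 for m in members):
        rt_apex = members[int(np.argmax(weights))].rt
    else:
        rt_apex = float(np.median(rts))
    charges = {m.precursor_charge for m in members if m.precursor_charge != 0}
    if len(charges) == 1:
        charge = charges.pop()
    elif len(charges) > 1:
        # conflicting assignments: keep the seed's, warn
        charge = members[0].precursor_charge
        logger.warning(
            "cluster %s: conflicting charges %s, keeping seed charge %d",
            compound_id, sorted(charges), charge,
        )
    else:
        charge = 0
    if all(m.mobility_known for m in members):
        im_center = float(np.average([m.inv_k0 for m in members], weights=weights))
        im_range = (min(m.inv_k0 for m in members), max(m.inv_k0 for m in members))
    else:
        im_center, im_range = float("nan"), (float("nan"), float("nan"))
    pooled = [p for m in members for p in m.peaks]
    return ConsensusSpectrum(
        compound_id=compound_id or f"{members[0].run_id}:{members[0].scan_id}",
        run_id=members[0].run_id,
        member_scan_ids=[m.scan_id for m in members],
        precursor_mz=prec_mz,
        charge=charge,
        rt_apex=rt_apex,
        rt_range=(float(rts.min()), float(rts.max())),
        inv_k0_center=im_center,
        inv_k0_range=im_range,
        peaks=_bin_peaks(pooled, frag_bin_tol),
    )


def merge_run(
    records: Sequence[SpectrumRecord],
    tol_rt: float = DEFAULT_TOL_RT,
    tol_mz: float = DEFAULT_TOL_MZ,
    tol_im: float = DEFAULT_TOL_IM,
    frag_bin_tol: float = DEFAULT_FRAG_BIN_TOL,
) -> List[ConsensusSpectrum]:
    """Group then merge all scans of one run; compounds numbered in seed order."""
    clusters = group_spectra(records, tol_rt=tol_rt, tol_mz=tol_mz, tol_im=tol_im)
    out = []
    for k, cluster in enumerate(clusters, start=1):
        out.append(
            merge_cluster(
                cluster, frag_bin_tol=frag_bin_tol, compound_id=f"cmpd{k:05d}"
            )
        )
    return out


def infer_charge(
    isotope_peaks: Sequence[Tuple[float, float]],
    max_charge: int = 8,
    tol: float = 0.01,
) -> int:
    """Infer the charge state from adjacent isotope-peak spacings.

    Picks the z in 1..max_charge whose expected spacing 1.0033548/z has the
    least mean absolute deviation from the observed adjacent spacings;
    returns 0 (unknown) if even the best z misses by more than ``tol`` Th.
    """
    if len(isotope_peaks) < 2:
        logger.warning("charge inference needs >= 2 peaks, got %d", len(isotope_peaks))
        return 0
    mzs = sorted(mz for mz, _ in isotope_peaks)
    spacings = np.diff(mzs)
    best_z, best_err = 0, float("inf")
    for z in range(1, max_charge + 1):
        err = float(np.mean(np.abs(spacings - ISOTOPE_SPACING / z)))
        if err < best_err:
            best_z, best_err = z, err
    return best_z if best_err <= tol else 0


# ---------------------------------------------------------------------------
# MGF I/O
#
# The dialect: standard BEGIN IONS / END IONS blocks with PEPMASS (m/z and
# optional intensity), CHARGE with sign, RTINSECONDS, and a TITLE of the
# exact form "compound=<id> run=<run_id> 1/K0=<value to 4 decimals>".
# Writing uses fixed float formats so that write -> read -> write is
# byte-identical.
# ---------------------------------------------------------------------------

_MZ_FMT = "{:.5f}"
_INT_FMT = "{:.6g}"
_RT_FMT = "{:.3f}"
_IM_FMT = "{:.4f}"

Spectrum = Union[SpectrumRecord, ConsensusSpectrum]


def _as_title_fields(spectrum: Spectrum) -> Tuple[str, str, float]:
    if isinstance(spectrum, ConsensusSpectrum):
        return spectrum.compound_id, spectrum.run_id, spectrum.inv_k0_center
    return spectrum.scan_id, spectrum.run_id, spectrum.inv_k0


def write_mgf(spectra: Sequence[Spectrum], path: Union[str, Path]) -> None:
    """Write consensus spectra (or plain records) as an annotated MGF file."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        for spectrum in spectra:
            compound_id, run_id, inv_k0 = _as_title_fields(spectrum)
            if isinstance(spectrum, ConsensusSpectrum):
                rt_min, charge = spectrum.rt_apex, spectrum.charge
                prec_int = 0.0
            else:
                rt_min, charge = spectrum.rt, spectrum.precursor_charge
                prec_int = spectrum.precursor_intensity
            fh.write("BEGIN IONS\n")
            im_txt = _IM_FMT.format(inv_k0) if inv_k0 > 0 else "NA"
            fh.write(f"TITLE=compound={compound_id} run={run_id} 1/K0={im_txt}\n")
            if prec_int > 0:
                fh.write(
                    "PEPMASS="
                    + _MZ_FMT.format(spectrum.precursor_mz)
                    + " "
                    + _INT_FMT.format(prec_int)
                    + "\n"
                )
            else:
                fh.write("PEPMASS=" + _MZ_FMT.format(spectrum.precursor_mz) + "\n")
            if charge:
                fh.write(f"CHARGE={charge}+\n")
            fh.write("RTINSECONDS=" + _RT_FMT.format(rt_min * 60.0) + "\n")
            for mz, inten in spectrum.peaks:
                fh.write(_MZ_FMT.format(mz) + " " + _INT_FMT.format(inten) + "\n")
            fh.write("END IONS\n")


def _check_nesting(path: Path) -> None:
    """Reject malformed BEGIN/END nesting with the offending line number."""
    depth = 0
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            token = line.strip().upper()
            if token == "BEGIN IONS":
                depth += 1
                if depth > 1:
                    raise MgfParseError(
                        f"{path}:{lineno}: nested BEGIN IONS without END IONS"
                    )
            elif token == "END IONS":
                depth -= 1
                if depth < 0:
                    raise MgfParseError(
                        f"{path}:{lineno}: END IONS without matching BEGIN IONS"
                    )
    if depth != 0:
        raise MgfParseError(f"{path}: unterminated BEGIN IONS block at end of file")


def _parse_title(title: str) -> Tuple[str, str, float]:
    compound_id, run_id, inv_k0 = title.strip(), "", float("nan")
    for token in title.split():
        if token.startswith("compound="):
            compound_id = token[len("compound="):]
        elif token.startswith("run="):
            run_id = token[len("run="):]
        elif token.startswith("1/K0="):
            value = token[len("1/K0="):]
            if value != "NA":
                inv_k0 = float(value)
    return compound_id, run_id, inv_k0


def read_mgf(path: Union[str, Path]) -> List[SpectrumRecord]:
    """Read an MGF file into spectrum records.

    1/K0 is taken from the TITLE token if present, else from a dedicated
    ``1/K0=`` header line; records without either are flagged
    mobility-unknown (inv_k0 = NaN) rather than rejected.  Unknown headers
    are tolerated.
    """
    path = Path(path)
    _check_nesting(path)
    records: List[SpectrumRecord] = []
    with _pymgf.MGF(str(path), convert_arrays=1, read_charges=True) as reader:
        for idx, entry in enumerate(reader, start=1):
            params = entry["params"]
            title = str(params.get("title", f"index{idx}"))
            compound_id, run_id, inv_k0 = _parse_title(title)
            if np.isnan(inv_k0) and "1/k0" in params:
                inv_k0 = float(params["1/k0"])
            pepmass = params.get("pepmass", (0.0, None))
            prec_mz = float(pepmass[0])
            prec_int = (
                float(pepmass[1])
                if len(pepmass) > 1 and pepmass[1] is not None
                else 0.0
            )
            charge_list = params.get("charge")
            charge = int(charge_list[0]) if charge_list else 0
            rt_s = float(params.get("rtinseconds", 0.0))
            peaks = list(
                zip(
                    entry["m/z array"].tolist(),
                    entry["intensity array"].tolist(),
                )
            )
            records.append(
                SpectrumRecord(
                    run_id=run_id,
                    scan_id=compound_id,
                    precursor_mz=prec_mz,
                    precursor_charge=charge,
                    rt=rt_s / 60.0,
                    inv_k0=inv_k0,
                    peaks=peaks,
                    precursor_intensity=prec_int,
                )
            )
    return records
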