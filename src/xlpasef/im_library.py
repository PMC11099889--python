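"""Precursor-specific ion-mobility library from grouped XSMs.

TIMS measures an inverse reduced mobility (1/K0, V*s/cm^2) for every
precursor.  Because 1/K0 is highly reproducible for a given peptide ion,
the values observed across all accepted XSMs of one precursor (cross-link
identity + charge) define a narrow extraction window for targeted
re-interrogation of the MS1 data.  Each library entry stores the mean 1/K0,
the observed range, and an extraction window width equal to the range
floored at a configurable minimum so single-observation precursors still
get a usable window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Tuple, Union

import numpy as np
import pandas as pd

from .xsm_results import XsmSet, precursor_key

__all__ = [
    "MobilityLibraryEntry",
    "build_mobility_library",
    "write_skyline_im_csv",
    "read_skyline_im_csv",
    "IM_UNITS",
    "DEFAULT_MIN_WINDOW",
]

logger = logging.getLogger(__name__)

IM_UNITS = "inverse_K0_Vsec_per_cm2"
#: Minimum total extraction window width (V*s/cm^2); +-0.025 matches the
#: mobility tolerance used when merging repeat MS/MS scans.
DEFAULT_MIN_WINDOW = 0.05


@dataclass(frozen=True)
class MobilityLibraryEntry:
    """Aggregated 1/K0 statistics for one precursor (cross-link + charge)."""

    precursor: str
    charge: int
    mean_inv_k0: float
    inv_k0_range: Tuple[float, float]
    n_observations: int
    window_width: float

    def __post_init__(self) -> None:
        lo, hi = self.inv_k0_range
        if not (lo <= self.mean_inv_k0 <= hi):
            raise ValueError(
                f"{self.precursor}: mean 1/K0 outside observed range"
            )


def build_mobility_library(
    xsms: XsmSet, min_window: float = DEFAULT_MIN_WINDOW
) -> List[MobilityLibraryEntry]:
    """Aggregate filtered target XSMs into one entry per precursor.

    Mean = arithmetic mean of all contributing XSM 1/K0 values; range =
    (min, max); window width = max(range width, ``min_window``).  XSMs with
    missing mobility are skipped with a warning.  Pure aggregation:
    permutation invariant, deterministic ordering by precursor key.
    """
    groups: Dict[Tuple[str, int], List[float]] = {}
    skipped = 0
    for rec in xsms.records:
        if np.isnan(rec.inv_k0):
            skipped += 1
            continue
        key = (
            precursor_key(
                rec.peptide_a, rec.pos_a, rec.peptide_b, rec.pos_b, rec.charge
            ),
            rec.charge,
        )
        groups.setdefault(key, []).append(rec.inv_k0)
    if skipped:
        logger.warning("mobility library: skipped %d XSMs without 1/K0", skipped)
    entries = []
    for (key, charge) in sorted(groups):
        # sorted so the float sum is permutation invariant (exact aggregation)
        values = sorted(groups[(key, charge)])
        lo, hi = min(values), max(values)
        entries.append(
            MobilityLibraryEntry(
                precursor=key,
                charge=charge,
                mean_inv_k0=float(np.mean(values)),
                inv_k0_range=(lo, hi),
                n_observations=len(values),
                window_width=max(hi - lo, min_window),
            )
        )
    return entries


def write_skyline_im_csv(
    entries: List[MobilityLibraryEntry], path: Union[str, Path]
) -> None:
    """Write entries as a Skyline-style ion mobility library CSV."""
    if not entries:
        raise ValueError("no library entries to write")
    df = pd.DataFrame(
        {
            "precursor": [e.precursor for e in entries],
            "charge": [e.charge for e in entries],
            "ion_mobility": [f"{e.mean_inv_k0:.4f}" for e in entries],
            "ion_mobility_units": IM_UNITS,
            "window_width": [f"{e.window_width:.4f}" for e in entries],
            "inv_k0_min": [f"{e.inv_k0_range[0]:.4f}" for e in entries],
            "inv_k0_max": [f"{e.inv_k0_range[1]:.4f}" for e in entries],
            "n_observations": [e.n_observations for e in entries],
        }
    )
    df.to_csv(path, index=False)


def read_skyline_im_csv(path: Union[str, Path]) -> List[MobilityLibraryEntry]:
    """Read a library CSV written by :func:`write_skyline_im_csv`."""
    df = pd.read_csv(path)
    entries = []
    for row in df.itertuples(index=False):
        entries.append(
            MobilityLibraryEntry(
                precursor=row.precursor,
                charge=int(row.charge),
                mean_inv_k0=float(row.ion_mobility),
                inv_k0_range=(float(row.inv_k0_min), float(row.inv_k0_max)),
                n_observations=int(row.n_observations),
                window_width=float(row.window_width),
            )
        )
    return entries
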