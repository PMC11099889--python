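"""Indexed retention time (iRT) calibration per run.

Spiked standard peptides with known reference iRT values anchor a linear
map iRT = slope * RT + intercept for each run, turning run-specific
retention times into a run-independent scale.  The calibration supports
projecting any run's observations onto the iRT axis (``to_irt``) and,
inversely, predicting where a precursor of known iRT should elute in a
run (``predict_rt``) together with an extraction-window half-width derived
from the fit's residual scatter.

The model is ordinary least squares with an optional single-worst-outlier
refit (removed when n >= 6 standards and its residual exceeds 3x the
residual SD), a deliberately minimal stand-in for vendor calibrators.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "IrtModel",
    "IndexedPrecursor",
    "fit_irt",
    "to_irt",
    "predict_rt",
    "read_standards_csv",
]

DEFAULT_WINDOW_K = 3.0
DEFAULT_WINDOW_FLOOR = 0.5  # minutes


@dataclass(frozen=True)
class IrtModel:
    """Per-run linear calibration iRT = slope * RT_min + intercept."""

    run_id: str
    slope: float
    intercept: float
    residual_sd: float  # iRT units
    n_standards: int
    standards: Tuple[Tuple[str, float, float], ...] = ()  # (name, ref_irt, obs_rt)

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError(
                f"run {self.run_id}: calibration slope must be positive "
                f"(elution order preserved), got {self.slope}"
            )
        if not np.isfinite(self.residual_sd):
            raise ValueError(f"run {self.run_id}: non-finite residual SD")


@dataclass(frozen=True)
class IndexedPrecursor:
    """Consensus iRT of a precursor across runs."""

    precursor: str
    per_run_rt: Tuple[Tuple[str, float], ...]
    consensus_irt: float
    irt_spread: float  # max - min of per-run iRTs


def _ols(ref_irt: np.ndarray, obs_rt: np.ndarray) -> Tuple[float, float, float]:
    fit = stats.linregress(obs_rt, ref_irt)
    resid = ref_irt - (fit.slope * obs_rt + fit.intercept)
    dof = max(len(ref_irt) - 2, 1)
    sd = float(np.sqrt(np.sum(resid**2) / dof))
    return float(fit.slope), float(fit.intercept), sd


def fit_irt(
    standards: Sequence[Tuple[float, float]],
    run_id: str = "",
    names: Sequence[str] = (),
    robust: bool = True,
) -> IrtModel:
    """Fit a run's RT -> iRT line from (reference_iRT, observed_RT) pairs.

    With ``robust`` and n >= 6 standards, the single worst standard is
    removed and the line refit if its residual exceeds 3x the residual SD.
    """
    if len(standards) < 2:
        raise ValueError(f"need >= 2 standards, got {len(standards)}")
    ref = np.array([s[0] for s in standards], dtype=float)
    rt = np.array([s[1] for s in standards], dtype=float)
    if np.ptp(rt) == 0:
        raise ValueError("standards have zero retention-time variance")
    slope, intercept, sd = _ols(ref, rt)
    used = np.ones(len(ref), dtype=bool)
    if robust and len(ref) >= 6 and sd > 0:
        resid = np.abs(ref - (slope * rt + intercept))
        worst = int(np.argmax(resid))
        if resid[worst] > 3 * sd:
            used[worst] = False
            slope, intercept, sd = _ols(ref[used], rt[used])
    table = tuple(
        (names[i] if i < len(names) else f"std{i + 1}", float(ref[i]), float(rt[i]))
        for i in range(len(ref))
        if used[i]
    )
    return IrtModel(
        run_id=run_id,
        slope=slope,
        intercept=intercept,
        residual_sd=sd,
        n_standards=int(used.sum()),
        standards=table,
    )


def to_irt(model: IrtModel, rt: float) -> float:
    """Project an observed retention time onto the iRT scale."""
    return model.slope * rt + model.intercept


def predict_rt(
    model: IrtModel,
    irt: float,
    k: float = DEFAULT_WINDOW_K,
    floor: float = DEFAULT_WINDOW_FLOOR,
) -> Tuple[float, float]:
    """Predict a run's RT for a given iRT, with an extraction half-width.

    Returns ``(rt_minutes, half_width_minutes)`` where the half-width is
    ``max(k * residual_SD / slope, floor)`` — the fit scatter mapped back to
    the RT axis, floored so near-perfect fits still get a usable window.
    """
    rt = (irt - model.intercept) / model.slope
    half_width = max(k * model.residual_sd / model.slope, floor)
    return rt, half_width


def read_standards_csv(path: Union[str, Path]) -> List[Tuple[str, float, float]]:
    """Read a standards table: columns name, reference_irt, observed_rt."""
    df = pd.read_csv(path)
    for col in ("name", "reference_irt", "observed_rt"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column: {col}")
    return [
        (str(r.name), float(r.reference_irt), float(r.observed_rt))
        for r in df.itertuples(index=False)
    ]
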