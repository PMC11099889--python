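"""Self-contained synthetic cross-linking studies with ground truth.

Emulates the structure of a DSBU/BSA benchmark experiment acquired by
DDA-PASEF: a tryptic digest of one carrier protein, DSBU cross-links
between reactive sites, four technical replicate runs plus a
cross-linker-free negative control, spiked retention-time standards, and
per-precursor ion mobility.  Everything is generated from one RNG seed and
written as plain-text files (FASTA, MGF, CSV, JSON) that the rest of the
package reads back, together with a truth record for closed-loop testing.

The carrier protein is a *synthetic* BSA-like sequence (seeded, fixed) that
embeds two real tryptic BSA peptides (KQTALVELLK, KFWGK) in cleavable
context so the canonical demonstration cross-link exists in the digest.

What the generator emulates — and what it does not: elution peaks are
noiseless Gaussians on a regular scan grid, mobility is an affine function
of m/z per charge state plus jitter, DDA stochasticity is a single
per-run identification probability (``p_xsm``), and matrix background is
uniform random single peaks.  Real data adds chimeric spectra, intensity-
dependent sampling, and correlated noise; passing tests on this generator
therefore demonstrate correctness of the pipeline's logic, not search-
engine-level performance on real runs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .chem_core import (
    DSBU,
    CrossLink,
    LinkerSpec,
    Peptide,
    crosslink_mass,
    fragment_ions,
    isotope_mz,
    precursor_mz,
)
from .spectra_merge import ConsensusSpectrum, write_mgf
from .xsm_results import precursor_key

__all__ = [
    "SynthConfig",
    "StudyTruth",
    "TrueCrossLink",
    "digest",
    "tryptic_spans",
    "sample_crosslinks",
    "synthetic_carrier_protein",
    "generate_study",
    "CARRIER_ACCESSION",
]

CARRIER_ACCESSION = "SYNBSA"

# Embedded real tryptic BSA peptides (from the canonical benchmark XL).
_EMBEDDED_PEPTIDES = ("KQTALVELLK", "KFWGK")

# amino-acid alphabet weighted roughly like a serum albumin composition
_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_WEIGHTS = np.array(
    [8, 5, 6, 9, 5, 3, 3, 2, 9, 10, 1, 2, 4, 3, 4, 5, 6, 6, 1, 3], dtype=float
)


def synthetic_carrier_protein(length: int = 583, seed: int = 583583) -> str:
    """Deterministic synthetic BSA-like protein sequence.

    Random draws with albumin-like residue frequencies, with the two
    embedded benchmark peptides placed after a K so they are tryptic
    products.  Same (length, seed) always yields the same sequence.
    """
    rng = np.random.default_rng(seed)
    p = _AA_WEIGHTS / _AA_WEIGHTS.sum()
    body = "".join(rng.choice(list(_AA), size=length, p=p))
    third = length // 3
    # splice each embedded peptide in after a forced K anchor
    seq = (
        body[:third]
        + "K" + _EMBEDDED_PEPTIDES[0]
        + body[third : 2 * third]
        + "K" + _EMBEDDED_PEPTIDES[1]
        + body[2 * third :]
    )
    return seq


def tryptic_spans(
    protein: str,
    missed_cleavages: int = 3,
    min_len: int = 5,
    max_len: int = 50,
) -> List[Tuple[str, int, int]]:
    """Fully specific tryptic peptides as (sequence, start_1based, n_missed).

    Cleaves C-terminal to every K and R (no proline exception); emits all
    products with up to ``missed_cleavages`` internal K/R and length within
    bounds, ordered by start position then length.
    """
    if not protein:
        raise ValueError("empty protein sequence")
    cut_after = [i for i, aa in enumerate(protein) if aa in "KR"]
    boundaries = [0] + [i + 1 for i in cut_after]
    if boundaries[-1] != len(protein):
        boundaries.append(len(protein))
    spans = []
    n_segments = len(boundaries) - 1
    for i in range(n_segments):
        for m in range(missed_cleavages + 1):
            j = i + m + 1
            if j > n_segments:
                break
            seq = protein[boundaries[i] : boundaries[j]]
            if min_len <= len(seq) <= max_len:
                spans.append((seq, boundaries[i] + 1, m))
    return spans


def digest(
    protein: str,
    missed_cleavages: int = 3,
    min_len: int = 5,
    max_len: int = 50,
) -> List[Peptide]:
    """In-silico tryptic digest returning peptide objects (see tryptic_spans)."""
    return [
        Peptide(seq)
        for seq, _, _ in tryptic_spans(protein, missed_cleavages, min_len, max_len)
    ]


def _reactive_positions(sequence: str, linker: LinkerSpec) -> List[int]:
    """Linkable 1-based positions; a C-terminal K is excluded because a
    linked K cannot be cleaved (the link implies a missed cleavage)."""
    positions = []
    for i, aa in enumerate(sequence, start=1):
        if aa not in linker.reactive_residues:
            continue
        if aa == "K" and i == len(sequence):
            continue
        positions.append(i)
    return positions


def sample_crosslinks(
    peptides: Sequence[Peptide],
    linker: LinkerSpec = DSBU,
    n: int = 20,
    seed: int = 0,
) -> List[CrossLink]:
    """Draw ``n`` distinct cross-links with uniformly sampled reactive sites."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    eligible = [
        (pep, _reactive_positions(pep.sequence, linker))
        for pep in peptides
        if _reactive_positions(pep.sequence, linker)
    ]
    if len(eligible) < 1:
        raise ValueError("no peptides with reactive sites for this linker")
    out: List[CrossLink] = []
    seen = set()
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 200 * n:
            raise ValueError(
                f"could not sample {n} distinct cross-links "
                f"({len(out)} found) from {len(eligible)} eligible peptides"
            )
        ia, ib = rng.integers(0, len(eligible), size=2)
        pep_a, sites_a = eligible[ia]
        pep_b, sites_b = eligible[ib]
        pos_a = int(sites_a[rng.integers(0, len(sites_a))])
        pos_b = int(sites_b[rng.integers(0, len(sites_b))])
        if pep_a.sequence == pep_b.sequence and pos_a == pos_b:
            continue
        ident = tuple(
            sorted([(pep_a.sequence, pos_a), (pep_b.sequence, pos_b)])
        )
        if ident in seen:
            continue
        seen.add(ident)
        out.append(
            CrossLink(
                alpha=pep_a, beta=pep_b,
                link_pos_alpha=pos_a, link_pos_beta=pos_b, linker=linker,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Study generation
# ---------------------------------------------------------------------------


@dataclass
class SynthConfig:
    """Study conditions for the synthetic benchmark.

    Defaults mirror the emulated experiment: 4 technical replicates at one
    collision-energy profile plus one cross-linker-free negative control,
    20 true DSBU cross-links and 20 decoys, per-run identification
    probability 0.5 (DDA stochasticity), 5 ppm fragment m/z jitter, 0.005
    V*s/cm^2 mobility jitter, 10 retention-time standards.
    """

    n_true_crosslinks: int = 20
    n_decoys: int = 20
    n_replicates: int = 4
    n_controls: int = 1
    replicate_label: str = "Low_CE"
    p_xsm: float = 0.5
    p_decoy_xsm: float = 0.8
    n_contaminants: int = 2  # true XLs whose signal is also planted in controls
    mz_jitter_ppm: float = 5.0
    im_jitter_sd: float = 0.005  # V*s/cm^2
    rt_jitter_sd: float = 0.05  # minutes
    n_standards: int = 10
    n_matrix_peaks: int = 300  # random background peaks per run
    gradient_min: float = 60.0
    scan_step_min: float = 0.02  # MS1 scan spacing
    peak_sigma_min: float = 0.06  # chromatographic peak SD
    abundance_mean: float = 5e4
    target_score_mean: float = 40.0
    target_score_sd: float = 8.0
    decoy_score_mean: float = 18.0
    decoy_score_sd: float = 6.0
    missed_cleavages: int = 3
    min_len: int = 5
    max_len: int = 50
    charges: Tuple[int, ...] = (3, 4)
    # per-charge mobility model 1/K0 = c0[z] + c1 * (m/z)/1000
    im_c0: Dict[int, float] = field(
        default_factory=lambda: {1: 0.9, 2: 0.7, 3: 0.52, 4: 0.56, 5: 0.5}
    )
    im_c1: float = 0.4
    isotope_ratios: Tuple[float, ...] = (1.0, 0.85, 0.5)


@dataclass
class TrueCrossLink:
    """Ground-truth record for one planted cross-link precursor."""

    peptide_a: str
    peptide_b: str
    pos_a: int
    pos_b: int
    site_a: int
    site_b: int
    charge: int
    neutral_mass: float
    mono_mz: float
    inv_k0: float
    irt: float
    abundance: float
    is_contaminant_in_control: bool = False

    @property
    def key(self) -> str:
        return precursor_key(
            self.peptide_a, self.pos_a, self.peptide_b, self.pos_b, self.charge
        )


@dataclass
class StudyTruth:
    """Everything needed to check pipeline output against the simulation."""

    seed: int
    protein: str
    true_crosslinks: List[TrueCrossLink]
    decoy_crosslinks: List[TrueCrossLink]
    run_manifest: List[Dict]  # run_id, replicate_group, is_control
    irt_transforms: Dict[str, Tuple[float, float]]  # run -> (slope, intercept)
    standards: List[Tuple[str, float]]  # (name, reference iRT)
    config: Dict

    def replicate_runs(self) -> List[str]:
        return [r["run_id"] for r in self.run_manifest if not r["is_control"]]

    def control_runs(self) -> List[str]:
        return [r["run_id"] for r in self.run_manifest if r["is_control"]]

    def to_json(self, path: Union[str, Path]) -> None:
        payload = dataclasses.asdict(self)
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "StudyTruth":
        raw = json.loads(Path(path).read_text())
        raw["true_crosslinks"] = [TrueCrossLink(**d) for d in raw["true_crosslinks"]]
        raw["decoy_crosslinks"] = [TrueCrossLink(**d) for d in raw["decoy_crosslinks"]]
        raw["irt_transforms"] = {
            k: tuple(v) for k, v in raw["irt_transforms"].items()
        }
        raw["standards"] = [tuple(s) for s in raw["standards"]]
        cfg = raw.get("config", {})
        # undo JSON's tuple->list and int-key->str coercions
        if "charges" in cfg:
            cfg["charges"] = tuple(cfg["charges"])
        if "isotope_ratios" in cfg:
            cfg["isotope_ratios"] = tuple(cfg["isotope_ratios"])
        if "im_c0" in cfg:
            cfg["im_c0"] = {int(k): v for k, v in cfg["im_c0"].items()}
        return cls(**raw)


def _protein_site(protein: str, sequence: str, pos: int) -> int:
    start = protein.find(sequence)
    return (start + pos) if start >= 0 else pos


def _true_inv_k0(cfg: SynthConfig, mz: float, z: int) -> float:
    return cfg.im_c0.get(z, 0.5) + cfg.im_c1 * mz / 1000.0


def _decoy_sequence(seq: str) -> str:
    """Reversed sequence keeping the C-terminal K/R anchor in place."""
    if seq[-1] in "KR":
        return seq[-2::-1] + seq[-1]
    return seq[::-1]


def generate_study(
    out_dir: Union[str, Path],
    config: Optional[SynthConfig] = None,
    seed: int = 7,
) -> StudyTruth:
    """Generate a complete synthetic study under ``out_dir``.

    Writes per run: an MS1 peak table CSV, a merged MGF of consensus MS/MS
    spectra for every XSM, an XSM CSV (replicate runs only; control runs
    are not searched), and a standards CSV with observed RTs; study-wide:
    the carrier FASTA, reference standards, and ``truth.json``.
    Byte-reproducible for a fixed (config, seed).
    """
    cfg = config or SynthConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    protein = synthetic_carrier_protein()
    peptides = digest(protein, cfg.missed_cleavages, cfg.min_len, cfg.max_len)
    # keep sampling tractable: cap at moderate peptide length for precursors
    precursor_pool = [p for p in peptides if len(p) <= 25]
    xls = sample_crosslinks(
        precursor_pool, DSBU, cfg.n_true_crosslinks, seed=int(rng.integers(2**31))
    )
    decoy_pool = [Peptide(_decoy_sequence(p.sequence)) for p in precursor_pool]
    decoy_xls = sample_crosslinks(
        decoy_pool, DSBU, cfg.n_decoys, seed=int(rng.integers(2**31))
    )

    def make_truth(xl: CrossLink, contaminant: bool) -> TrueCrossLink:
        z = int(rng.choice(cfg.charges))
        mass = crosslink_mass(xl)
        mz = precursor_mz(mass, z)
        return TrueCrossLink(
            peptide_a=xl.alpha.sequence, peptide_b=xl.beta.sequence,
            pos_a=xl.link_pos_alpha, pos_b=xl.link_pos_beta,
            site_a=_protein_site(protein, xl.alpha.sequence, xl.link_pos_alpha),
            site_b=_protein_site(protein, xl.beta.sequence, xl.link_pos_beta),
            charge=z, neutral_mass=mass, mono_mz=mz,
            inv_k0=_true_inv_k0(cfg, mz, z),
            irt=float(rng.uniform(10.0, 100.0)),
            abundance=float(rng.lognormal(np.log(cfg.abundance_mean), 0.4)),
            is_contaminant_in_control=contaminant,
        )

    truths = [make_truth(xl, i < cfg.n_contaminants) for i, xl in enumerate(xls)]
    decoy_truths = [make_truth(xl, False) for xl in decoy_xls]

    manifest = [
        {
            "run_id": f"{cfg.replicate_label}_{i + 1}",
            "replicate_group": cfg.replicate_label,
            "is_control": False,
        }
        for i in range(cfg.n_replicates)
    ] + [
        {"run_id": f"Control_{i + 1}", "replicate_group": "control", "is_control": True}
        for i in range(cfg.n_controls)
    ]

    # per-run affine iRT transform: iRT = a * RT + b
    transforms: Dict[str, Tuple[float, float]] = {}
    for run in manifest:
        a = 2.5 * (1.0 + rng.normal(0, 0.01))
        b = -20.0 + rng.normal(0, 1.0)
        transforms[run["run_id"]] = (float(a), float(b))

    standards = [
        (f"iRT_std_{i + 1:02d}", float(v))
        for i, v in enumerate(np.linspace(0.0, 100.0, cfg.n_standards))
    ]

    _write_fasta(out / "protein.fasta", CARRIER_ACCESSION, protein)

    for run in manifest:
        run_id = run["run_id"]
        a, b = transforms[run_id]
        rt_of = lambda irt: (irt - b) / a  # noqa: E731

        _write_standards(
            out / f"standards_{run_id}.csv", standards, rt_of, rng, cfg
        )
        planted = [] if run["is_control"] else truths
        contaminants = (
            [t for t in truths if t.is_contaminant_in_control]
            if run["is_control"]
            else []
        )
        _write_ms1(
            out / f"ms1_{run_id}.csv", planted + contaminants, rt_of, rng, cfg
        )
        if not run["is_control"]:
            xsm_rows, spectra = _simulate_xsms(
                run_id, truths, decoy_truths, rt_of, rng, cfg
            )
            _write_xsm_csv_rows(out / f"xsms_{run_id}.csv", xsm_rows)
            write_mgf(spectra, out / f"{run_id}.mgf")

    truth = StudyTruth(
        seed=seed,
        protein=protein,
        true_crosslinks=truths,
        decoy_crosslinks=decoy_truths,
        run_manifest=manifest,
        irt_transforms=transforms,
        standards=standards,
        config=dataclasses.asdict(cfg),
    )
    truth.to_json(out / "truth.json")
    _write_study_yaml(out, cfg, manifest)
    return truth


def _write_fasta(path: Path, accession: str, sequence: str) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    record = SeqRecord(
        Seq(sequence), id=accession, description="synthetic BSA-like carrier"
    )
    SeqIO.write([record], str(path), "fasta")


def _write_standards(path: Path, standards, rt_of, rng, cfg: SynthConfig) -> None:
    lines = ["name,reference_irt,observed_rt"]
    for name, irt in standards:
        rt = rt_of(irt) + rng.normal(0, cfg.rt_jitter_sd)
        lines.append(f"{name},{irt:.4f},{rt:.4f}")
    path.write_text("\n".join(lines) + "\n")


def _write_ms1(
    path: Path,
    planted: Sequence[TrueCrossLink],
    rt_of,
    rng,
    cfg: SynthConfig,
) -> None:
    rows: List[Tuple[float, float, float, float]] = []
    for t in planted:
        rt_center = rt_of(t.irt) + rng.normal(0, cfg.rt_jitter_sd)
        half_span = 3.5 * cfg.peak_sigma_min
        # shared scan grid across isotopes so coelution is measurable
        grid = np.arange(
            rt_center - half_span, rt_center + half_span, cfg.scan_step_min
        )
        for k, ratio in enumerate(cfg.isotope_ratios):
            mz_k = isotope_mz(t.mono_mz, t.charge, k)
            profile = (
                t.abundance
                * ratio
                * np.exp(-0.5 * ((grid - rt_center) / cfg.peak_sigma_min) ** 2)
            )
            for rt, inten in zip(grid, profile):
                mz_obs = mz_k * (1 + rng.normal(0, cfg.mz_jitter_ppm * 1e-6 / 3))
                im_obs = t.inv_k0 + rng.normal(0, cfg.im_jitter_sd / 3)
                rows.append((float(rt), float(mz_obs), float(inten), float(im_obs)))
    # matrix background: uniform random single peaks
    for _ in range(cfg.n_matrix_peaks):
        rows.append(
            (
                float(rng.uniform(0, cfg.gradient_min)),
                float(rng.uniform(300, 1700)),
                float(rng.lognormal(np.log(500), 1.0)),
                float(rng.uniform(0.6, 1.6)),
            )
        )
    rows.sort()
    lines = ["rt_min,mz,intensity,inv_k0"]
    for rt, mz, inten, im in rows:
        lines.append(f"{rt:.4f},{mz:.6f},{inten:.3f},{im:.4f}")
    path.write_text("\n".join(lines) + "\n")


def _truncated_normal(rng, mean: float, sd: float) -> float:
    return float(max(rng.normal(mean, sd), 0.0))


def _simulate_xsms(
    run_id: str,
    truths: Sequence[TrueCrossLink],
    decoys: Sequence[TrueCrossLink],
    rt_of,
    rng,
    cfg: SynthConfig,
):
    rows: List[Dict] = []
    spectra: List[ConsensusSpectrum] = []
    scan_no = 0
    for group, is_decoy, p, s_mean, s_sd in (
        (truths, False, cfg.p_xsm, cfg.target_score_mean, cfg.target_score_sd),
        (decoys, True, cfg.p_decoy_xsm, cfg.decoy_score_mean, cfg.decoy_score_sd),
    ):
        for t in group:
            if rng.random() >= p:
                continue
            scan_no += 1
            scan_id = f"cmpd{scan_no:05d}"
            rt = rt_of(t.irt) + rng.normal(0, cfg.rt_jitter_sd)
            prefix = "DECOY_" if is_decoy else ""
            rows.append(
                {
                    "run_id": run_id,
                    "scan": scan_id,
                    "peptide_a": t.peptide_a,
                    "peptide_b": t.peptide_b,
                    "pos_a": t.pos_a,
                    "pos_b": t.pos_b,
                    "protein_a": prefix + CARRIER_ACCESSION,
                    "protein_b": prefix + CARRIER_ACCESSION,
                    "site_a": t.site_a,
                    "site_b": t.site_b,
                    "score": round(_truncated_normal(rng, s_mean, s_sd), 3),
                    "decoy": int(is_decoy),
                    "mz": round(
                        t.mono_mz * (1 + rng.normal(0, cfg.mz_jitter_ppm * 1e-6)), 6
                    ),
                    "z": t.charge,
                    "rt_min": round(rt, 4),
                    "inv_k0": round(
                        t.inv_k0 + rng.normal(0, cfg.im_jitter_sd), 4
                    ),
                }
            )
            if not is_decoy:
                spectra.append(
                    _consensus_spectrum(scan_id, run_id, t, rt, rng, cfg)
                )
    return rows, spectra


def _consensus_spectrum(
    scan_id: str, run_id: str, t: TrueCrossLink, rt: float, rng, cfg: SynthConfig
) -> ConsensusSpectrum:
    xl = CrossLink(
        alpha=Peptide(t.peptide_a), beta=Peptide(t.peptide_b),
        link_pos_alpha=t.pos_a, link_pos_beta=t.pos_b, linker=DSBU,
    )
    frags = fragment_ions(xl, max_frag_charge=2, series=("b", "y"))
    peaks = []
    for ion in frags:
        mz_obs = ion.mz * (1 + rng.normal(0, cfg.mz_jitter_ppm * 1e-6))
        peaks.append((float(mz_obs), float(rng.lognormal(np.log(200), 0.8))))
    inv_k0 = t.inv_k0 + rng.normal(0, cfg.im_jitter_sd)
    return ConsensusSpectrum(
        compound_id=scan_id,
        run_id=run_id,
        member_scan_ids=[scan_id],
        precursor_mz=float(t.mono_mz * (1 + rng.normal(0, cfg.mz_jitter_ppm * 1e-6))),
        charge=t.charge,
        rt_apex=float(rt),
        rt_range=(float(rt), float(rt)),
        inv_k0_center=float(inv_k0),
        inv_k0_range=(float(inv_k0), float(inv_k0)),
        peaks=sorted(peaks),
    )


def _write_xsm_csv_rows(path: Path, rows: List[Dict]) -> None:
    import pandas as pd

    from .xsm_results import XSM_CSV_COLUMNS

    pd.DataFrame(rows, columns=XSM_CSV_COLUMNS).to_csv(path, index=False)


def _write_study_yaml(out: Path, cfg: SynthConfig, manifest: List[Dict]) -> None:
    import yaml

    doc = {
        "fasta": "protein.fasta",
        "tolerances": {"rt_min": 0.75, "mz_th": 0.015, "im": 0.025, "ppm": 10.0},
        "fdr": {"alpha": 0.05, "min_score": 15.0},
        "linker": "DSBU",
        "runs": [
            {
                "run_id": r["run_id"],
                "replicate_group": r["replicate_group"],
                "control": r["is_control"],
                "ms1": f"ms1_{r['run_id']}.csv",
                "standards": f"standards_{r['run_id']}.csv",
                "xsms": None if r["is_control"] else f"xsms_{r['run_id']}.csv",
                "mgf": None if r["is_control"] else f"{r['run_id']}.mgf",
            }
            for r in manifest
        ],
    }
    (out / "study.yaml").write_text(yaml.safe_dump(doc, sort_keys=False))
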