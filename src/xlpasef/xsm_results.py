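"""Cross-link spectrum match (XSM) tables: reading, merging, FDR, ProXL export.

A cross-link search engine assigns fragment spectra to cross-linked peptide
pairs and scores each assignment; one row of that output is an XSM.  After
runs are searched separately the per-run tables are merged and filtered at
a global false discovery rate estimated by the target-decoy approach, then
exported as ProXL-style XML for spectral-library assembly.

The FDR estimator is decoys/targets at each score threshold, with q-values
taken as the running minimum over thresholds (monotone non-increasing in
score).  Ties in score share one threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from lxml import etree

__all__ = [
    "XsmRecord",
    "XsmSet",
    "XSM_CSV_COLUMNS",
    "read_xsm_csv",
    "write_xsm_csv",
    "merge_xsm_sets",
    "assign_global_fdr",
    "filter_at_fdr",
    "write_proxl_xml",
    "read_proxl_xml",
    "crosslink_identity",
    "precursor_key",
]

logger = logging.getLogger(__name__)

#: Versioned XSM CSV schema (v1): one row per XSM.
XSM_CSV_COLUMNS = [
    "run_id", "scan", "peptide_a", "peptide_b", "pos_a", "pos_b",
    "protein_a", "protein_b", "site_a", "site_b", "score", "decoy",
    "mz", "z", "rt_min", "inv_k0",
]

_TRUE_TOKENS = {"1", "true", "t", "yes"}
_FALSE_TOKENS = {"0", "false", "f", "no"}


@dataclass
class XsmRecord:
    """One cross-link spectrum match."""

    run_id: str
    scan: str
    peptide_a: str
    peptide_b: str
    pos_a: int
    pos_b: int
    protein_a: str
    protein_b: str
    site_a: int
    site_b: int
    score: float
    is_decoy: bool
    precursor_mz: float
    charge: int
    rt: float  # minutes
    inv_k0: float  # NaN = missing
    q_value: float = float("nan")

    def identity(self) -> Tuple:
        return crosslink_identity(
            self.peptide_a, self.pos_a, self.peptide_b, self.pos_b
        )

    def key(self) -> Tuple:
        """Deduplication key: (run, scan, cross-link identity)."""
        return (self.run_id, self.scan, self.identity())


def crosslink_identity(
    peptide_a: str, pos_a: int, peptide_b: str, pos_b: int
) -> Tuple:
    """Charge-agnostic, order-agnostic cross-link identity.

    The unordered pair of (sequence, link position), canonicalised
    lexicographically so that swapping the two peptides gives the same
    identity.
    """
    a, b = (peptide_a, pos_a), (peptide_b, pos_b)
    return (a, b) if a <= b else (b, a)


def precursor_key(
    peptide_a: str, pos_a: int, peptide_b: str, pos_b: int, charge: int
) -> str:
    """Canonical textual precursor identifier.

    Grammar: ``<seqA>@<posA>--<seqB>@<posB>/<z>`` with the two
    (sequence, position) halves in lexicographic order, so the identifier is
    invariant under peptide swap.  Charge makes distinct precursors of the
    same cross-link distinct keys.
    """
    (sa, pa), (sb, pb) = crosslink_identity(peptide_a, pos_a, peptide_b, pos_b)
    return f"{sa}@{pa}--{sb}@{pb}/{charge}"


@dataclass
class XsmSet:
    """A validated collection of XSMs with source provenance."""

    records: List[XsmRecord] = field(default_factory=list)
    provenance: List[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def targets(self) -> List[XsmRecord]:
        return [r for r in self.records if not r.is_decoy]

    def decoys(self) -> List[XsmRecord]:
        return [r for r in self.records if r.is_decoy]


def _parse_decoy(value) -> bool:
    token = str(value).strip().lower()
    if token in _TRUE_TOKENS:
        return True
    if token in _FALSE_TOKENS:
        return False
    raise ValueError(f"unparsable decoy flag: {value!r}")


def _dedupe(records: Sequence[XsmRecord], context: str = "") -> List[XsmRecord]:
    seen: Dict[Tuple, XsmRecord] = {}
    dropped = 0
    for rec in records:
        key = rec.key()
        if key in seen:
            dropped += 1
            continue
        seen[key] = rec
    if dropped:
        logger.warning("%s: dropped %d duplicate (run, scan, xl) rows", context, dropped)
    return list(seen.values())


def read_xsm_csv(path: Union[str, Path]) -> XsmSet:
    """Read one XSM CSV (schema v1, see :data:`XSM_CSV_COLUMNS`)."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in XSM_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column: {', '.join(missing)}")
    has_q = "q_value" in df.columns
    records: List[XsmRecord] = []
    skipped = 0
    for row in df.itertuples(index=False):
        try:
            inv_k0_txt = getattr(row, "inv_k0").strip()
            q_txt = getattr(row, "q_value").strip() if has_q else ""
            records.append(
                XsmRecord(
                    run_id=row.run_id,
                    scan=row.scan,
                    peptide_a=row.peptide_a,
                    peptide_b=row.peptide_b,
                    pos_a=int(row.pos_a),
                    pos_b=int(row.pos_b),
                    protein_a=row.protein_a,
                    protein_b=row.protein_b,
                    site_a=int(row.site_a),
                    site_b=int(row.site_b),
                    score=float(row.score),
                    is_decoy=_parse_decoy(row.decoy),
                    precursor_mz=float(row.mz),
                    charge=int(row.z),
                    rt=float(row.rt_min),
                    inv_k0=float(inv_k0_txt) if inv_k0_txt else float("nan"),
                    q_value=float(q_txt) if q_txt else float("nan"),
                )
            )
        except (ValueError, TypeError):
            skipped += 1
    if skipped:
        logger.warning("%s: skipped %d unparsable rows", path, skipped)
    records = _dedupe(records, context=str(path))
    return XsmSet(records=records, provenance=[str(path)])


def write_xsm_csv(xsms: XsmSet, path: Union[str, Path]) -> None:
    """Write an XsmSet back to the v1 CSV schema (plus q_value if assigned)."""
    rows = []
    for r in xsms.records:
        rows.append({
            "run_id": r.run_id, "scan": r.scan,
            "peptide_a": r.peptide_a, "peptide_b": r.peptide_b,
            "pos_a": r.pos_a, "pos_b": r.pos_b,
            "protein_a": r.protein_a, "protein_b": r.protein_b,
            "site_a": r.site_a, "site_b": r.site_b,
            "score": r.score, "decoy": int(r.is_decoy),
            "mz": r.precursor_mz, "z": r.charge,
            "rt_min": r.rt, "inv_k0": r.inv_k0,
            "q_value": r.q_value,
        })
    pd.DataFrame(rows, columns=XSM_CSV_COLUMNS + ["q_value"]).to_csv(
        path, index=False
    )


def merge_xsm_sets(sets: Sequence[XsmSet]) -> XsmSet:
    """Union of XSM sets with (run, scan, identity) deduplication."""
    if not sets:
        raise ValueError("no input sets")
    pooled = [r for s in sets for r in s.records]
    provenance = [p for s in sets for p in s.provenance]
    return XsmSet(records=_dedupe(pooled, context="merge"), provenance=provenance)


def assign_global_fdr(xsms: XsmSet) -> XsmSet:
    """Assign target-decoy q-values over the merged set.

    At each score threshold, FDR_est = (#decoys >= threshold) /
    (#targets >= threshold) (1.0 when no targets remain); the q-value of a
    record is the running minimum of FDR_est over all thresholds at or
    below its score.  All records sharing a score share one threshold.
    Decoy records receive the q-value of their threshold too (informational).
    """
    records = sorted(
        xsms.records, key=lambda r: (-r.score, r.is_decoy, r.run_id, r.scan)
    )
    if not records:
        return XsmSet(records=[], provenance=list(xsms.provenance))
    n_decoys_total = sum(r.is_decoy for r in records)
    if n_decoys_total == 0:
        logger.warning(
            "no decoy XSMs present: FDR is uncalibrated, all q-values set to 0"
        )
        out = [replace(r, q_value=0.0) for r in records]
        return XsmSet(records=out, provenance=list(xsms.provenance))
    # walk thresholds from highest score down, computing raw FDR per
    # distinct score; then running-minimum from the lowest score upward.
    scores = np.array([r.score for r in records])
    is_decoy = np.array([r.is_decoy for r in records])
    cum_decoys = np.cumsum(is_decoy)
    cum_targets = np.cumsum(~is_decoy)
    # index of the last record at each distinct score (ties share threshold)
    raw_fdr = np.empty(len(records))
    i = 0
    while i < len(records):
        j = i
        while j + 1 < len(records) and scores[j + 1] == scores[i]:
            j += 1
        d, t = cum_decoys[j], cum_targets[j]
        raw_fdr[i : j + 1] = (d / t) if t > 0 else 1.0
        i = j + 1
    q = np.minimum.accumulate(raw_fdr[::-1])[::-1]
    out = [replace(r, q_value=float(qv)) for r, qv in zip(records, q)]
    return XsmSet(records=out, provenance=list(xsms.provenance))


def filter_at_fdr(
    xsms: XsmSet, alpha: float = 0.05, min_score: float = 15.0
) -> XsmSet:
    """Keep target XSMs with q <= alpha and score >= min_score."""
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    if any(np.isnan(r.q_value) for r in xsms.records):
        raise ValueError("q-values not assigned; run assign_global_fdr first")
    kept = [
        r
        for r in xsms.records
        if not r.is_decoy and r.q_value <= alpha and r.score >= min_score
    ]
    return XsmSet(records=kept, provenance=list(xsms.provenance))


# ---------------------------------------------------------------------------
# ProXL XML (schema subset)
# ---------------------------------------------------------------------------

_SCHEMA_PATH = Path(__file__).parent / "data" / "proxl_subset.xsd"


def _load_schema() -> etree.XMLSchema:
    return etree.XMLSchema(etree.parse(str(_SCHEMA_PATH)))


def _read_fasta_accessions(fasta_path: Union[str, Path]) -> Dict[str, str]:
    from Bio import SeqIO

    return {
        rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")
    }


def write_proxl_xml(
    xsms: XsmSet,
    fasta_path: Union[str, Path],
    search_metadata: Optional[dict] = None,
    path: Union[str, Path] = "results.proxl.xml",
    linker_name: str = "dsbu",
    linker_mass: float = 196.08479,
    linkable_residues: str = "KSTY",
) -> None:
    """Write filtered target XSMs as a ProXL-style import XML.

    The document groups PSMs under reported peptides (one per distinct
    cross-link identity + charge), declares the search program and linker,
    and validates against the bundled schema subset before writing.
    """
    meta = {"search_program": "xlpasef", "version": "1", **(search_metadata or {})}
    sequences = _read_fasta_accessions(fasta_path)
    for rec in xsms.records:
        for acc in (rec.protein_a, rec.protein_b):
            if acc not in sequences:
                raise ValueError(f"protein accession not in FASTA: {acc}")
    root = etree.Element("proxl_input")
    root.set("fasta_filename", Path(fasta_path).name)
    prog = etree.SubElement(root, "search_program")
    prog.set("name", meta["search_program"])
    prog.set("version", str(meta["version"]))
    linker = etree.SubElement(root, "linker")
    linker.set("name", linker_name)
    linker.set("mass", f"{linker_mass:.5f}")
    linker.set("linkable_residues", linkable_residues)

    groups: Dict[Tuple, List[XsmRecord]] = {}
    for rec in xsms.records:
        groups.setdefault(rec.identity() + (rec.charge,), []).append(rec)
    peptides_el = etree.SubElement(root, "reported_peptides")
    for key in sorted(groups):
        members = groups[key]
        (seq_a, pos_a), (seq_b, pos_b), charge = key
        rp = etree.SubElement(peptides_el, "reported_peptide")
        rp.set("type", "crosslink")
        rep = members[0]
        for seq, pos, acc, site in (
            (seq_a, pos_a, *_proteins_for(rep, seq_a, pos_a)),
            (seq_b, pos_b, *_proteins_for(rep, seq_b, pos_b)),
        ):
            pep = etree.SubElement(rp, "peptide")
            pep.set("sequence", seq)
            pep.set("linked_position", str(pos))
            pep.set("protein", acc)
            pep.set("protein_site", str(site))
        psms = etree.SubElement(rp, "psms")
        for rec in sorted(members, key=lambda r: (r.run_id, r.scan)):
            psm = etree.SubElement(psms, "psm")
            psm.set("run", rec.run_id)
            psm.set("scan", rec.scan)
            psm.set("charge", str(rec.charge))
            psm.set("precursor_mz", f"{rec.precursor_mz:.5f}")
            psm.set("score", f"{rec.score:.4f}")
            if not np.isnan(rec.q_value):
                psm.set("q_value", f"{rec.q_value:.6f}")
    _load_schema().assertValid(root)
    etree.ElementTree(root).write(
        str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8"
    )


def _proteins_for(rec: XsmRecord, seq: str, pos: int) -> Tuple[str, int]:
    # map the canonicalised half back to its protein annotation
    if (seq, pos) == (rec.peptide_a, rec.pos_a):
        return rec.protein_a, rec.site_a
    return rec.protein_b, rec.site_b


def read_proxl_xml(path: Union[str, Path]) -> List[dict]:
    """Parse a ProXL-subset XML back into dictionaries (round-trip check)."""
    tree = etree.parse(str(path))
    _load_schema().assertValid(tree)
    out = []
    for rp in tree.getroot().iter("reported_peptide"):
        peptides = [
            {
                "sequence": p.get("sequence"),
                "linked_position": int(p.get("linked_position")),
                "protein": p.get("protein"),
                "protein_site": int(p.get("protein_site")),
            }
            for p in rp.iter("peptide")
        ]
        psms = [
            {
                "run": m.get("run"),
                "scan": m.get("scan"),
                "charge": int(m.get("charge")),
                "precursor_mz": float(m.get("precursor_mz")),
                "score": float(m.get("score")),
            }
            for m in rp.iter("psm")
        ]
        out.append({"peptides": peptides, "psms": psms})
    return out
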