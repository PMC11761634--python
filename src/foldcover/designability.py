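"""Designability metrics: per-backbone design outcomes and TM-score
summaries.

A sampled backbone is *designable* when, among several sequences designed
for it, at least one predicted structure superposes onto the backbone with
RMSD strictly below 2.0 Å. Sequence design and structure prediction happen
outside this package; their per-design RMSD/TM tables are first-class input,
and the superposition/TM arithmetic on coordinate pairs is provided here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._geom import apply_transform, kabsch_rmsd, kabsch_transform
from .structio import BackboneStructure

DESIGNABLE_RMSD = 2.0
#: canonical number of designed sequences per backbone
DESIGNS_PER_STRUCTURE = 8


@dataclass
class DesignabilityRecord:
    """Per-structure design outcomes: the 8 (nominally) design RMSDs, the
    designable flag, and optional TM scores."""

    structure_id: str
    design_rmsds: list[float]
    min_rmsd: float
    designable: bool
    length: int | None = None
    tm_scores: list[float] | None = None
    max_tm: float | None = None


def flag_designable(
    rmsds: list[float], threshold: float = DESIGNABLE_RMSD
) -> tuple[float, bool]:
    """(min RMSD, designable) for one backbone's design RMSDs; designable
    iff the minimum is strictly below the threshold."""
    if len(rmsds) == 0:
        raise ValueError("need at least one design RMSD")
    arr = np.asarray(rmsds, dtype=float)
    if np.any(arr < 0) or not np.all(np.isfinite(arr)):
        raise ValueError("RMSDs must be finite and non-negative")
    mn = float(arr.min())
    return mn, mn < threshold


def ca_rmsd_aligned(designed: BackboneStructure, predicted: BackboneStructure) -> float:
    """CA RMSD after global Kabsch superposition with the identity residue
    correspondence (designed residue i vs predicted residue i)."""
    if designed.length != predicted.length:
        raise ValueError("structures must have equal length")
    return kabsch_rmsd(designed.ca, predicted.ca)


def _tm_from_distances(d: np.ndarray, d0: float) -> float:
    return float(np.mean(1.0 / (1.0 + (d / d0) ** 2)))


def tm_d0(length: int) -> float:
    """The standard TM-score normalization scale d0 = 1.24 (L−15)^{1/3} − 1.8."""
    if length < 16:
        raise ValueError("TM score undefined for length < 16")
    return 1.24 * (length - 15) ** (1.0 / 3.0) - 1.8


def tm_score(
    a: BackboneStructure,
    b: BackboneStructure,
    superpose: bool = True,
    max_iter: int = 20,
) -> float:
    """TM score between equal-length structures with the identity residue
    correspondence, normalized by the common length.

    TM = (1/L) Σ 1/(1 + (d_i/d0)²) with d0 = 1.24 (L−15)^{1/3} − 1.8. The
    superposition starts from a global Kabsch fit and is refined by
    iteratively refitting on close residues (d_i < 8 Å, then d_i < 2 d0),
    keeping the maximum TM over iterations — an approximation to a full
    TM-alignment search (no fragment seeding, fixed correspondence).
    ``superpose=False`` scores the coordinates as given.
    """
    if a.length != b.length:
        raise ValueError("structures must have equal length")
    length = a.length
    d0 = tm_d0(length)
    ca_a, ca_b = a.ca, b.ca
    if not superpose:
        d = np.linalg.norm(ca_a - ca_b, axis=1)
        return _tm_from_distances(d, d0)

    def _score(mask: np.ndarray) -> tuple[float, np.ndarray]:
        rot, trans = kabsch_transform(ca_b[mask], ca_a[mask])
        moved = apply_transform(ca_b, rot, trans)
        d = np.linalg.norm(ca_a - moved, axis=1)
        return _tm_from_distances(d, d0), d

    mask = np.ones(length, dtype=bool)
    best, d = _score(mask)
    cutoffs = [8.0, 2.0 * d0]
    prev = best
    for it in range(max_iter):
        cutoff = cutoffs[min(it, len(cutoffs) - 1)]
        mask = d < cutoff
        if mask.sum() < 3:
            mask = np.argsort(d)[:3]
            sel = np.zeros(length, dtype=bool)
            sel[mask] = True
            mask = sel
        tm, d = _score(mask)
        best = max(best, tm)
        if it >= len(cutoffs) - 1 and tm - prev < 1e-6:
            break
        prev = tm
    return best


def per_length_median_max_tm(records: list[DesignabilityRecord]) -> pd.DataFrame:
    """Median of max TM per exact structure length (even counts average the
    central pair)."""
    rows = [
        {"length": r.length, "max_tm": r.max_tm}
        for r in records
        if r.max_tm is not None and r.length is not None
    ]
    if not rows:
        return pd.DataFrame(columns=["length", "median_max_tm", "n"])
    df = pd.DataFrame(rows)
    out = (
        df.groupby("length")["max_tm"]
        .agg(median_max_tm="median", n="size")
        .reset_index()
    )
    return out


# ---------------------------------------------------------------------------
# Tables


def records_from_table(
    path, threshold: float = DESIGNABLE_RMSD
) -> list[DesignabilityRecord]:
    """Build designability records from a precomputed per-design TSV
    (columns: structure_id, design_index, rmsd, optional tm, optional
    length)."""
    df = pd.read_csv(path, sep="\t")
    needed = {"structure_id", "rmsd"}
    if not needed <= set(df.columns):
        raise ValueError(f"designability table needs columns {sorted(needed)}")
    out = []
    for sid, grp in df.groupby("structure_id", sort=False):
        rmsds = grp["rmsd"].astype(float).tolist()
        mn, flag = flag_designable(rmsds, threshold)
        tms = grp["tm"].astype(float).tolist() if "tm" in grp.columns else None
        length = int(grp["length"].iloc[0]) if "length" in grp.columns else None
        out.append(
            DesignabilityRecord(
                structure_id=str(sid),
                design_rmsds=rmsds,
                min_rmsd=mn,
                designable=flag,
                length=length,
                tm_scores=tms,
                max_tm=max(tms) if tms else None,
            )
        )
    return out


def write_records(records: list[DesignabilityRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "structure_id": r.structure_id,
                "min_rmsd": r.min_rmsd,
                "designable": r.designable,
                "max_tm": r.max_tm if r.max_tm is not None else "",
            }
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)
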