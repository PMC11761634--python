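"""Reading, validating, filtering and length-matching backbone structure sets.

A *backbone structure* is a single protein chain reduced to its N/CA/C/O
atoms. Reference sets (e.g. experimentally determined domains) additionally
carry crystallographic metadata used for quality filtering: resolution,
R_free and the experimental method. Only the four backbone atoms are ever
read; side chains, ligands and alternate models are out of scope.
"""

from __future__ import annotations

import re
import warnings
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: CA-CA distances outside this window within a contiguous segment are
#: flagged as geometry violations; > the upper bound marks a chain break.
CA_CA_MIN = 2.0
CA_CA_MAX = 4.5


class FormatError(ValueError):
    """The input file could not be parsed in the requested format."""


class ContentError(ValueError):
    """The file parsed, but its content violates a structural precondition."""


class Method(str, Enum):
    XRAY = "XRAY"
    EM = "EM"
    NMR = "NMR"
    PREDICTED = "PREDICTED"
    SYNTHETIC = "SYNTHETIC"


@dataclass
class StructureMetadata:
    """Experimental provenance of a structure; fields may be absent (None)."""

    resolution: float | None = None
    r_free: float | None = None
    method: Method | None = None

    def __post_init__(self) -> None:
        if self.resolution is not None and not self.resolution > 0:
            raise ValueError("resolution must be positive when present")
        if self.r_free is not None and not 0.0 <= self.r_free <= 1.0:
            raise ValueError("r_free must lie in [0, 1] when present")


@dataclass
class BackboneStructure:
    """One chain's backbone: per-residue (N, CA, C, O) coordinates in Å.

    ``chain_breaks`` holds 0-based residue indices i such that the chain is
    discontinuous between residues i and i+1. ``author_numbers`` preserves
    the residue numbering of the source file; all downstream indexing is
    positional (0-based, sequential).
    """

    id: str
    coords: np.ndarray  # (length, 4, 3) in BACKBONE_ATOMS order
    chain_breaks: list[int] = field(default_factory=list)
    author_numbers: list[int] | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1:] != (4, 3):
            raise ValueError("coords must have shape (length, 4, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if self.length < 2:
            raise ValueError("structure must have at least 2 residues")
        self.chain_breaks = sorted(set(self.chain_breaks))

    @property
    def length(self) -> int:
        return self.coords.shape[0]

    @property
    def ca(self) -> np.ndarray:
        return self.coords[:, 1, :]

    def segments(self) -> list[tuple[int, int]]:
        """Contiguous segments as half-open (start, stop) residue ranges."""
        starts = [0] + [b + 1 for b in self.chain_breaks]
        stops = [b + 1 for b in self.chain_breaks] + [self.length]
        return list(zip(starts, stops))

    def ca_violations(self) -> list[int]:
        """Indices i where d(CA_i, CA_{i+1}) within a segment falls outside
        the [2.0, 4.5] Å window. Flagged, not fatal."""
        bad = []
        for start, stop in self.segments():
            d = np.linalg.norm(np.diff(self.ca[start:stop], axis=0), axis=1)
            for k, dist in enumerate(d):
                if not CA_CA_MIN <= dist <= CA_CA_MAX:
                    bad.append(start + k)
        return bad


# ---------------------------------------------------------------------------
# PDB I/O


_RES_RE = re.compile(r"REMARK   2 RESOLUTION\.\s+([0-9.]+)\s+ANGSTROM")
_RFREE_RE = re.compile(r"REMARK   3   FREE R VALUE\s*(?:\(NO CUTOFF\))?\s*:\s*([0-9.]+)")


def _method_from_expdta(text: str) -> Method | None:
    t = text.upper()
    if "NMR" in t:
        return Method.NMR
    if "X-RAY" in t or "XRAY" in t:
        return Method.XRAY
    if "MICROSCOPY" in t or "CRYO" in t:
        return Method.EM
    if "PREDICTED" in t or "THEORETICAL" in t:
        return Method.PREDICTED
    if "SYNTHETIC" in t:
        return Method.SYNTHETIC
    return None


def _scan_header(lines: Iterable[str]) -> StructureMetadata:
    resolution = r_free = None
    method = None
    for line in lines:
        if line.startswith("ATOM") or line.startswith("HETATM"):
            break
        if resolution is None:
            m = _RES_RE.search(line)
            if m:
                resolution = float(m.group(1))
        if r_free is None:
            m = _RFREE_RE.search(line)
            if m:
                r_free = float(m.group(1))
        if method is None and line.startswith("EXPDTA"):
            method = _method_from_expdta(line[6:])
    return StructureMetadata(resolution=resolution, r_free=r_free, method=method)


def read_backbone(
    path: str | Path,
    format: str = "PDB",
    chain: str | None = None,
) -> tuple[BackboneStructure, StructureMetadata]:
    """Read one chain's backbone from a PDB file.

    By default the first chain (in order of appearance) is used; ``chain``
    selects one explicitly. Residues missing any of N/CA/C/O are dropped and
    introduce a chain break. Altlocs resolve to the highest-occupancy
    conformer. Metadata comes from REMARK 2 / REMARK 3 / EXPDTA records when
    present.
    """
    if format.upper() != "PDB":
        raise FormatError(f"unsupported format: {format!r}")
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        pdbf = PDBFile.read(str(path))
        atoms = pdbf.get_structure(model=1, altloc="occupancy")
    except Exception as exc:  # biotite raises various parse errors
        raise FormatError(f"could not parse {path} as PDB: {exc}") from exc

    meta = _scan_header(pdbf.lines)

    atoms = atoms[struc.filter_amino_acids(atoms) | (atoms.hetero == False)]  # noqa: E712
    atoms = atoms[np.isin(atoms.atom_name, BACKBONE_ATOMS)]
    if atoms.array_length() == 0:
        raise ContentError(f"{path}: no backbone atoms found")
    chain_ids = list(dict.fromkeys(atoms.chain_id))
    use_chain = chain if chain is not None else chain_ids[0]
    if use_chain not in chain_ids:
        raise ContentError(f"{path}: chain {use_chain!r} not present")
    atoms = atoms[atoms.chain_id == use_chain]

    res_ids = list(dict.fromkeys(atoms.res_id))
    res_ids.sort()
    coords, numbers, missing = [], [], []
    for rid in res_ids:
        sub = atoms[atoms.res_id == rid]
        per_atom = {}
        for name in BACKBONE_ATOMS:
            sel = sub[sub.atom_name == name]
            if sel.array_length() > 0:
                per_atom[name] = sel.coord[0]
        if len(per_atom) == 4:
            coords.append([per_atom[n] for n in BACKBONE_ATOMS])
            numbers.append(int(rid))
        else:
            absent = [n for n in BACKBONE_ATOMS if n not in per_atom]
            missing.append((int(rid), absent))
    if len(coords) < 2:
        detail = "; ".join(f"residue {rid} missing {','.join(a)}" for rid, a in missing[:5])
        raise ContentError(
            f"{path}: fewer than 2 complete backbone residues ({detail or 'none found'})"
        )
    coords = np.array(coords, dtype=float)

    breaks = []
    for i in range(len(numbers) - 1):
        gap = numbers[i + 1] - numbers[i] != 1
        dist = np.linalg.norm(coords[i + 1, 1] - coords[i, 1])
        if gap or dist > CA_CA_MAX:
            breaks.append(i)
    bb = BackboneStructure(
        id=path.stem, coords=coords, chain_breaks=breaks, author_numbers=numbers
    )
    return bb, meta


def write_backbone(
    s: BackboneStructure,
    path: str | Path,
    metadata: StructureMetadata | None = None,
    chain_id: str = "A",
) -> None:
    """Write minimal legal ATOM records (plus header remarks for metadata)."""
    n = s.length
    arr = struc.AtomArray(n * 4)
    arr.coord = s.coords.reshape(-1, 3)
    arr.chain_id = np.full(n * 4, chain_id)
    arr.res_id = np.repeat(np.arange(1, n + 1), 4)
    arr.res_name = np.full(n * 4, "GLY")
    arr.atom_name = np.tile(np.array(BACKBONE_ATOMS), n)
    arr.element = np.tile(np.array(["N", "C", "C", "O"]), n)
    arr.hetero = np.zeros(n * 4, dtype=bool)
    pdbf = PDBFile()
    pdbf.set_structure(arr)
    header: list[str] = []
    if metadata is not None:
        if metadata.method is not None:
            expdta = {
                Method.XRAY: "X-RAY DIFFRACTION",
                Method.EM: "ELECTRON MICROSCOPY",
                Method.NMR: "SOLUTION NMR",
                Method.PREDICTED: "PREDICTED",
                Method.SYNTHETIC: "SYNTHETIC",
            }[metadata.method]
            header.append(f"EXPDTA    {expdta}")
        if metadata.resolution is not None:
            header.append(
                f"REMARK   2 RESOLUTION.    {metadata.resolution:.2f} ANGSTROMS."
            )
        if metadata.r_free is not None:
            header.append(
                f"REMARK   3   FREE R VALUE                     : {metadata.r_free:.3f}"
            )
    pdbf.lines = header + pdbf.lines
    pdbf.write(str(path))


# ---------------------------------------------------------------------------
# Filtering and length matching


def filter_reference_set(
    records: Sequence[tuple[BackboneStructure, StructureMetadata]],
    max_resolution: float = 3.0,
    max_rfree: float = 0.25,
    exclude_nmr: bool = True,
) -> tuple[list[tuple[BackboneStructure, StructureMetadata]], Counter]:
    """Quality-filter a reference set: keep structures with resolution
    strictly below ``max_resolution`` Å, R_free strictly below ``max_rfree``,
    and (by default) no NMR structures. Records missing a required field are
    rejected with reason ``"missing field"``. Returns (kept, rejection
    counts); input order is preserved.
    """
    if not max_resolution > 0 or not max_rfree > 0:
        raise ValueError("thresholds must be positive")
    kept: list[tuple[BackboneStructure, StructureMetadata]] = []
    reasons: Counter = Counter()
    for rec in records:
        _, meta = rec
        if meta.resolution is None or meta.r_free is None:
            reasons["missing field"] += 1
            continue
        if exclude_nmr and meta.method == Method.NMR:
            reasons["nmr"] += 1
            continue
        if not meta.resolution < max_resolution:
            reasons["resolution"] += 1
            continue
        if not meta.r_free < max_rfree:
            reasons["r_free"] += 1
            continue
        kept.append(rec)
    return kept, reasons


def match_length_distribution(
    sample_lengths: Sequence[int],
    reference_lengths: Sequence[int],
    seed: int,
    tolerance: int = 0,
) -> tuple[list[int], dict[int, int]]:
    """Select sample indices so that selected lengths match the reference
    length distribution.

    For each reference length one sample of the same length (or the nearest
    length within ``tolerance``) is drawn without replacement. When a length
    bin is exhausted the draw falls back to with-replacement (with a
    warning); when no candidate exists within tolerance the reference entry
    is recorded as a shortfall. Deterministic given ``seed``.
    """
    if len(sample_lengths) == 0 or len(reference_lengths) == 0:
        raise ValueError("sample and reference length lists must be non-empty")
    rng = np.random.default_rng(seed)
    by_length: dict[int, list[int]] = {}
    for idx, ln in enumerate(sample_lengths):
        by_length.setdefault(int(ln), []).append(idx)
    pools = {ln: list(rng.permutation(ix)) for ln, ix in by_length.items()}
    all_by_length = {ln: list(ix) for ln, ix in by_length.items()}

    selected: list[int] = []
    shortfall: dict[int, int] = {}
    exhausted_draws = 0
    for ref_len in reference_lengths:
        ref_len = int(ref_len)
        candidates = [
            ln for ln in pools if abs(ln - ref_len) <= tolerance and pools[ln]
        ]
        if candidates:
            ln = min(candidates, key=lambda x: (abs(x - ref_len), x))
            selected.append(int(pools[ln].pop()))
            continue
        # bin exists but exhausted -> with replacement
        existing = [
            ln for ln in all_by_length if abs(ln - ref_len) <= tolerance
        ]
        if existing:
            ln = min(existing, key=lambda x: (abs(x - ref_len), x))
            selected.append(int(rng.choice(all_by_length[ln])))
            exhausted_draws += 1
            continue
        shortfall[ref_len] = shortfall.get(ref_len, 0) + 1
    if exhausted_draws:
        warnings.warn(
            f"{exhausted_draws} reference lengths drawn with replacement "
            "(sample length bins exhausted)",
            stacklevel=2,
        )
    return selected, shortfall


# ---------------------------------------------------------------------------
# Structure-set manifests


def read_manifest(
    path: str | Path,
) -> list[tuple[BackboneStructure, StructureMetadata]]:
    """Read a structure-set manifest TSV (columns: id, path, and optionally
    resolution, r_free, method). Manifest metadata overrides header-derived
    values. Relative paths resolve against the manifest's directory.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if "path" not in df.columns:
        raise FormatError(f"{path}: manifest needs a 'path' column")
    out = []
    for _, row in df.iterrows():
        p = Path(row["path"])
        if not p.is_absolute():
            p = path.parent / p
        bb, meta = read_backbone(p)
        if "id" in df.columns and not pd.isna(row.get("id")):
            bb.id = str(row["id"])
        res = row.get("resolution")
        if res is not None and not pd.isna(res):
            meta.resolution = float(res)
        rf = row.get("r_free")
        if rf is not None and not pd.isna(rf):
            meta.r_free = float(rf)
        mth = row.get("method")
        if mth is not None and not pd.isna(mth):
            meta.method = Method(str(mth).upper())
        out.append((bb, meta))
    return out
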