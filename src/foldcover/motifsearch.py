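"""Multi-segment tertiary motif search with a dynamic RMSD threshold.

A tertiary motif is an ordered set of short backbone segments (CA
coordinates). A structure matches when one contiguous, non-overlapping CA
window per segment superposes jointly onto the motif within a per-motif
RMSD cutoff. The cutoff is dynamic: it loosens with motif complexity,

    c(t) = σmax · (1 − 2/(N(N−1)) · Σ_k Σ_{i<j in segment k} e^{(i−j)/L})

where N is the total residue count, n_k the segment lengths, and L a
correlation length (default 20). Motifs made of many short segments have
little intra-segment correlation, so their threshold stays near σmax;
a single long segment is heavily correlated and gets a strict threshold.

The search enumerates candidate windows per segment (pruned by
segment-local RMSD against the same cutoff — a heuristic admissibility
argument validated against exhaustive search on small structures), then
scores each non-overlapping combination by the joint Kabsch RMSD of all
concatenated segments.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._geom import kabsch_rmsd as _kabsch_rmsd
from .structio import BackboneStructure, read_backbone

DEFAULT_SIGMA_MAX = 2.0
DEFAULT_CORRELATION_LENGTH = 20.0
#: combination-enumeration guard per (motif, structure) pair
MAX_COMBINATIONS = 500_000


@dataclass
class Motif:
    """Multi-segment CA query fragment with its threshold parameters."""

    name: str
    segments: list[np.ndarray]  # each (n_k, 3)
    sigma_max: float = DEFAULT_SIGMA_MAX
    correlation_length: float = DEFAULT_CORRELATION_LENGTH

    def __post_init__(self) -> None:
        self.segments = [np.asarray(seg, dtype=float) for seg in self.segments]
        for seg in self.segments:
            if seg.ndim != 2 or seg.shape[1] != 3 or seg.shape[0] < 1:
                raise ValueError("each segment must be a non-empty (n_k, 3) array")
        if self.total_residues < 2:
            raise ValueError("motif needs at least 2 residues in total")
        if not self.sigma_max > 0 or not self.correlation_length > 0:
            raise ValueError("sigma_max and correlation length must be positive")

    @property
    def segment_lengths(self) -> list[int]:
        return [seg.shape[0] for seg in self.segments]

    @property
    def total_residues(self) -> int:
        return sum(self.segment_lengths)


@dataclass
class MatchResult:
    """One motif hit: a (start, stop) CA window per segment plus the joint
    superposition RMSD."""

    structure_id: str
    placements: list[tuple[int, int]]
    rmsd: float


def rmsd_threshold(m: Motif) -> float:
    """Dynamic match cutoff c(t) for a motif (see module docstring).

    Linear in σmax; equals σmax when all segments have length 1 (the
    correlation sum is empty).
    """
    n_total = m.total_residues
    if n_total < 2:
        raise ValueError("threshold undefined for N < 2")
    corr = 0.0
    for n_k in m.segment_lengths:
        for i in range(1, n_k):
            for j in range(i + 1, n_k + 1):
                corr += np.exp((i - j) / m.correlation_length)
    return float(m.sigma_max * (1.0 - 2.0 / (n_total * (n_total - 1)) * corr))


def kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Minimal RMSD over proper rigid transforms (Kabsch; reflections
    excluded). Collinear point sets are solved but flagged with a warning."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    for pts in (a, b):
        if pts.shape[0] >= 3:
            centered = pts - pts.mean(axis=0)
            s = np.linalg.svd(centered, compute_uv=False)
            if s[1] < 1e-9 * max(s[0], 1e-300):
                warnings.warn("degenerate (collinear) point set in superposition", stacklevel=2)
    return _kabsch_rmsd(a, b)


def _segment_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Segment-local optimal RMSD, defined also for 1- and 2-point segments
    (exactly superposable up to a length mismatch)."""
    n = a.shape[0]
    if n == 1:
        return 0.0
    if n == 2:
        da = np.linalg.norm(a[1] - a[0])
        db = np.linalg.norm(b[1] - b[0])
        return abs(da - db) / 2.0
    return _kabsch_rmsd(a, b)


def _candidate_windows(
    m_seg: np.ndarray, s: BackboneStructure, threshold: float
) -> list[tuple[int, int, float]]:
    """All contiguous CA windows (within one chain segment) whose
    segment-local RMSD to the motif segment is <= threshold."""
    n_k = m_seg.shape[0]
    ca = s.ca
    out = []
    for start, stop in s.segments():
        for w0 in range(start, stop - n_k + 1):
            window = ca[w0 : w0 + n_k]
            r = _segment_rmsd(m_seg, window)
            if r <= threshold:
                out.append((w0, w0 + n_k, r))
    return out


def search_motif(
    m: Motif,
    s: BackboneStructure,
    threshold: float | None = None,
    max_matches: int = 100,
    ordered: bool = False,
) -> list[MatchResult]:
    """Find placements of a motif in a structure.

    One candidate window per segment is combined over non-overlapping
    placements; a combination matches when the joint Kabsch RMSD of the
    concatenated segment coordinates is <= threshold (default: the motif's
    dynamic threshold). By default segments may map to windows in any
    sequence order; ``ordered=True`` enforces query order along the chain.
    Results are sorted by RMSD ascending and truncated at ``max_matches``.
    """
    if threshold is None:
        threshold = rmsd_threshold(m)
    if not threshold > 0:
        raise ValueError("threshold must be positive")
    if s.length < m.total_residues:
        return []
    candidates = [_candidate_windows(seg, s, threshold) for seg in m.segments]
    if any(len(c) == 0 for c in candidates):
        return []
    n_comb = int(np.prod([len(c) for c in candidates]))
    if n_comb > MAX_COMBINATIONS:
        warnings.warn(
            f"{n_comb} window combinations exceed the enumeration guard; "
            "truncating candidate lists",
            stacklevel=2,
        )
        keep = max(2, int(MAX_COMBINATIONS ** (1.0 / len(candidates))))
        candidates = [sorted(c, key=lambda t: t[2])[:keep] for c in candidates]
    motif_cat = np.vstack(m.segments)
    ca = s.ca
    results = []
    for combo in itertools.product(*candidates):
        spans = [(w0, w1) for w0, w1, _ in combo]
        ok = True
        for (a0, a1), (b0, b1) in itertools.combinations(spans, 2):
            if a0 < b1 and b0 < a1:
                ok = False
                break
        if not ok:
            continue
        if ordered and any(
            spans[k][0] >= spans[k + 1][0] for k in range(len(spans) - 1)
        ):
            continue
        window_cat = np.vstack([ca[w0:w1] for w0, w1 in spans])
        r = _segment_rmsd(motif_cat, window_cat)
        if r <= threshold:
            results.append(MatchResult(structure_id=s.id, placements=spans, rmsd=r))
    results.sort(key=lambda mr: (mr.rmsd, mr.placements))
    return results[:max_matches]


def count_matches(
    motifs: list[Motif],
    sets: dict[str, list[BackboneStructure]],
    one_per_structure: bool = True,
    ordered: bool = False,
) -> pd.DataFrame:
    """Tabulate motif occurrences across named structure sets.

    Thresholds are recomputed per motif from its own σmax override. By
    default each structure contributes at most one counted match per motif;
    ``one_per_structure=False`` counts all placements.
    """
    rows = []
    for motif in motifs:
        thr = rmsd_threshold(motif)
        for set_name, structures in sets.items():
            count = 0
            for s in structures:
                hits = search_motif(motif, s, threshold=thr, ordered=ordered)
                if hits:
                    count += 1 if one_per_structure else len(hits)
            rows.append(
                {
                    "motif": motif.name,
                    "set": set_name,
                    "count": count,
                    "threshold": thr,
                    "sigma_max": motif.sigma_max,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Motif I/O


def motif_from_structure(
    s: BackboneStructure,
    name: str | None = None,
    sigma_max: float = DEFAULT_SIGMA_MAX,
) -> Motif:
    """Treat a (possibly discontinuous) backbone as a motif: chain breaks
    delimit segments; CA coordinates only."""
    segs = [s.ca[start:stop].copy() for start, stop in s.segments()]
    return Motif(name=name or s.id, segments=segs, sigma_max=sigma_max)


def excise_motif(
    s: BackboneStructure,
    windows: list[tuple[int, int]],
    name: str,
    sigma_max: float = DEFAULT_SIGMA_MAX,
) -> Motif:
    """Cut a motif out of a structure: one CA segment per (start, stop)
    residue window."""
    segs = [s.ca[w0:w1].copy() for w0, w1 in windows]
    return Motif(name=name, segments=segs, sigma_max=sigma_max)


def read_motif(
    path: str | Path,
    sigma_max: float = DEFAULT_SIGMA_MAX,
) -> Motif:
    """Read a motif from a multi-segment PDB fragment (numbering gaps or
    spatial breaks delimit segments)."""
    bb, _ = read_backbone(path)
    return motif_from_structure(bb, name=Path(path).stem, sigma_max=sigma_max)


def read_sigma_overrides(path) -> dict[str, float]:
    """Per-motif σmax override TSV (columns: motif_name, sigma_max)."""
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["motif_name"].astype(str), df["sigma_max"].astype(float)))
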