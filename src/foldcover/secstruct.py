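"""Three-state secondary structure: assignment, content, and the
before/after content vector field.

Assignment is a backbone-torsion window classifier (H / E / L) followed by
minimum-run-length smoothing — a deterministic, backbone-only stand-in for
hydrogen-bond-based assignment. Externally computed 8-state DSSP strings can
be ingested and collapsed to the same 3-state alphabet instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .structio import BackboneStructure
from .synth import backbone_torsions

MIN_RUN = {"H": 4, "E": 3}

# Torsion windows (degrees): helix and extended/sheet basins.
_H_PHI = (-100.0, -30.0)
_H_PSI = (-80.0, -5.0)
_E_PHI = (-170.0, -90.0)
_E_PSI_POS = (90.0, 180.0)
_E_PSI_NEG = (-180.0, -170.0)


@dataclass
class SSContent:
    """Helix / strand / loop fractions; they sum to 1."""

    alpha: float
    beta: float
    loop: float

    def __post_init__(self) -> None:
        for v in (self.alpha, self.beta, self.loop):
            if not 0.0 <= v <= 1.0 + 1e-12:
                raise ValueError("fractions must lie in [0, 1]")
        if abs(self.alpha + self.beta + self.loop - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")


def _raw_label(phi: float, psi: float) -> str:
    if np.isnan(phi) or np.isnan(psi):
        return "L"
    if _H_PHI[0] <= phi <= _H_PHI[1] and _H_PSI[0] <= psi <= _H_PSI[1]:
        return "H"
    if _E_PHI[0] <= phi <= _E_PHI[1] and (
        _E_PSI_POS[0] <= psi <= _E_PSI_POS[1] or _E_PSI_NEG[0] <= psi <= _E_PSI_NEG[1]
    ):
        return "E"
    return "L"


def _enforce_min_runs(labels: list[str]) -> list[str]:
    out = labels[:]
    i = 0
    n = len(out)
    while i < n:
        j = i
        while j < n and out[j] == out[i]:
            j += 1
        lab = out[i]
        if lab in MIN_RUN and (j - i) < MIN_RUN[lab]:
            for k in range(i, j):
                out[k] = "L"
        i = j
    return out


def assign_ss(s: BackboneStructure) -> str:
    """Per-residue H/E/L labels from backbone torsions.

    Termini and residues flanking chain breaks (whose phi or psi is
    undefined) are loops; H runs shorter than 4 and E runs shorter than 3
    are relabeled L.
    """
    if s.length < 3:
        raise ValueError("need at least 3 residues")
    phi, psi, _ = backbone_torsions(s)
    labels = [_raw_label(phi[i], psi[i]) for i in range(s.length)]
    return "".join(_enforce_min_runs(labels))


def ss_content(ss: str) -> SSContent:
    """Fractions of H, E and L over all residues of an SS string."""
    if len(ss) == 0:
        raise ValueError("empty secondary structure string")
    if set(ss) - set("HEL"):
        raise ValueError(f"labels must be H/E/L, got {set(ss) - set('HEL')}")
    n = len(ss)
    return SSContent(ss.count("H") / n, ss.count("E") / n, ss.count("L") / n)


def ss_vector_field(
    pairs: list[tuple[SSContent, SSContent]],
    grid_n: int,
    min_count: int = 3,
) -> pd.DataFrame:
    """Mean displacement field in (alpha, beta) content space.

    Each pair is a structure's content before and after a transformation
    (e.g. partial re-noising and denoising by a generative model). The unit
    square over (alpha, beta) is split into grid_n × grid_n cells; "before"
    points are binned and the per-cell mean of (after − before) is returned
    with its count. Cells with fewer than ``min_count`` pairs are flagged
    low-confidence. Empty cells are absent.
    """
    if not pairs:
        raise ValueError("pairs must be non-empty")
    if grid_n < 1:
        raise ValueError("grid_n must be >= 1")
    width = 1.0 / grid_n
    acc: dict[tuple[int, int], list[np.ndarray]] = {}
    for before, after in pairs:
        if before.alpha + before.beta > 1.0 + 1e-9 or after.alpha + after.beta > 1.0 + 1e-9:
            raise ValueError("content points must lie in the alpha+beta <= 1 simplex")
        col = min(int(before.alpha / width), grid_n - 1)
        row = min(int(before.beta / width), grid_n - 1)
        disp = np.array([after.alpha - before.alpha, after.beta - before.beta])
        acc.setdefault((row, col), []).append(disp)
    rows = []
    for (row, col) in sorted(acc):
        vs = np.array(acc[(row, col)])
        rows.append(
            {
                "row": row,
                "col": col,
                "d_alpha": vs[:, 0].mean(),
                "d_beta": vs[:, 1].mean(),
                "count": len(vs),
                "low_confidence": len(vs) < min_count,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# External DSSP adapter and TSV I/O


_DSSP_TO_3 = {"H": "H", "G": "H", "I": "H", "E": "E", "B": "E"}


def dssp_to_three_state(dssp: str) -> str:
    """Collapse 8-state DSSP letters to H/E/L (H,G,I→H; E,B→E; else L)."""
    return "".join(_DSSP_TO_3.get(c, "L") for c in dssp)


def write_ss_tsv(records: dict[str, str], path) -> None:
    pd.DataFrame(
        {"id": list(records), "ss_string": list(records.values())}
    ).to_csv(path, sep="\t", index=False)


def read_ss_tsv(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["id"].astype(str), df["ss_string"].astype(str)))
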