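"""Fixed-dimension structure embeddings.

Two routes produce the per-structure vectors on which distributional
distances are computed:

* a built-in rotation/translation-invariant geometric encoder: ten
  per-residue descriptor channels (backbone torsions, short-range CA
  distances, nearest-non-adjacent-neighbor geometry), mean-pooled and
  augmented with per-channel standard deviations into a 20-dimensional
  embedding;
* an adapter that reads externally computed per-structure embeddings
  (e.g. mean-pooled encoder states of learned models) from TSV.

Projection to the first two principal components supports the coverage
scatter and raster visualizations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .structio import BackboneStructure, ContentError
from .synth import backbone_torsions
from ._geom import dihedral

DESCRIPTOR_DIM = 10
EMBED_DIM = 2 * DESCRIPTOR_DIM
#: sequence-separation channel is clipped to +/- this value
SEP_CLIP = 16


@dataclass
class EmbeddingMatrix:
    """n structure embeddings with identity, grouping and optional
    designability / length annotations."""

    values: np.ndarray  # (n, d)
    ids: list[str]
    group: list[str]
    designable: np.ndarray | None = None  # (n,) bool
    length: np.ndarray | None = None  # (n,) int
    n_rejected: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        n = self.values.shape[0]
        if len(self.ids) != n or len(self.group) != n:
            raise ValueError("ids/group must match row count")
        if len(set(self.ids)) != n:
            dup = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise ValueError(f"duplicate ids: {dup[:5]}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("embedding values must be finite")
        if self.designable is not None:
            self.designable = np.asarray(self.designable, dtype=bool)
        if self.length is not None:
            self.length = np.asarray(self.length, dtype=int)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def dim(self) -> int:
        return self.values.shape[1]

    def subset(self, mask: np.ndarray) -> "EmbeddingMatrix":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return EmbeddingMatrix(
            values=self.values[idx],
            ids=[self.ids[i] for i in idx],
            group=[self.group[i] for i in idx],
            designable=None if self.designable is None else self.designable[idx],
            length=None if self.length is None else self.length[idx],
        )


def concat_embeddings(mats: list[EmbeddingMatrix]) -> EmbeddingMatrix:
    values = np.vstack([m.values for m in mats])
    ids = [i for m in mats for i in m.ids]
    group = [g for m in mats for g in m.group]
    has_flags = all(m.designable is not None for m in mats)
    desig = np.concatenate([m.designable for m in mats]) if has_flags else None
    has_len = all(m.length is not None for m in mats)
    length = np.concatenate([m.length for m in mats]) if has_len else None
    return EmbeddingMatrix(values, ids, group, desig, length)


# ---------------------------------------------------------------------------
# Built-in geometric encoder


def residue_descriptors(s: BackboneStructure) -> tuple[np.ndarray, np.ndarray]:
    """Per-residue 10-channel geometric descriptors for interior residues.

    Channels: (sin, cos) of phi and psi; CA distances d(i, i+2), d(i, i+3);
    nearest non-adjacent neighbor (|i-j| > 2) CA distance, clipped signed
    sequence separation, and (sin, cos) of the virtual CA dihedral
    CA(i-1)-CA(i)-CA(j)-CA(j+1) (CA(j-1) at the C-terminal edge). All
    channels are invariant to rigid transformation by construction.

    Returns (residue indices, r x 10 matrix).
    """
    n = s.length
    if n < 5:
        raise ContentError("need at least 5 residues for descriptors")
    phi, psi, _ = backbone_torsions(s)
    ca = s.ca
    breaks = set(s.chain_breaks)
    indices, rows = [], []
    for i in range(1, n - 3):
        # window i-1 .. i+3 must be contiguous
        if any(b in breaks for b in range(i - 1, i + 3)):
            continue
        if np.isnan(phi[i]) or np.isnan(psi[i]):
            continue
        cand = [j for j in range(1, n - 1) if abs(i - j) > 2]
        if not cand:
            continue
        dists = np.linalg.norm(ca[cand] - ca[i], axis=1)
        # tie-robust neighbor choice: lowest index among near-minimal
        # distances, so symmetric geometries stay rigid-transform invariant
        d_min = float(dists.min())
        j = cand[int(np.flatnonzero(dists <= d_min + 1e-6)[0])]
        d_nn = d_min
        sep = float(np.clip(j - i, -SEP_CLIP, SEP_CLIP))
        j2 = j + 1 if j + 1 < n else j - 1
        tau = dihedral(ca[i - 1], ca[i], ca[j], ca[j2])
        tau_r = np.radians(tau)
        rows.append(
            [
                np.sin(np.radians(phi[i])),
                np.cos(np.radians(phi[i])),
                np.sin(np.radians(psi[i])),
                np.cos(np.radians(psi[i])),
                float(np.linalg.norm(ca[i + 2] - ca[i])),
                float(np.linalg.norm(ca[i + 3] - ca[i])),
                d_nn,
                sep,
                np.sin(tau_r),
                np.cos(tau_r),
            ]
        )
        indices.append(i)
    if not rows:
        raise ContentError("no residue admits a full descriptor window")
    return np.array(indices), np.array(rows)


def mean_pool(per_residue: np.ndarray) -> np.ndarray:
    """Arithmetic mean over the residue dimension of an (r, k) matrix."""
    per_residue = np.asarray(per_residue, dtype=float)
    if per_residue.ndim != 2 or per_residue.shape[0] < 1:
        raise ValueError("need a non-empty (r, k) matrix")
    return per_residue.mean(axis=0)


def geometric_embed(s: BackboneStructure) -> np.ndarray:
    """20-dimensional structure embedding: per-channel (mean, std) of the
    interior-residue descriptors. Rigid-transform invariant within 1e-6."""
    _, desc = residue_descriptors(s)
    return np.concatenate([mean_pool(desc), desc.std(axis=0, ddof=0)])


def embed_structures(
    structures: list[BackboneStructure], group: str = "set"
) -> EmbeddingMatrix:
    values = np.array([geometric_embed(s) for s in structures])
    return EmbeddingMatrix(
        values=values,
        ids=[s.id for s in structures],
        group=[group] * len(structures),
        length=np.array([s.length for s in structures]),
    )


# ---------------------------------------------------------------------------
# TSV adapter (external encoders)


def read_embeddings(path) -> EmbeddingMatrix:
    """Read an embedding TSV: columns id, group, optional designable,
    optional length, then d numeric embedding columns. Rows containing
    non-finite values are dropped and counted in ``n_rejected``; duplicate
    ids are an error."""
    df = pd.read_csv(path, sep="\t")
    meta_cols = [c for c in ("id", "group", "designable", "length") if c in df.columns]
    if "id" not in meta_cols or "group" not in meta_cols:
        raise ValueError(f"{path}: embedding TSV needs 'id' and 'group' columns")
    num_cols = [c for c in df.columns if c not in meta_cols]
    if not num_cols:
        raise ValueError(f"{path}: no embedding columns found")
    values = df[num_cols].to_numpy(dtype=float)
    finite = np.all(np.isfinite(values), axis=1)
    n_rejected = int((~finite).sum())
    df = df[finite]
    values = values[finite]
    return EmbeddingMatrix(
        values=values,
        ids=df["id"].astype(str).tolist(),
        group=df["group"].astype(str).tolist(),
        designable=(
            df["designable"].astype(bool).to_numpy() if "designable" in df.columns else None
        ),
        length=df["length"].to_numpy(dtype=int) if "length" in df.columns else None,
        n_rejected=n_rejected,
    )


def write_embeddings(e: EmbeddingMatrix, path) -> None:
    data = {"id": e.ids, "group": e.group}
    if e.designable is not None:
        data["designable"] = e.designable
    if e.length is not None:
        data["length"] = e.length
    for k in range(e.dim):
        data[f"e{k}"] = e.values[:, k]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# PCA projection


def pca_project(
    e: EmbeddingMatrix,
    k: int = 2,
    standardize: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Project embeddings onto their first ``k`` principal components.

    The axes are fit on all rows of ``e`` (pool reference and sample rows
    into one matrix to obtain a common plane), centered by the pooled mean,
    optionally standardized. Per-axis sign is fixed so the largest-magnitude
    loading of each component is positive. Returns (n x k coordinates,
    explained-variance fractions).
    """
    if k > e.dim:
        raise ValueError("k cannot exceed embedding dimension")
    if not (e.n > e.dim or e.n >= 10):
        raise ValueError("too few rows for a stable PCA fit")
    x = e.values
    if standardize:
        sd = x.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        x = (x - x.mean(axis=0)) / sd
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(x)
    comps = pca.components_.copy()
    for axis in range(k):
        lead = int(np.argmax(np.abs(comps[axis])))
        if comps[axis, lead] < 0:
            comps[axis] = -comps[axis]
            coords[:, axis] = -coords[:, axis]
    return coords, pca.explained_variance_ratio_


def write_projection(e: EmbeddingMatrix, coords: np.ndarray, path) -> None:
    pd.DataFrame(
        {"id": e.ids, "group": e.group, "pc1": coords[:, 0], "pc2": coords[:, 1]}
    ).to_csv(path, sep="\t", index=False)
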