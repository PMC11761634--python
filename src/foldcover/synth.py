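"""Synthetic fixtures with known ground truth.

Three generators make every metric in the package testable without any
external data or pretrained encoder:

* torsion-specified backbones built by sequential internal-coordinate
  placement (ideal helix, ideal strand, hairpins, mixtures, perturbed
  copies) — ground truth for secondary structure, embeddings, tokens and
  motif search;
* multivariate-Gaussian embedding clouds whose exact Fréchet distance is
  available in closed form — the oracle for the moment-based estimator;
* Markov token streams with a known stationary distribution — the oracle
  for token frequency tables and KL divergence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import sqrtm

from ._geom import dihedral, place_atom
from .structio import BackboneStructure

# Ideal backbone geometry (Engh–Huber-like; internal consistency is what
# matters, not crystallographic exactness).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8

#: Canonical torsion classes (phi, psi) in degrees.
HELIX = (-57.0, -47.0)
STRAND = (-139.0, 135.0)


@dataclass
class TorsionSpec:
    """Per-residue (phi, psi, omega) in degrees; omega defaults to 180."""

    phi: np.ndarray
    psi: np.ndarray
    omega: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        self.psi = np.asarray(self.psi, dtype=float)
        if self.omega is None:
            self.omega = np.full_like(self.phi, 180.0)
        else:
            self.omega = np.asarray(self.omega, dtype=float)
        n = len(self.phi)
        if n < 2:
            raise ValueError("need at least 2 residues")
        if len(self.psi) != n or len(self.omega) != n:
            raise ValueError("phi, psi, omega must have equal length")
        for arr in (self.phi, self.psi, self.omega):
            if np.any(arr <= -180.0) or np.any(arr > 180.0):
                raise ValueError("torsions must lie in (-180, 180]")

    def __len__(self) -> int:
        return len(self.phi)

    @classmethod
    def uniform(cls, n: int, phi: float, psi: float, omega: float = 180.0) -> "TorsionSpec":
        return cls(np.full(n, phi), np.full(n, psi), np.full(n, omega))

    @classmethod
    def helix(cls, n: int) -> "TorsionSpec":
        return cls.uniform(n, *HELIX)

    @classmethod
    def strand(cls, n: int) -> "TorsionSpec":
        return cls.uniform(n, *STRAND)

    @classmethod
    def hairpin(cls, arm: int = 8) -> "TorsionSpec":
        """Two β-strand arms joined by a tight two-residue turn."""
        phi = [STRAND[0]] * arm + [57.0, 78.0] + [STRAND[0]] * arm
        psi = [STRAND[1]] * arm + [38.0, -5.0] + [STRAND[1]] * arm
        return cls(np.array(phi), np.array(psi))

    @classmethod
    def helix_hairpin(cls, helix_n: int = 12, arm: int = 6) -> "TorsionSpec":
        """An α-helix followed by a loop and a β-hairpin (alpha-beta mix)."""
        loop = [(-80.0, 100.0), (-70.0, 150.0), (-100.0, 120.0)]
        hp = cls.hairpin(arm)
        phi = [HELIX[0]] * helix_n + [p for p, _ in loop] + list(hp.phi)
        psi = [HELIX[1]] * helix_n + [s for _, s in loop] + list(hp.psi)
        return cls(np.array(phi), np.array(psi))


def build_backbone(spec: TorsionSpec, id: str = "synthetic") -> BackboneStructure:
    """Build N/CA/C/O coordinates from torsions by sequential NeRF placement.

    phi of the first residue and psi/omega of the last do not define chain
    geometry; psi of the last residue still orients its carbonyl O.
    """
    n = len(spec)
    coords = np.zeros((n, 4, 3))
    # Seed residue 0 in the xy-plane.
    coords[0, 0] = (0.0, 0.0, 0.0)  # N
    coords[0, 1] = (BOND_N_CA, 0.0, 0.0)  # CA
    theta = np.radians(ANGLE_N_CA_C)
    # C at the N-CA-C angle from the CA->N direction, in the xy-plane
    coords[0, 2] = coords[0, 1] + BOND_CA_C * np.array(
        [np.cos(np.pi - theta), np.sin(np.pi - theta), 0.0]
    )
    for i in range(n - 1):
        ni, cai, ci = coords[i, 0], coords[i, 1], coords[i, 2]
        n_next = place_atom(ni, cai, ci, BOND_C_N, ANGLE_CA_C_N, spec.psi[i])
        ca_next = place_atom(cai, ci, n_next, BOND_N_CA, ANGLE_C_N_CA, spec.omega[i])
        c_next = place_atom(ci, n_next, ca_next, BOND_CA_C, ANGLE_N_CA_C, spec.phi[i + 1])
        coords[i + 1, 0] = n_next
        coords[i + 1, 1] = ca_next
        coords[i + 1, 2] = c_next
    # Carbonyl O in the peptide plane, anti to the following N.
    for i in range(n):
        psi = spec.psi[i]
        o_dih = psi + 180.0
        if o_dih > 180.0:
            o_dih -= 360.0
        coords[i, 3] = place_atom(
            coords[i, 0], coords[i, 1], coords[i, 2], BOND_C_O, ANGLE_CA_C_O, o_dih
        )
    return BackboneStructure(id=id, coords=coords)


def backbone_torsions(
    s: BackboneStructure,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Recompute (phi, psi, omega) in degrees from coordinates.

    Undefined entries (termini and residues flanking chain breaks) are NaN:
    phi needs C(i-1), psi and omega need N(i+1)/CA(i+1).
    """
    n = s.length
    phi = np.full(n, np.nan)
    psi = np.full(n, np.nan)
    omega = np.full(n, np.nan)
    breaks = set(s.chain_breaks)
    for i in range(n):
        if i > 0 and (i - 1) not in breaks:
            phi[i] = dihedral(s.coords[i - 1, 2], s.coords[i, 0], s.coords[i, 1], s.coords[i, 2])
        if i < n - 1 and i not in breaks:
            psi[i] = dihedral(s.coords[i, 0], s.coords[i, 1], s.coords[i, 2], s.coords[i + 1, 0])
            omega[i] = dihedral(
                s.coords[i, 1], s.coords[i, 2], s.coords[i + 1, 0], s.coords[i + 1, 1]
            )
    return phi, psi, omega


def perturb_backbone(s: BackboneStructure, amplitude: float, seed: int) -> BackboneStructure:
    """Add i.i.d. zero-mean Gaussian displacement of std ``amplitude`` (Å)
    to every atom. Amplitude 0 returns an identical copy."""
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    coords = s.coords.copy()
    if amplitude > 0:
        rng = np.random.default_rng(seed)
        coords = coords + rng.normal(0.0, amplitude, size=coords.shape)
    return BackboneStructure(
        id=s.id, coords=coords, chain_breaks=list(s.chain_breaks),
        author_numbers=None if s.author_numbers is None else list(s.author_numbers),
    )


# ---------------------------------------------------------------------------
# Gaussian embedding clouds


@dataclass
class GaussianSpec:
    """A d-dimensional Gaussian with known moments, to be sampled as a
    synthetic embedding cloud."""

    mean: np.ndarray
    covariance: np.ndarray
    n: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        self.mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        self.covariance = np.atleast_2d(np.asarray(self.covariance, dtype=float))
        d = self.mean.shape[0]
        if self.covariance.shape != (d, d):
            raise ValueError("covariance shape must match mean dimension")
        if not np.allclose(self.covariance, self.covariance.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")
        w = np.linalg.eigvalsh(self.covariance)
        if w.size and w.min() < -1e-10 * max(w.max(), 1e-300):
            raise ValueError("covariance must be positive semi-definite")

    @property
    def dim(self) -> int:
        return self.mean.shape[0]


def sample_gaussian_embeddings(spec: GaussianSpec) -> np.ndarray:
    """Draw an (n, d) matrix from the spec's Gaussian; deterministic given
    its seed. Degenerate (rank-deficient) covariances are supported."""
    rng = np.random.default_rng(spec.seed)
    w, v = np.linalg.eigh(spec.covariance)
    w = np.clip(w, 0.0, None)
    root = v * np.sqrt(w)
    z = rng.standard_normal((spec.n, spec.dim))
    return spec.mean + z @ root.T


def analytic_fpd(a: GaussianSpec, b: GaussianSpec) -> float:
    """Closed-form Fréchet (2-Wasserstein²) distance between the two specs'
    true Gaussians: ||μa-μb||² + Tr(Σa + Σb - 2(ΣaΣb)^{1/2}).

    Serves as the independent oracle for the moment-estimated distance; the
    matrix square root here deliberately uses the general (non-symmetrized)
    product route.
    """
    if a.dim != b.dim:
        raise ValueError("dimension mismatch")
    dmu = a.mean - b.mean
    prod = a.covariance @ b.covariance
    root = sqrtm(prod)
    if np.iscomplexobj(root):
        root = root.real
    val = float(dmu @ dmu + np.trace(a.covariance + b.covariance - 2.0 * root))
    return max(val, 0.0)


def random_psd_spec(
    d: int, rng: np.random.Generator, n: int = 1000, mean_scale: float = 1.0
) -> GaussianSpec:
    """Random Gaussian spec with QΛQᵀ covariance, eigenvalues log-uniform in
    [1e-3, 10] to exercise ill-conditioned square roots."""
    m = rng.standard_normal((d, d))
    q, r = np.linalg.qr(m)
    q = q @ np.diag(np.sign(np.diag(r)))
    lam = 10.0 ** rng.uniform(-3, 1, size=d)
    cov = (q * lam) @ q.T
    cov = 0.5 * (cov + cov.T)
    mean = rng.normal(0.0, mean_scale, size=d)
    return GaussianSpec(mean=mean, covariance=cov, n=n, seed=int(rng.integers(2**31)))


# ---------------------------------------------------------------------------
# Markov token streams


def stationary_distribution(transition: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (left eigenvector
    of eigenvalue 1, normalized)."""
    transition = np.asarray(transition, dtype=float)
    w, v = np.linalg.eig(transition.T)
    idx = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, idx])
    pi = np.abs(pi)
    return pi / pi.sum()


def sample_markov_tokens(
    transition: np.ndarray, lengths: list[int], seed: int
) -> list[np.ndarray]:
    """Sample token sequences from a first-order Markov chain started at its
    stationary distribution. Deterministic given ``seed``; sampling is
    vectorized across sequences."""
    transition = np.asarray(transition, dtype=float)
    if transition.ndim != 2 or transition.shape[0] != transition.shape[1]:
        raise ValueError("transition must be square")
    rowsum = transition.sum(axis=1)
    if not np.allclose(rowsum, 1.0, atol=1e-9):
        raise ValueError("transition rows must sum to 1")
    rng = np.random.default_rng(seed)
    pi = stationary_distribution(transition)
    cum_pi = np.cumsum(pi)
    cum_t = np.cumsum(transition, axis=1)
    nseq = len(lengths)
    maxlen = max(lengths)
    lengths_arr = np.asarray(lengths)
    out = np.zeros((nseq, maxlen), dtype=np.int64)
    u0 = rng.random(nseq)
    out[:, 0] = np.searchsorted(cum_pi, u0, side="right")
    for t in range(1, maxlen):
        active = lengths_arr > t
        if not np.any(active):
            break
        u = rng.random(nseq)
        nxt = (cum_t[out[:, t - 1]] < u[:, None]).sum(axis=1)
        out[active, t] = nxt[active]
    return [out[i, : lengths[i]].copy() for i in range(nseq)]


# ---------------------------------------------------------------------------
# On-disk fixture sets


@dataclass
class FixtureManifest:
    ids: list[str] = field(default_factory=list)
    paths: list[str] = field(default_factory=list)


def make_structure_set(
    n: int,
    seed: int,
    classes: tuple[str, ...] = ("helix", "strand", "hairpin", "mixed"),
    length_range: tuple[int, int] = (24, 48),
    jitter: float = 0.05,
    prefix: str = "synth",
) -> list[BackboneStructure]:
    """Generate a diverse synthetic structure set: torsion-class backbones
    of varying length, each lightly perturbed in Cartesian space."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        cls = classes[int(rng.integers(len(classes)))]
        ln = int(rng.integers(length_range[0], length_range[1] + 1))
        if cls == "helix":
            spec = TorsionSpec.helix(ln)
        elif cls == "strand":
            spec = TorsionSpec.strand(ln)
        elif cls == "hairpin":
            spec = TorsionSpec.hairpin(arm=max(4, ln // 2 - 1))
        else:
            spec = TorsionSpec.helix_hairpin(helix_n=max(6, ln // 2), arm=max(4, ln // 4))
        s = build_backbone(spec, id=f"{prefix}_{cls}_{i:04d}")
        if jitter > 0:
            s = perturb_backbone(s, jitter, seed=int(rng.integers(2**31)))
        out.append(s)
    return out
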