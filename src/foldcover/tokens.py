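"""Discrete structural alphabet: tokenization, length-binned n-gram
frequencies, and KL divergence between token distributions.

Continuous embeddings can be compared through their moments; discrete
per-residue tokens cannot be mean-pooled, so structure sets are compared by
counting token frequencies per protein-length range — single tokens
(unigrams) and adjacent pairs (bigrams) — and computing the KL divergence
between reference and sample tables.

The built-in alphabet is a seeded centroid quantization (k-means) of the
geometric residue descriptors; externally computed 20-letter structural
alphabet strings (e.g. 3Di) are ingested through a letter adapter instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .structio import BackboneStructure
from .embed import residue_descriptors

DEFAULT_ALPHABET_SIZE = 20
#: default length bins: width 50 from 0 to 500, plus one overflow bin
DEFAULT_BIN_EDGES = tuple(range(0, 501, 50))
THREE_DI_LETTERS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class Codebook:
    """A structural alphabet: one centroid per token in descriptor space."""

    centroids: np.ndarray  # (A, k)
    fit_seed: int = 0

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        if self.centroids.ndim != 2 or self.centroids.shape[0] < 2:
            raise ValueError("need at least 2 centroids")
        if len(np.unique(self.centroids, axis=0)) != self.centroids.shape[0]:
            raise ValueError("centroids must be pairwise distinct")

    @property
    def alphabet_size(self) -> int:
        return self.centroids.shape[0]


@dataclass
class TokenSequence:
    """Per-residue token indices in [0, A); ``breaks`` lists positions t
    after which adjacency is interrupted (chain break or skipped residue),
    so (t, t+1) forms no bigram."""

    tokens: np.ndarray
    breaks: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.tokens = np.asarray(self.tokens, dtype=int)

    def __len__(self) -> int:
        return len(self.tokens)


def fit_codebook(
    descriptors: np.ndarray,
    alphabet_size: int = DEFAULT_ALPHABET_SIZE,
    seed: int = 0,
) -> Codebook:
    """Fit an alphabet by k-means over pooled residue descriptors.

    Requires at least 10 rows per token. Centroids are sorted
    lexicographically so the token indexing is canonical for a given fit.
    """
    descriptors = np.asarray(descriptors, dtype=float)
    if descriptors.ndim != 2:
        raise ValueError("descriptors must be (rows, k)")
    if descriptors.shape[0] < 10 * alphabet_size:
        raise ValueError(
            f"need >= {10 * alphabet_size} descriptor rows for A={alphabet_size}"
        )
    km = KMeans(n_clusters=alphabet_size, random_state=seed, n_init=10)
    km.fit(descriptors)
    cents = km.cluster_centers_
    order = np.lexsort(cents.T[::-1])
    return Codebook(centroids=cents[order], fit_seed=seed)


def assign_tokens(descriptors: np.ndarray, codebook: Codebook) -> np.ndarray:
    """Nearest-centroid (Euclidean) token per descriptor row; exact ties
    resolve to the lower token index (argmin convention)."""
    d2 = ((descriptors[:, None, :] - codebook.centroids[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d2, axis=1)


def tokenize(s: BackboneStructure, codebook: Codebook) -> TokenSequence:
    """Token sequence of a structure: one token per residue with a defined
    descriptor; adjacency breaks recorded where descriptor residues are not
    sequence-consecutive."""
    indices, desc = residue_descriptors(s)
    toks = assign_tokens(desc, codebook)
    breaks = [t for t in range(len(indices) - 1) if indices[t + 1] != indices[t] + 1]
    return TokenSequence(tokens=toks, breaks=breaks)


# ---------------------------------------------------------------------------
# Frequency tables


@dataclass
class FrequencyTable:
    """Length-binned, Laplace-smoothed unigram/bigram probability tables.

    Bin b covers lengths in [edges[b], edges[b+1]); the final row is an
    overflow bin for lengths beyond the last edge. ``unigram_counts`` /
    ``bigram_counts`` hold raw (pre-smoothing) totals per bin, used as
    aggregation weights.
    """

    bin_edges: np.ndarray
    unigram: np.ndarray  # (B, A)
    bigram: np.ndarray  # (B, A, A)
    unigram_counts: np.ndarray  # (B,)
    bigram_counts: np.ndarray  # (B,)
    pseudocount: float

    @property
    def n_bins(self) -> int:
        return self.unigram.shape[0]

    @property
    def alphabet_size(self) -> int:
        return self.unigram.shape[1]


def _bin_index(length: int, edges: np.ndarray) -> int:
    b = int(np.searchsorted(edges, length, side="right")) - 1
    if b < 0:
        b = 0
    if b >= len(edges) - 1:
        return len(edges) - 1  # overflow row
    return b


def count_frequencies(
    seqs: list[tuple[TokenSequence, int]],
    alphabet_size: int,
    bin_edges=DEFAULT_BIN_EDGES,
    pseudocount: float = 1.0,
) -> FrequencyTable:
    """Accumulate unigram and bigram counts per length bin and normalize
    with Laplace smoothing.

    Bigrams pair sequence-adjacent tokens within one sequence only, never
    across sequences or recorded adjacency breaks. Lengths beyond the last
    edge are routed to the overflow bin with a warning.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    edges = np.asarray(bin_edges, dtype=int)
    n_bins = len(edges)  # len(edges)-1 regular + 1 overflow
    uni = np.zeros((n_bins, alphabet_size))
    bi = np.zeros((n_bins, alphabet_size, alphabet_size))
    overflow = 0
    for seq, length in seqs:
        b = _bin_index(length, edges)
        if b == n_bins - 1:
            overflow += 1
        toks = seq.tokens
        if np.any(toks < 0) or np.any(toks >= alphabet_size):
            raise ValueError("token outside alphabet")
        np.add.at(uni[b], toks, 1)
        stop = set(seq.breaks)
        for t in range(len(toks) - 1):
            if t not in stop:
                bi[b, toks[t], toks[t + 1]] += 1
    if overflow:
        warnings.warn(f"{overflow} sequences routed to the overflow length bin", stacklevel=2)
    uni_counts = uni.sum(axis=1)
    bi_counts = bi.sum(axis=(1, 2))
    uni_s = uni + pseudocount
    bi_s = bi + pseudocount
    with np.errstate(invalid="ignore", divide="ignore"):
        uni_p = uni_s / uni_s.sum(axis=1, keepdims=True)
        bi_p = bi_s / bi_s.sum(axis=(1, 2), keepdims=True)
    if pseudocount == 0:
        uni_p = np.where(uni_s.sum(axis=1, keepdims=True) > 0, uni_p, 0.0)
        bi_p = np.where(bi_s.sum(axis=(1, 2), keepdims=True) > 0, bi_p, 0.0)
    return FrequencyTable(
        bin_edges=edges,
        unigram=uni_p,
        bigram=bi_p,
        unigram_counts=uni_counts,
        bigram_counts=bi_counts,
        pseudocount=pseudocount,
    )


# ---------------------------------------------------------------------------
# KL divergence


def kl_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """KL(p || q) in nats, with the 0·ln(0/q) = 0 convention. Raises if q
    has mass zero where p does not (cannot occur after smoothing)."""
    p = np.asarray(p, dtype=float).ravel()
    q = np.asarray(q, dtype=float).ravel()
    if p.shape != q.shape:
        raise ValueError("p and q must have equal length")
    if abs(p.sum() - 1.0) > 1e-6 or abs(q.sum() - 1.0) > 1e-6:
        raise ValueError("p and q must each sum to 1")
    support = p > 0
    if np.any(q[support] <= 0):
        raise ValueError("q has zero mass on the support of p")
    return float(np.sum(p[support] * np.log(p[support] / q[support])))


def kl_tables(reference: FrequencyTable, sample: FrequencyTable) -> dict:
    """Per-bin and reference-count-weighted aggregate KL divergences between
    two frequency tables, in both n-gram orders.

    Direction is KL(reference || sample): geometries present in the
    reference but missing from the samples dominate. The reverse direction
    is reported alongside. Bins with zero reference tokens are skipped.
    """
    if reference.alphabet_size != sample.alphabet_size or reference.n_bins != sample.n_bins:
        raise ValueError("tables must share alphabet and binning")
    out: dict = {"per_bin": [], "unigram": np.nan, "bigram": np.nan}
    uw = bw = 0.0
    uacc = bacc = 0.0
    uacc_rev = bacc_rev = 0.0
    for b in range(reference.n_bins):
        w_u = reference.unigram_counts[b]
        w_b = reference.bigram_counts[b]
        if w_u == 0:
            continue
        kl_u = kl_divergence(reference.unigram[b], sample.unigram[b])
        kl_b = (
            kl_divergence(reference.bigram[b].ravel(), sample.bigram[b].ravel())
            if w_b > 0
            else np.nan
        )
        kl_u_rev = kl_divergence(sample.unigram[b], reference.unigram[b])
        out["per_bin"].append(
            {
                "bin": b,
                "lo": int(reference.bin_edges[b]) if b < len(reference.bin_edges) - 1 else int(reference.bin_edges[-1]),
                "unigram_kl": kl_u,
                "bigram_kl": kl_b,
                "unigram_kl_reverse": kl_u_rev,
                "ref_tokens": float(w_u),
            }
        )
        uacc += w_u * kl_u
        uacc_rev += w_u * kl_u_rev
        uw += w_u
        if w_b > 0 and not np.isnan(kl_b):
            bacc += w_b * kl_b
            bacc_rev += w_b * kl_divergence(
                sample.bigram[b].ravel(), reference.bigram[b].ravel()
            )
            bw += w_b
    out["unigram"] = uacc / uw if uw else np.nan
    out["bigram"] = bacc / bw if bw else np.nan
    out["unigram_reverse"] = uacc_rev / uw if uw else np.nan
    out["bigram_reverse"] = bacc_rev / bw if bw else np.nan
    return out


# ---------------------------------------------------------------------------
# Serialization and external-alphabet adapters


def letters_to_tokens(letters: str, alphabet: str = THREE_DI_LETTERS) -> TokenSequence:
    """Map a structural-alphabet letter string to integer tokens."""
    lut = {c: i for i, c in enumerate(alphabet)}
    try:
        toks = [lut[c] for c in letters.upper()]
    except KeyError as exc:
        raise ValueError(f"unknown alphabet letter {exc.args[0]!r}") from exc
    return TokenSequence(tokens=np.array(toks, dtype=int))


def save_codebook(c: Codebook, path) -> None:
    a, k = c.centroids.shape
    header = f"# A={a} k={k} fit_seed={c.fit_seed}"
    np.savetxt(path, c.centroids, header=header, comments="")


def load_codebook(path) -> Codebook:
    with open(path) as fh:
        header = fh.readline().strip()
    fields = dict(tok.split("=") for tok in header.lstrip("# ").split())
    cents = np.loadtxt(path, skiprows=1, ndmin=2)
    return Codebook(centroids=cents, fit_seed=int(fields.get("fit_seed", 0)))


def write_token_tsv(records: list[tuple[str, int, TokenSequence]], path) -> None:
    rows = [
        {"id": sid, "length": length, "tokens": ",".join(map(str, seq.tokens))}
        for sid, length, seq in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_token_tsv(path) -> list[tuple[str, int, TokenSequence]]:
    """Read a token TSV (id, length, tokens). The tokens column holds either
    comma-separated integers or a bare structural-alphabet letter string."""
    df = pd.read_csv(Path(path), sep="\t")
    out = []
    for _, row in df.iterrows():
        raw = str(row["tokens"])
        if "," in raw or raw.isdigit():
            seq = TokenSequence(np.array([int(t) for t in raw.split(",")]))
        else:
            seq = letters_to_tokens(raw)
        out.append((str(row["id"]), int(row["length"]), seq))
    return out
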