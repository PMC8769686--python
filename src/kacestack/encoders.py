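"""Feature encodings for K-centred peptide fragments.

Eleven encodings map a fragment (default length 21 over the 21-symbol
alphabet) to a numeric vector; their ordered concatenation is the
2616-D *hybrid* representation:

======== ===== =================================================
tag        dim  description
======== ===== =================================================
AAI        525  mean physicochemical index value over non-dummy residues
AAC         21  amino-acid composition (counts / L)
DPC        441  dipeptide composition (counts / (L-1))
CKSAAGP    150  k-spaced residue-group pair composition, k = 0..5
CTF        343  conjoint-triad composition over 7 residue classes
Zscale     105  five Sandberg z-scales per position
BINA       441  positional one-hot over the 21-symbol alphabet
BLOS       420  BLOSUM62 row (20 scores) per position
GTPC       125  residue-group tripeptide composition
GDPC        25  residue-group dipeptide composition
NRF         20  alphabetical-rank value per flank position
======== ===== =================================================

A twelfth encoding, KNN, is kept apart from the hybrid: for each
neighbor-set size X it reports the fraction of positive fragments among
the query's X nearest training fragments under a normalized-BLOSUM62
distance.  Because the features are computed *from labels*, a sample
that can reach its own label through the pool inflates cross-validation
estimates; ``leave_one_out=True`` removes each query from its own
neighbor set (see ``evaluation.knn_leakage_audit``).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import resources
from .fragments import FragmentDataset, PeptideFragment
from .resources import ALPHABET, RANK_ALPHABET, STANDARD_RESIDUES

#: Conjoint-triad residue classes (dummy symbol joins the first class).
CTF_CLASSES: tuple[str, ...] = ("VGAO", "PFLI", "STMY", "WQNH", "RK", "ED", "C")

#: Five physicochemical residue groups (dummy symbol joins 'uncharged').
GROUP5: dict[str, str] = {
    "aliphatic": "IMLVAG",
    "aromatic": "WYF",
    "pos": "HRK",
    "neg": "ED",
    "uncharged": "QNPCTSO",
}

#: Hybrid concatenation order.
HYBRID_ORDER: tuple[str, ...] = (
    "AAI", "AAC", "DPC", "CKSAAGP", "CTF", "Zscale",
    "BINA", "BLOS", "GTPC", "GDPC", "NRF",
)

DEFAULT_NEIGHBOR_COUNTS: tuple[int, ...] = (2, 4, 8, 16, 32, 64, 128)


class EncodingError(ValueError):
    pass


@dataclass
class EncodingConfig:
    """Tables and layout parameters shared by all encoders."""

    window: int = 21
    alphabet: str = ALPHABET
    aai_table: pd.DataFrame | None = None      # rows: index names, cols: residues
    zscale_table: pd.DataFrame | None = None   # rows: residues, cols: z1..z5
    blosum62: pd.DataFrame | None = None       # 20x20, standard residues
    ctf_classes: tuple[str, ...] = CTF_CLASSES
    group5: dict[str, str] = field(default_factory=lambda: dict(GROUP5))
    cksaagp_k_max: int = 5

    def __post_init__(self) -> None:
        if len(set(self.alphabet)) != len(self.alphabet):
            raise EncodingError("alphabet symbols must be distinct")
        if self.aai_table is None:
            self.aai_table = resources.default_aai_table()
        if self.zscale_table is None:
            self.zscale_table = resources.zscale_table()
        if self.blosum62 is None:
            self.blosum62 = resources.blosum62()
        for name, partition in (("ctf_classes", self.ctf_classes),
                                ("group5", tuple(self.group5.values()))):
            joined = "".join(partition)
            if sorted(joined) != sorted(self.alphabet):
                # partitions only have to cover the default alphabet; toy
                # alphabets supply their own partitions
                if self.alphabet == ALPHABET:
                    raise EncodingError(f"{name} does not partition the alphabet")
        if self.cksaagp_k_max < 0:
            raise EncodingError("cksaagp_k_max must be >= 0")
        if self.cksaagp_k_max >= self.window - 1:
            raise EncodingError("cksaagp_k_max must be < window - 1")


@dataclass
class FeatureBlock:
    """A named n x d feature matrix produced by one encoder."""

    matrix: np.ndarray
    feature_names: list[str]
    encoding_tag: str

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise EncodingError(f"{self.encoding_tag}: matrix must be 2-D")
        if self.matrix.shape[1] != len(self.feature_names):
            raise EncodingError(
                f"{self.encoding_tag}: {self.matrix.shape[1]} columns but "
                f"{len(self.feature_names)} names"
            )
        if np.isnan(self.matrix).any():
            raise EncodingError(f"{self.encoding_tag}: NaN values in feature matrix")

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]


@dataclass
class HybridFeatureMatrix(FeatureBlock):
    """Concatenation of encoder blocks; remembers each block's column span."""

    block_slices: dict[str, slice] = field(default_factory=dict)


def _as_sequences(fragments) -> list[str]:
    if isinstance(fragments, FragmentDataset):
        return fragments.sequences
    out = []
    for f in fragments:
        out.append(f.residues if isinstance(f, PeptideFragment) else str(f))
    return out


def _indices(seqs: Sequence[str], alphabet: str, window: int) -> np.ndarray:
    """Map sequences to an (n, window) integer array over ``alphabet``."""
    lut = np.full(128, -1, dtype=np.int64)
    for i, ch in enumerate(alphabet):
        lut[ord(ch)] = i
    if not seqs:
        return np.zeros((0, window), dtype=np.int64)
    arr = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    if arr.size != len(seqs) * window:
        lens = {len(s) for s in seqs}
        raise EncodingError(f"fragments must all have length {window}, got {lens}")
    idx = lut[arr].reshape(len(seqs), window)
    if (idx < 0).any():
        bad = sorted({chr(c) for c in arr[lut[arr] < 0]})
        raise EncodingError(f"symbols outside alphabet: {bad}")
    return idx


def _kmer_profile(idx: np.ndarray, n_symbols: int, k: int) -> np.ndarray:
    """Overlapping k-mer composition: counts / (L - k + 1), row-major order."""
    n, L = idx.shape
    nwin = L - k + 1
    if nwin < 1:
        raise EncodingError(f"window too short for {k}-mers")
    code = np.zeros((n, nwin), dtype=np.int64)
    for j in range(k):
        code = code * n_symbols + idx[:, j:j + nwin]
    out = np.zeros((n, n_symbols ** k), dtype=float)
    rows = np.repeat(np.arange(n), nwin)
    np.add.at(out, (rows, code.ravel()), 1.0)
    return out / nwin


def _gapped_pair_profile(idx: np.ndarray, n_symbols: int, gap: int) -> np.ndarray:
    """Ordered pair composition at separation ``gap``: counts / (L - gap - 1)."""
    n, L = idx.shape
    npair = L - gap - 1
    if npair < 1:
        raise EncodingError(f"window too short for gap {gap}")
    code = idx[:, :npair] * n_symbols + idx[:, gap + 1:]
    out = np.zeros((n, n_symbols ** 2), dtype=float)
    rows = np.repeat(np.arange(n), npair)
    np.add.at(out, (rows, code.ravel()), 1.0)
    return out / npair


def _group_indices(idx: np.ndarray, alphabet: str,
                   partition: Iterable[str]) -> tuple[np.ndarray, int]:
    groups = list(partition)
    gmap = np.full(len(alphabet), -1, dtype=np.int64)
    for g, members in enumerate(groups):
        for ch in members:
            if ch in alphabet:
                gmap[alphabet.index(ch)] = g
    if (gmap < 0).any():
        missing = [alphabet[i] for i in np.flatnonzero(gmap < 0)]
        raise EncodingError(f"residues not covered by partition: {missing}")
    return gmap[idx], len(groups)


def _flank_positions(window: int) -> list[int]:
    """Center-relative offsets, upstream then downstream, center excluded."""
    half = (window - 1) // 2
    return [o for o in range(-half, half + 1) if o != 0]


def _position_names(window: int) -> list[str]:
    half = (window - 1) // 2
    return [f"{o:+d}" if o else "0" for o in range(-half, half + 1)]


# ---------------------------------------------------------------------------
# the eleven hybrid encoders


def encode_nrf(fragments, config: EncodingConfig | None = None) -> FeatureBlock:
    """Alphabetical-rank value (rank x 0.1) per flank position; center dropped."""
    config = config or EncodingConfig()
    seqs = _as_sequences(fragments)
    idx = _indices(seqs, config.alphabet, config.window)
    rank = np.array(
        [RANK_ALPHABET.index(ch) * 0.1 if ch in RANK_ALPHABET
         else config.alphabet.index(ch) * 0.1
         for ch in config.alphabet]
    )
    center = (config.window - 1) // 2
    keep = [j for j in range(config.window) if j != center]
    names = [f"NRF:p{o:+d}" for o in _flank_positions(config.window)]
    return FeatureBlock(rank[idx[:, keep]], names, "NRF")


def encode_bina(fragments, config: EncodingConfig | None = None) -> FeatureBlock:
    """Positional one-hot over the alphabet ('O' at the last index)."""
    config = config or EncodingConfig()
    idx = _indices(_as_sequences(fragments), config.alphabet, config.window)
    n, L = idx.shape
    A = len(config.alphabet)
    out = np.zeros((n, L * A), dtype=float)
    cols = np.arange(L) * A + idx
    np.put_along_axis(out, cols, 1.0, axis=1)
    names = [
        f"BINA:p{p}:{ch}"
        for p in _position_names(config.window) for ch in config.alphabet
    ]
    return FeatureBlock(out, names, "BINA")


def encode_aac(fragments, config: EncodingConfig | None = None) -> FeatureBlock:
    config = config or EncodingConfig()
    idx = _indices(_as_sequences(fragments), config.alphabet, config.window)
    prof = _kmer_profile(idx, len(config.alphabet), 1)
    return FeatureBlock(prof, [f"AAC:{c}" for c in config.alphabet], "AAC")


def encode_dpc(fragments, config: EncodingConfig | None = None) -> FeatureBlock:
    config = config or EncodingConfig()
    idx = _indices(_as_sequences(fragments), config.alphabet, config.window)
    prof = _kmer_profile(idx, len(config.alphabet), 2)
    names = [f"DPC:{a}{b}" for a in config.alphabet for b in config.alphabet]
    return FeatureBlock(prof, names, "DPC")


def encode_ctf(fragments, config: EncodingConfig | None = None) -> FeatureBlock:
    """Conjoint-triad composition over the 7 residue classes."""
    config = config or EncodingConfig()
    idx = _indices(_as_sequences(fragments), config.alphabet, config.window)
    gidx, ng = _group_indices(idx, config.alphabet, config.ctf_classes)
    prof = _kmer_profile(gidx, ng, 3)
    names = [
        f"CTF:c{a + 1}c{b + 1}c{c + 1}"
        for a in range(ng) for b in range(ng) for c in range(ng)
    ]
    return FeatureBlock(prof, names, "CTF")


def encode_aai(fragments, config: EncodingConfig | None = None) -> FeatureBlock:
    """Mean of each property index over the fragment's non-dummy residues."""
    config = config or EncodingConfig()
    table = config.aai_table
    missing = set(STANDARD_RESIDUES) - set(table.columns)
    if missing and config.alphabet == ALPHABET:
        raise EncodingError(f"aai_table missing residues: {sorted(missing)}")
    idx = _indices(_as_sequences(fragments), config.alphabet, config.window)
    # per-residue value matrix, with a 0 row for symbols absent from the table
    vals = np.zeros((len(config.alphabet), len(table.index)), dtype=float)
    informative = np.zeros(len(config.alphabet), dtype=bool)
    for i, ch in enumerate(config.alphabet):
        if ch in table.columns:
            vals[i] = table[ch].to_numpy()
            informative[i] = True
    counts = informative[idx].sum(axis=1)
    if (counts == 0).any():
        raise EncodingError("fragment with no standard residues")
    sums = vals[idx].sum(axis=1)
    out = sums / counts[:, None]
    return FeatureBlock(out, [f"AAI:{name}" for name in table.index], "AAI")


def encode_gdpc(fragments, config: EncodingConfig | None = None) -> FeatureBlock:
    config = config or EncodingConfig()
    idx = _indices(_as_sequences(fragments), config.alphabet, config.window)
    gidx, ng = _group_indices(idx, config.alphabet, config.group5.values())
    prof = _kmer_profile(gidx, ng, 2)
    gnames = list(config.group5)
    names = [f"GDPC:{a}.{b}" for a in gnames for b in gnames]
    return FeatureBlock(prof, names, "GDPC")


def encode_gtpc(fragments, config: EncodingConfig | None = None) -> FeatureBlock:
    config = config or EncodingConfig()
    idx = _indices(_as_sequences(fragments), config.alphabet, config.window)
    gidx, ng = _group_indices(idx, config.alphabet, config.group5.values())
    prof = _kmer_profile(gidx, ng, 3)
    gnames = list(config.group5)
    names = [f"GTPC:{a}.{b}.{c}" for a in gnames for b in gnames for c in gnames]
    return FeatureBlock(prof, names, "GTPC")


def encode_cksaagp(fragments, config: EncodingConfig | None = None) -> FeatureBlock:
    """k-spaced residue-group pair composition for k = 0..k_max."""
    config = config or EncodingConfig()
    idx = _indices(_as_sequences(fragments), config.alphabet, config.window)
    gidx, ng = _group_indices(idx, config.alphabet, config.group5.values())
    gnames = list(config.group5)
    blocks, names = [], []
    for k in range(config.cksaagp_k_max + 1):
        blocks.append(_gapped_pair_profile(gidx, ng, k))
        names.extend(f"CKSAAGP:k{k}:{a}.{b}" for a in gnames for b in gnames)
    return FeatureBlock(np.hstack(blocks), names, "CKSAAGP")


def encode_zscale(fragments, config: EncodingConfig | None = None) -> FeatureBlock:
    """Sandberg z1..z5 per position; dummy symbol contributes five zeros."""
    config = config or EncodingConfig()
    idx = _indices(_as_sequences(fragments), config.alphabet, config.window)
    table = config.zscale_table
    vals = np.zeros((len(config.alphabet), 5), dtype=float)
    for i, ch in enumerate(config.alphabet):
        if ch in table.index:
            vals[i] = table.loc[ch].to_numpy()
    out = vals[idx].reshape(idx.shape[0], -1)
    names = [
        f"Zscale:p{p}:z{z}"
        for p in _position_names(config.window) for z in range(1, 6)
    ]
    return FeatureBlock(out, names, "Zscale")


def encode_blosum62(fragments, config: EncodingConfig | None = None) -> FeatureBlock:
    """BLOSUM62 row (scores vs the 20 standard residues) per position."""
    config = config or EncodingConfig()
    idx = _indices(_as_sequences(fragments), config.alphabet, config.window)
    b62 = config.blosum62
    vals = np.zeros((len(config.alphabet), 20), dtype=float)
    for i, ch in enumerate(config.alphabet):
        if ch in b62.index:
            vals[i] = b62.loc[ch, list(STANDARD_RESIDUES)].to_numpy()
    out = vals[idx].reshape(idx.shape[0], -1)
    names = [
        f"BLOS:p{p}:{ch}"
        for p in _position_names(config.window) for ch in STANDARD_RESIDUES
    ]
    return FeatureBlock(out, names, "BLOS")


_ENCODERS = {
    "AAI": encode_aai,
    "AAC": encode_aac,
    "DPC": encode_dpc,
    "CKSAAGP": encode_cksaagp,
    "CTF": encode_ctf,
    "Zscale": encode_zscale,
    "BINA": encode_bina,
    "BLOS": encode_blosum62,
    "GTPC": encode_gtpc,
    "GDPC": encode_gdpc,
    "NRF": encode_nrf,
}

#: Hybrid block dimensions at the default configuration.
DEFAULT_BLOCK_DIMS = {
    "AAI": 525, "AAC": 21, "DPC": 441, "CKSAAGP": 150, "CTF": 343,
    "Zscale": 105, "BINA": 441, "BLOS": 420, "GTPC": 125, "GDPC": 25, "NRF": 20,
}
HYBRID_DIM = sum(DEFAULT_BLOCK_DIMS.values())  # 2616


def encode_hybrid(
    fragments,
    config: EncodingConfig | None = None,
    tags: Sequence[str] | None = None,
) -> HybridFeatureMatrix:
    """Concatenate encoder blocks in the fixed hybrid order.

    ``tags`` restricts the blocks (order is still the hybrid order); the
    default is all eleven, giving 2616 columns at the default config.
    """
    config = config or EncodingConfig()
    use = tuple(tags) if tags is not None else HYBRID_ORDER
    unknown = set(use) - set(HYBRID_ORDER)
    if unknown:
        raise EncodingError(f"unknown encoder tags: {sorted(unknown)}")
    use = tuple(t for t in HYBRID_ORDER if t in use)
    blocks = []
    for tag in use:
        try:
            blocks.append(_ENCODERS[tag](fragments, config))
        except Exception as e:
            raise EncodingError(f"encoder {tag} failed: {e}") from e
    matrix = np.hstack([b.matrix for b in blocks]) if blocks else np.zeros((0, 0))
    names = [n for b in blocks for n in b.feature_names]
    slices, start = {}, 0
    for b in blocks:
        slices[b.encoding_tag] = slice(start, start + b.n_features)
        start += b.n_features
    if use == HYBRID_ORDER and config.window == 21 and config.alphabet == ALPHABET \
            and len(config.aai_table.index) == resources.N_DEFAULT_AAI:
        assert matrix.shape[1] == HYBRID_DIM, matrix.shape
    return HybridFeatureMatrix(matrix, names, "HYBRID", block_slices=slices)


# ---------------------------------------------------------------------------
# KNN encoding (kept out of the hybrid)


@dataclass
class KNNReference:
    """Labeled neighbor pool plus the neighbor-set sizes X."""

    dataset: FragmentDataset
    neighbor_counts: tuple[int, ...] = DEFAULT_NEIGHBOR_COUNTS

    def __post_init__(self) -> None:
        if len(self.dataset) == 0:
            raise EncodingError("empty KNN reference pool")
        xs = tuple(self.neighbor_counts)
        if any(b <= a for a, b in zip(xs, xs[1:])):
            raise EncodingError("neighbor counts must be strictly increasing")
        if xs[-1] > len(self.dataset):
            raise EncodingError(
                f"neighbor count {xs[-1]} exceeds pool size {len(self.dataset)}"
            )
        self.neighbor_counts = xs


def _similarity_lut(config: EncodingConfig) -> np.ndarray:
    """Per-symbol-pair similarity: min-max normalized BLOSUM62; dummy pairs 0."""
    b62 = config.blosum62
    lo, hi = float(np.min(b62.to_numpy())), float(np.max(b62.to_numpy()))
    A = len(config.alphabet)
    sim = np.zeros((A, A), dtype=float)
    for i, a in enumerate(config.alphabet):
        for j, b in enumerate(config.alphabet):
            if a in b62.index and b in b62.columns:
                sim[i, j] = (float(b62.loc[a, b]) - lo) / (hi - lo)
    return sim


def knn_distances(
    query_fragments,
    reference: KNNReference,
    config: EncodingConfig | None = None,
) -> np.ndarray:
    """Pairwise distance F = 1 - mean positional similarity, queries x pool."""
    config = config or EncodingConfig()
    qidx = _indices(_as_sequences(query_fragments), config.alphabet, config.window)
    ridx = _indices(reference.dataset.sequences, config.alphabet, config.window)
    sim = _similarity_lut(config)
    acc = np.zeros((qidx.shape[0], ridx.shape[0]), dtype=float)
    for j in range(config.window):
        acc += sim[np.ix_(qidx[:, j], ridx[:, j])]
    return 1.0 - acc / config.window


def encode_knn(
    query_fragments,
    reference: KNNReference,
    config: EncodingConfig | None = None,
    leave_one_out: bool = False,
) -> FeatureBlock:
    """Fraction of positives among the X nearest pool fragments, per X.

    With ``leave_one_out=True`` the queries are taken to *be* the pool
    (same order, same length) and each query's own pool entry is
    excluded; otherwise a query that also sits in the pool keeps itself
    as a zero-distance neighbor, which is exactly the label-leakage
    behavior the audit in ``evaluation`` measures.
    """
    config = config or EncodingConfig()
    D = knn_distances(query_fragments, reference, config)
    if leave_one_out:
        if D.shape[0] != D.shape[1]:
            raise EncodingError(
                "leave_one_out requires the query set to be the reference pool"
            )
        np.fill_diagonal(D, np.inf)
    labels = reference.dataset.labels.astype(float)
    max_x = reference.neighbor_counts[-1]
    if leave_one_out and max_x > D.shape[1] - 1:
        raise EncodingError("neighbor count exceeds pool size under leave-one-out")
    # stable argsort: ties broken by reference-pool order
    order = np.argsort(D, axis=1, kind="stable")[:, :max_x]
    ranked_labels = labels[order]
    cols = [ranked_labels[:, :x].mean(axis=1) for x in reference.neighbor_counts]
    names = [f"KNN:X{x}" for x in reference.neighbor_counts]
    return FeatureBlock(np.column_stack(cols), names, "KNN")
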