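"""Protein and peptide-fragment containers and their file formats.

A candidate acetylation site is represented as a fixed-length peptide
*fragment*: a window (default 21 residues) over the 21-symbol alphabet
(20 standard amino acids plus the dummy symbol ``'O'``), centred on the
candidate lysine.  Positions of the window falling outside the protein's
termini are filled with ``'O'``.  Fragments carry an optional binary
label (1 = acetylated lysine, Kace; 0 = non-Kace) and optional
provenance (source protein id, 1-based lysine position).

Supported file formats (UTF-8, LF):

* protein FASTA (via Biopython),
* fragment FASTA, label carried as the second header token
  (``>id 1`` / ``>id pos``),
* fragment TSV with columns ``fragment`` and ``label``,
* site-annotation TSV with columns ``protein_id``, ``position``
  (1-based), ``label``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO

from .resources import ALPHABET

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 21
DUMMY = "O"

#: Ambiguity/non-standard codes mapped to the dummy symbol on extraction.
NON_STANDARD = set("BJUXZ")

_POS_TOKENS = {"1", "pos", "positive"}
_NEG_TOKENS = {"0", "neg", "negative"}


class FragmentError(ValueError):
    """Raised for malformed proteins, annotations or fragments."""


@dataclass(frozen=True)
class ProteinRecord:
    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FragmentError(f"protein {self.id!r}: empty sequence")


@dataclass(frozen=True)
class SiteAnnotation:
    """A candidate lysine site: 1-based position within ``protein_id``."""

    protein_id: str
    position: int
    label: int

    def __post_init__(self) -> None:
        if self.position < 1:
            raise FragmentError(
                f"site {self.protein_id}:{self.position}: position must be >= 1"
            )
        if self.label not in (0, 1):
            raise FragmentError(
                f"site {self.protein_id}:{self.position}: label must be 0/1"
            )


@dataclass(frozen=True)
class PeptideFragment:
    """A K-centred window over the 21-letter alphabet."""

    residues: str
    label: int | None = None
    provenance: tuple[str, int] | None = None

    def __post_init__(self) -> None:
        validate_fragment(self.residues)
        if self.label is not None and self.label not in (0, 1):
            raise FragmentError(f"fragment label must be 0/1, got {self.label!r}")

    @property
    def window(self) -> int:
        return len(self.residues)


def validate_fragment(residues: str, window: int | None = None) -> None:
    """Raise FragmentError unless ``residues`` is a valid K-centred window."""
    n = len(residues)
    if window is not None and n != window:
        raise FragmentError(f"fragment length {n} != expected {window}")
    if n % 2 == 0 or n < 1:
        raise FragmentError(f"fragment length must be odd, got {n}")
    bad = set(residues) - set(ALPHABET)
    if bad:
        raise FragmentError(f"fragment contains symbols outside alphabet: {sorted(bad)}")
    center = residues[(n - 1) // 2]
    if center != "K":
        raise FragmentError(f"fragment center residue is {center!r}, expected 'K'")


@dataclass
class FragmentDataset:
    """An ordered list of fragments with an aligned binary label vector."""

    fragments: list[PeptideFragment]
    labels: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.labels is None:
            self.labels = np.array(
                [f.label for f in self.fragments], dtype=int
            ) if self.fragments else np.zeros(0, dtype=int)
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.fragments) != len(self.labels):
            raise FragmentError(
                f"{len(self.fragments)} fragments but {len(self.labels)} labels"
            )
        if self.labels.size and not np.isin(self.labels, (0, 1)).all():
            raise FragmentError("labels must be binary")

    def __len__(self) -> int:
        return len(self.fragments)

    def __iter__(self) -> Iterator[PeptideFragment]:
        return iter(self.fragments)

    @property
    def sequences(self) -> list[str]:
        return [f.residues for f in self.fragments]

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())

    @property
    def n_negative(self) -> int:
        return int(len(self) - self.labels.sum())

    def subset(self, idx: Sequence[int]) -> "FragmentDataset":
        idx = np.asarray(idx, dtype=int)
        return FragmentDataset(
            [self.fragments[i] for i in idx], self.labels[idx].copy()
        )


# ---------------------------------------------------------------------------
# protein FASTA and site tables


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA file; sequences are uppercased, order preserved."""
    records: list[ProteinRecord] = []
    seen: dict[str, int] = {}
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            seq = str(rec.seq).upper()
            records.append(ProteinRecord(rec.id, seq))
            seen[rec.id] = seen.get(rec.id, 0) + 1
    except ValueError as e:  # headerless / malformed input
        raise FragmentError(
            f"{path}: malformed FASTA (no '>' header before sequence): {e}"
        ) from None
    dups = sorted(k for k, v in seen.items() if v > 1)
    if dups:
        raise FragmentError(f"duplicate FASTA ids: {dups}")
    return records


def read_site_table(path: str | Path) -> list[SiteAnnotation]:
    """Read a TSV of (protein_id, 1-based position, label) rows."""
    sites = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "protein_id":  # optional header
                continue
            if len(parts) != 3:
                raise FragmentError(f"{path}:{ln}: expected 3 columns, got {len(parts)}")
            sites.append(SiteAnnotation(parts[0], int(parts[1]), int(parts[2])))
    return sites


def extract_fragments(
    protein: ProteinRecord,
    sites: Iterable[SiteAnnotation],
    window: int = DEFAULT_WINDOW,
) -> list[PeptideFragment]:
    """Cut K-centred windows out of ``protein`` at each annotated site.

    Flanks extending past a terminus are padded with the dummy symbol;
    non-standard residue codes (B, J, U, X, Z) in the flanks are mapped
    to the dummy symbol with a warning.
    """
    if window % 2 == 0 or window < 1:
        raise FragmentError(f"window must be odd and positive, got {window}")
    half = (window - 1) // 2
    seq = protein.sequence
    out = []
    for site in sites:
        if site.protein_id != protein.id:
            raise FragmentError(
                f"site references {site.protein_id!r}, not protein {protein.id!r}"
            )
        if site.position > len(seq):
            raise FragmentError(
                f"{protein.id}: site position {site.position} beyond sequence "
                f"length {len(seq)}"
            )
        center = site.position - 1  # to 0-based
        if seq[center] != "K":
            raise FragmentError(
                f"{protein.id}:{site.position}: residue is {seq[center]!r}, not 'K'"
            )
        lo, hi = center - half, center + half + 1
        chunk = seq[max(lo, 0): min(hi, len(seq))]
        frag = DUMMY * max(0, -lo) + chunk + DUMMY * max(0, hi - len(seq))
        if set(frag) & NON_STANDARD:
            warnings.warn(
                f"{protein.id}:{site.position}: non-standard residues mapped to "
                f"'{DUMMY}'",
                stacklevel=2,
            )
            frag = "".join(DUMMY if c in NON_STANDARD else c for c in frag)
        out.append(
            PeptideFragment(frag, site.label, provenance=(protein.id, site.position))
        )
    return out


def extract_dataset(
    proteins: Sequence[ProteinRecord],
    sites: Sequence[SiteAnnotation],
    window: int = DEFAULT_WINDOW,
) -> FragmentDataset:
    """Extract fragments for all sites across a protein collection."""
    by_id = {p.id: p for p in proteins}
    frags: list[PeptideFragment] = []
    for site in sites:
        if site.protein_id not in by_id:
            raise FragmentError(f"site references unknown protein {site.protein_id!r}")
        frags.extend(extract_fragments(by_id[site.protein_id], [site], window))
    return FragmentDataset(frags)


# ---------------------------------------------------------------------------
# labeled fragment datasets


def _parse_label(token: str, where: str) -> int:
    t = token.strip().lower()
    if t in _POS_TOKENS:
        return 1
    if t in _NEG_TOKENS:
        return 0
    raise FragmentError(f"{where}: unknown label token {token!r}")


def read_fragment_dataset(
    path: str | Path, format: str = "tsv", window: int = DEFAULT_WINDOW
) -> FragmentDataset:
    """Read a labeled fragment dataset (``tsv`` or ``fasta-fragments``)."""
    frags: list[PeptideFragment] = []
    if format == "tsv":
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if parts[0] == "fragment":
                    continue
                if len(parts) != 2:
                    raise FragmentError(
                        f"{path}:{ln}: expected 2 columns, got {len(parts)}"
                    )
                seq, label = parts[0].upper(), _parse_label(parts[1], f"{path}:{ln}")
                try:
                    validate_fragment(seq, window)
                except FragmentError as e:
                    raise FragmentError(f"{path}:{ln}: {e}") from None
                frags.append(PeptideFragment(seq, label))
    elif format == "fasta-fragments":
        for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
            tokens = rec.description.split()
            if len(tokens) < 2:
                raise FragmentError(
                    f"{path}: record {i} ({rec.id}): header lacks a label token"
                )
            label = _parse_label(tokens[1], f"{path}: record {i}")
            seq = str(rec.seq).upper()
            try:
                validate_fragment(seq, window)
            except FragmentError as e:
                raise FragmentError(f"{path}: record {i} ({rec.id}): {e}") from None
            frags.append(PeptideFragment(seq, label))
    else:
        raise ValueError(f"unknown fragment dataset format {format!r}")
    ds = FragmentDataset(frags)
    logger.info(
        "read %d fragments from %s (%d positive, %d negative)",
        len(ds), path, ds.n_positive, ds.n_negative,
    )
    return ds


def write_fragment_dataset(
    dataset: FragmentDataset, path: str | Path, format: str = "tsv"
) -> None:
    """Write a labeled fragment dataset (UTF-8, LF line endings)."""
    with open(path, "w", newline="\n") as fh:
        if format == "tsv":
            fh.write("fragment\tlabel\n")
            for frag, y in zip(dataset.fragments, dataset.labels):
                fh.write(f"{frag.residues}\t{int(y)}\n")
        elif format == "fasta-fragments":
            for i, (frag, y) in enumerate(zip(dataset.fragments, dataset.labels)):
                name = (
                    f"{frag.provenance[0]}_{frag.provenance[1]}"
                    if frag.provenance else f"frag{i}"
                )
                fh.write(f">{name} {int(y)}\n{frag.residues}\n")
        else:
            raise ValueError(f"unknown fragment dataset format {format!r}")
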