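"""Per-residue resource tables used by the feature encoders.

Three tables live here:

* the BLOSUM62 substitution matrix (standard NCBI values, loaded from
  Biopython and restricted to the 20 standard residues),
* the five Sandberg z-scale descriptors per residue,
* a default amino-acid-index table of 525 physicochemical property
  vectors.

The z-scales are the published Sandberg et al. values.  The default
amino-acid-index table is a deterministic **synthetic** stand-in for the
AAindex database (which is not redistributable here): 525 property
vectors drawn once from a fixed-seed generator, one value per standard
residue, rounded to three decimals.  Its only structural commitments are
the index count (525) and the per-residue layout, which is all the
hybrid-feature contract needs; substitute real AAindex values via
``EncodingConfig.aai_table`` for production use.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

#: Canonical 21-symbol alphabet: the 20 standard residues in alphabetical
#: order followed by the terminal-gap dummy symbol 'O'.
ALPHABET = "ACDEFGHIKLMNPQRSTVWYO"

#: The 20 standard residues (no dummy), alphabetical.
STANDARD_RESIDUES = ALPHABET[:-1]

#: Alphabetical order with 'O' interleaved at its alphabetical position;
#: used only by the numerical-rank (NRF) encoding.
RANK_ALPHABET = "ACDEFGHIKLMNOPQRSTVWY"

#: Number of property indices in the default synthetic table.
N_DEFAULT_AAI = 525

_AAI_SEED = 190821  # fixed forever; the table is part of the package contract

#: Sandberg five z-scales (z1..z5) per standard residue.
ZSCALES: dict[str, tuple[float, float, float, float, float]] = {
    "A": (0.24, -2.32, 0.60, -0.14, 1.30),
    "C": (0.84, -1.67, 3.71, 0.18, -2.65),
    "D": (3.98, 0.93, 1.93, -2.46, 0.75),
    "E": (3.11, 0.26, -0.11, -3.04, -0.25),
    "F": (-4.22, 1.94, 1.06, 0.54, -0.62),
    "G": (2.05, -4.06, 0.36, -0.82, -0.38),
    "H": (2.47, 1.95, 0.26, 3.90, 0.09),
    "I": (-3.89, -1.73, -1.71, -0.84, 0.26),
    "K": (2.29, 0.89, -2.49, 1.49, 0.31),
    "L": (-4.28, -1.30, -1.49, -0.72, 0.84),
    "M": (-2.85, -0.22, 0.47, 1.94, -0.98),
    "N": (3.05, 1.62, 1.04, -1.15, 1.61),
    "P": (-1.66, 0.27, 1.84, 0.70, 2.00),
    "Q": (1.75, 0.50, -1.44, -1.34, 0.66),
    "R": (3.52, 2.50, -3.50, 1.99, -0.17),
    "S": (2.39, -1.07, 1.15, -1.39, 0.67),
    "T": (0.75, -2.18, -1.12, -1.46, -0.40),
    "V": (-2.59, -2.64, -1.54, -0.85, -0.02),
    "W": (-4.36, 3.94, 0.59, 3.44, -1.59),
    "Y": (-2.54, 2.44, 0.43, 0.04, -1.47),
}


@lru_cache(maxsize=1)
def blosum62() -> pd.DataFrame:
    """Standard BLOSUM62, as a 20x20 DataFrame over STANDARD_RESIDUES."""
    m = substitution_matrices.load("BLOSUM62")
    res = list(STANDARD_RESIDUES)
    data = np.array([[m[a, b] for b in res] for a in res], dtype=float)
    return pd.DataFrame(data, index=res, columns=res)


@lru_cache(maxsize=1)
def zscale_table() -> pd.DataFrame:
    """Sandberg z-scales as a 20x5 DataFrame (rows: residues, cols z1..z5)."""
    return pd.DataFrame.from_dict(
        ZSCALES, orient="index", columns=[f"z{i}" for i in range(1, 6)]
    ).loc[list(STANDARD_RESIDUES)]


@lru_cache(maxsize=1)
def default_aai_table() -> pd.DataFrame:
    """Synthetic default amino-acid-index table (525 indices x 20 residues).

    Rows are index names ``SYN0001``..``SYN0525``; columns are the 20
    standard residues in canonical order.  Values are fixed-seed draws
    from a standard normal, rounded to 3 decimals — a structural
    placeholder for AAindex, not real physicochemistry.
    """
    rng = np.random.default_rng(_AAI_SEED)
    values = np.round(rng.standard_normal((N_DEFAULT_AAI, 20)), 3)
    names = [f"SYN{i + 1:04d}" for i in range(N_DEFAULT_AAI)]
    return pd.DataFrame(values, index=names, columns=list(STANDARD_RESIDUES))
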