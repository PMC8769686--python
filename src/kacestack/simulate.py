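"""Synthetic motif-planted fragment datasets.

The generator emulates the statistical shape of an acetylation-site
dataset without any biology: negatives draw every flank residue from a
background distribution (uniform over the 20 standard residues by
default); positives additionally draw *enriched* residues at a few
fixed flank offsets with probability ``p_signal``.  The center is
always 'K'.  A fraction of fragments get terminal dummy padding to
exercise the 'O' code paths.  ``generate_species_suite`` produces six
balanced-train / imbalanced-test pairs whose sizes match the six
prokaryotic species datasets the real pipeline targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fragments import DEFAULT_WINDOW, FragmentDataset, PeptideFragment
from .resources import STANDARD_RESIDUES


class SimulationError(ValueError):
    pass


@dataclass
class MotifSpec:
    """Where and how strongly positives differ from background.

    ``signal_positions`` maps center-relative offsets (never 0) to the
    string of residues enriched there; with probability ``p_signal`` a
    positive fragment draws uniformly from that string instead of the
    background.  ``padding_rate`` is the fraction of fragments whose
    window is truncated at one terminus and dummy-filled.
    """

    signal_positions: dict[int, str] = field(
        default_factory=lambda: {-2: "ED", -1: "E", 1: "R"}
    )
    p_signal: float = 0.8
    background: np.ndarray | None = None  # over the 20 standard residues
    padding_rate: float = 0.1

    def __post_init__(self) -> None:
        if 0 in self.signal_positions:
            raise SimulationError("signal offsets must not include the center (0)")
        if not 0.0 <= self.p_signal <= 1.0:
            raise SimulationError("p_signal must be in [0, 1]")
        if not 0.0 <= self.padding_rate <= 1.0:
            raise SimulationError("padding_rate must be in [0, 1]")
        if self.background is None:
            self.background = np.full(20, 1 / 20)
        self.background = np.asarray(self.background, dtype=float)
        if self.background.shape != (20,) or not np.isclose(self.background.sum(), 1):
            raise SimulationError("background must be a distribution over 20 residues")


@dataclass
class SyntheticDatasetSpec:
    n_pos: int
    n_neg: int
    motif: MotifSpec = field(default_factory=MotifSpec)
    seed: int = 0
    window: int = DEFAULT_WINDOW

    def __post_init__(self) -> None:
        if self.n_pos < 0 or self.n_neg < 0:
            raise SimulationError("n_pos and n_neg must be >= 0")
        if self.n_pos + self.n_neg == 0:
            raise SimulationError("empty dataset requested")
        half = (self.window - 1) // 2
        for off in self.motif.signal_positions:
            if not -half <= off <= half:
                raise SimulationError(f"signal offset {off} outside window")


def generate_dataset(spec: SyntheticDatasetSpec) -> FragmentDataset:
    """Draw a labeled fragment dataset from ``spec`` (seed-reproducible)."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_pos + spec.n_neg
    L, half = spec.window, (spec.window - 1) // 2
    residues = np.array(list(STANDARD_RESIDUES))
    chars = rng.choice(residues, size=(n, L), p=spec.motif.background)
    chars[:, half] = "K"
    # plant the motif in the positives (first n_pos rows; shuffled below)
    for off, enriched in spec.motif.signal_positions.items():
        col = half + off
        hit = rng.random(spec.n_pos) < spec.motif.p_signal
        draws = rng.choice(list(enriched), size=spec.n_pos)
        chars[:spec.n_pos, col] = np.where(hit, draws, chars[:spec.n_pos, col])
    labels = np.concatenate(
        [np.ones(spec.n_pos, dtype=int), np.zeros(spec.n_neg, dtype=int)]
    )
    # terminal truncation: replace a random-length prefix or suffix with 'O'
    pad = rng.random(n) < spec.motif.padding_rate
    sides = rng.random(n) < 0.5
    lengths = rng.integers(1, half + 1, size=n)
    for i in np.flatnonzero(pad):
        if sides[i]:
            chars[i, :lengths[i]] = "O"
        else:
            chars[i, L - lengths[i]:] = "O"
    order = rng.permutation(n)
    frags = [
        PeptideFragment("".join(chars[i]), int(labels[i])) for i in order
    ]
    return FragmentDataset(frags, labels[order])


#: (train_pos, train_neg, test_pos, test_neg) per species; the balanced
#: train / imbalanced test convention of the six prokaryotic datasets.
SPECIES_SIZES: dict[str, tuple[int, int, int, int]] = {
    "E_coli": (6592, 6592, 361, 1384),
    "C_glutamicum": (1052, 1052, 83, 830),
    "M_tuberculosis": (865, 865, 68, 575),
    "B_subtilis": (1571, 1571, 125, 1165),
    "S_typhimurium": (198, 198, 10, 217),
    "G_kaustophilus": (206, 206, 17, 192),
}

_SUITE_MOTIFS: dict[str, dict[int, str]] = {
    "E_coli": {-2: "ED", -1: "E", 1: "R"},
    "C_glutamicum": {-3: "ST", 1: "FY"},
    "M_tuberculosis": {-1: "DE", 2: "KR"},
    "B_subtilis": {-4: "G", -1: "E", 3: "H"},
    "S_typhimurium": {-2: "D", 2: "WF"},
    "G_kaustophilus": {-1: "Q", 1: "LIV"},
}


def generate_species_suite(
    seed: int = 0, p_signal: float = 0.8
) -> dict[str, tuple[FragmentDataset, FragmentDataset]]:
    """Six (balanced train, imbalanced test) pairs at the species sizes."""
    suite = {}
    for i, (name, (tp, tn, ip, inn)) in enumerate(SPECIES_SIZES.items()):
        motif = MotifSpec(signal_positions=dict(_SUITE_MOTIFS[name]),
                          p_signal=p_signal)
        train = generate_dataset(
            SyntheticDatasetSpec(tp, tn, motif, seed=seed + 101 * i)
        )
        test = generate_dataset(
            SyntheticDatasetSpec(ip, inn, motif, seed=seed + 101 * i + 50)
        )
        suite[name] = (train, test)
    return suite
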