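"""Synthetic peptide datasets and toy proteomes with planted SUMOylation motifs.

Experimentally identified SUMOylation sites predominantly sit in the
consensus motif ΨKX[ED] — a large hydrophobic residue (Ψ) immediately before
the modified lysine, any residue after it, then aspartate or glutamate — or
the inverted motif [ED]XKΨ. The generator emulates that structure: each
positive window carries the consensus motif with probability ``p_consensus``
and the inverted motif with probability ``p_inverted`` (otherwise pure
background); negatives are background-only. By default both motif
probabilities are 0.5, so every positive carries one of the two motif
contexts — a clean, strongly learnable caricature of the real signal.

All randomness flows from the spec's integer seed, so identical
specifications reproduce identical datasets byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .peptide_io import (
    AMINO_ACIDS,
    LabeledDataset,
    PeptideWindow,
    Protein,
)

#: Large hydrophobic residues eligible as Ψ.
DEFAULT_PSI = "VILMF"
#: Acidic residues for the [ED] motif slot.
ACIDIC = "ED"

#: Approximate human-proteome residue composition (UniProt human averages),
#: offered as an alternative to the uniform default background.
HUMAN_LIKE_BACKGROUND = {
    "A": 0.070, "C": 0.023, "D": 0.047, "E": 0.071, "F": 0.037,
    "G": 0.066, "H": 0.026, "I": 0.043, "K": 0.057, "L": 0.100,
    "M": 0.021, "N": 0.036, "P": 0.063, "Q": 0.048, "R": 0.056,
    "S": 0.083, "T": 0.054, "V": 0.060, "W": 0.012, "Y": 0.027,
}


def _normalize_background(background) -> np.ndarray:
    if background is None:
        vec = np.full(20, 1.0 / 20.0)
    elif isinstance(background, dict):
        vec = np.array([background[aa] for aa in AMINO_ACIDS], dtype=np.float64)
    else:
        vec = np.asarray(background, dtype=np.float64)
    if vec.shape != (20,) or (vec < 0).any() or vec.sum() <= 0:
        raise ValueError("background must be 20 non-negative weights, not all zero")
    return vec / vec.sum()


@dataclass
class MotifModel:
    """Probabilistic model of SUMOylation sequence context around a lysine."""

    p_consensus: float = 0.5
    p_inverted: float = 0.5
    background: np.ndarray | dict | None = None
    L: int = 39
    psi: str = DEFAULT_PSI
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.p_consensus <= 1 and 0 <= self.p_inverted <= 1):
            raise ValueError("motif probabilities must be in [0,1]")
        if self.p_consensus + self.p_inverted > 1 + 1e-12:
            raise ValueError("p_consensus + p_inverted must not exceed 1")
        if self.L % 2 == 0 or self.L < 7:
            raise ValueError("window length must be odd and >= 7")
        self.background = _normalize_background(self.background)
        if abs(self.background.sum() - 1.0) > 1e-9:
            raise ValueError("background must sum to 1")


@dataclass
class SyntheticDatasetSpec:
    n_pos: int
    n_neg: int
    motif: MotifModel = field(default_factory=MotifModel)
    label_noise: float = 0.0

    def __post_init__(self) -> None:
        if self.n_pos < 0 or self.n_neg < 0:
            raise ValueError("counts must be non-negative")
        if not 0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must be in [0, 0.5)")


def _draw_windows(rng, motif: MotifModel, n: int, planted: bool) -> list[str]:
    """Draw n windows; plant motifs around the central K when requested."""
    bg = motif.background
    L, half = motif.L, (motif.L - 1) // 2
    codes = rng.choice(20, size=(n, L), p=bg)
    k_code = AMINO_ACIDS.index("K")
    codes[:, half] = k_code
    if planted and n:
        u = rng.random(n)
        consensus = u < motif.p_consensus
        inverted = (~consensus) & (u < motif.p_consensus + motif.p_inverted)
        psi_codes = np.array([AMINO_ACIDS.index(a) for a in motif.psi])
        ed_codes = np.array([AMINO_ACIDS.index(a) for a in ACIDIC])
        n_c, n_i = int(consensus.sum()), int(inverted.sum())
        # consensus ΨKX[ED]: Ψ at -1, E/D at +2 (X slot stays background)
        codes[consensus, half - 1] = rng.choice(psi_codes, size=n_c)
        codes[consensus, half + 2] = rng.choice(ed_codes, size=n_c)
        # inverted [ED]XKΨ: E/D at -2, Ψ at +1
        codes[inverted, half - 2] = rng.choice(ed_codes, size=n_i)
        codes[inverted, half + 1] = rng.choice(psi_codes, size=n_i)
    lut = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
    return [bytes(lut[row]).decode("ascii") for row in codes]


def generate_peptides(spec: SyntheticDatasetSpec) -> LabeledDataset:
    """Generate a labelled window dataset under the motif model.

    Positives carry a planted motif with the model's probabilities; negatives
    are pure background (central residue forced to K in both). With
    ``label_noise > 0`` that fraction of labels is flipped after generation.
    Deterministic given ``spec.motif.seed``.
    """
    rng = np.random.default_rng(spec.motif.seed)
    pos = _draw_windows(rng, spec.motif, spec.n_pos, planted=True)
    neg = _draw_windows(rng, spec.motif, spec.n_neg, planted=False)
    labels = np.concatenate(
        [np.ones(spec.n_pos, dtype=np.int64), np.zeros(spec.n_neg, dtype=np.int64)]
    )
    if spec.label_noise > 0 and labels.size:
        flip = rng.random(labels.size) < spec.label_noise
        labels = np.where(flip, 1 - labels, labels)
    windows = [
        PeptideWindow(f"SYN{i + 1:06d}", (spec.motif.L - 1) // 2 + 1, seq,
                      int(lab))
        for i, (seq, lab) in enumerate(zip(pos + neg, labels))
    ]
    return LabeledDataset(windows, labels)


def generate_proteome(
    n_proteins: int,
    length_range: tuple[int, int] = (80, 400),
    site_density: float = 0.3,
    seed: int = 0,
    background=None,
    n_duplicates: int = 0,
) -> tuple[list[Protein], list[tuple[str, int, int]]]:
    """Random toy proteome plus a site table for the benchmark pipeline.

    Each protein is drawn from the background composition; each of its
    lysines is labelled as a modified site with probability ``site_density``
    (label 1) or left as a candidate negative (label 0). ``n_duplicates``
    appends exact copies of the first proteins (fresh ids) to exercise
    sequence clustering.
    """
    lo, hi = length_range
    if not (1 <= lo <= hi):
        raise ValueError("invalid length range")
    if not 0 <= site_density <= 1:
        raise ValueError("site_density must be in [0,1]")
    rng = np.random.default_rng(seed)
    bg = _normalize_background(background)
    lut = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
    proteins: list[Protein] = []
    sites: list[tuple[str, int, int]] = []
    for i in range(n_proteins):
        length = int(rng.integers(lo, hi + 1))
        codes = rng.choice(20, size=length, p=bg)
        seq = bytes(lut[codes]).decode("ascii")
        proteins.append(Protein(f"TOY{i + 1:04d}", seq))
    for d in range(min(n_duplicates, n_proteins)):
        proteins.append(Protein(f"TOY{n_proteins + d + 1:04d}", proteins[d].sequence))
    for p in proteins:
        for j, ch in enumerate(p.sequence):
            if ch == "K" and site_density > 0:
                label = int(rng.random() < site_density)
                sites.append((p.id, j + 1, label))
    return proteins, sites
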