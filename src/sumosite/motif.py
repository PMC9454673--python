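"""Two-sample logo statistics: per-position residue enrichment/depletion.

For every non-central window position and every amino acid, the occurrence
frequency in modified peptides is compared against unmodified peptides with
a two-sample t-test on the 0/1 occurrence indicators (asymptotically the
two-proportion z-test) and Bonferroni correction over all
``(L - 1) x 20`` position/residue cells. Padding characters ('X') are
excluded from the per-position denominators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .peptide_io import AMINO_ACIDS
from .encoders import seq_codes


@dataclass(frozen=True)
class PositionResidueStats:
    """Enrichment statistics for one residue at one position offset.

    ``position`` is the offset from the central lysine (negative = N-side);
    the center itself (always K by construction) is never reported.
    """

    position: int
    residue: str
    freq_pos: float
    freq_neg: float
    delta: float
    p_raw: float
    p_adj: float
    direction: str  # "enriched" | "depleted" | "ns"


def _indicator_t_test(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Welch t-test p-value on binary indicator vectors."""
    if x.size < 2 or y.size < 2 or (x.std() == 0 and y.std() == 0):
        return 1.0
    _, p = stats.ttest_ind(x, y, equal_var=False)
    return float(p) if np.isfinite(p) else 1.0


def two_sample_logo(
    pos_sequences: list[str],
    neg_sequences: list[str],
    alpha: float = 0.05,
) -> list[PositionResidueStats]:
    """Compare residue composition of two aligned peptide sets per position.

    Inputs are equal-length window sequences (typically the modified and
    unmodified sets). Returns one record per (offset, residue); ``direction``
    is assigned only when the Bonferroni-adjusted p-value is below ``alpha``.
    """
    if not pos_sequences or not neg_sequences:
        raise ValueError("both peptide sets must be non-empty")
    L = len(pos_sequences[0])
    if len(neg_sequences[0]) != L:
        raise ValueError("peptide sets have different window lengths")
    half = (L - 1) // 2
    pos_codes = seq_codes(pos_sequences)
    neg_codes = seq_codes(neg_sequences)
    bonferroni = (L - 1) * len(AMINO_ACIDS)

    out: list[PositionResidueStats] = []
    for col in range(L):
        if col == half:
            continue
        offset = col - half
        pc, nc = pos_codes[:, col], neg_codes[:, col]
        pc, nc = pc[pc < 20], nc[nc < 20]  # drop 'X' padding
        if pc.size == 0 or nc.size == 0:
            continue
        for code, residue in enumerate(AMINO_ACIDS):
            xp = (pc == code).astype(np.float64)
            xn = (nc == code).astype(np.float64)
            fp, fn_ = float(xp.mean()), float(xn.mean())
            p_raw = _indicator_t_test(xp, xn)
            p_adj = min(1.0, p_raw * bonferroni)
            if p_adj < alpha:
                direction = "enriched" if fp > fn_ else "depleted"
            else:
                direction = "ns"
            out.append(
                PositionResidueStats(
                    offset, residue, fp, fn_, fp - fn_, p_raw, p_adj, direction
                )
            )
    return out


def significant(stats_list, direction: str | None = None):
    """Filter to significant cells, optionally by direction."""
    keep = [s for s in stats_list if s.direction != "ns"]
    if direction is not None:
        keep = [s for s in keep if s.direction == direction]
    return keep


def write_logo_csv(stats_list, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("position\tresidue\tfreq_pos\tfreq_neg\tdelta\tp_raw\tp_adj\tdirection\n")
        for s in stats_list:
            fh.write(
                f"{s.position}\t{s.residue}\t{s.freq_pos:.6f}\t{s.freq_neg:.6f}\t"
                f"{s.delta:.6f}\t{s.p_raw:.3e}\t{s.p_adj:.3e}\t{s.direction}\n"
            )
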