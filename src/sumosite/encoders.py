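"""Peptide-window feature encodings: EAAC, BLOSUM62, AAindex, ZScale.

Every encoder maps a window of length L onto a ``rows x channels`` matrix
(:class:`EncodedMatrix`) whose row-major flattening gives the feature vector
fed to the classifiers. For the default L = 39:

==========  =================  ========== =========
encoding    rows x channels    flattened  channels
==========  =================  ========== =========
EAAC        (L-w+1) x 20       700        AA frequencies in a sliding w-mer
BLOSUM62    L x 20             780        substitution-score row per residue
AAindex     L x n_props        546 (14)   physicochemical property values
ZScale      L x 5              195        z1..z5 descriptors
==========  =================  ========== =========

The channel order for amino-acid-indexed columns is fixed to
``ACDEFGHIKLMNPQRSTVWY``. The padding residue 'X' contributes a zero row
(BLOSUM62/AAindex/ZScale) or no count (EAAC).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from Bio.Align import substitution_matrices
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, cross_val_predict

from .peptide_io import AMINO_ACIDS, PAD, LabeledDataset, PeptideWindow

#: integer code of each residue; PAD ('X') gets code 20
_CODE = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_CODE[PAD] = 20
_N_AA = 20


@dataclass(frozen=True)
class EncodedMatrix:
    """A positions x channels feature matrix with row-major flatten order."""

    values: np.ndarray
    channel_names: tuple[str, ...]

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[1] != len(self.channel_names):
            raise ValueError("values must be 2-D with one column per channel")
        if not np.isfinite(v).all():
            raise ValueError("encoded matrix contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def flatten(self) -> np.ndarray:
        return self.values.reshape(-1)


def seq_codes(sequences: list[str]) -> np.ndarray:
    """Integer-encode equal-length sequences: (n, L) array of codes 0..20."""
    if not sequences:
        return np.empty((0, 0), dtype=np.int8)
    L = len(sequences[0])
    if any(len(s) != L for s in sequences):
        raise ValueError("sequences must all have the same length")
    arr = np.frombuffer("".join(sequences).encode("ascii"), dtype=np.uint8)
    codes = np.full(128, -1, dtype=np.int8)
    for ch, c in _CODE.items():
        codes[ord(ch)] = c
    out = codes[arr].reshape(len(sequences), L)
    if (out < 0).any():
        raise ValueError("sequences contain characters outside the AA alphabet")
    return out


# ---------------------------------------------------------------------------
# lookup tables


def _load_tsv(name: str) -> tuple[list[str], dict[str, np.ndarray]]:
    text = (resources.files("sumosite.data") / name).read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines() if ln and not ln.startswith("#")]
    header = lines[0].split("\t")
    rows = {}
    for ln in lines[1:]:
        parts = ln.split("\t")
        rows[parts[0]] = np.asarray([float(x) for x in parts[1:]], dtype=np.float64)
    return header[1:], rows


def load_zscale_table() -> dict[str, np.ndarray]:
    """ZScale five-descriptor table; includes an all-zero entry for 'X'."""
    _, rows = _load_tsv("zscale.tsv")
    rows[PAD] = np.zeros(5)
    return rows


@dataclass
class AAIndexTable:
    """Amino-acid property scales plus an ordered selection of property ids.

    ``properties`` maps property id -> vector of 20 values in the fixed
    channel order ``ACDEFGHIKLMNPQRSTVWY``. ``selected_ids`` determines which
    (and in what column order) properties the encoder uses.
    """

    properties: dict[str, np.ndarray]
    selected_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for pid, vec in self.properties.items():
            if vec.shape != (_N_AA,):
                raise ValueError(f"property {pid!r}: expected 20 values")
            if not np.isfinite(vec).all():
                raise ValueError(f"property {pid!r}: non-finite values")
        unknown = set(self.selected_ids) - set(self.properties)
        if unknown:
            raise ValueError(f"selected ids not in table: {sorted(unknown)}")
        if not self.selected_ids:
            self.selected_ids = sorted(self.properties)

    def with_selection(self, ids: list[str]) -> "AAIndexTable":
        return AAIndexTable(self.properties, list(ids))

    def matrix(self, standardize: bool = False) -> np.ndarray:
        """(21, n_selected) lookup: rows = AA codes, last row = 'X' zeros."""
        cols = []
        for pid in self.selected_ids:
            v = self.properties[pid].astype(np.float64)
            if standardize:
                v = (v - v.mean()) / v.std(ddof=0)
            cols.append(v)
        m = np.stack(cols, axis=1)
        return np.vstack([m, np.zeros((1, m.shape[1]))])


def load_aaindex_table(path=None) -> AAIndexTable:
    """Load the bundled curated property table, or a user file of the same
    tab-separated layout (columns in channel order, one property per row)."""
    if path is None:
        header, rows = _load_tsv("aaindex_like.tsv")
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
        lines = [ln for ln in text.splitlines() if ln and not ln.startswith("#")]
        header = lines[0].split("\t")[1:]
        rows = {
            ln.split("\t")[0]: np.asarray(
                [float(x) for x in ln.split("\t")[1:]], dtype=np.float64
            )
            for ln in lines[1:]
        }
    order = [header.index(aa) for aa in AMINO_ACIDS]
    props = {pid: vec[order] for pid, vec in rows.items()}
    return AAIndexTable(props)


def load_blosum62() -> np.ndarray:
    """(21, 20) BLOSUM62 lookup in channel order; 'X' row is all zeros.

    Sourced from biopython's copy of the standard NCBI matrix. The matrix's
    own X column is deliberately ignored so that padding positions encode as
    zero rows, consistently with the AAindex/ZScale conventions.
    """
    m = substitution_matrices.load("BLOSUM62")
    table = np.zeros((21, _N_AA), dtype=np.float64)
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            table[i, j] = m[a, b]
    return table


# ---------------------------------------------------------------------------
# encoders (batch-first; single-window wrappers build EncodedMatrix)

_EAAC_CHANNELS = tuple(AMINO_ACIDS)
_ZS_CHANNELS = ("z1", "z2", "z3", "z4", "z5")


def _eaac_batch(codes: np.ndarray, w: int) -> np.ndarray:
    n, L = codes.shape
    if w > L:
        raise ValueError(f"EAAC sub-window w={w} exceeds window length {L}")
    onehot = np.zeros((n, L, _N_AA), dtype=np.float64)
    valid = codes < _N_AA
    ii, jj = np.nonzero(valid)
    onehot[ii, jj, codes[ii, jj]] = 1.0
    csum = np.concatenate(
        [np.zeros((n, 1, _N_AA)), np.cumsum(onehot, axis=1)], axis=1
    )
    return (csum[:, w:] - csum[:, :-w]) / w  # (n, L-w+1, 20)


def encode_eaac(window: PeptideWindow | str, w: int = 5) -> EncodedMatrix:
    """Enhanced amino-acid composition: AA frequencies in a length-w window
    slid one position at a time from the N- to the C-terminus.

    Row i holds count(aa in slots i..i+w-1)/w for each of the 20 amino acids;
    'X' counts toward no channel, so row sums fall below 1 near padded ends.
    """
    seq = window.sequence if isinstance(window, PeptideWindow) else window
    vals = _eaac_batch(seq_codes([seq]), w)[0]
    return EncodedMatrix(vals, _EAAC_CHANNELS)


def _table_batch(codes: np.ndarray, table: np.ndarray) -> np.ndarray:
    return table[codes]  # (n, L, channels); code 20 ('X') hits the zero row


def encode_blosum62(window: PeptideWindow | str) -> EncodedMatrix:
    """Per-residue BLOSUM62 substitution-score rows; 'X' encodes as zeros."""
    seq = window.sequence if isinstance(window, PeptideWindow) else window
    vals = _table_batch(seq_codes([seq]), load_blosum62())[0]
    return EncodedMatrix(vals, _EAAC_CHANNELS)


def encode_aaindex(
    window: PeptideWindow | str,
    table: AAIndexTable,
    standardize: bool = False,
) -> EncodedMatrix:
    """Per-residue physicochemical property values (raw by default).

    ``standardize=True`` z-scores each property over the 20 amino acids
    before lookup; 'X' encodes as a zero row either way.
    """
    if not table.selected_ids:
        raise ValueError("AAIndexTable has no selected properties")
    seq = window.sequence if isinstance(window, PeptideWindow) else window
    vals = _table_batch(seq_codes([seq]), table.matrix(standardize))[0]
    return EncodedMatrix(vals, tuple(table.selected_ids))


def encode_zscale(window: PeptideWindow | str) -> EncodedMatrix:
    """Five-descriptor ZScale embedding per residue; 'X' encodes as zeros."""
    seq = window.sequence if isinstance(window, PeptideWindow) else window
    zs = load_zscale_table()
    table = np.vstack([zs[aa] for aa in AMINO_ACIDS] + [np.zeros(5)])
    vals = _table_batch(seq_codes([seq]), table)[0]
    return EncodedMatrix(vals, _ZS_CHANNELS)


def encode_windows(
    sequences: list[str],
    scheme: str,
    aaindex_table: AAIndexTable | None = None,
    w: int = 5,
    standardize: bool = False,
) -> np.ndarray:
    """Encode many equal-length windows at once -> (n, rows, channels).

    ``scheme`` is one of ``eaac``, ``blosum62``, ``aaindex``, ``zscale``.
    """
    codes = seq_codes(sequences)
    if scheme == "eaac":
        return _eaac_batch(codes, w)
    if scheme == "blosum62":
        return _table_batch(codes, load_blosum62())
    if scheme == "aaindex":
        if aaindex_table is None:
            aaindex_table = load_aaindex_table()
        return _table_batch(codes, aaindex_table.matrix(standardize))
    if scheme == "zscale":
        zs = load_zscale_table()
        table = np.vstack([zs[aa] for aa in AMINO_ACIDS] + [np.zeros(5)])
        return _table_batch(codes, table)
    raise ValueError(f"unknown encoding scheme {scheme!r}")


ENCODING_SCHEMES = ("eaac", "blosum62", "aaindex", "zscale")


# ---------------------------------------------------------------------------
# AAindex property selection


def _rf_cv_auc(
    X: np.ndarray, y: np.ndarray, cv_k: int, seed: int, n_trees: int
) -> float:
    skf = StratifiedKFold(n_splits=cv_k, shuffle=True, random_state=seed)
    rf = RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, n_jobs=1
    )
    scores = cross_val_predict(rf, X, y, cv=skf, method="predict_proba")[:, 1]
    return float(roc_auc_score(y, scores))


def rank_and_select_aaindex(
    dataset: LabeledDataset,
    table: AAIndexTable,
    cv_k: int = 5,
    k_grid=None,
    seed: int = 0,
    n_trees: int = 140,
) -> tuple[AAIndexTable, dict]:
    """Rank properties by single-property random-forest CV AUC and select the
    top-k set with the best combined CV AUC.

    Each property is scored alone (windows encoded with that property only,
    flattened, random-forest with ``n_trees`` trees, stratified ``cv_k``-fold
    AUC), properties are sorted by AUC descending (ties broken by property
    id), and each top-k prefix over ``k_grid`` (default 1..min(64, n_props),
    step 1) is re-scored the same way; the smallest k attaining the maximum
    AUC wins. Returns the table restricted to the winning selection plus a
    report with per-property and per-k AUCs.
    """
    y = dataset.labels
    if np.unique(y).size < 2:
        raise ValueError("property selection requires both classes")
    seqs = dataset.sequences
    all_ids = sorted(table.properties)
    if k_grid is None:
        k_grid = range(1, min(64, len(all_ids)) + 1)

    per_prop: dict[str, float] = {}
    for pid in all_ids:
        X = encode_windows(seqs, "aaindex", table.with_selection([pid]))
        per_prop[pid] = _rf_cv_auc(X.reshape(len(seqs), -1), y, cv_k, seed, n_trees)
    ranked = sorted(all_ids, key=lambda p: (-per_prop[p], p))

    per_k: dict[int, float] = {}
    for k in k_grid:
        if not 1 <= k <= len(ranked):
            raise ValueError(f"k={k} outside 1..{len(ranked)}")
        X = encode_windows(seqs, "aaindex", table.with_selection(ranked[:k]))
        per_k[k] = _rf_cv_auc(X.reshape(len(seqs), -1), y, cv_k, seed, n_trees)
    best_k = max(sorted(per_k), key=lambda k: (per_k[k], -k))
    report = {"per_property_auc": per_prop, "ranked": ranked, "per_k_auc": per_k,
              "best_k": best_k}
    return table.with_selection(ranked[:best_k]), report
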