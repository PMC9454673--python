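"""Sequence/site input, lysine-window extraction, and reproducible dataset splits.

Coordinates are 1-based and inclusive throughout the package: ``position = 1``
is the first residue of the protein. Peptide windows are fixed odd-length
strings centered on a lysine; positions that fall outside the protein are
padded with the placeholder residue ``'X'``, which every encoder treats as a
zero (or absent) channel.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The 20 standard amino acids in the fixed channel order used everywhere.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: Padding / unknown-residue placeholder.
PAD = "X"
#: Letters silently remapped to 'X' (ambiguity codes, rare residues, stop).
NONSTANDARD = set("BJOUZ*")

VALID_ALPHABET = set(AMINO_ACIDS) | {PAD}


class FastaParseError(ValueError):
    """Raised for empty or malformed FASTA input."""


@dataclass(frozen=True)
class Protein:
    """A protein sequence restricted to the 20 standard letters plus 'X'."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence) - VALID_ALPHABET
        if bad:
            raise ValueError(
                f"protein {self.id!r}: invalid residues {sorted(bad)}; "
                "sanitize input with read_fasta() or clean_sequence()"
            )


@dataclass(frozen=True)
class PeptideWindow:
    """Fixed odd-length peptide centered on a candidate lysine.

    ``position`` is the 1-based index of the central residue in the parent
    protein. ``label`` is 1 for a modified (SUMOylated) site, 0 for an
    unmodified one, or None when unknown.
    """

    protein_id: str
    position: int
    sequence: str
    label: int | None = None

    def __post_init__(self) -> None:
        L = len(self.sequence)
        if L % 2 == 0 or L < 3:
            raise ValueError(f"window length must be odd and >= 3, got {L}")
        bad = set(self.sequence) - VALID_ALPHABET
        if bad:
            raise ValueError(f"invalid residues in window: {sorted(bad)}")
        if self.label not in (None, 0, 1):
            raise ValueError(f"label must be 0/1/None, got {self.label!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def center(self) -> str:
        return self.sequence[len(self.sequence) // 2]


@dataclass
class LabeledDataset:
    """Aligned windows and binary labels."""

    windows: list[PeptideWindow]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if len(self.windows) != self.labels.shape[0]:
            raise ValueError("windows and labels must have equal length")
        if self.labels.size and not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary")

    def __len__(self) -> int:
        return len(self.windows)

    @property
    def sequences(self) -> list[str]:
        return [w.sequence for w in self.windows]

    def subset(self, indices) -> "LabeledDataset":
        idx = np.asarray(indices, dtype=np.intp)
        return LabeledDataset([self.windows[i] for i in idx], self.labels[idx])


@dataclass
class SplitPlan:
    """Independent-test indices plus a k-fold assignment of the CV indices.

    ``cv_fold_of`` maps dataset index -> fold id in ``1..k``. The independent
    set and the CV folds are disjoint and jointly cover ``0..n-1``.
    """

    independent_indices: np.ndarray
    cv_fold_of: dict[int, int]
    seed: int

    @property
    def cv_indices(self) -> np.ndarray:
        return np.asarray(sorted(self.cv_fold_of), dtype=np.intp)

    @property
    def n_folds(self) -> int:
        return max(self.cv_fold_of.values()) if self.cv_fold_of else 0

    def fold_indices(self, fold: int) -> np.ndarray:
        return np.asarray(
            sorted(i for i, f in self.cv_fold_of.items() if f == fold), dtype=np.intp
        )

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("index\tpartition\tfold\n")
            rows = [(int(i), "independent", 0) for i in self.independent_indices]
            rows += [(i, "cv", f) for i, f in self.cv_fold_of.items()]
            for i, part, f in sorted(rows):
                fh.write(f"{i}\t{part}\t{f}\n")

    @classmethod
    def from_tsv(cls, path, seed: int = 0) -> "SplitPlan":
        indep, folds = [], {}
        with open(path, encoding="utf-8") as fh:
            header = fh.readline()
            if not header.startswith("index"):
                raise ValueError(f"{path}: not a split-plan file")
            for line in fh:
                i, part, f = line.rstrip("\n").split("\t")
                if part == "independent":
                    indep.append(int(i))
                else:
                    folds[int(i)] = int(f)
        return cls(np.asarray(indep, dtype=np.intp), folds, seed)


def clean_sequence(seq: str, protein_id: str = "?") -> tuple[str, int]:
    """Uppercase and map non-standard letters (B, J, O, U, Z, *) to 'X'.

    Returns the cleaned sequence and the number of replacements made.
    Letters outside both sets raise, since they indicate non-protein input.
    """
    seq = seq.upper()
    out = []
    n_mapped = 0
    for ch in seq:
        if ch in VALID_ALPHABET:
            out.append(ch)
        elif ch in NONSTANDARD:
            out.append(PAD)
            n_mapped += 1
        else:
            raise FastaParseError(
                f"protein {protein_id!r}: unexpected character {ch!r}"
            )
    if n_mapped:
        logger.warning(
            "protein %s: mapped %d non-standard residue(s) to 'X'",
            protein_id, n_mapped,
        )
    return "".join(out), n_mapped


def read_fasta(path, on_duplicate: str = "error") -> list[Protein]:
    """Read a protein FASTA file into :class:`Protein` records.

    The record id is the header token before the first whitespace.
    ``on_duplicate`` is ``"error"`` (default) or ``"suffix"`` (append ``.2``,
    ``.3``, ... to repeated ids).
    """
    if on_duplicate not in ("error", "suffix"):
        raise ValueError("on_duplicate must be 'error' or 'suffix'")
    proteins: list[Protein] = []
    seen: dict[str, int] = {}
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except Exception as exc:  # pragma: no cover - biopython error passthrough
        raise FastaParseError(f"{path}: {exc}") from exc
    if not records:
        raise FastaParseError(f"{path}: no FASTA records found")
    for rec in records:
        pid = rec.id
        if not pid:
            raise FastaParseError(f"{path}: record with empty header")
        if pid in seen:
            if on_duplicate == "error":
                raise FastaParseError(f"{path}: duplicate record id {pid!r}")
            seen[pid] += 1
            pid = f"{pid}.{seen[pid]}"
        else:
            seen[pid] = 1
        seq, _ = clean_sequence(str(rec.seq), pid)
        if not seq:
            raise FastaParseError(f"{path}: record {pid!r} has empty sequence")
        proteins.append(Protein(pid, seq))
    return proteins


def write_fasta(proteins: list[Protein], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for p in proteins:
            fh.write(f">{p.id}\n")
            for i in range(0, len(p.sequence), 60):
                fh.write(p.sequence[i : i + 60] + "\n")


def read_site_table(path) -> list[tuple[str, int, int]]:
    """Read a tab-separated site table: ``protein_id  position  label``.

    A header line is tolerated (detected by a non-integer second column).
    """
    rows: list[tuple[str, int, int]] = []
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: expected 3 tab-separated columns")
            try:
                pos, label = int(parts[1]), int(parts[2])
            except ValueError:
                if ln == 1:
                    continue  # header
                raise ValueError(f"{path}:{ln}: non-integer position/label")
            rows.append((parts[0], pos, label))
    return rows


def write_site_table(rows, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("protein_id\tposition\tlabel\n")
        for pid, pos, label in rows:
            fh.write(f"{pid}\t{pos}\t{label}\n")


def extract_window(protein: Protein, position: int, L: int = 39) -> PeptideWindow:
    """Extract the L-mer centered at 1-based ``position``, padding with 'X'."""
    if L % 2 == 0 or L < 3:
        raise ValueError(f"window length must be odd and >= 3, got {L}")
    if not 1 <= position <= len(protein.sequence):
        raise ValueError(
            f"position {position} outside protein {protein.id!r} "
            f"(length {len(protein.sequence)})"
        )
    half = (L - 1) // 2
    seq = protein.sequence
    i = position - 1
    left = seq[max(0, i - half) : i]
    right = seq[i + 1 : i + 1 + half]
    return PeptideWindow(
        protein_id=protein.id,
        position=position,
        sequence=PAD * (half - len(left)) + left + seq[i] + right
        + PAD * (half - len(right)),
    )


def extract_lysine_windows(protein: Protein, L: int = 39) -> list[PeptideWindow]:
    """One window per lysine in the protein, in increasing position order."""
    return [
        extract_window(protein, i + 1, L)
        for i, ch in enumerate(protein.sequence)
        if ch == "K"
    ]


def build_dataset(
    proteins: list[Protein],
    sites: list[tuple[str, int, int]],
    L: int = 39,
    deduplicate: bool = False,
) -> LabeledDataset:
    """Extract labelled windows for a site table.

    Sites whose stated position is not a lysine are rejected. With
    ``deduplicate=True``, windows with identical sequences keep only the
    first occurrence (off by default; duplicates are left in place).
    """
    by_id = {p.id: p for p in proteins}
    windows, labels = [], []
    seen: set[str] = set()
    for pid, pos, label in sites:
        if pid not in by_id:
            raise KeyError(f"site table references unknown protein {pid!r}")
        prot = by_id[pid]
        if prot.sequence[pos - 1] != "K":
            raise ValueError(
                f"site {pid}:{pos} is {prot.sequence[pos - 1]!r}, not a lysine"
            )
        w = extract_window(prot, pos, L)
        if deduplicate:
            if w.sequence in seen:
                continue
            seen.add(w.sequence)
        windows.append(
            PeptideWindow(w.protein_id, w.position, w.sequence, int(label))
        )
        labels.append(int(label))
    return LabeledDataset(windows, np.asarray(labels))


def _stratified_take(rng: np.random.Generator, idx: np.ndarray, n_take: int):
    perm = rng.permutation(idx)
    return perm[:n_take], perm[n_take:]


def split_dataset(
    dataset: LabeledDataset, test_fraction: float = 0.1, seed: int = 0
) -> SplitPlan:
    """Stratified CV / independent-test split with a per-class floor rule.

    Within each class, ``floor((1 - test_fraction) * n_class)`` items go to
    the cross-validation partition and the remainder to the independent test
    set; e.g. 37,273 items per class at ``test_fraction=0.1`` give 33,545 CV
    and 3,728 independent items. Deterministic given the seed.
    """
    if not 0 < test_fraction < 1:
        raise ValueError(f"test_fraction must be in (0,1), got {test_fraction}")
    if len(dataset) == 0:
        raise ValueError("cannot split an empty dataset")
    rng = np.random.default_rng(seed)
    cv_parts, indep_parts = [], []
    for cls in (0, 1):
        idx = np.flatnonzero(dataset.labels == cls)
        if idx.size == 0:
            continue
        n_cv = int(np.floor((1.0 - test_fraction) * idx.size))
        cv, indep = _stratified_take(rng, idx, n_cv)
        cv_parts.append(cv)
        indep_parts.append(indep)
    cv_idx = np.sort(np.concatenate(cv_parts))
    indep_idx = np.sort(np.concatenate(indep_parts)) if indep_parts else np.array([], dtype=np.intp)
    fold_of = kfold_assign(cv_idx, labels=dataset.labels, k=5, seed=seed) \
        if cv_idx.size >= 5 and _both_classes(dataset.labels[cv_idx]) else {int(i): 1 for i in cv_idx}
    return SplitPlan(indep_idx.astype(np.intp), fold_of, seed)


def _both_classes(labels: np.ndarray) -> bool:
    return bool(np.unique(labels).size == 2)


def kfold_assign(
    cv_indices, labels=None, k: int = 5, seed: int = 0
) -> dict[int, int]:
    """Stratified assignment of indices to folds ``1..k``.

    Per class, shuffled indices are dealt round-robin so class fold sizes
    differ by at most one. With ``labels=None`` the split is unstratified.
    """
    cv_indices = np.asarray(cv_indices, dtype=np.intp)
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if k > cv_indices.size:
        raise ValueError(f"k={k} exceeds number of CV items {cv_indices.size}")
    rng = np.random.default_rng(seed)
    fold_of: dict[int, int] = {}
    if labels is None:
        groups = [cv_indices]
    else:
        labels = np.asarray(labels)
        groups = [
            cv_indices[labels[cv_indices] == cls]
            for cls in np.unique(labels[cv_indices])
        ]
    for grp in groups:
        perm = rng.permutation(grp)
        for j, idx in enumerate(perm):
            fold_of[int(idx)] = j % k + 1
    return fold_of
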