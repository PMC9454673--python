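"""Benchmark construction: cluster -> representatives -> filter -> balance -> split.

Mirrors the standard PTM-benchmark recipe: proteins are clustered at 40%
sequence identity (greedy incremental clustering in decreasing length order,
the CD-HIT strategy, with a simple alignment-based identity), one
representative per cluster is kept (the member with the most SUMOylation
sites), its SUMOylated lysines become positives, its remaining lysines
become candidate negatives, candidates carrying any other PTM annotation are
discarded, negatives are down-sampled to the positive count, fixed-length
windows are cut, and the result is split 9:1 into cross-validation and
independent partitions with a stratified five-fold assignment.

The clustering here is a self-contained simplification of CD-HIT (identity =
aligned matches / shorter sequence length, with a shared-3-mer prefilter);
it reproduces the pipeline's structure, not CD-HIT's exact cluster counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio import Align

from .peptide_io import (
    LabeledDataset,
    Protein,
    SplitPlan,
    build_dataset,
    split_dataset,
)

logger = logging.getLogger(__name__)

PTM_KINDS = ("sumoylation", "other_ptm", "none")


@dataclass(frozen=True)
class SiteAnnotation:
    """A lysine position with its modification annotation."""

    protein_id: str
    position: int
    annotation: str

    def __post_init__(self) -> None:
        if self.annotation not in PTM_KINDS:
            raise ValueError(f"annotation must be one of {PTM_KINDS}")
        if self.position < 1:
            raise ValueError("positions are 1-based")


@dataclass
class ClusterAssignment:
    cluster_of: dict[str, int]
    representative_of: dict[int, str] = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len(self.representative_of)

    def members(self, cid: int) -> list[str]:
        return [p for p, c in self.cluster_of.items() if c == cid]


def _kmer_set(seq: str, k: int = 3) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


_aligner = Align.PairwiseAligner(
    mode="global",
    match_score=1,
    mismatch_score=0,
    open_gap_score=-1,
    extend_gap_score=-0.5,
)


def sequence_identity(a: str, b: str) -> float:
    """Aligned match count divided by the shorter sequence's length."""
    if not _kmer_set(a) & _kmer_set(b):
        return 0.0
    aln = _aligner.align(a, b)[0]
    identities = int(aln.counts().identities)
    return identities / min(len(a), len(b))


def greedy_cluster(
    proteins: list[Protein],
    identity_threshold: float = 0.40,
    sumo_site_counts: dict[str, int] | None = None,
) -> ClusterAssignment:
    """Greedy incremental clustering in decreasing length order.

    Each sequence joins the first existing cluster whose *seed* (founding
    sequence) it matches at >= ``identity_threshold``, otherwise it founds a
    new cluster. The representative of each cluster is the member with the
    most SUMOylation sites (ties: longer sequence, then lexicographic id);
    with no site counts supplied every count is zero and the tie-break rules
    decide.
    """
    if not proteins:
        raise ValueError("no proteins to cluster")
    if not 0 < identity_threshold <= 1:
        raise ValueError("identity threshold must be in (0,1]")
    counts = sumo_site_counts or {}
    order = sorted(
        proteins, key=lambda p: (-len(p.sequence), p.id)
    )
    seeds: list[tuple[int, Protein]] = []
    cluster_of: dict[str, int] = {}
    for prot in order:
        for cid, seed in seeds:
            if sequence_identity(prot.sequence, seed.sequence) >= identity_threshold:
                cluster_of[prot.id] = cid
                break
        else:
            cid = len(seeds)
            seeds.append((cid, prot))
            cluster_of[prot.id] = cid
    by_id = {p.id: p for p in proteins}
    assignment = ClusterAssignment(cluster_of)
    for cid, _ in seeds:
        members = assignment.members(cid)
        rep = min(
            members,
            key=lambda pid: (-counts.get(pid, 0), -len(by_id[pid].sequence), pid),
        )
        assignment.representative_of[cid] = rep
    return assignment


def build_benchmark(
    proteins: list[Protein],
    sites: list[tuple[str, int, int]],
    ptm_annotations: list[tuple[str, int, str]] | None = None,
    L: int = 39,
    seed: int = 0,
    identity_threshold: float = 0.40,
    test_fraction: float = 0.1,
    k_folds: int = 5,
) -> tuple[LabeledDataset, SplitPlan, dict]:
    """Run the full benchmark pipeline; returns dataset, split plan, and a
    stage-by-stage count log.

    ``sites`` rows are ``(protein_id, position, label)`` with label 1 marking
    a SUMOylation site (label-0 rows are ignored; candidate negatives are
    derived from the representatives' remaining lysines).
    ``ptm_annotations`` rows are ``(protein_id, position, ptm_type)``; any
    annotated candidate negative is excluded.
    """
    by_id = {p.id: p for p in proteins}
    positives = {(pid, pos) for pid, pos, lab in sites if lab == 1}
    for pid, pos in positives:
        if by_id[pid].sequence[pos - 1] != "K":
            raise ValueError(f"annotated site {pid}:{pos} is not a lysine")
    counts: dict[str, int] = {}
    for pid, _ in positives:
        counts[pid] = counts.get(pid, 0) + 1

    stage_log: dict[str, int] = {
        "proteins_in": len(proteins),
        "sites_in": len(positives),
    }
    clusters = greedy_cluster(proteins, identity_threshold, counts)
    reps = set(clusters.representative_of.values())
    stage_log["clusters"] = clusters.n_clusters
    stage_log["representatives"] = len(reps)

    pos_sites = sorted((pid, pos) for pid, pos in positives if pid in reps)
    stage_log["positives"] = len(pos_sites)
    if not pos_sites:
        raise ValueError("no positive sites remain after clustering")

    neg_candidates = sorted(
        (pid, i + 1)
        for pid in sorted(reps)
        for i, ch in enumerate(by_id[pid].sequence)
        if ch == "K" and (pid, i + 1) not in positives
    )
    stage_log["candidate_negatives"] = len(neg_candidates)

    annotated = {
        (pid, pos) for pid, pos, _ in (ptm_annotations or [])
    }
    neg_clean = [s for s in neg_candidates if s not in annotated]
    stage_log["negatives_after_ptm_filter"] = len(neg_clean)

    rng = np.random.default_rng(seed)
    n_take = min(len(pos_sites), len(neg_clean))
    if n_take < len(pos_sites):
        logger.warning(
            "only %d clean negatives for %d positives; truncating positives",
            len(neg_clean), len(pos_sites),
        )
        pos_sites = [
            pos_sites[i] for i in sorted(rng.choice(len(pos_sites), n_take,
                                                    replace=False))
        ]
    neg_sample = [
        neg_clean[i]
        for i in sorted(rng.choice(len(neg_clean), n_take, replace=False))
    ]
    stage_log["negatives_sampled"] = len(neg_sample)
    stage_log["dataset_size"] = len(pos_sites) + len(neg_sample)

    rows = [(pid, pos, 1) for pid, pos in pos_sites] + [
        (pid, pos, 0) for pid, pos in neg_sample
    ]
    dataset = build_dataset(proteins, rows, L=L)
    plan = split_dataset(dataset, test_fraction=test_fraction, seed=seed)
    if plan.n_folds != k_folds and len(dataset) >= 2 * k_folds:
        from .peptide_io import kfold_assign

        plan.cv_fold_of = kfold_assign(
            plan.cv_indices, labels=dataset.labels, k=k_folds, seed=seed
        )
    for stage, count in stage_log.items():
        logger.info("benchmark stage %-28s %d", stage, count)
    return dataset, plan, stage_log


def read_ptm_table(path) -> list[tuple[str, int, str]]:
    """Read a PLMD-like annotation table: ``protein_id  position  ptm_type``."""
    rows = []
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: expected 3 columns")
            try:
                pos = int(parts[1])
            except ValueError:
                if ln == 1:
                    continue
                raise
            rows.append((parts[0], pos, parts[2]))
    return rows
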