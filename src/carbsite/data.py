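"""Dataset curation rules, redundancy clustering, splits and epoch sampling.

The training corpus mixes carbohydrate binders with putative nonbinders.
Curation rules implemented here:

* small-molecule entries whose ligand set turns out to contain a noncovalent
  carbohydrate are reassigned to the binder class;
* antibody antigens carrying an N-glycosylation sequon N-X-(S/T) with X != P
  are excluded from the nonbinder set;
* sequences are clustered at 60% global identity and whole clusters are
  assigned to train/validation/test at 80/5/15 by entry count, so no two
  similar sequences straddle a split;
* each training epoch samples one entry per cluster, and entries with a
  predicted-structure counterpart use it 60% of the time.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import Align

__all__ = [
    "DatasetEntry",
    "ClusterSplit",
    "reassign_carbohydrate_complexes",
    "has_nxst_motif",
    "pairwise_identity",
    "cluster_sequences",
    "assign_splits",
    "epoch_sample",
    "write_manifest",
    "read_manifest",
]

BINDER_CLASSES = ("carb_binder", "small_molecule_nonbinder", "putative_nonbinder")
SPLIT_FRACTIONS = (0.80, 0.05, 0.15)
AF2_PROB = 0.6


@dataclass
class DatasetEntry:
    """One protein of the corpus with its class and structure paths."""

    id: str
    sequence: str
    binder_class: str
    crystal_path: str | None = None
    predicted_path: str | None = None
    has_bound_carb: bool = False
    has_noncovalent_carb_ligand: bool = False
    source_dataset: str = ""
    split: str | None = None

    def __post_init__(self):
        if self.binder_class not in BINDER_CLASSES:
            raise ValueError(f"unknown binder_class {self.binder_class!r}")
        if self.has_bound_carb and self.binder_class != "carb_binder":
            raise ValueError("has_bound_carb entries must be carb_binder")


@dataclass
class ClusterSplit:
    """A clustering of entry ids plus the cluster-level split assignment."""

    clusters: list[list[str]]
    assignment: dict[int, str]
    fractions: tuple[float, float, float] = SPLIT_FRACTIONS
    seed: int = 0

    def split_of(self, entry_id: str) -> str:
        for ci, members in enumerate(self.clusters):
            if entry_id in members:
                return self.assignment[ci]
        raise KeyError(entry_id)

    def entries_in(self, split: str) -> list[str]:
        return [
            eid
            for ci, members in enumerate(self.clusters)
            if self.assignment[ci] == split
            for eid in members
        ]


def reassign_carbohydrate_complexes(entries: list[DatasetEntry]) -> list[DatasetEntry]:
    """Move small-molecule entries holding a noncovalent carbohydrate to binders.

    Idempotent: a second pass changes nothing.
    """
    for e in entries:
        if e.binder_class == "small_molecule_nonbinder" and e.has_noncovalent_carb_ligand:
            e.binder_class = "carb_binder"
            e.has_bound_carb = True
    return entries


def has_nxst_motif(sequence: str) -> bool:
    """True iff the sequence contains the N-glycosylation sequon N-X-(S/T), X != P."""
    seq = sequence.upper()
    for i in range(len(seq) - 2):
        if seq[i] == "N" and seq[i + 1] != "P" and seq[i + 2] in ("S", "T"):
            return True
    return False


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def pairwise_identity(a: str, b: str, aligner: Align.PairwiseAligner | None = None) -> float:
    """Global-alignment sequence identity: matches over alignment length."""
    if not a or not b:
        return 0.0
    if aligner is None:
        aligner = _make_aligner()
    aln = aligner.align(a, b)[0]
    counts = aln.counts()
    return counts.identities / aln.length


def cluster_sequences(
    sequences: dict[str, str] | list[tuple[str, str]], identity: float = 0.6
) -> list[list[str]]:
    """Greedy centroid clustering at a global-identity threshold.

    Sequences are processed longest-first; each joins the first cluster whose
    centroid it matches at >= ``identity``, else founds a new cluster whose
    centroid it becomes.  An external clustering tool (e.g. MMseqs) can stand
    behind the same contract via :func:`clusters_from_tsv`.
    """
    if not 0 < identity <= 1:
        raise ValueError("identity must be in (0, 1]")
    items = list(sequences.items()) if isinstance(sequences, dict) else list(sequences)
    if not items:
        return []
    items.sort(key=lambda kv: (-len(kv[1]), kv[0]))
    aligner = _make_aligner()
    centroids: list[str] = []
    clusters: list[list[str]] = []
    for sid, seq in items:
        for ci, cseq in enumerate(centroids):
            if pairwise_identity(seq, cseq, aligner) >= identity:
                clusters[ci].append(sid)
                break
        else:
            centroids.append(seq)
            clusters.append([sid])
    return clusters


def clusters_from_tsv(path: str | Path) -> list[list[str]]:
    """Adapter: read an MMseqs-style two-column (centroid, member) TSV."""
    groups: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            rep, member = line.split()[:2]
            groups.setdefault(rep, []).append(member)
    return list(groups.values())


def assign_splits(
    clusters: list[list[str]],
    fractions: tuple[float, float, float] = SPLIT_FRACTIONS,
    seed: int = 0,
    pinned: dict[str, str] | None = None,
) -> ClusterSplit:
    """Assign whole clusters to train/val/test, filling by entry count.

    Clusters containing pinned entries go to the pinned split; a cluster
    pinned to two different splits is a conflict.  Remaining clusters are
    shuffled by ``seed`` and greedily assigned to whichever split has the
    largest remaining entry deficit (ties favor train, then val, then test).
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    pinned = pinned or {}
    names = ("train", "val", "test")
    assignment: dict[int, str] = {}
    for ci, members in enumerate(clusters):
        pins = {pinned[m] for m in members if m in pinned}
        if len(pins) > 1:
            raise ValueError(f"cluster {ci} pinned to multiple splits: {sorted(pins)}")
        if pins:
            assignment[ci] = pins.pop()
    total = sum(len(c) for c in clusters)
    counts = {s: sum(len(clusters[ci]) for ci, sp in assignment.items() if sp == s)
              for s in names}
    free = [ci for ci in range(len(clusters)) if ci not in assignment]
    rng = np.random.default_rng(seed)
    rng.shuffle(free)
    targets = {s: f * total for s, f in zip(names, fractions)}
    for ci in free:
        deficits = [(targets[s] - counts[s], -i) for i, s in enumerate(names)]
        s = names[max(range(3), key=lambda i: deficits[i])]
        assignment[ci] = s
        counts[s] += len(clusters[ci])
    return ClusterSplit(clusters=clusters, assignment=assignment,
                        fractions=fractions, seed=seed)


def epoch_sample(
    entries_by_cluster: list[list[DatasetEntry]],
    af2_prob: float = AF2_PROB,
    seed: int = 0,
    epoch: int = 0,
) -> list[tuple[DatasetEntry, str]]:
    """One (entry, structure-choice) pair per cluster for this epoch.

    The entry is drawn uniformly within its cluster; the predicted structure
    is chosen with probability ``af2_prob`` when the entry has one, else the
    crystal structure is used.  Reproducible per (seed, epoch).
    """
    if not 0 <= af2_prob <= 1:
        raise ValueError("af2_prob must be in [0, 1]")
    rng = np.random.default_rng([seed, epoch])
    out = []
    for members in entries_by_cluster:
        entry = members[rng.integers(len(members))]
        use_predicted = (
            entry.predicted_path is not None and rng.random() < af2_prob
        )
        out.append((entry, "predicted" if use_predicted else "crystal"))
    return out


_MANIFEST_FIELDS = [
    "id", "sequence", "binder_class", "crystal_path", "predicted_path",
    "has_bound_carb", "has_noncovalent_carb_ligand", "source_dataset", "split",
]


def write_manifest(entries: list[DatasetEntry], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=_MANIFEST_FIELDS)
        w.writeheader()
        for e in entries:
            row = {k: getattr(e, k) for k in _MANIFEST_FIELDS}
            row["has_bound_carb"] = int(e.has_bound_carb)
            row["has_noncovalent_carb_ligand"] = int(e.has_noncovalent_carb_ligand)
            w.writerow(row)
    return path


def read_manifest(path: str | Path) -> list[DatasetEntry]:
    entries = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            entries.append(
                DatasetEntry(
                    id=row["id"],
                    sequence=row["sequence"],
                    binder_class=row["binder_class"],
                    crystal_path=row["crystal_path"] or None,
                    predicted_path=row["predicted_path"] or None,
                    has_bound_carb=bool(int(row["has_bound_carb"])),
                    has_noncovalent_carb_ligand=bool(
                        int(row["has_noncovalent_carb_ligand"])
                    ),
                    source_dataset=row["source_dataset"],
                    split=row["split"] or None,
                )
            )
    return entries
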