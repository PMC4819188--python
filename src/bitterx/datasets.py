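"""Training-set assembly and splitting for both classification tasks.

Two dataset kinds are built here:

* ``bitterant`` — molecules labeled bitter (+1) or non-bitter (−1).  True
  non-bitter compounds are scarce, so the negative class is topped up with
  decoys: a large candidate pool is clustered by Tanimoto distance on path
  fingerprints and one central representative per cluster is taken as a
  presumed non-bitterant.
* ``pair`` — (molecule, receptor) pairs labeled interacting (+1) or not
  (−1).  Experimentally negative pairs are used first; the remainder are
  pseudo-negatives made by mismatching positive pairs, keeping the
  per-receptor negative counts as balanced as possible.

Both constructions produce exactly class-balanced datasets.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .chemio import Fingerprint, Molecule, path_fingerprint, tanimoto_similarity


@dataclass
class LabeledDataset:
    """Entries with ±1 labels; ``kind`` is 'bitterant' or 'pair'."""

    kind: str
    entry_ids: list[str]
    labels: np.ndarray  # ±1 ints
    # bitterant kind: entry_id -> Molecule; pair kind: entry_id -> (mol_id, receptor_id)
    payload: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.entry_ids) != len(set(self.entry_ids)):
            raise ValueError("entry ids must be unique")
        if not set(np.unique(self.labels)) <= {-1, 1}:
            raise ValueError("labels must be +1 or -1")
        if len(self.entry_ids) != self.labels.size:
            raise ValueError("ids and labels length mismatch")

    def __len__(self) -> int:
        return self.labels.size

    @property
    def n_positive(self) -> int:
        return int((self.labels == 1).sum())

    @property
    def n_negative(self) -> int:
        return int((self.labels == -1).sum())


@dataclass
class SplitAssignment:
    train_ids: list[str]
    test_ids: list[str]
    train_fraction: float

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test ids overlap")


# ---------------------------------------------------------------------------
# Decoy clustering
# ---------------------------------------------------------------------------

def _similarity_matrix(fps: list[Fingerprint]) -> np.ndarray:
    mat = np.stack([fp.bits for fp in fps]).astype(np.uint8)
    inter = mat @ mat.T
    pops = mat.sum(axis=1)
    union = pops[:, None] + pops[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    np.fill_diagonal(sim, 1.0)
    return sim


def _medoid_of(cluster: np.ndarray, sim: np.ndarray, ids: list[str]) -> int:
    """Member with maximal mean within-cluster similarity; ties broken by
    lexicographic molecule id."""
    sub = sim[np.ix_(cluster, cluster)]
    means = sub.mean(axis=1)
    best = np.flatnonzero(means == means.max())
    if best.size > 1:
        best = best[np.argsort([ids[cluster[i]] for i in best], kind="stable")[:1]]
    return int(cluster[best[0]])


def cluster_representatives(
    mols: list[Molecule],
    k: int,
    seed: int = 0,
    method: str = "kmedoids",
    max_iter: int = 50,
) -> list[Molecule]:
    """Cluster molecules into ``k`` groups and return one central member each.

    Distance is 1 − Tanimoto on path fingerprints.  The default is a seeded
    k-medoids; ``method='leader'`` gives Butina-style leader clustering
    (cluster count then controlled by a similarity cutoff chosen to yield k
    leaders greedily).  The representative of a cluster is the member with
    maximal mean similarity to its cluster, ties broken by lexicographic id.
    """
    n = len(mols)
    if k > n:
        raise ValueError(f"requested {k} clusters from {n} molecules")
    if k == n:
        return list(mols)
    fps = [path_fingerprint(m) for m in mols]
    sim = _similarity_matrix(fps)
    ids = [m.id for m in mols]

    if method == "leader":
        order = np.argsort(ids, kind="stable")
        leaders: list[int] = []
        assign = np.full(n, -1)
        # greedy leaders until k, then attach remaining to nearest leader
        for idx in order:
            if len(leaders) < k:
                leaders.append(int(idx))
                assign[idx] = len(leaders) - 1
            else:
                assign[idx] = int(np.argmax(sim[idx, leaders]))
        medoids = [
            _medoid_of(np.flatnonzero(assign == c), sim, ids) for c in range(k)
        ]
        return [mols[i] for i in medoids]

    rng = np.random.default_rng(seed)
    medoids = list(rng.choice(n, size=k, replace=False))
    for _ in range(max_iter):
        assign = np.argmax(sim[:, medoids], axis=1)
        # keep every cluster non-empty: medoids always belong to themselves
        for c, m in enumerate(medoids):
            assign[m] = c
        new_medoids = [
            _medoid_of(np.flatnonzero(assign == c), sim, ids) for c in range(k)
        ]
        if new_medoids == medoids:
            break
        medoids = new_medoids
    return [mols[i] for i in medoids]


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------

def assemble_bitterant_dataset(
    positives: list[Molecule],
    true_negatives: list[Molecule],
    decoy_pool: list[Molecule],
    seed: int = 0,
    cluster_method: str = "kmedoids",
) -> LabeledDataset:
    """Balanced bitter/non-bitter dataset.

    Negatives are the experimentally confirmed non-bitterants plus decoy
    cluster representatives drawn from ``decoy_pool`` so that the negative
    class exactly matches the positive class in size.  Pool members whose
    structure duplicates a positive or true negative are excluded before
    clustering.
    """
    if len(true_negatives) > len(positives):
        raise ValueError("more true negatives than positives; cannot balance")
    known = {m.canonical_smiles for m in positives} | {
        m.canonical_smiles for m in true_negatives
    }
    pool = [m for m in decoy_pool if m.canonical_smiles not in known]
    n_decoys = len(positives) - len(true_negatives)
    if n_decoys > len(pool):
        raise ValueError(
            f"decoy pool has {len(pool)} eligible molecules; {n_decoys} needed"
        )
    decoys = (
        cluster_representatives(pool, n_decoys, seed=seed, method=cluster_method)
        if n_decoys
        else []
    )
    entries = (
        [(m, 1) for m in positives]
        + [(m, -1) for m in true_negatives]
        + [(m, -1) for m in decoys]
    )
    return LabeledDataset(
        kind="bitterant",
        entry_ids=[m.id for m, _ in entries],
        labels=np.array([lab for _, lab in entries]),
        payload={m.id: m for m, _ in entries},
    )


def assemble_pair_dataset(
    positive_pairs: list[tuple[str, str]],
    negative_evidence: list[tuple[str, str]] | None = None,
    seed: int = 0,
    extra_molecules: list[str] | None = None,
) -> LabeledDataset:
    """Balanced interaction dataset of (molecule_id, receptor_id) pairs.

    Experimental negatives for receptors that appear in the positive set are
    used first; the negative class is then topped up with pseudo-negatives
    made by mismatching positive-set molecules (plus any
    ``extra_molecules``) with positive-set receptors, excluding any known
    positive pair and keeping per-receptor negative counts as balanced as
    possible (max−min ≤ 1 where feasible).
    """
    if not positive_pairs:
        raise ValueError("positive pair set is empty")
    negative_evidence = negative_evidence or []
    pos_set = set(positive_pairs)
    receptors = sorted({r for _, r in positive_pairs})
    molecules = sorted({m for m, _ in positive_pairs} | set(extra_molecules or []))

    negatives: list[tuple[str, str]] = []
    for pair in negative_evidence:
        if pair[1] in set(receptors) and pair not in pos_set and pair not in negatives:
            negatives.append(pair)
            if len(negatives) == len(positive_pairs):
                break

    rng = np.random.default_rng(seed)
    neg_per_receptor = Counter(r for _, r in negatives)
    candidates = {
        r: [m for m in molecules if (m, r) not in pos_set] for r in receptors
    }
    taken = set(negatives)
    while len(negatives) < len(positive_pairs):
        # fill the currently least-served receptor that still has candidates
        open_receptors = [
            r for r in receptors if any((m, r) not in taken for m in candidates[r])
        ]
        if not open_receptors:
            raise ValueError(
                "cannot generate enough distinct non-positive pairs to balance"
            )
        counts = np.array([neg_per_receptor[r] for r in open_receptors])
        r = open_receptors[int(np.flatnonzero(counts == counts.min())[0])]
        avail = [m for m in candidates[r] if (m, r) not in taken]
        m = avail[int(rng.integers(len(avail)))]
        negatives.append((m, r))
        taken.add((m, r))
        neg_per_receptor[r] += 1

    entries = [(p, 1) for p in positive_pairs] + [(p, -1) for p in negatives]
    return LabeledDataset(
        kind="pair",
        entry_ids=[f"{m}|{r}|{lab:+d}" for (m, r), lab in entries],
        labels=np.array([lab for _, lab in entries]),
        payload={
            f"{m}|{r}|{lab:+d}": (m, r) for (m, r), lab in entries
        },
    )


def stratified_split(
    ds: LabeledDataset,
    train_fraction: float = 0.8,
    seed: int = 0,
    train_counts: dict[int, int] | None = None,
) -> SplitAssignment:
    """Per-class random split; train count per class is
    floor(train_fraction × class size) unless ``train_counts`` overrides it
    with explicit per-label counts."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    ids = np.array(ds.entry_ids, dtype=object)
    train: list[str] = []
    test: list[str] = []
    for label in (1, -1):
        members = ids[ds.labels == label]
        if members.size == 0:
            continue
        n_train = (
            train_counts[label]
            if train_counts is not None
            else int(np.floor(train_fraction * members.size))
        )
        if n_train == 0 or n_train == members.size:
            raise ValueError(
                f"class {label:+d} would get an empty train or test partition"
            )
        perm = rng.permutation(members.size)
        train.extend(members[perm[:n_train]].tolist())
        test.extend(members[perm[n_train:]].tolist())
    return SplitAssignment(train_ids=train, test_ids=test, train_fraction=train_fraction)


# ---------------------------------------------------------------------------
# Text serialization
# ---------------------------------------------------------------------------

def write_dataset_tsv(ds: LabeledDataset) -> str:
    """Serialize a dataset as tab-delimited text.

    bitterant kind: ``id<TAB>smiles<TAB>label``;
    pair kind: ``molecule_id<TAB>receptor_id<TAB>label``.
    """
    lines = []
    for eid, lab in zip(ds.entry_ids, ds.labels):
        if ds.kind == "bitterant":
            lines.append(f"{eid}\t{ds.payload[eid].canonical_smiles}\t{lab:+d}")
        else:
            m, r = ds.payload[eid]
            lines.append(f"{m}\t{r}\t{lab:+d}")
    return "\n".join(lines) + "\n"
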