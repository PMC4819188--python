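"""Decoy clustering, balanced dataset assembly, and stratified splits."""

import numpy as np
import pytest

from bitterx.chemio import parse_and_standardize, path_fingerprint, tanimoto_similarity
from bitterx.datasets import (
    LabeledDataset,
    assemble_bitterant_dataset,
    assemble_pair_dataset,
    cluster_representatives,
    stratified_split,
    write_dataset_tsv,
)
from bitterx.synthetic import synth_molecules


def _toy_dataset(n_pos, n_neg):
    ids = [f"p{i}" for i in range(n_pos)] + [f"n{i}" for i in range(n_neg)]
    labels = np.array([1] * n_pos + [-1] * n_neg)
    return LabeledDataset(kind="pair", entry_ids=ids, labels=labels,
                          payload={i: (i, "r") for i in ids})


class TestClusterRepresentatives:
    def test_k_equal_n_returns_all(self, small_molecules):
        reps = cluster_representatives(small_molecules, len(small_molecules), seed=0)
        assert reps == small_molecules

    def test_k_too_large_errors(self, small_molecules):
        with pytest.raises(ValueError):
            cluster_representatives(small_molecules, len(small_molecules) + 1)

    def test_two_structural_families(self):
        # linear alkanes vs polycyclic aromatics: far apart in path space
        alkanes = [parse_and_standardize("C" * k, mol_id=f"a{k}") for k in range(3, 8)]
        aromatics = [
            parse_and_standardize(s, mol_id=f"b{i}")
            for i, s in enumerate(
                ["c1ccc2ccccc2c1", "c1ccc2cc3ccccc3cc2c1", "Oc1ccc2ccccc2c1",
                 "Nc1ccc2ccccc2c1", "c1ccc2ccccc2c1C"]
            )
        ]
        reps = cluster_representatives(alkanes + aromatics, 2, seed=0)
        families = []
        for rep in reps:
            fp = path_fingerprint(rep)
            sim_a = max(tanimoto_similarity(fp, path_fingerprint(m)) for m in alkanes)
            sim_b = max(tanimoto_similarity(fp, path_fingerprint(m)) for m in aromatics)
            families.append("alkane" if sim_a > sim_b else "aromatic")
        assert sorted(families) == ["alkane", "aromatic"]

    def test_deterministic_under_seed(self, small_molecules):
        r1 = cluster_representatives(small_molecules, 10, seed=5)
        r2 = cluster_representatives(small_molecules, 10, seed=5)
        assert [m.id for m in r1] == [m.id for m in r2]

    def test_leader_method_also_returns_k(self, small_molecules):
        reps = cluster_representatives(small_molecules, 8, seed=0, method="leader")
        assert len({m.id for m in reps}) == 8


class TestBitterantAssembly:
    def test_balance_without_true_negatives(self):
        mols = synth_molecules(60, seed=2)
        ds = assemble_bitterant_dataset(mols[:5], [], mols[5:], seed=0)
        assert len(ds) == 10
        assert ds.n_positive == ds.n_negative == 5

    def test_duplicates_excluded_from_pool(self):
        mols = synth_molecules(40, seed=3)
        positives = mols[:6]
        pool = positives + mols[6:]  # positives duplicated into the pool
        ds = assemble_bitterant_dataset(positives, [], pool, seed=0)
        pos_smiles = {m.canonical_smiles for m in positives}
        neg_ids = [e for e, l in zip(ds.entry_ids, ds.labels) if l == -1]
        neg_smiles = {ds.payload[e].canonical_smiles for e in neg_ids}
        assert not (neg_smiles & pos_smiles)

    def test_pool_too_small_errors(self):
        mols = synth_molecules(10, seed=4)
        with pytest.raises(ValueError):
            assemble_bitterant_dataset(mols[:8], [], mols[8:], seed=0)

    def test_serialization_layout(self):
        mols = synth_molecules(12, seed=5)
        ds = assemble_bitterant_dataset(mols[:3], [], mols[3:], seed=0)
        lines = write_dataset_tsv(ds).strip().splitlines()
        assert len(lines) == 6
        assert all(len(l.split("\t")) == 3 for l in lines)


class TestPairAssembly:
    def test_single_mismatch_with_extra_molecule(self):
        ds = assemble_pair_dataset([("m1", "r1")], seed=0, extra_molecules=["m2"])
        negs = [ds.payload[e] for e, l in zip(ds.entry_ids, ds.labels) if l == -1]
        assert negs == [("m2", "r1")]

    def test_pseudo_negative_avoids_positives(self):
        positives = [("m1", "r1"), ("m2", "r2"), ("m3", "r1"), ("m4", "r2")]
        ds = assemble_pair_dataset(positives, seed=0)
        negs = [ds.payload[e] for e, l in zip(ds.entry_ids, ds.labels) if l == -1]
        assert not (set(negs) & set(positives))
        assert len(negs) == 4

    def test_receptor_balance_on_toy_instance(self):
        positives = [("m1", "r1"), ("m2", "r1"), ("m3", "r2"), ("m4", "r2")]
        ds = assemble_pair_dataset(positives, seed=0)
        negs = [ds.payload[e] for e, l in zip(ds.entry_ids, ds.labels) if l == -1]
        counts = {"r1": 0, "r2": 0}
        for _, r in negs:
            counts[r] += 1
        assert counts == {"r1": 2, "r2": 2}

    def test_negative_evidence_used_first(self):
        positives = [("m1", "r1"), ("m2", "r2")]
        evidence = [("m9", "r1")]
        ds = assemble_pair_dataset(positives, evidence, seed=0)
        negs = {ds.payload[e] for e, l in zip(ds.entry_ids, ds.labels) if l == -1}
        assert ("m9", "r1") in negs

    def test_impossible_balance_errors(self):
        # one molecule, one receptor: no non-positive pair can exist
        with pytest.raises(ValueError):
            assemble_pair_dataset([("m1", "r1")], seed=0)

    def test_empty_positive_set_errors(self):
        with pytest.raises(ValueError):
            assemble_pair_dataset([], seed=0)


class TestStratifiedSplit:
    def test_floor_rule_per_class(self):
        ds = _toy_dataset(539, 539)
        split = stratified_split(ds, 0.8, seed=0)
        train_pos = sum(1 for i in split.train_ids if i.startswith("p"))
        train_neg = sum(1 for i in split.train_ids if i.startswith("n"))
        assert (train_pos, train_neg) == (431, 431)
        assert len(split.train_ids) == 862
        assert len(split.test_ids) == 216

    def test_explicit_count_override(self):
        ds = _toy_dataset(260, 260)
        split = stratified_split(ds, 0.8, seed=0, train_counts={1: 209, -1: 209})
        assert len(split.train_ids) == 418
        assert len(split.test_ids) == 102

    def test_disjoint_exhaustive(self):
        ds = _toy_dataset(25, 17)
        split = stratified_split(ds, 0.6, seed=3)
        assert set(split.train_ids) | set(split.test_ids) == set(ds.entry_ids)
        assert not set(split.train_ids) & set(split.test_ids)

    def test_reproducible_under_seed(self):
        ds = _toy_dataset(30, 30)
        s1 = stratified_split(ds, 0.8, seed=9)
        s2 = stratified_split(ds, 0.8, seed=9)
        assert s1.train_ids == s2.train_ids and s1.test_ids == s2.test_ids

    def test_empty_partition_errors(self):
        ds = _toy_dataset(2, 2)
        with pytest.raises(ValueError):
            stratified_split(ds, 0.1, seed=0)
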