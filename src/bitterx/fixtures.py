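"""Self-contained demonstration assets: a trained synthetic model bundle.

Builds a complete, working model bundle from synthetic molecules and
receptor sequences with a planted interaction rule, so the end-to-end
query pipeline can be exercised (and demonstrated) without any curated
data.  The planted rules are chemically arbitrary by construction — they
give the SVMs a learnable signal, nothing more.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from . import receptors as rf
from .chemio import Molecule, descriptor_matrix
from .datasets import LabeledDataset, assemble_pair_dataset
from .pipeline import ModelBundle
from .svm import BITTERANT_SVM, PAIR_SVM, SVMConfig, train_final_model
from .synthetic import synth_molecules, synth_sequences

#: Compact descriptor panels for the demo models (registry subsets).
DEMO_BITTERANT_DESCRIPTORS = [
    "molecular_weight", "logp", "tpsa", "h_bond_donors", "h_bond_acceptors",
    "rotatable_bonds", "ring_count", "aromatic_rings", "heteroatom_count",
    "fraction_csp3", "chi1", "kappa2",
]
DEMO_PAIR_DESCRIPTORS = [
    "molecular_weight", "logp", "tpsa", "aromatic_rings", "heteroatom_count",
    "nitrogen_count", "oxygen_count", "rotatable_bonds",
]


def planted_bitter_label(mol: Molecule) -> int:
    """Demo ground truth: aromatic molecules with a heteroatom are 'bitter'."""
    ring_aromatic = any(a.GetIsAromatic() for a in mol.mol.GetAtoms())
    hetero = any(a.GetSymbol() not in ("C", "H") for a in mol.mol.GetAtoms())
    return 1 if (ring_aromatic and hetero) else -1


def build_demo_bundle(
    directory: str | Path | None = None,
    n_molecules: int = 120,
    n_receptors: int = 25,
    lam: int = 20,
    w: float = 0.05,
    seed: int = 0,
) -> ModelBundle:
    """Train both demo models and (optionally) save a bundle directory."""
    mols = synth_molecules(n_molecules, seed=seed)
    labels = np.array([planted_bitter_label(m) for m in mols])
    if len(np.unique(labels)) < 2:
        raise RuntimeError("planted labeling degenerated to a single class")

    X_bit, _ = descriptor_matrix(mols, DEMO_BITTERANT_DESCRIPTORS)
    bitter_model = train_final_model(
        X_bit,
        labels,
        SVMConfig(**BITTERANT_SVM, cv_folds=5, seed=seed),
        DEMO_BITTERANT_DESCRIPTORS,
        kind="bitterant",
    )

    panel = synth_sequences(n_receptors, length=300, seed=seed + 1)
    table = rf.load_tscale()
    rec_mat, rec_names = rf.receptor_feature_matrix(panel, table, lam, w)
    # planted interaction rule: N-containing molecules pair with A-rich receptors
    a_freq = rec_mat[:, 0]
    a_rich = a_freq > np.median(a_freq)
    bitter_mols = [m for m, lab in zip(mols, labels) if lab == 1]
    has_n = {
        m.id: any(a.GetSymbol() == "N" for a in m.mol.GetAtoms()) for m in bitter_mols
    }
    positive_pairs = [
        (m.id, r.name)
        for m in bitter_mols
        for r, rich in zip(panel, a_rich)
        if has_n[m.id] == bool(rich)
    ]
    rng = np.random.default_rng(seed + 2)
    keep = rng.permutation(len(positive_pairs))[: max(60, 4 * n_receptors)]
    positive_pairs = [positive_pairs[i] for i in sorted(keep)]
    pair_ds = assemble_pair_dataset(positive_pairs, seed=seed + 3)

    mol_by_id = {m.id: m for m in mols}
    rec_by_name = {r.name: i for i, r in enumerate(panel)}
    X_mol, _ = descriptor_matrix(
        [mol_by_id[pair_ds.payload[e][0]] for e in pair_ds.entry_ids],
        DEMO_PAIR_DESCRIPTORS,
    )
    X_rec = np.vstack(
        [rec_mat[rec_by_name[pair_ds.payload[e][1]]] for e in pair_ds.entry_ids]
    )
    X_pair = np.hstack([X_mol, X_rec])
    pair_model = train_final_model(
        X_pair,
        pair_ds.labels,
        SVMConfig(**PAIR_SVM, cv_folds=5, seed=seed),
        DEMO_PAIR_DESCRIPTORS + rec_names,
        kind="pair",
    )

    bundle = ModelBundle(
        bitterant_model=bitter_model,
        pair_model=pair_model,
        receptor_panel=panel,
        lam=lam,
        w=w,
    )
    if directory is not None:
        bundle.save(directory)
    return bundle


def write_fixture_files(directory: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write SMILES lists, FASTA and a labeled dataset table to a directory."""
    from .datasets import write_dataset_tsv

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    mols = synth_molecules(60, seed=seed)
    smiles_path = d / "molecules.smi"
    smiles_path.write_text(
        "".join(f"{m.canonical_smiles}\t{m.id}\n" for m in mols)
    )
    panel = synth_sequences(25, seed=seed + 1)
    fasta_path = d / "receptors.fasta"
    fasta_path.write_text("".join(f">{s.name}\n{s.residues}\n" for s in panel))
    labels = np.array([planted_bitter_label(m) for m in mols])
    ds = LabeledDataset(
        kind="bitterant",
        entry_ids=[m.id for m in mols],
        labels=labels,
        payload={m.id: m for m in mols},
    )
    ds_path = d / "bitterant_dataset.tsv"
    ds_path.write_text(write_dataset_tsv(ds))
    return {"smiles": smiles_path, "fasta": fasta_path, "dataset": ds_path}
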