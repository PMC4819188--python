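"""Seeded synthetic molecules, receptor sequences, and planted-signal data.

Everything the training machinery needs can be generated here without any
external download: valid small molecules assembled from a fragment
grammar, receptor-like random sequences, and Gaussian feature matrices
with a planted class signal.  Feature-level generators bypass chemistry on
purpose so model-layer tests isolate model-layer failures; the molecule
and sequence generators exercise the chemistry and sequence layers
separately.  All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem

from .chemio import Molecule, parse_and_standardize
from .receptors import AMINO_ACIDS, ReceptorSequence

# Fragment grammar: prefix + scaffold + chain + terminal, concatenated as
# SMILES text.  Every combination parses; duplicates are removed by
# canonical SMILES.
_PREFIXES = ["", "C", "CC", "CC(C)", "CCC", "OC"]
_SCAFFOLDS = [
    "",
    "c1ccccc1",
    "c1ccncc1",
    "c1ccc2ccccc2c1",
    "C1CCCCC1",
    "C1CCNCC1",
    "C1CCOC1",
    "c1ccsc1",
    "c1ccc(cc1)",
]
_CHAINS = ["", "C", "CC", "CCC", "CCCC", "CCCCC", "CN", "CO", "CCN"]
_TERMINALS = [
    "",
    "O",
    "N",
    "Cl",
    "F",
    "Br",
    "C(=O)O",
    "C(=O)N",
    "OC",
    "N(C)C",
    "S",
    "C#N",
    "C(C)=O",
    "C(=O)OC",
]


@dataclass
class SyntheticSpec:
    """Planted-signal dataset parameters.

    ``effect_size`` is the standardized mean shift applied to the
    informative features of the positive class; ``label_noise`` is the
    per-sample flip probability.
    """

    n_samples: int = 400
    n_features: int = 50
    n_informative: int = 5
    effect_size: float = 1.5
    label_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative > self.n_features:
            raise ValueError("n_informative cannot exceed n_features")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if not 0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must lie in [0, 0.5)")


def synth_molecules(n: int, seed: int = 0) -> list[Molecule]:
    """Generate ``n`` distinct, standardizable molecules under the grammar."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    seen: set[str] = set()
    out: list[Molecule] = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 200 * n + 1000:
            raise RuntimeError(f"grammar exhausted after {attempts} attempts")
        smi = (
            _PREFIXES[rng.integers(len(_PREFIXES))]
            + _SCAFFOLDS[rng.integers(len(_SCAFFOLDS))]
            + _CHAINS[rng.integers(len(_CHAINS))]
            + _TERMINALS[rng.integers(len(_TERMINALS))]
        )
        if not smi or Chem.MolFromSmiles(smi) is None:
            continue
        mol = parse_and_standardize(smi, "SMILES", mol_id=f"synth{len(out):04d}")
        if mol.canonical_smiles in seen:
            continue
        seen.add(mol.canonical_smiles)
        out.append(mol)
    return out


def synth_sequences(n: int, length: int = 300, seed: int = 0) -> list[ReceptorSequence]:
    """Uniform-composition random sequences of TAS2R-like length."""
    rng = np.random.default_rng(seed)
    letters = np.array(list(AMINO_ACIDS))
    return [
        ReceptorSequence(
            name=f"R{i + 1:02d}",
            residues="".join(letters[rng.integers(20, size=length)]),
        )
        for i in range(n)
    ]


def synth_labeled_dataset(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Two balanced Gaussian classes with a planted mean shift.

    Returns (X, y, informative_idx): features are standard normal, the
    first ``n_informative`` feature indices (a fixed, known ground truth)
    are shifted by ``effect_size`` in the positive class, and labels are
    flipped with probability ``label_noise``.
    """
    rng = np.random.default_rng(spec.seed)
    n_pos = spec.n_samples // 2
    n_neg = spec.n_samples - n_pos
    X = rng.standard_normal((spec.n_samples, spec.n_features))
    y = np.concatenate([np.ones(n_pos, dtype=int), -np.ones(n_neg, dtype=int)])
    informative = np.arange(spec.n_informative)
    X[: n_pos, informative] += spec.effect_size
    if spec.label_noise > 0:
        flips = rng.random(spec.n_samples) < spec.label_noise
        y[flips] *= -1
    perm = rng.permutation(spec.n_samples)
    return X[perm], y[perm], informative
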