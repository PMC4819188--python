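"""Small-molecule I/O, standardization, descriptors and path fingerprints.

Molecules enter as SMILES strings or MDL MOL blocks, are standardized
(salt stripping to the largest organic fragment, charge neutralization,
canonical SMILES), and are then featurized through an open descriptor
registry or hashed linear-path fingerprints for similarity work.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, Lipinski, QED, rdMolDescriptors
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")

#: Heavy-atom ceiling for query molecules (very large inputs are refused).
DEFAULT_ATOM_LIMIT = 200

#: Linear-path fingerprint defaults: paths of 1..7 bonds hashed to 1024 bits.
DEFAULT_FP_BITS = 1024
DEFAULT_FP_MAX_PATH = 7


class MoleculeParseError(ValueError):
    """The input text could not be parsed into a chemical structure."""


class MoleculeSizeError(ValueError):
    """The molecule exceeds the configured heavy-atom limit."""


class DescriptorRegistryError(KeyError):
    """A requested descriptor name is not registered."""


@dataclass(frozen=True)
class Molecule:
    """A standardized small molecule.

    ``atom_count`` counts heavy atoms (hydrogens implicit).  ``mol`` holds
    the underlying RDKit graph of the standardized largest fragment.
    """

    id: str
    canonical_smiles: str
    source_format: str
    atom_count: int
    mol: Chem.Mol = field(repr=False, compare=False)

    def __hash__(self) -> int:  # identity by id + structure
        return hash((self.id, self.canonical_smiles))


@dataclass
class DescriptorVector:
    molecule_id: str
    names: list[str]
    values: np.ndarray  # NaN flags a failed computation

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values.tolist()))


@dataclass
class Fingerprint:
    """Fixed-length bit set from linear-path enumeration."""

    molecule_id: str
    bits: np.ndarray  # bool array

    @property
    def n_bits(self) -> int:
        return self.bits.size

    def popcount(self) -> int:
        return int(self.bits.sum())


_LARGEST_FRAGMENT = rdMolStandardize.LargestFragmentChooser()
_UNCHARGER = rdMolStandardize.Uncharger()


def parse_and_standardize(
    text: str,
    format: str = "SMILES",
    mol_id: str | None = None,
    atom_limit: int = DEFAULT_ATOM_LIMIT,
) -> Molecule:
    """Parse SMILES or MOL-block text into a standardized :class:`Molecule`.

    Standardization strips salts/solvents to the largest organic fragment,
    neutralizes charges where chemically sensible, and canonicalizes the
    SMILES.  Standardizing the output again is a fixed point.

    Raises
    ------
    MoleculeParseError
        If the text is empty or not chemically parseable.
    MoleculeSizeError
        If the heavy-atom count exceeds ``atom_limit``.
    """
    if not text or not text.strip():
        raise MoleculeParseError("empty molecule input")
    fmt = format.upper()
    if fmt == "SMILES":
        raw = Chem.MolFromSmiles(text.strip())
    elif fmt in ("MOL", "SDF"):
        raw = Chem.MolFromMolBlock(text, sanitize=True)
    else:
        raise ValueError(f"unknown molecule format: {format!r}")
    if raw is None:
        snippet = text.strip().splitlines()[0][:60]
        raise MoleculeParseError(f"could not parse {fmt} input: {snippet!r}")

    mol = rdMolStandardize.Cleanup(raw)
    mol = _LARGEST_FRAGMENT.choose(mol)
    mol = _UNCHARGER.uncharge(mol)
    Chem.SanitizeMol(mol)
    n_heavy = mol.GetNumHeavyAtoms()
    if n_heavy > atom_limit:
        raise MoleculeSizeError(
            f"molecule has {n_heavy} heavy atoms; the limit is {atom_limit}"
        )
    smi = Chem.MolToSmiles(mol)
    return Molecule(
        id=mol_id if mol_id is not None else smi,
        canonical_smiles=smi,
        source_format=fmt,
        atom_count=n_heavy,
        mol=mol,
    )


def read_smiles_file(text: str, atom_limit: int = DEFAULT_ATOM_LIMIT) -> list[Molecule]:
    """Read a SMILES list, one molecule per line, optional tab-separated id."""
    out: list[Molecule] = []
    for i, line in enumerate(text.splitlines()):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        smi = parts[0].strip()
        mid = parts[1].strip() if len(parts) > 1 and parts[1].strip() else f"mol{i + 1}"
        out.append(parse_and_standardize(smi, "SMILES", mol_id=mid, atom_limit=atom_limit))
    return out


# ---------------------------------------------------------------------------
# Descriptor registry
# ---------------------------------------------------------------------------

def _count_atoms(symbol: str):
    def counter(mol: Chem.Mol) -> float:
        return float(sum(1 for a in mol.GetAtoms() if a.GetSymbol() == symbol))

    return counter


def _max_abs_partial_charge(mol: Chem.Mol) -> float:
    v = Descriptors.MaxAbsPartialCharge(mol)
    return float(v)


#: Open registry of 2D physicochemical / topological descriptors.  The
#: active subset used by a trained model is a config list; before feature
#: selection the full registry is the candidate pool.
DESCRIPTOR_REGISTRY: dict[str, object] = {
    "molecular_weight": Descriptors.MolWt,
    "exact_mass": Descriptors.ExactMolWt,
    "heavy_atom_count": lambda m: float(m.GetNumHeavyAtoms()),
    "logp": Crippen.MolLogP,
    "molar_refractivity": Crippen.MolMR,
    "tpsa": Descriptors.TPSA,
    "labute_asa": Descriptors.LabuteASA,
    "h_bond_donors": Lipinski.NumHDonors,
    "h_bond_acceptors": Lipinski.NumHAcceptors,
    "nhoh_count": Lipinski.NHOHCount,
    "no_count": Lipinski.NOCount,
    "rotatable_bonds": Lipinski.NumRotatableBonds,
    "ring_count": Descriptors.RingCount,
    "aromatic_rings": Lipinski.NumAromaticRings,
    "saturated_rings": Lipinski.NumSaturatedRings,
    "aliphatic_rings": Lipinski.NumAliphaticRings,
    "heteroatom_count": Lipinski.NumHeteroatoms,
    "fraction_csp3": Lipinski.FractionCSP3,
    "valence_electrons": Descriptors.NumValenceElectrons,
    "radical_electrons": Descriptors.NumRadicalElectrons,
    "formal_charge": lambda m: float(Chem.GetFormalCharge(m)),
    "chi0": Descriptors.Chi0,
    "chi1": Descriptors.Chi1,
    "chi0v": Descriptors.Chi0v,
    "chi1v": Descriptors.Chi1v,
    "chi2v": Descriptors.Chi2v,
    "chi3v": Descriptors.Chi3v,
    "chi4v": Descriptors.Chi4v,
    "chi0n": Descriptors.Chi0n,
    "chi1n": Descriptors.Chi1n,
    "chi2n": Descriptors.Chi2n,
    "chi3n": Descriptors.Chi3n,
    "chi4n": Descriptors.Chi4n,
    "kappa1": Descriptors.Kappa1,
    "kappa2": Descriptors.Kappa2,
    "kappa3": Descriptors.Kappa3,
    "hall_kier_alpha": Descriptors.HallKierAlpha,
    "balaban_j": Descriptors.BalabanJ,
    "bertz_ct": Descriptors.BertzCT,
    "ipc_log": lambda m: float(np.log1p(Descriptors.Ipc(m))),
    "max_partial_charge": Descriptors.MaxPartialCharge,
    "min_partial_charge": Descriptors.MinPartialCharge,
    "max_abs_partial_charge": _max_abs_partial_charge,
    "qed": QED.qed,
    "num_amide_bonds": rdMolDescriptors.CalcNumAmideBonds,
    "num_spiro_atoms": rdMolDescriptors.CalcNumSpiroAtoms,
    "num_bridgehead_atoms": rdMolDescriptors.CalcNumBridgeheadAtoms,
    "num_stereocenters": rdMolDescriptors.CalcNumAtomStereoCenters,
    "carbon_count": _count_atoms("C"),
    "nitrogen_count": _count_atoms("N"),
    "oxygen_count": _count_atoms("O"),
    "sulfur_count": _count_atoms("S"),
    "halogen_count": lambda m: float(
        sum(1 for a in m.GetAtoms() if a.GetSymbol() in ("F", "Cl", "Br", "I"))
    ),
    "estate_vsa1": Descriptors.EState_VSA1,
    "estate_vsa2": Descriptors.EState_VSA2,
    "slogp_vsa1": Descriptors.SlogP_VSA1,
    "slogp_vsa2": Descriptors.SlogP_VSA2,
    "smr_vsa1": Descriptors.SMR_VSA1,
    "peoe_vsa1": Descriptors.PEOE_VSA1,
}


def registry_names() -> list[str]:
    """All registered descriptor names in registry order."""
    return list(DESCRIPTOR_REGISTRY)


def compute_descriptors(mol: Molecule, names: list[str] | None = None) -> DescriptorVector:
    """Compute registered descriptors for one molecule.

    Unknown names raise :class:`DescriptorRegistryError`; a computation that
    fails or returns a non-finite number is flagged as NaN (missing), to be
    removed later by the feature prefilter.
    """
    if names is None:
        names = registry_names()
    values = np.empty(len(names), dtype=float)
    for j, name in enumerate(names):
        try:
            fn = DESCRIPTOR_REGISTRY[name]
        except KeyError:
            raise DescriptorRegistryError(
                f"descriptor {name!r} is not in the registry"
            ) from None
        try:
            v = float(fn(mol.mol))
        except Exception:
            v = math.nan
        values[j] = v if math.isfinite(v) else math.nan
    return DescriptorVector(molecule_id=mol.id, names=list(names), values=values)


def descriptor_matrix(
    mols: list[Molecule], names: list[str] | None = None
) -> tuple[np.ndarray, list[str]]:
    """Stack descriptor vectors into an (n_molecules, n_descriptors) matrix."""
    if names is None:
        names = registry_names()
    X = np.vstack([compute_descriptors(m, names).values for m in mols])
    return X, list(names)


# ---------------------------------------------------------------------------
# Fingerprints
# ---------------------------------------------------------------------------

def path_fingerprint(
    mol: Molecule,
    n_bits: int = DEFAULT_FP_BITS,
    max_path: int = DEFAULT_FP_MAX_PATH,
) -> Fingerprint:
    """Hash linear bond paths (1..max_path bonds) into a fixed bit set.

    This is a path-based fingerprint dialect in the FP2 family; it is
    deterministic and graph-determined but not bit-compatible with any
    third-party tool.
    """
    if n_bits < 64 or (n_bits & (n_bits - 1)) != 0:
        raise ValueError("n_bits must be a power of two >= 64")
    bv = Chem.RDKFingerprint(
        mol.mol, minPath=1, maxPath=max_path, fpSize=n_bits, branchedPaths=False
    )
    bits = np.zeros(n_bits, dtype=bool)
    bits[list(bv.GetOnBits())] = True
    if not bits.any() and mol.atom_count > 0:
        # bond-less molecules (single heavy atom) have no paths; hash the
        # atom itself so the fingerprint is never empty
        bits[zlib.crc32(mol.canonical_smiles.encode()) % n_bits] = True
    return Fingerprint(molecule_id=mol.id, bits=bits)


def tanimoto_similarity(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto coefficient |a AND b| / |a OR b|; 0.0 when both are empty."""
    if a.n_bits != b.n_bits:
        raise ValueError(f"fingerprint length mismatch: {a.n_bits} vs {b.n_bits}")
    union = int(np.logical_or(a.bits, b.bits).sum())
    if union == 0:
        return 0.0
    inter = int(np.logical_and(a.bits, b.bits).sum())
    return inter / union
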