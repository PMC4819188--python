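"""Receptor sequence encoding: pseudo amino acid composition on the T-scale.

Each TAS2R primary sequence is encoded as the classic pseudo amino acid
composition (PseAAC): the 20 residue frequencies plus lambda sequence-order
correlation factors theta_k, computed from a 5-dimensional residue property
scale.  The bundled scale is the T-scale (principal components of
topological descriptors over 67 amino acids); any 20x5 scale table can be
substituted through the config.

With f_u the frequency of residue u and theta_k the k-th correlation
factor, the feature vector is

    x_u      = f_u / (1 + w * sum_k theta_k)           u = 1..20
    x_{20+k} = w * theta_k / (1 + w * sum_k theta_k)   k = 1..lambda

so the 20+lambda values are non-negative and sum to one.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from importlib import resources

import numpy as np
from Bio import SeqIO

#: Canonical residue alphabet and its fixed ordering in feature vectors.
AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

DEFAULT_LAMBDA = 20
DEFAULT_WEIGHT = 0.05


class SequenceValidationError(ValueError):
    """A record is empty or contains a non-standard residue letter."""


@dataclass(frozen=True)
class ReceptorSequence:
    name: str
    residues: str

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass
class ScaleTable:
    """Per-residue property vectors, 20 rows x 5 columns (T1..T5).

    After :meth:`standardized`, every column has zero mean and unit
    variance over the 20 standard residues.
    """

    values: np.ndarray  # (20, 5), rows in AMINO_ACIDS order
    is_standardized: bool = False

    def standardized(self) -> "ScaleTable":
        if self.is_standardized:
            return self
        mu = self.values.mean(axis=0)
        sd = self.values.std(axis=0)  # population SD over the 20 residues
        return ScaleTable(values=(self.values - mu) / sd, is_standardized=True)

    def row(self, residue: str) -> np.ndarray:
        return self.values[_AA_INDEX[residue]]


@dataclass
class ReceptorFeatureVector:
    name: str
    values: np.ndarray  # length 20 + lam
    lam: int
    w: float

    @property
    def composition(self) -> np.ndarray:
        return self.values[:20]

    @property
    def correlation(self) -> np.ndarray:
        return self.values[20:]


def load_tscale() -> ScaleTable:
    """Load and standardize the bundled T-scale table."""
    text = resources.files("bitterx.data").joinpath("tscale.tsv").read_text()
    return parse_scale_table(text).standardized()


def parse_scale_table(text: str) -> ScaleTable:
    """Parse a 20-row, 5-column residue scale from tab-delimited text."""
    rows: dict[str, np.ndarray] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        aa, vals = parts[0], parts[1:]
        if aa not in _AA_INDEX or len(vals) != 5:
            raise ValueError(f"bad scale-table row: {line!r}")
        rows[aa] = np.array([float(v) for v in vals])
    missing = set(AMINO_ACIDS) - set(rows)
    if missing:
        raise ValueError(f"scale table missing residues: {sorted(missing)}")
    return ScaleTable(values=np.vstack([rows[aa] for aa in AMINO_ACIDS]))


def validate_sequence(name: str, residues: str, impute_unknown: bool = False) -> str:
    """Uppercase, strip whitespace, and check the residue alphabet.

    With ``impute_unknown`` non-standard letters are replaced by 'X'
    placeholders to be imputed at encoding time; otherwise they raise.
    """
    seq = "".join(residues.split()).upper()
    if not seq:
        raise SequenceValidationError(f"record {name!r} has an empty sequence")
    for pos, ch in enumerate(seq, start=1):
        if ch not in _AA_INDEX and not impute_unknown:
            raise SequenceValidationError(
                f"record {name!r}: illegal residue {ch!r} at position {pos}"
            )
    return seq


def read_receptor_fasta(text: str, impute_unknown: bool = False) -> list[ReceptorSequence]:
    """Read receptor sequences from FASTA text, preserving record order."""
    records = list(SeqIO.parse(io.StringIO(text), "fasta"))
    if not records:
        raise SequenceValidationError("no FASTA records found")
    out = []
    for rec in records:
        seq = validate_sequence(rec.id, str(rec.seq), impute_unknown=impute_unknown)
        out.append(ReceptorSequence(name=rec.id, residues=seq))
    return out


def _residue_rows(seq: str, table: ScaleTable) -> np.ndarray:
    """Scale rows for each sequence position; unknown letters map to the
    column mean, which is zero after standardization."""
    rows = np.zeros((len(seq), table.values.shape[1]))
    for i, ch in enumerate(seq):
        idx = _AA_INDEX.get(ch)
        if idx is not None:
            rows[i] = table.values[idx]
    return rows


def tscale_correlation(seq: ReceptorSequence, k: int, table: ScaleTable) -> float:
    """Sequence-order correlation factor theta_k.

    theta_k = (1/(L-k)) * sum_i Theta(R_i, R_{i+k}) where
    Theta(a, b) = (1/5) * sum_t (T_t(a) - T_t(b))^2.  Always >= 0.
    """
    L = seq.length
    if not 1 <= k < L:
        raise ValueError(f"need 1 <= k < L; got k={k}, L={L}")
    if not table.is_standardized:
        raise ValueError("scale table must be standardized before encoding")
    rows = _residue_rows(seq.residues, table)
    diffs = rows[:-k] - rows[k:]
    return float(np.mean(np.mean(diffs**2, axis=1)))


def pseaac_features(
    seq: ReceptorSequence,
    table: ScaleTable | None = None,
    lam: int = DEFAULT_LAMBDA,
    w: float = DEFAULT_WEIGHT,
) -> ReceptorFeatureVector:
    """Classic PseAAC feature vector of length 20 + lam (sums to one)."""
    if table is None:
        table = load_tscale()
    if w <= 0:
        raise ValueError("w must be positive")
    L = seq.length
    if L <= lam:
        raise ValueError(
            f"sequence {seq.name!r} has length {L} <= lambda={lam}; lower lambda"
        )
    counts = np.zeros(20)
    for ch in seq.residues:
        idx = _AA_INDEX.get(ch)
        if idx is not None:
            counts[idx] += 1
    freqs = counts / L
    thetas = np.array([tscale_correlation(seq, k, table) for k in range(1, lam + 1)])
    denom = 1.0 + w * thetas.sum()
    values = np.concatenate([freqs / denom, w * thetas / denom])
    return ReceptorFeatureVector(name=seq.name, values=values, lam=lam, w=w)


def pseaac_feature_names(lam: int = DEFAULT_LAMBDA) -> list[str]:
    """Feature names matching :func:`pseaac_features` ordering."""
    return [f"aa_{aa}" for aa in AMINO_ACIDS] + [f"theta_{k}" for k in range(1, lam + 1)]


def receptor_feature_matrix(
    seqs: list[ReceptorSequence],
    table: ScaleTable | None = None,
    lam: int = DEFAULT_LAMBDA,
    w: float = DEFAULT_WEIGHT,
) -> tuple[np.ndarray, list[str]]:
    """Stack PseAAC vectors for many receptors into a feature matrix."""
    if table is None:
        table = load_tscale()
    X = np.vstack([pseaac_features(s, table, lam, w).values for s in seqs])
    return X, pseaac_feature_names(lam)
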