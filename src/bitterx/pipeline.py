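"""The two-stage query: bitterant verification, then TAS2R recognition.

A model bundle directory holds everything a query needs:

    bundle/
      config.yaml        # receptor encoding parameters (lambda, w)
      receptors.fasta    # the receptor panel to rank
      bitterant_model/   # text-serialized SVM+Platt bundle (kind=bitterant)
      pair_model/        # text-serialized SVM+Platt bundle (kind=pair)

Stage 1 computes the bitterant model's descriptors for the query molecule
and calibrates its decision value into a bitterness probability; the
molecule is called bitter at probability >= 0.5.  Stage 2 (run only for
predicted bitterants) concatenates the molecule's pair-model descriptors
with each receptor's PseAAC features, scores every (molecule, receptor)
pair, and returns all receptors ranked by interaction probability
(0% = confident non-interaction, 100% = confident interaction), ties
broken by receptor name.  Results are written as an XML report with a
fixed attribute order so identical queries produce byte-identical files
up to the timestamp-derived job id.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field
from pathlib import Path
from xml.sax.saxutils import quoteattr

import numpy as np
import yaml

from . import receptors as rf
from .chemio import DESCRIPTOR_REGISTRY, Molecule, compute_descriptors, parse_and_standardize
from .svm import TrainedModel, load_model, save_model

logger = logging.getLogger("bitterx")

BITTER_THRESHOLD = 0.5


@dataclass
class PredictionResult:
    job_name: str
    job_id: str
    molecule: Molecule
    is_bitter: bool
    bitter_probability: float
    receptor_ranking: list[tuple[str, float]] = field(default_factory=list)


@dataclass
class ModelBundle:
    """Loaded prediction assets: both models, receptor panel, encoding."""

    bitterant_model: TrainedModel
    pair_model: TrainedModel
    receptor_panel: list[rf.ReceptorSequence]
    lam: int
    w: float
    _receptor_features: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        table = rf.load_tscale()
        for seq in self.receptor_panel:
            vec = rf.pseaac_features(seq, table, self.lam, self.w)
            self._receptor_features[seq.name] = vec.values

    @classmethod
    def load(cls, directory: str | Path) -> "ModelBundle":
        d = Path(directory)
        cfg = yaml.safe_load((d / "config.yaml").read_text())
        panel = rf.read_receptor_fasta((d / "receptors.fasta").read_text())
        return cls(
            bitterant_model=load_model(d / "bitterant_model"),
            pair_model=load_model(d / "pair_model"),
            receptor_panel=panel,
            lam=int(cfg["receptor"]["lambda"]),
            w=float(cfg["receptor"]["w"]),
        )

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        (d / "config.yaml").write_text(
            yaml.safe_dump({"receptor": {"lambda": self.lam, "w": self.w}})
        )
        fasta = "".join(
            f">{s.name}\n{s.residues}\n" for s in self.receptor_panel
        )
        (d / "receptors.fasta").write_text(fasta)
        save_model(self.bitterant_model, d / "bitterant_model")
        save_model(self.pair_model, d / "pair_model")


def _molecular_feature_subvector(mol: Molecule, names: list[str]) -> np.ndarray:
    """Descriptor values for the molecular members of a feature-name list."""
    vec = compute_descriptors(mol, names)
    if np.isnan(vec.values).any():
        bad = [n for n, v in zip(names, vec.values) if np.isnan(v)]
        raise ValueError(
            f"descriptor(s) {bad} failed for molecule {mol.id!r}"
        )
    return vec.values


def verify_bitterant(mol: Molecule, model: TrainedModel) -> tuple[bool, float]:
    """Stage 1: bitterness probability and the >= 0.5 bitter/non-bitter call."""
    if model.kind != "bitterant":
        raise ValueError("verification requires a bitterant-kind model")
    x = _molecular_feature_subvector(mol, model.feature_names)
    prob = float(model.predict_probability(x[None, :])[0])
    return prob >= BITTER_THRESHOLD, prob


def rank_receptors(
    mol: Molecule, bundle: ModelBundle
) -> list[tuple[str, float]]:
    """Stage 2: score the molecule against every receptor in the panel.

    Returns (receptor name, probability) sorted by probability descending,
    ties broken by receptor name, covering the full panel.
    """
    model = bundle.pair_model
    if model.kind != "pair":
        raise ValueError("recognition requires a pair-kind model")
    mol_names = [n for n in model.feature_names if n in DESCRIPTOR_REGISTRY]
    rec_names = [n for n in model.feature_names if n not in DESCRIPTOR_REGISTRY]
    if mol_names + rec_names != model.feature_names:
        raise ValueError("pair model expects molecular features before receptor features")
    mol_part = _molecular_feature_subvector(mol, mol_names)
    all_names = rf.pseaac_feature_names(bundle.lam)
    rec_idx = [all_names.index(n) for n in rec_names]
    rows = []
    panel_names = []
    for seq in bundle.receptor_panel:
        rec_part = bundle._receptor_features[seq.name][rec_idx]
        rows.append(np.concatenate([mol_part, rec_part]))
        panel_names.append(seq.name)
    probs = model.predict_probability(np.vstack(rows))
    ranking = sorted(zip(panel_names, probs.tolist()), key=lambda t: (-t[1], t[0]))
    return ranking


def render_xml(result: PredictionResult) -> str:
    """Byte-stable XML report (fixed attribute order, full precision)."""
    lines = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f"<bitterx job_id={quoteattr(result.job_id)} job_name={quoteattr(result.job_name)}>",
        f"  <molecule smiles={quoteattr(result.molecule.canonical_smiles)}"
        f" atoms={quoteattr(str(result.molecule.atom_count))}/>",
        f"  <verification probability={quoteattr(repr(result.bitter_probability))}"
        f" class={quoteattr('bitter' if result.is_bitter else 'non-bitter')}/>",
        "  <recognition>",
    ]
    for rank, (name, prob) in enumerate(result.receptor_ranking, start=1):
        lines.append(
            f"    <receptor name={quoteattr(name)} probability={quoteattr(repr(prob))}"
            f" rank={quoteattr(str(rank))}/>"
        )
    lines += ["  </recognition>", "</bitterx>", ""]
    return "\n".join(lines)


def run_query(
    input_text: str,
    format: str,
    job_name: str,
    bundle: ModelBundle,
    out_dir: str | Path | None = None,
    mol_id: str | None = None,
) -> PredictionResult:
    """Parse, standardize, verify, and (for bitterants) rank receptors.

    ``job_name`` is mandatory; the job id derives from the current date
    and time.  An XML report is always written when ``out_dir`` is given,
    including for non-bitter verdicts (with an empty recognition section).
    """
    if not job_name or not job_name.strip():
        raise ValueError("job_name is mandatory")
    job_id = _dt.datetime.now().strftime("%Y%m%d%H%M%S%f")
    try:
        mol = parse_and_standardize(input_text, format, mol_id=mol_id)
        logger.info("job %s: parsed %s (%d atoms)", job_id, mol.id, mol.atom_count)
        is_bitter, prob = verify_bitterant(mol, bundle.bitterant_model)
        logger.info("job %s: verification p=%.4f -> %s", job_id, prob,
                    "bitter" if is_bitter else "non-bitter")
        ranking = rank_receptors(mol, bundle) if is_bitter else []
        if ranking:
            logger.info("job %s: top receptor %s (p=%.4f)", job_id, *ranking[0])
    except Exception as exc:
        raise type(exc)(f"[job {job_name!r}] {exc}") from exc
    result = PredictionResult(
        job_name=job_name.strip(),
        job_id=job_id,
        molecule=mol,
        is_bitter=is_bitter,
        bitter_probability=prob,
        receptor_ranking=ranking,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        path = out / f"{result.job_name}_{mol.id}.xml"
        path.write_text(render_xml(result), encoding="utf-8")
        logger.info("job %s: report written to %s", job_id, path)
    return result
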