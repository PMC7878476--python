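"""Cross-link satisfaction scoring of structures and multi-model ensembles.

A cross-link is *satisfied* by a model when the inter-residue distance is
within the geometric reach of the cross-link chemistry: 21 Å for
acid-acid (ADH) and 16 Å for acid-lysine (DMTMM) contacts, inclusive.
The distance convention defaults to Cα–Cα, which is robust for models
lacking side-chain atoms and consistent with the magnitude of the bounds;
Cβ and reactive-terminal-atom rules are available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import gemmi
import numpy as np

from .linker_chemistry import CrosslinkerSpec, REGISTRY
from .xl_tables import CrosslinkRecord

# Terminal side-chain atom carrying the reactive group, per residue type.
REACTIVE_TERMINAL_ATOM = {"K": "NZ", "D": "CG", "E": "CD"}

# Fallback order per atom rule: first present atom wins.
_ATOM_RULES = {
    "CA": ("CA",),
    "CB": ("CB", "CA"),
}


@dataclass
class StructureModel:
    """One structural model: per-residue atom coordinates for one chain.

    ``atoms`` maps residue number -> {atom name -> xyz (Å)};
    ``restypes`` maps residue number -> one-letter residue code.
    """

    model_id: str
    atoms: dict[int, dict[str, np.ndarray]]
    restypes: dict[int, str] = field(default_factory=dict)
    chain_id: str = "A"

    def residues(self) -> list[int]:
        return sorted(self.atoms)

    def atom_xyz(self, residue: int, atom_rule: str) -> np.ndarray:
        if residue not in self.atoms:
            raise KeyError(
                f"residue {residue} not present in model {self.model_id}")
        res_atoms = self.atoms[residue]
        if atom_rule == "reactive-terminal":
            restype = self.restypes.get(residue, "")
            names = (REACTIVE_TERMINAL_ATOM.get(restype, "CA"), "CB", "CA")
        else:
            try:
                names = _ATOM_RULES[atom_rule]
            except KeyError:
                raise ValueError(f"unknown atom rule {atom_rule!r}") from None
        for name in names:
            if name in res_atoms:
                return res_atoms[name]
        raise KeyError(
            f"no atom for rule {atom_rule!r} in residue {residue} "
            f"of model {self.model_id}")


@dataclass
class StructureEnsemble:
    """Ordered list of models sharing a residue numbering."""

    models: list[StructureModel]

    def __len__(self) -> int:
        return len(self.models)

    def common_residues(self) -> set[int]:
        sets = [set(m.atoms) for m in self.models]
        return set.intersection(*sets) if sets else set()


@dataclass
class SatisfactionReport:
    """Per-model and per-link satisfaction summary for an ensemble."""

    model_ids: list[str]
    link_labels: list[str]
    satisfied: np.ndarray            # bool, shape (n_models, n_links)
    flagged_missing: np.ndarray      # bool, same shape: residue absent

    @property
    def per_model_counts(self) -> np.ndarray:
        return self.satisfied.sum(axis=1)

    @property
    def per_link_fractions(self) -> np.ndarray:
        return self.satisfied.mean(axis=0)

    @property
    def best_models(self) -> list[str]:
        counts = self.per_model_counts
        best = counts.max()
        return [m for m, c in zip(self.model_ids, counts) if c == best]

    def histogram(self) -> dict[int, int]:
        """Number of models per satisfied-link count; bins sum to n_models."""
        counts = self.per_model_counts
        return {int(k): int((counts == k).sum())
                for k in range(self.satisfied.shape[1] + 1)}


# ------------------------------------------------------------- PDB I/O

def _one_letter(resname: str) -> str:
    code = gemmi.find_tabulated_residue(resname)
    return code.one_letter_code.upper() if code else "X"


def read_pdb_ensemble(path: str, chain_id: str | None = None
                      ) -> StructureEnsemble:
    """Read a multi-MODEL PDB file into an ensemble (one chain per model)."""
    structure = gemmi.read_structure(str(path))
    structure.setup_entities()
    models = []
    for model in structure:
        chains = list(model)
        if chain_id is not None:
            chains = [c for c in chains if c.name == chain_id]
            if not chains:
                raise ValueError(f"chain {chain_id!r} absent in model {model.num}")
        chain = chains[0]
        atoms: dict[int, dict[str, np.ndarray]] = {}
        restypes: dict[int, str] = {}
        for residue in chain:
            num = residue.seqid.num
            atoms[num] = {
                atom.name: np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                for atom in residue
            }
            restypes[num] = _one_letter(residue.name)
        models.append(StructureModel(
            model_id=str(model.num), atoms=atoms, restypes=restypes,
            chain_id=chain.name))
    return StructureEnsemble(models=models)


_THREE_LETTER = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR", "X": "UNK",
}


def write_pdb_ensemble(ensemble: StructureEnsemble, path: str) -> None:
    """Write an ensemble as a multi-MODEL PDB file via gemmi."""
    structure = gemmi.Structure()
    structure.name = "ensemble"
    for i, model in enumerate(ensemble.models, start=1):
        gmodel = gemmi.Model(i)
        chain = gemmi.Chain(model.chain_id)
        for resnum in model.residues():
            residue = gemmi.Residue()
            residue.name = _THREE_LETTER.get(
                model.restypes.get(resnum, "X"), "UNK")
            residue.seqid = gemmi.SeqId(resnum, " ")
            for name, xyz in model.atoms[resnum].items():
                atom = gemmi.Atom()
                atom.name = name
                atom.element = gemmi.Element(name[0])
                atom.pos = gemmi.Position(*map(float, xyz))
                residue.add_atom(atom)
            chain.add_residue(residue)
        gmodel.add_chain(chain)
        structure.add_model(gmodel)
    structure.setup_entities()
    structure.write_pdb(str(path))


# ----------------------------------------------------------- operations

def pair_distance(model: StructureModel, residue_a: int, residue_b: int,
                  atom_rule: str = "CA") -> float:
    """Euclidean distance (Å) between two residues under an atom rule."""
    xa = model.atom_xyz(residue_a, atom_rule)
    xb = model.atom_xyz(residue_b, atom_rule)
    return float(np.linalg.norm(xa - xb))


def satisfied(link: CrosslinkRecord, model: StructureModel,
              registry: dict[str, CrosslinkerSpec] | None = None,
              atom_rule: str = "CA") -> bool:
    """True iff the link distance is within (<=, inclusive) the chemistry's
    maximum distance."""
    reg = REGISTRY if registry is None else registry
    if link.chemistry not in reg:
        raise KeyError(f"chemistry {link.chemistry!r} not registered")
    spec = reg[link.chemistry]
    d = pair_distance(model, link.residue_a, link.residue_b, atom_rule)
    return d <= spec.max_distance


def score_ensemble(links: Sequence[CrosslinkRecord],
                   ensemble: StructureEnsemble,
                   registry: dict[str, CrosslinkerSpec] | None = None,
                   atom_rule: str = "CA") -> SatisfactionReport:
    """Score every link against every model.

    Models missing a linked residue contribute "unsatisfiable" (False)
    for that link and are flagged rather than dropped, so the histogram
    mass always equals the number of models.
    """
    if not links:
        raise ValueError("link list is empty")
    if not ensemble.models:
        raise ValueError("ensemble is empty")
    reg = REGISTRY if registry is None else registry
    n_models, n_links = len(ensemble.models), len(links)
    sat = np.zeros((n_models, n_links), dtype=bool)
    missing = np.zeros((n_models, n_links), dtype=bool)
    for i, model in enumerate(ensemble.models):
        for j, link in enumerate(links):
            try:
                sat[i, j] = satisfied(link, model, reg, atom_rule)
            except KeyError as exc:
                if link.chemistry not in reg:
                    raise
                missing[i, j] = True
    labels = [f"{l.residue_a}-{l.residue_b}:{l.chemistry}" for l in links]
    return SatisfactionReport(
        model_ids=[m.model_id for m in ensemble.models],
        link_labels=labels, satisfied=sat, flagged_missing=missing)


def threshold_sensitivity(links: Sequence[CrosslinkRecord],
                          ensemble: StructureEnsemble,
                          thresholds: Sequence[float],
                          atom_rule: str = "CA") -> np.ndarray:
    """Satisfied-count curve per model over a shared threshold sweep.

    Applies each candidate threshold to every link regardless of
    chemistry, as a robustness check on the chemistry-specific bounds.
    Returns an (n_models, n_thresholds) count array, non-decreasing along
    the threshold axis.
    """
    thresholds = list(thresholds)
    if any(t <= 0 for t in thresholds):
        raise ValueError("thresholds must be positive")
    if sorted(thresholds) != thresholds:
        raise ValueError("thresholds must be sorted ascending")
    counts = np.zeros((len(ensemble.models), len(thresholds)), dtype=int)
    for i, model in enumerate(ensemble.models):
        dists = []
        for link in links:
            try:
                dists.append(pair_distance(
                    model, link.residue_a, link.residue_b, atom_rule))
            except KeyError:
                dists.append(math.inf)
        d = np.array(dists)
        for k, t in enumerate(thresholds):
            counts[i, k] = int((d <= t).sum())
    return counts
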