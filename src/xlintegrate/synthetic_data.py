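"""Seeded synthetic-data generators for every pipeline stage.

Each generator draws from an independent RNG stream derived from
(seed, stage-name), so adding a generator never perturbs existing
fixtures, and every output is a pure function of its arguments.

What these emulate — and what they do not: cross-link tables carry
planted true (geometrically satisfiable) and decoy (unsatisfiable)
pairs, but no peptide-level ambiguity or search-engine FDR structure;
structural ensembles are a base conformation plus isotropic Gaussian
jitter, not a physically relaxed ensemble; FP curves are the exact
depletion model plus Gaussian noise; peak lists are uniform draws over
plausible amide ppm ranges with planted displacements.
"""

from __future__ import annotations

import zlib

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .binding_models import TitrationCurve, dilution_series, \
    fraction_bound_one_site
from .collapse_model import BeadChain, BOND_LENGTH
from .ensemble_satisfaction import StructureEnsemble, StructureModel
from .linker_chemistry import CrosslinkerSpec, REGISTRY
from .nmr_csp import Peak, PeakList
from .xl_tables import CrosslinkRecord

MIN_SELF_AVOID = 3.5  # Å, minimum pairwise bead distance in generated chains


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent RNG stream for (seed, stage)."""
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(stage.encode())]))


# ----------------------------------------------------------- structures

def gen_chain(n: int, seed: int, compactness: float = 0.5,
              max_attempts: int = 200) -> BeadChain:
    """Self-avoiding random bead chain with fixed 3.8 Å bonds.

    Grows the chain bead by bead with rejection of placements closer
    than 3.5 Å to any previous bead; ``compactness`` in [0, 1] biases
    new bonds back toward the centroid (0 = straight-ish, 1 = tightly
    turning). Restarts on dead ends; raises after ``max_attempts``
    restarts.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    rng = stage_rng(seed, "chain")
    for _attempt in range(max_attempts):
        coords = np.zeros((n, 3))
        coords[1] = (BOND_LENGTH, 0.0, 0.0)
        ok = True
        for i in range(2, n):
            placed = False
            for _trial in range(60):
                direction = rng.normal(size=3)
                if compactness > 0:
                    to_center = coords[:i].mean(axis=0) - coords[i - 1]
                    norm = np.linalg.norm(to_center)
                    if norm > 1e-9:
                        direction = (1 - compactness) * direction \
                            + compactness * rng.uniform(0, 2) * to_center / norm
                direction /= np.linalg.norm(direction)
                candidate = coords[i - 1] + BOND_LENGTH * direction
                d = np.linalg.norm(coords[:i - 1] - candidate, axis=1)
                if (d >= MIN_SELF_AVOID).all():
                    coords[i] = candidate
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            return BeadChain(coords)
    raise RuntimeError(
        f"could not grow a self-avoiding chain of {n} beads "
        f"after {max_attempts} restarts; reduce compactness")


def gen_ensemble(base: BeadChain | np.ndarray, n_models: int,
                 jitter: float, seed: int) -> StructureEnsemble:
    """Ensemble of CA-only models: base coordinates plus per-model
    isotropic Gaussian jitter (Å)."""
    if n_models < 1:
        raise ValueError("need n_models >= 1")
    if jitter < 0:
        raise ValueError("jitter must be >= 0")
    coords = base.coords if isinstance(base, BeadChain) else np.asarray(base)
    rng = stage_rng(seed, "ensemble")
    models = []
    for m in range(n_models):
        xyz = coords + rng.normal(0.0, jitter, size=coords.shape) \
            if jitter > 0 else coords.copy()
        atoms = {i + 1: {"CA": xyz[i]} for i in range(len(xyz))}
        restypes = {i + 1: "A" for i in range(len(xyz))}
        models.append(StructureModel(model_id=str(m + 1), atoms=atoms,
                                     restypes=restypes))
    return StructureEnsemble(models=models)


def plant_crosslinks(model: StructureModel, chemistry: str,
                     n_true: int, n_decoy: int, seed: int,
                     protein: str = "SYN", condition: str = "synthetic",
                     decoy_margin: float = 2.0,
                     min_separation: int = 3,
                     registry: dict[str, CrosslinkerSpec] | None = None
                     ) -> tuple[list[CrosslinkRecord], dict]:
    """Sample cross-link records with known satisfaction labels.

    True links are residue pairs within the chemistry's distance bound on
    the source model; decoys lie beyond bound + ``decoy_margin`` Å.
    Residue types in the records are rewritten to be
    chemistry-compatible. Returns (records, ground truth) where the
    truth maps each canonical residue pair to its planted label.
    """
    reg = REGISTRY if registry is None else registry
    spec = reg[chemistry]
    rng = stage_rng(seed, "plant_crosslinks")
    residues = model.residues()
    xyz = np.array([model.atoms[r]["CA"] for r in residues])
    dmat = squareform(pdist(xyz))
    n = len(residues)
    iu, ju = np.triu_indices(n, k=min_separation)
    d = dmat[iu, ju]
    true_pool = np.flatnonzero(d <= spec.max_distance)
    decoy_pool = np.flatnonzero(d > spec.max_distance + decoy_margin)
    if len(true_pool) < n_true or len(decoy_pool) < n_decoy:
        raise ValueError(
            f"infeasible request: {len(true_pool)} satisfiable and "
            f"{len(decoy_pool)} decoy pairs available "
            f"(asked for {n_true} + {n_decoy})")
    chosen_true = rng.choice(true_pool, size=n_true, replace=False)
    chosen_decoy = rng.choice(decoy_pool, size=n_decoy, replace=False)
    type_a = sorted(spec.reactive_pair[0])
    type_b = sorted(spec.reactive_pair[1])
    records: list[CrosslinkRecord] = []
    truth: dict[tuple[int, int], bool] = {}
    for pool, label in ((chosen_true, True), (chosen_decoy, False)):
        for k in pool:
            ra, rb = residues[iu[k]], residues[ju[k]]
            records.append(CrosslinkRecord(
                protein_a=protein, residue_a=ra,
                restype_a=str(rng.choice(type_a)),
                protein_b=protein, residue_b=rb,
                restype_b=str(rng.choice(type_b)),
                chemistry=chemistry, condition=condition))
            truth[(ra, rb)] = label
    return records, truth


# ------------------------------------------------------------------- FP

def gen_fp_curve(kd: float, tracer: float = 0.2, top_dose: float = 150.0,
                 n_points: int = 12, plateaus: tuple[float, float] = (50.0, 200.0),
                 sigma: float = 5.0, replicates: int = 3,
                 seed: int = 0) -> TitrationCurve:
    """Synthetic one-site FP titration: exact depletion model + Gaussian
    noise (mP). Defaults mirror a typical plate assay: 0.2 µM tracer,
    two-fold dilutions from 150 µM plus zero, triplicate, σ = 5 mP."""
    if kd <= 0:
        raise ValueError("kd must be positive")
    rng = stage_rng(seed, "fp_curve")
    series = dilution_series(top_dose, n_points)
    p_free, p_bound = plateaus
    conc = np.tile(series, replicates)
    frac = fraction_bound_one_site(tracer, conc, kd)
    signal = p_free + (p_bound - p_free) * frac
    noise = rng.normal(0.0, sigma, size=signal.shape) if sigma > 0 else 0.0
    return TitrationCurve(
        concentrations=conc, polarizations=signal + noise,
        replicates=np.repeat(np.arange(replicates), len(series)),
        tracer_conc=tracer)


def gen_competition_curve(kd1: float, kd2: float, comp1_conc: float = 3.125,
                          tracer: float = 0.2, top_dose: float = 150.0,
                          n_points: int = 12,
                          plateaus: tuple[float, float, float] = (50.0, 120.0, 200.0),
                          sigma: float = 5.0, replicates: int = 3,
                          seed: int = 0) -> TitrationCurve:
    """Synthetic competition titration: tracer pre-incubated with a fixed
    competitor (Kd1), titrated with the second partner (Kd2)."""
    from .binding_models import competitive_equilibrium
    rng = stage_rng(seed, "fp_competition")
    series = dilution_series(top_dose, n_points)
    conc = np.tile(series, replicates)
    p_free, p_b1, p_b2 = plateaus
    signal = np.empty_like(conc)
    for i, h in enumerate(conc):
        fr = competitive_equilibrium(tracer, comp1_conc, h, kd1, kd2)
        signal[i] = fr["free"] * p_free + fr["bound1"] * p_b1 \
            + fr["bound2"] * p_b2
    noise = rng.normal(0.0, sigma, size=signal.shape) if sigma > 0 else 0.0
    return TitrationCurve(
        concentrations=conc, polarizations=signal + noise,
        replicates=np.repeat(np.arange(replicates), len(series)),
        tracer_conc=tracer, competitor_conc=comp1_conc, competitor_kd=kd1)


# ------------------------------------------------------------------ NMR

AMIDE_H_RANGE = (6.0, 10.0)   # ppm
AMIDE_N_RANGE = (100.0, 135.0)


def gen_peaklists(n_residues: int, perturbed_set: set[int],
                  magnitude: float = 0.02, jitter: float = 0.0,
                  seed: int = 0, proline_positions: set[int] | None = None
                  ) -> tuple[PeakList, PeakList, dict]:
    """Reference and titrated HSQC peak lists with planted perturbations.

    Reference peaks are uniform over plausible amide ranges (δH 6–10,
    δN 100–135 ppm). Perturbed residues are displaced by ``magnitude``
    ppm of combined CSP (split between H and N); all peaks get Gaussian
    jitter of scale ``jitter`` ppm in δH (scaled ×1/0.14 in δN).
    Prolines have no amide peak and are skipped. Returns (reference,
    titrated, ground truth with planted combined CSP per assignment).
    """
    if not perturbed_set <= set(range(1, n_residues + 1)):
        raise ValueError("perturbed_set must be within residue range")
    prolines = proline_positions or set()
    rng = stage_rng(seed, "peaklists")
    types = "ACDEFGHIKLMNQRSTVWY"  # no proline; prolines set explicitly
    ref_peaks, tit_peaks = [], []
    truth: dict[str, float] = {}
    for res in range(1, n_residues + 1):
        if res in prolines:
            continue
        restype = str(types[rng.integers(len(types))])
        key = f"{restype}{res}"
        dh = rng.uniform(*AMIDE_H_RANGE)
        dn = rng.uniform(*AMIDE_N_RANGE)
        ref_peaks.append(Peak(key, dh, dn))
        if res in perturbed_set:
            # split the planted combined CSP between the two dimensions
            theta = rng.uniform(0, np.pi / 2)
            ddh = magnitude * np.cos(theta)
            ddn = magnitude * np.sin(theta) / 0.14
        else:
            ddh = ddn = 0.0
        jh = rng.normal(0, jitter) if jitter > 0 else 0.0
        jn = rng.normal(0, jitter / 0.14) if jitter > 0 else 0.0
        tit_peaks.append(Peak(key, dh + ddh + jh, dn + ddn + jn))
        truth[key] = magnitude if res in perturbed_set else 0.0
    return (PeakList.from_records(ref_peaks, "reference"),
            PeakList.from_records(tit_peaks, "titrated"), truth)


# --------------------------------------------------------------- tables

def gen_random_xl_table(n_records: int, n_residues: int, seed: int,
                        chemistries: tuple[str, ...] = ("ADH", "DMTMM"),
                        conditions: tuple[str, ...] = ("PBS_150mM",
                                                       "PBS_285mM"),
                        protein: str = "SYN",
                        duplicate_rate: float = 0.3
                        ) -> list[CrosslinkRecord]:
    """Randomized cross-link table for set-operation oracle tests:
    random residue pairs, chemistry-consistent residue types, random
    condition tags, and a controlled duplicate rate (including swapped
    orientations)."""
    rng = stage_rng(seed, "xl_table")
    records: list[CrosslinkRecord] = []
    for _ in range(n_records):
        if records and rng.random() < duplicate_rate:
            src = records[rng.integers(len(records))]
            if rng.random() < 0.5:  # swapped orientation duplicate
                records.append(CrosslinkRecord(
                    src.protein_b, src.residue_b, src.restype_b,
                    src.protein_a, src.residue_a, src.restype_a,
                    src.chemistry, src.condition))
            else:
                records.append(src)
            continue
        chem = str(rng.choice(chemistries))
        spec = REGISTRY[chem]
        ra, rb = sorted(rng.choice(
            np.arange(1, n_residues + 1), size=2, replace=False))
        records.append(CrosslinkRecord(
            protein_a=protein, residue_a=int(ra),
            restype_a=str(rng.choice(sorted(spec.reactive_pair[0]))),
            protein_b=protein, residue_b=int(rb),
            restype_b=str(rng.choice(sorted(spec.reactive_pair[1]))),
            chemistry=chem, condition=str(rng.choice(conditions))))
    return records
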