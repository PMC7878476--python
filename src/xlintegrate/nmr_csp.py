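"""HSQC titration analysis: peak matching, combined chemical-shift
perturbation (CSP), perturbed-residue calling, titration-series tracking.

The combined perturbation for an amide peak displaced by (ΔδH, ΔδN) is

    Δδ = sqrt(ΔδH² + (α·ΔδN)²),   α = 0.14 by default,

the standard nitrogen scaling that puts ¹⁵N displacements on the ¹H ppm
scale. Perturbed residues are called either against the mean CSP
(excluding prolines, which lack an amide peak) or a fixed ppm cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

DEFAULT_N_SCALE = 0.14


@dataclass
class Peak:
    assignment: str      # e.g. "K47" or an unassigned id like "u12"
    dh_ppm: float
    dn_ppm: float

    @property
    def residue_number(self) -> int | None:
        digits = "".join(c for c in self.assignment if c.isdigit())
        return int(digits) if digits else None

    @property
    def residue_type(self) -> str | None:
        head = self.assignment[:1]
        return head if head.isalpha() else None


@dataclass
class PeakList:
    peaks: dict[str, Peak]        # assignment -> peak (one per assignment)
    label: str = ""               # titration tag, e.g. "0x", "2x"

    @classmethod
    def from_records(cls, records: list[Peak], label: str = "") -> "PeakList":
        peaks: dict[str, Peak] = {}
        for p in records:
            if p.assignment in peaks:
                raise ValueError(f"duplicate assignment {p.assignment!r}")
            if not (np.isfinite(p.dh_ppm) and np.isfinite(p.dn_ppm)):
                raise ValueError(f"non-finite shift for {p.assignment!r}")
            peaks[p.assignment] = p
        return cls(peaks=peaks, label=label)


def read_peaklist(path: str, label: str = "") -> PeakList:
    """Read a TSV peak list with columns assignment, dH_ppm, dN_ppm."""
    df = pd.read_csv(path, sep="\t", dtype={"assignment": str})
    for col in ("assignment", "dH_ppm", "dN_ppm"):
        if col not in df.columns:
            raise ValueError(f"missing mandatory column(s): {col}")
    return PeakList.from_records(
        [Peak(r["assignment"], float(r["dH_ppm"]), float(r["dN_ppm"]))
         for _, r in df.iterrows()], label=label)


def write_peaklist(peaklist: PeakList, path: str) -> None:
    pd.DataFrame(
        [{"assignment": p.assignment, "dH_ppm": p.dh_ppm, "dN_ppm": p.dn_ppm}
         for p in peaklist.peaks.values()],
        columns=["assignment", "dH_ppm", "dN_ppm"],
    ).to_csv(path, sep="\t", index=False)


def match_peaks(reference: PeakList, titrated: PeakList,
                tolerance_h: float = 0.05, tolerance_n: float = 0.5
                ) -> tuple[list[tuple[Peak, Peak]], list[Peak], list[Peak]]:
    """Pair reference and titrated peaks.

    Shared assignments match by key. Remaining peaks match by globally
    optimal nearest-neighbour assignment within the tolerance ellipse
    ((ΔδH/tolH)² + (ΔδN/tolN)² ≤ 1); each peak matches at most once.
    Returns (matched pairs, unmatched reference, unmatched titrated).
    """
    if not reference.peaks or not titrated.peaks:
        raise ValueError("both peak lists must be non-empty")
    matched: list[tuple[Peak, Peak]] = []
    shared = set(reference.peaks) & set(titrated.peaks)
    for key in sorted(shared):
        matched.append((reference.peaks[key], titrated.peaks[key]))
    ref_rest = [p for k, p in sorted(reference.peaks.items())
                if k not in shared]
    tit_rest = [p for k, p in sorted(titrated.peaks.items())
                if k not in shared]
    unmatched_ref: list[Peak] = []
    unmatched_tit = list(tit_rest)
    if ref_rest and tit_rest:
        cost = np.full((len(ref_rest), len(tit_rest)), np.inf)
        for i, rp in enumerate(ref_rest):
            for j, tp in enumerate(tit_rest):
                e = ((rp.dh_ppm - tp.dh_ppm) / tolerance_h) ** 2 + \
                    ((rp.dn_ppm - tp.dn_ppm) / tolerance_n) ** 2
                if e <= 1.0:
                    cost[i, j] = e
        # large finite sentinel keeps the assignment solvable
        big = 1e6
        rows, cols = linear_sum_assignment(np.where(np.isinf(cost), big, cost))
        taken = set()
        for i, j in zip(rows, cols):
            if cost[i, j] <= 1.0:
                matched.append((ref_rest[i], tit_rest[j]))
                taken.add((i, j))
        matched_ref_idx = {i for i, _ in taken}
        matched_tit_idx = {j for _, j in taken}
        unmatched_ref = [p for i, p in enumerate(ref_rest)
                         if i not in matched_ref_idx]
        unmatched_tit = [p for j, p in enumerate(tit_rest)
                         if j not in matched_tit_idx]
    else:
        unmatched_ref = list(ref_rest)
    return matched, unmatched_ref, unmatched_tit


@dataclass
class CSPProfile:
    deltas: dict[str, float]          # assignment -> Δδ (ppm), >= 0
    n_scale: float
    threshold: float | None = None
    perturbed: dict[str, bool] = field(default_factory=dict)

    def nonproline(self) -> dict[str, float]:
        return {k: v for k, v in self.deltas.items() if not k.startswith("P")}


def csp(matched: list[tuple[Peak, Peak]],
        n_scale: float = DEFAULT_N_SCALE) -> CSPProfile:
    """Combined CSP per matched assignment."""
    deltas = {}
    for ref, tit in matched:
        dh = tit.dh_ppm - ref.dh_ppm
        dn = tit.dn_ppm - ref.dn_ppm
        deltas[ref.assignment] = float(np.sqrt(dh ** 2 + (n_scale * dn) ** 2))
    return CSPProfile(deltas=deltas, n_scale=n_scale)


def call_perturbed(profile: CSPProfile,
                   threshold_rule: str | float = "mean") -> CSPProfile:
    """Flag perturbed residues.

    ``threshold_rule="mean"``: threshold is the mean Δδ over non-proline
    assignments; flags are strict (Δδ > threshold). A float gives a fixed
    ppm cutoff instead.
    """
    if not profile.deltas:
        raise ValueError("empty CSP profile")
    if threshold_rule == "mean":
        vals = list(profile.nonproline().values())
        threshold = float(np.mean(vals)) if vals else 0.0
    else:
        threshold = float(threshold_rule)
    flags = {k: v > threshold for k, v in profile.deltas.items()}
    return CSPProfile(deltas=dict(profile.deltas), n_scale=profile.n_scale,
                      threshold=threshold, perturbed=flags)


def titration_series(profiles: dict[float, CSPProfile]
                     ) -> tuple[pd.DataFrame, list[str]]:
    """Assemble per-residue Δδ trajectories over molar ratios.

    Returns a table (rows = assignments, columns = ratios ascending) and
    the list of assignments with non-monotone trajectories, flagged for
    review. Raises if assignments differ between titration points,
    listing the discrepant ones.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two titration points")
    ratios = sorted(profiles)
    keysets = {r: set(profiles[r].deltas) for r in ratios}
    common = set.intersection(*keysets.values())
    union = set.union(*keysets.values())
    if common != union:
        raise ValueError(
            "inconsistent assignments across titration points: "
            + ", ".join(sorted(union - common)))
    table = pd.DataFrame(
        {r: [profiles[r].deltas[k] for k in sorted(common)] for r in ratios},
        index=sorted(common))
    nonmono = [
        k for k in table.index
        if not np.all(np.diff(table.loc[k].to_numpy()) >= -1e-12)
    ]
    return table, nonmono
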