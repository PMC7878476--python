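"""Sequence-level electrostatics: net charge per residue (NCPR) profiles.

NCPR is the mean formal charge over a sliding window (default 10
residues): D/E count −1, K/R count +1, H is 0 by default (configurable
fractional protonation), everything else 0. Charge-complementary blocks
are extracted as maximal runs of |NCPR| above a threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

STANDARD_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")


def residue_charges(sequence: str, histidine_charge: float = 0.0,
                    permissive: bool = False) -> np.ndarray:
    charges = np.zeros(len(sequence))
    for i, aa in enumerate(sequence):
        if aa in "DE":
            charges[i] = -1.0
        elif aa in "KR":
            charges[i] = 1.0
        elif aa == "H":
            charges[i] = histidine_charge
        elif aa not in STANDARD_RESIDUES:
            if not permissive:
                raise ValueError(
                    f"non-standard residue {aa!r} at position {i + 1}")
    return charges


@dataclass
class ChargeProfile:
    values: np.ndarray   # length = len(sequence) - window + 1
    window: int
    start_positions: np.ndarray  # 1-based window start per value


def ncpr(sequence: str, window: int = 10, histidine_charge: float = 0.0,
         permissive: bool = False) -> ChargeProfile:
    """Sliding-window mean charge; value reported at the window start."""
    if not 1 <= window <= len(sequence):
        raise ValueError("window must be in [1, len(sequence)]")
    charges = residue_charges(sequence, histidine_charge, permissive)
    kernel = np.ones(window) / window
    values = np.convolve(charges, kernel, mode="valid")
    starts = np.arange(1, len(values) + 1)
    return ChargeProfile(values=values, window=window, start_positions=starts)


def charge_blocks(profile: ChargeProfile, threshold: float
                  ) -> list[tuple[int, int, str]]:
    """Maximal contiguous runs with |NCPR| >= threshold and constant sign.

    Returns (start, end, sign) in 1-based profile coordinates; sign is
    "+" or "-".
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    blocks = []
    run_start = None
    run_sign = 0
    for i, v in enumerate(profile.values):
        sign = 1 if v >= threshold else (-1 if v <= -threshold else 0)
        if sign != run_sign:
            if run_sign != 0:
                blocks.append((run_start + 1, i, "+" if run_sign > 0 else "-"))
            run_start, run_sign = i, sign
    if run_sign != 0:
        blocks.append((run_start + 1, len(profile.values),
                       "+" if run_sign > 0 else "-"))
    return blocks
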