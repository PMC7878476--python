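"""Equilibrium binding models and fitting for fluorescence-polarization
(FP) titrations.

A fluorescent tracer (e.g. a FITC-labelled J-domain at 0.2 µM) is
titrated with a binding partner; polarization rises as tracer is bound.
At tracer concentrations comparable to the dissociation constant the
simple hyperbola L/(L+Kd) is biased by ligand depletion, so the one-site
model here solves the exact quadratic mass balance. The competition
model couples two partners for the same tracer site (e.g. a C-terminal
domain pre-incubated at fixed concentration versus a titrated Hsp70) and
solves the coupled mass balances numerically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lmfit import Parameters, minimize as lmfit_minimize
from scipy.optimize import brentq


@dataclass
class TitrationCurve:
    """FP concentration series (µM / mP) with replicates."""

    concentrations: np.ndarray     # titrant, µM (one entry per measurement)
    polarizations: np.ndarray      # mP
    replicates: np.ndarray         # replicate index per measurement
    tracer_conc: float             # µM
    competitor_conc: float | None = None   # fixed competitor, µM
    competitor_kd: float | None = None     # its Kd, µM (if known)

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.polarizations = np.asarray(self.polarizations, dtype=float)
        self.replicates = np.asarray(self.replicates, dtype=int)
        if (self.concentrations < 0).any():
            raise ValueError("concentrations must be >= 0")
        if len(np.unique(self.concentrations)) < 5:
            raise ValueError("need >= 5 distinct concentrations to fit")

    @classmethod
    def read_tsv(cls, path: str, tracer_conc: float,
                 competitor_conc: float | None = None,
                 competitor_kd: float | None = None) -> "TitrationCurve":
        df = pd.read_csv(path, sep="\t")
        for col in ("conc_uM", "mP", "replicate"):
            if col not in df.columns:
                raise ValueError(f"missing mandatory column(s): {col}")
        return cls(df["conc_uM"].to_numpy(), df["mP"].to_numpy(),
                   df["replicate"].to_numpy(), tracer_conc,
                   competitor_conc, competitor_kd)

    def write_tsv(self, path: str) -> None:
        pd.DataFrame({
            "conc_uM": self.concentrations,
            "mP": self.polarizations,
            "replicate": self.replicates,
        }).to_csv(path, sep="\t", index=False)


@dataclass
class BindingFit:
    kd: float
    fp_min: float
    fp_max: float
    kd_stderr: float | None
    fp_min_stderr: float | None
    fp_max_stderr: float | None
    converged: bool
    model: str                    # "one_site" or "competitive"
    extras: dict = field(default_factory=dict)


def dilution_series(top: float = 150.0, n_points: int = 12,
                    factor: float = 2.0) -> np.ndarray:
    """Descending geometric dilution series from ``top`` plus a zero point."""
    series = top / factor ** np.arange(n_points - 1)
    return np.append(series, 0.0)


def fraction_bound_one_site(tracer_conc: float, ligand_conc, kd: float):
    """Exact fraction of tracer bound, with ligand depletion.

    Solves the quadratic mass balance for the complex concentration:
    the root of x² − (T + L + Kd)x + T·L in [0, min(T, L)].
    Vectorized over ``ligand_conc``.
    """
    if kd <= 0:
        raise ValueError("Kd must be positive")
    if tracer_conc < 0:
        raise ValueError("tracer concentration must be >= 0")
    ligand = np.asarray(ligand_conc, dtype=float)
    if (ligand < 0).any():
        raise ValueError("ligand concentrations must be >= 0")
    t = tracer_conc
    if t == 0:
        # tracer-free limit: report the site-occupancy hyperbola
        frac = ligand / (ligand + kd)
        return frac if frac.shape else float(frac)
    b = t + ligand + kd
    # numerically stable smaller quadratic root
    disc = np.sqrt(np.maximum(b ** 2 - 4.0 * t * ligand, 0.0))
    complex_conc = 2.0 * t * ligand / (b + disc)
    frac = complex_conc / t
    return frac if frac.shape else float(frac)


def competitive_equilibrium(tracer_conc: float, comp1_conc: float,
                            comp2_conc: float, kd1: float, kd2: float,
                            tol: float = 1e-12, max_iter: int = 200
                            ) -> dict[str, float]:
    """Equilibrium of one tracer J binding two mutually exclusive
    competitors C (Kd1) and H (Kd2).

    Mass balances: Jf(1 + Cf/Kd1 + Hf/Kd2) = Jt with
    Cf = Ct/(1 + Jf/Kd1), Hf = Ht/(1 + Jf/Kd2). The single unknown Jf is
    bracketed in [0, Jt] and solved by Brent's method; the residual is
    monotone in Jf so the root is unique. Returns tracer fractions
    (free, bound1, bound2), which sum to 1.
    """
    if kd1 <= 0 or kd2 <= 0:
        raise ValueError("dissociation constants must be positive")
    if min(tracer_conc, comp1_conc, comp2_conc) < 0:
        raise ValueError("concentrations must be >= 0")
    jt = tracer_conc
    if jt == 0:
        return {"free": 1.0, "bound1": 0.0, "bound2": 0.0}

    def residual(jf: float) -> float:
        cf = comp1_conc / (1.0 + jf / kd1)
        hf = comp2_conc / (1.0 + jf / kd2)
        return jf * (1.0 + cf / kd1 + hf / kd2) - jt

    xtol = max(jt * 1e-16, 5e-324)
    jf = brentq(residual, 0.0, jt, xtol=xtol, rtol=8.9e-16, maxiter=max_iter)
    if abs(residual(jf)) > max(tol, 1e-10) * jt:
        raise RuntimeError(
            "equilibrium solver did not converge: relative residual "
            f"{residual(jf) / jt:g}")
    cf = comp1_conc / (1.0 + jf / kd1)
    hf = comp2_conc / (1.0 + jf / kd2)
    bound1 = jf * cf / kd1 / jt
    bound2 = jf * hf / kd2 / jt
    return {"free": jf / jt, "bound1": bound1, "bound2": bound2}


def fp_signal(fractions: dict[str, float],
              plateaus: dict[str, float]) -> float:
    """Linear polarization mixture: Σ fraction × plateau (mP)."""
    return float(sum(fractions[k] * plateaus[k] for k in fractions))


def cheng_prusoff_ec50(kd2: float, comp1_conc: float, kd1: float) -> float:
    """Apparent EC50 of the titrated partner in the presence of a fixed
    competitor, in the non-depleting limit: Kd2·(1 + [C]/Kd1)."""
    return kd2 * (1.0 + comp1_conc / kd1)


# ----------------------------------------------------------------- fits

def _one_site_model(params: Parameters, conc: np.ndarray,
                    tracer: float) -> np.ndarray:
    frac = fraction_bound_one_site(tracer, conc, params["kd"].value)
    return params["fp_min"].value + (
        params["fp_max"].value - params["fp_min"].value) * frac


def fit_one_site(curve: TitrationCurve,
                 kd_guesses: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0)
                 ) -> BindingFit:
    """Least-squares fit of (Kd, FP_min, FP_max) to a one-site depletion
    model, with multistart over Kd guesses; best-χ² start wins.

    Non-convergence (or a degenerate flat curve) yields a flagged fit,
    never an exception.
    """
    conc, fp = curve.concentrations, curve.polarizations
    best = None
    for guess in kd_guesses:
        params = Parameters()
        params.add("kd", value=guess, min=1e-6)
        params.add("fp_min", value=float(fp[conc == conc.min()].mean()))
        params.add("fp_max", value=float(fp[conc == conc.max()].mean()))
        try:
            out = lmfit_minimize(
                lambda p: _one_site_model(p, conc, curve.tracer_conc) - fp,
                params, method="leastsq")
        except Exception:
            continue
        if best is None or out.chisqr < best.chisqr:
            best = out
    if best is None:
        return BindingFit(np.nan, np.nan, np.nan, None, None, None,
                          converged=False, model="one_site")
    p = best.params
    signal_span = abs(p["fp_max"].value - p["fp_min"].value)
    noise_scale = float(np.std(fp)) + 1e-12
    converged = bool(best.success) and signal_span > 0.5 * noise_scale \
        and p["kd"].stderr is not None \
        and p["kd"].stderr < 10 * abs(p["kd"].value)
    return BindingFit(
        kd=float(p["kd"].value), fp_min=float(p["fp_min"].value),
        fp_max=float(p["fp_max"].value),
        kd_stderr=p["kd"].stderr, fp_min_stderr=p["fp_min"].stderr,
        fp_max_stderr=p["fp_max"].stderr,
        converged=converged, model="one_site",
        extras={"chisqr": float(best.chisqr)})


def apparent_ec50(curve: TitrationCurve) -> float:
    """Model-free EC50: titrant concentration at half-maximal signal,
    by monotone interpolation of replicate-averaged responses."""
    df = pd.DataFrame({"c": curve.concentrations, "fp": curve.polarizations})
    mean = df.groupby("c")["fp"].mean().sort_index()
    c = mean.index.to_numpy()
    y = mean.to_numpy()
    half = (y[0] + y[-1]) / 2.0
    rising = y[-1] >= y[0]
    yy = y if rising else -y
    hh = half if rising else -half
    idx = np.searchsorted(yy, hh)
    idx = int(np.clip(idx, 1, len(c) - 1))
    y0, y1 = yy[idx - 1], yy[idx]
    if y1 == y0:
        return float(c[idx])
    w = (hh - y0) / (y1 - y0)
    return float(c[idx - 1] + w * (c[idx] - c[idx - 1]))


def fit_competition(curve: TitrationCurve, kd1: float,
                    plateau_free: float | None = None,
                    plateau_bound1: float | None = None,
                    kd_guesses: tuple[float, ...] = (0.1, 1.0, 10.0)
                    ) -> BindingFit:
    """Fit Kd2 of the titrated partner through the competitive
    equilibrium, with the fixed competitor's concentration and Kd1 known.

    The free-tracer and competitor-complex plateaus should be supplied
    from control curves (a no-ligand well and a competitor-saturation
    well); fitting them freely is unidentifiable because the free and
    competitor-bound fractions co-vary along the titration. When absent,
    both are fixed to the mean zero-titrant signal — exact at the start
    of the titration and a good approximation while competitor depletion
    by the tracer is small. Also reports the model-free apparent EC50
    and the Cheng–Prusoff prediction Kd2·(1 + [C]/Kd1).
    """
    if curve.competitor_conc is None:
        raise ValueError("curve has no fixed competitor concentration")
    comp1 = curve.competitor_conc
    conc, fp = curve.concentrations, curve.polarizations

    def model(params: Parameters) -> np.ndarray:
        pf = params["p_free"].value
        p1 = params["p_bound1"].value
        p2 = params["p_bound2"].value
        kd2 = params["kd2"].value
        out = np.empty_like(conc)
        for i, h in enumerate(conc):
            fr = competitive_equilibrium(curve.tracer_conc, comp1, h,
                                         kd1, kd2)
            out[i] = fr["free"] * pf + fr["bound1"] * p1 + fr["bound2"] * p2
        return out

    best = None
    for guess in kd_guesses:
        params = Parameters()
        params.add("kd2", value=guess, min=1e-6)
        baseline = float(fp[conc == conc.min()].mean())
        params.add("p_free",
                   value=plateau_free if plateau_free is not None
                   else baseline, vary=False)
        params.add("p_bound1",
                   value=plateau_bound1 if plateau_bound1 is not None
                   else baseline, vary=False)
        params.add("p_bound2", value=float(fp[conc == conc.max()].mean()))
        try:
            out = lmfit_minimize(lambda p: model(p) - fp, params,
                                 method="leastsq")
        except Exception:
            continue
        if best is None or out.chisqr < best.chisqr:
            best = out
    if best is None:
        return BindingFit(np.nan, np.nan, np.nan, None, None, None,
                          converged=False, model="competitive")
    p = best.params
    ec50 = apparent_ec50(curve)
    extras = {
        "chisqr": float(best.chisqr),
        "apparent_ec50": ec50,
        "cheng_prusoff_ec50": cheng_prusoff_ec50(
            p["kd2"].value, comp1, kd1),
        "plateau_free": float(p["p_free"].value),
        "plateau_bound1": float(p["p_bound1"].value),
        "plateau_bound2": float(p["p_bound2"].value),
    }
    return BindingFit(
        kd=float(p["kd2"].value),
        fp_min=float(p["p_free"].value), fp_max=float(p["p_bound2"].value),
        kd_stderr=p["kd2"].stderr, fp_min_stderr=p["p_free"].stderr,
        fp_max_stderr=p["p_bound2"].stderr,
        converged=bool(best.success), model="competitive", extras=extras)
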