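"""qPCR standard curves, efficiency, and abundance correction.

A standard curve is the OLS fit of quantification cycle (Cq) on log10
template copies over a plasmid dilution series. Its slope gives the
amplification efficiency E = 10^(-1/slope) - 1 (a perfectly doubling
reaction has slope -1/log10(2) = -3.3219 and E = 1, i.e. 100%).

Efficiency correction rescales each gene's copy numbers toward what an
ideal (E = 1) reaction would have reported:

    corrected = observed * (2 / (1 + E)) ** Cq_ref

with Cq_ref the gene's mean observed Cq equivalent under its curve. The
rule is a documented convention (it preserves rank order within a gene and
is the identity at E = 1) and can be switched off.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (DegenerateInputError, InsufficientDataError,
                     InvalidArgumentError, MissingCurveError)

log = logging.getLogger(__name__)

#: slope of a perfectly doubling reaction, Cq per log10 copies
IDEAL_SLOPE = -1.0 / np.log10(2.0)


def efficiency_from_slope(slope: float) -> float:
    """Amplification efficiency E = 10^(-1/slope) - 1 on the 0-1 scale."""
    return 10.0 ** (-1.0 / slope) - 1.0


@dataclass(frozen=True)
class StandardCurve:
    """Fitted standard curve for one gene: Cq = slope * log10(copies) + intercept."""

    gene: str
    slope: float
    intercept: float
    r2: float
    cq_range: tuple[float, float] | None = None

    @property
    def efficiency(self) -> float:
        return efficiency_from_slope(self.slope)

    def predict_cq(self, copies) -> np.ndarray:
        """Expected Cq for a template copy number."""
        return self.slope * np.log10(np.asarray(copies, dtype=float)) + self.intercept


def fit_standard_curve(log10_copies, cq, gene: str) -> StandardCurve:
    """Ordinary least squares of Cq on log10 copies for one gene."""
    x = np.asarray(log10_copies, dtype=float)
    y = np.asarray(cq, dtype=float)
    if x.shape != y.shape:
        raise InvalidArgumentError("log10_copies and cq must have equal length")
    if x.size < 3:
        raise InsufficientDataError(
            f"standard curve for {gene!r} needs >= 3 points, got {x.size}")
    if np.ptp(x) == 0:
        raise DegenerateInputError(
            f"log10_copies for {gene!r} has zero variance")
    res = stats.linregress(x, y)
    return StandardCurve(gene=gene, slope=float(res.slope),
                         intercept=float(res.intercept),
                         r2=float(res.rvalue ** 2),
                         cq_range=(float(y.min()), float(y.max())))


def quantify(cq, curve: StandardCurve, dilution_factor: float = 1.0,
             soil_mass_g: float = 1.0):
    """Back-calculate copies per g dry soil from a Cq value.

    copies = 10^((cq - intercept) / slope) * dilution_factor / soil_mass_g.
    Cq values outside the fitted range are extrapolated with a warning.
    """
    if soil_mass_g <= 0:
        raise InvalidArgumentError(f"soil_mass_g must be > 0, got {soil_mass_g}")
    cq_arr = np.asarray(cq, dtype=float)
    if curve.cq_range is not None:
        lo, hi = curve.cq_range
        if np.any((cq_arr < lo) | (cq_arr > hi)):
            log.warning("Cq outside standard-curve range [%.2f, %.2f] for %s; "
                        "extrapolating", lo, hi, curve.gene)
    copies = 10.0 ** ((cq_arr - curve.intercept) / curve.slope)
    out = copies * dilution_factor / soil_mass_g
    return float(out) if np.isscalar(cq) else out


def correction_factor(curve: StandardCurve, observed: np.ndarray) -> float:
    """Per-gene rescaling factor (2 / (1+E))^Cq_ref; 1.0 when E = 1."""
    cq_equiv = curve.predict_cq(observed)
    cq_ref = float(np.mean(cq_equiv))
    return (2.0 / (1.0 + curve.efficiency)) ** cq_ref


def efficiency_correct(table: pd.DataFrame,
                       curves: dict[str, StandardCurve]) -> pd.DataFrame:
    """Efficiency-correct a long abundance table gene by gene."""
    genes = table["gene"].unique()
    missing = [g for g in genes if g not in curves]
    if missing:
        raise MissingCurveError(
            f"no standard curve for gene(s): {sorted(missing)}")
    out = table.copy()
    for gene in genes:
        mask = out["gene"] == gene
        vals = out.loc[mask, "copies_per_g"].to_numpy(float)
        out.loc[mask, "copies_per_g"] = vals * correction_factor(curves[gene], vals)
    return out


def synthesize_standard_curves(genes, seed: int = 0,
                               efficiency_range=(0.85, 1.05),
                               n_points: int = 6,
                               cq_noise_sd: float = 1.75) -> dict[str, StandardCurve]:
    """Simulate plausible dilution-series fits for a panel of genes.

    Synthetic stand-in for wet-lab standard curves: slopes drawn so that
    efficiencies land in ``efficiency_range``, Gaussian Cq noise sized so
    the fitted R^2 falls in the 0.94-0.98 band typical of these assays.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for gene in genes:
        eff = rng.uniform(*efficiency_range)
        slope = -1.0 / np.log10(1.0 + eff)
        intercept = rng.uniform(36.0, 40.0)
        x = np.linspace(2.0, 7.0, n_points)
        y = slope * x + intercept + rng.normal(0.0, cq_noise_sd, n_points)
        out[gene] = fit_standard_curve(x, y, gene)
    return out
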