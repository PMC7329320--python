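"""Seeded multi-site qPCR experiment generator.

Emulates a survey of alfalfa-system soils spanning a climate gradient,
incubated under an environmental control and three global-change stressors
(drying-wetting cycles, warming, N deposition): 54 sites x 4 treatments =
216 per-sample units under the defaults.

The dependency structure is climate -> stoichiometry -> gene abundance ->
disturbance response: MAT/MAP drive soil total C and N (total P is nearly
climate-independent); per-gene log10 abundances respond linearly to
standardized stoichiometry, climate and biomass-marker predictors; and each
stressor multiplies abundance by exp(-magnitude) with a magnitude that is
itself a linear function of site predictors, so the resistance index
computed downstream varies across sites in a configured, recoverable way.

All randomness flows from one integer seed through named substreams, so a
stage rerun in isolation reproduces the corresponding slice of a full run.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .config import EffectConfig, SITE_PREDICTORS
from .errors import InvalidArgumentError, InvalidConfigError
from .panel import ALL_GENES, GenePanel, STRESSORS, default_panel

SITE_COLUMNS = ["site_id", "province", "mat", "map",
                "total_c", "total_n", "total_p", "cn", "cp", "np"]
ABUNDANCE_COLUMNS = ["site_id", "gene", "treatment", "copies_per_g"]

N_PROVINCES = 21


def substream(seed: int, name: str) -> np.random.Generator:
    """Derive a named, independent random substream from one global seed."""
    tag = int.from_bytes(hashlib.sha256(name.encode()).digest()[:4], "little")
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x, dtype=float)
    return (x - x.mean()) / sd


def _site_zmatrix(sites: pd.DataFrame, log_stoich: bool = False) -> dict[str, np.ndarray]:
    """Standardized site predictors; stoichiometry optionally on the log scale
    (totals and ratios are log-normal, so effects are proportional there)."""
    out = {}
    for p in SITE_PREDICTORS:
        x = sites[p].to_numpy(float)
        if log_stoich and p not in ("mat", "map"):
            x = np.log(x)
        out[p] = _zscore(x)
    return out


def generate_sites(n_sites: int, seed: int,
                   config: EffectConfig | None = None) -> pd.DataFrame:
    """Generate a per-site table of climate and soil C:N:P stoichiometry.

    MAT and MAP are uniform over the configured gradients; soil total C and
    N depend log-linearly on standardized MAP/MAT plus log-normal noise;
    total P is near-independent. The C/N, C/P and N/P ratios are computed
    exactly from the totals.
    """
    if n_sites < 2:
        raise InvalidArgumentError(f"n_sites must be >= 2, got {n_sites}")
    config = (config or EffectConfig()).validate()
    rng = substream(seed, "sites")
    sm = config.site_model
    mat = rng.uniform(*sm.mat_range, n_sites)
    map_ = rng.uniform(*sm.map_range, n_sites)
    z_mat, z_map = _zscore(mat), _zscore(map_)
    totals = {}
    for name in ("total_c", "total_n", "total_p"):
        mean, s_map, s_mat, sd = sm.totals[name]
        eps = rng.normal(0.0, sd, n_sites) if sd > 0 else np.zeros(n_sites)
        totals[name] = np.exp(np.log(mean) + s_map * z_map + s_mat * z_mat + eps)
    df = pd.DataFrame({
        "site_id": [f"S{i + 1:02d}" for i in range(n_sites)],
        "province": [f"province_{(i % N_PROVINCES) + 1:02d}"
                     for i in range(n_sites)],
        "mat": mat,
        "map": map_,
        "total_c": totals["total_c"],
        "total_n": totals["total_n"],
        "total_p": totals["total_p"],
    })
    df["cn"] = df["total_c"] / df["total_n"]
    df["cp"] = df["total_c"] / df["total_p"]
    df["np"] = df["total_n"] / df["total_p"]
    return df


def generate_control_abundances(sites: pd.DataFrame,
                                panel: GenePanel | None = None,
                                config: EffectConfig | None = None,
                                seed: int = 0) -> pd.DataFrame:
    """Generate control-treatment gene copy numbers for every site.

    log10 abundance = intercept + sum_p slope_p * z(predictor_p) + noise.
    The biomass markers (16S, ITS) are generated first; their standardized
    log10 abundances then serve as predictors for the functional genes.
    """
    if len(sites) == 0:
        raise InvalidArgumentError("sites table is empty")
    panel = panel or default_panel()
    config = (config or EffectConfig()).validate()
    rng = substream(seed, "control")
    z = _site_zmatrix(sites)
    n = len(sites)
    records = []
    log_marker: dict[str, np.ndarray] = {}
    marker_order = [g for g in ALL_GENES if g in panel.biomass_markers]
    gene_order = marker_order + [g for g in ALL_GENES
                                 if g in panel.functional_genes]
    for gene in gene_order:
        slopes = config.slopes.get(gene, {})
        mu = np.full(n, config.intercepts[gene], dtype=float)
        for pred, b in slopes.items():
            if pred in z:
                mu += b * z[pred]
            elif pred == "log_16S":
                mu += b * _zscore(log_marker["bact_16S"])
            elif pred == "log_ITS":
                mu += b * _zscore(log_marker["fungal_ITS"])
        noise = (rng.normal(0.0, config.abundance_noise_sd, n)
                 if config.abundance_noise_sd > 0 else np.zeros(n))
        log10_ab = mu + noise
        if gene in marker_order:
            log_marker[gene] = log10_ab
        records.append(pd.DataFrame({
            "site_id": sites["site_id"].to_numpy(),
            "gene": gene,
            "treatment": "control",
            "copies_per_g": 10.0 ** log10_ab,
        }))
    return pd.concat(records, ignore_index=True)


def disturbance_magnitude(sites: pd.DataFrame, gene: str, stressor: str,
                          config: EffectConfig, seed: int | None = None,
                          rng: np.random.Generator | None = None) -> np.ndarray:
    """Per-site log-scale effect magnitude for one gene under one stressor."""
    dm = config.disturbance[stressor]
    z = _site_zmatrix(sites, log_stoich=True)
    m = np.full(len(sites), dm.baseline.get(gene, 0.0), dtype=float)
    for pred, b in dm.slopes.items():
        m += b * z[pred]
    if rng is None:
        rng = substream(seed or 0, f"disturb:{stressor}")
    if dm.noise_sd > 0:
        m += rng.normal(0.0, dm.noise_sd, len(sites))
    return np.clip(m, 0.0, None)


def apply_disturbance(control: pd.DataFrame, sites: pd.DataFrame,
                      stressor: str, config: EffectConfig | None = None,
                      seed: int = 0) -> pd.DataFrame:
    """Apply one stressor to a control abundance table.

    Treated abundance = control * exp(-magnitude); suppression is the
    default direction (the resistance index depends only on |change|).
    """
    if stressor not in STRESSORS:
        raise InvalidArgumentError(
            f"unknown stressor {stressor!r}; expected one of {STRESSORS}")
    config = (config or EffectConfig()).validate()
    rng = substream(seed, f"disturb:{stressor}")
    site_index = {s: i for i, s in enumerate(sites["site_id"])}
    missing = set(control["site_id"]) - set(site_index)
    if missing:
        raise InvalidArgumentError(
            f"control table has sites absent from site table: {sorted(missing)}")
    out = []
    for gene, sub in control.groupby("gene", sort=False):
        m_all = disturbance_magnitude(sites, gene, stressor, config, rng=rng)
        idx = np.array([site_index[s] for s in sub["site_id"]])
        out.append(pd.DataFrame({
            "site_id": sub["site_id"].to_numpy(),
            "gene": gene,
            "treatment": stressor,
            "copies_per_g": sub["copies_per_g"].to_numpy() * np.exp(-m_all[idx]),
        }))
    return pd.concat(out, ignore_index=True)


@dataclass
class ExperimentBundle:
    """A complete synthetic experiment with its generating parameters."""

    site_table: pd.DataFrame
    abundances: pd.DataFrame
    ground_truth: dict[str, Any] = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        """Per-sample incubation units (site x treatment pairs)."""
        return len(self.abundances[["site_id", "treatment"]].drop_duplicates())


def generate_experiment(config: EffectConfig | None = None,
                        n_sites: int = 54, seed: int = 0) -> ExperimentBundle:
    """Generate the full experiment: sites, control, and all three stressors."""
    config = (config or EffectConfig()).validate()
    sites = generate_sites(n_sites, seed, config)
    panel = default_panel()
    control = generate_control_abundances(sites, panel, config, seed)
    tables = [control]
    for stressor in STRESSORS:
        tables.append(apply_disturbance(control, sites, stressor, config, seed))
    abundances = pd.concat(tables, ignore_index=True)
    if (abundances["copies_per_g"] <= 0).any():
        raise InvalidConfigError("generated nonpositive abundance")
    ground_truth = {"config": config, "n_sites": n_sites, "seed": seed}
    return ExperimentBundle(sites, abundances, ground_truth)
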