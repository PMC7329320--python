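"""Configuration for the synthetic experiment generator and the pipeline.

The generator is an *effect model*: site climate (MAT, MAP) drives soil
C:N:P stoichiometry on the log scale; stoichiometry (plus the biomass
markers) drives log10 gene abundance through a per-gene slope matrix; and
each global-change stressor suppresses abundance by a multiplicative factor
whose log magnitude depends on site stoichiometry/climate, so that the
resistance index computed downstream is predictable from those drivers.

Default slope signs encode the reported correlation structure between
stoichiometry and functional-gene abundance (total N, C/P and N/P positive
with all functional genes; total C positive with the N-cycling subset;
total P negative with the P activators phoD/pqqC; C/N negative with
phoD/phoC/pqqC/nirK/fungcbhIR/GH74; climate linked only to
nirK/phoC/pqqC/fungcbhIR). Magnitudes are free parameters; the default
|slope| is 0.3 on the log10 scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from typing import Any

import yaml

from .errors import InvalidConfigError
from .panel import ALL_GENES, FUNCTIONAL_GENES, STRESSORS

#: site-level predictors usable in slope dictionaries
SITE_PREDICTORS = ("mat", "map", "total_c", "total_n", "total_p", "cn", "cp", "np")
#: additional predictors for functional genes (log10 biomass-marker abundance)
MARKER_PREDICTORS = ("log_16S", "log_ITS")


def _functional_slopes() -> dict[str, dict[str, float]]:
    s = {g: {} for g in FUNCTIONAL_GENES}
    # Genes within a group do not respond to stoichiometry with identical
    # strength (reported correlation strengths vary gene by gene), so the
    # stoichiometry slope magnitudes cycle through weak/typical/strong
    # multipliers of the 0.3 default within each group. This within-group
    # contrast is what compositional (Hellinger) ordination sees.
    stoich_scale = {}
    by_group: dict[str, int] = {}
    from .panel import _PANEL
    for g in FUNCTIONAL_GENES:
        grp = _PANEL[g][0]
        k = by_group.get(grp, 0)
        by_group[grp] = k + 1
        stoich_scale[g] = (0.4, 1.0, 1.6)[k % 3]
    for g in FUNCTIONAL_GENES:
        f = stoich_scale[g]
        # total N, C/P and N/P positive with every functional gene
        s[g]["total_n"] = 0.3 * f
        s[g]["cp"] = 0.3 * f
        s[g]["np"] = 0.3 * f
        # biomass markers positive with most genes
        s[g]["log_16S"] = 0.3
        s[g]["log_ITS"] = 0.3
    for g in ("amoA-b", "nifH", "narG", "nirS", "nosZ"):
        s[g]["total_c"] = 0.3
    for g in ("phoD", "pqqC"):
        s[g]["total_p"] = -0.3
    for g in ("phoD", "phoC", "pqqC", "nirK", "fungcbhIR", "GH74"):
        s[g]["cn"] = -0.3
    # climate is linked to these four genes only (one variable each)
    for g in ("nirK", "phoC"):
        s[g]["mat"] = 0.3
    for g in ("pqqC", "fungcbhIR"):
        s[g]["map"] = 0.3
    # C-cycling decomposers lean fungal: stronger ITS, weaker 16S loading,
    # which induces the reported bacterial:fungal-ratio link for this group.
    for g in ("fungcbhIR", "GH74", "GH31", "GH51"):
        s[g]["log_ITS"] = 0.45
        s[g]["log_16S"] = 0.15
    return s


def _marker_slopes() -> dict[str, dict[str, float]]:
    # biomass tracks fertility: bacteria with N and rainfall, fungi with C
    return {
        "bact_16S": {"total_n": 0.2, "map": 0.1},
        "fungal_ITS": {"total_c": 0.2, "cn": 0.15},
    }


def _default_intercepts() -> dict[str, float]:
    # log10 copies per g dry soil, in the range qPCR surveys of these
    # markers typically report
    return {
        "fungcbhIR": 6.5, "GH74": 6.8, "GH31": 7.0, "GH51": 6.6,
        "amoA-a": 6.8, "amoA-b": 7.2, "nifH": 7.5, "narG": 7.8,
        "nirK": 7.4, "nirS": 7.0, "norB": 6.9, "nosZ": 7.1,
        "phoD": 7.6, "phoC": 6.9, "BPP": 6.2, "pqqC": 6.7,
        "bact_16S": 9.5, "fungal_ITS": 8.0,
    }


def _default_disturbance() -> dict[str, "DisturbanceModel"]:
    # Per-gene baseline log-effect magnitudes (natural-log units) ordered by
    # the reported resistance ranking: phoD/phoC most sensitive to
    # drying-wetting; nosZ and GH51 most sensitive to warming (amoA-a least);
    # the C-cycling glycoside-hydrolase genes most sensitive to N deposition
    # while amoA-b/nirS/narG/norB resist it best.
    base = {g: 0.4 for g in FUNCTIONAL_GENES}

    dw = dict(base)
    dw.update({"phoD": 0.9, "phoC": 0.7, "nosZ": 0.15, "BPP": 0.35})
    warm = dict(base)
    warm.update({"nosZ": 0.8, "GH51": 0.8, "amoA-a": 0.15, "BPP": 0.35})
    nd = dict(base)
    nd.update({
        "GH31": 0.85, "GH51": 0.85, "GH74": 0.85, "fungcbhIR": 0.5,
        "amoA-b": 0.15, "nirS": 0.15, "narG": 0.15, "norB": 0.15,
        "phoD": 0.3, "phoC": 0.3, "BPP": 0.6,
    })

    # Negative slope => the predictor raises resistance (smaller effect).
    # Rainfall history buffers drying-wetting, thermal history buffers
    # warming, and C/P with total C and N buffer N deposition.
    return {
        "drying_wetting": DisturbanceModel(
            baseline=dw, slopes={"map": -0.25, "cp": -0.05}, noise_sd=0.25),
        "warming": DisturbanceModel(
            baseline=warm, slopes={"mat": -0.25, "cp": -0.05}, noise_sd=0.25),
        "n_deposition": DisturbanceModel(
            baseline=nd,
            slopes={"cp": -0.2, "total_c": -0.12, "total_n": -0.12},
            noise_sd=0.25),
    }


@dataclass
class SiteModel:
    """Climate gradients and the climate->stoichiometry dependence.

    Stoichiometric totals are generated on the natural-log scale:
    ``log(total) = log(mean) + slope_map * z(MAP) + slope_mat * z(MAT) + eps``
    which keeps them strictly positive and right-skewed, as soil surveys
    show. Total P is near-independent of climate by default.
    """

    mat_range: tuple[float, float] = (0.0, 20.0)
    map_range: tuple[float, float] = (100.0, 1600.0)
    #: total -> (mean g/kg, slope on z(MAP), slope on z(MAT), log-noise SD)
    totals: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: {
            "total_c": (12.0, 0.30, -0.10, 0.25),
            "total_n": (1.2, 0.35, 0.00, 0.20),
            "total_p": (0.65, 0.05, 0.00, 0.25),
        })


@dataclass
class DisturbanceModel:
    """Log-scale effect magnitude model for one stressor.

    ``magnitude(site, gene) = baseline[gene] + sum_p slopes[p] * z(p) + eps``
    clipped at zero; treated abundance = control * exp(-magnitude).
    """

    baseline: dict[str, float] = field(default_factory=dict)
    slopes: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 0.1


@dataclass
class EffectConfig:
    """All generating parameters of the synthetic multi-site experiment."""

    site_model: SiteModel = field(default_factory=SiteModel)
    intercepts: dict[str, float] = field(default_factory=_default_intercepts)
    slopes: dict[str, dict[str, float]] = field(
        default_factory=lambda: {**_marker_slopes(), **_functional_slopes()})
    abundance_noise_sd: float = 0.25
    disturbance: dict[str, DisturbanceModel] = field(
        default_factory=_default_disturbance)
    seed: int | None = None

    def validate(self) -> "EffectConfig":
        for name, val in [("abundance_noise_sd", self.abundance_noise_sd)]:
            if not math.isfinite(val) or val < 0:
                raise InvalidConfigError(f"{name} must be finite and >= 0, got {val}")
        for gene, sl in self.slopes.items():
            if gene not in ALL_GENES:
                raise InvalidConfigError(f"unknown gene in slopes: {gene!r}")
            for pred, v in sl.items():
                if pred not in SITE_PREDICTORS + MARKER_PREDICTORS:
                    raise InvalidConfigError(
                        f"unknown predictor {pred!r} for gene {gene!r}")
                if not math.isfinite(v):
                    raise InvalidConfigError(
                        f"non-finite slope for {gene!r}/{pred!r}")
        for gene, v in self.intercepts.items():
            if gene not in ALL_GENES:
                raise InvalidConfigError(f"unknown gene in intercepts: {gene!r}")
            if not math.isfinite(v):
                raise InvalidConfigError(f"non-finite intercept for {gene!r}")
        for stressor, dm in self.disturbance.items():
            if stressor not in STRESSORS:
                raise InvalidConfigError(f"unknown stressor: {stressor!r}")
            if not math.isfinite(dm.noise_sd) or dm.noise_sd < 0:
                raise InvalidConfigError(
                    f"noise_sd for {stressor!r} must be finite and >= 0")
            for gene, b in dm.baseline.items():
                if gene not in ALL_GENES or not math.isfinite(b):
                    raise InvalidConfigError(
                        f"bad disturbance baseline for {gene!r} in {stressor!r}")
            for pred, v in dm.slopes.items():
                if pred not in SITE_PREDICTORS or not math.isfinite(v):
                    raise InvalidConfigError(
                        f"bad disturbance slope {pred!r} in {stressor!r}")
        for total, spec_ in self.site_model.totals.items():
            if len(spec_) != 4 or spec_[0] <= 0 or any(
                    not math.isfinite(x) for x in spec_) or spec_[3] < 0:
                raise InvalidConfigError(f"bad site model entry for {total!r}")
        return self

    def replace(self, **kw) -> "EffectConfig":
        return replace(self, **kw)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


_SCALAR_KEYS = {"abundance_noise_sd", "seed"}


def effect_config_from_dict(doc: dict[str, Any]) -> EffectConfig:
    """Build an :class:`EffectConfig` from a plain mapping, rejecting unknown keys."""
    if not isinstance(doc, dict):
        raise InvalidConfigError("config document must be a mapping")
    known = {"site_model", "intercepts", "slopes", "disturbance"} | _SCALAR_KEYS
    unknown = set(doc) - known
    if unknown:
        raise InvalidConfigError(f"unknown config keys: {sorted(unknown)}")
    cfg = EffectConfig()
    sm = doc.get("site_model")
    if sm is not None:
        sm_unknown = set(sm) - {"mat_range", "map_range", "totals"}
        if sm_unknown:
            raise InvalidConfigError(f"unknown site_model keys: {sorted(sm_unknown)}")
        site = SiteModel(
            mat_range=tuple(sm.get("mat_range", cfg.site_model.mat_range)),
            map_range=tuple(sm.get("map_range", cfg.site_model.map_range)),
            totals={k: tuple(v) for k, v in sm.get(
                "totals", cfg.site_model.totals).items()},
        )
        cfg = cfg.replace(site_model=site)
    if "intercepts" in doc:
        cfg = cfg.replace(intercepts={**cfg.intercepts, **doc["intercepts"]})
    if "slopes" in doc:
        merged = {g: dict(s) for g, s in cfg.slopes.items()}
        for g, s in doc["slopes"].items():
            merged.setdefault(g, {}).update(s)
        cfg = cfg.replace(slopes=merged)
    if "disturbance" in doc:
        dist = dict(cfg.disturbance)
        for stressor, dm in doc["disturbance"].items():
            dm_unknown = set(dm) - {"baseline", "slopes", "noise_sd"}
            if dm_unknown:
                raise InvalidConfigError(
                    f"unknown disturbance keys for {stressor!r}: {sorted(dm_unknown)}")
            prev = dist.get(stressor, DisturbanceModel())
            dist[stressor] = DisturbanceModel(
                baseline={**prev.baseline, **dm.get("baseline", {})},
                slopes={**prev.slopes, **dm.get("slopes", {})},
                noise_sd=dm.get("noise_sd", prev.noise_sd),
            )
        cfg = cfg.replace(disturbance=dist)
    for k in _SCALAR_KEYS & set(doc):
        cfg = cfg.replace(**{k: doc[k]})
    return cfg.validate()


def load_effect_config(path) -> EffectConfig:
    """Load an effect config from a YAML (or JSON) document."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    return effect_config_from_dict(doc or {})


@dataclass
class TreatmentMetadata:
    """Design constants of the incubation treatments, carried as annotations.

    The disturbance model is phenomenological; these constants document the
    conditions each treatment label stands for.
    """

    warming_delta_c: float = 4.5
    n_dose_kg_ha_yr: float = 25.0
    whc_percent: float = 50.0
    dw_cycles: int = 4
    dw_wet_days: int = 2
    dw_dry_days: int = 5
    incubation: str = "1 month"


@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration."""

    simulate: EffectConfig | None = field(default_factory=EffectConfig)
    input_sites: str | None = None
    input_abundance: str | None = None
    standard_curves: str | None = None
    n_sites: int = 54
    treatment: TreatmentMetadata = field(default_factory=TreatmentMetadata)
    n_perm: int = 999
    n_trees: int = 500
    rf_n_perm: int = 99
    alpha: float = 0.05
    log10_transform: bool = True
    group_resistance_mode: str = "mean"
    seed: int = 0

    def validate(self) -> "PipelineConfig":
        if self.simulate is None and (
                self.input_sites is None or self.input_abundance is None):
            raise InvalidConfigError(
                "config must provide either a 'simulate' block or both "
                "'input_sites' and 'input_abundance' paths")
        if self.n_perm < 99:
            raise InvalidConfigError("n_perm must be >= 99")
        if self.group_resistance_mode not in ("mean", "eq2"):
            raise InvalidConfigError("group_resistance_mode must be 'mean' or 'eq2'")
        return self


def pipeline_config_from_dict(doc: dict[str, Any]) -> PipelineConfig:
    if not isinstance(doc, dict):
        raise InvalidConfigError("pipeline config must be a mapping")
    known = {"simulate", "input_sites", "input_abundance", "standard_curves",
             "n_sites", "treatment", "n_perm", "n_trees", "rf_n_perm",
             "alpha", "log10_transform", "group_resistance_mode", "seed"}
    unknown = set(doc) - known
    if unknown:
        raise InvalidConfigError(f"unknown pipeline config keys: {sorted(unknown)}")
    kw: dict[str, Any] = {k: doc[k] for k in known & set(doc)
                          if k not in ("simulate", "treatment")}
    if "simulate" in doc:
        kw["simulate"] = (effect_config_from_dict(doc["simulate"])
                          if doc["simulate"] is not None else None)
    if "treatment" in doc:
        t = doc["treatment"]
        t_unknown = set(t) - set(TreatmentMetadata.__dataclass_fields__)
        if t_unknown:
            raise InvalidConfigError(f"unknown treatment keys: {sorted(t_unknown)}")
        kw["treatment"] = TreatmentMetadata(**t)
    elif "input_sites" in doc and "simulate" not in doc:
        kw.setdefault("simulate", None)
    cfg = PipelineConfig(**kw)
    return cfg.validate()


def load_pipeline_config(path) -> PipelineConfig:
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    return pipeline_config_from_dict(doc or {})
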