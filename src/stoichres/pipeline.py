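"""End-to-end orchestration: simulate -> correct -> resistance -> normalize
-> variance partitioning -> predictor importance -> path models.

Every stage writes its TSV outputs under one output directory and is
re-derivable from the config plus the single global seed (per-stage
substreams are derived by name, so a stage rerun in isolation matches the
full run). A machine-readable JSON report records the config snapshot,
input hashes, per-stage outputs, design constants and warnings.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import qpcr, tables
from .config import PipelineConfig
from .errors import StoichresError
from .importance import permutation_significance
from .panel import FUNCTIONAL_GROUPS, STRESSORS, default_panel
from .resistance import group_resistance, normalize_group, resistance_table
from .sem import PathModel, fit_path_model, prune_to_optimal
from .simulate import generate_experiment, substream
from .varpart import (CLIMATE_SET, STOICH_SET, correlation_heatmap_stats,
                      hellinger, permutation_test_fraction, varpart2)

log = logging.getLogger(__name__)

PREDICTOR_COLUMNS = list(CLIMATE_SET) + list(STOICH_SET)


@dataclass
class RunReport:
    """Auditable record of one pipeline run."""

    config: dict
    seed: int
    outputs: dict[str, list[str]] = field(default_factory=dict)
    input_hashes: dict[str, str] = field(default_factory=dict)
    design_constants: dict = field(default_factory=dict)
    n_samples: int | None = None
    timing_s: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    failed_stage: str | None = None

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=str)


def _hash_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


SEM_STOICH_VARS = ("log_total_c", "log_total_n", "log_cp")


def default_sem_model(resistance_var: str = "resistance") -> PathModel:
    """A-priori model: climate -> stoichiometry -> resistance, plus the
    direct climate -> resistance paths that pruning is expected to test.

    Stoichiometry enters on the log scale (totals and ratios are log-normal
    across sites, and linear paths are assumed). The compositional path
    total C -> C/P is included a priori: the ratio contains total C, so
    conditional independence given climate would be structurally wrong."""
    edges = []
    for clim in ("mat", "map"):
        for s in SEM_STOICH_VARS:
            edges.append((clim, s))
        edges.append((clim, resistance_var))
    edges.append(("log_total_c", "log_cp"))
    for s in SEM_STOICH_VARS:
        edges.append((s, resistance_var))
    return PathModel(("mat", "map", *SEM_STOICH_VARS, resistance_var),
                     tuple(edges))


def sem_data(sites: pd.DataFrame, resistance_scores: pd.Series) -> pd.DataFrame:
    """Assemble the per-site SEM variable table for one group x stressor."""
    data = pd.DataFrame({
        "mat": sites["mat"],
        "map": sites["map"],
        "log_total_c": np.log(sites["total_c"]),
        "log_total_n": np.log(sites["total_n"]),
        "log_cp": np.log(sites["cp"]),
    }, index=sites.index)
    data["resistance"] = resistance_scores.loc[data.index]
    return data


def run_all(config: PipelineConfig, outdir) -> RunReport:
    """Execute every pipeline stage in order; see the module docstring."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    report = RunReport(
        config=dataclasses.asdict(config), seed=seed,
        design_constants=dataclasses.asdict(config.treatment))
    marker = outdir / "FAILED"
    if marker.exists():
        marker.unlink()

    def record(stage, paths, t0):
        report.outputs[stage] = [str(p) for p in paths]
        report.timing_s[stage] = round(time.perf_counter() - t0, 3)

    stage = "simulate"
    try:
        t0 = time.perf_counter()
        if config.simulate is not None:
            bundle = generate_experiment(config.simulate, config.n_sites, seed)
            sites, abundance = bundle.site_table, bundle.abundances
            report.n_samples = bundle.n_samples
        else:
            sites = tables.read_site_table(config.input_sites)
            abundance = tables.read_abundance_table(config.input_abundance)
            report.input_hashes[config.input_sites] = _hash_file(config.input_sites)
            report.input_hashes[config.input_abundance] = _hash_file(
                config.input_abundance)
            report.n_samples = len(
                abundance[["site_id", "treatment"]].drop_duplicates())
        site_path = outdir / "sites.tsv"
        ab_path = outdir / "abundance.tsv"
        tables.write_site_table(sites, site_path)
        tables.write_abundance_table(abundance, ab_path)
        record(stage, [site_path, ab_path], t0)

        stage = "quantify"
        t0 = time.perf_counter()
        if config.standard_curves:
            curves = tables.read_standard_curves(config.standard_curves)
            report.input_hashes[config.standard_curves] = _hash_file(
                config.standard_curves)
            abundance = qpcr.efficiency_correct(abundance, curves)
            corr_path = outdir / "abundance_corrected.tsv"
            tables.write_abundance_table(abundance, corr_path)
            record(stage, [corr_path], t0)
        else:
            report.outputs[stage] = []
            report.warnings.append(
                "no standard curves supplied; efficiency correction skipped")

        panel = default_panel()
        control = abundance[abundance["treatment"] == "control"]
        func_genes = panel.functional_genes

        stage = "resistance"
        t0 = time.perf_counter()
        res_frames = []
        for stressor in STRESSORS:
            treated = abundance[abundance["treatment"] == stressor]
            if treated.empty:
                report.warnings.append(f"no rows for stressor {stressor!r}")
                continue
            rt = resistance_table(control, treated, stressor)
            if rt.attrs.get("excluded"):
                report.warnings.append(
                    f"{stressor}: excluded {len(rt.attrs['excluded'])} records "
                    "with nonpositive control")
            res_frames.append(rt)
        resistance = pd.concat(res_frames, ignore_index=True)
        res_path = outdir / "resistance.tsv"
        resistance.to_csv(res_path, sep="\t", index=False)
        record(stage, [res_path], t0)

        stage = "normalize"
        t0 = time.perf_counter()
        control_wide = tables.to_wide(control)
        score_rows, gres_rows = [], []
        for group in FUNCTIONAL_GROUPS:
            genes = panel.members(group)
            scores = normalize_group(control_wide, genes)
            for sid, sc in scores.items():
                score_rows.append({"sample_id": sid, "group": group, "score": sc})
            for stressor in STRESSORS:
                sub = resistance[resistance["stressor"] == stressor]
                gr = group_resistance(sub, genes,
                                      mode=config.group_resistance_mode)
                for sid, sc in gr.items():
                    gres_rows.append({"site_id": sid, "group": group,
                                      "stressor": stressor, "score": sc})
        scores_path = outdir / "group_scores.tsv"
        gres_path = outdir / "group_resistance.tsv"
        pd.DataFrame(score_rows).to_csv(scores_path, sep="\t", index=False)
        gres = pd.DataFrame(gres_rows)
        gres.to_csv(gres_path, sep="\t", index=False)
        record(stage, [scores_path, gres_path], t0)

        site_idx = sites.set_index("site_id").loc[control_wide.index]
        X_M = site_idx[list(CLIMATE_SET)]
        X_S = site_idx[list(STOICH_SET)]

        stage = "varpart"
        t0 = time.perf_counter()
        vp_seed = int(substream(seed, "varpart").integers(0, 2 ** 31))
        vp_rows = []
        for group in FUNCTIONAL_GROUPS:
            genes = panel.members(group)
            mat = control_wide[genes]
            Y = hellinger(np.log10(mat) if config.log10_transform else mat)
            res = varpart2(Y, X_M, X_S, group=group)
            res.p_M = permutation_test_fraction(Y, X_M, X_S, "M",
                                                config.n_perm, vp_seed)
            res.p_S = permutation_test_fraction(Y, X_M, X_S, "S",
                                                config.n_perm, vp_seed + 1)
            vp_rows.append(res.to_dict())
        vp_path = outdir / "varpart.tsv"
        pd.DataFrame(vp_rows).to_csv(vp_path, sep="\t", index=False)
        gene_log = np.log10(control_wide[func_genes + panel.biomass_markers])
        heat = correlation_heatmap_stats(site_idx[PREDICTOR_COLUMNS], gene_log)
        heat_path = outdir / "heatmap_stats.tsv"
        heat.to_csv(heat_path, sep="\t", index=False)
        record(stage, [vp_path, heat_path], t0)

        stage = "importance"
        t0 = time.perf_counter()
        imp_seed = int(substream(seed, "importance").integers(0, 2 ** 31))
        imp_frames = []
        X_sites = site_idx[PREDICTOR_COLUMNS]
        gres_wide = gres.pivot_table(index="site_id", columns=["group", "stressor"],
                                     values="score")
        for k, (group, stressor) in enumerate(
                [(g, s) for g in FUNCTIONAL_GROUPS for s in STRESSORS]):
            y = gres_wide[(group, stressor)].loc[X_sites.index]
            out = permutation_significance(
                X_sites, y.to_numpy(), n_perm=config.rf_n_perm,
                n_trees=config.n_trees, seed=imp_seed + k, alpha=config.alpha)
            out.insert(0, "response", f"{group}:{stressor}")
            imp_frames.append(out)
        imp_path = outdir / "importance.tsv"
        pd.concat(imp_frames, ignore_index=True).to_csv(
            imp_path, sep="\t", index=False)
        record(stage, [imp_path], t0)

        stage = "sem"
        t0 = time.perf_counter()
        edge_rows, fit_rows = [], []
        for group in FUNCTIONAL_GROUPS:
            for stressor in STRESSORS:
                data = sem_data(site_idx, gres_wide[(group, stressor)])
                model = default_sem_model()
                optimal, opt_fit, apriori_fit = prune_to_optimal(
                    model, data, alpha=config.alpha)
                for label, fit in (("apriori", apriori_fit), ("optimal", opt_fit)):
                    for _, row in fit.coefficients.iterrows():
                        edge_rows.append({
                            "group": group, "stressor": stressor, "model": label,
                            "source": row["source"], "target": row["target"],
                            "beta": row["beta"], "p": row["p"]})
                    fit_rows.append({
                        "group": group, "stressor": stressor, "model": label,
                        "chi2": fit.chi2, "df": fit.df, "p": fit.p_fit,
                        "rmsea": fit.rmsea, "aic": fit.aic, "n": fit.n})
        sem_edges_path = outdir / "sem_edges.tsv"
        sem_fit_path = outdir / "sem_fit.tsv"
        pd.DataFrame(edge_rows).to_csv(sem_edges_path, sep="\t", index=False)
        pd.DataFrame(fit_rows).to_csv(sem_fit_path, sep="\t", index=False)
        record(stage, [sem_edges_path, sem_fit_path], t0)
    except StoichresError as exc:
        marker.write_text(f"stage {stage} failed: {exc}\n")
        report.failed_stage = stage
        (outdir / "report.json").write_text(report.to_json())
        raise StoichresError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (outdir / "report.json").write_text(report.to_json())
    return report
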