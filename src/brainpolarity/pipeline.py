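"""End-to-end orchestration: simulate -> polarity -> regimes -> maps -> stats.

Runs every stage of the polarity analysis on a (simulated or loaded)
cohort, writes per-stage artifacts as plain files so any stage can be
re-run independently, and emits a machine-readable JSON summary plus a
short human-readable report.  Given the same configuration and seed the
summary is bit-identical across runs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import connectivity as conn
from . import copp as copp_mod
from . import io as bio
from . import itineraries as itin
from . import participation as part
from . import polarity as pol
from . import regimes as reg
from .simulate import SimulationConfig, generate_cohort, write_cohort

logger = logging.getLogger("brainpolarity")

ALL_STAGES = ("simulate", "polarity", "regimes", "ppm", "copp", "itinerary",
              "dfnc", "stats")


@dataclass
class PipelineConfig:
    """Resolved parameters for a full pipeline run.

    Stage parameters default to the analysis conventions: k = 3 polarity
    regimes, k = 2 participation-map clusters, k = 13 co-polarization
    patterns, k = 5 connectivity states, alpha = 0.001 with 47 independent
    spatial units for the polarization test, 22-TR windows, a
    [0.05, 0.15] Hz pass band and a 1.25 map z-threshold.
    """

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    dpr_k: int = 3
    ppm_k: int = 2
    copp_k: int = 13
    dfnc_k: int = 5
    alpha: float = 0.001
    n_independent_units: int = 47
    window_length: int = 22
    band_hz: tuple[float, float] = (0.05, 0.15)
    map_z_threshold: float = 1.25
    replicates: int = 10
    discretization_mode: str = "gaussian_threshold"
    stages: tuple = ALL_STAGES
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def run_pipeline(config: PipelineConfig, out_dir: str | Path,
                 write_volumes: bool = False) -> dict:
    """Run the configured stages and return the summary dict.

    Artifacts land in ``out_dir``: the resolved configuration, the cohort
    table, per-subject proportion CSVs, fitted state models (JSON), effect
    tables (CSV), the summary JSON and a plain-text report.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = set(config.stages)
    summary: dict = {"seed": config.seed}

    cfg_echo = dataclasses.asdict(config)
    (out / "config.json").write_text(json.dumps(_jsonable(cfg_echo), indent=2))

    # dependency gating
    if "itinerary" in stages and "copp" not in stages:
        logger.warning("itinerary stage requires copp; skipping itinerary")
        stages.discard("itinerary")
    for need, dependents in (("polarity", {"regimes", "ppm", "copp"}),
                             ("regimes", {"ppm", "dfnc", "stats"})):
        if need not in stages:
            dropped = stages & dependents
            if dropped:
                logger.warning("%s stage disabled; skipping %s", need, sorted(dropped))
                stages -= dependents

    # --- simulate ----------------------------------------------------------
    sim = dataclasses.replace(config.simulation, seed=config.seed)
    subjects, cohort = generate_cohort(sim)
    if "simulate" in stages:
        cohort.to_csv(out / "cohort.csv", index=False)
        if write_volumes:
            write_cohort(subjects, cohort, out / "volumes", config=sim)
    groups = cohort["group"].to_numpy()
    summary["n_hc"] = int((groups == "HC").sum())
    summary["n_sz"] = int((groups == "SZ").sum())

    if "polarity" not in stages:
        _finish(out, summary)
        return summary

    # --- polarity coding ---------------------------------------------------
    ials, props_list = [], []
    for subj in subjects:
        z = pol.zscore_voxels(subj.volume)
        ial = pol.discretize_ial(z, mode=config.discretization_mode)
        props = pol.polarity_proportions(ial)
        pol.polarity_metric(props)
        ials.append(ial)
        props_list.append(props)
        pd.DataFrame({
            "tr": np.arange(props.h.size), "h": props.h, "l": props.l,
            "n": props.n, "pi": props.pi_metric,
        }).to_csv(out / f"{subj.subject_id}_props.csv", index=False)
    summary["mean_h"] = float(np.mean([p.h.mean() for p in props_list]))

    if "regimes" not in stages:
        _finish(out, summary)
        return summary

    # --- dynamic polarity regimes -----------------------------------------
    dpr = reg.fit_dpr(
        [p.stacked() for p in props_list],
        k=config.dpr_k, seed=config.seed, replicates=config.replicates,
    )
    bio.write_state_model(dpr, out / "dpr_model.json")
    occ = reg.occupancy_rates(dpr)
    pd.DataFrame(occ, columns=dpr.state_names).assign(
        subject_id=cohort["subject_id"]).to_csv(out / "dpr_occupancy.csv", index=False)
    pol_occ = reg.polarized_occupancy(dpr)
    dpr_effect = conn.nuisance_regression(pol_occ, "group", cohort,
                                          drop_collinear=True)
    summary["dpr_centroids"] = dpr.centroids
    summary["mean_polarized_occupancy"] = {
        "HC": float(pol_occ[groups == "HC"].mean()),
        "SZ": float(pol_occ[groups == "SZ"].mean()),
    }
    summary["sz_effect_on_polarized_occupancy"] = dpr_effect

    # --- participation maps ------------------------------------------------
    if "ppm" in stages:
        maps = [
            part.compute_ppm(ial, lab, subject_id=sid)
            for ial, lab, sid in zip(ials, dpr.labels, cohort["subject_id"])
        ]
        valid = [m for m in maps if m.is_valid]
        pd.DataFrame(
            np.vstack([m.values for m in valid]),
        ).assign(subject_id=[m.subject_id for m in valid]).to_csv(
            out / "ppms.csv", index=False)
        if len(valid) >= config.ppm_k:
            ppm_model = part.cluster_ppms(
                valid, k=config.ppm_k, seed=config.seed,
                replicates=config.replicates)
            summary["ppm_cluster_sizes"] = [
                int(sum(l[0] == j for l in ppm_model.labels))
                for j in range(config.ppm_k)
            ]
        from .simulate import generate_network_maps
        net_maps = generate_network_maps(sim)
        net_part = np.vstack([
            part.network_participation(m, net_maps, config.map_z_threshold)
            for m in valid
        ])
        pd.DataFrame(net_part).to_csv(out / "network_participation.csv", index=False)
        gd = part.voxelwise_group_difference(
            valid, groups=[cohort.set_index("subject_id").loc[m.subject_id, "group"]
                           for m in valid],
            contrast="group")
        summary["ppm_groupdiff_fdr_voxels"] = int(gd["fdr_mask"].sum())

    # --- co-polarization patterns -----------------------------------------
    copp_model = None
    if "copp" in stages:
        k_copp = min(config.copp_k, sum(i.n_timepoints for i in ials) // 10)
        copp_model = copp_mod.fit_copps(
            ials, k=k_copp, seed=config.seed, replicates=max(3, config.replicates // 2))
        classes = copp_mod.classify_copps(
            copp_model, alpha=config.alpha,
            n_independent_units=config.n_independent_units)
        bio.write_state_model(copp_model, out / "copp_model.json")
        summary["copp_k"] = k_copp
        summary["copp_classes"] = classes
        summary["copp_centroid_means"] = copp_model.centroid_means

    # --- itineraries -------------------------------------------------------
    if "itinerary" in stages and copp_model is not None:
        hc_mask = groups == "HC"
        tm_hc = itin.estimate_transitions(
            copp_model.labels, n_states=copp_model.k,
            group_mask=hc_mask, group="HC")
        tm_sz = itin.estimate_transitions(
            copp_model.labels, n_states=copp_model.k,
            group_mask=~hc_mask, group="SZ")
        mu = np.asarray(copp_model.centroid_means)
        sources = [int(np.argmax(mu)), int(np.argmin(mu))]
        sources = [s for s in sources if tm_hc.defined_rows[s] and tm_sz.defined_rows[s]]
        report = itin.compare_group_itineraries(
            tm_hc, tm_sz, sources, polarity_class=copp_model.polarity_class)
        (out / "itineraries.json").write_text(json.dumps(_jsonable(report), indent=2))
        summary["itineraries"] = report

    # --- dFNC --------------------------------------------------------------
    if "dfnc" in stages:
        windowed = []
        for subj in subjects:
            tcs = conn.bandpass_timecourses(
                subj.network_timecourses, tr_seconds=sim.tr_seconds,
                low_hz=config.band_hz[0], high_hz=config.band_hz[1])
            windowed.append(conn.sliding_window_fnc(
                tcs, window_length=config.window_length))
        dfnc = conn.fit_dfnc_states(
            windowed, k=config.dfnc_k, seed=config.seed,
            replicates=config.replicates)
        bio.write_state_model(dfnc, out / "dfnc_model.json")
        tests = {}
        for name, mask in (("HC", groups == "HC"), ("SZ", groups == "SZ")):
            tab = conn.dpr_within_dfnc_test(
                dpr.labels, dfnc.labels, window_length=config.window_length,
                n_states=config.dfnc_k, group_mask=mask)
            tab.to_csv(out / f"dpr_within_dfnc_{name}.csv", index=False)
            tests[name] = tab.to_dict(orient="list")
        summary["dpr_within_dfnc"] = tests

    # --- static FNC mediation ---------------------------------------------
    if "stats" in stages:
        fnc = np.vstack([conn.static_fnc(s.network_timecourses) for s in subjects])
        med = conn.fnc_mediation_comparison(fnc, cohort, pol_occ,
                                            drop_collinear=True)
        med["group_only"].to_csv(out / "fnc_group_effects.csv", index=False)
        med["group_with_occupancy"].to_csv(
            out / "fnc_group_effects_with_occupancy.csv", index=False)
        summary["fnc_mediation"] = {
            "n_group_sig_without_occupancy": med["n_group_sig_without_occupancy"],
            "n_group_sig_with_occupancy": med["n_group_sig_with_occupancy"],
            "n_group_absorbed": med["n_group_absorbed"],
        }

    _finish(out, summary)
    return summary


def _finish(out: Path, summary: dict) -> None:
    summary_j = _jsonable(summary)
    (out / "summary.json").write_text(json.dumps(summary_j, indent=2, sort_keys=True))
    (out / "report.txt").write_text(_render_report(summary_j))


def _render_report(summary: dict) -> str:
    lines = ["Whole-brain polarity pipeline report", "=" * 36, ""]
    lines.append(f"cohort: {summary.get('n_hc', '?')} HC / {summary.get('n_sz', '?')} SZ"
                 f" (seed {summary.get('seed')})")
    if "mean_h" in summary:
        lines.append(f"grand mean h(t): {summary['mean_h']:.3f}")
    if "mean_polarized_occupancy" in summary:
        occ = summary["mean_polarized_occupancy"]
        lines.append(
            f"polarized-regime occupancy: HC {occ['HC']:.3f}, SZ {occ['SZ']:.3f}")
    if "sz_effect_on_polarized_occupancy" in summary:
        eff = summary["sz_effect_on_polarized_occupancy"]
        lines.append(
            f"SZ effect on polarized occupancy: beta={eff['beta']:.3f}, "
            f"p={eff['p']:.2e}")
    if "copp_classes" in summary:
        pos = summary["copp_classes"].count("positive")
        neg = summary["copp_classes"].count("negative")
        lines.append(f"CoPPs: {summary['copp_k']} fitted, "
                     f"{pos} positively / {neg} negatively polarized")
    if "itineraries" in summary:
        for src, entry in summary["itineraries"].items():
            for grp, it in entry.items():
                lines.append(
                    f"itinerary from CoPP {src} ({grp}): orbit length "
                    f"{it['orbit_length']}")
    if "fnc_mediation" in summary:
        m = summary["fnc_mediation"]
        lines.append(
            f"FNC group effects: {m['n_group_sig_without_occupancy']} significant "
            f"alone, {m['n_group_sig_with_occupancy']} after polarization covariate")
    return "\n".join(lines) + "\n"
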