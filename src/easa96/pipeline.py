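"""End-to-end analysis of one run: QC -> depletion -> calls -> quality.

The run proceeds, per read-out: 680 nm bubble test (well exclusion), group
summaries at the analysis read, interference and pipetting QC, depletion
and classification by all three statistical routes (the configured primary
route drives the calls), assay-quality metrics, and finally the cross-run
control-chart verdict.  Everything intermediate is retained in the result
set so a run is auditable well by well.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Mapping, Optional

import numpy as np
import yaml

from . import qc as qc_mod
from .classify import (
    AssayCall,
    Call,
    InferenceConfig,
    bayesian_call,
    chemical_call,
    frequentist_call,
    ksd_call,
    run_call,
)
from .depletion import (
    control_pct_depletion,
    nc_pct_depletion_sd,
    signal_window,
    summarize_groups,
    tc_depletion,
)
from .errors import ManifestError, NotEvaluableError
from .layout import PlateLayout
from .plate_io import (
    ANALYSIS_TIMEPOINT_MIN,
    BUBBLE_680,
    AssayModality,
    PlateReading,
    read_plate_csv,
)
from .quality import fit_pc_dose_response, z_factor
from .simulate import SimulatedRun

ROUTES = ("frequentist", "bayesian", "ksd")


@dataclass
class AnalyzeOptions:
    inference: InferenceConfig = field(default_factory=InferenceConfig)
    qc_spec: qc_mod.QCSpec = field(default_factory=qc_mod.QCSpec)
    primary_route: str = "frequentist"
    routes: tuple = ROUTES  # statistical routes to compute
    use_pda_abs_in_run_call: bool = True
    analysis_timepoint_min: int = ANALYSIS_TIMEPOINT_MIN
    mcmc_seed: int = 0

    def __post_init__(self) -> None:
        if self.primary_route not in ROUTES:
            raise ValueError(f"primary_route must be one of {ROUTES}")
        if self.primary_route not in self.routes:
            raise ValueError("primary_route must be among the computed routes")


def _call_to_dict(call: AssayCall) -> dict:
    d = {
        "call": call.call.value,
        "pct_depletion": call.pct_depletion,
        "borderline_type1": call.borderline_type1,
        "borderline_type2": call.borderline_type2,
        "anomalous_negative": call.anomalous_negative,
    }
    if call.estimate is not None:
        d["estimate"] = asdict(call.estimate)
    if call.diagnostics:
        d["diagnostics"] = {
            k: (list(v) if isinstance(v, tuple) else v) for k, v in call.diagnostics.items()
        }
    return d


def analyze_run(
    plates: Mapping,
    bubble_reads: Mapping,
    layout: PlateLayout,
    options: Optional[AnalyzeOptions] = None,
    chart_states: Optional[Mapping[AssayModality, qc_mod.ControlChartState]] = None,
) -> dict:
    """Analyze one run and return the result set (a JSON-ready dict).

    ``plates`` maps (modality, timepoint) to a :class:`PlateReading`;
    ``bubble_reads`` maps each modality to its 680 nm read.  When
    ``chart_states`` is given it is updated in place per modality and a
    charted parameter out of limits marks the whole run excluded.
    """
    options = options or AnalyzeOptions()
    cfg, spec = options.inference, options.qc_spec
    results: dict = {
        "plate_ids": {},
        "config": {"alpha": cfg.alpha, "sidedness": cfg.sidedness,
                   "ksd_factor": cfg.ksd_factor, "primary_route": options.primary_route},
        "modalities": {},
        "run_calls": {},
        "excluded": False,
    }
    per_chem_modality_calls: dict[str, dict] = {}

    for modality in (AssayModality.NBT_ABS, AssayModality.PDA_ABS, AssayModality.PDA_FLUOR):
        key = (modality, options.analysis_timepoint_min)
        if key not in plates:
            raise ManifestError(
                f"missing {options.analysis_timepoint_min} min read for {modality.value}"
            )
        if modality not in bubble_reads:
            raise ManifestError(f"missing 680 nm bubble read for {modality.value}")
        reading = plates[key]
        results["plate_ids"][modality.value] = reading.plate_id

        excluded = qc_mod.bubble_test(bubble_reads[modality], layout, spec, modality)
        groups = summarize_groups(reading, layout, excluded)
        interference = qc_mod.interference_check(groups, layout, spec, modality)
        within_cv, between_cv, slope, slope_p = qc_mod.pipetting_qc(reading, layout, spec)

        report = qc_mod.QCReport(
            excluded_wells={str(w): "bubble" for w in sorted(excluded)},
            interference=interference,
            within_step_cv=within_cv,
            between_step_cv=between_cv,
            trend_slope=slope,
            trend_slope_p=slope_p,
            trend_warning=slope_p < spec.trend_alpha,
        )

        window = signal_window(groups)
        nc_sd_pct = nc_pct_depletion_sd(groups)
        mod_result: dict = {
            "qc": {
                "excluded_wells": report.excluded_wells,
                "within_step_cv_pct": within_cv,
                "between_step_cv_pct": between_cv,
                "trend_slope": slope,
                "trend_slope_p": slope_p,
                "trend_warning": report.trend_warning,
                "interference": {
                    layout.slot_name(s): asdict(f) for s, f in interference.items()
                },
            },
            "signal_window": window,
            "nc_pct_depletion_sd": nc_sd_pct,
            "chemicals": {},
        }

        for slot in layout.occupied_slots():
            name = layout.slot_name(slot)
            chem_result: dict = {}
            if interference[slot].assay_na:
                na = AssayCall(call=Call.NOT_AVAILABLE)
                chem_result = {r: _call_to_dict(na) for r in options.routes}
                chem_result["depletion"] = None
                calls = {r: na for r in options.routes}
            else:
                est = tc_depletion(groups, slot)
                chem_result["depletion"] = asdict(est)
                calls = {}
                if "frequentist" in options.routes:
                    calls["frequentist"] = frequentist_call(groups, cfg, slot=slot)
                if "bayesian" in options.routes:
                    # stable per (run seed, read-out, slot) so reruns reproduce
                    mod_index = list(AssayModality).index(modality)
                    seed = int(
                        np.random.SeedSequence(
                            [options.mcmc_seed, mod_index, slot]
                        ).generate_state(1)[0]
                        % 2**31
                    )
                    calls["bayesian"] = bayesian_call(
                        {
                            "blank": groups["blank"].values,
                            "nc": groups["nc"].values,
                            "tc": groups[("tc", slot)].values,
                            "tc_blank": groups[("tc_blank", slot)].values,
                        },
                        cfg,
                        seed=seed,
                    )
                if "ksd" in options.routes:
                    calls["ksd"] = ksd_call(
                        est.pct_depletion, nc_sd_pct, cfg, depletion_abs=est.depletion_abs
                    )
                for route, c in calls.items():
                    chem_result[route] = _call_to_dict(c)
            mod_result["chemicals"][name] = chem_result
            if options.use_pda_abs_in_run_call or modality is not AssayModality.PDA_ABS:
                per_chem_modality_calls.setdefault(name, {})[modality.value] = calls[
                    options.primary_route
                ]

        # quality metrics: PC dose-response and Z-factor
        curve_levels, curve_pcts = [], []
        for level in range(1, 8):
            pc = groups[("pc", level)]
            pcts = [
                control_pct_depletion(v, groups["nc"].mean, groups["blank"].mean)
                for v in pc.values
            ]
            curve_levels.append(level)
            curve_pcts.append(pcts)
        top_conc = _top_concentration(plates, modality)
        concs = [top_conc * 2.0 ** (1 - lv) for lv in curve_levels]
        fit = fit_pc_dose_response(concs, curve_pcts)
        sample_stats = {}
        for slot in layout.occupied_slots():
            name = layout.slot_name(slot)
            if not interference[slot].assay_na:
                est = tc_depletion(groups, slot)
                sample_stats[name] = (est.pct_depletion, groups[("tc", slot)].sd or 0.0)
        pc_top = groups[("pc", 1)]
        try:
            zres = z_factor(sample_stats, pc_top.sd or 0.0, window)
            z_doc = asdict(zres)
        except NotEvaluableError as exc:
            z_doc = {"z": None, "note": str(exc)}
        mod_result["quality"] = {
            "z_factor": z_doc,
            "pc_ic50_mmol": fit.ic50,
            "pc_fit_method": fit.method,
        }

        # control charting
        nc = groups["nc"]
        run_params = {
            "ss_mean": groups["blank"].mean,
            "nc_mean": nc.mean,
            "nc_cv": 100.0 * (nc.sd or 0.0) / nc.mean,
            "pc_ic50": fit.ic50,
        }
        mod_result["chart_parameters"] = run_params
        if chart_states is not None and modality in chart_states:
            new_state, outlier, tripped = qc_mod.update_control_chart(
                chart_states[modality], run_params, spec
            )
            chart_states[modality] = new_state  # type: ignore[index]
            mod_result["chart_outlier"] = outlier
            mod_result["chart_tripped"] = tripped
            if outlier:
                results["excluded"] = True
                results.setdefault("exclusion_reasons", []).append(
                    f"{modality.value}: control chart violation on {tripped}"
                )
        results["modalities"][modality.value] = mod_result

    for name, calls in per_chem_modality_calls.items():
        try:
            results["run_calls"][name] = run_call(calls).value
        except NotEvaluableError:
            results["run_calls"][name] = None
    return results


def _top_concentration(plates: Mapping, modality: AssayModality) -> float:
    # positive-control stock differs per read-out: 3 mmol/L benzyl bromide
    # (NBT) or 1 / 0.1 mmol/L glutaraldehyde, each diluted 40 uL into 200 uL
    return {
        AssayModality.NBT_ABS: 0.6,
        AssayModality.PDA_ABS: 0.2,
        AssayModality.PDA_FLUOR: 0.02,
    }[modality]


def analyze_simulated_run(
    run: SimulatedRun,
    options: Optional[AnalyzeOptions] = None,
    chart_states: Optional[Mapping] = None,
) -> dict:
    return analyze_run(run.plates, run.bubble_reads, run.layout, options, chart_states)


def combine_runs(run_results: list[dict]) -> dict[str, dict]:
    """Chemical-level majority vote over the run calls of repeated runs."""
    by_chem: dict[str, list[Call]] = {}
    for res in run_results:
        if res.get("excluded"):
            continue
        for name, call in res["run_calls"].items():
            if call is not None:
                by_chem.setdefault(name, []).append(Call(call))
    out = {}
    for name, calls in by_chem.items():
        try:
            final, n_eval = chemical_call(calls)
            out[name] = {"call": final.value, "n_runs": len(calls), "n_evaluable": n_eval}
        except NotEvaluableError:
            out[name] = {"call": None, "n_runs": len(calls), "n_evaluable": 0}
    return out


# ---------------------------------------------------------------------------
# file-based manifests for the CLI


def load_manifest(path) -> dict:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    for key in ("plates", "layout"):
        if key not in doc:
            raise ManifestError(f"manifest lacks required key {key!r}")
    return doc


def analyze_manifest(path, options: Optional[AnalyzeOptions] = None) -> dict:
    """Analyze a run described by a YAML manifest of plate CSV paths.

    Schema::

        layout: layout.json
        plates:
          nbt_abs: {"50": nbt_50.csv, "680": nbt_680.csv}
          pda_abs: {"50": pda_50.csv, "680": pda_680.csv}
          pda_fluor: {"50": fluor_50.csv, "680": fluor_680.csv}
    """
    import os

    doc = load_manifest(path)
    base = os.path.dirname(os.path.abspath(path))
    rel = lambda p: p if os.path.isabs(p) else os.path.join(base, p)
    with open(rel(doc["layout"])) as fh:
        layout = PlateLayout.from_json(fh.read())
    options = options or AnalyzeOptions()
    plates, bubbles = {}, {}
    for mod_name, reads in doc["plates"].items():
        modality = AssayModality(mod_name)
        for t_key, csv_path in reads.items():
            if str(t_key) == "680":
                bubbles[modality] = read_plate_csv(
                    rel(csv_path), f"{mod_name}-680", BUBBLE_680, 5,
                    fluorescence_scale=modality.is_fluorescence,
                )
            else:
                t = int(t_key)
                plates[(modality, t)] = read_plate_csv(
                    rel(csv_path), f"{mod_name}-{t}", modality, t
                )
    return analyze_run(plates, bubbles, layout, options)
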