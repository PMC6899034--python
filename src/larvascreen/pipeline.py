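"""End-to-end orchestration: simulate → (render/segment) → score → call →
fit dose-response → validation cascade → report.

Every stage writes plain CSV/JSON artifacts into the output directory and
the run closes with a manifest of SHA-256 hashes, so reruns with the same
config and seed are bit-identical on tabular outputs and silent input
changes are detectable.

Campaign-level tables are written combined with a ``plate_id`` column
(one ``layout.csv`` / ``measurements.csv`` / ``zscores.csv`` per run)
rather than one file per plate — diffable and friendlier to hundreds of
plates.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cascade as cascade_mod
from . import hits as hits_mod
from .campaign import (
    CampaignTruth,
    build_campaign,
    simulate_dose_series,
    simulate_measurements,
    simulate_validation_outcomes,
)
from .config import PipelineConfig
from .doseresponse import fit_4pl, fold_sensitivity, select_screening_dose
from .errors import LarvaScreenError

log = logging.getLogger(__name__)

#: demo toxicity curves (bottom, top, ec50, hill) used by the
#: dose-response stage of a simulated run; EC50s in the stated units.
#: The mutant worm is several hundred times more bortezomib-sensitive
#: than wild type; the heterozygous fly is two-fold more sensitive.
DEMO_CURVES = {
    "worm": {
        "unit": "nM",
        "mutant": (5.0, 100.0, 60.0, 1.5),
        "wild_type": (5.0, 100.0, 18000.0, 1.5),
    },
    "fly": {
        "unit": "uM",
        "mutant": (10.0, 100.0, 9.0, 2.0),       # heterozygote
        "wild_type": (10.0, 100.0, 18.0, 2.0),
    },
}


def _titration(ec50: float, factor: float = 50.0, n: int = 8) -> np.ndarray:
    """Dose grid spanning ``factor`` below to ``factor`` above the EC50,
    plus an untreated point."""
    return np.concatenate([[0.0], np.geomspace(ec50 / factor, ec50 * factor, n)])


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Run the full simulated screening campaign; returns the result bundle.

    The pipeline seed overrides the campaign seed so one integer pins the
    whole run.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    ccfg = config.campaign.model_copy(update={"seed": config.seed})
    species = ccfg.format.species
    ss = np.random.SeedSequence(config.seed)
    rng_meas, rng_dr, rng_val = (np.random.default_rng(c) for c in ss.spawn(3))

    log.info("stage=simulate n_compounds=%d", ccfg.n_compounds)
    truth, layout = build_campaign(ccfg)
    measurements = simulate_measurements(layout, truth, rng_meas)

    log.info("stage=score plates=%d", layout.plate_id.nunique())
    zscores, plate_qc = _score(config, measurements, layout, species)

    log.info("stage=call")
    rule = hits_mod.PRESETS["worm" if species == "worm" else "fly"]
    enh = hits_mod.ENHANCER if species == "worm" else None
    z_by_rep = _split_replicates(zscores, layout, ccfg.n_replicates)
    calls = hits_mod.call_consensus(z_by_rep, rule, enhancer_rule=enh)
    suppressors = calls.loc[calls.call == "suppressor", "compound_id"].tolist()
    rate = hits_mod.hit_rate(len(suppressors), ccfg.n_compounds, precision=1)
    rep_sets = [hits_mod.single_replicate_positives(t, rule) for t in z_by_rep]
    venn = hits_mod.replicate_overlap(rep_sets) if len(rep_sets) >= 2 else {}

    log.info("stage=fit-dr species=%s", species)
    dr = _dose_response_stage(config, species, rng_dr)

    log.info("stage=cascade suppressors=%d", len(suppressors))
    cascade_rules = cascade_mod.CascadeRules(
        nrf2_window_uM=config.cascade.nrf2_window_uM,
        nrf2_lower_exclusionary=config.cascade.nrf2_lower_exclusionary,
    )
    if suppressors:
        outcomes = simulate_validation_outcomes(
            truth, suppressors, rng_val, config.cascade
        )
        matrix = cascade_mod.build_matrix(outcomes)
        status = cascade_mod.classify_all(matrix, cascade_rules)
        summary = cascade_mod.cascade_summary(
            matrix, precision=config.cascade.precision, rules=cascade_rules
        )
    else:
        outcomes = pd.DataFrame(
            columns=["compound_id", "paradigm", "dose", "result", "ec50_uM"]
        )
        matrix = cascade_mod.build_matrix(outcomes)
        status = pd.DataFrame(columns=["compound_id", *cascade_mod.FLAGS])
        summary = pd.DataFrame(columns=["stage", "numerator", "denominator", "percent"])

    bundle = {
        "config": config,
        "truth": truth,
        "layout": layout,
        "measurements": measurements,
        "zscores": zscores,
        "plate_qc": plate_qc,
        "hits": calls,
        "suppressors": suppressors,
        "hit_rate_percent": rate,
        "venn": venn,
        "dose_response": dr,
        "outcomes": outcomes,
        "cascade_status": status,
        "cascade_summary": summary,
    }
    write_bundle(bundle, out)
    generate_report(bundle, out)
    _write_manifest(out)
    return bundle


def _score(config, measurements, layout, species):
    from .plate import score_campaign

    return score_campaign(
        measurements, layout,
        outlier_side=config.outlier_side,
        use_normalized=(species == "fly"),
        min_separation=config.qc_min_separation,
        max_eliminated_fraction=config.qc_max_eliminated_fraction,
    )


def _split_replicates(zscores, layout, n_replicates):
    keyed = zscores.merge(
        layout[["plate_id", "well", "replicate"]], on=["plate_id", "well"], how="left"
    )
    return [
        keyed[keyed.replicate == rep].reset_index(drop=True)
        for rep in range(1, n_replicates + 1)
    ]


def _dose_response_stage(config, species, rng):
    preset = DEMO_CURVES[species]
    sigma = config.campaign.noise_sigma
    curves, rows = {}, []
    for genotype in ("wild_type", "mutant"):
        series = simulate_dose_series(
            preset[genotype], _titration(preset[genotype][2]), n_reps=4,
            noise_sigma=sigma, rng=rng, genotype=genotype, drug="bortezomib",
            dose_unit=preset["unit"],
        )
        curve = fit_4pl(series, ec50_bounds_factor=config.dose_response.ec50_bounds_factor)
        curves[genotype] = curve
        rows.append({
            "genotype": genotype, "drug": "bortezomib",
            "bottom": curve.bottom, "top": curve.top, "ec50": curve.ec50,
            "hill": curve.hill, "rss": curve.rss, "n_points": curve.n_points,
            "converged": curve.converged, "dose_unit": curve.dose_unit,
        })
    fold = fold_sensitivity(curves["wild_type"], curves["mutant"])
    dose = select_screening_dose(
        curves["mutant"], config.dose_response.target_reduction
    )
    return {
        "curves": pd.DataFrame(rows),
        "fold_sensitivity": fold,
        "screening_dose": dose,
        "dose_unit": preset["unit"],
        "target_reduction": config.dose_response.target_reduction,
    }


def write_bundle(bundle: dict, out: Path) -> None:
    cfg: PipelineConfig = bundle["config"]
    (out / "campaign.yaml").write_text(
        yaml.safe_dump(cfg.model_dump(mode="json"), sort_keys=True)
    )
    bundle["truth"].effects.to_csv(out / "truth.csv", index=False)
    bundle["layout"].to_csv(out / "layout.csv", index=False)
    bundle["measurements"].to_csv(out / "measurements.csv", index=False)
    bundle["zscores"].to_csv(out / "zscores.csv", index=False)
    bundle["plate_qc"].to_csv(out / "plate_qc.csv", index=False)
    bundle["hits"].to_csv(out / "hits.csv", index=False)
    (out / "venn.json").write_text(
        json.dumps(hits_mod.venn_json(bundle["venn"]), indent=2)
    )
    dr = bundle["dose_response"]
    dr["curves"].to_csv(out / "curves.csv", index=False)
    pd.DataFrame([{
        "drug": "bortezomib",
        "dose": dr["screening_dose"],
        "dose_unit": dr["dose_unit"],
        "target_reduction": dr["target_reduction"],
    }]).to_csv(out / "doses_selected.csv", index=False)
    bundle["outcomes"].to_csv(out / "outcomes.csv", index=False)
    bundle["cascade_status"].to_csv(out / "status.csv", index=False)
    bundle["cascade_summary"].to_csv(out / "summary.csv", index=False)


def generate_report(bundle: dict, out: Path) -> None:
    """Write report.md + report.json summarizing every stage."""
    out = Path(out)
    n_comp = bundle["config"].campaign.n_compounds
    supp = bundle["suppressors"]
    venn = hits_mod.venn_json(bundle["venn"])
    dr = bundle["dose_response"]
    qc = bundle["plate_qc"]
    summary = bundle["cascade_summary"]

    report = {
        "n_compounds": n_comp,
        "n_plates": int(bundle["layout"].plate_id.nunique()),
        "plates_passing_qc": int(qc.passed.sum()) if len(qc) else 0,
        "n_suppressors": len(supp),
        "hit_rate_percent": bundle["hit_rate_percent"],
        "venn": venn,
        "fold_sensitivity": dr["fold_sensitivity"],
        "screening_dose": dr["screening_dose"],
        "dose_unit": dr["dose_unit"],
        "cascade": summary.to_dict(orient="records"),
        "all_assay_active": _all_assay_active(bundle["cascade_status"]),
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, default=float))

    lines = [
        "# Screening campaign report",
        "",
        f"- compounds screened: {n_comp} in "
        f"{bundle['config'].campaign.n_replicates} replicates",
        f"- plates passing QC: {report['plates_passing_qc']}/{report['n_plates']}",
        f"- suppressor hits: {len(supp)} "
        f"(hit rate {bundle['hit_rate_percent']}%)",
        f"- genotype fold-sensitivity (EC50 ratio): "
        f"{dr['fold_sensitivity']:.2f}",
        f"- selected screening dose: {dr['screening_dose']:.1f} {dr['dose_unit']} "
        f"(target reduction {dr['target_reduction']:.0%})",
        "",
        "## Replicate overlap",
        "",
    ]
    if venn:
        lines += [f"- region {k}: {v}" for k, v in venn.items()]
    else:
        lines.append("- no hits; Venn omitted")
    lines += ["", "## Plate QC", "", qc.to_markdown(index=False) if len(qc) else "(none)"]
    lines += ["", "## Validation cascade", "",
              summary.to_markdown(index=False) if len(summary) else "(no hits)"]
    (out / "report.md").write_text("\n".join(lines) + "\n")
    _plot_zscatter(bundle, out)


def _all_assay_active(status: pd.DataFrame) -> list[str]:
    if len(status) == 0 or "all_assay_active" not in status.columns:
        return []
    return status.loc[status.all_assay_active.astype(bool), "compound_id"].tolist()


def _plot_zscatter(bundle: dict, out: Path) -> None:
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except Exception:  # plotting is diagnostic only
        return
    z = bundle["zscores"].dropna(subset=["z"])
    if z.empty:
        return
    fig, ax = plt.subplots(figsize=(7, 3))
    ax.scatter(range(len(z)), z.z, s=2, alpha=0.4)
    ax.axhline(2.0, color="red", lw=0.8, ls="--")
    ax.set_xlabel("well index")
    ax.set_ylabel("Z-score")
    fig.tight_layout()
    fig.savefig(out / "zscore_scatter.png", dpi=100)
    plt.close(fig)


def _write_manifest(out: Path) -> None:
    manifest = {}
    for path in sorted(out.iterdir()):
        if path.name == "manifest.json" or path.is_dir():
            continue
        manifest[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def verify_manifest(out: str | Path) -> list[str]:
    """Return the names of files whose content no longer matches the manifest."""
    out = Path(out)
    manifest = json.loads((out / "manifest.json").read_text())
    bad = []
    for name, digest in manifest.items():
        p = out / name
        if not p.exists() or hashlib.sha256(p.read_bytes()).hexdigest() != digest:
            bad.append(name)
    return bad


def load_config(path: str | Path) -> PipelineConfig:
    """Load and schema-validate a YAML pipeline config."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    try:
        return PipelineConfig.model_validate(data)
    except Exception as exc:  # pydantic ValidationError
        raise LarvaScreenError(f"invalid pipeline config {path}: {exc}") from exc
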