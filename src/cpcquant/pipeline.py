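"""Configuration-driven orchestration of the five analyses.

A single YAML document selects one analysis (itc, centromere, spread,
tethering or massphot), its parameters and a seed; ``run_pipeline`` executes
it end-to-end — generating synthetic inputs where no input files are given —
and writes every intermediate table as CSV, a provenance log, and optional
figures.  Re-running the persisted config with the same seed reproduces all
numeric outputs exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from cpcquant import __version__, centromere, itc, massphot, profiles, stats, synthetic

__all__ = ["PipelineConfig", "ConfigError", "run_pipeline", "write_report", "load_config"]

ANALYSES = ("itc", "centromere", "spread", "tethering", "massphot")

log = logging.getLogger("cpcquant")


class ConfigError(ValueError):
    """Configuration schema violation; the message names the field path."""


@dataclass
class PipelineConfig:
    analysis: str
    outdir: str = "cpcquant_out"
    seed: int = 0
    make_figures: bool = False
    params: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        if not isinstance(data, dict):
            raise ConfigError("config: expected a mapping")
        analysis = data.get("analysis")
        if analysis not in ANALYSES:
            raise ConfigError(f"analysis: must be one of {ANALYSES}, got {analysis!r}")
        seed = data.get("seed", 0)
        if not isinstance(seed, int):
            raise ConfigError("seed: must be an integer")
        params = data.get(analysis, data.get("params", {})) or {}
        if not isinstance(params, dict):
            raise ConfigError(f"{analysis}: parameter section must be a mapping")
        cfg = cls(
            analysis=analysis,
            outdir=str(data.get("outdir", "cpcquant_out")),
            seed=seed,
            make_figures=bool(data.get("make_figures", False)),
            params=params,
        )
        _VALIDATORS[analysis](cfg.params)
        return cfg


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        return PipelineConfig.from_dict(yaml.safe_load(fh))


def _require(params: dict, path: str, keys: list[str]) -> None:
    for k in keys:
        if k not in params:
            raise ConfigError(f"{path}.{k}: required field missing")


def _validate_itc(p: dict) -> None:
    if "isotherm_csv" in p:
        if not Path(p["isotherm_csv"]).exists():
            raise ConfigError(f"itc.isotherm_csv: no such file {p['isotherm_csv']!r}")
    else:
        _require(p, "itc", ["binding"])
        _require(p["binding"], "itc.binding", ["KD_nM", "dH_kcal_mol"])


def _validate_conditions(p: dict, path: str) -> None:
    _require(p, path, ["conditions"])
    if not isinstance(p["conditions"], dict) or not p["conditions"]:
        raise ConfigError(f"{path}.conditions: must be a nonempty mapping")


def _validate_centromere(p: dict) -> None:
    _validate_conditions(p, "centromere")
    _require(p, "centromere", ["reference_condition"])
    if p["reference_condition"] not in p["conditions"]:
        raise ConfigError(
            "centromere.reference_condition: label not present in centromere.conditions"
        )
    if "channel_map" in p and not isinstance(p["channel_map"], dict):
        raise ConfigError("centromere.channel_map: must be a mapping channel->page")


def _validate_spread(p: dict) -> None:
    _validate_conditions(p, "spread")
    for label, cond in p["conditions"].items():
        pm = (cond or {}).get("pool_model", "inner_only")
        if pm not in ("inner_only", "dual_pool", "both"):
            raise ConfigError(f"spread.conditions.{label}.pool_model: invalid {pm!r}")


def _validate_tethering(p: dict) -> None:
    _validate_conditions(p, "tethering")
    _require(p, "tethering", ["control"])
    if p["control"] not in p["conditions"]:
        raise ConfigError("tethering.control: label not present in tethering.conditions")


def _validate_massphot(p: dict) -> None:
    if "events_csv" in p:
        if not Path(p["events_csv"]).exists():
            raise ConfigError(f"massphot.events_csv: no such file {p['events_csv']!r}")
    else:
        _require(p, "massphot", ["components"])


_VALIDATORS = {
    "itc": _validate_itc,
    "centromere": _validate_centromere,
    "spread": _validate_spread,
    "tethering": _validate_tethering,
    "massphot": _validate_massphot,
}


# ---------------------------------------------------------------------------
# Analysis runners.  Each returns {table_name: DataFrame}.


def _scheme_from(p: dict) -> itc.TitrationScheme:
    sp = dict(p.get("scheme", {}))
    return itc.TitrationScheme(**sp)


def _run_itc(cfg: PipelineConfig) -> dict[str, pd.DataFrame]:
    p = cfg.params
    scheme = _scheme_from(p)
    if "isotherm_csv" in p:
        iso = itc.read_isotherm_csv(p["isotherm_csv"])
    else:
        b = p["binding"]
        params = itc.BindingParameters(
            N=b.get("N", 1.0),
            KD_M=b["KD_nM"] * 1e-9,
            dH_kcal_mol=b["dH_kcal_mol"],
            dilution_offset_kcal_mol=b.get("dilution_offset_kcal_mol", 0.0),
        )
        iso = itc.simulate_isotherm(
            scheme, params, noise_sd_kcal_mol=p.get("noise_sd_kcal_mol", 0.0),
            seed=cfg.seed,
        )
    fit = itc.fit_isotherm(iso, scheme)
    iso_df = pd.DataFrame(
        {
            "molar_ratio": iso.molar_ratio,
            "q_per_mol_kcal": iso.q_per_mol,
            "included": iso.included.astype(int),
        }
    )
    fit_df = pd.DataFrame(
        [
            {
                "N": fit.params.N,
                "KD_nM": fit.KD_nM,
                "KD_se_nM": fit.se.get("KD_M", np.nan) * 1e9,
                "dH_kcal_mol": fit.params.dH_kcal_mol,
                "dH_se": fit.se.get("dH_kcal_mol", np.nan),
                "dilution_offset_kcal_mol": fit.params.dilution_offset_kcal_mol,
                "dG_kcal_mol": fit.dG_kcal_mol,
                "minus_TdS_kcal_mol": fit.minus_TdS_kcal_mol,
                "c_value": itc.c_value(scheme, fit.params.KD_M, fit.params.N),
                "rss": fit.rss,
                "converged": fit.converged,
                "warnings": ";".join(fit.warnings),
            }
        ]
    )
    return {"isotherm": iso_df, "fit": fit_df}


def _cell_scene(ch_amps: dict[str, float], n_spots: int, seed: int, p: dict) -> synthetic.ImageScene:
    """Random field of centromere foci with the given per-channel amplitudes."""
    size = int(p.get("image_size_px", 192))
    px = float(p.get("pixel_size_um", synthetic.DEFAULT_PIXEL_SIZE_UM))
    sigma = float(p.get("spot_sigma_um", 0.13))
    rng = np.random.default_rng(seed)
    margin = 8 * sigma
    wx = wy = size * px
    spots = [
        synthetic.SpotTruth(
            centroid_um=(rng.uniform(margin, wx - margin), rng.uniform(margin, wy - margin)),
            sigma_um=sigma,
            amplitude=dict(ch_amps),
        )
        for _ in range(n_spots)
    ]
    return synthetic.ImageScene(
        width_px=size, height_px=size, pixel_size_um=px,
        channels=tuple(ch_amps), spots=spots,
        background_level=float(p.get("background_level", 100.0)),
        gaussian_sd=float(p.get("noise_sd", 2.0)),
        seed=seed,
    )


def _run_centromere(cfg: PipelineConfig) -> dict[str, pd.DataFrame]:
    p = cfg.params
    n_cells = int(p.get("n_cells_per_condition", 20))
    n_spots = int(p.get("n_spots_per_cell", 12))
    measurements: list[centromere.CellMeasurement] = []
    ss = np.random.SeedSequence(cfg.seed)
    for (label, cond), child in zip(
        sorted(p["conditions"].items()), ss.spawn(len(p["conditions"]))
    ):
        amp = float((cond or {}).get("marker_amplitude", 500.0))
        aca = float((cond or {}).get("aca_amplitude", 1000.0))
        for cell_i, cell_seed in enumerate(child.generate_state(n_cells)):
            scene = _cell_scene(
                {"ACA": aca, "marker": amp}, n_spots, int(cell_seed >> 1), p
            )
            images, _ = synthetic.generate_cell_image(scene)
            foci = centromere.detect_foci(images["ACA"])
            per_spot = []
            for f in foci:
                rm = centromere.measure_ring(images["marker"], f)
                if "ring_clipped_by_border" not in rm.flags:
                    per_spot.append(rm.corrected)
            if not per_spot:
                continue
            measurements.append(
                centromere.CellMeasurement(
                    cell_id=f"{label}_{cell_i}", condition=label,
                    ring_mean=float(np.mean(per_spot)), background_mean=0.0,
                    corrected=float(np.mean(per_spot)),
                )
            )
    centromere.normalize_condition(measurements, p["reference_condition"])
    cells = centromere.measurements_to_frame(measurements)
    table = cells.rename(columns={"normalized": "value", "condition": "group"})[
        ["value", "group"]
    ]
    H, p_global, pairwise = stats.kruskal_dunn(table, adjust=p.get("adjust", "holm"))
    summary = pd.DataFrame([{"H": H, "p": p_global}])
    return {"cells": cells, "kruskal": summary, "dunn": pairwise}


def _run_spread(cfg: PipelineConfig) -> dict[str, pd.DataFrame]:
    p = cfg.params
    n_pairs = int(p.get("n_pairs_per_condition", 50))
    sep = float(p.get("inter_kt_sep_um", 1.0))
    per_image = int(p.get("pairs_per_image", 10))
    rows = []
    profile_rows = []
    ss = np.random.SeedSequence(cfg.seed)
    for (label, cond), child in zip(
        sorted(p["conditions"].items()), ss.spawn(len(p["conditions"]))
    ):
        pm = (cond or {}).get("pool_model", "inner_only")
        n_images = int(np.ceil(n_pairs / per_image))
        got = 0
        for img_seed in child.generate_state(n_images):
            base = synthetic.ImageScene(
                width_px=int(p.get("image_size_px", 256)),
                height_px=int(p.get("image_size_px", 256)),
                pixel_size_um=float(p.get("pixel_size_um", synthetic.DEFAULT_PIXEL_SIZE_UM)),
                channels=("ACA", "marker"),
                background_level=float(p.get("background_level", 50.0)),
                gaussian_sd=float(p.get("noise_sd", 2.0)),
                seed=int(img_seed >> 1),
            )
            images, truth_pairs = synthetic.generate_spread_image(
                base, sep, n_pairs=min(per_image, n_pairs - got), pool_model=pm,
                marker_sigma_um=float(p.get("marker_sigma_um", 0.15)),
                dual_offset_frac=float(p.get("dual_offset_frac", 0.8)),
            )
            foci = centromere.detect_foci(images["ACA"])
            cents = [
                (f.centroid_px[0] * base.pixel_size_um, f.centroid_px[1] * base.pixel_size_um)
                for f in foci
            ]
            # detection reports array-index coordinates; shift to physical
            cents = [(x + 0.5 * base.pixel_size_um, y + 0.5 * base.pixel_size_um) for x, y in cents]
            kt_pairs, _ = profiles.assign_pairs(cents, max_sep_um=p.get("max_sep_um", 1.5))
            for kp in kt_pairs:
                try:
                    prof = profiles.extract_profile(images, kp, base.pixel_size_um)
                    res = profiles.fwhm(prof, "marker")
                except ValueError:
                    continue
                rows.append(
                    {
                        "condition": label, "pool_model": pm,
                        "separation_um": kp.separation_um,
                        "fwhm_marker_um": res.fwhm_um,
                        "n_crossings": res.n_crossings,
                    }
                )
                for pos, aca_v, m_v in zip(
                    prof.positions_um,
                    prof.normalized_intensity["ACA"],
                    prof.normalized_intensity["marker"],
                ):
                    profile_rows.append(
                        {
                            "condition": label, "pair": len(rows) - 1,
                            "position_um": pos, "ACA": aca_v, "marker": m_v,
                        }
                    )
            got += len(truth_pairs)
            if got >= n_pairs:
                break
    per_pair = pd.DataFrame(rows)
    table = per_pair.rename(columns={"fwhm_marker_um": "value", "condition": "group"})[
        ["value", "group"]
    ]
    if table["group"].nunique() >= 2:
        H, p_global, pairwise = stats.kruskal_dunn(table)
        summary = pd.DataFrame([{"H": H, "p": p_global}])
    else:
        summary = pd.DataFrame([{"H": np.nan, "p": np.nan}])
        pairwise = pd.DataFrame()
    return {
        "pairs": per_pair,
        "profiles": pd.DataFrame(profile_rows),
        "kruskal": summary,
        "dunn": pairwise,
    }


def _run_tethering(cfg: PipelineConfig) -> dict[str, pd.DataFrame]:
    p = cfg.params
    n_cells = int(p.get("n_cells_per_condition", 20))
    rows = []
    ss = np.random.SeedSequence(cfg.seed)
    for (label, cond), child in zip(
        sorted(p["conditions"].items()), ss.spawn(len(p["conditions"]))
    ):
        tgt = float((cond or {}).get("target_amplitude", 500.0))
        gfp = float((cond or {}).get("gfp_amplitude", 500.0))
        for cell_i, cell_seed in enumerate(child.generate_state(n_cells)):
            scene = _cell_scene({"marker": tgt, "GFP": gfp}, 1, int(cell_seed >> 1), p)
            images, _ = synthetic.generate_cell_image(scene)
            foci = centromere.detect_foci(images["GFP"])
            if not foci:
                continue
            try:
                ratio = centromere.recruitment_ratio(
                    images["marker"], images["GFP"], foci[0]
                )
            except ValueError:
                continue
            rows.append({"cell_id": f"{label}_{cell_i}", "group": label, "value": ratio})
    cells = pd.DataFrame(rows)
    F, p_global, comparisons = stats.anova_dunnett(cells[["value", "group"]], p["control"])
    return {
        "cells": cells,
        "anova": pd.DataFrame([{"F": F, "p": p_global}]),
        "dunnett": comparisons,
    }


def _run_massphot(cfg: PipelineConfig) -> dict[str, pd.DataFrame]:
    p = cfg.params
    if "events_csv" in p:
        events = pd.read_csv(p["events_csv"])["mass_kD"].to_numpy(float)
    else:
        mix = synthetic.MassMixture(
            components=[tuple(c) for c in p["components"]],
            n_events=int(p.get("n_events", 5000)),
            seed=cfg.seed,
        )
        events = synthetic.generate_mass_events(mix)
    peaks = massphot.kde_peaks(
        events,
        bandwidth_kD=p.get("bandwidth_kD"),
        weight_floor=float(p.get("weight_floor", 0.05)),
    )
    peaks_df = pd.DataFrame(
        [{"location_kD": q.location_kD, "sd_kD": q.sd_kD, "weight": q.weight} for q in peaks]
    )
    out = {"events": pd.DataFrame({"mass_kD": events}), "peaks": peaks_df}
    if "candidates" in p:
        cands = [
            massphot.ComplexComposition(
                components=[tuple(c) for c in cand["components"]], name=name
            )
            for name, cand in p["candidates"].items()
        ]
        out["assignments"] = massphot.assign_species(
            peaks, cands, tol_sd=float(p.get("tol_sd", 1.0))
        )
    return out


_RUNNERS = {
    "itc": _run_itc,
    "centromere": _run_centromere,
    "spread": _run_spread,
    "tethering": _run_tethering,
    "massphot": _run_massphot,
}


def run_pipeline(cfg: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Execute one configured analysis end-to-end and write its report."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        log.info("cpcquant %s | analysis=%s seed=%d", __version__, cfg.analysis, cfg.seed)
        results = _RUNNERS[cfg.analysis](cfg)
        write_report(results, outdir, make_figures=cfg.make_figures, analysis=cfg.analysis)
        with open(outdir / "config.yaml", "w") as fh:
            yaml.safe_dump(
                {
                    "analysis": cfg.analysis,
                    "seed": cfg.seed,
                    "outdir": str(cfg.outdir),
                    "make_figures": cfg.make_figures,
                    cfg.analysis: cfg.params,
                    "version": __version__,
                },
                fh,
            )
        log.info("wrote %d tables to %s", len(results), outdir)
        return results
    finally:
        log.removeHandler(handler)
        handler.close()


def write_report(
    results: dict[str, pd.DataFrame], outdir, make_figures: bool = False,
    analysis: str = "",
) -> list[Path]:
    """Persist result tables as CSV (always) and figures (optionally)."""
    if not results:
        raise ValueError("empty results: nothing to report")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, df in results.items():
        path = outdir / f"{name}.csv"
        df.to_csv(path, index=False)
        written.append(path)
    if make_figures:
        written.extend(_figures(results, outdir, analysis))
    return written


def _figures(results: dict[str, pd.DataFrame], outdir: Path, analysis: str) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    if analysis == "itc" and "isotherm" in results:
        iso = results["isotherm"]
        fig, ax = plt.subplots(figsize=(4, 3))
        inc = iso["included"] == 1
        ax.plot(iso.loc[inc, "molar_ratio"], iso.loc[inc, "q_per_mol_kcal"], "ks", ms=4)
        ax.plot(iso.loc[~inc, "molar_ratio"], iso.loc[~inc, "q_per_mol_kcal"], "ko",
                mfc="none", ms=4)
        ax.set_xlabel("molar ratio")
        ax.set_ylabel("kcal/mol of injectant")
        fig.tight_layout()
        path = outdir / "isotherm.png"
        fig.savefig(path, dpi=150)
        plt.close(fig)
        written.append(path)
    if analysis == "spread" and "profiles" in results and len(results["profiles"]):
        prof = results["profiles"]
        fig, ax = plt.subplots(figsize=(4, 3))
        for cond, sub in prof.groupby("condition"):
            mean = sub.groupby("position_um")["marker"].mean()
            ax.plot(mean.index, mean.values, label=f"{cond} marker")
        ax.set_xlabel("position along pair axis (um)")
        ax.set_ylabel("normalized intensity")
        ax.legend(fontsize=7)
        fig.tight_layout()
        path = outdir / "line_profiles.png"
        fig.savefig(path, dpi=150)
        plt.close(fig)
        written.append(path)
    if analysis in ("centromere", "tethering") and "cells" in results:
        cells = results["cells"]
        value_col = "normalized" if "normalized" in cells else "value"
        group_col = "condition" if "condition" in cells else "group"
        fig, ax = plt.subplots(figsize=(4, 3))
        for i, (cond, sub) in enumerate(cells.groupby(group_col)):
            x = np.full(len(sub), i) + np.linspace(-0.15, 0.15, len(sub))
            ax.plot(x, sub[value_col], "o", ms=3, alpha=0.6)
            ax.hlines(sub[value_col].mean(), i - 0.25, i + 0.25, color="red")
        ax.set_xticks(range(cells[group_col].nunique()))
        ax.set_xticklabels(sorted(cells[group_col].unique()), rotation=45, ha="right", fontsize=7)
        ax.set_ylabel(value_col)
        fig.tight_layout()
        path = outdir / "scatter_means.png"
        fig.savefig(path, dpi=150)
        plt.close(fig)
        written.append(path)
    return written
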