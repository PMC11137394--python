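"""Config-driven orchestration of the monitoring workflows.

A single YAML (or dict) configuration selects stages and parameters; `run`
executes them in order — generate/ingest spectra, pretreat, sample-size
check, Scenario A monitoring or Scenario B comparison, colorimetry — and
writes CSV tables, plots and a manifest into the output directory.  One
global seed fans out to per-stage seeds through a fixed stage-name hash,
so identical config + seed reproduces identical numerical artifacts while
stages stay decoupled.

`render_report` turns a manifest into a single human-readable markdown
summary.
"""

from __future__ import annotations

import hashlib
import json
import time
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from . import color as lc
from . import mspc, pretreat, sampling, synth
from .io import SpectraSet, read_spectra, write_spectra

__all__ = ["RunConfig", "RunManifest", "ConfigError", "run", "render_report", "demo_config"]

STAGES = ("generate", "pretreat", "samplesize", "monitor", "compare", "colorimetry")


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass
class RunConfig:
    """Validated run configuration; see :func:`demo_config` for the shape."""

    raw: dict
    out_dir: Path
    seed: int
    stages: list[str]

    @classmethod
    def from_dict(cls, cfg: dict) -> "RunConfig":
        if not isinstance(cfg, dict):
            raise ConfigError("configuration must be a mapping")
        stages = cfg.get("stages", ["generate", "monitor"])
        for s in stages:
            if s not in STAGES:
                raise ConfigError(f"unknown stage {s!r}; valid: {STAGES}")
        spectra = cfg.get("spectra", {})
        has_synth = "synthetic" in spectra
        has_real = "cal_path" in spectra or "test_path" in spectra
        if has_synth and has_real:
            raise ConfigError(
                "spectra config must use either synthetic specs or real input "
                "paths, not both"
            )
        if ("monitor" in stages or "compare" in stages or "samplesize" in stages) and not (
            has_synth or has_real
        ):
            raise ConfigError("spectral stages requested but no spectra source given")
        return cls(
            raw=cfg,
            out_dir=Path(cfg.get("out_dir", "leafspec_out")),
            seed=int(cfg.get("seed", 0)),
            stages=list(stages),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def digest(self) -> str:
        canon = yaml.safe_dump(self.raw, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        return (self.seed * 1000003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class RunManifest:
    """What a run produced: config digest, seeds, timings, artifact paths."""

    config_digest: str
    version: str
    seed: int
    stage_seeds: dict[str, int]
    timings_s: dict[str, float]
    artifacts: dict[str, str]
    summary: dict = field(default_factory=dict)

    def save(self, path: Path) -> Path:
        path.write_text(json.dumps(asdict(self), indent=2, default=str))
        return path


# ---------------------------------------------------------------------------
# helpers


def demo_config(seed: int = 1, out_dir: str = "leafspec_demo") -> dict:
    """The bundled demo: canonical synthetic monitoring narrative.

    A healthy calibration set, one polluted set with a changed 1000/1580
    correlation ratio (T² signature) and one with new variation at
    1300 cm^-1 (SPEx signature), plus a sample-size check and a spotted
    vs unspotted colorimetry comparison.
    """
    return {
        "seed": seed,
        "out_dir": out_dir,
        "stages": ["generate", "samplesize", "monitor", "colorimetry"],
        "spectra": {
            "synthetic": {
                "preset": "default",
                "n_cal": 150,
                "n_test": 30,
                "effects": [
                    {"kind": "modelled_change", "targets": [1000.0], "magnitude": 1.5},
                    {"kind": "new_variation", "targets": [1300.0], "magnitude": 0.8},
                ],
            }
        },
        "model": {"n_components": 9},
        "charts": {"primary_level": 0.98, "report_levels": [0.997, 0.998], "log_scale": True},
        "samplesize": {"n_components": 3, "repeats": 10, "w": 5, "tau": 0.02},
        "colorimetry": {
            "synthetic": {
                "n_leaves": 8,
                "spot_fraction": 0.5,
                "spot_offset": [40, 40, 0],
                "cast_gain": 0.2,
            }
        },
    }


def _monitor_config(cfg: dict) -> mspc.MonitorConfig:
    model = cfg.get("model", {})
    charts = cfg.get("charts", {})
    return mspc.MonitorConfig(
        n_components=model.get("n_components", "auto"),
        ev_threshold=model.get("ev_threshold", 0.95),
        primary_level=charts.get("primary_level", 0.98),
        report_levels=tuple(charts.get("report_levels", (0.997, 0.998))),
        contribution_level=charts.get("contribution_level", 0.998),
        limit_method=charts.get("limit_method", "empirical"),
        limit_basis=charts.get("limit_basis", "cross_validated"),
        min_fraction=charts.get("min_fraction", 0.5),
        t2_formula=charts.get("t2_formula", "as_printed"),
    )


def _build_spec(syn: dict, seed: int) -> synth.SyntheticSpectraSpec:
    preset = syn.get("preset", "default")
    if preset == "default":
        return synth.default_spec(seed=seed)
    if preset == "saturating":
        return synth.saturating_spec(seed=seed)
    raise ConfigError(f"unknown synthetic preset {preset!r}")


def _effects(syn: dict) -> list[synth.PollutionEffect]:
    return [
        synth.PollutionEffect(e["kind"], list(e["targets"]), float(e["magnitude"]),
                              e.get("description", ""))
        for e in syn.get("effects", [])
    ]


def _chart_frame(chart: mspc.ControlChart) -> pd.DataFrame:
    rows = []
    lim = chart.limits[chart.primary_level]
    for sid, v, f in zip(chart.sample_ids, chart.values, chart.flags):
        rows.append(
            {"sample_id": sid, "statistic": chart.statistic, "value": v,
             "limit": lim, "flag": bool(f)}
        )
    return pd.DataFrame(rows)


def _plot_chart(chart: mspc.ControlChart, path: Path, log_scale: bool = True) -> None:
    fig, ax = plt.subplots(figsize=(7, 3))
    ax.plot(chart.values, "o-", ms=3, lw=0.7, label=chart.statistic.upper())
    for lv, lim in sorted(chart.limits.items()):
        ax.axhline(lim, ls="--", lw=0.8, label=f"{lv * 100:g}% limit")
    if log_scale:
        ax.set_yscale("log")
    ax.set_xlabel("sample")
    ax.set_ylabel(chart.statistic.upper())
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


# ---------------------------------------------------------------------------
# the driver


def run(config: RunConfig | dict | str | Path) -> RunManifest:
    """Execute the configured stages; returns the manifest (also saved as
    ``manifest.json`` in the output directory)."""
    if isinstance(config, (str, Path)):
        config = RunConfig.from_yaml(config)
    elif isinstance(config, dict):
        config = RunConfig.from_dict(config)
    cfg = config.raw
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)

    artifacts: dict[str, str] = {}
    timings: dict[str, float] = {}
    summary: dict = {}
    stage_seeds = {s: config.stage_seed(s) for s in config.stages}

    def _stage(name):
        return name in config.stages

    cal = test_sets = None
    syn = cfg.get("spectra", {}).get("synthetic")
    spectra_cfg = cfg.get("spectra", {})

    try:
        # ------------------------------------------------ generate / ingest
        t0 = time.perf_counter()
        if syn is not None and (_stage("generate") or _stage("monitor") or
                                _stage("samplesize") or _stage("compare")):
            spec = _build_spec(syn, stage_seeds.get("generate", config.seed))
            gseed = stage_seeds.get("generate", config.seed)
            cal, _ = synth.generate_healthy(spec, int(syn.get("n_cal", 150)), seed=gseed)
            test_sets = []
            for k, eff in enumerate(_effects(syn)):
                pset, truth = synth.apply_pollution(
                    spec, [eff], int(syn.get("n_test", 30)), seed=gseed + 1 + k
                )
                test_sets.append((eff.kind, pset, truth))
            if _stage("generate"):
                p = out / "calibration.csv"
                write_spectra(cal, p, "wide")
                artifacts["calibration_csv"] = str(p)
                for kind, pset, _ in test_sets:
                    p = out / f"test_{kind}.csv"
                    write_spectra(pset, p, "wide")
                    artifacts[f"test_{kind}_csv"] = str(p)
        elif "cal_path" in spectra_cfg:
            cal = read_spectra(
                spectra_cfg["cal_path"],
                spectra_cfg.get("dialect", "wide"),
                spectra_cfg.get("modality", "raman"),
            )
            test_sets = []
            if "test_path" in spectra_cfg:
                tset = read_spectra(
                    spectra_cfg["test_path"],
                    spectra_cfg.get("dialect", "wide"),
                    spectra_cfg.get("modality", "raman"),
                )
                test_sets.append(("test", tset, None))
        timings["generate"] = time.perf_counter() - t0

        # ------------------------------------------------ pretreat
        if _stage("pretreat"):
            t0 = time.perf_counter()
            if cal is None:
                raise ConfigError("pretreat stage needs a spectra source")
            steps = cfg.get("pretreatment", {}).get(cal.modality)
            pcfg = (
                pretreat.PretreatConfig([(s["name"], s.get("params", {})) for s in steps])
                if steps
                else None
            )
            cal, plog = pretreat.run_pretreatment(cal, pcfg)
            new_tests = []
            for kind, pset, truth in test_sets or []:
                pset, _ = pretreat.run_pretreatment(pset, pcfg)
                new_tests.append((kind, pset, truth))
            test_sets = new_tests
            p = out / "pretreatment_log.csv"
            pd.DataFrame(plog).to_csv(p, index=False)
            artifacts["pretreatment_log"] = str(p)
            timings["pretreat"] = time.perf_counter() - t0

        # ------------------------------------------------ samplesize
        if _stage("samplesize"):
            t0 = time.perf_counter()
            if cal is None:
                raise ConfigError("samplesize stage needs a spectra source")
            ss = cfg.get("samplesize", {})
            curve = sampling.variation_vs_n(
                cal,
                n_components=int(ss.get("n_components", 3)),
                repeats=int(ss.get("repeats", 20)),
                seed=stage_seeds["samplesize"],
            )
            rec = sampling.recommend_n(curve, int(ss.get("w", 5)), float(ss.get("tau", 0.02)))
            vario = sampling.variogram_scores(cal, int(ss.get("n_components", 3)))
            p = out / "variation_curve.csv"
            pd.DataFrame(
                {"n": curve.n_values, "var_raw": curve.var_raw,
                 "var_reconstructed": curve.var_reconstructed}
            ).to_csv(p, index=False)
            artifacts["variation_curve"] = str(p)
            p = out / "variogram.csv"
            pd.DataFrame(
                {"lag": vario.lags, "gamma": vario.gamma, "count": vario.counts}
            ).to_csv(p, index=False)
            artifacts["variogram"] = str(p)
            summary["n_required"] = rec.n_required
            summary["samplesize_converged"] = rec.converged
            timings["samplesize"] = time.perf_counter() - t0

        # ------------------------------------------------ monitor (Scenario A)
        if _stage("monitor"):
            t0 = time.perf_counter()
            if cal is None or not test_sets:
                raise ConfigError("monitor stage needs calibration and test spectra")
            mcfg = _monitor_config(cfg)
            log_scale = cfg.get("charts", {}).get("log_scale", True)
            monitor = mspc.PCAMonitor(mcfg.n_components, mcfg.ev_threshold, mcfg.eps).fit(cal)
            rows = []
            for kind, pset, _ in test_sets:
                rep = mspc.monitor_scenario_a(cal, pset, mcfg, monitor=monitor)
                for chart in (rep.t2_chart, rep.spex_chart):
                    p = out / f"chart_{kind}_{chart.statistic}.csv"
                    _chart_frame(chart).to_csv(p, index=False)
                    artifacts[f"chart_{kind}_{chart.statistic}"] = str(p)
                    pimg = out / f"chart_{kind}_{chart.statistic}.png"
                    _plot_chart(chart, pimg, log_scale)
                    artifacts[f"chart_{kind}_{chart.statistic}_png"] = str(pimg)
                rows.append(rep.summary | {"test_set": kind})
            p = out / "monitoring_summary.csv"
            pd.DataFrame(rows).to_csv(p, index=False)
            artifacts["monitoring_summary"] = str(p)
            summary["monitoring"] = rows
            timings["monitor"] = time.perf_counter() - t0

        # ------------------------------------------------ compare (Scenario B)
        if _stage("compare"):
            t0 = time.perf_counter()
            if cal is None or not test_sets:
                raise ConfigError("compare stage needs two spectra sets")
            mcfg = _monitor_config(cfg)
            kind, pset, _ = test_sets[0]
            diff = mspc.compare_scenario_b(cal, pset, mcfg)
            p = out / "loading_differences.csv"
            cols = {"wavenumber": cal.axis, "mean_difference": diff.mean_difference}
            for (i, j, c), d in zip(diff.pairs, diff.loading_diffs):
                cols[f"pair_h{i}_p{j}_cos{c:.3f}"] = d
            pd.DataFrame(cols).to_csv(p, index=False)
            artifacts["loading_differences"] = str(p)
            timings["compare"] = time.perf_counter() - t0

        # ------------------------------------------------ colorimetry
        if _stage("colorimetry"):
            t0 = time.perf_counter()
            ccfg = cfg.get("colorimetry", {})
            csyn = ccfg.get("synthetic")
            if csyn is None:
                raise ConfigError("only synthetic colorimetry sources are configured here")
            cseed = stage_seeds["colorimetry"]
            rng = np.random.default_rng(cseed)
            g = float(csyn.get("cast_gain", 0.2))
            cast = np.hstack(
                [np.diag(1 + rng.uniform(-g, g, 3)), rng.uniform(-0.03, 0.03, 3)[:, None]]
            )
            reports = {}
            for name, spot in (("control", 0.0), ("treated", float(csyn.get("spot_fraction", 0.5)))):
                img, truth = synth.generate_leaf_image(
                    n_leaves=int(csyn.get("n_leaves", 8)),
                    spot_fraction=spot,
                    spot_offset=tuple(csyn.get("spot_offset", (40, 40, 0))),
                    cast=cast,
                    seed=cseed + (0 if name == "control" else 1),
                )
                p = out / f"leaves_{name}.png"
                lc.save_image(img, p)
                artifacts[f"image_{name}"] = str(p)
                model = lc.fit_color_correction(lc.extract_patches(img, truth.layout))
                corr = lc.apply_color_correction(img, model)
                labels = lc.segment_leaves(corr, exclude=truth.chart_mask)
                rep = lc.summarize_leaf_colors(corr, labels)
                reports[name] = rep
                p = out / f"leaf_colors_{name}.csv"
                pd.DataFrame(
                    [
                        {
                            "label": r.label, "pixel_count": r.pixel_count,
                            "meanR": r.mean_rgb[0], "meanG": r.mean_rgb[1],
                            "meanB": r.mean_rgb[2], "stdR": r.std_rgb[0],
                            "stdG": r.std_rgb[1], "stdB": r.std_rgb[2],
                            "cx": r.centroid[0], "cy": r.centroid[1],
                        }
                        for r in rep.leaves
                    ]
                ).to_csv(p, index=False)
                artifacts[f"leaf_colors_{name}"] = str(p)
            comp = lc.compare_color_groups(reports["control"], reports["treated"])
            summary["colorimetry"] = comp
            timings["colorimetry"] = time.perf_counter() - t0
    except ConfigError:
        raise
    except Exception as exc:
        raise RuntimeError(f"stage failure: {exc}") from exc

    manifest = RunManifest(
        config_digest=config.digest(),
        version=_version(),
        seed=config.seed,
        stage_seeds=stage_seeds,
        timings_s={k: round(v, 4) for k, v in timings.items()},
        artifacts=artifacts,
        summary=summary,
    )
    manifest.save(out / "manifest.json")
    return manifest


def _version() -> str:
    from . import __version__

    return __version__


def render_report(manifest: RunManifest, path: str | Path | None = None) -> str:
    """Single markdown summary of a run: signalling percentages, common
    peaks with direction, sample-size recommendation, color comparison."""
    lines = ["# leafspec run report", ""]
    lines.append(f"config digest: `{manifest.config_digest}`  ")
    lines.append(f"seed: {manifest.seed}")
    lines.append("")
    mon = manifest.summary.get("monitoring")
    if mon:
        lines.append("## Scenario A monitoring")
        lines.append("")
        lines.append("| test set | method | T2 up [%] | SPEx up [%] | common peaks |")
        lines.append("|---|---|---|---|---|")
        any_flag = False
        for row in mon:
            peaks = ", ".join(row.get("common_peaks", [])) or "-"
            lines.append(
                f"| {row.get('test_set', '?')} | {row.get('method', '?')} | "
                f"{row.get('t2_up_pct', 0):.1f} | {row.get('spex_up_pct', 0):.1f} | {peaks} |"
            )
            any_flag = any_flag or row.get("t2_up_pct", 0) > 0 or row.get("spex_up_pct", 0) > 0
        if not any_flag:
            lines.append("")
            lines.append("no samples flagged")
        lines.append("")
    if "n_required" in manifest.summary:
        conv = "" if manifest.summary.get("samplesize_converged", True) else " (not converged)"
        lines.append("## Sample-size recommendation")
        lines.append("")
        lines.append(f"recommended calibration samples: **{manifest.summary['n_required']}**{conv}")
        lines.append("")
    col = manifest.summary.get("colorimetry")
    if col:
        lines.append("## Colorimetry")
        lines.append("")
        lines.append(f"between-group mean color distance: {col['between_distance']:.2f}")
        lines.append(f"dispersion ratio (treated / control): {col['dispersion_ratio']:.2f}")
        lines.append("")
    if manifest.artifacts:
        lines.append("## Artifacts")
        lines.append("")
        for k, v in sorted(manifest.artifacts.items()):
            if not Path(v).exists():
                raise FileNotFoundError(f"manifest artifact missing: {v}")
            lines.append(f"- {k}: `{v}`")
        lines.append("")
    text = "\n".join(lines)
    if path is not None:
        Path(path).write_text(text)
    return text
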