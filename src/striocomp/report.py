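"""Assemble per-run tables and figures (volumetry, histograms, zones).

Figures are convenience artifacts; every number a downstream consumer might
quote is written to a CSV first, and the figures are rendered from those
same tables.  Given identical stage outputs the tables are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .io_core import AnalysisConfig


@dataclass
class RunReport:
    out_dir: Path
    tables: dict[str, Path] = field(default_factory=dict)
    figures: dict[str, Path] = field(default_factory=dict)
    config: dict = field(default_factory=dict)


def _require(name: str, obj) -> None:
    if obj is None:
        raise ValueError(f"missing stage output: {name}")


def build_report(
    out_dir: str | Path,
    config: AnalysisConfig,
    volumetry: pd.DataFrame | None = None,
    histograms_case: pd.DataFrame | None = None,
    histograms_control: pd.DataFrame | None = None,
    zone_table: pd.DataFrame | None = None,
    family_results: dict | None = None,
    seed: int | None = None,
) -> RunReport:
    """Write the run's tables (CSV) and figures (PNG) to ``out_dir``.

    Only the sections whose stage outputs are provided are rendered; the
    volumetry table is obligatory.
    """
    _require("volumetry", volumetry)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report = RunReport(out_dir=out_dir, config=config.to_dict())
    if seed is not None:
        report.config["rng_seed"] = seed

    vol_sorted = volumetry.sort_values(
        [c for c in ("subject_id", "nucleus", "threshold") if c in volumetry.columns]
    ).reset_index(drop=True)
    path = out_dir / "volumetry.csv"
    vol_sorted.to_csv(path, index=False)
    report.tables["volumetry"] = path

    fig, ax = plt.subplots(figsize=(6, 4))
    summary = vol_sorted.groupby(["nucleus", "threshold"])[
        ["matrix_like", "striosome_like"]
    ].mean()
    summary.plot.bar(ax=ax, color=["tab:blue", "tab:red"])
    ax.set_ylabel("mean voxels")
    ax.set_title("Compartment volumetry")
    fig.tight_layout()
    fig_path = out_dir / "volumetry.png"
    fig.savefig(fig_path, dpi=120)
    plt.close(fig)
    report.figures["volumetry"] = fig_path

    if histograms_case is not None and histograms_control is not None:
        hist = _histogram_overlay_table(histograms_case, histograms_control)
        path = out_dir / "histograms.csv"
        hist.to_csv(path, index=False)
        report.tables["histograms"] = path
        fig, ax = plt.subplots(figsize=(7, 4))
        for compartment, style in (("matrix", "-"), ("striosome", "--")):
            sub = hist[hist["compartment"] == compartment]
            if sub.empty:
                continue
            ax.plot(sub["bin_left"], sub["case_mean"], style, color="tab:orange",
                    label=f"{compartment} case")
            ax.plot(sub["bin_left"], sub["control_mean"], style, color="tab:green",
                    label=f"{compartment} control")
        ax.set_xlabel("connection probability (bin left edge)")
        ax.set_ylabel("mean voxels per bin")
        ax.legend(fontsize=8)
        ax.set_title("Biased-range probability histograms")
        fig.tight_layout()
        fig_path = out_dir / "histograms.png"
        fig.savefig(fig_path, dpi=120)
        plt.close(fig)
        report.figures["histograms"] = fig_path

    if zone_table is not None:
        zt = zone_table.sort_values("zone").reset_index(drop=True)
        path = out_dir / "zones.csv"
        zt.to_csv(path, index=False)
        report.tables["zones"] = path
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.bar(zt["zone"], zt["normalized_case_pct"], color="tab:orange")
        ax.axhline(100.0, color="tab:green", linestyle=":", label="control = 100%")
        ax.set_ylabel("normalized matrix-like volume (%)")
        ax.tick_params(axis="x", rotation=75, labelsize=7)
        ax.legend()
        fig.tight_layout()
        fig_path = out_dir / "zones.png"
        fig.savefig(fig_path, dpi=120)
        plt.close(fig)
        report.figures["zones"] = fig_path

    if family_results is not None:
        rows = []
        for fam_id, fam in sorted(family_results.items()):
            table = fam.results.assign(family=fam_id, bh_threshold=fam.threshold)
            rows.append(table)
        path = out_dir / "test_families.csv"
        pd.concat(rows, ignore_index=True).to_csv(path, index=False)
        report.tables["test_families"] = path

    pd.Series(report.config, dtype=object).to_csv(out_dir / "resolved_config.csv")
    report.tables["resolved_config"] = out_dir / "resolved_config.csv"
    return report


def _histogram_overlay_table(
    case: pd.DataFrame, control: pd.DataFrame
) -> pd.DataFrame:
    """Per-bin cohort means from long-form per-subject histogram tables."""
    for name, df in (("case", case), ("control", control)):
        missing = {"compartment", "bin_left", "count"} - set(df.columns)
        if missing:
            raise ValueError(f"{name} histogram table missing columns {sorted(missing)}")
    case_mean = (
        case.groupby(["compartment", "bin_left"])["count"].mean().rename("case_mean")
    )
    ctrl_mean = (
        control.groupby(["compartment", "bin_left"])["count"]
        .mean()
        .rename("control_mean")
    )
    merged = pd.concat([case_mean, ctrl_mean], axis=1).reset_index()
    merged["delta"] = merged["case_mean"] - merged["control_mean"]
    return merged.sort_values(["compartment", "bin_left"]).reset_index(drop=True)
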