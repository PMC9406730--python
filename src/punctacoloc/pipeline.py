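"""End-to-end orchestration: read -> quantify -> statistics -> tables.

Runs are driven by a YAML config that round-trips losslessly, so the run
manifest written next to each quant table is sufficient to reproduce the
identical analysis.  Exit-code policy for the CLI: 0 clean, 2 partial
per-sample failures, 1 fatal.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .coloc import HemisphereQuant, QuantConfig, quantify_hemisphere
from .io import (
    QUANT_COLUMNS,
    Calibration,
    read_hemisphere,
    read_sample_sheet,
    write_quant_table,
)
from .segmentation import ThresholdSpec
from .stats import (
    ALPHA_DEFAULT,
    StatReport,
    kruskal_wallis,
    mann_whitney,
    one_way_anova,
    summarize_groups,
    two_way_anova,
)

__all__ = ["RunConfig", "run_quantify", "run_stats", "stats_report_rows"]

logger = logging.getLogger(__name__)

STATS_COLUMNS = (
    "response", "test", "term", "group_a", "group_b",
    "statistic", "df1", "df2", "p", "p_adj", "n_dropped",
)


@dataclass(frozen=True)
class RunConfig:
    """Full pipeline configuration; serializes to/from YAML losslessly."""

    calibration: Calibration = field(default_factory=Calibration)
    threshold: ThresholdSpec = field(default_factory=ThresholdSpec)
    min_area_px: int = 100
    connectivity: int = 8
    segmentation_mode: str = "2d"
    tau_overlap: float = 0.1
    positivity_rule: str = "mask_overlap"
    alpha: float = ALPHA_DEFAULT
    posthoc: str = "bonferroni"
    ss_type: int = 2
    log_level: str = "INFO"

    def quant_config(self) -> QuantConfig:
        return QuantConfig(
            threshold=self.threshold,
            min_area_px=self.min_area_px,
            connectivity=self.connectivity,
            tau_overlap=self.tau_overlap,
            positivity_rule=self.positivity_rule,  # type: ignore[arg-type]
        )

    def to_dict(self) -> dict:
        return {
            "calibration": dataclasses.asdict(self.calibration),
            "threshold": dataclasses.asdict(self.threshold),
            "segmentation": {
                "min_area_px": self.min_area_px,
                "connectivity": self.connectivity,
                "mode": self.segmentation_mode,
            },
            "coloc": {
                "tau_overlap": self.tau_overlap,
                "positivity_rule": self.positivity_rule,
            },
            "stats": {"alpha": self.alpha, "posthoc": self.posthoc, "ss_type": self.ss_type},
            "log_level": self.log_level,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        cal = d.get("calibration", {})
        thr = d.get("threshold", {})
        seg = d.get("segmentation", {})
        col = d.get("coloc", {})
        st = d.get("stats", {})
        return cls(
            calibration=Calibration(**cal) if not isinstance(cal, Calibration) else cal,
            threshold=ThresholdSpec(**thr) if not isinstance(thr, ThresholdSpec) else thr,
            min_area_px=int(seg.get("min_area_px", 100)),
            connectivity=int(seg.get("connectivity", 8)),
            segmentation_mode=str(seg.get("mode", "2d")),
            tau_overlap=float(col.get("tau_overlap", 0.1)),
            positivity_rule=str(col.get("positivity_rule", "mask_overlap")),
            alpha=float(st.get("alpha", ALPHA_DEFAULT)),
            posthoc=str(st.get("posthoc", "bonferroni")),
            ss_type=int(st.get("ss_type", 2)),
            log_level=str(d.get("log_level", "INFO")),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def run_quantify(
    samples_path: str | Path,
    config: RunConfig,
    outdir: str | Path,
) -> tuple[pd.DataFrame, list[str]]:
    """Quantify every sample in a sheet; returns (table, failed sample ids).

    Per-sample failures are logged and skipped; zero successes is fatal.
    Writes ``quant.csv`` and a machine-readable ``manifest.json`` (config
    echo, software version, per-sample thresholds) into ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = read_sample_sheet(samples_path)
    if not records:
        raise ValueError(f"sample sheet {samples_path} has no rows")

    qconfig = config.quant_config()
    rows: list[HemisphereQuant] = []
    failures: list[str] = []
    for rec in records:
        sid = rec["sample_id"]
        try:
            sample = read_hemisphere(rec["path"], rec, config.calibration)
            quant = quantify_hemisphere(sample, qconfig)
            logger.info(
                "sample %s: thresholds GFP=%.6g mCherry=%.6g, %d GFP / %d mCherry punctae",
                sid, quant.gfp_threshold, quant.mcherry_threshold,
                quant.n_gfp_punctae, quant.n_mcherry_punctae,
            )
            rows.append(quant)
        except Exception as exc:
            logger.error("sample %s failed: %s", sid, exc)
            failures.append(str(sid))
    if not rows:
        raise RuntimeError("no sample could be quantified")

    quant_path = outdir / "quant.csv"
    write_quant_table(rows, quant_path)
    manifest = {
        "software": {"name": "punctacoloc", "version": __version__},
        "config": config.to_dict(),
        "samples_sheet": str(samples_path),
        "n_samples": len(records),
        "n_quantified": len(rows),
        "failed_samples": failures,
        "thresholds": {
            r.sample_id: {"gfp": r.gfp_threshold, "mcherry": r.mcherry_threshold}
            for r in rows
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return pd.read_csv(quant_path, float_precision="round_trip"), failures


def stats_report_rows(report: StatReport) -> list[dict]:
    """Flatten a StatReport into stats-table rows (one per term/pair)."""
    rows = []
    for term, p in report.p_values.items():
        stat_key = next(
            (k for k in report.statistics if k.endswith(term) or k == term),
            next(iter(report.statistics)),
        )
        df = report.df.get(term, ())
        rows.append({
            "response": report.response, "test": report.test, "term": term,
            "group_a": "", "group_b": "",
            "statistic": report.statistics[stat_key],
            "df1": df[0] if len(df) > 0 else None,
            "df2": df[1] if len(df) > 1 else None,
            "p": p, "p_adj": None, "n_dropped": report.n_dropped,
        })
    if report.posthoc is not None:
        for _, pr in report.posthoc.iterrows():
            rows.append({
                "response": report.response, "test": report.test, "term": "posthoc",
                "group_a": pr["group_a"], "group_b": pr["group_b"],
                "statistic": pr["statistic"], "df1": None, "df2": None,
                "p": pr["p_raw"], "p_adj": pr["p_adj"], "n_dropped": report.n_dropped,
            })
    return rows


def run_stats(
    quant: str | Path | pd.DataFrame,
    config: RunConfig,
    plan: Sequence[Mapping],
    outdir: str | Path | None = None,
) -> pd.DataFrame:
    """Run the planned tests against a quant table.

    Each plan entry is a mapping with keys ``response``, ``test`` (anova2 |
    anova1 | kruskal_wallis | mann_whitney) and ``factors`` (one factor
    name, or two for anova2).
    """
    table = (
        quant if isinstance(quant, pd.DataFrame)
        else pd.read_csv(quant, float_precision="round_trip")
    )
    all_rows: list[dict] = []
    for entry in plan:
        response = entry["response"]
        test = entry["test"]
        factors = entry["factors"]
        if isinstance(factors, str):
            factors = [factors]
        if response not in table.columns:
            raise ValueError(f"planned response {response!r} not in quant table")
        for fac in factors:
            if fac not in table.columns:
                raise ValueError(f"planned factor {fac!r} not in quant table")

        if test == "anova2":
            if len(factors) != 2:
                raise ValueError("anova2 requires exactly 2 factors")
            report = two_way_anova(
                table, response, factors[0], factors[1],
                alpha=config.alpha, ss_type=config.ss_type,
            )
        elif test == "anova1":
            report = one_way_anova(
                table, response, factors[0], alpha=config.alpha, posthoc=config.posthoc,
            )
        elif test == "kruskal_wallis":
            report = kruskal_wallis(
                table, response, factors[0], alpha=config.alpha, posthoc=config.posthoc,
            )
        elif test == "mann_whitney":
            sub = table.dropna(subset=[response])
            levels = sorted(sub[factors[0]].unique())
            if len(levels) != 2:
                raise ValueError(
                    f"mann_whitney requires exactly 2 groups, factor {factors[0]!r} "
                    f"has {len(levels)}"
                )
            x = sub.loc[sub[factors[0]] == levels[0], response].to_numpy(dtype=float)
            y = sub.loc[sub[factors[0]] == levels[1], response].to_numpy(dtype=float)
            report = mann_whitney(x, y)
            report.response = response
            report.n_dropped = len(table) - len(sub)
            report.group_summaries = summarize_groups(sub, response, factors[0])
        else:
            raise ValueError(f"unknown test {test!r}")
        all_rows.extend(stats_report_rows(report))

    out = pd.DataFrame(all_rows, columns=list(STATS_COLUMNS))
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        out.to_csv(outdir / "stats.csv", index=False)
    return out
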