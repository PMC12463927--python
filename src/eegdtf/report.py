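"""Result presentation and pipeline orchestration.

Significant electrodes are grouped by scalp lobe and direction of the group
difference; significant directed edges are labelled by their region pair
and an anterior-posterior orientation:

* **bottom-up** — source posterior to target in the order
  occipital < parietal < central < temporal < frontal;
* **top-down** — source anterior to target;
* **within-region** — same region.

The temporal electrodes (T7/T8) sit laterally rather than on the
anterior-posterior axis; they are ranked between central and frontal, and
any edge touching them is additionally flagged ``lateral``.

:func:`run_pipeline` executes the full chain — synthetic (or on-disk) input
-> preprocessing -> band power -> connectivity -> statistics -> summaries —
from a validated configuration mapping and writes all tables plus a
machine-readable ``summary.json``.
"""

from __future__ import annotations

import json
import time
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from . import io as _io
from .connectivity import cohort_connectivity_table, rank_index
from .montage import MontageSpec, REGIONS, default_montage
from .spectral import DEFAULT_BANDS, Band, cohort_band_table
from .stats import compare_groups, correlate_edges_with_score
from .synthetic import BandEffect, CohortSpec, Coupling, generate_cohorts

__all__ = [
    "map_region",
    "classify_orientation",
    "summarize_electrodes",
    "summarize_edges",
    "ConfigError",
    "load_config",
    "run_pipeline",
]

#: Posterior-to-anterior rank used for edge orientation.
_ORIENTATION_RANK = {
    "occipital": 0, "parietal": 1, "central": 2, "temporal": 3, "frontal": 4,
}


def map_region(electrode: str, montage: Optional[MontageSpec] = None) -> str:
    """Scalp region of an electrode under the (default) montage."""
    montage = montage or default_montage()
    return montage.region(electrode)


def classify_orientation(source_region: str, target_region: str) -> str:
    """bottom-up / top-down / within-region for a directed region pair."""
    for r in (source_region, target_region):
        if r not in _ORIENTATION_RANK:
            raise ValueError(f"unknown region {r!r}")
    s, t = _ORIENTATION_RANK[source_region], _ORIENTATION_RANK[target_region]
    if s < t:
        return "bottom-up"
    if s > t:
        return "top-down"
    return "within-region"


def summarize_electrodes(
    comparisons: pd.DataFrame,
    montage: Optional[MontageSpec] = None,
    fdr_alpha: float = 0.05,
) -> pd.DataFrame:
    """Lobe-grouped counts of significant electrodes per band x direction.

    One row per band x direction x region with the electrode count and the
    ';'-joined electrode list (regions with zero significant electrodes get
    a zero-count row so totals are easy to audit).
    """
    montage = montage or default_montage()
    sig = comparisons[comparisons["q"] < fdr_alpha]
    rows: List[dict] = []
    for (band, direction), sub in sig.groupby(["band", "direction"], sort=True):
        by_region: Dict[str, List[str]] = {r: [] for r in REGIONS}
        for el in sorted(sub["electrode"]):
            by_region[montage.region(el)].append(el)
        for region in REGIONS:
            els = by_region[region]
            rows.append({
                "band": band, "direction": direction, "region": region,
                "count": len(els), "electrodes": ";".join(els),
            })
    return pd.DataFrame(rows, columns=["band", "direction", "region", "count", "electrodes"])


def summarize_edges(
    comparisons: pd.DataFrame,
    montage: Optional[MontageSpec] = None,
    fdr_alpha: float = 0.05,
) -> pd.DataFrame:
    """Significant directed edges labelled by region pair and orientation."""
    montage = montage or default_montage()
    sig = comparisons[comparisons["q"] < fdr_alpha]
    rows: List[dict] = []
    for _, row in sig.sort_values(["band", "source", "target"]).iterrows():
        sreg = montage.region(row["source"])
        treg = montage.region(row["target"])
        rows.append({
            "band": row["band"],
            "source": row["source"], "target": row["target"],
            "source_region": sreg, "target_region": treg,
            "orientation": classify_orientation(sreg, treg),
            "lateral": sreg == "temporal" or treg == "temporal",
            "direction": row["direction"],
            "effect": row["effect"], "effect_type": row["effect_type"],
            "q": row["q"],
        })
    return pd.DataFrame(rows, columns=[
        "band", "source", "target", "source_region", "target_region",
        "orientation", "lateral", "direction", "effect", "effect_type", "q",
    ])


# ---------------------------------------------------------------------------
# Configuration


class ConfigError(ValueError):
    """Invalid pipeline configuration; the message names the field."""


DEFAULT_CONFIG: Dict[str, dict] = {
    "seed": 0,
    "out_dir": "eegdtf_results",
    "input": {"dir": None},
    "cohort": {
        "n_per_group": 20,
        "duration_s": 300.0,
        "sample_rate_hz": 250.0,
        "noise_sd": 1.0,
        "band_effects": [],
        "couplings": [],
        "moca": {"NC": [26.70, 1.38], "MCI": [19.91, 2.98]},
        "moca_link_slope": None,
        "coupling_scale_sd": 0.0,
    },
    "preprocess": {"lo_hz": 1.0, "hi_hz": 30.0, "epoch_s": 5.0},
    "welch": {"segment_s": 2.0, "overlap": 0.5, "window": "hamming"},
    "connectivity": {
        "order": 2,
        "surrogates": 1000,
        "alpha": 0.05,
        "grid_hz": 0.5,
        "bands": ["delta", "theta", "alpha"],
    },
    "stats": {"alpha": 0.05, "fdr_alpha": 0.05},
}


def _merge(defaults: dict, user: dict, path: str = "") -> dict:
    out = dict(defaults)
    for key, val in user.items():
        full = f"{path}{key}"
        if key not in defaults:
            raise ConfigError(f"{full}: unknown field")
        if isinstance(defaults[key], dict) and not isinstance(val, dict):
            raise ConfigError(f"{full}: expected a mapping")
        if isinstance(defaults[key], dict) and key != "moca":
            out[key] = _merge(defaults[key], val, path=f"{full}.")
        else:
            out[key] = val
    return out


def load_config(source: Union[str, Path, dict, None]) -> dict:
    """Merge a YAML file or mapping over the defaults and validate it."""
    if source is None:
        user: dict = {}
    elif isinstance(source, dict):
        user = source
    else:
        user = yaml.safe_load(Path(source).read_text()) or {}
    cfg = _merge(DEFAULT_CONFIG, user)
    c = cfg["cohort"]
    if c["n_per_group"] < 1:
        raise ConfigError("cohort.n_per_group: must be >= 1")
    if c["duration_s"] <= 0:
        raise ConfigError("cohort.duration_s: must be > 0")
    if not 0 < cfg["connectivity"]["alpha"] < 1:
        raise ConfigError("connectivity.alpha: must be in (0, 1)")
    if cfg["connectivity"]["surrogates"] < 20:
        raise ConfigError("connectivity.surrogates: must be >= 20")
    if cfg["connectivity"]["order"] != "auto" and int(cfg["connectivity"]["order"]) < 1:
        raise ConfigError("connectivity.order: must be >= 1 or 'auto'")
    if not 0 < cfg["preprocess"]["lo_hz"] < cfg["preprocess"]["hi_hz"]:
        raise ConfigError("preprocess.lo_hz/hi_hz: need 0 < lo < hi")
    return cfg


def _cohort_spec_from_config(cfg: dict) -> CohortSpec:
    c = cfg["cohort"]
    effects = [BandEffect(group=e["group"], band=e["band"],
                          electrodes=tuple(e["electrodes"]),
                          multiplier=float(e["multiplier"]))
               for e in c["band_effects"]]
    couplings = [Coupling(group=x["group"], source=x["source"], target=x["target"],
                          band=x["band"], strength=float(x["strength"]),
                          lag=int(x["lag"]))
                 for x in c["couplings"]]
    return CohortSpec(
        n_subjects_per_group=int(c["n_per_group"]),
        duration_s=float(c["duration_s"]),
        sample_rate_hz=float(c["sample_rate_hz"]),
        band_effects=effects,
        couplings=couplings,
        noise_sd=float(c["noise_sd"]),
        moca_mean_sd={g: tuple(v) for g, v in c["moca"].items()},
        moca_link_slope=c["moca_link_slope"],
        coupling_scale_sd=float(c["coupling_scale_sd"]),
        seed=int(cfg["seed"]),
    )


def _bands_from_names(names: Sequence[str]) -> Tuple[Band, ...]:
    by_name = {b.name: b for b in DEFAULT_BANDS}
    out = []
    for n in names:
        if n not in by_name:
            raise ConfigError(f"connectivity.bands: unknown band {n!r}")
        out.append(by_name[n])
    return tuple(out)


def run_pipeline(
    config: Union[str, Path, dict, None] = None,
    out_dir: Optional[Union[str, Path]] = None,
) -> Path:
    """Execute the full analysis and write all result tables.

    Outputs in the result directory: ``manifest.csv``, ``band_power.csv``,
    ``electrode_comparisons.csv``, ``connectivity.csv``,
    ``edge_comparisons.csv``, ``correlations.csv``, ``region_summary.csv``,
    ``edge_findings.csv``, ``summary.json`` and ``run_log.txt``.
    """
    cfg = load_config(config)
    out = Path(out_dir) if out_dir is not None else Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    log_lines: List[str] = []

    def log(msg: str) -> None:
        log_lines.append(f"[{time.strftime('%H:%M:%S')}] {msg}")

    seed = int(cfg["seed"])
    montage = default_montage()
    log(f"seed={seed}")
    conn_cfg = cfg["connectivity"]
    rank = rank_index(int(conn_cfg["surrogates"]), float(conn_cfg["alpha"]))
    log(f"surrogates={conn_cfg['surrogates']} alpha={conn_cfg['alpha']} "
        f"rank_index={rank}")

    if cfg["input"]["dir"]:
        recordings = _io.load_dir(cfg["input"]["dir"])
        manifest = pd.DataFrame(
            [{"subject_id": r.subject_id, "group": r.group, "moca": r.moca}
             for r in recordings]
        )
        log(f"loaded {len(recordings)} recordings from {cfg['input']['dir']}")
    else:
        spec = _cohort_spec_from_config(cfg)
        recordings, manifest = generate_cohorts(spec, montage)
        log(f"generated {len(recordings)} synthetic recordings "
            f"({spec.n_subjects_per_group} per group, {spec.duration_s:.0f}s "
            f"at {spec.sample_rate_hz:.0f}Hz)")
    manifest.to_csv(out / "manifest.csv", index=False)

    pp, we, st = cfg["preprocess"], cfg["welch"], cfg["stats"]
    bands = _bands_from_names(conn_cfg["bands"])

    band_table = cohort_band_table(
        recordings, bands=bands,
        segment_s=float(we["segment_s"]), overlap_frac=float(we["overlap"]),
        window=we["window"], lo=float(pp["lo_hz"]), hi=float(pp["hi_hz"]),
        epoch_length_s=float(pp["epoch_s"]),
    )
    band_table.to_csv(out / "band_power.csv", index=False)
    electrode_cmp = compare_groups(
        band_table, value_col="power", unit_cols="electrode",
        alpha=float(st["alpha"]), fdr_alpha=float(st["fdr_alpha"]),
    )
    electrode_cmp.to_csv(out / "electrode_comparisons.csv", index=False)
    log(f"band power: {len(band_table)} rows; "
        f"{int(electrode_cmp['significant'].sum())} significant electrode/band units")

    conn_table = cohort_connectivity_table(
        recordings, bands=bands, order=conn_cfg["order"],
        n_surrogates=int(conn_cfg["surrogates"]), alpha=float(conn_cfg["alpha"]),
        seed=seed, grid_step=float(conn_cfg["grid_hz"]),
        f_lo=float(pp["lo_hz"]), f_hi=float(pp["hi_hz"]),
        lo=float(pp["lo_hz"]), hi=float(pp["hi_hz"]),
        epoch_length_s=float(pp["epoch_s"]),
    )
    conn_table.to_csv(out / "connectivity.csv", index=False)
    edge_cmp = compare_groups(
        conn_table, value_col="value", unit_cols=["source", "target"],
        alpha=float(st["alpha"]), fdr_alpha=float(st["fdr_alpha"]),
    )
    edge_cmp.to_csv(out / "edge_comparisons.csv", index=False)
    log(f"connectivity: {len(conn_table)} edge rows; "
        f"{int(edge_cmp['significant'].sum())} significant edge/band units")

    sig_edges = [
        (r["band"], r["source"], r["target"])
        for _, r in edge_cmp[edge_cmp["significant"]].iterrows()
    ]
    correlations = correlate_edges_with_score(conn_table, edges=sig_edges or None)
    if sig_edges:
        correlations.to_csv(out / "correlations.csv", index=False)
    else:
        correlations.head(0).to_csv(out / "correlations.csv", index=False)
    log(f"correlations: {len(correlations) if sig_edges else 0} edge(s)")

    region_summary = summarize_electrodes(electrode_cmp, montage,
                                          fdr_alpha=float(st["fdr_alpha"]))
    edge_findings = summarize_edges(edge_cmp, montage,
                                    fdr_alpha=float(st["fdr_alpha"]))
    region_summary.to_csv(out / "region_summary.csv", index=False)
    edge_findings.to_csv(out / "edge_findings.csv", index=False)

    summary = {
        "seed": seed,
        "n_subjects": len(recordings),
        "surrogate_rank_index": rank,
        "significant_electrodes": {
            f"{row['band']}|{row['direction']}|{row['region']}": row["count"]
            for _, row in region_summary.iterrows() if row["count"] > 0
        },
        "significant_edges": [
            {k: row[k] for k in ("band", "source", "target", "orientation", "direction")}
            for _, row in edge_findings.iterrows()
        ],
        "correlations": (
            correlations.round(6).to_dict(orient="records") if sig_edges else []
        ),
        "config": {k: v for k, v in cfg.items() if k != "out_dir"},
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    log("done")
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return out
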