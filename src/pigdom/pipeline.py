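"""End-to-end orchestration: events -> sociomatrices -> I&SI -> Elo ->
Glicko -> temporal dynamics -> statistical panel, with every stage's
outputs written to disk and a manifest of file hashes for determinism
audits."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import dynamics as dyn
from . import stats as st
from .elo import EloParams, elo_sequence, trajectories_frame
from .events import filter_and_merge_fights, summarize_dyadic
from .glicko import GlickoParams, glicko_hourly, histories_frame
from .io import Dataset, compute_adg, write_interactions
from .isi import isi_rank
from .sociomatrix import binarize, build_sociomatrix

__all__ = ["RunConfig", "run_all", "index_table"]


@dataclass(frozen=True)
class RunConfig:
    """Resolved settings for a full pipeline run; written beside the
    outputs so every run is self-describing."""

    seed: int = 0
    min_dur_s: float = 3.0
    merge_gap_s: float = 8.0
    elo: EloParams = field(default_factory=EloParams)
    glicko: GlickoParams = field(default_factory=GlickoParams)
    isi_restarts: int = 20
    stability_definition: str = "rank_fixation"
    plateau_eps: float = 10.0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RunConfig":
        d = dict(d)
        if "elo" in d and isinstance(d["elo"], Mapping):
            d["elo"] = EloParams(**d["elo"])
        if "glicko" in d and isinstance(d["glicko"], Mapping):
            d["glicko"] = GlickoParams(**d["glicko"])
        return cls(**d)


def _clean(obj):
    """JSON-safe structure: numpy scalars to python, NaN to None."""
    if isinstance(obj, dict):
        return {str(k): _clean(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_clean(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        x = float(obj)
        return x if math.isfinite(x) else None
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(_clean(obj), indent=2, sort_keys=True) + "\n")


def index_table(
    dataset: Dataset, config: RunConfig
) -> tuple[pd.DataFrame, dict[str, dict]]:
    """Per-animal hierarchy indices (isi_rank, elo, glicko) over all pens,
    plus the per-pen I&SI solutions."""
    rows: dict[str, dict] = {}
    isi_results: dict[str, dict] = {}
    for pen in dataset.pens:
        ids = [a.animal_id for a in dataset.animals_in_pen(pen)]
        recs = dataset.interactions_in_pen(pen)
        B = binarize(build_sociomatrix(recs, pen, ids))
        solution = isi_rank(B, seed=config.seed, n_restarts=config.isi_restarts)
        ranks = solution.ranks()
        elo = elo_sequence(dataset, pen, config.elo)
        glicko = glicko_hourly(dataset, pen, config.glicko)
        for aid in ids:
            rows[aid] = {
                "pen_id": pen,
                "isi_rank": ranks[aid],
                "elo": elo[aid].final_rating,
                "glicko": glicko[aid].rating,
            }
        isi_results[pen] = {
            "order": list(solution.order),
            "I": solution.I,
            "SI": solution.SI,
            "seed": solution.seed,
            "n_restarts_used": solution.n_restarts_used,
            "multiple_optima_flag": solution.multiple_optima,
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "animal_id"
    return table, isi_results


def run_all(dataset: Dataset, config: RunConfig, outdir) -> dict:
    """Run every stage on a validated dataset, writing all artefacts under
    ``outdir``; returns the stats report bundle.

    Written files: filtered interactions, per-animal dyadic summary,
    per-pen sociomatrices (raw and binary, TSV with id headers), I&SI
    solutions, Elo and Glicko trajectory tables, per-pen dynamics
    bundles, the stability table under both definitions, the stats
    report, the resolved config, and ``manifest.json`` with a sha256 per
    file.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write_json(config.to_dict(), outdir / "config.json")

    filtered = filter_and_merge_fights(
        dataset.interactions, config.min_dur_s, config.merge_gap_s
    )
    ds = dataset.with_interactions(filtered)
    write_interactions(ds.interactions, outdir / "interactions_filtered.csv")

    summary = summarize_dyadic(ds.interactions, ds.animals)
    summary.to_csv(outdir / "dyadic_summary.tsv", sep="\t")

    glicko_by_pen: dict[str, dict] = {}
    for pen in ds.pens:
        ids = [a.animal_id for a in ds.animals_in_pen(pen)]
        recs = ds.interactions_in_pen(pen)
        W = build_sociomatrix(recs, pen, ids)
        B = binarize(W)
        W.to_frame().to_csv(outdir / f"sociomatrix_{pen}.tsv", sep="\t")
        B.to_frame().to_csv(outdir / f"binary_{pen}.tsv", sep="\t")
        elo = elo_sequence(ds, pen, config.elo)
        trajectories_frame(elo.values()).to_csv(
            outdir / f"elo_{pen}.tsv", sep="\t", index=False
        )
        _write_json(
            {aid: t.final_rating for aid, t in elo.items()},
            outdir / f"elo_final_{pen}.json",
        )
        glicko = glicko_hourly(ds, pen, config.glicko)
        glicko_by_pen[pen] = glicko
        histories_frame(glicko.values()).to_csv(
            outdir / f"glicko_{pen}.tsv", sep="\t", index=False
        )

    indices, isi_results = index_table(ds, config)
    for pen, sol in isi_results.items():
        _write_json(sol, outdir / f"isi_{pen}.json")
    indices.to_csv(outdir / "indices.tsv", sep="\t")

    # temporal dynamics
    meta = {a.animal_id: a for a in ds.animals}
    stab_frames = []
    for definition in ("rank_fixation", "rating_plateau"):
        t = dyn.stability_table(glicko_by_pen, definition, config.plateau_eps)
        t["definition"] = definition
        stab_frames.append(t)
    stability = pd.concat(stab_frames, ignore_index=True)
    stability["sex"] = [meta[a].sex.value for a in stability["animal_id"]]
    stability = stability[["animal_id", "pen_id", "sex", "definition", "stability_h"]]
    stability.to_csv(outdir / "stability.tsv", sep="\t", index=False)

    for pen, states in glicko_by_pen.items():
        ranks = dyn.hourly_ranks(states)
        top, emergence_h = dyn.first_rank_emergence(ranks)
        corr = dyn.hourly_final_correlation(states)
        _write_json(
            {
                "pen_id": pen,
                "first_rank_animal": top,
                "first_rank_emergence_h": emergence_h,
                "hourly_final_correlation": corr.to_dict(orient="records"),
            },
            outdir / f"dynamics_{pen}.json",
        )

    report = _stats_report(ds, summary, indices, stability, config)
    _write_json(report, outdir / "stats_report.json")
    _stats_tsv(report, outdir / "stats_report.tsv")

    manifest = {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(outdir.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    _write_json(manifest, outdir / "manifest.json")
    return report


def _stats_report(
    ds: Dataset,
    summary: pd.DataFrame,
    indices: pd.DataFrame,
    stability: pd.DataFrame,
    config: RunConfig,
) -> dict:
    report: dict[str, Any] = {}

    corr = st.index_correlations(indices[["isi_rank", "elo", "glicko"]])
    report["index_correlations"] = corr.to_dict(orient="records")

    # partial correlations of each index with each behavior indicator,
    # the other five indicators as covariates
    partials = []
    for index_col in ("isi_rank", "elo", "glicko"):
        for indicator in st.BEHAVIOR_COVARIATES:
            others = [c for c in st.BEHAVIOR_COVARIATES if c != indicator]
            r, p = st.partial_correlation(
                indices[index_col].to_numpy(),
                summary.loc[indices.index, indicator].to_numpy(),
                summary.loc[indices.index, others],
            )
            partials.append(
                {"index": index_col, "indicator": indicator, "r": r, "p": p,
                 "covariates": others}
            )
    # covariate panel: backtest score, initial body weight, ADG, with the
    # six behavior indicators as covariates
    meta = {a.animal_id: a for a in ds.animals}
    extra = pd.DataFrame(
        {
            "backtest": [meta[a].backtest_mean for a in indices.index],
            "initial_bw_kg": [meta[a].initial_bw_kg for a in indices.index],
            "adg": [compute_adg(meta[a]) for a in indices.index],
        },
        index=indices.index,
    )
    for index_col in ("isi_rank", "elo", "glicko"):
        for indicator in extra.columns:
            mask = extra[indicator].notna()
            if mask.sum() > len(st.BEHAVIOR_COVARIATES) + 2:
                r, p = st.partial_correlation(
                    indices.loc[mask, index_col].to_numpy(),
                    extra.loc[mask, indicator].to_numpy(dtype=float),
                    summary.loc[indices.index[mask], st.BEHAVIOR_COVARIATES],
                )
            else:
                r, p = float("nan"), float("nan")
            partials.append(
                {"index": index_col, "indicator": indicator, "r": r, "p": p,
                 "covariates": st.BEHAVIOR_COVARIATES}
            )
    report["partial_correlations"] = partials

    regressions = {}
    joined = indices.join(summary)
    for index_col in ("isi_rank", "elo", "glicko"):
        fit = st.multiple_regression(joined, index_col)
        regressions[index_col] = {
            "n": fit.attrs["n"],
            "coefficients": fit.reset_index().to_dict(orient="records"),
        }
    report["regressions"] = regressions

    sexes = {a.sex.value for a in ds.animals}
    contrasts = {}
    if len(sexes) == 2:
        for definition in ("rank_fixation", "rating_plateau"):
            sub = stability[stability["definition"] == definition].copy()
            sub["parity"] = [meta[a].parity for a in sub["animal_id"]]
            sub["sire_id"] = [meta[a].sire_id for a in sub["animal_id"]]
            sub["initial_bw_kg"] = [meta[a].initial_bw_kg for a in sub["animal_id"]]
            res = st.sex_contrast(sub, with_covariates=True)
            contrasts[definition] = dataclasses.asdict(res)
    report["sex_contrast"] = contrasts
    return report


def _stats_tsv(report: dict, path: Path) -> None:
    """Flat TSV mirror of the stats report (one section per block)."""
    lines = ["section\tkey\tvalue"]
    for row in report["index_correlations"]:
        lines.append(
            f"index_correlation\t{row['index_a']}~{row['index_b']}\t"
            f"rho={row['rho']:.6g};p={row['p_value']:.6g}"
        )
    for row in report["partial_correlations"]:
        r = row["r"]
        p = row["p"]
        r_s = "NA" if r is None or not math.isfinite(r) else f"{r:.6g}"
        p_s = "NA" if p is None or not math.isfinite(p) else f"{p:.6g}"
        lines.append(
            f"partial_correlation\t{row['index']}~{row['indicator']}\tr={r_s};p={p_s}"
        )
    for resp, block in report["regressions"].items():
        for c in block["coefficients"]:
            lines.append(
                f"regression[{resp}]\t{c['covariate']}\t"
                f"B={c['B']:.6g};SE={c['SE']:.6g};t={c['t']:.6g};p={c['p']:.6g}"
            )
    for definition, c in report["sex_contrast"].items():
        lines.append(
            f"sex_contrast[{definition}]\tfemale_vs_barrow\t"
            f"female={c['mean_female']:.6g}±{c['se_female']:.6g};"
            f"barrow={c['mean_barrow']:.6g}±{c['se_barrow']:.6g};p={c['p_value']:.6g}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
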