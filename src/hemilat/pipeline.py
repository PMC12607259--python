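"""Orchestration: scheme -> connectivity -> LI tables -> cohort statistics.

Three entry points mirror the analysis stages and are also exposed by the
``hemilat`` command line:

* :func:`cmd_compute_li` — per-session connectivity and LI tables from a
  manifest of parcel time-series files;
* :func:`cmd_simulate` — synthetic three-arm longitudinal cohort on disk;
* :func:`cmd_analyze` — the inference battery on a long-format cohort
  table: baseline group comparisons, per-cell one-sample lateralization
  tests, the group-by-time mixed model on LI changes, and partial
  correlations between LI changes and behaviour changes with
  Benjamini-Hochberg correction over each declared family.

Every command writes a JSON manifest recording the seed, config hash and
input digests, so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import hemilat
from hemilat.connectivity import compute_fc, load_censor_mask, load_timeseries
from hemilat.lateralization import network_laterality, pair_table
from hemilat.parcellation import load_scheme
from hemilat.synthetic import AsymmetrySpec, BehaviourModel, CohortSpec, simulate_cohort
from hemilat import stats

__all__ = [
    "load_config",
    "cmd_compute_li",
    "cmd_simulate",
    "cmd_analyze",
    "li_deltas",
]


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ValueError("config must be a YAML mapping")
    return config


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _write_manifest(out_dir: Path, config: dict, inputs: dict, extra: dict) -> None:
    manifest = {
        "config_hash": _config_hash(config),
        "hemilat_version": hemilat.__version__,
        "inputs": inputs,
        **extra,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def cmd_compute_li(config: dict) -> pd.DataFrame:
    """Compute pair- and network-level LI tables for every manifest session.

    Config keys: ``scheme`` (scheme CSV), ``manifest`` (CSV with columns
    subject, time, path and optional censor_path), ``network``, ``out_dir``.
    Writes ``pair_li_<subject>_<time>.csv`` per session plus a combined
    ``network_li.csv`` and a manifest; returns the network-level table.
    """
    scheme_path = Path(config["scheme"])
    manifest_path = Path(config["manifest"])
    network = config.get("network", "FPN")
    out_dir = Path(config["out_dir"])
    scheme = load_scheme(scheme_path, one_based=bool(config.get("one_based", False)))
    sessions = pd.read_csv(manifest_path)
    for col in ("subject", "time", "path"):
        if col not in sessions.columns:
            raise ValueError(f"manifest is missing column {col!r}")
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    input_digests = {"scheme": _sha256(scheme_path), "manifest": _sha256(manifest_path)}
    written: list[Path] = []
    try:
        for _, sess in sessions.iterrows():
            ts_path = Path(sess["path"])
            data = load_timeseries(ts_path)
            mask = None
            if "censor_path" in sessions.columns and isinstance(sess.get("censor_path"), str):
                mask = load_censor_mask(sess["censor_path"])
            fc = compute_fc(data, mask)
            input_digests[str(ts_path)] = _sha256(ts_path)
            pairs = pair_table(fc, scheme)
            pair_path = out_dir / f"pair_li_{sess['subject']}_{sess['time']}.csv"
            pairs.to_csv(pair_path, index=False)
            written.append(pair_path)
            net = network_laterality(fc, scheme, network)
            rows.append(
                {
                    "subject": sess["subject"],
                    "time": sess["time"],
                    "network": network,
                    "li_he": net.li_he,
                    "li_intra": net.li_intra,
                    "n_pairs_used": net.n_pairs_used_he,
                    "n_pairs_excluded": net.n_pairs_excluded_he,
                    "mFC": hemilat.mean_whole_brain_fc(fc),
                }
            )
    except Exception as err:
        for path in written:
            path.unlink(missing_ok=True)
        raise RuntimeError(f"compute-li failed while processing sessions: {err}") from err
    table = pd.DataFrame(rows)
    table.to_csv(out_dir / "network_li.csv", index=False)
    _write_manifest(
        out_dir, config, input_digests,
        {"stage": "compute_li", "network": network, "n_sessions": len(table)},
    )
    return table


def _cohort_spec_from_config(config: dict, seed: int | None = None) -> CohortSpec:
    sim = dict(config.get("simulate", {}))
    asym_base = AsymmetrySpec(**sim.pop("asymmetry_base", {}))
    kwargs: dict = {"asymmetry_base": asym_base}
    if "asymmetry" in sim:
        kwargs["asymmetry"] = {
            (g, t): tuple(v) for (g, t), v in (
                ((k.split("/")[0], k.split("/")[1]), v) for k, v in sim.pop("asymmetry").items()
            )
        }
    if "behaviour" in sim:
        kwargs["behaviour"] = {
            name: BehaviourModel(**params) for name, params in sim.pop("behaviour").items()
        }
    kwargs.update(sim)
    if seed is not None:
        kwargs["seed"] = seed
    elif "seed" in config:
        kwargs.setdefault("seed", config["seed"])
    return CohortSpec(**kwargs)


def cmd_simulate(config: dict, seed: int | None = None) -> pd.DataFrame:
    """Generate a synthetic cohort on disk from the config's simulate block."""
    spec = _cohort_spec_from_config(config, seed)
    out_dir = Path(config["out_dir"])
    result = simulate_cohort(
        spec, out_dir=out_dir, keep_timeseries=bool(config.get("keep_timeseries", False))
    )
    _write_manifest(
        out_dir, config, {},
        {"stage": "simulate", "seed": spec.seed, "generator": result.manifest},
    )
    return result.table


def li_deltas(
    cohort: pd.DataFrame,
    baseline_time: str = "B0",
    value_cols: tuple[str, ...] = ("li_he", "li_intra"),
    carry_cols: tuple[str, ...] = ("group", "age", "sex", "education", "mFD", "mFC"),
    score_cols: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Within-subject change table: post-session minus baseline, per subject.

    One row per subject and post-baseline timepoint for subjects measured
    at both; ``value_cols`` and ``score_cols`` become ``d_<name>`` change
    columns. Session-level covariates (mFD, mFC) take their post-session
    values; constant demographics are carried through.
    """
    base = cohort[cohort["time"] == baseline_time].set_index("subject")
    rows = []
    for time in [t for t in cohort["time"].unique() if t != baseline_time]:
        for _, rec in cohort[cohort["time"] == time].iterrows():
            if rec["subject"] not in base.index:
                continue
            b = base.loc[rec["subject"]]
            row = {"subject": rec["subject"], "time": time}
            for col in carry_cols:
                row[col] = rec[col]
            for col in value_cols + tuple(score_cols):
                row[f"d_{col}"] = rec[col] - b[col]
            rows.append(row)
    return pd.DataFrame(rows)


def cmd_analyze(config: dict) -> dict:
    """Run the full inference battery on a long-format cohort table.

    Config keys (all optional except ``cohort`` and ``out_dir``):
    ``baseline_measures`` (columns compared CG vs TG and across all arms at
    baseline), ``li_outcomes`` (default li_he, li_intra),
    ``behaviour`` (score columns correlated with LI change; one FDR family
    per LI outcome), ``covariates`` (LMM and partial-correlation
    confounders), ``baseline_time`` / ``patient_groups``.
    Writes ``results.csv``, ``results.json`` and ``report.txt``.
    """
    cohort_path = Path(config["cohort"])
    out_dir = Path(config["out_dir"])
    cohort = pd.read_csv(cohort_path)
    baseline_time = config.get("baseline_time", "B0")
    li_outcomes = list(config.get("li_outcomes", ["li_he", "li_intra"]))
    behaviour = list(config.get("behaviour", []))
    covariates = list(config.get("covariates", ["age", "sex", "education", "mFD", "mFC"]))
    patient_groups = list(config.get("patient_groups", ["CG", "TG"]))
    baseline_measures = list(config.get("baseline_measures", []))
    alpha = float(config.get("alpha", 0.05))

    needed = {"subject", "group", "time", *li_outcomes}
    missing = sorted(needed - set(cohort.columns))
    if missing:
        raise ValueError(f"cohort table is missing declared columns: {missing}")

    records: list[dict] = []

    def add(section: str, name: str, res: stats.StatTestResult, family: str | None = None):
        df = res.df
        records.append(
            {
                "section": section,
                "name": name,
                "statistic": res.statistic,
                "df1": df[0] if isinstance(df, tuple) else df,
                "df2": df[1] if isinstance(df, tuple) else np.nan,
                "p": res.p,
                "effect_size": res.effect_size,
                "effect_kind": res.effect_kind,
                "method": res.method,
                "family": family,
            }
        )

    base = cohort[cohort["time"] == baseline_time]

    # baseline group comparisons (two-arm t, all-arm ANOVA)
    for measure in baseline_measures:
        arms = [base.loc[base["group"] == g, measure].dropna().to_numpy() for g in patient_groups]
        if all(len(a) >= 2 for a in arms) and len(arms) == 2:
            add("baseline", f"{measure}_{patient_groups[0]}_vs_{patient_groups[1]}",
                stats.pooled_t(arms[0], arms[1]))
        all_arms = [base.loc[base["group"] == g, measure].dropna().to_numpy()
                    for g in base["group"].unique()]
        if len(all_arms) > 2 and all(len(a) >= 2 for a in all_arms):
            add("baseline", f"{measure}_all_groups", stats.one_way_anova(all_arms))

    # per-cell lateralization pattern: one-sample t against 0, FDR over
    # the cells of each LI outcome
    for outcome in li_outcomes:
        cell_results = []
        for (group, time), chunk in cohort.groupby(["group", "time"], observed=True):
            vals = chunk[outcome].dropna().to_numpy()
            if len(vals) >= 2:
                cell_results.append((f"{outcome}_{group}_{time}", stats.one_sample_t(vals)))
        adj = stats.fdr_bh([r.p for _, r in cell_results])
        for (name, res), p_adj in zip(cell_results, adj):
            add("lateralization", name, res, family=f"one_sample_{outcome}")
            records[-1]["p_fdr"] = float(p_adj)

    # longitudinal: group-by-time LMM on within-subject LI changes
    patients = cohort[cohort["group"].isin(patient_groups)]
    deltas = li_deltas(
        patients, baseline_time=baseline_time,
        value_cols=tuple(li_outcomes), score_cols=tuple(behaviour),
    )
    lmm_results = {}
    if deltas["time"].nunique() >= 2:
        for outcome in li_outcomes:
            m = stats.fit_group_time_lmm(deltas, f"d_{outcome}", covariates)
            lmm_results[outcome] = m
            for term, res in m.tests.items():
                add("mixed_model", f"d_{outcome}_{term}", res)

    # brain-behaviour coupling: partial correlations of LI change with
    # behaviour change, one FDR family per (group, time, LI outcome)
    for outcome in li_outcomes:
        for group in patient_groups:
            for time in deltas["time"].unique():
                chunk = deltas[(deltas["group"] == group) & (deltas["time"] == time)]
                fam = f"partial_{outcome}_{group}_{time}"
                fam_results = []
                for score in behaviour:
                    sub = chunk.dropna(subset=[f"d_{outcome}", f"d_{score}"] + covariates)
                    if len(sub) <= len(covariates) + 3:
                        continue
                    res = stats.partial_correlation(
                        sub[f"d_{outcome}"].to_numpy(),
                        sub[f"d_{score}"].to_numpy(),
                        sub[covariates].to_numpy(),
                    )
                    fam_results.append((f"{fam}_{score}", res))
                adj = stats.fdr_bh([r.p for _, r in fam_results])
                for (name, res), p_adj in zip(fam_results, adj):
                    add("brain_behaviour", name, res, family=fam)
                    records[-1]["p_fdr"] = float(p_adj)

    results = pd.DataFrame(records)
    if "p_fdr" in results.columns:
        results["uncorrected_only"] = (results["p"] < alpha) & (results["p_fdr"] >= alpha)
    out_dir.mkdir(parents=True, exist_ok=True)
    results.to_csv(out_dir / "results.csv", index=False)
    payload = {
        "alpha": alpha,
        "n_sessions": len(cohort),
        "tests": results.to_dict(orient="records"),
    }
    (out_dir / "results.json").write_text(json.dumps(payload, indent=2, default=float))
    _write_report(out_dir / "report.txt", results, lmm_results, alpha)
    _write_manifest(
        out_dir, config, {"cohort": _sha256(cohort_path)},
        {"stage": "analyze", "n_tests": len(results)},
    )
    return {"results": results, "lmm": lmm_results}


def _write_report(path: Path, results: pd.DataFrame, lmm_results: dict, alpha: float) -> None:
    lines = ["hemilat analysis report", "=" * 40, ""]
    for section, chunk in results.groupby("section", sort=False):
        lines.append(f"[{section}]")
        for _, row in chunk.iterrows():
            df2 = "" if pd.isna(row["df2"]) else f", {row['df2']:.2f}"
            stat = f"{row['method']}: stat={row['statistic']:.3f} df=({row['df1']:.0f}{df2}) p={row['p']:.4f}"
            if "p_fdr" in row and not pd.isna(row.get("p_fdr", np.nan)):
                stat += f" p_fdr={row['p_fdr']:.4f}"
                if row.get("uncorrected_only"):
                    stat += " [uncorrected-only]"
            flag = " *" if row["p"] < alpha else ""
            lines.append(f"  {row['name']}: {stat}{flag}")
        lines.append("")
    for outcome, m in lmm_results.items():
        lines.append(
            f"LMM {outcome}: tau2={m.tau2:.5f} sigma2={m.sigma2:.5f} "
            f"n_obs={m.n_obs} n_subjects={m.n_subjects} df={m.df_method}"
        )
    path.write_text("\n".join(lines) + "\n")
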