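"""End-to-end orchestration: inputs -> COP indices -> ΔHbO -> connectivity
-> network AUC metrics -> group statistics -> report tables.

The pipeline consumes either a synthetic cohort (generated in-process from a
:class:`~swaynet.synthetic_cohort.CohortDesign`) or files on disk in the
layout written by :func:`~swaynet.synthetic_cohort.write_cohort`, and emits
the study's table set: per-participant COP metrics, per-participant network
AUCs, demographic tests, mixed-ANOVA tables with multiplicity control,
simple effects, and brain–behavior correlations, plus a reproducibility
manifest (config hash, seed, package versions).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import tempfile
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .fnirs_preprocess import PreprocessConfig, preprocess_recording, read_intensity_csv
from .group_stats import (SampleSummary, bonferroni, chi_square_2x2, fdr_bh,
                          mixed_anova_2x2, pearson_corr_test, pooled_t_test,
                          simple_effects)
from .network_topology import (SparsityGrid, min_connected_sparsity,
                               network_metrics)
from .posturography import aggregate_trials, cop_metrics, read_cop_csv
from .roi_connectivity import ROI_ORDER, connectivity_matrix, default_channel_map, roi_average
from .synthetic_cohort import CohortDataset, CohortDesign, generate_cohort

__all__ = ["RunConfig", "ReportBundle", "run_pipeline", "write_report",
           "load_cohort", "auc_table_tidy"]

log = logging.getLogger("swaynet")

GLOBAL_METRICS = ("sigma", "Eg", "Eloc")
NODAL_METRICS = tuple(f"Ne_{roi}" for roi in ROI_ORDER)
COP_METRICS = ("AREA", "ML_V", "AP_V", "V", "ML_RMS", "AP_RMS", "RMS")


@dataclass(frozen=True)
class RunConfig:
    mode: str = "synthetic"  # or "files"
    design: CohortDesign = field(default_factory=CohortDesign)
    input_dir: str | None = None  # files mode
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    sparsity_min: float | None = None  # None -> determined from the data
    sparsity_max: float = 0.50
    sparsity_step: float = 0.01
    #: participants whose FC cannot form a connected graph below this
    #: sparsity are excluded from the network stage (QC policy)
    sparsity_connect_cap: float = 0.40
    n_rand: int = 1000
    seed: int = 0
    alpha: float = 0.05

    def __post_init__(self):
        if self.mode not in ("synthetic", "files"):
            raise ValueError("mode must be 'synthetic' or 'files'")
        if self.mode == "files" and not self.input_dir:
            raise ValueError("files mode requires input_dir")


@dataclass
class ReportBundle:
    cop_table: pd.DataFrame
    network_table: pd.DataFrame | None
    demographics_table: pd.DataFrame
    demographic_tests: pd.DataFrame
    anova_tables: pd.DataFrame
    simple_effects_table: pd.DataFrame
    correlation_table: pd.DataFrame | None
    manifest: dict


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in sorted(obj.items(),
                                                        key=lambda kv: str(kv[0]))}
    if isinstance(obj, (list, tuple, set, frozenset, np.ndarray)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, (str, int, float, bool)) or obj is None:
        return obj
    return str(obj)


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(_jsonable(dataclasses.asdict(config)), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_cohort(indir) -> CohortDataset:
    """Read a cohort from the on-disk layout of ``write_cohort``."""
    indir = Path(indir)
    participants = pd.read_csv(indir / "participants.csv")
    manifest = pd.read_csv(indir / "manifest.csv")
    group_of = dict(zip(participants["participant"], participants["group"]))
    cop_trials: dict = {}
    fnirs: dict = {}
    for row in manifest.itertuples():
        path = indir / row.path
        if not path.exists():
            raise FileNotFoundError(f"manifest entry missing on disk: {path}")
        key = (row.participant, row.condition)
        if row.kind == "cop":
            trial = read_cop_csv(path, condition=row.condition,
                                 trial_index=int(row.trial),
                                 participant_id=row.participant)
            cop_trials.setdefault(key, []).append(trial)
        elif row.kind == "fnirs":
            fnirs[key] = read_intensity_csv(path)
    for key in cop_trials:
        fnirs.setdefault(key, None)
    # the generating design is unknown for file cohorts
    return CohortDataset(design=None, participants=participants,
                         cop_trials=cop_trials, fnirs=fnirs,
                         channel_map=default_channel_map())


def _stage(name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, *exc):
            log.info("stage %s: %.2f s", name, time.perf_counter() - self.t0)
    return _Timer()


def _anova_block(long: pd.DataFrame, measures, label: str) -> pd.DataFrame:
    rows = []
    for m in measures:
        sub = long[long["metric"] == m]
        try:
            tab = mixed_anova_2x2(sub)
        except Exception as err:
            raise RuntimeError(f"ANOVA failed for {label} metric {m}: {err}") from err
        for effect, r in tab.iterrows():
            rows.append({"family": label, "metric": m, "effect": effect,
                         "F": r["F"], "df1": int(r["df1"]), "df2": int(r["df2"]),
                         "p": r["p"], "eta_p_sq": r["eta_p_sq"]})
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute all stages; deterministic under ``config.seed``."""
    t_start = time.perf_counter()
    if config.mode == "synthetic":
        design = dataclasses.replace(config.design, master_seed=config.seed)
        with _stage("generate"):
            dataset = generate_cohort(design)
    else:
        with _stage("ingest"):
            dataset = load_cohort(config.input_dir)

    group_of = dict(zip(dataset.participants["participant"],
                        dataset.participants["group"]))

    with _stage("posturography"):
        cop_rows = []
        for (pid, cond), trials in sorted(dataset.cop_trials.items()):
            agg = aggregate_trials([cop_metrics(t) for t in trials])
            cop_rows.append({"participant": pid, "group": group_of[pid],
                             "condition": cond, **agg.as_dict()})
        cop_table = pd.DataFrame(cop_rows)

    have_fnirs = any(rec is not None for rec in dataset.fnirs.values())
    network_table = None
    fc_by_key = {}
    if have_fnirs:
        with _stage("preprocess+connectivity"):
            qc_flagged = 0
            for key, rec in sorted(dataset.fnirs.items()):
                if rec is None:
                    continue
                hemo = preprocess_recording(rec, config.preprocess)
                if hemo.artifact_mask is not None:
                    qc_flagged += int(hemo.artifact_mask.sum())
                roi = roi_average(hemo, dataset.channel_map)
                fc_by_key[key] = connectivity_matrix(roi)
            log.info("QC: %d artifact samples interpolated across cohort",
                     qc_flagged)
        with _stage("network"):
            keys = sorted(fc_by_key)
            # QC: a noisy matrix may not admit a connected graph below the
            # density ceiling; such participants are excluded (and logged)
            # rather than forcing an over-dense sweep on everyone
            s_req = {k: min_connected_sparsity([fc_by_key[k]],
                                               labels=[f"{k[0]}/{k[1]}"])
                     for k in keys}
            excluded = [k for k in keys
                        if s_req[k] > config.sparsity_connect_cap]
            keys = [k for k in keys if s_req[k] <= config.sparsity_connect_cap]
            if excluded:
                log.warning("network QC: excluded %d recording(s): %s",
                            len(excluded),
                            [f"{k[0]}/{k[1]}" for k in excluded])
            if not keys:
                raise RuntimeError("no recording passes the connectivity QC")
            if config.sparsity_min is None:
                s_min = max(s_req[k] for k in keys)
            else:
                s_min = config.sparsity_min
            grid = SparsityGrid(s_min=s_min, s_max=config.sparsity_max,
                                step=config.sparsity_step)
            ss = np.random.SeedSequence(entropy=(config.seed, 777))
            net_rows = []
            for key, child in zip(keys, ss.spawn(len(keys))):
                mset = network_metrics(fc_by_key[key], grid=grid,
                                       n_rand=config.n_rand, seed=child)
                pid, cond = key
                net_rows.append({"participant": pid, "group": group_of[pid],
                                 "condition": cond, **mset.as_dict()})
            network_table = pd.DataFrame(net_rows)
            network_table.attrs["sparsity_min"] = s_min
            network_table.attrs["qc_excluded"] = [
                f"{k[0]}/{k[1]}" for k in excluded]

    with _stage("statistics"):
        demo = dataset.participants
        demo_tests = []
        for col, label in (("age", "Age (years)"), ("height_cm", "Height (cm)"),
                           ("weight_kg", "Weight (kg)")):
            summaries = [
                SampleSummary(mean=float(sub[col].mean()),
                              sd=float(sub[col].std(ddof=1)), n=len(sub))
                for _, sub in demo.groupby("group", sort=False)]
            t, df, p = pooled_t_test(*summaries)
            demo_tests.append({"characteristic": label, "statistic": t,
                               "test": "t", "df": df, "p": p})
        groups = list(dict.fromkeys(demo["group"]))
        tbl = [[int(((demo["group"] == g) & (demo["sex"] == s)).sum())
                for s in ("M", "F")] for g in groups]
        try:
            chi2, df, p = chi_square_2x2(tbl)
        except ValueError:  # a sex absent from the whole sample
            chi2, df, p = float("nan"), 1, float("nan")
        demo_tests.append({"characteristic": "Male/female", "statistic": chi2,
                           "test": "chi2", "df": df, "p": p})
        demographic_tests = pd.DataFrame(demo_tests)

        cop_long = cop_table.melt(
            id_vars=["participant", "group", "condition"],
            value_vars=list(COP_METRICS), var_name="metric")
        anova = _anova_block(cop_long, COP_METRICS, "cop")
        if network_table is not None:
            # repeated-measures analyses need both conditions per person;
            # QC exclusions may have removed one
            n_cond = network_table.groupby("participant")["condition"].nunique()
            complete = n_cond[n_cond == 2].index
            net_long = network_table[
                network_table["participant"].isin(complete)].melt(
                id_vars=["participant", "group", "condition"],
                value_vars=list(GLOBAL_METRICS + NODAL_METRICS),
                var_name="metric")
            a_glob = _anova_block(net_long, GLOBAL_METRICS, "network_global")
            a_nod = _anova_block(net_long, NODAL_METRICS, "network_nodal")
            # multiplicity control: Bonferroni over the 3 global metrics,
            # BH-FDR over the 10 ROIs, within each effect
            a_glob["p_adj"] = a_glob.groupby("effect")["p"].transform(
                lambda p: bonferroni(p, m=len(GLOBAL_METRICS)))
            a_nod["p_adj"] = a_nod.groupby("effect")["p"].transform(fdr_bh)
            anova = pd.concat([anova, a_glob, a_nod], ignore_index=True)
        else:
            net_long = None

        se_rows = []
        inter = anova[(anova["effect"] == "interaction")
                      & (anova["p"] < config.alpha)]
        for _, row in inter.iterrows():
            source = cop_long if row["family"] == "cop" else net_long
            se = simple_effects(source[source["metric"] == row["metric"]])
            se.insert(0, "metric", row["metric"])
            se_rows.append(se)
        simple_effects_table = (pd.concat(se_rows, ignore_index=True)
                                if se_rows else pd.DataFrame(
            columns=["metric", "contrast", "family", "statistic", "df",
                     "p", "p_adj"]))

        correlation_table = None
        if network_table is not None:
            merged = cop_table.merge(network_table,
                                     on=["participant", "group", "condition"])
            corr_rows = []
            for (group, cond), sub in merged.groupby(["group", "condition"]):
                for beh in ("AREA", "AP_RMS"):
                    for brain in ("sigma", "Ne_R_S1"):
                        if len(sub) < 3:
                            continue
                        res = pearson_corr_test(sub[beh], sub[brain])
                        corr_rows.append({
                            "group": group, "condition": cond,
                            "behavior": beh, "brain": brain,
                            "r": res.r, "n": res.n, "p": res.p})
            correlation_table = pd.DataFrame(corr_rows)

    manifest = {
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "mode": config.mode,
        "n_participants": int(len(dataset.participants)),
        "n_rand": config.n_rand,
        "sparsity_min": (None if network_table is None
                         else float(network_table.attrs["sparsity_min"])),
        "network_qc_excluded": (None if network_table is None else
                                network_table.attrs.get("qc_excluded", [])),
        "elapsed_s": round(time.perf_counter() - t_start, 2),
        "versions": {"swaynet": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__},
    }
    return ReportBundle(cop_table=cop_table, network_table=network_table,
                        demographics_table=dataset.participants,
                        demographic_tests=demographic_tests,
                        anova_tables=anova,
                        simple_effects_table=simple_effects_table,
                        correlation_table=correlation_table,
                        manifest=manifest)


def auc_table_tidy(network_table: pd.DataFrame) -> pd.DataFrame:
    """Long form of the AUC table: participant, condition, metric, roi,
    value (roi empty for the global metrics)."""
    long = network_table.melt(
        id_vars=["participant", "group", "condition"],
        value_vars=list(GLOBAL_METRICS + NODAL_METRICS), var_name="metric")
    nodal = long["metric"].str.startswith("Ne_")
    long["roi"] = np.where(nodal, long["metric"].str.replace("Ne_", "", n=1), "")
    long.loc[nodal, "metric"] = "Ne"
    return long[["participant", "group", "condition", "metric", "roi", "value"]]


def _atomic_write(write_fn, path: Path) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    os.close(fd)
    try:
        write_fn(tmp)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def write_report(bundle: ReportBundle, directory) -> list[Path]:
    """Persist all tables as CSV plus the JSON manifest (temp-then-rename)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = {
        "cop_metrics.csv": bundle.cop_table,
        "demographics.csv": bundle.demographics_table,
        "demographic_tests.csv": bundle.demographic_tests,
        "anova.csv": bundle.anova_tables,
        "simple_effects.csv": bundle.simple_effects_table,
    }
    if bundle.network_table is not None:
        files["network_auc.csv"] = bundle.network_table
        files["network_auc_tidy.csv"] = auc_table_tidy(bundle.network_table)
    if bundle.correlation_table is not None:
        files["correlations.csv"] = bundle.correlation_table
    written = []
    for name, df in files.items():
        path = directory / name
        _atomic_write(lambda tmp, df=df: df.to_csv(tmp, index=False), path)
        written.append(path)
    mpath = directory / "manifest.json"
    _atomic_write(lambda tmp: Path(tmp).write_text(
        json.dumps(bundle.manifest, indent=2, sort_keys=True)), mpath)
    written.append(mpath)
    return written
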