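"""End-to-end orchestration: simulate -> preprocess -> ERP -> statistics.

A single seeded configuration drives a full synthetic study: a control
cohort plus responder/non-responder PTSD cohorts assessed pre and post
treatment, preprocessed and averaged per subject, compared with the
cluster permutation test, scored behaviourally and clinically, and fed
into the PLSC correlational analysis.  Every run writes a manifest
recording resolved parameters, exclusions and output hashes, and is
byte-reproducible from (config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behaviour import behaviour_table, score_behaviour
from .clinical import (adjust_pvalues, baseline_change_regression, chi_square_yates,
                       classify_responder, compare_groups, mann_whitney_u,
                       prepost_table, score_htq, sensitivity_model)
from .cluster import permutation_test
from .erp import (average_condition, difference_wave, grand_average,
                  measure_component)
from .montage import channel_index
from .plsc import contributions_table, plsc_analysis
from .preprocess import (apply_trial_count_exclusion, bandpass_filter,
                         extract_epochs, reject_artifacts)
from .synth import (CohortConfig, cohort_components, generate_behavioural_log,
                    generate_htq_cohort, generate_trial_sequence, synthesize_eeg,
                    _substream)

#: Per-group behavioural generator settings (omission rate, commission
#: rate, RT mean, RT SD), patterned on the task statistics of healthy
#: controls vs a chronic-PTSD cohort, with responders improving post.
_BEHAVIOUR_PROFILES = {
    ("control", "pre"): (0.005, 0.003, 405.0, 74.0),
    ("responder", "pre"): (0.07, 0.005, 376.0, 130.0),
    ("responder", "post"): (0.04, 0.006, 360.0, 102.0),
    ("non_responder", "pre"): (0.04, 0.005, 451.0, 139.0),
    ("non_responder", "post"): (0.03, 0.005, 409.0, 110.0),
}


@dataclass
class RunConfig:
    """Validated configuration for a full pipeline run."""
    seed: int = 0
    n_trials: int = 120
    artifact_rate: float = 0.08
    cohort: CohortConfig = field(default_factory=lambda: CohortConfig(
        n_controls=8, n_responders=6, n_non_responders=6))
    raw_thresh_uv: float = 100.0
    slow_thresh_uv: float = 50.0
    fast_thresh_uv: float = 35.0
    min_valid_fraction: float = 0.30
    band_low_hz: float = 0.5
    band_high_hz: float = 50.0
    cluster_channels: tuple[str, ...] = ("Fz", "Cz")
    cluster_window_ms: tuple[float, float] = (200.0, 600.0)
    cluster_alpha: float = 0.05
    n_permutations: int = 500
    n_bootstrap: int = 500
    alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort = CohortConfig(**raw.pop("cohort", {}))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("cluster_channels", "cluster_window_ms"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(cohort=cohort, **raw)

    def resolved(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"] = dataclasses.asdict(self.cohort)
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _subject_phases(cfg: CohortConfig):
    """(subject_id, group, phases) for every simulated subject."""
    out = []
    k = 0
    for group, n in (("responder", cfg.n_responders),
                     ("non_responder", cfg.n_non_responders)):
        for _ in range(n):
            k += 1
            out.append((f"S{k:03d}", group, ("pre", "post")))
    for i in range(cfg.n_controls):
        out.append((f"C{i + 1:03d}", "control", ("pre",)))
    return out


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute every stage and write tables, figures and a manifest.

    Returns the manifest dictionary.  Group-contrast stages are skipped
    (with a logged notice) when a group is empty.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = config
    cohort = dataclasses.replace(cfg.cohort, seed=cfg.seed)
    notices: list[str] = []
    manifest: dict = {"package_version": __version__,
                      "config": cfg.resolved(), "notices": notices}

    # ---- stage 1-2: simulate + preprocess ------------------------------
    subjects = _subject_phases(cohort)
    epoch_sets: dict[tuple[str, str], object] = {}
    behaviour_rows = {}
    for sid, group, phases in subjects:
        for phase in phases:
            sub_seed = int(_substream(cfg.seed, "subject", sid, phase)
                           .integers(2 ** 31))
            sequence = generate_trial_sequence(cfg.n_trials, seed=sub_seed)
            comps = cohort_components(group, phase, cohort)
            rec, _truth = synthesize_eeg(sequence, comps,
                                         artifact_rate=cfg.artifact_rate,
                                         seed=sub_seed)
            filtered = bandpass_filter(rec, cfg.band_low_hz, cfg.band_high_hz)
            epochs = reject_artifacts(
                extract_epochs(filtered, sequence.events()),
                cfg.raw_thresh_uv, cfg.slow_thresh_uv, cfg.fast_thresh_uv)
            epoch_sets[(sid, phase)] = epochs
            om, com, rt_m, rt_sd = _BEHAVIOUR_PROFILES[(group, phase)]
            log = generate_behavioural_log(sequence, om, com, rt_m, rt_sd,
                                           seed=sub_seed)
            behaviour_rows[(sid, phase)] = (group, score_behaviour(sequence, log))

    baseline_sets = {sid: epoch_sets[(sid, "pre")] for sid, _, _ in subjects}
    included, excluded, report = apply_trial_count_exclusion(
        baseline_sets, cfg.min_valid_fraction)
    report.to_csv(outdir / "exclusion_report.csv", index=False)
    manifest["excluded_subjects"] = excluded
    group_of = {sid: group for sid, group, _ in subjects}

    # ---- stage 3: ERP averages, difference waves, measures -------------
    diff_waves: dict[tuple[str, str], object] = {}
    measures = []
    for (sid, phase), epochs in epoch_sets.items():
        if sid not in included:
            continue
        go = average_condition(epochs, "GO", label=sid)
        nogo = average_condition(epochs, "NOGO", label=sid)
        diff = difference_wave(nogo, go)
        diff_waves[(sid, phase)] = diff
        for comp, ch in (("P3d", "Cz"), ("P3d", "Fz"), ("SPWd", "Cz"), ("SPWd", "Pz")):
            m = measure_component(diff, comp, ch)
            measures.append({"subject_id": sid, "phase": phase,
                             "group": group_of[sid], "component": comp,
                             "channel": ch, "amplitude_uv": m.amplitude_uv,
                             "latency_ms": m.latency_ms,
                             "mean_amplitude_uv": m.mean_amplitude_uv})
    measures_df = pd.DataFrame(measures)
    measures_df.to_csv(outdir / "component_measures.csv", index=False)

    def _grand(group, phase):
        waves = [w for (sid, ph), w in diff_waves.items()
                 if ph == phase and group_of[sid] == group]
        return grand_average(waves, label=f"{group}-{phase}") if waves else None

    grands = {(g, ph): _grand(g, ph)
              for g in ("control", "responder", "non_responder")
              for ph in ("pre", "post")}
    _plot_grand_averages(grands, outdir / "grand_average_difference_waves.png")

    # ---- stage 4: cluster statistics -----------------------------------
    ch_idx = [channel_index(c) for c in cfg.cluster_channels]

    def _stack(group, phase):
        return np.stack([w.data[ch_idx] for (sid, ph), w in diff_waves.items()
                         if ph == phase and group_of[sid] == group])

    cluster_summaries = {}
    ptsd_pre = [w.data[ch_idx] for (sid, ph), w in diff_waves.items()
                if ph == "pre" and group_of[sid] != "control"]
    time_ms = next(iter(diff_waves.values())).time_ms if diff_waves else None
    if cohort.n_controls > 0 and ptsd_pre:
        res = permutation_test(
            (np.stack(ptsd_pre), _stack("control", "pre")), design="independent",
            n_permutations=cfg.n_permutations, seed=cfg.seed,
            cluster_alpha=cfg.cluster_alpha, alpha=cfg.alpha,
            channel_names=cfg.cluster_channels, time_ms=time_ms,
            time_window_ms=cfg.cluster_window_ms)
        cluster_summaries["ptsd_vs_control_baseline"] = res
    else:
        notices.append("group contrast ptsd_vs_control_baseline skipped: empty group")
    resp_ids = [sid for sid in included if group_of[sid] == "responder"
                and (sid, "post") in diff_waves]
    if len(resp_ids) >= 5:
        prepost = np.stack([diff_waves[(sid, "post")].data[ch_idx]
                            - diff_waves[(sid, "pre")].data[ch_idx]
                            for sid in resp_ids])
        res = permutation_test(prepost, design="paired",
                               n_permutations=cfg.n_permutations, seed=cfg.seed,
                               cluster_alpha=cfg.cluster_alpha, alpha=cfg.alpha,
                               channel_names=cfg.cluster_channels, time_ms=time_ms,
                               time_window_ms=cfg.cluster_window_ms)
        cluster_summaries["responders_post_vs_pre"] = res
    else:
        notices.append("paired contrast responders_post_vs_pre skipped: "
                       "fewer than 5 responders")
    cluster_json = {}
    for name, res in cluster_summaries.items():
        res.summary().to_csv(outdir / f"clusters_{name}.csv", index=False)
        cluster_json[name] = {
            "n_permutations": res.n_permutations, "exhaustive": res.exhaustive,
            "significant_clusters": len(res.significant),
            "clusters": res.summary().to_dict("records")}
    (outdir / "cluster_results.json").write_text(json.dumps(cluster_json, indent=2))

    # ---- stage 5: behavioural tables -----------------------------------
    beh_pre = behaviour_table({sid: s for (sid, ph), (g, s) in behaviour_rows.items()
                               if ph == "pre"})
    beh_pre["group"] = beh_pre["subject_id"].map(group_of)
    beh_pre["cohort"] = np.where(beh_pre["group"] == "control", "control", "ptsd")
    beh_pre.to_csv(outdir / "behaviour_baseline.csv", index=False)
    value_cols = ["omissions", "commissions", "rt_median_ms", "rt_sd_ms"]
    if cohort.n_controls > 1 and (beh_pre["cohort"] == "ptsd").sum() > 1:
        compare_groups(beh_pre, "cohort", value_cols, "ptsd", "control",
                       m=4).to_csv(outdir / "behaviour_ptsd_vs_control.csv",
                                   index=False)
    else:
        notices.append("behaviour group comparison skipped: empty group")
    if cohort.n_responders > 1 and cohort.n_non_responders > 1:
        compare_groups(beh_pre[beh_pre["cohort"] == "ptsd"], "group", value_cols,
                       "responder", "non_responder", m=4).to_csv(
            outdir / "behaviour_responders_vs_nonresponders.csv", index=False)
        pre_rows, post_rows = [], []
        for (sid, ph), (g, s) in behaviour_rows.items():
            if g == "control":
                continue
            (pre_rows if ph == "pre" else post_rows).append(
                {"subject_id": sid, "group": g, **s.as_dict()})
        pre_df = pd.DataFrame(pre_rows).sort_values("subject_id")
        post_df = pd.DataFrame(post_rows).sort_values("subject_id")
        tabs = []
        for g in ("responder", "non_responder"):
            t = prepost_table(pre_df[pre_df.group == g], post_df[post_df.group == g],
                              value_cols, m=8)
            t.insert(0, "group", g)
            tabs.append(t)
        pd.concat(tabs).to_csv(outdir / "behaviour_prepost.csv", index=False)

    # ---- stage 6: clinical statistics ----------------------------------
    htq_cohort = generate_htq_cohort(cohort)
    htq_cohort.htq.to_csv(outdir / "htq.csv", index=False)
    htq_cohort.metadata.to_csv(outdir / "metadata.csv", index=False)
    item_cols = [f"item_{j:02d}" for j in range(1, 17)]
    records = {}
    for row in htq_cohort.htq.itertuples(index=False):
        rec = score_htq(np.array([getattr(row, c) for c in item_cols]),
                        subject_id=row.subject_id, timepoint=row.timepoint)
        records[(row.subject_id, row.timepoint)] = rec
    sids = htq_cohort.metadata["subject_id"].tolist()
    responder_calls = {sid: classify_responder(records[(sid, "pre")],
                                               records[(sid, "post")])
                       for sid in sids}
    meta = htq_cohort.metadata.copy()
    meta["classified"] = meta["subject_id"].map(responder_calls)
    meta.to_csv(outdir / "responder_classification.csv", index=False)

    scores = pd.DataFrame([
        {"subject_id": sid, "timepoint": tp, "total": rec.total,
         **rec.subscales}
        for (sid, tp), rec in records.items()])
    dims = ["total"] + list(records[(sids[0], "pre")].subscales)
    pre_scores = scores[scores.timepoint == "pre"].sort_values("subject_id")
    post_scores = scores[scores.timepoint == "post"].sort_values("subject_id")
    prepost_table(pre_scores, post_scores, dims, m=6).to_csv(
        outdir / "htq_prepost.csv", index=False)

    # Table-1-shaped baseline comparison of responders vs non-responders
    merged = meta.merge(pre_scores, on="subject_id")
    t1_rows = []
    for measure, kind in (("age", "mw"), ("total", "mw"), ("sex", "chi2"),
                          ("medication", "chi2")):
        r = merged[merged.group == "responder"]
        nr = merged[merged.group == "non_responder"]
        if len(r) < 2 or len(nr) < 2:
            notices.append("baseline characteristics table skipped: empty group")
            break
        if kind == "mw":
            u, p = mann_whitney_u(r[measure], nr[measure])
            t1_rows.append({"measure": measure, "test": "mann-whitney",
                            "statistic": u, "p": p})
        else:
            x = (merged[measure] == merged[measure].iloc[0]).astype(int) \
                if merged[measure].dtype == object else merged[measure]
            tab = pd.crosstab(merged.group, x).to_numpy()
            if tab.shape == (2, 2) and (tab.sum(axis=0) > 0).all():
                chi2, p = chi_square_yates(tab)
                t1_rows.append({"measure": measure, "test": "chi2_yates",
                                "statistic": chi2, "p": p})
    if t1_rows:
        pd.DataFrame(t1_rows).to_csv(outdir / "baseline_characteristics.csv",
                                     index=False)

    # baseline-severity regression and medication sensitivity model
    pre_totals = pre_scores.set_index("subject_id")["total"]
    change = (post_scores.set_index("subject_id")["total"] - pre_totals)
    slope, intercept, r2, fstat, fp = baseline_change_regression(
        pre_totals[sids], change[sids])
    manifest["baseline_regression"] = {"slope": slope, "intercept": intercept,
                                       "r_squared": r2, "F": fstat, "p": fp}
    try:
        sens = sensitivity_model(
            -change[sids],
            [1 if responder_calls[s] == "responder" else 0 for s in sids],
            meta.set_index("subject_id").loc[sids, "medication"])
        sens.to_csv(outdir / "sensitivity_model.csv", index=False)
    except ValueError as err:
        notices.append(f"sensitivity model skipped: {err}")

    # ---- stage 7: PLSC --------------------------------------------------
    pre_items = htq_cohort.htq[htq_cohort.htq.timepoint == "pre"] \
        .set_index("subject_id").loc[sids, item_cols].to_numpy(float)
    post_items = htq_cohort.htq[htq_cohort.htq.timepoint == "post"] \
        .set_index("subject_id").loc[sids, item_cols].to_numpy(float)
    X = pre_items - post_items  # item decrease, positive = improvement
    Y = htq_cohort.erp_change.set_index("subject_id") \
        .loc[sids, ["cz_p3d_change_uv", "pz_spwd_change_uv"]].to_numpy(float)
    keep_items = X.std(axis=0, ddof=1) > 0
    if not keep_items.all():
        dropped = [c for c, k in zip(item_cols, keep_items) if not k]
        notices.append(f"PLSC: dropped constant item-change column(s) {dropped}")
    X = X[:, keep_items]
    kept_cols = [c for c, k in zip(item_cols, keep_items) if k]
    if len(sids) >= 10:
        res = plsc_analysis(X, Y, n_perm=cfg.n_permutations,
                            n_boot=cfg.n_bootstrap, seed=cfg.seed)
        contributions_table(res, kept_cols, ["cz_p3d_change_uv",
                                             "pz_spwd_change_uv"]).to_csv(
            outdir / "plsc_contributions.csv", index=False)
        pd.DataFrame({"subject_id": sids, "latent_x1": res.latent_x[:, 0],
                      "latent_y1": res.latent_y[:, 0]}).to_csv(
            outdir / "plsc_latent_scores.csv", index=False)
        manifest["plsc"] = {
            "variance_explained": res.variance_explained.tolist(),
            "dim_p_values": res.dim_p_values.tolist(),
            "latent_correlation": res.latent_correlation.tolist()}
    else:
        notices.append("PLSC skipped: fewer than 10 PTSD subjects")

    # ---- manifest -------------------------------------------------------
    outputs = sorted(p.name for p in outdir.iterdir()
                     if p.is_file() and p.name != "manifest.json")
    manifest["outputs"] = {name: _sha256(outdir / name) for name in outputs}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     sort_keys=True))
    return manifest


def _plot_grand_averages(grands: dict, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
    colors = {"control": "0.5", "responder": "tab:green",
              "non_responder": "tab:red"}
    for ax, ch in zip(axes, ("Fz", "Cz")):
        for (group, phase), wave in grands.items():
            if wave is None or phase != "pre":
                continue
            ax.plot(wave.time_ms, wave.channel(ch), color=colors[group],
                    label=group.replace("_", "-"))
        ax.axvline(0, color="k", lw=0.5)
        ax.set_title(f"NOGO-GO difference wave, {ch}")
        ax.set_xlabel("time (ms)")
    axes[0].set_ylabel("amplitude (uV)")
    axes[0].legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
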