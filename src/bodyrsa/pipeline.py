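"""End-to-end orchestration: simulate -> GLM -> RSA -> inference.

Runs the full analysis on a simulated cohort and writes every stage
output (CSV/JSON) to a run directory, with all randomness derived from
a single master seed. Stages can also be called individually on the
serialized outputs of their predecessors.
"""

from __future__ import annotations

import json
import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from . import __version__
from .design import BODY_PART_CONDITIONS, CONDITIONS
from .synth import CohortConfig, SimulatedParticipant, generate_cohort, save_cohort
from . import glm as g
from .rsa import RDM, mds_embed, mean_rdm, split_half_rdm, within_between_correlations
from .partitions import anosim_permutation_test, hypothesized_partition, mantel_test
from .classify import decode
from . import groupstats as gs

__all__ = ["PipelineConfig", "run_pipeline", "report", "participant_betas"]


@dataclass
class PipelineConfig:
    """All knobs of the full analysis, serialized with every run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    hpf_cutoff: float = 128.0
    whitening: str = "ar1_global"
    global_scaling: bool = True
    p_activation: float = 0.01
    mantel_n_permutations: int = 9999
    decode_n_bootstraps: int = 100
    run_decoding: bool = True
    save_bold: bool = False
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, default=str)


def participant_betas(
    p: SimulatedParticipant,
    hpf_cutoff: float = 128.0,
    whitening: str = "ar1_global",
    global_scaling: bool = True,
    n_dummy: int = 5,
) -> tuple[np.ndarray, list[g.BetaEstimates]]:
    """Per-run GLM amplitudes for one participant.

    The first ``n_dummy`` volumes of data and motion are discarded
    before design construction (onsets shift accordingly); each run is
    globally scaled to grand mean 100. Returns (n_runs x 10 x voxels in
    canonical condition order, per-run estimate objects).
    """
    betas = []
    per_run = []
    for Y, mo, sched in zip(p.bold_runs, p.motion_runs, p.schedules):
        Ya = Y[:, n_dummy:].T  # volumes x voxels
        if global_scaling:
            Ya = g.global_scale(Ya)
        X = g.build_design_matrix(
            sched,
            motion=mo[n_dummy:],
            hpf_cutoff=hpf_cutoff,
            n_dummy_volumes=n_dummy,
        )
        est = g.fit_glm(Ya, X, whitening=whitening)
        order = [est.condition_names.index(c) for c in CONDITIONS]
        per_run.append(est.betas[order])
        betas.append(est)
    return np.stack(per_run), betas


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute every stage and write all outputs under ``outdir``."""
    out = Path(outdir)
    (out / "rsa").mkdir(parents=True, exist_ok=True)
    (out / "stats").mkdir(exist_ok=True)
    cohort = generate_cohort(config.cohort, config.seed)
    if config.save_bold:
        save_cohort(cohort, out / "cohort")

    n_dummy = config.cohort.design.n_dummy_volumes
    hyp = hypothesized_partition()
    contrast = np.zeros(len(CONDITIONS))
    contrast[CONDITIONS.index("whole_body")] = 1.0
    contrast[CONDITIONS.index("chair")] = -1.0
    bp_idx = [CONDITIONS.index(c) for c in BODY_PART_CONDITIONS]

    rows = []
    rdms: list[RDM] = []
    groups: list[str] = []
    decode_rows = []
    uni_rows = []
    for p in cohort.participants:
        all_betas, per_run = participant_betas(
            p, config.hpf_cutoff, config.whitening, config.global_scaling,
            n_dummy=n_dummy,
        )
        mean_over_runs = all_betas.mean(axis=0)
        for ci, cond in zip(bp_idx, BODY_PART_CONDITIONS):
            uni_rows.append(
                {"id": p.id, "group": p.group, "condition": cond,
                 "beta": float(mean_over_runs[ci].mean())}
            )
        fd = np.mean(
            [gs.framewise_displacement(mo[n_dummy:]).mean_fd for mo in p.motion_runs]
        )
        tmap = g.compute_contrast(per_run, contrast)
        act = g.detect_activation(tmap, p_uncorrected=config.p_activation)
        rdm = split_half_rdm(all_betas[:, bp_idx, :])
        rdm.to_csv(out / "rsa" / f"rdm_{p.id}.csv")
        ano = anosim_permutation_test(rdm, hyp)
        rdms.append(rdm)
        groups.append(p.group)
        row = {
            "id": p.id,
            "group": p.group,
            "kappa": p.patterns.cohesion,
            "mean_fd": float(fd),
            "activated": act.activated,
            "activation_volume_mm3": act.volume_mm3,
            "anosim_r": ano.r,
            "anosim_p": ano.p,
            **{f"trait_{k}": v for k, v in p.trait_scores.items()},
        }
        if config.run_decoding:
            cv = decode(
                all_betas[:, bp_idx, :],
                partition=hyp,
                n_bootstraps=config.decode_n_bootstraps,
                seed=p.seed,
            )
            row["accuracy"] = cv.mean_accuracy
            row["accuracy_minus_chance"] = cv.accuracy_minus_chance
            for f, a in enumerate(cv.fold_accuracies):
                decode_rows.append(
                    {"id": p.id, "group": p.group, "fold": f, "accuracy": float(a)}
                )
        rows.append(row)
    table = pd.DataFrame(rows)
    table.to_csv(out / "participants.csv", index=False)
    if decode_rows:
        pd.DataFrame(decode_rows).to_csv(out / "stats" / "decode_folds.csv", index=False)

    gnames = sorted(config.cohort.groups)
    summary: dict = {"groups": gnames, "n": {gn: int((table.group == gn).sum()) for gn in gnames}}

    # group-mean RDMs, MDS, group-level ANOSIM, Mantel between groups
    group_rdms = {}
    for gi, gn in enumerate(gnames):
        idx = [i for i, grp in enumerate(groups) if grp == gn]
        m = mean_rdm([rdms[i] for i in idx])
        group_rdms[gn] = m
        m.to_csv(out / "rsa" / f"mean_rdm_{gn}.csv")
        emb = mds_embed(m, seed=config.seed + gi)
        emb.to_csv(out / "rsa" / f"mds_{gn}.csv")
        ano = anosim_permutation_test(m, hyp)
        summary[f"anosim_{gn}"] = {"R": ano.r, "P": ano.p, "rank": ano.rank}
    mant = mantel_test(
        group_rdms[gnames[0]],
        group_rdms[gnames[1]],
        n_permutations=config.mantel_n_permutations,
        seed=config.seed + 17,
    )
    summary["mantel"] = {"R": mant.r, "P": mant.p, "n_permutations": mant.n_permutations}

    # within/between representational correlations: mixed ANOVA and
    # the head-motion ANCOVA
    wb = within_between_correlations(rdms, groups)
    wb["id"] = table["id"].to_numpy()
    wb["mean_fd"] = table["mean_fd"].to_numpy()
    wb.to_csv(out / "rsa" / "within_between.csv", index=False)
    long = wb.melt(
        id_vars=["id", "group", "mean_fd"],
        value_vars=["within_r", "between_r"],
        var_name="corr_type",
        value_name="r",
    )
    aov = gs.mixed_anova(long, dv="r", within="corr_type", between="group", subject="id")
    ancova = gs.mixed_anova(
        long, dv="r", within="corr_type", between="group", subject="id",
        covariate="mean_fd",
    )
    summary["correlation_anova"] = json.loads(aov.effects.to_json(orient="index"))
    summary["correlation_ancova"] = json.loads(ancova.effects.to_json(orient="index"))

    # activation ratio chi-square and FD group comparison
    act_tab = np.array(
        [
            [
                int((table.activated & (table.group == gn)).sum()),
                int((~table.activated & (table.group == gn)).sum()),
            ]
            for gn in gnames
        ]
    )
    summary["activation_table"] = act_tab.tolist()
    try:
        chi = gs.chi_square_2x2(act_tab)
        summary["activation_chi_square"] = {
            "chi2": chi.statistic, "df": chi.df, "p": chi.p, "cramers_v": chi.cramers_v,
        }
    except ValueError as e:
        summary["activation_chi_square"] = {"undefined": str(e)}
    fd_by = [table.loc[table.group == gn, "mean_fd"].to_numpy() for gn in gnames]
    fd_t = gs.two_sample_t(fd_by[0], fd_by[1], mode="welch")
    summary["fd_group_t"] = {
        "t": fd_t.t, "df": fd_t.df, "p": fd_t.p, "cohens_d": fd_t.cohens_d,
        "means": [float(x.mean()) for x in fd_by],
    }

    # decoding group statistics
    if config.run_decoding:
        acc = {gn: table.loc[table.group == gn, "accuracy_minus_chance"].to_numpy() for gn in gnames}
        dec = {}
        for gn in gnames:
            sd = acc[gn].std(ddof=1)
            if sd > 0:
                t, p = sp_stats.ttest_1samp(acc[gn], 0.0)
                t, p, d = float(t), float(p), float(acc[gn].mean() / sd)
            else:  # every participant at the same (e.g. ceiling) accuracy
                t = np.inf if acc[gn].mean() > 0 else 0.0
                p, d = (0.0, np.inf) if acc[gn].mean() > 0 else (1.0, 0.0)
            dec[f"vs_chance_{gn}"] = {
                "t": t, "df": int(acc[gn].size - 1), "p": p, "cohens_d": d,
                "mean_accuracy_minus_chance": float(acc[gn].mean()),
            }
        try:
            bt = gs.two_sample_t(acc[gnames[0]], acc[gnames[1]], mode="student")
            dec["group_difference"] = {
                "t": bt.t, "df": bt.df, "p": bt.p, "cohens_d": bt.cohens_d,
            }
        except ValueError as e:  # e.g. ceiling accuracy in both groups
            dec["group_difference"] = {"undefined": str(e)}
        summary["decoding"] = dec

    # trait correlations (younger group only, as in the study design)
    child = table[table.group == "child_adolescent"]
    if len(child) >= 4:
        score_cols = [c for c in table.columns if c.startswith("trait_")]
        scores = child[score_cols].rename(columns=lambda c: c[len("trait_"):])
        try:
            rep = gs.spearman_with_bonferroni(child["anosim_r"].to_numpy(), scores)
            partials = {}
            for col in scores.columns:
                r, dfree, p = gs.partial_correlation(
                    child["anosim_r"].to_numpy(), scores[col].to_numpy(),
                    child["mean_fd"].to_numpy(),
                )
                partials[col] = {"r": r, "df": dfree, "p": p}
            rep.table.to_csv(out / "stats" / "trait_spearman.csv", index=False)
            summary["trait_correlations"] = {
                "bonferroni_threshold": rep.corrected_threshold,
                "spearman": json.loads(
                    rep.table.set_index("score").to_json(orient="index")
                ),
                "partial_fd": partials,
            }
        except ValueError as e:  # e.g. ANOSIM R at ceiling for everyone
            summary["trait_correlations"] = {"undefined": str(e)}

    # univariate regional average activation: body part x group ANOVA
    uni = pd.DataFrame(uni_rows)
    uni.to_csv(out / "stats" / "univariate_means.csv", index=False)
    uaov = gs.mixed_anova(uni, dv="beta", within="condition", between="group", subject="id")
    summary["univariate_anova"] = json.loads(uaov.effects.to_json(orient="index"))
    ph = gs.posthoc_pairwise(uni, dv="beta", within="condition", subject="id")
    ph.to_csv(out / "stats" / "univariate_posthoc.csv", index=False)

    (out / "stats" / "summary.json").write_text(json.dumps(summary, indent=1))
    (out / "config.json").write_text(config.to_json())
    prov = {
        "package_version": __version__,
        "numpy": np.__version__,
        "master_seed": config.seed,
        "config_sha256": hashlib.sha256(config.to_json().encode()).hexdigest(),
    }
    (out / "provenance.json").write_text(json.dumps(prov, indent=1))
    return summary


def report(run_dir: str | Path) -> str:
    """Human-readable summary of a completed run directory."""
    d = Path(run_dir)
    missing = [
        name
        for name in ("stats/summary.json", "participants.csv", "config.json")
        if not (d / name).exists()
    ]
    if missing:
        raise FileNotFoundError(
            f"run directory {d} is missing stage outputs: {missing}"
        )
    s = json.loads((d / "stats" / "summary.json").read_text())
    lines = [f"bodyrsa run report: {d}", ""]
    for gn in s["groups"]:
        a = s[f"anosim_{gn}"]
        lines.append(
            f"ANOSIM [{gn}, n={s['n'][gn]}]: R = {a['R']:.3f}, P = {a['P']:.3f} "
            f"(rank {a['rank']}/420)"
        )
    m = s["mantel"]
    lines.append(f"Mantel between group-mean RDMs: R = {m['R']:.3f}, P = {m['P']:.4g}")
    chi = s["activation_chi_square"]
    if "chi2" in chi:
        lines.append(
            f"Activation ratio: chi2(1) = {chi['chi2']:.3f}, P = {chi['p']:.3f}, "
            f"Cramer's V = {chi['cramers_v']:.2f}"
        )
    else:
        lines.append(f"Activation ratio chi-square: {chi['undefined']}")
    fd = s["fd_group_t"]
    lines.append(
        f"Mean FD group difference: t({fd['df']:.1f}) = {fd['t']:.3f}, "
        f"P = {fd['p']:.3f}, d = {fd['cohens_d']:.2f}"
    )
    for eff, r in s["correlation_anova"].items():
        lines.append(
            f"Corr-type ANOVA {eff}: F({r['df1']},{r['df2']}) = {r['F']:.3f}, "
            f"P = {r['p']:.3f}, partial eta2 = {r['partial_eta_sq']:.3f}"
        )
    if "decoding" in s:
        for k, r in s["decoding"].items():
            if "undefined" in r:
                lines.append(f"Decoding {k}: undefined ({r['undefined']})")
                continue
            lines.append(
                f"Decoding {k}: t({r['df']:.1f}) = {r['t']:.3f}, P = {r['p']:.4g}"
                + (
                    f", mean acc-chance = {r['mean_accuracy_minus_chance']:.3f}"
                    if "mean_accuracy_minus_chance" in r
                    else ""
                )
            )
    if "trait_correlations" in s:
        tc = s["trait_correlations"]
        if "undefined" in tc:
            lines.append(f"Trait Spearman: undefined ({tc['undefined']})")
        else:
            sig = [k for k, v in tc["spearman"].items() if v["significant_bonferroni"]]
            lines.append(
                f"Trait Spearman (Bonferroni threshold "
                f"{tc['bonferroni_threshold']:.3f}): "
                + (f"significant: {', '.join(sig)}" if sig else "none significant")
            )
    return "\n".join(lines)
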