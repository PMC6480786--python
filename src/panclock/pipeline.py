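"""Pipeline orchestration: simulate/ingest -> recurrence -> DE -> derive ->
score -> survival -> crosstalk, with stage-wise TSV outputs and a JSON run
manifest.

Each stage is a pure function of (inputs, config, seed); per-stage seeds are
derived from the single run seed by hashing the stage name, so stages are
individually re-runnable and a rerun with the same seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import AnalysisConfig
from .io import (CohortBundle, clock_genes, hypoxia_signature,
                 read_cohort_bundle, write_cohort_bundle)
from . import crosstalk as ct_mod
from . import de as de_mod
from . import recurrence as rec_mod
from . import scoring as sc_mod
from . import survival as sv_mod
from .simulate import SimulationDesign, simulate_cohort

logger = logging.getLogger(__name__)

STAGES = ["ingest", "recurrence", "de", "derive", "score", "survival",
          "crosstalk"]

HIF_TARGETS = ["CA9", "VEGFA", "LDHA"]


def stage_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed derived from the run seed and stage name."""
    return (seed ^ zlib.crc32(stage.encode())) % (2 ** 31)


class StageError(RuntimeError):
    """A pipeline stage failed; the failing stage is named."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _checksums(directory: Path) -> dict[str, str]:
    out = {}
    for p in sorted(directory.glob("*.tsv")):
        out[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    return out


# ---------------------------------------------------------------------------
# stages


def stage_ingest(out_dir: Path, input_dir: str | Path | None = None,
                 design: SimulationDesign | None = None) -> CohortBundle:
    if (input_dir is None) == (design is None):
        raise ValueError("provide exactly one of input_dir or design")
    if design is not None:
        bundle = simulate_cohort(design)
    else:
        bundle = read_cohort_bundle(input_dir)
    data_dir = out_dir / "data"
    write_cohort_bundle(bundle, data_dir)
    return bundle


def stage_recurrence(bundle: CohortBundle, config: AnalysisConfig,
                     out_dir: Path) -> pd.DataFrame:
    fractions = rec_mod.alteration_fractions(bundle)
    verdicts = rec_mod.classify_recurrent(
        fractions, config.recurrence_fraction, config.min_cancers,
        config.deletion_mode)
    fractions.to_csv(out_dir / "alteration_fractions.tsv", sep="\t")
    verdicts.to_csv(out_dir / "recurrence.tsv", sep="\t")
    return verdicts


def stage_de(bundle: CohortBundle, config: AnalysisConfig, out_dir: Path
             ) -> pd.DataFrame:
    de_dir = out_dir / "de"
    de_dir.mkdir(exist_ok=True)
    results = {}
    for cohort in bundle:
        res = de_mod.moderated_t_de(cohort.expr_tumour, cohort.expr_normal)
        res.to_csv(de_dir / f"{cohort.name}.tsv", sep="\t")
        results[cohort.name] = res
    concordance = de_mod.cross_cancer_concordance(
        results, config.de_fc_linear, config.de_p,
        use_adjusted=config.p_adjust_for_filters == "bh")
    concordance.to_csv(out_dir / "concordance.tsv", sep="\t")
    return concordance


def stage_derive(recurrence: pd.DataFrame, concordance: pd.DataFrame,
                 config: AnalysisConfig, out_dir: Path) -> sc_mod.GeneSetDerivation:
    universe = [g for g in clock_genes() if g in recurrence.index]
    if not universe:
        raise ValueError("no clock gene present in the copy-number tables")
    derivation = sc_mod.derive_gene_sets(
        recurrence.loc[universe],
        concordance.loc[[g for g in universe if g in concordance.index]],
        config.min_cancers)
    derivation.evidence.to_csv(out_dir / "gene_set_evidence.tsv", sep="\t")
    pd.DataFrame({
        "gene": derivation.clock_loss + derivation.clock_gain,
        "set": (["clock_loss"] * len(derivation.clock_loss)
                + ["clock_gain"] * len(derivation.clock_gain)),
    }).to_csv(out_dir / "gene_sets.tsv", sep="\t", index=False)
    return derivation


def stage_score(bundle: CohortBundle, derivation: sc_mod.GeneSetDerivation,
                out_dir: Path) -> dict[str, pd.DataFrame]:
    """Per-cohort score and stratification tables (tumour and normal samples)."""
    score_dir = out_dir / "scores"
    score_dir.mkdir(exist_ok=True)
    hyp_genes = hypoxia_signature()
    tables = {}
    for cohort in bundle:
        frames = []
        for tissue, expr in (("tumour", cohort.expr_tumour),
                             ("normal", cohort.expr_normal)):
            df = pd.DataFrame(index=pd.Index(expr.sample_ids, name="sample_id"))
            df["tissue"] = tissue
            if derivation.clock_loss:
                df["clock_loss_score"] = sc_mod.score_patients(
                    expr, derivation.clock_loss)
            if derivation.clock_gain:
                df["clock_gain_score"] = sc_mod.score_patients(
                    expr, derivation.clock_gain)
            if any(g in expr.gene_ids for g in hyp_genes):
                df["hypoxia_score"] = sc_mod.score_patients(
                    expr, [g for g in hyp_genes if g in expr.gene_ids])
            frames.append(df)
        tum = frames[0]
        # stratification labels are defined on tumour samples, per cohort
        for key in ("clock_loss_score", "clock_gain_score"):
            if key in tum.columns and tum[key].nunique() > 3:
                base = key.replace("_score", "")
                tum[f"{base}_quartile"] = sc_mod.stratify(tum[key], "quartile")
                tum[f"{base}_median"] = sc_mod.stratify(tum[key], "median")
                if "hypoxia_score" in tum.columns:
                    tum[f"{base}_hypoxia_group"] = sc_mod.stratify(
                        tum[key], "joint", tum["hypoxia_score"])
        table = pd.concat(frames)
        table.to_csv(score_dir / f"{cohort.name}.tsv", sep="\t")
        tables[cohort.name] = table
    return tables


def stage_survival(bundle: CohortBundle, scores: dict[str, pd.DataFrame],
                   config: AnalysisConfig, out_dir: Path) -> pd.DataFrame:
    """Per-cohort KM/log-rank, Cox quartile contrasts (with and without TNM)
    and fixed-horizon AUCs for each derived score."""
    rows = []
    for cohort in bundle:
        table = scores[cohort.name]
        tum = table[table["tissue"] == "tumour"]
        clin = cohort.clinical.table.set_index("sample_id").loc[tum.index]
        times = clin["os_time"].to_numpy(float)
        events = clin["os_event"].to_numpy(int)
        stage = clin["tnm_stage"]
        for base in ("clock_loss", "clock_gain"):
            qcol = f"{base}_quartile"
            if qcol not in tum.columns:
                continue
            labels = tum[qcol]
            km = sv_mod.km_logrank(times, events, labels.to_numpy())
            row = {"cancer_type": cohort.name, "gene_set": base,
                   "logrank_chi2": km.logrank_chi2, "logrank_p": km.logrank_p}
            try:
                uni = sv_mod.cox_regression(
                    times, events, sv_mod.quartile_dummies(labels))
                for c in uni.index:
                    row[f"uni_HR_{c}"] = uni.loc[c, "hazard_ratio"]
                    row[f"uni_p_{c}"] = uni.loc[c, "p"]
            except Exception as exc:  # degenerate small cohorts
                logger.warning("univariate Cox failed for %s/%s: %s",
                               cohort.name, base, exc)
            has_stage = stage.notna()
            if has_stage.sum() >= 8 and stage[has_stage].nunique() > 1:
                cov = sv_mod.quartile_dummies(labels[has_stage])
                cov["tnm_stage"] = stage[has_stage].astype(float).to_numpy()
                try:
                    multi = sv_mod.cox_regression(
                        times[has_stage.to_numpy()], events[has_stage.to_numpy()], cov)
                    for c in multi.index:
                        row[f"multi_HR_{c}"] = multi.loc[c, "hazard_ratio"]
                        row[f"multi_p_{c}"] = multi.loc[c, "p"]
                except Exception as exc:
                    logger.warning("multivariate Cox failed for %s/%s: %s",
                                   cohort.name, base, exc)
            score_vec = tum[f"{base}_score"].to_numpy(float)
            try:
                row["auc_score"] = sv_mod.roc_auc_at_horizon(
                    score_vec, times, events, config.horizon_days).auc
                if has_stage.all() and stage.nunique() > 1:
                    row["auc_stage"] = sv_mod.roc_auc_at_horizon(
                        stage.to_numpy(float), times, events,
                        config.horizon_days).auc
                    lp = sv_mod.combined_predictor(
                        score_vec, stage.to_numpy(float), times, events)
                    row["auc_combined"] = sv_mod.roc_auc_at_horizon(
                        lp.to_numpy(), times, events, config.horizon_days).auc
            except ValueError as exc:
                logger.warning("horizon ROC skipped for %s/%s: %s",
                               cohort.name, base, exc)
            rows.append(row)
    summary = pd.DataFrame(rows)
    summary.to_csv(out_dir / "survival_summary.tsv", sep="\t", index=False)
    return summary


def stage_crosstalk(bundle: CohortBundle, scores: dict[str, pd.DataFrame],
                    derivation: sc_mod.GeneSetDerivation,
                    config: AnalysisConfig, out_dir: Path) -> pd.DataFrame:
    """Hypoxia-clock association, joint four-group Cox, tumour-vs-normal
    tests, PCoA/PERMANOVA ordination and HIF-target correlation exports."""
    xt_dir = out_dir / "crosstalk"
    xt_dir.mkdir(exist_ok=True)
    seed = stage_seed(config.seed, "crosstalk")
    rows = []
    for cohort in bundle:
        table = scores[cohort.name]
        tum = table[table["tissue"] == "tumour"]
        nor = table[table["tissue"] == "normal"]
        clin = cohort.clinical.table.set_index("sample_id").loc[tum.index]
        times = clin["os_time"].to_numpy(float)
        events = clin["os_event"].to_numpy(int)
        row = {"cancer_type": cohort.name}
        for base in ("clock_loss", "clock_gain"):
            skey = f"{base}_score"
            if skey not in tum.columns or "hypoxia_score" not in tum.columns:
                continue
            assoc = ct_mod.spearman_assoc(tum[skey].to_numpy(),
                                          tum["hypoxia_score"].to_numpy())
            row[f"{base}_hypoxia_rho"] = assoc.rho
            row[f"{base}_hypoxia_p"] = assoc.p
            gcol = f"{base}_hypoxia_group"
            if gcol in tum.columns:
                groups = tum[gcol]
                dummies = pd.DataFrame({
                    f"{lab}_vs_low/low": (groups == lab).astype(float)
                    for lab in ("low/high", "high/low", "high/high")})
                try:
                    fit = sv_mod.cox_regression(times, events, dummies)
                    for c in fit.index:
                        row[f"{base}_{c}_HR"] = fit.loc[c, "hazard_ratio"]
                        row[f"{base}_{c}_p"] = fit.loc[c, "p"]
                except Exception as exc:
                    logger.warning("joint Cox failed for %s/%s: %s",
                                   cohort.name, base, exc)
            if skey in nor.columns and nor[skey].notna().any():
                u, p = ct_mod.mannwhitney_test(tum[skey].to_numpy(),
                                               nor[skey].dropna().to_numpy())
                row[f"{base}_tumour_vs_normal_U"] = u
                row[f"{base}_tumour_vs_normal_p"] = p
        # ordination on the loss-set genes, tumour vs normal
        if derivation.clock_loss:
            expr = pd.concat([cohort.expr_tumour.values.loc[derivation.clock_loss],
                              cohort.expr_normal.values.loc[derivation.clock_loss]],
                             axis=1)
            labels = (["tumour"] * cohort.expr_tumour.values.shape[1]
                      + ["normal"] * cohort.expr_normal.values.shape[1])
            ordn = ct_mod.pcoa_permanova(expr, labels,
                                         n_permutations=config.n_permutations,
                                         seed=seed)
            row["permanova_F"] = ordn.permanova_F
            row["permanova_p"] = ordn.permanova_p
            ordn.coordinates.iloc[:, :2].to_csv(
                xt_dir / f"pcoa_{cohort.name}.tsv", sep="\t")
        # circular-heatmap export: HIF targets ranked by descending loss score
        if "clock_loss_score" in tum.columns:
            present = [g for g in HIF_TARGETS
                       if g in cohort.expr_tumour.gene_ids]
            if present:
                assoc, export = ct_mod.score_gene_correlation(
                    tum["clock_loss_score"], cohort.expr_tumour, present)
                export.to_csv(xt_dir / f"hif_targets_{cohort.name}.tsv", sep="\t")
                for g in assoc.index:
                    row[f"hif_{g}_rho"] = assoc.loc[g, "rho"]
        rows.append(row)
    summary = pd.DataFrame(rows)
    summary.to_csv(out_dir / "crosstalk_summary.tsv", sep="\t", index=False)
    return summary


# ---------------------------------------------------------------------------
# orchestration


def run_pipeline(config: AnalysisConfig, out_dir: str | Path,
                 input_dir: str | Path | None = None,
                 design: SimulationDesign | None = None) -> dict:
    """Run every stage in order, writing intermediate tables and a manifest.

    Exactly one of ``input_dir`` (a cohort directory in the data_io layout) or
    ``design`` (a :class:`~panclock.simulate.SimulationDesign`) must be given.
    A stage failure aborts with the failing stage named; outputs of completed
    stages are retained for debugging.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"tool": "panclock", "version": __version__,
                      "seed": config.seed, "config": config.to_dict(),
                      "stages": []}
    state: dict = {}

    def run(stage: str, fn):
        try:
            state[stage] = fn()
        except Exception as exc:
            raise StageError(stage, exc) from exc
        manifest["stages"].append({"stage": stage, "status": "ok"})

    run("ingest", lambda: stage_ingest(out_dir, input_dir, design))
    manifest["input_checksums"] = _checksums(out_dir / "data")
    run("recurrence", lambda: stage_recurrence(state["ingest"], config, out_dir))
    run("de", lambda: stage_de(state["ingest"], config, out_dir))
    run("derive", lambda: stage_derive(state["recurrence"], state["de"],
                                       config, out_dir))
    run("score", lambda: stage_score(state["ingest"], state["derive"], out_dir))
    run("survival", lambda: stage_survival(state["ingest"], state["score"],
                                           config, out_dir))
    run("crosstalk", lambda: stage_crosstalk(state["ingest"], state["score"],
                                             state["derive"], config, out_dir))
    manifest["outputs"] = sorted(str(p.relative_to(out_dir))
                                 for p in out_dir.rglob("*.tsv"))
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def report_summary(out_dir: str | Path) -> str:
    """Collate a human-readable markdown report from a completed run.

    Missing stage outputs are flagged as absent; the report is still produced.
    """
    out_dir = Path(out_dir)
    lines = ["# panclock run report", ""]

    gs_path = out_dir / "gene_sets.tsv"
    lines.append("## Derived gene sets")
    if gs_path.exists():
        gs = pd.read_csv(gs_path, sep="\t")
        loss = gs.loc[gs["set"] == "clock_loss", "gene"].tolist()
        gain = gs.loc[gs["set"] == "clock_gain", "gene"].tolist()
        if not loss and not gain:
            lines.append("no genes passed derivation")
        lines.append(f"Clock^Loss members ({len(loss)}): {', '.join(loss) or '-'}")
        lines.append(f"Clock^Gain members ({len(gain)}): {', '.join(gain) or '-'}")
    else:
        lines.append("ABSENT: gene_sets.tsv")
    lines.append("")

    sv_path = out_dir / "survival_summary.tsv"
    lines.append("## Survival models (per cohort)")
    if sv_path.exists():
        sv = pd.read_csv(sv_path, sep="\t")
        lines.append(sv.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
    else:
        lines.append("ABSENT: survival_summary.tsv")
    lines.append("")

    xt_path = out_dir / "crosstalk_summary.tsv"
    lines.append("## Hypoxia-clock crosstalk")
    if xt_path.exists():
        xt = pd.read_csv(xt_path, sep="\t")
        lines.append(xt.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
    else:
        lines.append("ABSENT: crosstalk_summary.tsv")
    lines.append("")

    text = "\n".join(lines)
    (out_dir / "report.md").write_text(text)
    return text
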