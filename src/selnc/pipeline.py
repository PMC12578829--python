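"""End-to-end orchestration: catalogue -> RIDL -> differential expression
-> prognosis, with a final candidate report and a reproducibility manifest.

A candidate receives the final flag only when all four conditions hold:
SE-associated, differentially expressed in the target subtype,
prognostic, and carrying a valid RIDL.  All stage outputs are persisted;
the manifest records seeds, parameters and checksums of inputs and
outputs (wall times go to a separate log so reruns are bitwise
reproducible).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from selnc import __version__
from selnc.formats_io import (
    read_bed,
    read_clinical,
    read_fasta,
    read_gtf,
    read_matrix,
)
from selnc.se_catalog import chromosome_density, identify_se_lncrnas
from selnc.ridl_seekrp import (
    RIDLParams,
    ScoringScheme,
    build_kmer_reference,
    call_ridls,
    classify_se_lncrna,
)
from selnc.expression_analytics import subtype_de_summary
from selnc.survival_prognosis import (
    lasso_cox_path,
    risk_group_analysis,
    risk_score,
    rsf_fit,
    feature_importance,
    time_dependent_auc,
    univariate_screen,
)

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    se_bed: str
    genes_gtf: str
    transcripts_fasta: str
    te_fasta: str
    functional_ref_fasta: str
    expression_tsv: str
    clinical_tsv: str
    out_dir: str
    seed: int = 0
    catalog_mode: str = "gene_overlap"
    tss_window_bp: int = 2000
    biotype_filter: str = "any"
    target_subtype: str = "Basal"
    de_alpha: float = 0.05
    de_lfc_min: float = 1.0
    screen_alpha: float = 0.05
    lasso_folds: int = 5
    lasso_rule: str = "1se"
    n_trees: int = 200
    min_node_events: int = 3
    auc_horizon: float | None = None
    kmer_k: int = 4
    align: dict = field(default_factory=dict)
    ridl: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        cfg = cls(**data)
        for key in ("se_bed", "genes_gtf", "transcripts_fasta", "te_fasta",
                    "functional_ref_fasta", "expression_tsv", "clinical_tsv"):
            p = Path(getattr(cfg, key))
            if not p.exists():
                raise FileNotFoundError(f"input {key} not found: {p}")
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> pd.DataFrame:
    """Execute every stage, persist artifacts and return the candidate report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    counts: dict[str, int] = {}

    def stage(name):
        class _Ctx:
            def __enter__(self_inner):
                logger.info("stage %s started", name)
                self_inner.t0 = _time.perf_counter()
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                timings[name] = _time.perf_counter() - self_inner.t0
                if exc is not None:
                    logger.error("stage %s failed: %s", name, exc)
                    raise StageError(name, exc)
                logger.info("stage %s done in %.2fs", name, timings[name])
        return _Ctx()

    with stage("load"):
        ses = read_bed(config.se_bed)
        genes = read_gtf(config.genes_gtf, config.biotype_filter)
        transcripts = read_fasta(config.transcripts_fasta)
        te_library = read_fasta(config.te_fasta)
        functional_ref = read_fasta(config.functional_ref_fasta)
        expression = read_matrix(config.expression_tsv)
        clinical = read_clinical(config.clinical_tsv)

    with stage("catalog"):
        catalog = identify_se_lncrnas(ses, genes, mode=config.catalog_mode,
                                      window_bp=config.tss_window_bp)
        catalog.write(out / "catalog.tsv")
        chromosome_density(catalog, genes).to_csv(out / "density.tsv",
                                                  sep="\t", index=False)
        se_lncrnas = sorted(catalog.se_lncrna_ids)
        counts["se_lncrnas"] = len(se_lncrnas)

    if not se_lncrnas:
        logger.warning("no SE-lncRNAs identified; emitting empty report")
        report = pd.DataFrame(columns=[
            "gene_id", "de_target", "prognostic", "risk_model_member",
            "ridl_status", "final_flag"])
        report.to_csv(out / "report.tsv", sep="\t", index=False)
        (out / "manifest.json").write_text(json.dumps({
            "version": __version__, "seed": config.seed,
            "counts": {**counts, "final_flagged": 0}}, indent=2))
        return report

    with stage("ridl"):
        scheme = ScoringScheme(**config.align)
        params = RIDLParams(shuffle_seed=config.seed, **config.ridl)
        reference = build_kmer_reference(functional_ref, k=config.kmer_k)
        seq_of = {t.id: t for t in transcripts}
        ridl_status: dict[str, str] = {}
        ridl_rows = []
        for gid in se_lncrnas:
            if gid not in seq_of:
                ridl_status[gid] = "no_RIDL"
                continue
            calls = call_ridls(seq_of[gid], te_library, reference, scheme, params)
            ridl_status[gid] = classify_se_lncrna(calls)
            for c in calls:
                frag = c.fragment or ("", "")
                ridl_rows.append((
                    gid, ridl_status[gid], frag[0], frag[1], c.klass,
                    c.family or "", c.hit.score if c.hit else "",
                    c.hit.identity if c.hit else "",
                    "" if c.kmer_delta is None else c.kmer_delta,
                ))
        pd.DataFrame(ridl_rows, columns=[
            "seq_id", "status", "fragment_start", "fragment_end", "klass",
            "family", "score", "identity", "kmer_delta"]).to_csv(
            out / "ridl_calls.tsv", sep="\t", index=False)
        counts["valid_ridl"] = sum(s == "valid_RIDL" for s in ridl_status.values())

    with stage("de"):
        shared_samples = [sid for sid in expression.sample_ids
                          if sid in set(clinical.sample_ids)]
        if clinical.subtype is None:
            raise ValueError("clinical table lacks a subtype column")
        sub_of = dict(zip(clinical.sample_ids, clinical.subtype))
        col_idx = [expression.sample_ids.index(sid) for sid in shared_samples]
        sub_expr = expression.subset_features(
            [f for f in expression.feature_ids if f in set(se_lncrnas)])
        from selnc.formats_io import ExpressionMatrix as _EM
        sub_expr = _EM(sub_expr.feature_ids, shared_samples,
                       sub_expr.values[:, col_idx], expression.scale)
        labels = [sub_of[sid] for sid in shared_samples]
        de = subtype_de_summary(sub_expr, labels, alpha=config.de_alpha,
                                lfc_min=config.de_lfc_min)
        de_rows = []
        for sub, results in de["results"].items():
            for r in results:
                de_rows.append((r.feature_id, sub, r.log2fc, r.t_mod, r.p, r.q,
                                int(r.feature_id in de["de_sets"][sub])))
        pd.DataFrame(de_rows, columns=[
            "feature", "subtype", "log2fc", "t_mod", "p", "q", "de_flag"]).to_csv(
            out / "de.tsv", sep="\t", index=False)
        de_target = de["de_sets"].get(config.target_subtype, set())
        counts["de_target"] = len(de_target)

    with stage("prognosis"):
        X = sub_expr.values.T  # sample x feature
        time_v = np.array([clinical.time[clinical.sample_ids.index(s)]
                           for s in shared_samples])
        event_v = np.array([clinical.event[clinical.sample_ids.index(s)]
                            for s in shared_samples])
        screen = univariate_screen(X, time_v, event_v,
                                   feature_ids=sub_expr.feature_ids,
                                   alpha=config.screen_alpha)
        pd.DataFrame({
            "feature": screen.feature_ids, "beta": screen.beta,
            "p": screen.p, "q": screen.q, "logrank_p": screen.logrank_p,
        }).to_csv(out / "screen.tsv", sep="\t", index=False)
        prognostic = set(screen.significant)
        counts["prognostic"] = len(prognostic)

        # funnel intersection (both orders give the same set; record both)
        candidates = sorted(prognostic & de_target)
        (out / "funnel.json").write_text(json.dumps({
            "prognostic_then_de": sorted(prognostic & de_target),
            "de_then_prognostic": sorted(de_target & prognostic),
        }, indent=2))

        selected = candidates
        fidx = {f: i for i, f in enumerate(sub_expr.feature_ids)}
        if len(candidates) >= 2:
            try:
                path = lasso_cox_path(
                    X[:, [fidx[f] for f in candidates]], time_v, event_v,
                    feature_ids=candidates, cv_folds=config.lasso_folds,
                    rule=config.lasso_rule, seed=config.seed)
                pd.DataFrame(path.beta, index=path.feature_ids,
                             columns=[f"{l:.6g}" for l in path.lambdas]).to_csv(
                    out / "lasso_path.tsv", sep="\t")
                if path.selected_features:
                    selected = path.selected_features
            except ValueError as exc:
                logger.warning("LASSO selection skipped: %s", exc)
        (out / "selected.txt").write_text("".join(f"{f}\n" for f in selected))

        scores = np.zeros(len(shared_samples))
        model = None
        if selected and event_v.sum() >= 2:
            model = rsf_fit(X[:, [fidx[f] for f in selected]], time_v, event_v,
                            feature_ids=selected, n_trees=config.n_trees,
                            min_node_events=config.min_node_events,
                            seed=config.seed)
            scores = risk_score(model, X[:, [fidx[f] for f in selected]])
        pd.DataFrame({"sample": shared_samples, "risk_score": scores}).to_csv(
            out / "risk_scores.tsv", sep="\t", index=False,
            float_format="%.10g")

        horizon = config.auc_horizon or float(np.median(time_v))
        auc_rows = []
        if model is not None:
            try:
                auc_rows.append((horizon,
                                 time_dependent_auc(scores, time_v, event_v, horizon)))
            except ValueError as exc:
                logger.warning("AUC at t=%.3g unavailable: %s", horizon, exc)
            try:
                rga = risk_group_analysis(scores, time_v, event_v)
                (out / "km_logrank.json").write_text(json.dumps({
                    "chi2": rga.chi2, "logrank_p": rga.logrank_p,
                    "score_time_rho": rga.score_time_rho,
                    "threshold": rga.threshold}, indent=2))
            except ValueError as exc:
                logger.warning("risk-group analysis unavailable: %s", exc)
            imp = feature_importance(model, X[:, [fidx[f] for f in selected]],
                                     time_v, event_v, seed=config.seed)
            pd.DataFrame(imp, columns=["feature", "importance"]).to_csv(
                out / "importance.tsv", sep="\t", index=False,
                float_format="%.10g")
        pd.DataFrame(auc_rows, columns=["horizon", "auc"]).to_csv(
            out / "auc.tsv", sep="\t", index=False, float_format="%.10g")

    with stage("report"):
        rows = []
        selected_set = set(selected)
        for gid in se_lncrnas:
            de_flag = gid in de_target
            prog_flag = gid in prognostic
            ridl = ridl_status.get(gid, "no_RIDL")
            final = de_flag and prog_flag and ridl == "valid_RIDL"
            rows.append((gid, int(de_flag), int(prog_flag),
                         int(gid in selected_set), ridl, int(final)))
        report = pd.DataFrame(rows, columns=[
            "gene_id", "de_target", "prognostic", "risk_model_member",
            "ridl_status", "final_flag"])
        report.to_csv(out / "report.tsv", sep="\t", index=False)
        counts["final_flagged"] = int(report["final_flag"].sum())

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {k: v for k, v in vars(config).items()},
        "inputs": {k: _sha256(Path(getattr(config, k)))
                   for k in ("se_bed", "genes_gtf", "transcripts_fasta",
                             "te_fasta", "functional_ref_fasta",
                             "expression_tsv", "clinical_tsv")},
        "outputs": {p.name: _sha256(p) for p in sorted(out.glob("*.tsv"))},
        "counts": counts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    (out / "run.log").write_text(
        "".join(f"{k}\t{v:.3f}s\n" for k, v in timings.items()))
    return report
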