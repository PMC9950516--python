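"""End-to-end pipeline: raw recordings -> hemoglobin -> connectivity ->
topology -> group statistics -> tidy result tables.

The stage order and statistical plan mirror the resting-state analysis the
package implements: HbO-only connectivity, midline removal, Fisher-z
rectification, a 0.40-0.90 threshold sweep with AUC summaries, two-sample
t-tests (plain for global metrics, BH-FDR-corrected across edges and across
the ten ROIs for nodal metrics), and Pearson correlations between the
significantly different nodal metrics and the CRS-R scales within the
patient group.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .connectivity import (DEFAULT_THRESHOLDS, ConnectivityMatrix,
                           build_connectivity, edge_profile, group_mean_matrix)
from .metrics import (GLOBAL_METRIC_NAMES, NODAL_METRIC_NAMES,
                      metric_curves_and_auc, roi_average)
from .montage import (ChannelAtlas, RawIntensitySeries, SubjectRecord,
                      ValidationError, demographics_summary)
from .preprocess import PreprocessConfig, run_preprocess
from .stats import (chi_square_2x2, crsr_correlation,
                    edgewise_comparison, normality_check, two_sample_t,
                    bh_fdr)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]

CRSR_SCALES = ("total", "auditory", "visual", "motor", "oromotor",
               "communication", "arousal")


@dataclass
class RunConfig:
    """Everything the pipeline needs beyond the data itself."""

    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    threshold_scale: str = "r"  # binarize on r (default) or rectified z
    n_nulls: int = 100
    compute_sigma: bool = True
    seed: int = 0
    alpha_global: float = 0.05
    alpha_nodal: float = 0.05
    alpha_edge: float = 0.01
    fdr_method: str = "fdr_bh"
    t_variant: str = "student"
    disconnected: str = "exclude"
    gate_correlations: bool = True  # only correlate significant metrics
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["thresholds"] = [float(t) for t in self.thresholds]
        d["preprocess"]["band_hz"] = list(self.preprocess.band_hz)
        d["preprocess"]["mbll"] = {
            "extinction": np.asarray(self.preprocess.mbll.extinction).tolist(),
            "dpf": np.asarray(self.preprocess.mbll.dpf).tolist(),
            "distance_cm": self.preprocess.mbll.distance_cm,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        from .preprocess import MbllCoefficients

        d = dict(d)
        pp = dict(d.pop("preprocess", {}))
        if "mbll" in pp:
            pp["mbll"] = MbllCoefficients(**pp["mbll"])
        if "band_hz" in pp:
            pp["band_hz"] = tuple(pp["band_hz"])
        if "thresholds" in d:
            d["thresholds"] = tuple(d["thresholds"])
        known = cls.__dataclass_fields__
        bad = [k for k in list(d) + list(pp) if k not in known
               and k not in PreprocessConfig.__dataclass_fields__]
        if bad:
            raise ValidationError(f"unknown config keys: {bad}")
        return cls(preprocess=PreprocessConfig(**pp), **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


@dataclass
class PipelineResult:
    config: RunConfig
    included: list[str]
    excluded: dict[str, str]  # subject id -> reason
    matrices: dict[str, ConnectivityMatrix]
    group_mean_z: dict[str, np.ndarray]
    edge_profiles: pd.DataFrame
    global_auc: pd.DataFrame  # subject, group, metric, auc
    nodal_auc: pd.DataFrame  # subject, group, hemisphere, roi, metric, auc
    demographics: pd.DataFrame
    gender_chi2: tuple[float, float] | None
    global_tests: pd.DataFrame
    nodal_tests: pd.DataFrame
    edge_tests: pd.DataFrame
    correlations: pd.DataFrame
    normality: pd.DataFrame
    log: list[str]

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.config.to_yaml(out / "config.yaml")
        nodes = None
        for sid, m in self.matrices.items():
            nodes = m.nodes
            break
        for group, z in self.group_mean_z.items():
            pd.DataFrame(z, index=nodes, columns=nodes).to_csv(
                out / f"group_mean_z_{group}.tsv", sep="\t")
        self.edge_profiles.to_csv(out / "edge_profiles.tsv", sep="\t",
                                  index=False)
        self.global_auc.to_csv(out / "global_auc.tsv", sep="\t", index=False)
        self.nodal_auc.to_csv(out / "nodal_auc.tsv", sep="\t", index=False)
        self.demographics.to_csv(out / "demographics.tsv", sep="\t")
        self.global_tests.to_csv(out / "global_tests.tsv", sep="\t", index=False)
        self.nodal_tests.to_csv(out / "nodal_tests.tsv", sep="\t", index=False)
        self.edge_tests.to_csv(out / "significant_edges.tsv", sep="\t",
                               index=False)
        self.correlations.to_csv(out / "crsr_correlations.tsv", sep="\t",
                                 index=False)
        self.normality.to_csv(out / "normality.tsv", sep="\t", index=False)
        meta = {"included": self.included, "excluded": self.excluded}
        (out / "subjects.json").write_text(json.dumps(meta, indent=1,
                                                      sort_keys=True))
        (out / "pipeline.log").write_text("\n".join(self.log) + "\n")


def _comparison_row(comp, metric, **extra) -> dict:
    return {"metric": metric,
            "mean_hc": comp.mean_a, "sd_hc": comp.sd_a, "n_hc": comp.n_a,
            "mean_mcs": comp.mean_b, "sd_mcs": comp.sd_b, "n_mcs": comp.n_b,
            "t": comp.t, "df": comp.df, "p_raw": comp.p_raw, **extra}


def run_pipeline(
    raws: list[RawIntensitySeries],
    records: list[SubjectRecord],
    atlas: ChannelAtlas,
    config: RunConfig | None = None,
) -> PipelineResult:
    """Run the complete analysis on a cohort held in memory.

    ``records`` supplies the group label (HC/MCS) and clinical scores for
    every subject id appearing in ``raws``.
    """
    cfg = config or RunConfig()
    log: list[str] = [f"pipeline config: seed={cfg.seed}, "
                      f"thresholds={list(cfg.thresholds)}, "
                      f"n_nulls={cfg.n_nulls}, sigma={cfg.compute_sigma}"]
    record_by_id = {r.id: r for r in records}
    missing = [r.subject_id for r in raws if r.subject_id not in record_by_id]
    if missing:
        raise ValidationError(f"no clinical record for subjects: {missing}")
    for rec in records:
        if rec.total_mismatch:
            log.append(f"{rec.id}: stored CRS-R total {rec.stored_total} != "
                       f"subscale sum {rec.crsr_total}; using the sum")

    # --- stage 1: preprocessing with subject exclusion ------------------
    hbo_by_id: dict[str, np.ndarray] = {}
    excluded: dict[str, str] = {}
    for raw in raws:
        res = run_preprocess(raw, cfg.preprocess)
        log.extend(res.log)
        if res.excluded:
            excluded[raw.subject_id] = res.exclusion_reason or "unknown"
            continue
        hbo_by_id[raw.subject_id] = res.hemo.hbo
    included = sorted(hbo_by_id)
    log.append(f"included {len(included)} subjects, excluded {len(excluded)}")
    if len(included) < 4:
        raise ValidationError("too few subjects after exclusion")

    # --- stage 2: connectivity -----------------------------------------
    matrices = {sid: build_connectivity(hbo_by_id[sid], atlas)
                for sid in included}
    group_of = {sid: record_by_id[sid].group for sid in included}
    groups = ("HC", "MCS")
    ids_by_group = {g: [sid for sid in included if group_of[sid] == g]
                    for g in groups}
    for g in groups:
        if len(ids_by_group[g]) < 2:
            raise ValidationError(f"group {g} has fewer than 2 subjects")
    group_mean_z = {g: group_mean_matrix([matrices[s] for s in ids_by_group[g]])
                    for g in groups}

    prof_rows = []
    for sid in included:
        prof = edge_profile(matrices[sid], cfg.thresholds,
                            scale=cfg.threshold_scale)
        row = {"subject": sid, "group": group_of[sid],
               "mean_edges": prof.mean_count}
        row.update({f"tau_{t:.2f}": c
                    for t, c in zip(prof.thresholds, prof.counts)})
        prof_rows.append(row)
    edge_profiles = pd.DataFrame(prof_rows)

    # --- stage 3: topology sweep + AUC ----------------------------------
    rng = np.random.default_rng(cfg.seed)
    glob_rows, nodal_rows = [], []
    for sid in included:
        curves = metric_curves_and_auc(
            matrices[sid], cfg.thresholds, n_nulls=cfg.n_nulls,
            seed=int(rng.integers(0, 2**31 - 1)),
            compute_sigma=cfg.compute_sigma, scale=cfg.threshold_scale,
            disconnected=cfg.disconnected)
        for name in GLOBAL_METRIC_NAMES:
            if name not in curves:
                continue
            glob_rows.append({"subject": sid, "group": group_of[sid],
                              "metric": name, "auc": curves[name].auc})
        for name in NODAL_METRIC_NAMES:
            per_roi = roi_average(curves[name].auc, matrices[sid].nodes, atlas)
            for (hemi, roi), value in sorted(per_roi.items()):
                nodal_rows.append({"subject": sid, "group": group_of[sid],
                                   "hemisphere": hemi, "roi": roi,
                                   "metric": name, "auc": value})
    global_auc = pd.DataFrame(glob_rows)
    nodal_auc = pd.DataFrame(nodal_rows)

    # --- stage 4: demographics ------------------------------------------
    incl_records = [record_by_id[sid] for sid in included]
    demographics = demographics_summary(incl_records)
    gender_chi2 = None
    if all(g in demographics.index for g in groups):
        table = np.array([[demographics.loc[g, "male"],
                           demographics.loc[g, "female"]] for g in groups],
                         dtype=int)
        try:
            gender_chi2 = chi_square_2x2(table)
            log.append(f"gender chi-square: chi2={gender_chi2[0]:.3f} "
                       f"p={gender_chi2[1]:.3f}")
        except ValidationError as exc:
            log.append(f"gender chi-square skipped: {exc}")

    # --- stage 5: group statistics --------------------------------------
    def group_values(df, metric, g, **sel):
        q = (df["metric"] == metric) & (df["group"] == g)
        for k, v in sel.items():
            q &= df[k] == v
        return df.loc[q, "auc"].to_numpy()

    norm_rows = []
    glob_test_rows = []
    # edge-count comparison (total number of edges = mean over thresholds)
    hc_e = edge_profiles.loc[edge_profiles.group == "HC", "mean_edges"]
    mcs_e = edge_profiles.loc[edge_profiles.group == "MCS", "mean_edges"]
    comp = two_sample_t(hc_e, mcs_e, cfg.t_variant, "edge_count",
                        alpha=cfg.alpha_global)
    glob_test_rows.append(_comparison_row(comp, "edge_count",
                                          significant=comp.significant))
    for metric in GLOBAL_METRIC_NAMES:
        if metric == "sigma" and not cfg.compute_sigma:
            continue
        a = group_values(global_auc, metric, "HC")
        b = group_values(global_auc, metric, "MCS")
        for g, vals in (("HC", a), ("MCS", b)):
            try:
                w, p = normality_check(vals)
                norm_rows.append({"variable": f"{metric}_auc", "group": g,
                                  "W": w, "p": p})
            except ValidationError:
                pass
        comp = two_sample_t(a, b, cfg.t_variant, metric,
                            alpha=cfg.alpha_global)
        glob_test_rows.append(_comparison_row(comp, metric,
                                              significant=comp.significant))
    global_tests = pd.DataFrame(glob_test_rows)

    nodal_test_rows = []
    for metric in NODAL_METRIC_NAMES:
        rois = sorted({(h, r) for h, r in
                       zip(nodal_auc.hemisphere, nodal_auc.roi)})
        comps = []
        for hemi, roi in rois:
            a = group_values(nodal_auc, metric, "HC", hemisphere=hemi, roi=roi)
            b = group_values(nodal_auc, metric, "MCS", hemisphere=hemi, roi=roi)
            comps.append(((hemi, roi),
                          two_sample_t(a, b, cfg.t_variant,
                                       f"{metric}_{hemi}_{roi}",
                                       alpha=cfg.alpha_nodal)))
        p_adj, reject = bh_fdr(np.array([c.p_raw for _, c in comps]),
                               q=cfg.alpha_nodal, method=cfg.fdr_method)
        for ((hemi, roi), c), pa, rej in zip(comps, p_adj, reject):
            nodal_test_rows.append({
                **_comparison_row(c, metric), "hemisphere": hemi, "roi": roi,
                "p_fdr": pa, "significant": bool(rej)})
    nodal_tests = pd.DataFrame(nodal_test_rows)

    z_hc = np.stack([matrices[s].z for s in ids_by_group["HC"]])
    z_mcs = np.stack([matrices[s].z for s in ids_by_group["MCS"]])
    edge_tests = edgewise_comparison(z_hc, z_mcs, alpha=cfg.alpha_edge,
                                     fdr_method=cfg.fdr_method,
                                     variant=cfg.t_variant)
    nodes = matrices[included[0]].nodes
    edge_tests.insert(0, "channel_i", [nodes[i] for i in edge_tests["i"]])
    edge_tests.insert(1, "channel_j", [nodes[j] for j in edge_tests["j"]])
    n_sig = int(edge_tests["significant"].sum())
    log.append(f"edgewise comparison: {n_sig} significant connections "
               f"(p<{cfg.alpha_edge} FDR)")

    # --- stage 6: CRS-R correlations (patient group) ---------------------
    corr_rows = []
    mcs_ids = ids_by_group["MCS"]
    sig_nodal = nodal_tests[nodal_tests["significant"]] if cfg.gate_correlations \
        else nodal_tests
    for _, row in sig_nodal.iterrows():
        metric, hemi, roi = row["metric"], row["hemisphere"], row["roi"]
        sel = ((nodal_auc.metric == metric) & (nodal_auc.group == "MCS")
               & (nodal_auc.hemisphere == hemi) & (nodal_auc.roi == roi))
        vals = (nodal_auc.loc[sel].set_index("subject")
                .loc[mcs_ids, "auc"].to_numpy())
        for scale in CRSR_SCALES:
            scores = np.array([
                record_by_id[s].crsr_total if scale == "total"
                else record_by_id[s].crsr_subscales[scale] for s in mcs_ids],
                dtype=float)
            try:
                res = crsr_correlation(vals, scores,
                                       metric=f"{metric}_{hemi}_{roi}",
                                       scale=scale)
            except ValidationError as exc:
                log.append(f"correlation skipped ({metric} {hemi} {roi} "
                           f"vs {scale}): {exc}")
                continue
            corr_rows.append({"metric": res.metric, "scale": res.scale,
                              "r": res.r, "p": res.p, "n": res.n})
    sig_global = global_tests[global_tests["significant"]] if cfg.gate_correlations \
        else global_tests
    for _, row in sig_global.iterrows():
        metric = row["metric"]
        if metric == "edge_count":
            vals = (edge_profiles.set_index("subject")
                    .loc[mcs_ids, "mean_edges"].to_numpy())
        else:
            sel = (global_auc.metric == metric) & (global_auc.group == "MCS")
            vals = (global_auc.loc[sel].set_index("subject")
                    .loc[mcs_ids, "auc"].to_numpy())
        for scale in CRSR_SCALES:
            scores = np.array([
                record_by_id[s].crsr_total if scale == "total"
                else record_by_id[s].crsr_subscales[scale] for s in mcs_ids],
                dtype=float)
            try:
                res = crsr_correlation(vals, scores, metric=metric,
                                       scale=scale)
            except ValidationError as exc:
                log.append(f"correlation skipped ({metric} vs {scale}): {exc}")
                continue
            corr_rows.append({"metric": res.metric, "scale": res.scale,
                              "r": res.r, "p": res.p, "n": res.n})
    correlations = pd.DataFrame(
        corr_rows, columns=["metric", "scale", "r", "p", "n"])

    return PipelineResult(
        config=cfg, included=included, excluded=excluded, matrices=matrices,
        group_mean_z=group_mean_z, edge_profiles=edge_profiles,
        global_auc=global_auc, nodal_auc=nodal_auc,
        demographics=demographics, gender_chi2=gender_chi2,
        global_tests=global_tests, nodal_tests=nodal_tests,
        edge_tests=edge_tests, correlations=correlations,
        normality=pd.DataFrame(norm_rows, columns=["variable", "group",
                                                   "W", "p"]),
        log=log)
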