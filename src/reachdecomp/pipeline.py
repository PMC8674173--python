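"""End-to-end orchestration: simulate -> preprocess -> decompose ->
features -> fit -> evaluate.

`run_pipeline` is a pure function of its `PipelineConfig` (including
the seed): re-running with the same config reproduces every artifact.
A single seed fans out deterministically to per-stage child seeds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict, fields, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import features as feat
from . import morphology as morph
from . import stats as st
from .models import ModelConfig, loso_classify, loso_regress
from .preprocess import preprocess_recording
from .segment import decompose_velocity, elements_to_frame
from .simulate import ParticipantRecord, SimParams, simulate_cohort, write_cohort

log = logging.getLogger("reachdecomp")


@dataclass
class CohortConfig:
    n_healthy: int = 10
    n_ataxia: int = 20
    n_parkinsonism: int = 0
    severity_range: tuple[float, float] = (3.0, 24.0)
    pediatric_fraction: float = 0.15
    repeat_visits: int = 0
    visit_drift_mean: float = 0.5
    visit_drift_sd: float = 1.0


@dataclass
class PipelineConfig:
    out_dir: str = "pipeline_out"
    seed: int = 0
    log_level: str = "INFO"
    write_recordings: bool = False
    cohort: CohortConfig = field(default_factory=CohortConfig)
    features: feat.FeatureConfig = field(default_factory=feat.FeatureConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    sim_overrides: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        def build(dc_cls, data):
            allowed = {f.name for f in fields(dc_cls)}
            unknown = set(data) - allowed
            if unknown:
                raise ValueError(f"unknown config keys for {dc_cls.__name__}: {sorted(unknown)}")
            return data

        raw = dict(raw)
        build(cls, raw)
        kwargs = dict(raw)
        if "cohort" in kwargs:
            cc = dict(build(CohortConfig, kwargs["cohort"]))
            if "severity_range" in cc:
                cc["severity_range"] = tuple(cc["severity_range"])
            kwargs["cohort"] = CohortConfig(**cc)
        if "features" in kwargs:
            fc = dict(build(feat.FeatureConfig, kwargs["features"]))
            if "excluded_features" in fc:
                fc["excluded_features"] = tuple(fc["excluded_features"])
            kwargs["features"] = feat.FeatureConfig(**fc)
        if "model" in kwargs:
            mc = dict(build(ModelConfig, kwargs["model"]))
            if "length_scale_bounds" in mc:
                mc["length_scale_bounds"] = tuple(mc["length_scale_bounds"])
            kwargs["model"] = ModelConfig(**mc)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cohort"]["severity_range"] = list(d["cohort"]["severity_range"])
        d["features"]["excluded_features"] = list(d["features"]["excluded_features"])
        d["model"]["length_scale_bounds"] = list(d["model"]["length_scale_bounds"])
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[stage: {stage}] {cause}")
        self.stage = stage


@dataclass
class PipelineResult:
    report: st.EvaluationReport
    manifest: pd.DataFrame
    elements: pd.DataFrame
    feature_table: pd.DataFrame
    estimates: pd.DataFrame
    paths: dict


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2**31 - 1)) for c in ss.spawn(n)]


def decompose_cohort(records: list[ParticipantRecord], feature_cfg=None):
    """Preprocess + decompose every recording of a cohort.

    Returns (retained elements list, per-(participant, visit) element
    dict, normalized profile arrays aligned with the elements).
    """
    all_elements = []
    for rec in records:
        for hand, recording in rec.recordings.items():
            vs = preprocess_recording(recording)
            kept, _ = decompose_velocity(vs)
            all_elements.extend(kept)
    return all_elements


def _morphology_scores(elements):
    """LOSO PC scores per element, grouped by participant."""
    shapes = np.array([morph.normalize_element(e.profile) for e in elements])
    pids = np.array([e.participant_id for e in elements])
    profiles_by_pid = {pid: shapes[pids == pid] for pid in pd.unique(pids)}
    scores_by_pid = morph.loso_scores(profiles_by_pid)
    # re-expand to per-element order
    scores = np.empty((len(elements), 2))
    for pid in profiles_by_pid:
        scores[pids == pid] = scores_by_pid[pid]
    return shapes, scores


def build_cohort_features(
    elements,
    config: feat.FeatureConfig | None = None,
    hand: str | None = None,
    precomputed_scores=None,
):
    """Feature table over a cohort's retained elements.

    ``hand`` restricts the vector to one hand's elements (used for the
    hand-specific model variants); morphology PCA scores stay those of
    the cohort-level LOSO fit.
    """
    config = config or feat.FeatureConfig()
    if precomputed_scores is None:
        _, scores = _morphology_scores(elements)
    else:
        scores = precomputed_scores
    by_key: dict = {}
    for i, e in enumerate(elements):
        by_key.setdefault((e.participant_id, e.visit_id), []).append(i)
    vectors = {}
    for key, idx in by_key.items():
        if hand is not None:
            idx = [i for i in idx if elements[i].hand == hand]
        sub = [elements[i] for i in idx]
        if len(sub) < config.min_elements:
            log.warning("skipping %s: too few elements", key)
            continue
        vectors[key] = feat.build_feature_vector(
            sub, scores[idx, 0], scores[idx, 1], config
        )
    return feat.feature_table(vectors, config)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _child_seeds(config.seed, 4)
    paths: dict = {}

    # ---- simulate -------------------------------------------------------
    try:
        c = config.cohort
        if c.n_healthy + c.n_ataxia + c.n_parkinsonism == 0:
            raise ValueError("cohort is empty: nothing to simulate")
        base = SimParams(**config.sim_overrides) if config.sim_overrides else None
        records = simulate_cohort(
            c.n_healthy,
            c.n_ataxia,
            c.n_parkinsonism,
            seed=seeds[0],
            severity_range=tuple(c.severity_range),
            pediatric_fraction=c.pediatric_fraction,
            repeat_visits=c.repeat_visits,
            visit_drift_mean=c.visit_drift_mean,
            visit_drift_sd=c.visit_drift_sd,
            base_params=base,
        )
        manifest = pd.DataFrame(
            [
                dict(
                    participant_id=r.participant_id,
                    visit_id=r.visit_id,
                    group=r.group,
                    clinical_score=r.clinical_score,
                    score_scale=r.score_scale,
                    upper_limb_score=r.upper_limb_score,
                    severity=r.severity,
                    pediatric_flag=r.pediatric_flag,
                    handedness=r.handedness,
                )
                for r in records
            ]
        )
        if config.write_recordings:
            write_cohort(records, out / "recordings")
        paths["manifest"] = out / "manifest.csv"
        manifest.to_csv(paths["manifest"], index=False)
    except Exception as err:
        raise StageError("simulate", err) from err

    # ---- decompose ------------------------------------------------------
    try:
        elements = decompose_cohort(records)
        element_frame = elements_to_frame(elements)
        paths["elements"] = out / "elements.csv"
        element_frame.to_csv(paths["elements"], index=False)
    except Exception as err:
        raise StageError("decompose", err) from err

    # ---- features (incl. LOSO morphology) -------------------------------
    try:
        shapes, scores = _morphology_scores(elements)
        table = build_cohort_features(elements, config.features,
                                      precomputed_scores=scores)
        paths["features"] = out / "features.csv"
        table.to_csv(paths["features"])
    except Exception as err:
        raise StageError("features", err) from err

    # ---- fit ------------------------------------------------------------
    try:
        meta = manifest.set_index(["participant_id", "visit_id"]).loc[table.index]
        model_cfg = replace(config.model, random_seed=seeds[1])
        bars_mask = (meta["score_scale"] == "bars").to_numpy()
        X = table[bars_mask]
        y = meta.loc[bars_mask, "clinical_score"].to_numpy(float)
        participants = X.index.get_level_values(0).to_numpy()
        pediatric = meta.loc[bars_mask, "pediatric_flag"].to_numpy(bool)
        reg = loso_regress(X, y, participants, pediatric, model_cfg)
        estimates = reg.estimates.copy()
        estimates["severity"] = meta.loc[bars_mask, "severity"].to_numpy(float)
        estimates["group"] = meta.loc[bars_mask, "group"].to_numpy()

        # hand-specific estimates, same training protocol
        hand_estimates = {}
        for hand_kind in ("dominant", "nondominant"):
            sub_elements_hand = []
            handed = manifest.set_index(["participant_id", "visit_id"])["handedness"]
            for e in elements:
                dom = handed.loc[(e.participant_id, e.visit_id)]
                want = dom if hand_kind == "dominant" else ("left" if dom == "right" else "right")
                if e.hand == want:
                    sub_elements_hand.append(e)
            idx_map = {id(e): i for i, e in enumerate(elements)}
            sc = scores[[idx_map[id(e)] for e in sub_elements_hand]]
            t_hand = build_cohort_features(
                sub_elements_hand, config.features, precomputed_scores=sc
            )
            t_hand = t_hand.loc[t_hand.index.intersection(X.index)]
            m = meta.loc[t_hand.index]
            keep = (m["score_scale"] == "bars").to_numpy()
            res = loso_regress(
                t_hand[keep],
                m.loc[keep, "clinical_score"].to_numpy(float),
                t_hand.index.get_level_values(0).to_numpy()[keep],
                m.loc[keep, "pediatric_flag"].to_numpy(bool),
                model_cfg,
            )
            hand_estimates[hand_kind] = res.estimates["estimate"]
        estimates["estimate_dominant"] = hand_estimates["dominant"].reindex(estimates.index)
        estimates["estimate_nondominant"] = hand_estimates["nondominant"].reindex(estimates.index)
        paths["estimates"] = out / "estimates.csv"
        estimates.to_csv(paths["estimates"])

        classifications = {}
        group_all = meta["group"]
        for task, (pos, neg) in {
            "ataxia_vs_control": ("ataxia", "healthy"),
            "ataxia_vs_parkinsonism": ("ataxia", "parkinsonism"),
        }.items():
            mask = group_all.isin([pos, neg]).to_numpy()
            if len(group_all[mask].unique()) < 2:
                continue
            res = loso_classify(
                table[mask],
                group_all[mask].to_numpy(),
                table.index.get_level_values(0).to_numpy()[mask],
                meta.loc[mask, "pediatric_flag"].to_numpy(bool),
                model_cfg,
                positive_class=pos,
            )
            classifications[task] = res.estimates
    except Exception as err:
        raise StageError("fit", err) from err

    # ---- evaluate -------------------------------------------------------
    try:
        r, p = st.pearson(estimates["estimate"], estimates["label"])
        report = st.EvaluationReport(
            rmse=st.rmse(estimates["estimate"], estimates["label"]),
            r_squared=r**2,
            pearson_r=r,
            pearson_p=p,
        )
        for task, est in classifications.items():
            is_pos = (est["label"] == "ataxia").astype(int).to_numpy()
            auc, ci = st.auc_ci(est["estimate"].to_numpy(), is_pos, seed=seeds[2])
            report.auc[task] = dict(auc=auc, ci=ci)
        # reliability across repeated visits
        wide = estimates["estimate"].unstack("visit_id")
        if wide.shape[1] >= 2:
            pairs = wide.dropna()
            if len(pairs) >= 2:
                report.icc31 = st.icc31(pairs.to_numpy()[:, :2])
        # group comparison: retained element counts per participant-visit
        counts = element_frame.groupby(["participant_id", "visit_id"]).size()
        groups = [
            counts[meta.index[group_all == g]].to_numpy()
            for g in ("healthy", "ataxia", "parkinsonism")
            if (group_all == g).sum() >= 2
        ]
        if len(groups) >= 2:
            f_stat, p_anova = st.welch_anova(groups)
            report.group_tests["element_count_welch_anova"] = dict(F=f_stat, p=p_anova)
        both = estimates.dropna(subset=["estimate_dominant", "estimate_nondominant"])
        if len(both) >= 3:
            report.extras["hand_consistency_r"] = st.pearson(
                both["estimate_dominant"], both["estimate_nondominant"]
            )[0]
        paths["metrics"] = out / "metrics.json"
        report.to_json(paths["metrics"])
    except Exception as err:
        raise StageError("evaluate", err) from err

    return PipelineResult(
        report=report,
        manifest=manifest,
        elements=element_frame,
        feature_table=table,
        estimates=estimates,
        paths=paths,
    )
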