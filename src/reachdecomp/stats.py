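"""Evaluation statistics for fitted pipelines.

Point metrics (RMSE, squared Pearson), AUC with a participant-level
bootstrap percentile CI, ICC(3,1) with its F-based CI, and the group
comparison tests (Welch's ANOVA, Games-Howell post hoc, Welch's t,
one-sample t, Pearson). Standard tests are delegated to
scipy/pingouin; RMSE, the AUC bootstrap and the report container are
local.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps
from sklearn.metrics import roc_auc_score


def rmse(estimates, labels) -> float:
    e = np.asarray(estimates, dtype=float)
    y = np.asarray(labels, dtype=float)
    if e.shape != y.shape or e.size == 0:
        raise ValueError("estimates and labels must have equal non-zero length")
    return float(np.sqrt(np.mean((e - y) ** 2)))


def pearson(x, y) -> tuple[float, float]:
    r, p = sps.pearsonr(np.asarray(x, float), np.asarray(y, float))
    return float(r), float(p)


def r_squared(estimates, labels) -> float:
    """Squared Pearson correlation of estimates vs labels."""
    return pearson(estimates, labels)[0] ** 2


def coefficient_of_determination(estimates, labels) -> float:
    y = np.asarray(labels, float)
    e = np.asarray(estimates, float)
    return float(1.0 - np.sum((y - e) ** 2) / np.sum((y - np.mean(y)) ** 2))


def auc_ci(
    scores,
    labels,
    n_boot: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, tuple[float, float]]:
    """AUC (Mann-Whitney relation) with a bootstrap percentile CI.

    Bootstrap resamples participants (rows) with replacement; resamples
    with a single class are redrawn implicitly by skipping.
    """
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) != 2:
        raise ValueError("both classes must be present")
    auc = float(roc_auc_score(y, s))
    rng = np.random.default_rng(seed)
    boots = []
    n = len(y)
    while len(boots) < n_boot:
        idx = rng.integers(0, n, n)
        if len(np.unique(y[idx])) < 2:
            continue
        boots.append(roc_auc_score(y[idx], s[idx]))
    lo, hi = np.percentile(boots, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return auc, (float(lo), float(hi))


def icc31(matrix, alpha: float = 0.05) -> dict:
    """ICC(3,1): single-rater, consistency, two-way mixed effects.

    ``matrix`` is participants x repeated measures; rows with missing
    values are dropped (restricted to complete cases) with a warning.
    Computed from the two-way ANOVA mean squares,
    ICC = (MS_R - MS_E) / (MS_R + (k-1) MS_E), with the F-based CI of
    McGraw & Wong. Returns icc, (lo, hi) 95% CI, F, p.
    """
    m = pd.DataFrame(np.asarray(matrix, dtype=float))
    complete = m.dropna()
    n, k = complete.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 participants with >= 2 measures")
    if n < m.shape[0]:
        import warnings

        warnings.warn("incomplete rows dropped for ICC computation")
    x = complete.to_numpy()
    gm = x.mean()
    ss_rows = k * np.sum((x.mean(axis=1) - gm) ** 2)
    ss_cols = n * np.sum((x.mean(axis=0) - gm) ** 2)
    ss_err = np.sum((x - gm) ** 2) - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    if ms_e == 0.0:  # perfectly consistent raters
        return dict(icc=1.0, ci=(1.0, 1.0), f=float("inf"), p=0.0)
    icc = (ms_r - ms_e) / (ms_r + (k - 1) * ms_e)
    f_obs = ms_r / ms_e
    df1, df2 = n - 1, (n - 1) * (k - 1)
    p = float(sps.f.sf(f_obs, df1, df2))
    f1 = f_obs / sps.f.ppf(1 - alpha / 2, df1, df2)
    f2 = f_obs * sps.f.ppf(1 - alpha / 2, df2, df1)
    lo = (f1 - 1) / (f1 + k - 1)
    hi = (f2 - 1) / (f2 + k - 1)
    return dict(icc=float(icc), ci=(float(lo), float(hi)), f=float(f_obs), p=p)


def welch_anova(groups) -> tuple[float, float]:
    """Welch's heteroscedastic one-way ANOVA over a list of samples."""
    data = pd.concat(
        [pd.DataFrame({"y": np.asarray(g, float), "g": i}) for i, g in enumerate(groups)],
        ignore_index=True,
    )
    res = pg.welch_anova(data=data, dv="y", between="g")
    return float(res["F"].iloc[0]), float(res["p_unc"].iloc[0])


def games_howell(groups, names=None) -> pd.DataFrame:
    """Games-Howell pairwise comparisons; returns one row per pair."""
    if names is None:
        names = [str(i) for i in range(len(groups))]
    data = pd.concat(
        [
            pd.DataFrame({"y": np.asarray(g, float), "g": name})
            for name, g in zip(names, groups)
        ],
        ignore_index=True,
    )
    res = pg.pairwise_gameshowell(data=data, dv="y", between="g")
    return res.rename(columns={"pval": "p"})


def welch_t(a, b) -> tuple[float, float]:
    t, p = sps.ttest_ind(np.asarray(a, float), np.asarray(b, float), equal_var=False)
    return float(t), float(p)


def one_sample_t(deltas, popmean: float = 0.0) -> tuple[float, float]:
    x = np.asarray(deltas, dtype=float)
    if np.std(x, ddof=1) == 0:
        return (0.0, 1.0) if np.allclose(x, popmean) else (np.inf, 0.0)
    t, p = sps.ttest_1samp(x, popmean)
    return float(t), float(p)


@dataclass
class EvaluationReport:
    rmse: float | None = None
    r_squared: float | None = None
    pearson_r: float | None = None
    pearson_p: float | None = None
    auc: dict = field(default_factory=dict)  # task -> {auc, ci}
    icc31: dict | None = None
    group_tests: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = asdict(self)
        path.write_text(json.dumps(payload, indent=2, default=_jsonable))
        return path


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, pd.DataFrame):
        return x.to_dict(orient="records")
    return str(x)
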