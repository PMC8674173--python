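"""Per-participant engineered features from pooled movement elements.

The default feature vector has 53 entries:

* 27 statistical aggregations (9 each) of element duration, log
  distance, and log mean speed;
* 1 power-law scaling exponent alpha (slope of log mean speed on log
  distance);
* 9 aggregations of log-ratios of consecutive unsigned distances;
* 4 central cells of the normalized 2D histogram of consecutive signed
  AP-axis distances (the "small consecutive movements" region);
* 18 aggregations (9 each) of the first two principal-component scores
  of normalized element morphologies;

minus a fixed, documented exclusion list of the 6 least informative
aggregations (minima and ranges pinned by the exclusion thresholds).
All logarithms are natural.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .segment import MovementElement

AGG_NAMES = ("mean", "sd", "min", "max", "range", "iqr", "median", "p10", "p90")

#: default aggregations dropped to arrive at the 53-feature set
DEFAULT_EXCLUDED = (
    "duration_min",
    "duration_range",
    "log_distance_min",
    "log_speed_min",
    "log_ratio_min",
    "log_ratio_range",
)


@dataclass
class AggregationSet:
    mean: float
    sd: float
    min: float
    max: float
    range: float
    iqr: float
    median: float
    p10: float
    p90: float

    def as_dict(self, prefix: str) -> dict[str, float]:
        return {f"{prefix}_{k}": getattr(self, k) for k in AGG_NAMES}


@dataclass
class PowerLawFit:
    alpha: float
    intercept: float
    n_points: int


@dataclass
class TransitionHistogram:
    bin_edges: np.ndarray
    probabilities: np.ndarray  # (n_bins, n_bins), rows = prior element
    small_region: dict[str, float]  # named central-cell probabilities
    n_pairs: int


@dataclass
class FeatureConfig:
    small_threshold_m: float = 0.02
    n_small_cells_per_axis: int = 2
    n_outer_bins: int = 4
    hist_range_m: float = 0.5
    min_elements: int = 5
    excluded_features: tuple[str, ...] = DEFAULT_EXCLUDED

    @property
    def n_features(self) -> int:
        return 27 + 1 + 9 + self.n_small_cells_per_axis**2 + 18 - len(self.excluded_features)


def aggregate(values) -> AggregationSet:
    """Nine standard summary statistics of a non-empty sequence.

    Percentiles use linear interpolation between order statistics; the
    standard deviation is the n-1 sample version (0 for n = 1).
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("cannot aggregate an empty sequence")
    sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    p10, p25, p75, p90 = np.percentile(x, [10, 25, 75, 90])
    return AggregationSet(
        mean=float(np.mean(x)),
        sd=sd,
        min=float(np.min(x)),
        max=float(np.max(x)),
        range=float(np.max(x) - np.min(x)),
        iqr=float(p75 - p25),
        median=float(np.median(x)),
        p10=float(p10),
        p90=float(p90),
    )


def size_speed_duration_features(elements: list[MovementElement]) -> dict[str, float]:
    """27 aggregations over duration, log distance and log mean speed."""
    if not elements:
        raise ValueError("no elements")
    dur = [e.duration_s for e in elements]
    log_d = [np.log(e.distance_m) for e in elements]
    log_v = [np.log(e.mean_speed_ms) for e in elements]
    out: dict[str, float] = {}
    out.update(aggregate(dur).as_dict("duration"))
    out.update(aggregate(log_d).as_dict("log_distance"))
    out.update(aggregate(log_v).as_dict("log_speed"))
    return out


def fit_power_law(elements: list[MovementElement]) -> PowerLawFit:
    """OLS slope of log mean speed on log distance (the exponent alpha)."""
    if len(elements) < 2:
        raise ValueError("need at least two elements for a power-law fit")
    log_d = np.array([np.log(e.distance_m) for e in elements])
    log_v = np.array([np.log(e.mean_speed_ms) for e in elements])
    if np.ptp(log_d) == 0:
        raise ValueError("degenerate fit: all distances equal")
    slope, intercept = np.polyfit(log_d, log_v, 1)
    return PowerLawFit(alpha=float(slope), intercept=float(intercept), n_points=len(elements))


def _histogram_edges(config: FeatureConfig) -> np.ndarray:
    t, r = config.small_threshold_m, config.hist_range_m
    k = config.n_small_cells_per_axis
    outer_neg = np.linspace(-r, -t, config.n_outer_bins + 1)[:-1]
    small = np.linspace(-t, t, k + 1)
    outer_pos = np.linspace(t, r, config.n_outer_bins + 1)[1:]
    return np.concatenate([outer_neg, small, outer_pos])


def transition_features(
    elements_ap: list[MovementElement],
    config: FeatureConfig | None = None,
) -> TransitionHistogram:
    """Normalized 2D histogram of consecutive signed AP distances.

    Pairs are formed from temporally adjacent retained elements within
    the same hand. Features are the probabilities of the central cells
    where both elements have |signed distance| <= small_threshold_m.
    """
    config = config or FeatureConfig()
    edges = _histogram_edges(config)
    k = config.n_small_cells_per_axis
    n_bins = len(edges) - 1
    small_lo = config.n_outer_bins  # index of first small cell per axis

    prior, subseq = [], []
    for hand in sorted({e.hand for e in elements_ap}):
        els = sorted(
            (e for e in elements_ap if e.hand == hand), key=lambda e: e.start_time_s
        )
        d = [e.signed_distance_m for e in els]
        prior.extend(d[:-1])
        subseq.extend(d[1:])

    small_names = [
        f"trans_small_{i}_{j}" for i in range(k) for j in range(k)
    ]
    if len(prior) == 0:
        warnings.warn("fewer than 2 AP elements: transition features set to 0")
        probs = np.zeros((n_bins, n_bins))
        return TransitionHistogram(edges, probs, {n: 0.0 for n in small_names}, 0)

    eps = 1e-12
    lim = config.hist_range_m
    p = np.clip(prior, -lim + eps, lim - eps)
    s = np.clip(subseq, -lim + eps, lim - eps)
    counts, _, _ = np.histogram2d(p, s, bins=[edges, edges])
    probs = counts / counts.sum()
    small = {
        f"trans_small_{i}_{j}": float(probs[small_lo + i, small_lo + j])
        for i in range(k)
        for j in range(k)
    }
    return TransitionHistogram(edges, probs, small, len(prior))


def consecutive_ratio_features(elements: list[MovementElement]) -> dict[str, float]:
    """Aggregations of log(D_{i+1}/D_i) pooled over (hand, axis) streams."""
    ratios: list[float] = []
    streams = sorted({(e.hand, e.axis) for e in elements})
    for hand, axis in streams:
        els = sorted(
            (e for e in elements if e.hand == hand and e.axis == axis),
            key=lambda e: e.start_time_s,
        )
        d = np.array([e.distance_m for e in els])
        if len(d) >= 2:
            ratios.extend(np.log(d[1:] / d[:-1]))
    if not ratios:
        raise ValueError("no consecutive element pairs for ratio features")
    return aggregate(ratios).as_dict("log_ratio")


def morphology_features(pc1_scores, pc2_scores) -> dict[str, float]:
    out: dict[str, float] = {}
    out.update(aggregate(pc1_scores).as_dict("pc1"))
    out.update(aggregate(pc2_scores).as_dict("pc2"))
    return out


def feature_names(config: FeatureConfig | None = None) -> list[str]:
    """The documented, fixed feature order of the default vector."""
    config = config or FeatureConfig()
    k = config.n_small_cells_per_axis
    names = (
        [f"duration_{a}" for a in AGG_NAMES]
        + [f"log_distance_{a}" for a in AGG_NAMES]
        + [f"log_speed_{a}" for a in AGG_NAMES]
        + ["alpha"]
        + [f"log_ratio_{a}" for a in AGG_NAMES]
        + [f"trans_small_{i}_{j}" for i in range(k) for j in range(k)]
        + [f"pc1_{a}" for a in AGG_NAMES]
        + [f"pc2_{a}" for a in AGG_NAMES]
    )
    return [n for n in names if n not in config.excluded_features]


def build_feature_vector(
    elements: list[MovementElement],
    pc1_scores,
    pc2_scores,
    config: FeatureConfig | None = None,
) -> pd.Series:
    """Assemble the per-participant feature vector in documented order.

    `elements` are the retained movement elements pooled across hands
    and axes; transition features use the AP axis only. Morphology
    scores must come from a PCA that did not train on this participant.
    """
    config = config or FeatureConfig()
    if len(elements) < config.min_elements:
        raise ValueError(
            f"participant has {len(elements)} elements, fewer than "
            f"min_elements={config.min_elements}"
        )
    if pc1_scores is None or pc2_scores is None or len(pc1_scores) == 0:
        raise ValueError("missing morphology scores")
    values: dict[str, float] = {}
    values.update(size_speed_duration_features(elements))
    values["alpha"] = fit_power_law(elements).alpha
    values.update(consecutive_ratio_features(elements))
    ap = [e for e in elements if e.axis == "AP"]
    values.update(transition_features(ap, config).small_region)
    values.update(morphology_features(pc1_scores, pc2_scores))
    names = feature_names(config)
    vec = pd.Series({n: values[n] for n in names}, name="features")
    assert len(vec) == config.n_features
    return vec


def feature_table(vectors: dict, config: FeatureConfig | None = None) -> pd.DataFrame:
    """Stack per-(participant, visit) feature Series into one table."""
    df = pd.DataFrame(
        {key: vec for key, vec in vectors.items()}
    ).T
    df = df[feature_names(config)]
    df.index.names = ["participant_id", "visit_id"]
    return df
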