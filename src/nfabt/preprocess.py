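"""Cohort preprocessing pipeline.

Stages, in the order the driver enforces:

1. drop features with observed missingness above 90% (strict);
2. add 0/1 presence indicators for surviving features with missingness
   above 50% (strict; 0 = missing, 1 = present);
3. median imputation of missing continuous cells (medians over observed
   cells only);
4. categorical encodings: sex Male->1 / Female->2; cancer type
   ALL/AML/CLL/CML -> 1..4; history and behaviour flags No->0 / Yes->1;
   troponin T binarized at an assay positivity cutoff (default 0.014);
5. first-timepoint anchoring of heart rate and blood pressures
   (left-align each series to its first recorded day);
6. z-score normalization of continuous features using training-split
   statistics (min-max available via ``method="minmax"``).

Pearson correlation matrices over patient baselines are provided per
feature group for collinearity screening.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort
from .schema import FeatureSpec, CohortSchema

__all__ = [
    "PreprocessReport",
    "CorrelationMatrix",
    "drop_high_missingness",
    "add_missingness_indicators",
    "median_impute",
    "encode_features",
    "anchor_first_timepoint",
    "normalize_continuous",
    "correlation_matrix",
    "run_pipeline",
    "ANCHOR_FEATURES",
    "TROPONIN_CUTOFF",
]

logger = logging.getLogger(__name__)

ANCHOR_FEATURES = ("heart_rate", "sbp", "dbp")
TROPONIN_CUTOFF = 0.014  # ng/mL, conventional assay positivity threshold

ENCODINGS: dict[str, dict[str, int]] = {
    "sex": {"Male": 1, "Female": 2},
    "cancer_type": {"ALL": 1, "AML": 2, "CLL": 3, "CML": 4},
}
_FLAG_CODES = {"No": 0, "Yes": 1}


@dataclass
class PreprocessReport:
    """What each pipeline stage did, for audit and reuse on held-out data."""

    dropped_features: list[str] = field(default_factory=list)
    indicator_features: list[str] = field(default_factory=list)
    imputation_values: dict[str, float] = field(default_factory=dict)
    encoding_map: dict[str, dict[str, int]] = field(default_factory=dict)
    normalization_stats: dict[str, tuple[float, float]] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "dropped_features": self.dropped_features,
            "indicator_features": self.indicator_features,
            "imputation_values": self.imputation_values,
            "encoding_map": self.encoding_map,
            "normalization_stats": {k: list(v) for k, v in self.normalization_stats.items()},
            "warnings": self.warnings,
        }


def _missing_fraction(cohort: Cohort, name: str) -> float:
    spec = cohort.schema[name]
    n_missing = 0
    n_total = 0
    for r in cohort.records:
        if spec.time_varying:
            vals = r.series.get(name)
            if vals is None:
                continue
            n_total += len(vals)
            n_missing += int(np.isnan(vals).sum())
        elif name in r.static:
            n_total += 1
            v = r.static[name]
            if v is None or (isinstance(v, float) and math.isnan(v)):
                n_missing += 1
    return n_missing / n_total if n_total else 0.0


def _drop_feature(schema: CohortSchema, names: set[str]) -> CohortSchema:
    return CohortSchema(
        features=tuple(f for f in schema.features if f.name not in names),
        n_default=schema.n_default,
        horizon_default=schema.horizon_default,
    )


def _add_spec(schema: CohortSchema, spec: FeatureSpec) -> CohortSchema:
    return CohortSchema(
        features=schema.features + (spec,),
        n_default=schema.n_default,
        horizon_default=schema.horizon_default,
    )


def drop_high_missingness(
    cohort: Cohort, threshold: float = 0.90, report: PreprocessReport | None = None
) -> tuple[Cohort, PreprocessReport]:
    """Remove features whose observed missing fraction exceeds threshold
    (strict inequality)."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    report = report or PreprocessReport()
    out = cohort.copy()
    dropped = [n for n in out.schema.names if _missing_fraction(out, n) > threshold]
    for r in out.records:
        for n in dropped:
            r.series.pop(n, None)
            r.static.pop(n, None)
    out.schema = _drop_feature(out.schema, set(dropped))
    report.dropped_features.extend(dropped)
    return out, report


def add_missingness_indicators(
    cohort: Cohort, threshold: float = 0.50, report: PreprocessReport | None = None
) -> tuple[Cohort, PreprocessReport]:
    """Append ``<name>_present`` (1 = present, 0 = missing) for surviving
    features with missing fraction above threshold (strict)."""
    report = report or PreprocessReport()
    out = cohort.copy()
    for name in list(out.schema.names):
        frac = _missing_fraction(out, name)
        if frac <= threshold:
            continue
        spec = out.schema[name]
        ind_name = f"{name}_present"
        if ind_name in out.schema:
            raise ValueError(f"indicator name collision: {ind_name}")
        for r in out.records:
            if spec.time_varying:
                r.series[ind_name] = (~np.isnan(r.series[name])).astype(float)
            else:
                v = r.static.get(name)
                miss = v is None or (isinstance(v, float) and math.isnan(v))
                r.static[ind_name] = 0.0 if miss else 1.0
        out.schema = _add_spec(
            out.schema,
            FeatureSpec(
                ind_name, spec.group, "binary",
                category_counts={"0": 1, "1": 1},
                time_varying=spec.time_varying,
            ),
        )
        report.indicator_features.append(ind_name)
    return out, report


def median_impute(
    cohort: Cohort, report: PreprocessReport | None = None
) -> tuple[Cohort, PreprocessReport]:
    """Replace each missing continuous cell by the feature's median over
    observed cells; observed cells are never altered."""
    report = report or PreprocessReport()
    out = cohort.copy()
    for spec in out.schema.continuous():
        name = spec.name
        if spec.time_varying:
            observed = np.concatenate(
                [r.series[name][~np.isnan(r.series[name])] for r in out.records if name in r.series]
            )
        else:
            observed = np.array(
                [
                    r.static[name]
                    for r in out.records
                    if name in r.static
                    and r.static[name] is not None
                    and not (isinstance(r.static[name], float) and math.isnan(r.static[name]))
                ],
                dtype=float,
            )
        any_missing = any(
            np.isnan(r.series[name]).any() if spec.time_varying and name in r.series
            else (name in r.static and isinstance(r.static[name], float) and math.isnan(r.static[name]))
            for r in out.records
        )
        if not any_missing:
            continue
        if observed.size == 0:
            raise ValueError(f"feature {name!r} has no observed cells; median undefined")
        med = float(np.median(observed))
        report.imputation_values[name] = med
        for r in out.records:
            if spec.time_varying and name in r.series:
                vals = r.series[name]
                vals[np.isnan(vals)] = med
            elif name in r.static:
                v = r.static[name]
                if isinstance(v, float) and math.isnan(v):
                    r.static[name] = med
    return out, report


def encode_features(
    cohort: Cohort,
    troponin_cutoff: float = TROPONIN_CUTOFF,
    report: PreprocessReport | None = None,
) -> tuple[Cohort, PreprocessReport]:
    """Apply the fixed categorical encodings; idempotent on already-encoded
    values. Troponin T is binarized at the positivity cutoff."""
    report = report or PreprocessReport()
    out = cohort.copy()
    for spec in out.schema.features:
        if spec.kind == "continuous":
            continue
        if spec.name in ENCODINGS:
            mapping = ENCODINGS[spec.name]
        elif spec.kind == "binary" and set(spec.category_counts) == {"No", "Yes"}:
            mapping = _FLAG_CODES
        else:
            continue
        report.encoding_map[spec.name] = dict(mapping)
        codes = set(mapping.values())
        for r in out.records:
            v = r.static.get(spec.name)
            if v is None:
                continue
            if isinstance(v, (int, float)) and not isinstance(v, bool):
                if float(v) in {float(c) for c in codes}:
                    r.static[spec.name] = int(v)
                    continue
                raise ValueError(f"{spec.name}: unknown code {v!r}")
            if v not in mapping:
                raise ValueError(f"{spec.name}: unknown category {v!r}")
            r.static[spec.name] = mapping[v]
    if "troponin_t" in out.schema:
        report.encoding_map["troponin_t"] = {"negative": 0, "positive": 1}
        for r in out.records:
            if "troponin_t" in r.series:
                vals = r.series["troponin_t"]
                ok = ~np.isnan(vals)
                already = np.isin(vals[ok], (0.0, 1.0)).all() if ok.any() else True
                if not already:
                    vals[ok] = (vals[ok] > troponin_cutoff).astype(float)
    return out, report


def anchor_first_timepoint(
    cohort: Cohort, features: tuple[str, ...] = ANCHOR_FEATURES
) -> Cohort:
    """Left-align each listed series to its first non-missing recording.

    Leading missing days are removed and the remaining days re-indexed, so
    day 0 of the anchored feature is its first actual recording. Other
    series and the labels keep their original indexing; a series with no
    recording at all is an error.
    """
    out = cohort.copy()
    for r in out.records:
        for name in features:
            if name not in r.series:
                continue
            vals = r.series[name]
            obs = np.flatnonzero(~np.isnan(vals))
            if obs.size == 0:
                raise ValueError(f"{r.id}: series {name!r} is entirely missing")
            first = int(obs[0])
            if first == 0:
                continue
            shifted = np.full_like(vals, np.nan)
            shifted[: len(vals) - first] = vals[first:]
            # tail-pad with the last recorded value to preserve length
            shifted[len(vals) - first :] = vals[obs[-1]]
            r.series[name] = shifted
    return out


def normalize_continuous(
    cohort: Cohort,
    stats: dict[str, tuple[float, float]] | None = None,
    method: str = "zscore",
    report: PreprocessReport | None = None,
) -> tuple[Cohort, PreprocessReport]:
    """Scale continuous features; binary/categorical codes are untouched.

    With ``stats=None`` the (center, scale) pairs are fitted on this
    cohort and stored in the report for reuse on held-out splits; passing
    stored stats applies them unchanged. Zero-variance features are
    centered and scaled by 1 with a logged warning.
    """
    if method not in ("zscore", "minmax"):
        raise ValueError(f"unknown normalization method {method!r}")
    report = report or PreprocessReport()
    out = cohort.copy()
    fit = stats is None
    stats = {} if fit else dict(stats)
    for spec in out.schema.continuous():
        name = spec.name
        if spec.time_varying:
            allvals = np.concatenate([r.series[name] for r in out.records if name in r.series])
        else:
            allvals = np.array(
                [r.static[name] for r in out.records if name in r.static], dtype=float
            )
        if np.isnan(allvals).any():
            raise ValueError(f"{name}: missing cells remain; impute before normalizing")
        if fit:
            if method == "zscore":
                center, scale = float(allvals.mean()), float(allvals.std(ddof=0))
            else:
                center, scale = float(allvals.min()), float(allvals.max() - allvals.min())
            if scale == 0.0:
                msg = f"{name}: zero variance; scaled by 1"
                logger.warning(msg)
                report.warnings.append(msg)
                scale = 1.0
            stats[name] = (center, scale)
        if name not in stats:
            raise KeyError(f"no stored normalization stats for {name!r}")
        center, scale = stats[name]
        for r in out.records:
            if spec.time_varying and name in r.series:
                r.series[name] = (r.series[name] - center) / scale
            elif name in r.static:
                r.static[name] = (float(r.static[name]) - center) / scale
    report.normalization_stats.update(stats)
    return out, report


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric Pearson coefficient matrix over patient baselines."""

    feature_names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.feature_names),) * 2:
            raise ValueError("matrix shape does not match feature list")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("matrix is not symmetric")
        if np.nanmax(np.abs(v)) > 1.0 + 1e-12:
            raise ValueError("coefficients exceed 1 in magnitude")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_names, columns=self.feature_names)

    def heatmap(self, path: str) -> None:
        """Export a labelled heatmap (collinearity screen figure)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(0.5 * len(self.feature_names) + 2,) * 2)
        im = ax.imshow(self.values, vmin=-1, vmax=1, cmap="RdBu_r")
        ax.set_xticks(range(len(self.feature_names)), self.feature_names, rotation=90)
        ax.set_yticks(range(len(self.feature_names)), self.feature_names)
        fig.colorbar(im, ax=ax, label="Pearson r")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def correlation_matrix(cohort: Cohort, group: str) -> CorrelationMatrix:
    """Pairwise Pearson correlations of one feature group across patients
    (numeric baseline values: static codes, or day-0 series)."""
    specs = [f for f in cohort.schema.by_group(group)]
    if len(specs) < 2:
        raise ValueError(f"group {group!r} has fewer than 2 features")
    base = cohort.baseline_frame()
    cols = []
    names = []
    for spec in specs:
        col = pd.to_numeric(base[spec.name], errors="raise")
        if col.isna().any():
            raise ValueError(f"{spec.name}: missing cells; impute before correlating")
        if col.std(ddof=0) == 0.0:
            raise ValueError(f"{spec.name}: zero variance")
        cols.append(col.to_numpy(dtype=float))
        names.append(spec.name)
    mat = np.corrcoef(np.vstack(cols))
    mat = np.clip((mat + mat.T) / 2.0, -1.0, 1.0)
    return CorrelationMatrix(feature_names=tuple(names), values=mat)


def run_pipeline(
    cohort: Cohort,
    drop_threshold: float = 0.90,
    indicator_threshold: float = 0.50,
    method: str = "zscore",
    stats: dict[str, tuple[float, float]] | None = None,
) -> tuple[Cohort, PreprocessReport]:
    """Full preprocessing in the contracted stage order.

    Anchoring information (leading missing runs of the vitals) is captured
    before imputation so the anchoring stage still sees it.
    """
    report = PreprocessReport()
    c, report = drop_high_missingness(cohort, drop_threshold, report)
    c, report = add_missingness_indicators(c, indicator_threshold, report)
    # capture leading-missing structure before imputation erases it
    lead: dict[tuple[str, str], int] = {}
    for r in c.records:
        for name in ANCHOR_FEATURES:
            if name in r.series:
                obs = np.flatnonzero(~np.isnan(r.series[name]))
                if obs.size == 0:
                    raise ValueError(f"{r.id}: series {name!r} is entirely missing")
                lead[(r.id, name)] = int(obs[0])
    c, report = median_impute(c, report)
    c, report = encode_features(c, report=report)
    for r in c.records:
        for name in ANCHOR_FEATURES:
            first = lead.get((r.id, name), 0)
            if first and name in r.series:
                vals = r.series[name]
                shifted = np.empty_like(vals)
                shifted[: len(vals) - first] = vals[first:]
                shifted[len(vals) - first :] = vals[-1]
                r.series[name] = shifted
    c, report = normalize_continuous(c, stats=stats, method=method, report=report)
    return c, report
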