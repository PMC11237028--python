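"""Synthetic blood-cancer cohort generation.

Generates cohorts with the marginal structure of the reference 98-patient
study: static demographics drawn by quota or proportionally, baseline
vitals/labs from truncated Gaussians, daily AR(1) trajectories, a daily
packed-red-blood-cell transfusion label from a logistic ground-truth risk
model (~7% daily prevalence at defaults), and per-cell missingness.

Missing cells are marked with NaN (continuous) or None (categorical) —
never a numeric sentinel.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .schema import CohortSchema, FeatureSpec, build_default_schema

__all__ = [
    "PatientRecord",
    "Cohort",
    "RiskParams",
    "sample_cohort",
    "sample_trajectories",
    "assign_daily_labels",
    "inject_missingness",
    "write_cohort",
    "read_cohort",
    "make_cohort",
]

logger = logging.getLogger(__name__)


@dataclass
class PatientRecord:
    """One patient: static features, daily series, and daily outcome labels."""

    id: str
    static: dict[str, object] = field(default_factory=dict)
    series: dict[str, np.ndarray] = field(default_factory=dict)
    labels: np.ndarray | None = None

    @property
    def horizon(self) -> int:
        """Number of days T covered by the series (0 if baseline-only)."""
        if not self.series:
            return 0
        return len(next(iter(self.series.values())))

    def validate(self) -> None:
        lengths = {len(v) for v in self.series.values()}
        if len(lengths) > 1:
            raise ValueError(f"{self.id}: series lengths differ: {sorted(lengths)}")
        if self.labels is not None and self.series:
            if len(self.labels) != self.horizon:
                raise ValueError(f"{self.id}: labels length != series length")


@dataclass
class Cohort:
    """A schema plus patient records; regenerating with the same seed is
    bit-identical."""

    schema: CohortSchema
    records: list[PatientRecord]
    seed: int = 0

    def __len__(self) -> int:
        return len(self.records)

    def validate(self) -> None:
        for r in self.records:
            r.validate()

    def copy(self) -> "Cohort":
        recs = [
            PatientRecord(
                id=r.id,
                static=dict(r.static),
                series={k: v.copy() for k, v in r.series.items()},
                labels=None if r.labels is None else r.labels.copy(),
            )
            for r in self.records
        ]
        return Cohort(schema=self.schema, records=recs, seed=self.seed)

    def baseline_frame(self) -> pd.DataFrame:
        """Patient-level frame: static features plus day-0 series values."""
        rows = []
        for r in self.records:
            row: dict[str, object] = {"patient_id": r.id, **r.static}
            for name, vals in r.series.items():
                row[name] = vals[0] if len(vals) else np.nan
            rows.append(row)
        return pd.DataFrame(rows).set_index("patient_id")

    def day_frame(self) -> pd.DataFrame:
        """Day-level frame: one row per (patient, day) with series values
        and the label."""
        rows = []
        for r in self.records:
            for t in range(r.horizon):
                row: dict[str, object] = {"patient_id": r.id, "day": t}
                for name, vals in r.series.items():
                    row[name] = vals[t]
                if r.labels is not None:
                    row["label"] = int(r.labels[t])
                rows.append(row)
        return pd.DataFrame(rows)


# --- sampling ---------------------------------------------------------------


def _quota_labels(counts: dict[str, int], n: int, rng: np.random.Generator) -> list[str]:
    total = sum(counts.values())
    if n == total:
        pool = [lab for lab, c in counts.items() for _ in range(c)]
        perm = rng.permutation(len(pool))
        return [pool[i] for i in perm]
    labels = list(counts)
    p = np.array([counts[l] for l in labels], dtype=float)
    p /= p.sum()
    idx = rng.choice(len(labels), size=n, p=p)
    return [labels[i] for i in idx]


def _draw_truncnorm(
    spec: FeatureSpec, n: int, rng: np.random.Generator
) -> np.ndarray:
    lo, hi = spec.range
    if spec.sd == 0:
        return np.full(n, spec.mean)
    a, b = (lo - spec.mean) / spec.sd, (hi - spec.mean) / spec.sd
    return stats.truncnorm.rvs(a, b, loc=spec.mean, scale=spec.sd, size=n, random_state=rng)


def sample_cohort(
    schema: CohortSchema | None = None,
    n: int | None = None,
    seed: int = 0,
    quota: bool | None = None,
) -> Cohort:
    """Draw n patients' static features and baseline vitals/labs.

    Demographics use quota sampling (exact category counts) when
    ``n`` equals the schema's reference size, proportional sampling
    otherwise; ``quota`` overrides the default choice. Continuous features
    are truncated Gaussians; coupled features (hematocrit) are drawn
    conditionally on their partner preserving marginal moments.
    """
    schema = schema or build_default_schema()
    n = schema.n_default if n is None else int(n)
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not schema.features:
        raise ValueError("schema has no features")
    if quota is None:
        quota = n == schema.n_default

    rng = np.random.default_rng(seed)
    records = [PatientRecord(id=f"P{i:05d}") for i in range(n)]

    for spec in schema.static():
        if spec.kind == "continuous":
            vals = _draw_truncnorm(spec, n, rng)
            for r, v in zip(records, vals):
                r.static[spec.name] = float(v)
        else:
            if quota:
                labs = _quota_labels(spec.category_counts, n, rng)
            else:
                names = list(spec.category_counts)
                p = np.array([spec.category_counts[l] for l in names], dtype=float)
                p /= p.sum()
                labs = [names[i] for i in rng.choice(len(names), size=n, p=p)]
            for r, v in zip(records, labs):
                r.static[spec.name] = v

    # Baselines as length-1 series; trajectories extend them.
    baselines: dict[str, np.ndarray] = {}
    for spec in schema.time_varying():
        if spec.couple_to is not None:
            partner_name, rho = spec.couple_to
            partner = baselines[partner_name]
            pspec = schema[partner_name]
            slope = rho * spec.sd / pspec.sd
            eps = rng.standard_normal(n) * spec.sd * math.sqrt(1.0 - rho**2)
            vals = spec.mean + slope * (partner - pspec.mean) + eps
            vals = np.clip(vals, *spec.range)
        else:
            vals = _draw_truncnorm(spec, n, rng)
        baselines[spec.name] = vals
        for r, v in zip(records, vals):
            r.series[spec.name] = np.array([v], dtype=float)

    return Cohort(schema=schema, records=records, seed=seed)


def sample_trajectories(
    cohort: Cohort, horizon: int | None = None, autocorr: float = 0.7, seed: int = 0
) -> Cohort:
    """Extend baselines to T-day stationary AR(1) trajectories.

    Each time-varying feature follows an AR(1) centred on the patient's
    baseline with the feature's SD as the marginal (stationary) SD; day 0
    is the baseline draw itself. ``autocorr`` is the lag-1 coefficient.
    """
    if not 0.0 <= autocorr < 1.0:
        raise ValueError(f"autocorr must be in [0, 1), got {autocorr}")
    horizon = cohort.schema.horizon_default if horizon is None else int(horizon)
    if horizon < 1:
        raise ValueError(f"horizon must be >= 1, got {horizon}")

    out = cohort.copy()
    rng = np.random.default_rng(seed)
    innov_scale = math.sqrt(1.0 - autocorr**2)
    for spec in out.schema.time_varying():
        lo, hi = spec.range
        for r in out.records:
            base = float(r.series[spec.name][0])
            x = np.empty(horizon)
            x[0] = base
            if horizon > 1:
                eps = rng.standard_normal(horizon - 1) * spec.sd * innov_scale
                for t in range(1, horizon):
                    x[t] = base + autocorr * (x[t - 1] - base) + eps[t - 1]
            r.series[spec.name] = np.clip(x, lo, hi)
    return out


# --- daily transfusion labels -----------------------------------------------


@dataclass(frozen=True)
class RiskParams:
    """Ground-truth logistic risk model for the daily transfusion label.

    The linear risk score rises as hemoglobin, PaO2, systolic pressure and
    platelets fall below their cohort means and as pH drops below 7.40
    (acidosis); alkalosis carries no extra risk. Weights are per standard
    deviation of the corresponding feature. ``intercept`` is calibrated so
    the default synthetic cohort has ~7% daily positive prevalence;
    ``threshold`` is the deterministic-mode cut on the (intercept-free)
    score.
    """

    w_hgb: float = 1.5
    w_pao2: float = 0.8
    w_ph: float = 0.8
    w_sbp: float = 0.3
    w_platelet: float = 0.3
    intercept: float = -5.21  # calibrated; see docs/methods.md
    threshold: float = 1.0
    mode: str = "logistic"  # "logistic" | "threshold" | "trend"
    trend_drop: float = 1.0  # g/dL day-over-day Hgb fall that triggers a trend label


_RISK_FEATURES = ("hgb", "pao2", "ph", "sbp", "platelet")
# Reference means/SDs of the risk features (the default schema values).
_REF = {
    "hgb": (8.93, 2.50),
    "pao2": (34.54, 7.25),
    "ph": (7.35, 0.06),
    "sbp": (124.64, 21.64),
    "platelet": (108.88, 67.66),
}


def risk_score(
    hgb: np.ndarray,
    pao2: np.ndarray,
    ph: np.ndarray,
    sbp: np.ndarray | None = None,
    platelet: np.ndarray | None = None,
    params: RiskParams | None = None,
) -> np.ndarray:
    """Intercept-free linear risk score of the ground-truth label model."""
    p = params or RiskParams()
    s = p.w_hgb * (_REF["hgb"][0] - np.asarray(hgb, float)) / _REF["hgb"][1]
    s = s + p.w_pao2 * (_REF["pao2"][0] - np.asarray(pao2, float)) / _REF["pao2"][1]
    s = s + p.w_ph * np.maximum(0.0, 7.40 - np.asarray(ph, float)) / _REF["ph"][1]
    if sbp is not None:
        s = s + p.w_sbp * (_REF["sbp"][0] - np.asarray(sbp, float)) / _REF["sbp"][1]
    if platelet is not None:
        s = s + p.w_platelet * (_REF["platelet"][0] - np.asarray(platelet, float)) / _REF["platelet"][1]
    return s


def assign_daily_labels(
    cohort: Cohort, risk_params: RiskParams | None = None, seed: int = 0
) -> Cohort:
    """Attach a daily {0,1} packed-RBC label to every record.

    Modes: ``logistic`` draws Bernoulli(sigmoid(score + intercept)) per
    day; ``threshold`` labels 1 deterministically when the intercept-free
    score exceeds ``threshold``; ``trend`` labels 1 when hemoglobin fell by
    more than ``trend_drop`` since the previous day (a purely sequential
    signal, invisible to models that only see the current day).
    """
    p = risk_params or RiskParams()
    rng = np.random.default_rng(seed)
    out = cohort.copy()
    needed = ("hgb",) if p.mode == "trend" else _RISK_FEATURES[:3]
    for r in out.records:
        for name in needed:
            if name not in r.series:
                raise ValueError(f"record {r.id} lacks required feature {name!r}")
        T = r.horizon
        if T == 0:
            raise ValueError(f"record {r.id} has no trajectories")
        if p.mode == "trend":
            hgb = r.series["hgb"]
            lab = np.zeros(T, dtype=int)
            if T > 1:
                lab[1:] = (hgb[:-1] - hgb[1:] > p.trend_drop).astype(int)
        else:
            s = risk_score(
                r.series["hgb"],
                r.series["pao2"],
                r.series["ph"],
                r.series.get("sbp"),
                r.series.get("platelet"),
                p,
            )
            if p.mode == "threshold":
                lab = (s > p.threshold).astype(int)
            elif p.mode == "logistic":
                prob = 1.0 / (1.0 + np.exp(-(s + p.intercept)))
                lab = (rng.random(T) < prob).astype(int)
            else:
                raise ValueError(f"unknown label mode {p.mode!r}")
        r.labels = lab
    return out


def calibrate_intercept(
    target_prevalence: float = 0.07,
    n: int = 20000,
    horizon: int = 7,
    seed: int = 12345,
) -> float:
    """Solve for the logistic intercept giving the target daily prevalence
    on a large default cohort (bisection on the mean predicted probability)."""
    c = sample_trajectories(
        sample_cohort(n=n, seed=seed), horizon=horizon, seed=seed + 1
    )
    scores = np.concatenate(
        [
            risk_score(
                r.series["hgb"], r.series["pao2"], r.series["ph"],
                r.series.get("sbp"), r.series.get("platelet"),
            )
            for r in c.records
        ]
    )
    lo, hi = -20.0, 10.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        prev = float(np.mean(1.0 / (1.0 + np.exp(-(scores + mid)))))
        if prev > target_prevalence:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


# --- missingness ------------------------------------------------------------


def inject_missingness(cohort: Cohort, seed: int = 0) -> Cohort:
    """Mask each cell independently with its feature's missing_rate.

    Continuous cells become NaN; categorical static cells become None.
    """
    rng = np.random.default_rng(seed)
    out = cohort.copy()
    for spec in out.schema.features:
        rate = spec.missing_rate
        if rate == 0.0:
            continue
        for r in out.records:
            if spec.time_varying:
                vals = r.series[spec.name]
                mask = rng.random(len(vals)) < rate
                vals[mask] = np.nan
            elif spec.name in r.static:
                if rng.random() < rate:
                    r.static[spec.name] = np.nan if spec.kind == "continuous" else None
    return out


def make_cohort(
    n: int | None = None,
    horizon: int | None = None,
    seed: int = 0,
    autocorr: float = 0.7,
    risk_params: RiskParams | None = None,
    missingness: bool = True,
    schema: CohortSchema | None = None,
) -> Cohort:
    """Full pipeline: baselines -> trajectories -> labels -> missingness.

    Sub-stages use seeds derived deterministically from ``seed``. Labels
    are assigned from the complete (pre-missingness) trajectories.
    """
    schema = schema or build_default_schema()
    c = sample_cohort(schema, n=n, seed=seed)
    c = sample_trajectories(c, horizon=horizon, autocorr=autocorr, seed=seed + 1)
    c = assign_daily_labels(c, risk_params=risk_params, seed=seed + 2)
    if missingness:
        c = inject_missingness(c, seed=seed + 3)
    return c


# --- persistence ------------------------------------------------------------

_LABEL_FEATURE = "prbc_label"
_STATIC_DAY = -1


def write_cohort(cohort: Cohort, path: str) -> None:
    """Write a long-format CSV (patient id, day, feature, value, missing)
    plus a ``<path>.schema.json`` sidecar. Static features use day=-1."""
    rows = []
    for r in cohort.records:
        for name, val in r.static.items():
            missing = val is None or (isinstance(val, float) and math.isnan(val))
            rows.append((r.id, _STATIC_DAY, name, "" if missing else val, int(missing)))
        for name, vals in r.series.items():
            for t, v in enumerate(vals):
                missing = math.isnan(v)
                rows.append((r.id, t, name, "" if missing else repr(float(v)), int(missing)))
        if r.labels is not None:
            for t, y in enumerate(r.labels):
                rows.append((r.id, t, _LABEL_FEATURE, int(y), 0))
    df = pd.DataFrame(rows, columns=["patient_id", "day", "feature", "value", "missing"])
    df.to_csv(path, index=False)
    sidecar = {"schema": cohort.schema.to_dict(), "seed": cohort.seed}
    with open(str(path) + ".schema.json", "w") as fh:
        json.dump(sidecar, fh, indent=1)


def read_cohort(path: str) -> Cohort:
    """Read a cohort written by :func:`write_cohort`; validates uniqueness
    of (id, day, feature) and flags out-of-range observed values in the log."""
    df = pd.read_csv(path, dtype={"value": str}, keep_default_na=False)
    with open(str(path) + ".schema.json") as fh:
        sidecar = json.load(fh)
    schema = CohortSchema.from_dict(sidecar["schema"])

    dup = df.duplicated(subset=["patient_id", "day", "feature"])
    if dup.any():
        bad = df.loc[dup, ["patient_id", "day", "feature"]].iloc[0].tolist()
        raise ValueError(f"duplicate (id, day, feature) rows, first: {bad}")

    records: dict[str, PatientRecord] = {}
    for pid, g in df.groupby("patient_id", sort=True):
        rec = PatientRecord(id=str(pid))
        series_vals: dict[str, dict[int, float]] = {}
        labels: dict[int, int] = {}
        for _, row in g.iterrows():
            name, day, missing = row["feature"], int(row["day"]), bool(int(row["missing"]))
            if name == _LABEL_FEATURE:
                labels[day] = int(row["value"])
                continue
            if day == _STATIC_DAY:
                spec = schema[name] if name in schema else None
                if missing:
                    rec.static[name] = (
                        np.nan if spec is not None and spec.kind == "continuous" else None
                    )
                elif spec is not None and spec.kind == "continuous":
                    rec.static[name] = float(row["value"])
                else:
                    rec.static[name] = row["value"]
            else:
                v = math.nan if missing else float(row["value"])
                if not missing and name in schema:
                    spec = schema[name]
                    if spec.kind == "continuous":
                        lo, hi = spec.range
                        if not lo <= v <= hi:
                            logger.warning(
                                "value out of plausible range: %s day %d %s=%g not in [%g, %g]",
                                pid, day, name, v, lo, hi,
                            )
                series_vals.setdefault(name, {})[day] = v
        for name, by_day in series_vals.items():
            T = max(by_day) + 1
            arr = np.full(T, np.nan)
            for t, v in by_day.items():
                arr[t] = v
            rec.series[name] = arr
        if labels:
            T = max(labels) + 1
            rec.labels = np.array([labels.get(t, 0) for t in range(T)], dtype=int)
        records[rec.id] = rec

    cohort = Cohort(schema=schema, records=list(records.values()), seed=int(sidecar.get("seed", 0)))
    cohort.validate()
    return cohort
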