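"""Cohort schema: per-feature generative and encoding metadata.

The default schema describes a 98-patient blood-cancer cohort with 61
features: 16 demographic features (with exact category counts), 4 clinical
vitals and 33 laboratory values (with published means/SDs), plus 8
high-missingness features that the preprocessing stage is expected to drop.
Continuous features are modelled as truncated Gaussians; demographic
features carry category counts so that quota sampling can reproduce the
published cohort composition exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

__all__ = ["FeatureSpec", "CohortSchema", "build_default_schema", "GROUPS"]

GROUPS = ("demographic", "clinical", "lab1", "lab2", "lab3")
KINDS = ("continuous", "binary", "categorical")


@dataclass(frozen=True)
class FeatureSpec:
    """Generative and encoding metadata for one cohort feature.

    Parameters
    ----------
    name : str
        Unique feature identifier.
    group : str
        One of :data:`GROUPS` (demographic, clinical, or one of three
        laboratory panels).
    kind : str
        ``continuous``, ``binary`` or ``categorical``.
    mean, sd : float, optional
        Marginal Gaussian parameters, in the feature's own units
        (continuous features only).
    category_counts : mapping, optional
        label -> count map for binary/categorical features; counts sum to
        the reference cohort size for quota-sampled features.
    unit : str
        Physical unit, for documentation and plots.
    missing_rate : float
        Per-cell Bernoulli missingness probability in [0, 1].
    plausible_range : tuple, optional
        (lo, hi) truncation bounds for the generator; defaults to
        mean +/- 4 SD clipped to physiological hard limits.
    time_varying : bool
        Whether the feature has a daily trajectory (vitals and labs) or a
        single static value (demographics and history).
    couple_to : tuple, optional
        (other_feature, rho): generate this feature conditionally Gaussian
        on another one with correlation rho, preserving the marginal
        mean/SD. Used for the hemoglobin-hematocrit link.
    """

    name: str
    group: str
    kind: str
    mean: float | None = None
    sd: float | None = None
    category_counts: Mapping[str, int] | None = None
    unit: str = ""
    missing_rate: float = 0.0
    plausible_range: tuple[float, float] | None = None
    time_varying: bool = False
    couple_to: tuple[str, float] | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r} for {self.name}")
        if self.kind not in KINDS:
            raise ValueError(f"unknown kind {self.kind!r} for {self.name}")
        if self.kind == "continuous":
            if self.mean is None or self.sd is None:
                raise ValueError(f"{self.name}: continuous features need mean and sd")
            if self.sd < 0:
                raise ValueError(f"{self.name}: sd must be nonnegative")
        elif not self.category_counts:
            raise ValueError(f"{self.name}: {self.kind} features need category_counts")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError(f"{self.name}: missing_rate outside [0, 1]")
        if self.plausible_range is not None:
            lo, hi = self.plausible_range
            if not lo < hi:
                raise ValueError(f"{self.name}: plausible_range lo must be < hi")

    @property
    def range(self) -> tuple[float, float]:
        """Effective truncation bounds (mean +/- 4 SD if not set explicitly)."""
        if self.plausible_range is not None:
            return self.plausible_range
        if self.kind != "continuous":
            raise ValueError(f"{self.name} has no numeric range")
        return (self.mean - 4.0 * self.sd, self.mean + 4.0 * self.sd)

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["category_counts"] is not None:
            d["category_counts"] = dict(d["category_counts"])
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "FeatureSpec":
        d = dict(d)
        if d.get("plausible_range") is not None:
            d["plausible_range"] = tuple(d["plausible_range"])
        if d.get("couple_to") is not None:
            name, rho = d["couple_to"]
            d["couple_to"] = (name, float(rho))
        return cls(**d)


@dataclass(frozen=True)
class CohortSchema:
    """An ordered feature list plus default cohort dimensions."""

    features: tuple[FeatureSpec, ...]
    n_default: int = 98
    horizon_default: int = 7

    def __post_init__(self) -> None:
        names = [f.name for f in self.features]
        if len(names) != len(set(names)):
            raise ValueError("feature names are not unique")

    def __getitem__(self, name: str) -> FeatureSpec:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(f.name == name for f in self.features)

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.features]

    def by_group(self, group: str) -> list[FeatureSpec]:
        if group not in GROUPS:
            raise ValueError(f"unknown group {group!r}")
        return [f for f in self.features if f.group == group]

    def continuous(self) -> list[FeatureSpec]:
        return [f for f in self.features if f.kind == "continuous"]

    def time_varying(self) -> list[FeatureSpec]:
        return [f for f in self.features if f.time_varying]

    def static(self) -> list[FeatureSpec]:
        return [f for f in self.features if not f.time_varying]

    def to_dict(self) -> dict:
        return {
            "features": [f.to_dict() for f in self.features],
            "n_default": self.n_default,
            "horizon_default": self.horizon_default,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortSchema":
        return cls(
            features=tuple(FeatureSpec.from_dict(f) for f in d["features"]),
            n_default=int(d["n_default"]),
            horizon_default=int(d["horizon_default"]),
        )


# --- default schema ---------------------------------------------------------

#: Features excluded by preprocessing for >90% missingness.
HIGH_MISSINGNESS_FEATURES = (
    "bmi",
    "chemotherapy_interval",
    "chloride",
    "anion_gap",
    "total_iron",
    "iron_binding_capacity",
    "lactate",
    "transferrin",
)

#: Laboratory features with majority missingness in the default schema
#: (these acquire 0/1 presence indicators during preprocessing).
PARTIAL_MISSINGNESS = {"troponin_t": 0.60, "ck_mb": 0.55, "ferritin": 0.55}

_LAB_MISSING = 0.05
_CLIN_MISSING = 0.02

# Cohort composition of the 98-patient reference study.
_DEMOGRAPHICS: list[tuple[str, dict[str, int]]] = [
    ("sex", {"Male": 55, "Female": 43}),
    (
        "age_band",
        {"18-32": 12, "32-46": 23, "46-60": 23, "60-74": 24, "74-88": 14, "88-90": 2},
    ),
    ("cancer_type", {"ALL": 22, "AML": 27, "CLL": 33, "CML": 16}),
]

# History / behaviour flags: (name, no-count, yes-count).
_HISTORY: list[tuple[str, int, int]] = [
    ("diabetes", 71, 27),
    ("heart_disease", 74, 24),
    ("respiratory_disease", 84, 14),
    ("chronic_kidney_disease", 86, 12),
    ("smoking", 65, 33),
    ("alcohol", 82, 16),
    ("chemotherapy", 32, 66),
    ("sepsis", 88, 10),
    ("active_infection", 75, 23),
    ("fever", 81, 17),
    ("antibiotic_injection", 34, 64),
    ("blood_transfusion_history", 43, 55),
    ("active_bleeding", 95, 3),
]

# (name, mean, sd, unit, hard physiological limits or None)
_CLINICAL = [
    ("sbp", 124.64, 21.64, "mmHg", (50.0, 260.0)),
    ("dbp", 75.74, 11.76, "mmHg", (25.0, 160.0)),
    ("heart_rate", 77.13, 14.46, "bpm", (20.0, 230.0)),
    ("lvef", 50.82, 5.26, "%", (10.0, 80.0)),
]

_LAB1 = [
    ("base_excess", 2.26, 4.69, "mmol/L", (-30.0, 30.0)),
    ("tco2", 39.95, 6.92, "mmol/L", (5.0, 80.0)),
    ("ph", 7.35, 0.06, "", (6.8, 7.8)),
    ("pao2", 34.54, 7.25, "mmHg", (10.0, 120.0)),
    ("spo2", 93.72, 3.14, "%", (50.0, 100.0)),
    ("hgb", 8.93, 2.50, "g/dL", (0.5, 20.0)),
    ("hct", 28.93, 7.58, "%", (5.0, 65.0)),
    ("mch", 29.82, 2.87, "pg", (10.0, 50.0)),
    ("mchc", 33.37, 2.749, "g/dL", (20.0, 45.0)),
    ("mcv", 86.41, 7.159, "fL", (50.0, 130.0)),
    ("rdw", 17.51, 1.61, "%", (10.0, 35.0)),
    ("platelet", 108.88, 67.66, "10^3/uL", (1.0, 1000.0)),
]

_LAB2 = [
    ("na", 138.62, 5.82, "mmol/L", (110.0, 170.0)),
    ("k", 4.072, 0.681, "mmol/L", (1.5, 8.0)),
    ("mg", 1.94, 0.26, "mg/dL", (0.5, 5.0)),
    ("phosphate", 4.25, 0.75, "mg/dL", (0.5, 12.0)),
    ("calcium", 8.45, 0.82, "mg/dL", (4.0, 15.0)),
    ("bicarbonate", 22.23, 4.19, "mmol/L", (5.0, 45.0)),
    ("ferritin", 124.42, 19.08, "ng/mL", (1.0, 2000.0)),
    ("pt", 14.13, 2.06, "s", (8.0, 60.0)),
    ("ptt", 35.03, 9.02, "s", (15.0, 150.0)),
    ("bun", 30.97, 16.09, "mg/dL", (2.0, 200.0)),
    ("creatinine", 1.196, 0.58, "mg/dL", (0.1, 15.0)),
]

_LAB3 = [
    ("alt", 60.19, 22.22, "U/L", (1.0, 2000.0)),
    ("ast", 59.58, 27.29, "U/L", (1.0, 2000.0)),
    ("alp", 466.31, 151.93, "U/L", (10.0, 3000.0)),
    ("albumin", 3.262, 0.48, "g/dL", (1.0, 6.0)),
    ("bilirubin_total", 1.134, 0.562, "mg/dL", (0.05, 30.0)),
    ("bilirubin_direct", 0.59, 0.29, "mg/dL", (0.0, 20.0)),
    ("ck", 134.23, 132.098, "U/L", (5.0, 5000.0)),
    ("ck_mb", 26.63, 17.67, "U/L", (0.5, 500.0)),
    ("ldh", 828.19, 510.078, "U/L", (50.0, 10000.0)),
    ("troponin_t", 0.031, 0.171, "ng/mL", (0.0, 10.0)),
]

# Placeholder distributions for the high-missingness features; values are
# generated but almost always masked, so only the shapes matter.
_EXCLUDED = [
    ("bmi", "clinical", 26.0, 5.0, "kg/m^2", (12.0, 60.0)),
    ("chemotherapy_interval", "clinical", 21.0, 7.0, "days", (1.0, 120.0)),
    ("chloride", "lab2", 102.0, 5.0, "mmol/L", (70.0, 140.0)),
    ("anion_gap", "lab2", 12.0, 4.0, "mmol/L", (0.0, 40.0)),
    ("total_iron", "lab2", 60.0, 30.0, "ug/dL", (5.0, 400.0)),
    ("iron_binding_capacity", "lab2", 300.0, 60.0, "ug/dL", (50.0, 700.0)),
    ("lactate", "lab1", 2.0, 1.5, "mmol/L", (0.2, 25.0)),
    ("transferrin", "lab3", 220.0, 50.0, "mg/dL", (50.0, 600.0)),
]


def _trunc(mean: float, sd: float, hard: tuple[float, float] | None) -> tuple[float, float]:
    lo, hi = mean - 4.0 * sd, mean + 4.0 * sd
    if hard is not None:
        lo, hi = max(lo, hard[0]), min(hi, hard[1])
    return (lo, hi)


def build_default_schema() -> CohortSchema:
    """Build the 61-feature default cohort schema.

    Demographic features carry the published category counts (so quota
    sampling at n=98 reproduces them exactly); vitals and labs carry the
    published means/SDs; the 8 features the preprocessing stage excludes
    for >90% missingness are present with missing_rate 0.95. Hematocrit is
    generated conditionally on hemoglobin (rho=0.9) to reflect their
    physiological link while keeping its published marginal moments.
    """
    feats: list[FeatureSpec] = []
    for name, counts in _DEMOGRAPHICS:
        feats.append(
            FeatureSpec(name, "demographic", "categorical", category_counts=counts)
        )
    for name, no, yes in _HISTORY:
        feats.append(
            FeatureSpec(
                name, "demographic", "binary", category_counts={"No": no, "Yes": yes}
            )
        )
    panels = [("clinical", _CLINICAL), ("lab1", _LAB1), ("lab2", _LAB2), ("lab3", _LAB3)]
    for group, rows in panels:
        for name, mean, sd, unit, hard in rows:
            feats.append(
                FeatureSpec(
                    name,
                    group,
                    "continuous",
                    mean=mean,
                    sd=sd,
                    unit=unit,
                    missing_rate=PARTIAL_MISSINGNESS.get(
                        name, _CLIN_MISSING if group == "clinical" else _LAB_MISSING
                    ),
                    plausible_range=_trunc(mean, sd, hard),
                    time_varying=True,
                    couple_to=("hgb", 0.9) if name == "hct" else None,
                )
            )
    for name, group, mean, sd, unit, hard in _EXCLUDED:
        feats.append(
            FeatureSpec(
                name,
                group,
                "continuous",
                mean=mean,
                sd=sd,
                unit=unit,
                missing_rate=0.95,
                plausible_range=_trunc(mean, sd, hard),
                time_varying=True,
            )
        )
    return CohortSchema(features=tuple(feats), n_default=98, horizon_default=7)
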