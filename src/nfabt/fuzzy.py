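"""Fuzzy-basis-function (FBF) inference core.

Each input variable carries an ordered triangular membership-function
partition that is normal (every MF peaks at 1), complete (every point of
the universe has positive coverage) and consistent. Interior MFs have
their feet at the neighbouring centers, so memberships sum to exactly 1
between the extreme centers (partition of unity); the extreme MFs become
shoulders that stay at 1 out to the universe edge.

A rule i maps an antecedent cell (one MF per active input) to an output MF
with center theta_i. The fuzzy basis function of rule i is the product of
its antecedent memberships,

    d_i(z) = prod_j mu_{A_j^i}(z_j),

and the system output is the FBF-weighted sum of consequent centers,

    f(z) = sum_i d_i(z) * theta_i        (unnormalized)
    f(z) = sum_i d_i theta_i / sum_i d_i (normalized, the default),

which for triangular partitions is the classic singleton-fuzzifier /
product-inference / centroid-defuzzifier system. Under a complete grid
rule base the two forms coincide between extreme centers because the FBFs
themselves form a partition of unity.

Rules are learned from data by Wang-Mendel table lookup, and inference can
be distributed over a swarm of agents that each hold a share of the rule
base and report partial sums.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone

import numpy as np

__all__ = [
    "TriangularMF",
    "FuzzyPartition",
    "FuzzyRule",
    "RuleBase",
    "FBFSystem",
    "AlarmDecision",
    "default_partitions",
    "build_system",
    "enumerate_rule_space",
    "learn_rules",
    "complete_rule_base",
    "alarm",
    "UncoveredInputError",
]

logger = logging.getLogger(__name__)


class UncoveredInputError(ValueError):
    """No rule has positive basis activation at the given input."""


@dataclass(frozen=True)
class TriangularMF:
    """A triangular membership function, possibly with a shoulder.

    ``left_foot``/``right_foot`` of -inf/+inf make the MF a left/right
    shoulder: membership stays 1 beyond the center on that side.
    """

    label: str
    center: float
    left_foot: float
    right_foot: float

    def __post_init__(self) -> None:
        if not self.left_foot < self.center < self.right_foot:
            raise ValueError(
                f"MF {self.label!r}: need left_foot < center < right_foot, "
                f"got {self.left_foot}, {self.center}, {self.right_foot}"
            )

    def __call__(self, z: float | np.ndarray) -> float | np.ndarray:
        z = np.asarray(z, dtype=float)
        left = np.isinf(self.left_foot)
        right = np.isinf(self.right_foot)
        up = (
            np.ones_like(z)
            if left
            else np.clip((z - self.left_foot) / (self.center - self.left_foot), 0.0, 1.0)
        )
        down = (
            np.ones_like(z)
            if right
            else np.clip((self.right_foot - z) / (self.right_foot - self.center), 0.0, 1.0)
        )
        out = np.minimum(up, down)
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class FuzzyPartition:
    """An ordered, normal, complete, consistent triangular partition."""

    variable: str
    universe: tuple[float, float]
    mfs: tuple[TriangularMF, ...]

    def __post_init__(self) -> None:
        lo, hi = self.universe
        if not lo < hi:
            raise ValueError(f"{self.variable}: universe lo must be < hi")
        centers = [m.center for m in self.mfs]
        if any(b <= a for a, b in zip(centers, centers[1:])):
            raise ValueError(f"{self.variable}: MF centers must strictly increase")

    def __len__(self) -> int:
        return len(self.mfs)

    @property
    def centers(self) -> tuple[float, ...]:
        return tuple(m.center for m in self.mfs)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(m.label for m in self.mfs)

    def membership(self, mf_index: int, z: float | np.ndarray) -> float | np.ndarray:
        """mu of one MF at z (piecewise linear; shoulders saturate at 1)."""
        if not 0 <= mf_index < len(self.mfs):
            raise IndexError(f"{self.variable}: MF index {mf_index} out of range")
        return self.mfs[mf_index](z)

    def membership_matrix(self, z: np.ndarray) -> np.ndarray:
        """(n, K) matrix of memberships of n points in all K MFs."""
        z = np.atleast_1d(np.asarray(z, dtype=float))
        return np.column_stack([m(z) for m in self.mfs])

    def is_complete(self, n_grid: int = 1000) -> bool:
        """Grid-scan check: max membership > 0 everywhere on the universe."""
        grid = np.linspace(*self.universe, n_grid)
        return bool(self.membership_matrix(grid).max(axis=1).min() > 0.0)

    @classmethod
    def from_centers(
        cls,
        variable: str,
        universe: tuple[float, float],
        centers: list[float] | tuple[float, ...],
        labels: list[str] | tuple[str, ...],
    ) -> "FuzzyPartition":
        """Build the canonical partition-of-unity triangular family.

        Interior MFs put their feet at the neighbouring centers; the two
        extreme MFs become shoulders (infinite outer foot) so completeness
        holds even when the extreme centers sit inside — or outside — the
        stated universe.
        """
        if len(centers) != len(labels):
            raise ValueError("centers and labels length mismatch")
        if len(centers) < 2:
            raise ValueError("need at least 2 MFs")
        mfs = []
        for k, (c, lab) in enumerate(zip(centers, labels)):
            lf = -np.inf if k == 0 else centers[k - 1]
            rf = np.inf if k == len(centers) - 1 else centers[k + 1]
            mfs.append(TriangularMF(label=lab, center=float(c), left_foot=lf, right_foot=rf))
        return cls(variable=variable, universe=tuple(universe), mfs=tuple(mfs))

    def to_dict(self) -> dict:
        return {
            "variable": self.variable,
            "universe": list(self.universe),
            "centers": list(self.centers),
            "labels": list(self.labels),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FuzzyPartition":
        return cls.from_centers(d["variable"], tuple(d["universe"]), d["centers"], d["labels"])


# --- default partitions -----------------------------------------------------

#: Universes of discourse of the three candidate inputs and the output.
DEFAULT_UNIVERSES = {
    "hgb": (7.0, 16.6),
    "pao2": (40.0, 80.0),
    "ph": (6.3, 7.8),
    "blood_state": (0.0, 1.0),
}

#: MF centers, in ascending order.
DEFAULT_CENTERS = {
    "hgb": (8.0, 10.25, 14.1, 16.6),
    "pao2": (30.0, 47.5, 65.75, 90.0),
    "ph": (7.35, 7.4, 7.45),
    "blood_state": (0.25, 0.75),
}

# Linguistic labels, assigned in their published order to ascending centers.
DEFAULT_LABELS = {
    "hgb": ("Very Low", "Low", "Normal", "High"),
    "pao2": ("Normal", "Mild Hypoxemia", "Moderate Hypoxemia", "Severe Hypoxemia"),
    "ph": ("Acidosis", "Normal", "Alkalosis"),
    "blood_state": ("Low", "Normal"),
}


def default_partitions() -> tuple[FuzzyPartition, FuzzyPartition, FuzzyPartition, FuzzyPartition]:
    """The three input partitions (hgb, pao2, ph) and the output partition.

    The PaO2 centers {30, 90} fall outside the stated universe [40, 80];
    shoulder MFs make the partition complete on the union of universe and
    center span, so the printed centers remain the operative quantities.
    """
    parts = []
    for name in ("hgb", "pao2", "ph", "blood_state"):
        parts.append(
            FuzzyPartition.from_centers(
                name, DEFAULT_UNIVERSES[name], DEFAULT_CENTERS[name], DEFAULT_LABELS[name]
            )
        )
    return tuple(parts)


# --- rules and systems ------------------------------------------------------


@dataclass(frozen=True)
class FuzzyRule:
    """IF z_1 is A_1 and ... and z_m is A_m THEN k is B.

    ``antecedent`` holds one MF index per active input (in system input
    order); ``consequent`` indexes the output partition; ``degree`` is the
    Wang-Mendel learning confidence in [0, 1].
    """

    antecedent: tuple[int, ...]
    consequent: int
    degree: float = 1.0


@dataclass
class RuleBase:
    rules: list[FuzzyRule] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rules)

    def __iter__(self):
        return iter(self.rules)

    def validate(self, n_mfs: tuple[int, ...], n_out: int) -> None:
        seen: set[tuple[int, ...]] = set()
        for r in self.rules:
            if len(r.antecedent) != len(n_mfs):
                raise ValueError("rule antecedent arity mismatch")
            if any(not 0 <= a < k for a, k in zip(r.antecedent, n_mfs)):
                raise ValueError(f"rule antecedent {r.antecedent} out of range")
            if not 0 <= r.consequent < n_out:
                raise ValueError(f"rule consequent {r.consequent} out of range")
            if r.antecedent in seen:
                raise ValueError(f"duplicate antecedent cell {r.antecedent}")
            seen.add(r.antecedent)


@dataclass
class FBFSystem:
    """Input partitions, output partition, rule base and inference flags."""

    input_partitions: tuple[FuzzyPartition, ...]
    output_partition: FuzzyPartition
    rules: RuleBase = field(default_factory=RuleBase)
    normalize: bool = True

    def __post_init__(self) -> None:
        if not self.input_partitions:
            raise ValueError("system needs at least one input partition")
        self.rules.validate(self.n_mfs, len(self.output_partition))

    @property
    def n_mfs(self) -> tuple[int, ...]:
        return tuple(len(p) for p in self.input_partitions)

    @property
    def input_names(self) -> tuple[str, ...]:
        return tuple(p.variable for p in self.input_partitions)

    @property
    def thetas(self) -> tuple[float, ...]:
        """Output centers theta_i indexed by consequent."""
        return self.output_partition.centers

    # -- basis and inference --

    def fuzzy_basis(self, antecedent: tuple[int, ...], z) -> float | np.ndarray:
        """d_i(z) = prod_j mu_{A_j^i}(z_j) for one antecedent cell.

        ``z`` is one value per active input, or a (n, m) batch.
        """
        z = np.asarray(z, dtype=float)
        single = z.ndim == 1
        Z = np.atleast_2d(z)
        if Z.shape[1] != len(self.input_partitions):
            raise ValueError(
                f"expected {len(self.input_partitions)} inputs, got {Z.shape[1]}"
            )
        d = np.ones(Z.shape[0])
        for j, (part, a) in enumerate(zip(self.input_partitions, antecedent)):
            d *= part.membership(a, Z[:, j])
        return float(d[0]) if single else d

    def basis_matrix(self, Z: np.ndarray) -> np.ndarray:
        """(n, R) matrix of FBF activations for all rules at n inputs."""
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        mu = [p.membership_matrix(Z[:, j]) for j, p in enumerate(self.input_partitions)]
        D = np.empty((Z.shape[0], len(self.rules)))
        for i, r in enumerate(self.rules):
            d = np.ones(Z.shape[0])
            for j, a in enumerate(r.antecedent):
                d *= mu[j][:, a]
            D[:, i] = d
        return D

    def infer(self, z) -> float | np.ndarray:
        """f(z): FBF-weighted sum of consequent centers.

        Normalized (default): sum_i d_i theta_i / sum_i d_i, bounded by
        [min theta, max theta]. With ``normalize=False`` the literal
        unnormalized sum is returned. Raises
        :class:`UncoveredInputError` when no rule covers z.
        """
        if len(self.rules) == 0:
            raise ValueError("rule base is empty")
        z = np.asarray(z, dtype=float)
        single = z.ndim == 1
        Z = np.atleast_2d(z)
        D = self.basis_matrix(Z)
        theta = np.array([self.thetas[r.consequent] for r in self.rules])
        num = D @ theta
        if self.normalize:
            den = D.sum(axis=1)
            if np.any(den <= 0.0):
                bad = Z[den <= 0.0][0]
                raise UncoveredInputError(f"uncovered input: no rule active at z={bad}")
            out = num / den
        else:
            out = num
        return float(out[0]) if single else out

    def swarm_infer(
        self,
        z,
        swarm_size: int = 1,
        assignment: list[int] | np.ndarray | None = None,
    ) -> tuple[float, list[dict]]:
        """Distribute the rule base over ``swarm_size`` agents.

        ``assignment`` maps each rule index to an agent id (default
        round-robin) and must cover every rule exactly once. Each agent
        reports its partial sums (sum d_i theta_i, sum d_i); the aggregate
        reproduces :meth:`infer` exactly.
        """
        if swarm_size < 1:
            raise ValueError("swarm_size must be >= 1")
        R = len(self.rules)
        if assignment is None:
            assignment = [i % swarm_size for i in range(R)]
        assignment = list(assignment)
        if len(assignment) != R:
            raise ValueError(f"assignment must cover all {R} rules exactly once")
        if any(not 0 <= a < swarm_size for a in assignment):
            raise ValueError("assignment references an agent outside the swarm")

        z = np.asarray(z, dtype=float)
        if z.ndim != 1:
            raise ValueError("swarm_infer takes a single input vector")
        theta = self.thetas
        partials = [
            {"agent": a, "rules": 0, "weighted_sum": 0.0, "basis_sum": 0.0}
            for a in range(swarm_size)
        ]
        for i, rule in enumerate(self.rules):
            d = self.fuzzy_basis(rule.antecedent, z)
            p = partials[assignment[i]]
            p["rules"] += 1
            p["weighted_sum"] += d * theta[rule.consequent]
            p["basis_sum"] += d
        num = sum(p["weighted_sum"] for p in partials)
        den = sum(p["basis_sum"] for p in partials)
        if self.normalize:
            if den <= 0.0:
                raise UncoveredInputError(f"uncovered input: no rule active at z={z}")
            return num / den, partials
        return num, partials

    # -- serialization --

    def to_dict(self) -> dict:
        return {
            "inputs": [p.to_dict() for p in self.input_partitions],
            "output": self.output_partition.to_dict(),
            "normalize": self.normalize,
            "rules": [
                {"antecedent": list(r.antecedent), "consequent": r.consequent, "degree": r.degree}
                for r in self.rules
            ],
        }

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "FBFSystem":
        return cls(
            input_partitions=tuple(FuzzyPartition.from_dict(p) for p in d["inputs"]),
            output_partition=FuzzyPartition.from_dict(d["output"]),
            rules=RuleBase(
                [
                    FuzzyRule(tuple(r["antecedent"]), int(r["consequent"]), float(r["degree"]))
                    for r in d["rules"]
                ]
            ),
            normalize=bool(d.get("normalize", True)),
        )

    @classmethod
    def load(cls, path: str) -> "FBFSystem":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def build_system(inputs: list[str] | tuple[str, ...] = ("hgb", "pao2"), normalize: bool = True) -> FBFSystem:
    """An FBFSystem over a subset of the default inputs with an empty rule
    base. Valid input names: hgb, pao2, ph."""
    hgb, pao2, ph, out = default_partitions()
    by_name = {"hgb": hgb, "pao2": pao2, "ph": ph}
    try:
        parts = tuple(by_name[name] for name in inputs)
    except KeyError as e:
        raise ValueError(f"unknown fuzzy input {e.args[0]!r}") from None
    return FBFSystem(input_partitions=parts, output_partition=out, normalize=normalize)


def enumerate_rule_space(system: FBFSystem) -> tuple[list[FuzzyRule], int]:
    """All candidate rules: antecedent cells x consequent choices.

    The count is (prod_j K_j) * K_out — e.g. two 4-MF inputs with a 2-MF
    output give 4^2 * 2 = 32 candidates.
    """
    if not system.input_partitions:
        raise ValueError("no active inputs")
    cells = itertools.product(*(range(k) for k in system.n_mfs))
    rules = [
        FuzzyRule(antecedent=cell, consequent=c)
        for cell in cells
        for c in range(len(system.output_partition))
    ]
    return rules, len(rules)


def learn_rules(system: FBFSystem, data) -> RuleBase:
    """Wang-Mendel table-lookup rule learning.

    For each sample (z, k): pick the max-membership MF of every input and
    of the output (ties -> lower index), with rule degree the product of
    those memberships; keep the single highest-degree rule per antecedent
    cell (ties -> lower consequent index). Inputs outside their universe
    are clipped with a logged warning.

    ``data`` is an iterable of (z, k) pairs or a tuple (Z, k_vec).
    """
    if isinstance(data, tuple) and len(data) == 2 and np.ndim(data[0]) == 2:
        Z = np.asarray(data[0], dtype=float)
        K = np.asarray(data[1], dtype=float)
    else:
        pairs = list(data)
        if not pairs:
            raise ValueError("empty training data")
        Z = np.array([np.asarray(z, dtype=float) for z, _ in pairs])
        K = np.array([float(k) for _, k in pairs])
    if Z.size == 0:
        raise ValueError("empty training data")
    if Z.shape[1] != len(system.input_partitions):
        raise ValueError("training inputs have wrong arity")

    # clip to the partition's effective support (universe extended to the
    # extreme centers, where shoulders keep membership positive)
    for j, part in enumerate(system.input_partitions):
        lo = min(part.universe[0], part.centers[0])
        hi = max(part.universe[1], part.centers[-1])
        out_of = (Z[:, j] < lo) | (Z[:, j] > hi)
        if out_of.any():
            logger.warning(
                "%d/%d samples outside %s universe; clipped",
                int(out_of.sum()), len(Z), part.variable,
            )
            Z[:, j] = np.clip(Z[:, j], lo, hi)

    mu_in = [p.membership_matrix(Z[:, j]) for j, p in enumerate(system.input_partitions)]
    mu_out = system.output_partition.membership_matrix(K)
    best_in = [m.argmax(axis=1) for m in mu_in]  # argmax ties -> lower index
    best_out = mu_out.argmax(axis=1)
    degree = mu_out[np.arange(len(K)), best_out].copy()
    for j, m in enumerate(mu_in):
        degree *= m[np.arange(len(K)), best_in[j]]

    table: dict[tuple[int, ...], FuzzyRule] = {}
    for s in range(len(K)):
        cell = tuple(int(b[s]) for b in best_in)
        cand = FuzzyRule(antecedent=cell, consequent=int(best_out[s]), degree=float(degree[s]))
        old = table.get(cell)
        if (
            old is None
            or cand.degree > old.degree
            or (cand.degree == old.degree and cand.consequent < old.consequent)
        ):
            table[cell] = cand
    return RuleBase(rules=[table[c] for c in sorted(table)])


def complete_rule_base(system: FBFSystem, rules: RuleBase) -> RuleBase:
    """Fill antecedent cells missing from a learned rule base.

    Wang-Mendel only creates rules for cells the data visited; an input
    falling in an unvisited cell would otherwise be uncovered. Each empty
    cell inherits the consequent of the nearest learned cell (Manhattan
    distance in MF-index space, ties toward lower cells) with degree 0.
    """
    if len(rules) == 0:
        raise ValueError("cannot complete an empty rule base")
    learned = {r.antecedent: r for r in rules}
    out = list(rules)
    for cell in itertools.product(*(range(k) for k in system.n_mfs)):
        if cell in learned:
            continue
        nearest = min(
            learned,
            key=lambda c: (sum(abs(a - b) for a, b in zip(c, cell)), c),
        )
        out.append(FuzzyRule(antecedent=cell, consequent=learned[nearest].consequent, degree=0.0))
    out.sort(key=lambda r: r.antecedent)
    return RuleBase(rules=out)


# --- alarming ---------------------------------------------------------------


@dataclass(frozen=True)
class AlarmDecision:
    """The alarm verdict for one inferred blood-state value."""

    state_value: float
    state_label: str  # "Low" | "Normal"
    alarm: bool
    message: dict


def alarm(
    state_value: float,
    threshold: float = 0.5,
    inputs: dict[str, float] | None = None,
    timestamp: str | None = None,
) -> AlarmDecision:
    """Map an inferred blood-state value f(z) to an alarm decision.

    A value below ``threshold`` means the blood state is Low and the
    transfusion alarm fires; the boundary value itself maps to Normal (no
    alarm). The message is a structured record ready for gateway delivery.
    """
    if not 0.0 <= state_value <= 1.0:
        raise ValueError(f"state_value {state_value} outside [0, 1]")
    low = state_value < threshold
    label = "Low" if low else "Normal"
    message = {
        "event": "transfusion_alarm" if low else "status",
        "state_value": float(state_value),
        "state_label": label,
        "threshold": float(threshold),
        "inputs": dict(inputs or {}),
        "timestamp": timestamp or datetime.now(timezone.utc).isoformat(),
    }
    return AlarmDecision(state_value=float(state_value), state_label=label, alarm=low, message=message)
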