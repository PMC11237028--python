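"""Noise-robustness evaluation of the FBF alarming system.

Adds white Gaussian measurement noise (AWGN) to the fuzzy inputs at given
signal-to-noise ratios and scores the inferred blood state against the
ground-truth state by RMSE, sweeping input-pair scenarios over repeated
train/test splits. Signal power for the SNR is the per-feature variance
(AC power): large physiological offsets (pH ~ 7.35) would otherwise make
the nominal SNRs meaningless.

Ground truth is encoded on the output-center scale: a day labelled as
requiring transfusion maps to the Low center 0.25, other days to the
Normal center 0.75, so RMSE is commensurate with the range of f(z).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort
from .fuzzy import build_system, complete_rule_base, learn_rules

__all__ = ["NoiseSpec", "ScenarioResult", "add_awgn", "rmse", "scenario_eval", "DEFAULT_PAIRS"]

DEFAULT_PAIRS: tuple[tuple[str, str], ...] = (("hgb", "pao2"), ("hgb", "ph"), ("pao2", "ph"))
DEFAULT_SNRS: tuple[float, ...] = (30.0, 10.0, 5.0)

#: label -> output-center encoding of the ground-truth blood state
STATE_OF_LABEL = {1: 0.25, 0: 0.75}


@dataclass(frozen=True)
class NoiseSpec:
    """One noise condition: SNR in dB, or None for the clean condition."""

    snr_db: float | None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.snr_db is not None and not np.isfinite(self.snr_db):
            raise ValueError("snr_db must be finite (or None for clean)")

    @property
    def name(self) -> str:
        return "clean" if self.snr_db is None else f"snr_{self.snr_db:g}dB"


def add_awgn(values: np.ndarray, snr_db: float | None, seed: int = 0) -> np.ndarray:
    """Additive zero-mean Gaussian noise at the given SNR.

    Noise variance is Var(values) / 10^(snr_db/10) per column (features in
    columns for 2-D input). ``snr_db=None`` returns the values unchanged.
    """
    values = np.asarray(values, dtype=float)
    if snr_db is None:
        return values.copy()
    rng = np.random.default_rng(seed)
    var = values.var(axis=0)
    if np.any(var <= 0.0):
        raise ValueError("zero-variance signal: SNR-scaled noise undefined")
    sigma = np.sqrt(var / 10.0 ** (snr_db / 10.0))
    return values + rng.standard_normal(values.shape) * sigma


def rmse(predictions, targets) -> float:
    """Root-mean-square error between two equal-length series."""
    p = np.asarray(predictions, dtype=float)
    t = np.asarray(targets, dtype=float)
    if p.shape != t.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {t.shape}")
    if p.size == 0:
        raise ValueError("empty input")
    return float(np.sqrt(np.mean((p - t) ** 2)))


@dataclass
class ScenarioResult:
    """Mean RMSE per noise condition for one input pair."""

    input_pair: tuple[str, str]
    rmse_by_condition: dict[str, float]
    runs: int
    per_run: dict[str, list[float]] = field(default_factory=dict)


def _day_samples(cohort: Cohort, features: tuple[str, str]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack (patient_idx, z, state) over all days, dropping missing cells."""
    Z, states, owner = [], [], []
    for pi, r in enumerate(cohort.records):
        if r.labels is None:
            raise ValueError("cohort has no labels; run assign_daily_labels first")
        cols = np.column_stack([r.series[f] for f in features])
        ok = ~np.isnan(cols).any(axis=1)
        Z.append(cols[ok])
        states.append(np.array([STATE_OF_LABEL[int(y)] for y in r.labels[ok]]))
        owner.append(np.full(int(ok.sum()), pi))
    return np.concatenate(owner), np.vstack(Z), np.concatenate(states)


def scenario_eval(
    cohort: Cohort,
    pairs: tuple[tuple[str, str], ...] = DEFAULT_PAIRS,
    snrs: tuple[float, ...] = DEFAULT_SNRS,
    runs: int = 10,
    seed: int = 0,
    train_frac: float = 0.7,
) -> list[ScenarioResult]:
    """Input-pair x noise-condition sweep of the FBF system.

    Per run: patients are split 70/30 into train/test (re-drawn from the
    run seed), Wang-Mendel rules are learned on the train days, and the
    inferred blood state on the test days is scored by RMSE against the
    encoded ground truth — once clean and once per SNR with AWGN applied
    to the test inputs only (measurement-noise reading). Reported RMSEs
    are means over ``runs``.
    """
    if runs < 1:
        raise ValueError("runs must be >= 1")
    known = {"hgb", "pao2", "ph"}
    for pair in pairs:
        if not set(pair) <= known:
            raise ValueError(f"unknown input pair {pair}")

    n_patients = len(cohort.records)
    conditions = [NoiseSpec(None)] + [NoiseSpec(s) for s in snrs]
    results = []
    for pair in pairs:
        owner, Z, states = _day_samples(cohort, pair)
        per_run: dict[str, list[float]] = {c.name: [] for c in conditions}
        for run in range(runs):
            rng = np.random.default_rng(seed + 1000 * run)
            perm = rng.permutation(n_patients)
            n_train = max(1, int(round(train_frac * n_patients)))
            train_p = set(perm[:n_train].tolist())
            tr = np.isin(owner, list(train_p))
            te = ~tr
            if not te.any():
                raise ValueError("empty test split")
            system = build_system(pair)
            system.rules = complete_rule_base(system, learn_rules(system, (Z[tr], states[tr])))
            # common random numbers: one noise realization per run, scaled
            # to each SNR, so condition contrasts are not masked by
            # independent draws
            noise = np.random.default_rng(seed + 1000 * run + 1).standard_normal(Z[te].shape)
            sig_sd = Z[te].std(axis=0)
            if np.any(sig_sd <= 0.0):
                raise ValueError("zero-variance test signal: SNR-scaled noise undefined")
            for cond in conditions:
                if cond.snr_db is None:
                    Zte = Z[te]
                else:
                    sigma = sig_sd / 10.0 ** (cond.snr_db / 20.0)
                    Zte = Z[te] + noise * sigma
                f = system.infer(Zte)
                per_run[cond.name].append(rmse(f, states[te]))
        results.append(
            ScenarioResult(
                input_pair=pair,
                rmse_by_condition={k: float(np.mean(v)) for k, v in per_run.items()},
                runs=runs,
                per_run=per_run,
            )
        )
    return results


def results_table(results: list[ScenarioResult]) -> pd.DataFrame:
    """Scenario results as a pairs x conditions table (rows in input-pair
    order, columns clean first then decreasing SNR)."""
    rows = {}
    for r in results:
        label = f"FBF with {r.input_pair[0]} and {r.input_pair[1]} inputs"
        rows[label] = r.rmse_by_condition
    return pd.DataFrame(rows).T
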