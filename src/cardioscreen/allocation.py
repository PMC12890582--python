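"""Stratified minimisation allocation of patients to training vs test sets.

Pocock-Simon-style marginal minimisation with a target train:test ratio.
For each incoming patient and each candidate arm, the imbalance score is the
sum over balancing factors of the range of *ratio-adjusted* level counts at
the patient's factor levels, where arm g's adjusted count is
``count_g / weight_g`` and the candidate patient contributes one adjusted
unit to the arm under consideration.  With probability ``p_deterministic``
the arm with the strictly lower score is taken; ties (including the empty
state) and the remaining probability mass fall to a ratio-weighted random
draw.  This convention simultaneously balances each factor margin between
arms and drives the overall train fraction to the target ratio.

Default balancing factors mirror prognostic practice for a VHD screening
study: recruitment setting, dominant (most severe) lesion slot, and that
lesion's grade.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .cohort import PatientRecord, dominant_lesion

__all__ = ["AllocationConfig", "AllocationState", "allocate_patient", "allocate_cohort",
           "DEFAULT_FACTORS", "simple_randomisation"]

GROUPS = ("train", "test")


def _factor_setting(p: PatientRecord) -> str:
    return p.setting.value


def _factor_dominant_type(p: PatientRecord) -> str:
    return dominant_lesion(p.echo)[0]


def _factor_dominant_grade(p: PatientRecord) -> str:
    return str(int(dominant_lesion(p.echo)[1]))


DEFAULT_FACTORS: dict[str, Callable[[PatientRecord], str]] = {
    "setting": _factor_setting,
    "vhd_type": _factor_dominant_type,
    "vhd_grade": _factor_dominant_grade,
}


@dataclass
class AllocationConfig:
    factors: dict[str, Callable[[PatientRecord], str]] = field(
        default_factory=lambda: dict(DEFAULT_FACTORS))
    target_ratio: tuple[float, float] = (79.0, 21.0)  # train : test
    p_deterministic: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.target_ratio) <= 0:
            raise ValueError("target_ratio weights must be positive")
        if not 0.0 <= self.p_deterministic <= 1.0:
            raise ValueError("p_deterministic must be a probability")
        if not self.factors:
            raise ValueError("at least one balancing factor is required")


@dataclass
class AllocationState:
    """Mutable per-group per-factor-level counts plus the seeded RNG."""

    config: AllocationConfig
    counts: dict[str, dict[str, dict[str, int]]] = field(default_factory=dict)
    n_assigned: dict[str, int] = field(default_factory=lambda: {g: 0 for g in GROUPS})
    rng: np.random.Generator | None = None

    def __post_init__(self) -> None:
        if not self.counts:
            self.counts = {g: {f: {} for f in self.config.factors} for g in GROUPS}
        if self.rng is None:
            self.rng = np.random.default_rng(self.config.seed)

    @property
    def weights(self) -> dict[str, float]:
        w = np.asarray(self.config.target_ratio, dtype=float)
        w = w / w.sum()
        return {"train": float(w[0]), "test": float(w[1])}

    def record(self, p: PatientRecord, group: str) -> None:
        for fname, fn in self.config.factors.items():
            level = fn(p)
            self.counts[group][fname][level] = self.counts[group][fname].get(level, 0) + 1
        self.n_assigned[group] += 1


def _imbalance_score(st: AllocationState, levels: dict[str, str], candidate: str) -> float:
    w = st.weights
    score = 0.0
    for fname, level in levels.items():
        adjusted = []
        for g in GROUPS:
            c = st.counts[g][fname].get(level, 0) / w[g]
            if g == candidate:
                c += 1.0
            adjusted.append(c)
        score += max(adjusted) - min(adjusted)
    return score


def _ratio_draw(st: AllocationState) -> str:
    w = st.weights
    return "train" if st.rng.random() < w["train"] else "test"


def allocate_patient(p: PatientRecord, st: AllocationState) -> tuple[str, AllocationState]:
    """Assign one patient; returns (group, state).  The state is updated in place."""
    levels = {f: fn(p) for f, fn in st.config.factors.items()}
    scores = {g: _imbalance_score(st, levels, g) for g in GROUPS}
    if st.rng.random() < st.config.p_deterministic:
        if abs(scores["train"] - scores["test"]) < 1e-12:
            group = _ratio_draw(st)
        else:
            group = min(GROUPS, key=lambda g: scores[g])
    else:
        group = _ratio_draw(st)
    st.record(p, group)
    return group, st


def allocate_cohort(cohort: list[PatientRecord],
                    preassigned: dict[str, str] | None = None,
                    cfg: AllocationConfig | None = None) -> dict[str, str]:
    """Sequentially allocate a cohort; preassigned patients keep their group
    and seed the factor counts before the remaining patients arrive."""
    cfg = cfg or AllocationConfig()
    preassigned = preassigned or {}
    ids = {p.id for p in cohort}
    unknown = set(preassigned) - ids
    if unknown:
        raise ValueError(f"preassigned ids not in cohort: {sorted(unknown)[:5]}")
    bad = {g for g in preassigned.values() if g not in GROUPS}
    if bad:
        raise ValueError(f"unknown groups in preassignment: {bad}")
    st = AllocationState(config=cfg)
    assignment: dict[str, str] = {}
    for p in cohort:
        if p.id in preassigned:
            g = preassigned[p.id]
            st.record(p, g)
            assignment[p.id] = g
    for p in cohort:
        if p.id in assignment:
            continue
        g, st = allocate_patient(p, st)
        assignment[p.id] = g
    return assignment


def simple_randomisation(cohort: list[PatientRecord], cfg: AllocationConfig | None = None
                         ) -> dict[str, str]:
    """Ratio-weighted i.i.d. randomisation baseline (no covariate balancing)."""
    cfg = cfg or AllocationConfig()
    rng = np.random.default_rng(cfg.seed)
    w = np.asarray(cfg.target_ratio, dtype=float)
    p_train = float(w[0] / w.sum())
    return {p.id: ("train" if rng.random() < p_train else "test") for p in cohort}


def marginal_imbalance(cohort: list[PatientRecord], assignment: dict[str, str],
                       cfg: AllocationConfig | None = None) -> float:
    """Max over factors and levels of |train proportion - test proportion|."""
    cfg = cfg or AllocationConfig()
    train = [p for p in cohort if assignment[p.id] == "train"]
    test = [p for p in cohort if assignment[p.id] == "test"]
    if not train or not test:
        return 1.0
    worst = 0.0
    for fn in cfg.factors.values():
        levels = {fn(p) for p in cohort}
        for level in levels:
            pt = sum(1 for p in train if fn(p) == level) / len(train)
            pe = sum(1 for p in test if fn(p) == level) / len(test)
            worst = max(worst, abs(pt - pe))
    return worst
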