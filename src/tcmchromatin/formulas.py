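"""Formula-level aggregation and the resampling synergy test.

A formula's modification profile is the attribute-wise sum of its member
profiles; it is histone-modifying iff at least one member is.  To ask
whether real formulas mix chromatinization directions less than chance,
each histone-modifying formula's normalized net heterochromatinization
f = (n_het - n_eu) / (n_het + n_eu) is compared with the mean f of its
histone-modifying members (difference Δ), and the |Δ| distribution is
ranked against that of size-matched random control formulas drawn from
the pool of medicinals making up the real formulas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .catalog import FormulaRecord, ModificationCatalog
from .profiling import (
    ChromatinCall,
    PotencyProfile,
    chromatin_call,
    is_histone_modifying,
)

CLASSES = ("me", "ph", "ac", "all")


def formula_profile(formula: FormulaRecord,
                    member_profiles: dict[str, PotencyProfile]) -> PotencyProfile:
    """Attribute-wise sum of the member profiles."""
    missing = [m for m in formula.member_ids if m not in member_profiles]
    if missing:
        raise ValueError(
            f"formula {formula.formula_id!r}: missing member profiles {missing}")
    members = [member_profiles[m] for m in formula.member_ids]
    return PotencyProfile(
        entity_id=formula.formula_id,
        n_pairs=np.sum([m.n_pairs for m in members], axis=0),
        n_activating=np.sum([m.n_activating for m in members], axis=0),
        n_inhibiting=np.sum([m.n_inhibiting for m in members], axis=0),
    )


def formula_is_histone_modifying(formula: FormulaRecord,
                                 member_calls: dict[str, ChromatinCall]) -> bool:
    """A formula is histone-modifying iff any member is."""
    return any(member_calls[m].label != "non_modifying"
               for m in formula.member_ids)


def _net_fraction(call: ChromatinCall, cls: str) -> float:
    tallies = call.per_class[cls]
    denom = tallies["n_het"] + tallies["n_eu"]
    if denom == 0:
        return 0.0
    return tallies["net"] / denom


def heterochromatinization_difference(
        formula: FormulaRecord, member_calls: dict[str, ChromatinCall],
        formula_call: ChromatinCall) -> dict[str, float]:
    """Per-class Δ = f(formula) - mean f over histone-modifying members."""
    modifying = [m for m in formula.member_ids
                 if member_calls[m].label != "non_modifying"]
    if not modifying:
        raise ValueError(
            f"formula {formula.formula_id!r} has no histone-modifying member")
    out = {}
    for cls in CLASSES:
        member_f = np.mean([_net_fraction(member_calls[m], cls)
                            for m in modifying])
        out[cls] = float(_net_fraction(formula_call, cls) - member_f)
    return out


def generate_control_formulas(pool: list[str], n_controls: int, size: int,
                              seed: int,
                              modifying_ids: set[str] | None = None,
                              target_median: float | None = None,
                              max_redraws: int = 100,
                              match_strategy: str = "auto") -> list[FormulaRecord]:
    """Size-matched random formulas from the real formulas' member pool.

    Each control is a uniform sample without replacement of ``size``
    members.  When ``target_median`` is given, the set must reproduce the
    real formulas' median count of histone-modifying members (per
    ``modifying_ids``).  ``match_strategy`` controls how:

    - ``reject``: redraw the whole set up to ``max_redraws`` times until
      its median matches, then error.  This only works when the pool's
      sampling distribution already centers on the target.
    - ``stratified``: enforce the median by construction -- each control
      draws a fixed number of modifying members (uniformly from the
      modifying part of the pool) and the rest from the remainder, with
      the counts chosen so the set median lands on the target.
    - ``auto`` (default): try ``reject`` briefly, fall back to
      ``stratified``.

    Fully reproducible from ``seed``.
    """
    if n_controls < 1:
        raise ValueError("n_controls must be >= 1")
    if size > len(pool):
        raise ValueError(f"control size {size} exceeds pool size {len(pool)}")
    if match_strategy not in ("reject", "stratified", "auto"):
        raise ValueError(f"unknown match strategy {match_strategy!r}")
    pool = sorted(pool)
    rng = np.random.default_rng(seed)

    def draw_set() -> list[FormulaRecord]:
        return [
            FormulaRecord(f"CTRL{k:04d}", tuple(
                pool[i] for i in rng.choice(len(pool), size=size, replace=False)))
            for k in range(n_controls)
        ]

    if target_median is None:
        return draw_set()
    modifying_ids = modifying_ids or set()

    def set_median(controls: list[FormulaRecord]) -> float:
        return float(np.median([
            sum(1 for m in c.member_ids if m in modifying_ids)
            for c in controls]))

    achieved = None
    if match_strategy in ("reject", "auto"):
        budget = max_redraws if match_strategy == "reject" else min(max_redraws, 20)
        for _ in range(budget):
            controls = draw_set()
            achieved = set_median(controls)
            if achieved == target_median:
                return controls
        if match_strategy == "reject":
            raise RuntimeError(
                f"control generation: could not match the real formulas' "
                f"median histone-modifying member count (target "
                f"{target_median}, last achieved {achieved}) in "
                f"{max_redraws} redraws")

    # stratified construction: fix each control's modifying-member count
    mod_pool = [m for m in pool if m in modifying_ids]
    rest_pool = [m for m in pool if m not in modifying_ids]
    m_low = int(np.floor(target_median))
    n_high = int(round((target_median - m_low) * n_controls))
    counts = [m_low + 1] * n_high + [m_low] * (n_controls - n_high)
    for m in counts:
        if m > min(size, len(mod_pool)) or size - m > len(rest_pool):
            raise RuntimeError(
                f"control generation: target median {target_median} "
                f"modifying members is unattainable with pool of "
                f"{len(mod_pool)} modifying / {len(rest_pool)} other "
                f"medicinals at control size {size}")
    controls = []
    for k, m in enumerate(counts):
        picked = [mod_pool[i] for i in rng.choice(len(mod_pool), size=m,
                                                  replace=False)]
        picked += [rest_pool[i] for i in rng.choice(len(rest_pool),
                                                    size=size - m,
                                                    replace=False)]
        controls.append(FormulaRecord(f"CTRL{k:04d}", tuple(picked)))
    return controls


@dataclass
class SynergyReport:
    """Real vs control |Δ| comparison for each chemistry class."""

    real_deltas: dict[str, list[float]]      # class -> Δ per real formula
    control_deltas: dict[str, list[float]]
    summary: dict[str, dict[str, float]]     # class -> medians, p-values, flag
    n_controls: int
    control_seed: int | None
    median_size: float
    median_modifying: float

    def to_dict(self) -> dict:
        return {
            "summary": self.summary, "n_controls": self.n_controls,
            "control_seed": self.control_seed, "median_size": self.median_size,
            "median_modifying": self.median_modifying,
            "real_deltas": self.real_deltas,
            "control_deltas": self.control_deltas,
        }


def synergy_comparison(real_deltas: dict[str, list[float]],
                       control_deltas: dict[str, list[float]],
                       n_controls: int = 0, control_seed: int | None = None,
                       median_size: float = float("nan"),
                       median_modifying: float = float("nan"),
                       alpha: float = 0.05) -> SynergyReport:
    """Rank-compare |Δ| of real formulas against controls per class.

    The headline statistic is the two-sided rank-sum P.  The synergy
    direction flag uses the one-sided (real |Δ| stochastically smaller)
    rank-sum P at ``alpha``, which keeps its null firing rate at the
    nominal level while implying the direction of the effect.
    """
    summary = {}
    for cls in CLASSES:
        real = np.abs(np.asarray(real_deltas[cls], dtype=float))
        ctrl = np.abs(np.asarray(control_deltas[cls], dtype=float))
        if len(real) == 0 or len(ctrl) == 0:
            raise ValueError(f"class {cls}: empty Δ list")
        if np.ptp(np.concatenate([real, ctrl])) == 0:
            p_two, p_less = 1.0, 1.0
        else:
            p_two = float(stats.mannwhitneyu(real, ctrl,
                                             alternative="two-sided").pvalue)
            p_less = float(stats.mannwhitneyu(real, ctrl,
                                              alternative="less").pvalue)
        med_r, med_c = float(np.median(real)), float(np.median(ctrl))
        summary[cls] = {
            "median_abs_real": med_r,
            "median_abs_control": med_c,
            "p_two_sided": p_two,
            "p_less": p_less,
            "direction": bool(med_r < med_c),
            "synergy_flag": bool(p_less < alpha),
        }
    return SynergyReport(real_deltas, control_deltas, summary, n_controls,
                         control_seed, median_size, median_modifying)


def run_synergy_analysis(formulas: list[FormulaRecord],
                         member_profiles: dict[str, PotencyProfile],
                         member_calls: dict[str, ChromatinCall],
                         modcat: ModificationCatalog,
                         n_controls: int = 199, seed: int | None = 0,
                         granularity: str = "distinct_modifications") -> SynergyReport:
    """End-to-end synergy test for a set of real formulas.

    Restricts to histone-modifying formulas, computes their Δ lists, draws
    median-matched control formulas from the union of their members, and
    rank-compares the |Δ| distributions.
    """
    modifying = [f for f in formulas
                 if formula_is_histone_modifying(f, member_calls)]
    if not modifying:
        raise ValueError("no histone-modifying formulas")
    modifying_ids = {mid for mid, call in member_calls.items()
                     if call.label != "non_modifying"}
    pool = sorted({m for f in modifying for m in f.member_ids})
    sizes = [len(f.member_ids) for f in modifying]
    mod_counts = [sum(1 for m in f.member_ids if m in modifying_ids)
                  for f in modifying]
    median_size = float(np.median(sizes))
    median_modifying = float(np.median(mod_counts))
    control_size = int(np.floor(median_size + 0.5))

    def deltas_for(formula_set: list[FormulaRecord]) -> dict[str, list[float]]:
        out: dict[str, list[float]] = {cls: [] for cls in CLASSES}
        for f in formula_set:
            if not formula_is_histone_modifying(f, member_calls):
                continue
            prof = formula_profile(f, member_profiles)
            fcall = chromatin_call(prof, modcat, granularity=granularity)
            d = heterochromatinization_difference(f, member_calls, fcall)
            for cls in CLASSES:
                out[cls].append(d[cls])
        return out

    real_deltas = deltas_for(modifying)
    controls = generate_control_formulas(
        pool, n_controls, control_size, seed=seed,
        modifying_ids=modifying_ids, target_median=median_modifying)
    control_deltas = deltas_for(controls)
    if not control_deltas["all"]:
        raise ValueError("no histone-modifying control formulas")
    return synergy_comparison(real_deltas, control_deltas,
                              n_controls=n_controls, control_seed=seed,
                              median_size=median_size,
                              median_modifying=median_modifying)
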