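"""Chemo-epigenetic potency profiling of medicinals.

A medicinal modifies histone mark X if any of its constituent chemicals
interacts with an enzyme of the family catalysing X; its X potency is the
number of such chemical-protein interaction pairs.  Interactions whose
direction the source database leaves unspecified are assumed inhibiting.
The net of heterochromatic versus euchromatic modifications classifies a
medicinal as chromatin condensing, unpacking or poising.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import (
    InteractionRecord,
    MedicinalCatalog,
    MedicinalRecord,
    ModificationCatalog,
)
from .constants import (
    ATTRIBUTE_ORDER,
    CHEMISTRY_CLASSES,
    EUCHROMATIC,
    HETEROCHROMATIC,
)
from .scoring import ScoreTable

_ATTR_INDEX = {code: i for i, code in enumerate(ATTRIBUTE_ORDER)}

POTENCY_MODES = ("count", "signed")
GRANULARITIES = ("distinct_modifications", "interaction_pairs")
DIRECTIONS = ("count", "direction_aware")


@dataclass
class PotencyProfile:
    """Per-entity tallies over the 18 modification attributes.

    ``n_pairs = n_activating + n_inhibiting`` holds per attribute, with
    unspecified interactions already folded into the inhibiting tally.
    """

    entity_id: str
    n_pairs: np.ndarray       # shape (18,), ints in ATTRIBUTE_ORDER
    n_activating: np.ndarray
    n_inhibiting: np.ndarray

    def potency(self, mode: str = "count") -> np.ndarray:
        if mode == "count":
            return self.n_pairs
        if mode == "signed":
            return self.n_activating - self.n_inhibiting
        raise ValueError(f"unknown potency mode {mode!r}")

    def pairs_for(self, attribute: str) -> int:
        return int(self.n_pairs[_ATTR_INDEX[attribute]])


@dataclass
class ChromatinCall:
    """Condensing / unpacking / poising classification of one entity."""

    entity_id: str
    label: str
    per_class: dict[str, dict[str, float]] = field(default_factory=dict)
    # per_class[cls] = {"net": ..., "n_het": ..., "n_eu": ...}

    def net(self, cls: str = "all") -> float:
        return self.per_class[cls]["net"]


@dataclass
class CorrelationResult:
    attribute_code: str
    score_mode: str
    r: float
    p: float
    n: int


def _interaction_frame(interactions: list[InteractionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.chemical_id, r.protein_id, r.action) for r in interactions],
        columns=["chemical_id", "protein_id", "action"])


def build_potency_profile(medicinal: MedicinalRecord,
                          interactions: list[InteractionRecord],
                          modcat: ModificationCatalog) -> PotencyProfile:
    """Profile a single medicinal (see build_potency_profiles for batches)."""
    cat = MedicinalCatalog(records={medicinal.medicinal_id: medicinal})
    return build_potency_profiles(cat, interactions, modcat)[0]


def build_potency_profiles(catalog: MedicinalCatalog,
                           interactions: list[InteractionRecord],
                           modcat: ModificationCatalog) -> list[PotencyProfile]:
    """Profile every medicinal in the catalog, in catalog order.

    A pair is one (chemical of the medicinal, enzyme of the attribute)
    combination present in the interaction table; two chemicals hitting
    the same enzyme count as two pairs.  Proteins absent from the
    modification catalog never match.
    """
    idf = _interaction_frame(interactions)
    prot2attr = pd.DataFrame(
        [(p, code) for code in ATTRIBUTE_ORDER for p in modcat.proteins_for(code)],
        columns=["protein_id", "attribute_code"])
    merged = idf.merge(prot2attr, on="protein_id", how="inner")
    chem2med = pd.DataFrame(
        [(c, rec.medicinal_id) for rec in catalog for c in rec.chemical_ids],
        columns=["chemical_id", "medicinal_id"])
    merged = merged.merge(chem2med, on="chemical_id", how="inner")
    merged["activating"] = merged["action"] == "activation"
    tallies = merged.groupby(["medicinal_id", "attribute_code"]).agg(
        n_pairs=("action", "size"), n_act=("activating", "sum"))
    out = []
    for rec in catalog:
        n_pairs = np.zeros(18, dtype=int)
        n_act = np.zeros(18, dtype=int)
        if rec.medicinal_id in tallies.index.get_level_values(0):
            sub = tallies.loc[rec.medicinal_id]
            for code, row in sub.iterrows():
                i = _ATTR_INDEX[code]
                n_pairs[i] = row["n_pairs"]
                n_act[i] = row["n_act"]
        out.append(PotencyProfile(rec.medicinal_id, n_pairs, n_act,
                                  n_pairs - n_act))
    return out


def is_histone_modifying(profile: PotencyProfile) -> bool:
    """True iff any attribute (including ATP remodeling) has a pair."""
    return bool(profile.n_pairs.sum() > 0)


def _class_masks() -> dict[str, np.ndarray]:
    masks = {}
    for cls, codes in CHEMISTRY_CLASSES.items():
        mask = np.zeros(18, dtype=bool)
        for c in codes:
            mask[_ATTR_INDEX[c]] = True
        masks[cls] = mask
    return masks


_CLASS_MASKS = _class_masks()


def chromatin_call(profile: PotencyProfile, modcat: ModificationCatalog,
                   granularity: str = "distinct_modifications",
                   direction: str = "count") -> ChromatinCall:
    """Classify an entity's chromatin effect.

    Default tallies count distinct attributes touched (one vote per
    modification); ``interaction_pairs`` weights by pair counts.  In
    ``direction_aware`` mode an activating pair pushes toward the
    attribute's own conformation and an inhibiting pair toward the
    opposite one.  The ambivalent ATP attribute counts toward
    histone-modifying status but toward neither side of the net.
    """
    if granularity not in GRANULARITIES:
        raise ValueError(f"unknown granularity {granularity!r}")
    if direction not in DIRECTIONS:
        raise ValueError(f"unknown direction mode {direction!r}")
    conf = np.array([modcat.conformation[a] for a in ATTRIBUTE_ORDER])
    het_attr = conf == HETEROCHROMATIC
    eu_attr = conf == EUCHROMATIC
    if direction == "count":
        het_weight = np.where(het_attr, profile.n_pairs, 0)
        eu_weight = np.where(eu_attr, profile.n_pairs, 0)
    else:
        # activation pushes the attribute's conformation, inhibition the
        # opposite conformation
        het_weight = (np.where(het_attr, profile.n_activating, 0)
                      + np.where(eu_attr, profile.n_inhibiting, 0))
        eu_weight = (np.where(eu_attr, profile.n_activating, 0)
                     + np.where(het_attr, profile.n_inhibiting, 0))
    per_class = {}
    for cls, mask in _CLASS_MASKS.items():
        hw, ew = het_weight[mask], eu_weight[mask]
        if granularity == "distinct_modifications":
            n_het, n_eu = int((hw > 0).sum()), int((ew > 0).sum())
        else:
            n_het, n_eu = int(hw.sum()), int(ew.sum())
        per_class[cls] = {"net": n_het - n_eu, "n_het": n_het, "n_eu": n_eu}
    net_all = per_class["all"]["net"]
    if not is_histone_modifying(profile):
        label = "non_modifying"
    elif net_all > 0:
        label = "condensing"
    elif net_all < 0:
        label = "unpacking"
    else:
        label = "poising"
    return ChromatinCall(profile.entity_id, label, per_class)


def correlate_scores_with_potency(score_table: ScoreTable,
                                  profiles: list[PotencyProfile],
                                  attribute_code: str,
                                  score_mode: str = "nature_only",
                                  potency_mode: str = "count") -> CorrelationResult:
    """Pearson correlation of TCM score against one attribute's potency.

    Restricted to histone-modifying medicinals with a non-NA score, as the
    correlation screen of the analysis requires; two-sided P from the
    exact t transform with n-2 df.
    """
    scores = score_table.scores(score_mode)
    xs, ys = [], []
    for prof in profiles:
        if not is_histone_modifying(prof):
            continue
        s = scores.get(prof.entity_id, np.nan)
        if s is None or np.isnan(s):
            continue
        xs.append(float(s))
        ys.append(float(prof.potency(potency_mode)[_ATTR_INDEX[attribute_code]]))
    if len(xs) < 3:
        raise ValueError(
            f"correlation needs >= 3 usable medicinals, got {len(xs)}")
    x, y = np.array(xs), np.array(ys)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError(
            f"zero variance in {'score' if np.ptp(x) == 0 else attribute_code}"
            f" values; correlation undefined")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(attribute_code, score_mode, float(r), float(p),
                             len(x))


def correlation_screen(score_table: ScoreTable, profiles: list[PotencyProfile],
                       score_mode: str = "nature_only",
                       potency_mode: str = "count") -> pd.DataFrame:
    """All-18-attribute correlation screen; zero-variance attributes get NaN."""
    rows = []
    for code in ATTRIBUTE_ORDER:
        try:
            res = correlate_scores_with_potency(
                score_table, profiles, code, score_mode, potency_mode)
            rows.append((code, score_mode, res.r, res.p, res.n,
                         res.p < 0.05))
        except ValueError:
            rows.append((code, score_mode, np.nan, np.nan, 0, False))
    return pd.DataFrame(rows, columns=["attribute_code", "score_mode", "r",
                                       "p", "n", "significant"])


def materia_medica_summary(calls: list[ChromatinCall]) -> dict[str, float]:
    """Fractions of histone-modifying medicinals and of each chromatin class.

    Class fractions are taken among the histone-modifying medicinals and
    partition them exactly; with none modifying they are NaN.
    """
    if not calls:
        raise ValueError("no chromatin calls supplied")
    n = len(calls)
    n_mod = sum(1 for c in calls if c.label != "non_modifying")
    counts = {lab: sum(1 for c in calls if c.label == lab)
              for lab in ("condensing", "unpacking", "poising")}
    summary = {
        "n_total": n,
        "n_modifying": n_mod,
        "frac_modifying": n_mod / n,
    }
    for lab, k in counts.items():
        summary[f"n_{lab}"] = k
        summary[f"frac_{lab}"] = k / n_mod if n_mod else float("nan")
    return summary


def profiles_to_tsv(profiles: list[PotencyProfile], path,
                    calls: list[ChromatinCall] | None = None) -> None:
    rows = []
    call_by_id = {c.entity_id: c for c in (calls or [])}
    for prof in profiles:
        row = {"entity_id": prof.entity_id}
        for i, code in enumerate(ATTRIBUTE_ORDER):
            row[code] = int(prof.n_pairs[i])
        row["n_activating"] = int(prof.n_activating.sum())
        row["n_inhibiting"] = int(prof.n_inhibiting.sum())
        if prof.entity_id in call_by_id:
            call = call_by_id[prof.entity_id]
            row["label"] = call.label
            row["net_all"] = call.net("all")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
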