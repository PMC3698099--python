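"""Quantification of TCM nature and flavor annotations.

The cold-hot nature maps onto a seven-level integer scale, cold (-3)
through hot (+3).  Each flavor token carries +1 (yang: sweet, pungent,
plain) or -1 (yin: sour, bitter, salty), halved for "mild" grades, and a
medicinal's flavor score is the sum over its tokens.  The yin-yang score
is nature + flavor.  Missing annotations propagate as NA (NaN).
"""

from __future__ import annotations

import logging
import math
from collections.abc import Iterable
from dataclasses import dataclass

import pandas as pd

from .catalog import MedicinalCatalog
from .constants import FLAVOR_SCORES, NATURE_SCORES

logger = logging.getLogger(__name__)

SCORE_MODES = ("full", "flavor_only", "nature_only")


def nature_score(nature_token: str | None) -> float:
    """Map a nature token to its integer cold-hot score; absent -> NaN."""
    if nature_token is None:
        return math.nan
    try:
        return float(NATURE_SCORES[nature_token])
    except KeyError:
        raise ValueError(f"unknown nature token {nature_token!r}") from None


def flavor_score(flavor_tokens: Iterable[str]) -> float:
    """Sum of per-token flavor values; empty token set -> NaN."""
    tokens = list(flavor_tokens)
    if not tokens:
        return math.nan
    total = 0.0
    for tok in tokens:
        try:
            total += FLAVOR_SCORES[tok]
        except KeyError:
            raise ValueError(f"unknown flavor token {tok!r}") from None
    return total


def yinyang_score(nature_token: str | None, flavor_tokens: Iterable[str],
                  mode: str = "full") -> float:
    """Composite yin-yang score under the requested mode.

    ``full`` = nature + flavor; ``flavor_only`` and ``nature_only`` use a
    single component.  NA in any required component makes the result NA.
    """
    if mode not in SCORE_MODES:
        raise ValueError(f"unknown score mode {mode!r}")
    n = nature_score(nature_token)
    f = flavor_score(flavor_tokens)
    if mode == "nature_only":
        return n
    if mode == "flavor_only":
        return f
    return n + f


@dataclass
class ScoreTable:
    """Per-medicinal cold-hot, flavor and yin-yang scores (NaN = NA)."""

    table: pd.DataFrame  # index medicinal_id; columns cold_hot, flavor, yinyang

    def scores(self, mode: str) -> pd.Series:
        col = {"full": "yinyang", "flavor_only": "flavor",
               "nature_only": "cold_hot"}[mode]
        return self.table[col]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", na_rep="NA")


def score_catalog(catalog: MedicinalCatalog) -> ScoreTable:
    """Score every medicinal in the catalog, preserving catalog order."""
    rows = {}
    for rec in catalog:
        n = nature_score(rec.nature_token)
        f = flavor_score(rec.flavor_tokens)
        rows[rec.medicinal_id] = {"cold_hot": n, "flavor": f, "yinyang": n + f}
    df = pd.DataFrame.from_dict(rows, orient="index",
                                columns=["cold_hot", "flavor", "yinyang"])
    df.index.name = "medicinal_id"
    logger.info("scored %d medicinals (%d NA nature, %d NA flavor)",
                len(df), int(df["cold_hot"].isna().sum()),
                int(df["flavor"].isna().sum()))
    return ScoreTable(df)
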