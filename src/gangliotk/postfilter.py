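"""Post-search filtering of LipidSearch-style result tables.

Identification software exports are noisy: early-eluting solvent-front
features, tiny integration artifacts, and low-confidence matches survive
into the raw table.  The cleanup applied here keeps a row only when

    retention time  >  2 min      (past the solvent front)
    peak area       >  1000       (above integration noise)
    score           <  0.5        (confident identification)

with *strict* inequalities — "more than / greater than / less than" — so
rows sitting exactly on a threshold are removed.  The score column is a
generic keep-if-smaller identification score (LipidSearch's internal
"t-score" definition is proprietary); its column name is configurable.
Filtering is pure (table in, table out) and emits a machine-readable
report of how many rows each criterion removed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

from .chem import AdductIon

__all__ = [
    "FilterReport",
    "apply_filters",
    "restrict_adducts",
    "DEFAULT_RT_MIN",
    "DEFAULT_AREA_MIN",
    "DEFAULT_SCORE_MAX",
]

DEFAULT_RT_MIN = 2.0       # minutes
DEFAULT_AREA_MIN = 1000.0  # integrated intensity
DEFAULT_SCORE_MAX = 0.5


@dataclass(frozen=True)
class FilterReport:
    """Row counts removed per criterion (a row failing several criteria is
    counted under each)."""

    n_input: int
    n_kept: int
    removed_by_rt: int
    removed_by_area: int
    removed_by_score: int
    thresholds: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_kept": self.n_kept,
            "removed_by_rt": self.removed_by_rt,
            "removed_by_area": self.removed_by_area,
            "removed_by_score": self.removed_by_score,
            "thresholds": self.thresholds,
        }


def _require_columns(table: pd.DataFrame, cols: list[str]) -> None:
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"results table missing column(s): {missing}")


def apply_filters(
    table: pd.DataFrame,
    rt_min: float = DEFAULT_RT_MIN,
    area_min: float = DEFAULT_AREA_MIN,
    score_max: float = DEFAULT_SCORE_MAX,
    *,
    rt_col: str = "rt",
    area_col: str = "area",
    score_col: str = "score",
) -> tuple[pd.DataFrame, FilterReport]:
    """Keep rows with rt > rt_min AND area > area_min AND score < score_max.

    Inequalities are strict; input row order is preserved; the input table
    is not mutated.  Returns (filtered copy, report).
    """
    _require_columns(table, [rt_col, area_col, score_col])
    rt_ok = table[rt_col] > rt_min
    area_ok = table[area_col] > area_min
    score_ok = table[score_col] < score_max
    keep = rt_ok & area_ok & score_ok
    report = FilterReport(
        n_input=len(table),
        n_kept=int(keep.sum()),
        removed_by_rt=int((~rt_ok).sum()),
        removed_by_area=int((~area_ok).sum()),
        removed_by_score=int((~score_ok).sum()),
        thresholds={"rt_min": rt_min, "area_min": area_min,
                    "score_max": score_max},
    )
    return table.loc[keep].copy(), report


# any well-formed adduct token, e.g. "+H", "+HCOO", "-2H", "+NH4"
_ADDUCT_TOKEN = re.compile(r"[+-]\d*[A-Za-z][A-Za-z0-9]*")


def _adduct_ok(label: str, allowed: frozenset[int]) -> bool | None:
    """True if the label is an allowed deprotonation, False for any other
    recognizable adduct token (e.g. "+HCOO"), None for garbage strings."""
    s = str(label).strip()
    try:
        return AdductIon.from_label(s).n_protons_removed in allowed
    except ValueError:
        return False if _ADDUCT_TOKEN.fullmatch(s) else None


def restrict_adducts(
    table: pd.DataFrame,
    allowed: tuple[str, ...] = ("-H", "-2H"),
    *,
    adduct_col: str = "adduct",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep rows whose adduct is one of ``allowed`` (negative-mode
    deprotonations).  Rows with unparseable adduct strings are returned in
    a separate flagged table rather than silently dropped.

    Returns (kept, flagged).
    """
    _require_columns(table, [adduct_col])
    allowed_n = frozenset(
        AdductIon.from_label(lb).n_protons_removed for lb in allowed
    )
    status = table[adduct_col].map(lambda lb: _adduct_ok(lb, allowed_n))
    kept = table.loc[status == True].copy()  # noqa: E712 (status is object-typed)
    flagged = table.loc[status.isna()].copy()
    return kept, flagged
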