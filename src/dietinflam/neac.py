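"""Dietary non-enzymatic antioxidant capacity (NEAC) scoring.

NEAC is estimated on the TEAC scale (Trolox equivalent antioxidant capacity,
mmol TE per kg of edible food): each food item's daily gram intake is matched
against a TEAC content table and the per-item capacities are summed,

    ``NEAC (mmol TE/day) = sum_items grams/day / 1000 * TEAC (mmol TE/kg)``.

Coffee dominates total antioxidant intake in many populations, so totals are
computed both with and without coffee-flagged items; the no-coffee total is
the conventional exposure in descriptive tables.  Items absent from the TEAC
table are skipped with a logged count — FFQ/TEAC mismatches are expected.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import SubjectIntake, TeacTable

logger = logging.getLogger("dietinflam.neac")

__all__ = ["NeacResult", "item_teac", "compute_neac", "batch_neac", "score_item_frame"]


@dataclass
class NeacResult:
    """Per-subject antioxidant capacity, with and without coffee."""

    subject_id: str
    teac_total: float            # mmol TE/day, all matched items
    teac_total_no_coffee: float  # mmol TE/day, coffee-flagged items excluded
    n_items_matched: int
    include_coffee: bool = False

    @property
    def value(self) -> float:
        """The total selected as the exposure by the ``include_coffee`` flag."""
        return self.teac_total if self.include_coffee else self.teac_total_no_coffee


def item_teac(grams_per_day: float, teac_content_per_kg: float) -> float:
    """Daily antioxidant capacity from one item (mmol TE/day)."""
    if grams_per_day < 0 or teac_content_per_kg < 0:
        raise ValueError(
            f"negative input: grams={grams_per_day}, teac_content={teac_content_per_kg}"
        )
    return grams_per_day / 1000.0 * teac_content_per_kg


def compute_neac(
    subject: SubjectIntake, teac_table: TeacTable, include_coffee: bool = False
) -> NeacResult:
    """Sum item-level TEAC over a subject's matched food items."""
    if subject.item_grams is None:
        raise ValueError(f"subject {subject.subject_id} has no item_grams")
    contents = teac_table.contents
    coffee = teac_table.coffee_items
    matched, unmatched = [], []
    for item, grams in subject.item_grams.items():
        if item in contents:
            matched.append((item, grams))
        else:
            unmatched.append(item)
    if not matched:
        raise ValueError(
            f"subject {subject.subject_id}: no food item matches the TEAC table"
        )
    if unmatched:
        logger.info(
            "subject %s: %d unmatched item(s) skipped: %s",
            subject.subject_id, len(unmatched), unmatched,
        )
    total = math.fsum(item_teac(g, contents[i]) for i, g in matched)
    no_coffee = math.fsum(item_teac(g, contents[i]) for i, g in matched if i not in coffee)
    return NeacResult(subject.subject_id, total, no_coffee, len(matched), include_coffee)


def batch_neac(
    subjects: list[SubjectIntake], teac_table: TeacTable, include_coffee: bool = False
) -> tuple[list[NeacResult], list[tuple[str, str]]]:
    """Elementwise :func:`compute_neac`; failures go to the exclusion list."""
    results, excluded = [], []
    for subject in subjects:
        try:
            results.append(compute_neac(subject, teac_table, include_coffee))
        except ValueError as exc:
            excluded.append((subject.subject_id, str(exc)))
    return results, excluded


def score_item_frame(items: pd.DataFrame, teac_table: TeacTable) -> pd.DataFrame:
    """Vectorised NEAC for a wide subject × item gram table.

    ``items`` has a ``subject_id`` column (or index) plus one gram column per
    food item.  Returns subject_id, teac_total, teac_total_no_coffee and the
    matched-item count.
    """
    frame = items.reset_index() if "subject_id" not in items.columns else items
    contents = teac_table.contents
    coffee = teac_table.coffee_items
    cols = [c for c in frame.columns if c in contents]
    if not cols:
        raise ValueError("no item column matches the TEAC table")
    skipped = [c for c in frame.columns if c not in contents and c != "subject_id"]
    if skipped:
        logger.info("%d unmatched item column(s) skipped: %s", len(skipped), skipped)
    grams = frame[cols].to_numpy(float)
    if (grams < 0).any():
        raise ValueError("negative gram intakes in item table")
    weights = np.array([contents[c] for c in cols]) / 1000.0
    no_coffee_weights = np.array([0.0 if c in coffee else contents[c] for c in cols]) / 1000.0
    return pd.DataFrame(
        {
            "subject_id": frame["subject_id"].astype(str).to_numpy(),
            "teac_total": grams @ weights,
            "teac_total_no_coffee": grams @ no_coffee_weights,
            "n_items_matched": len(cols),
        }
    )
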