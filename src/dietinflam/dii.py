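"""Energy-adjusted dietary inflammatory index (E-DII) scoring.

The index aggregates, over food parameters (nutrients, a few whole foods),
how far a subject's diet sits from a global reference intake, weighted by each
parameter's literature-derived inflammatory effect score:

1. raw daily intake is converted to a density per 1000 kcal of total energy;
2. the density is standardised against the reference global mean and SD,
   ``z = (density - mean) / sd``;
3. the z-score is mapped to a proportion in (0, 1) — by default the standard
   normal CDF — then centred and doubled, ``2p - 1``, giving a symmetric score
   in (-1, 1);
4. the centred proportion is multiplied by the parameter's effect score
   (positive = pro-inflammatory, negative = anti-inflammatory) and the
   products are summed over all parameters available for the subject.

Higher totals indicate a more pro-inflammatory diet.  Each contribution is
bounded by ``|effect score|``, so the total is strictly bounded by the sum of
absolute effect scores over the parameters used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .io import ParameterReference, SubjectIntake

__all__ = [
    "EdiiResult",
    "energy_density",
    "parameter_score",
    "compute_edii",
    "batch_edii",
    "score_intake_frame",
]


@dataclass
class EdiiResult:
    """Per-subject E-DII decomposition."""

    subject_id: str
    edii_total: float
    contributions: dict[str, float]
    densities: dict[str, float]
    n_parameters_used: int


def energy_density(raw_intake: float, energy_kcal: float) -> float:
    """Convert a raw daily intake to a density per 1000 kcal."""
    if not (energy_kcal > 0):
        raise ValueError(f"energy_kcal must be positive, got {energy_kcal}")
    if raw_intake < 0:
        raise ValueError(f"raw_intake must be nonnegative, got {raw_intake}")
    return raw_intake * 1000.0 / energy_kcal


def parameter_score(
    density: float, global_mean: float, global_sd: float, effect_score: float
) -> float:
    """Signed inflammatory contribution of one parameter.

    ``(2 * Phi((density - mean)/sd) - 1) * effect_score``, strictly inside
    ``(-|effect_score|, +|effect_score|)`` for finite density.
    """
    vals = np.asarray([density, global_mean, global_sd, effect_score], float)
    if not np.isfinite(vals).all():
        raise ValueError(f"non-finite input to parameter_score: {vals}")
    if global_sd <= 0:
        raise ValueError(f"global_sd must be positive, got {global_sd}")
    z = (density - global_mean) / global_sd
    return (2.0 * float(ndtr(z)) - 1.0) * effect_score


def compute_edii(subject: SubjectIntake, reference: ParameterReference) -> EdiiResult:
    """Score one subject against a parameter reference.

    Only parameters present both in the subject's intakes and in the reference
    enter the sum; reference parameters the subject lacks are simply not used
    (absence is not a zero intake) and show up as a reduced
    ``n_parameters_used``.
    """
    usable = [name for name in subject.parameter_intakes if name in reference]
    if not usable:
        raise ValueError(
            f"subject {subject.subject_id}: no intake parameter resolves against the reference"
        )
    densities: dict[str, float] = {}
    contributions: dict[str, float] = {}
    for name in usable:
        rec = reference[name]
        d = energy_density(subject.parameter_intakes[name], subject.energy_kcal)
        densities[name] = d
        contributions[name] = parameter_score(d, rec.global_mean, rec.global_sd, rec.effect_score)
    total = math.fsum(contributions.values())
    return EdiiResult(subject.subject_id, total, contributions, densities, len(usable))


def batch_edii(
    subjects: list[SubjectIntake], reference: ParameterReference
) -> tuple[list[EdiiResult], list[tuple[str, str]]]:
    """Score a collection of subjects, preserving input order.

    Per-subject failures do not abort the batch; they are returned as
    ``(subject_id, reason)`` pairs for the exclusion manifest.
    """
    results: list[EdiiResult] = []
    excluded: list[tuple[str, str]] = []
    for subject in subjects:
        try:
            results.append(compute_edii(subject, reference))
        except ValueError as exc:
            excluded.append((subject.subject_id, str(exc)))
    return results, excluded


def score_intake_frame(
    frame: pd.DataFrame,
    reference: ParameterReference,
    energy_col: str = "energy_kcal",
    method: str = "normal",
) -> pd.DataFrame:
    """Vectorised scoring of a wide intake table.

    ``frame`` holds one row per subject with ``subject_id``, ``energy_col``
    and raw-intake columns; columns are intersected with the reference.
    ``method="normal"`` maps z-scores through the standard normal CDF (the
    default construction); ``method="empirical"`` replaces the CDF with the
    within-sample empirical percentile of the density (mid-ranks), an
    alternative occasionally used when no external reference is trusted.
    """
    if method not in ("normal", "empirical"):
        raise ValueError(f"unknown proportion method {method!r}")
    params = [c for c in frame.columns if c in reference]
    if not params:
        raise ValueError("no intake column resolves against the reference")
    energy = frame[energy_col].to_numpy(float)
    if (energy <= 0).any():
        raise ValueError("all subjects must have positive energy intake")
    raw = frame[params].to_numpy(float)
    dens = raw * 1000.0 / energy[:, None]
    means = np.array([reference[p].global_mean for p in params])
    sds = np.array([reference[p].global_sd for p in params])
    effects = np.array([reference[p].effect_score for p in params])
    if method == "normal":
        prop = ndtr((dens - means) / sds)
    else:
        n = len(frame)
        order = np.argsort(dens, axis=0, kind="stable")
        ranks = np.empty_like(dens)
        rows = np.arange(n)
        for j in range(dens.shape[1]):
            ranks[order[:, j], j] = rows
        prop = (ranks + 0.5) / n
    contrib = (2.0 * prop - 1.0) * effects
    out = pd.DataFrame(
        {
            "subject_id": frame["subject_id"].astype(str).to_numpy(),
            "edii_total": contrib.sum(axis=1),
            "n_parameters_used": len(params),
        }
    )
    for j, p in enumerate(params):
        out[f"contrib_{p}"] = contrib[:, j]
    return out
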