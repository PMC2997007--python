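"""Kinetic regulation-mode classification of treatment:LPS time profiles.

Each gene's response to a compound is summarized as a log2 time profile of
its (compound+LPS):(LPS only) expression ratio.  Profiles are classified into
four regulation modes keyed to three anchor times (early 0.5 h, delayed 2 h,
up 4 h):

- early down-regulation followed by up-regulation
- early non-response followed by up-regulation
- delayed down-regulation followed by up-regulation
- other (residual)

A direction call at an anchor time uses a symmetric log2 threshold theta:
DOWN if log2 ratio <= -theta, UP if >= +theta, NONE otherwise.  Treatment
similarity is measured as mode concordance: the percentage of a reference
treatment's mode group whose genes receive the same mode under another
treatment.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

#: Default direction threshold: 1.5-fold in linear scale, well below the
#: 3-fold hit threshold but above typical replicate noise.
DEFAULT_THETA = float(np.log2(1.5))

DEFAULT_EARLY_T = 0.5
DEFAULT_DELAYED_T = 2.0
DEFAULT_UP_T = 4.0


class RegulationMode(str, Enum):
    EARLY_DOWN_THEN_UP = "early_down_then_up"
    EARLY_NONE_THEN_UP = "early_none_then_up"
    DELAYED_DOWN_THEN_UP = "delayed_down_then_up"
    OTHER = "other"


class BaselineDirection(str, Enum):
    UP = "up"
    DOWN = "down"


@dataclass(frozen=True)
class ConcordanceResult:
    reference_treatment: str
    other_treatment: str
    mode_group: RegulationMode
    n_group: int
    n_same: int
    percent_same: float  # NaN when the group is empty

    @property
    def empty_group(self) -> bool:
        return self.n_group == 0


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, matching printed percentages."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def build_profiles(matrix: pd.DataFrame, treatment: str) -> pd.DataFrame:
    """Log2 time profiles for one treatment from a linear ratio matrix.

    Returns genes x times (columns sorted ascending).  Genes missing at any
    time point for the treatment are dropped.
    """
    if not isinstance(matrix.columns, pd.MultiIndex):
        raise ValueError("build_profiles needs a (treatment, time_h) column MultiIndex")
    if treatment not in matrix.columns.get_level_values("treatment"):
        raise ValueError(f"treatment {treatment!r} not in matrix")
    sub = matrix.xs(treatment, axis=1, level="treatment").sort_index(axis=1)
    if sub.shape[1] < 2:
        raise ValueError(f"treatment {treatment!r} has fewer than 2 time points")
    sub = sub.dropna(axis=0, how="any")
    if (sub.to_numpy(dtype=float) <= 0).any():
        raise ValueError("linear ratios must be strictly positive")
    return np.log2(sub)


def _direction(value: float, theta: float) -> int:
    """-1 DOWN, +1 UP, 0 NONE at a single anchor."""
    if value <= -theta:
        return -1
    if value >= theta:
        return 1
    return 0


def classify_mode(
    profile: pd.Series | Mapping[float, float],
    theta: float = DEFAULT_THETA,
    early_t: float = DEFAULT_EARLY_T,
    delayed_t: float = DEFAULT_DELAYED_T,
    up_t: float = DEFAULT_UP_T,
) -> RegulationMode:
    """Classify one log2 profile into a regulation mode.

    Precedence (the modes are treated as disjoint): early-down beats
    delayed-down beats early-none; anything else is OTHER.
    """
    if theta <= 0:
        raise ValueError("theta must be positive")
    prof = dict(profile.items()) if isinstance(profile, pd.Series) else dict(profile)
    for t in (early_t, delayed_t, up_t):
        if t not in prof:
            name = getattr(profile, "name", None)
            who = f" for gene {name!r}" if name else ""
            raise ValueError(f"profile missing anchor time {t}{who}")
    early = _direction(prof[early_t], theta)
    delayed = _direction(prof[delayed_t], theta)
    up = _direction(prof[up_t], theta)
    if early == -1 and up == 1:
        return RegulationMode.EARLY_DOWN_THEN_UP
    if early != -1 and delayed == -1 and up == 1:
        return RegulationMode.DELAYED_DOWN_THEN_UP
    if early == 0 and up == 1:
        return RegulationMode.EARLY_NONE_THEN_UP
    return RegulationMode.OTHER


def classify_modes(
    profiles: pd.DataFrame,
    theta: float = DEFAULT_THETA,
    early_t: float = DEFAULT_EARLY_T,
    delayed_t: float = DEFAULT_DELAYED_T,
    up_t: float = DEFAULT_UP_T,
) -> pd.Series:
    """Classify every row of a genes x times log2 profile matrix."""
    return pd.Series(
        {
            gene: classify_mode(profiles.loc[gene], theta, early_t, delayed_t, up_t)
            for gene in profiles.index
        },
        name="mode",
    )


def classify_baseline(profile: pd.Series, theta: float = DEFAULT_THETA) -> BaselineDirection:
    """Up/Down tag from the LPS-vs-vehicle profile's initial response.

    If the first time point is within (-theta, +theta) the sign of the
    largest-magnitude excursion anywhere in the profile decides; an all-zero
    profile defaults to UP.
    """
    if len(profile) == 0:
        raise ValueError("empty profile")
    vals = profile.sort_index().to_numpy(dtype=float)
    first = vals[0]
    if first >= theta:
        return BaselineDirection.UP
    if first <= -theta:
        return BaselineDirection.DOWN
    peak = vals[int(np.argmax(np.abs(vals)))]
    return BaselineDirection.DOWN if peak < 0 else BaselineDirection.UP


def concordance(
    modes_ref: Mapping[str, RegulationMode],
    modes_other: Mapping[str, RegulationMode],
    group: RegulationMode,
    reference_treatment: str = "reference",
    other_treatment: str = "other",
) -> ConcordanceResult:
    """Fraction of the reference mode group retained by another treatment.

    percent_same = 100 * n_same / n_group, rounded half-up to one decimal.
    An empty group yields n_group = 0 and percent NaN (flagged via
    ``empty_group``).
    """
    group = RegulationMode(group)
    members = [g for g, m in modes_ref.items() if RegulationMode(m) == group]
    missing = [g for g in members if g not in modes_other]
    if missing:
        raise ValueError(f"genes in reference group missing from other treatment: {missing}")
    n_group = len(members)
    n_same = sum(1 for g in members if RegulationMode(modes_other[g]) == group)
    percent = round_half_up(100.0 * n_same / n_group, 1) if n_group else float("nan")
    return ConcordanceResult(
        reference_treatment, other_treatment, group, n_group, n_same, percent
    )


def concordance_table(
    modes_by_treatment: Mapping[str, Mapping[str, RegulationMode]],
    reference: str,
) -> pd.DataFrame:
    """All-groups, all-treatments concordance against a reference treatment."""
    if reference not in modes_by_treatment:
        raise ValueError(f"reference treatment {reference!r} not present")
    rows = []
    for other, modes_other in modes_by_treatment.items():
        if other == reference:
            continue
        for group in RegulationMode:
            res = concordance(
                modes_by_treatment[reference], modes_other, group, reference, other
            )
            rows.append(
                {
                    "reference": res.reference_treatment,
                    "other": res.other_treatment,
                    "mode_group": res.mode_group.value,
                    "n_group": res.n_group,
                    "n_same": res.n_same,
                    "percent_same": res.percent_same,
                }
            )
    return pd.DataFrame(rows)


class RegulationModeClassifier(BaseEstimator):
    """Rule-based kinetic mode classifier in scikit-learn clothing.

    Parameters
    ----------
    theta : float
        Symmetric log2 threshold separating up/down from non-response.
    early_t, delayed_t, up_t : float
        Anchor times (hours) for the early, delayed and up calls.

    ``predict`` takes a genes x times DataFrame of log2 treatment:LPS ratios
    and returns one mode per gene.  ``fit`` only validates that the anchor
    times are present (the rule has no free parameters to learn).
    """

    def __init__(
        self,
        theta: float = DEFAULT_THETA,
        early_t: float = DEFAULT_EARLY_T,
        delayed_t: float = DEFAULT_DELAYED_T,
        up_t: float = DEFAULT_UP_T,
    ):
        self.theta = theta
        self.early_t = early_t
        self.delayed_t = delayed_t
        self.up_t = up_t

    def fit(self, X: pd.DataFrame, y=None):
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        missing = [t for t in (self.early_t, self.delayed_t, self.up_t) if t not in X.columns]
        if missing:
            raise ValueError(f"profile matrix missing anchor times {missing}")
        self.anchor_times_ = (self.early_t, self.delayed_t, self.up_t)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X: pd.DataFrame) -> pd.Series:
        return classify_modes(X, self.theta, self.early_t, self.delayed_t, self.up_t)
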