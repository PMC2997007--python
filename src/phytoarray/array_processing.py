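"""Two-color focused-array processing: spot tables to normalized ratio matrices.

The focused array carries ~228 immune-related genes, each printed as four
replicate spots, hybridized with a Cy3-labelled control sample and a
Cy5-labelled test sample.  The per-gene readout is the test:control intensity
ratio.  The chain implemented here is

    background correction -> per-spot ratio -> replicate aggregation
    -> housekeeping-reference normalization -> fold-change filtering

A ratio matrix is a pandas DataFrame indexed by gene symbol with one column
per experimental condition.  Conditions are either a plain treatment label or
a ``(treatment, time_h)`` pair (MultiIndex).  Metadata (reference gene, ratio
semantics) travels in ``DataFrame.attrs``.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

#: Functional categories in the order the hit tables are laid out.
CATEGORIES = (
    "cytokines",
    "chemotaxis_migration",
    "inflammatory_response",
    "other",
    "housekeeping",
)

#: Intensity floor applied after background subtraction, in scanner units.
INTENSITY_FLOOR = 1.0

SPOT_COLUMNS = [
    "probe_id",
    "gene_symbol",
    "replicate",
    "ch_control_fg",
    "ch_control_bg",
    "ch_test_fg",
    "ch_test_bg",
    "flag",
]

DESIGN_COLUMNS = ["gene_symbol", "gene_id", "category", "is_housekeeping"]
MANIFEST_COLUMNS = ["hybridization_id", "treatment", "time_h", "test_label", "control_label"]


class ValidationError(ValueError):
    """Raised when an input table violates its schema or invariants."""


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_design(path) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t")
    validate_design(design)
    return design


def validate_design(design: pd.DataFrame) -> None:
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise ValidationError(f"array design missing columns: {missing}")
    if design["gene_symbol"].duplicated().any():
        dups = design.loc[design["gene_symbol"].duplicated(), "gene_symbol"].tolist()
        raise ValidationError(f"duplicate gene symbols in design: {dups}")
    unknown = set(design["category"]) - set(CATEGORIES)
    if unknown:
        raise ValidationError(f"unknown categories in design: {sorted(unknown)}")


def read_spot_table(path) -> pd.DataFrame:
    spots = pd.read_csv(path, sep="\t")
    validate_spot_table(spots)
    return spots


def validate_spot_table(spots: pd.DataFrame) -> None:
    missing = [c for c in SPOT_COLUMNS if c not in spots.columns]
    if missing:
        raise ValidationError(f"spot table missing columns: {missing}")
    if spots.duplicated(subset=["gene_symbol", "replicate"]).any():
        raise ValidationError("duplicate (gene_symbol, replicate) rows in spot table")
    for ch in ("ch_control_fg", "ch_control_bg", "ch_test_fg", "ch_test_bg"):
        vals = spots[ch].to_numpy(dtype=float)
        bad = ~np.isfinite(vals) | (vals < 0)
        if bad.any():
            probe = spots.loc[np.flatnonzero(bad)[0], "probe_id"]
            raise ValidationError(
                f"negative or non-finite intensity in channel {ch!r} at probe {probe!r}"
            )
    bad_flags = set(spots["flag"]) - {"ok", "bad"}
    if bad_flags:
        raise ValidationError(f"unknown spot flags: {sorted(bad_flags)}")


def read_manifest(path) -> pd.DataFrame:
    manifest = pd.read_csv(path, sep="\t")
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ValidationError(f"manifest missing columns: {missing}")
    if manifest.duplicated(subset=["treatment", "time_h"]).any():
        raise ValidationError("duplicate (treatment, time_h) pairs in manifest")
    return manifest


def write_ratio_matrix(matrix: pd.DataFrame, path) -> None:
    """Write a ratio matrix as TSV with ``treatment@time`` column headers."""
    out = matrix.copy()
    if isinstance(out.columns, pd.MultiIndex):
        out.columns = [f"{t}@{h:g}" for t, h in out.columns]
    out.index.name = "gene_symbol"
    out.to_csv(path, sep="\t")


def read_ratio_matrix(path) -> pd.DataFrame:
    matrix = pd.read_csv(path, sep="\t", index_col="gene_symbol")
    if all("@" in c for c in matrix.columns):
        pairs = [c.rsplit("@", 1) for c in matrix.columns]
        matrix.columns = pd.MultiIndex.from_tuples(
            [(t, float(h)) for t, h in pairs], names=["treatment", "time_h"]
        )
    return matrix


# ---------------------------------------------------------------------------
# spot-level operations
# ---------------------------------------------------------------------------

def background_correct(fg, bg, floor: float = INTENSITY_FLOOR, probe_id=None, channel=None):
    """Background-subtract a channel, flooring at ``floor`` intensity units.

    Works elementwise on scalars or arrays; the floor keeps every downstream
    ratio strictly positive.
    """
    fg = np.asarray(fg, dtype=float)
    bg = np.asarray(bg, dtype=float)
    bad = ~np.isfinite(fg) | ~np.isfinite(bg) | (fg < 0) | (bg < 0)
    if np.any(bad):
        where = f" at probe {probe_id!r}" if probe_id is not None else ""
        which = f" channel {channel!r}" if channel is not None else ""
        raise ValidationError(f"negative or non-finite intensity{which}{where}")
    out = np.maximum(fg - bg, floor)
    return float(out) if out.ndim == 0 else out


def spot_ratios(spots: pd.DataFrame, floor: float = INTENSITY_FLOOR) -> pd.DataFrame:
    """Per-spot test:control ratios after background correction.

    Flagged ('bad') spots are dropped.  Returns columns gene_symbol,
    replicate, ratio.
    """
    validate_spot_table(spots)
    ok = spots[spots["flag"] == "ok"]
    control = background_correct(
        ok["ch_control_fg"].to_numpy(), ok["ch_control_bg"].to_numpy(), floor
    )
    test = background_correct(ok["ch_test_fg"].to_numpy(), ok["ch_test_bg"].to_numpy(), floor)
    return pd.DataFrame(
        {
            "gene_symbol": ok["gene_symbol"].to_numpy(),
            "replicate": ok["replicate"].to_numpy(),
            "ratio": test / control,
        }
    )


def aggregate_replicates(ratios: Sequence[float], method: str = "median") -> float:
    """Collapse replicate spot ratios for one gene into a single value.

    ``median`` is the default (robust against one aberrant spot out of four);
    ``mean`` is offered as the alternative reading of per-array averaging.
    """
    arr = np.asarray(list(ratios), dtype=float)
    if arr.size == 0:
        raise ValidationError("no usable replicate ratios to aggregate")
    if method == "median":
        return float(np.median(arr))
    if method == "mean":
        return float(np.mean(arr))
    raise ValidationError(f"unknown aggregation method {method!r}")


def process_hybridization(
    spots: pd.DataFrame,
    design: pd.DataFrame,
    aggregate: str = "median",
    floor: float = INTENSITY_FLOOR,
) -> pd.Series:
    """Per-gene aggregated ratio for one hybridization.

    Genes with zero unflagged spots come back as NaN (missing) and are
    counted in a log record.
    """
    per_spot = spot_ratios(spots, floor)
    agg = per_spot.groupby("gene_symbol")["ratio"].apply(
        lambda r: aggregate_replicates(r.to_numpy(), aggregate)
    )
    result = agg.reindex(design["gene_symbol"])
    n_missing = int(result.isna().sum())
    if n_missing:
        logger.info("hybridization: %d gene(s) missing (all spots flagged)", n_missing)
    return result


def process_experiment(
    spot_tables: Mapping[str, pd.DataFrame],
    manifest: pd.DataFrame,
    design: pd.DataFrame,
    aggregate: str = "median",
    reference_gene: str | None = "ACTB",
    floor: float = INTENSITY_FLOOR,
) -> pd.DataFrame:
    """Assemble the genes x (treatment, time) ratio matrix for an experiment.

    Each hybridization in the manifest contributes one column.  If
    ``reference_gene`` is given the matrix is normalized to that housekeeping
    gene's row.  Ratio semantics follow the chip design recorded in the
    manifest (typically test vs same-time vehicle).
    """
    columns = {}
    for row in manifest.itertuples(index=False):
        hyb = row.hybridization_id
        if hyb not in spot_tables:
            raise ValidationError(f"manifest references missing hybridization {hyb!r}")
        columns[(row.treatment, float(row.time_h))] = process_hybridization(
            spot_tables[hyb], design, aggregate, floor
        )
    matrix = pd.DataFrame(columns)
    matrix.columns = pd.MultiIndex.from_tuples(matrix.columns, names=["treatment", "time_h"])
    matrix = matrix.sort_index(axis=1)
    matrix.attrs["semantics"] = "test_vs_vehicle"
    if reference_gene is not None:
        matrix = normalize_to_reference(matrix, reference_gene, design)
    return matrix


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def normalize_to_reference(
    matrix: pd.DataFrame, reference_gene: str, design: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Divide every gene's ratio by the reference (housekeeping) gene's ratio.

    The reference row becomes exactly 1.0 in every condition; applying the
    operation twice equals applying it once.
    """
    if reference_gene not in matrix.index:
        raise ValidationError(f"reference gene {reference_gene!r} not in matrix")
    if design is not None:
        row = design.loc[design["gene_symbol"] == reference_gene]
        if row.empty or not bool(row["is_housekeeping"].iloc[0]):
            raise ValidationError(
                f"reference gene {reference_gene!r} is not housekeeping-flagged in the design"
            )
    ref = matrix.loc[reference_gene]
    bad = ~(ref > 0) | ~np.isfinite(ref.to_numpy(dtype=float))
    if bad.any():
        offending = list(ref.index[bad])
        raise ValidationError(
            f"reference gene {reference_gene!r} non-positive or missing in conditions: {offending}"
        )
    out = matrix.div(ref, axis=1)
    out.attrs = dict(matrix.attrs)
    out.attrs["reference_gene"] = reference_gene
    return out


class ReferenceNormalizer(TransformerMixin, BaseEstimator):
    """Housekeeping-reference normalization as a scikit-learn transformer.

    Parameters
    ----------
    reference_gene : str, default "ACTB"
        Gene whose row defines the per-condition scale.  Beta-actin is the
        conventional choice among the five spotted housekeeping controls.
    """

    def __init__(self, reference_gene: str = "ACTB"):
        self.reference_gene = reference_gene

    def fit(self, X: pd.DataFrame, y=None):
        if self.reference_gene not in X.index:
            raise ValidationError(f"reference gene {self.reference_gene!r} not in matrix")
        self.reference_row_ = X.loc[self.reference_gene].copy()
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return normalize_to_reference(X, self.reference_gene)


# ---------------------------------------------------------------------------
# ratio semantics
# ---------------------------------------------------------------------------

def ratio_of_ratios(test_vs_vehicle, lps_vs_vehicle):
    """(compound+LPS : vehicle) / (LPS : vehicle) = compound+LPS : LPS.

    Both arguments must refer to the same gene and time point; this is the
    treatment:LPS ratio reported throughout the hit tables.
    """
    a = np.asarray(test_vs_vehicle, dtype=float)
    b = np.asarray(lps_vs_vehicle, dtype=float)
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValidationError("ratio_of_ratios requires strictly positive ratios")
    out = a / b
    return float(out) if out.ndim == 0 else out


def treatment_vs_lps(matrix: pd.DataFrame, lps_treatment: str = "LPS") -> pd.DataFrame:
    """Convert a vehicle-referenced matrix into treatment:LPS ratios.

    Every non-LPS column is divided by the LPS column at the same time point.
    Treatment labels of the form ``"<compound>+LPS"`` are shortened to the
    compound name in the output.
    """
    if not isinstance(matrix.columns, pd.MultiIndex):
        raise ValidationError("treatment_vs_lps needs (treatment, time_h) columns")
    treatments = matrix.columns.get_level_values("treatment")
    if lps_treatment not in set(treatments):
        raise ValidationError(f"LPS treatment {lps_treatment!r} not in matrix")
    lps = matrix.xs(lps_treatment, axis=1, level="treatment")
    cols = {}
    for treatment, time_h in matrix.columns:
        if treatment == lps_treatment:
            continue
        if time_h not in lps.columns:
            raise ValidationError(
                f"no LPS column at time {time_h} to match treatment {treatment!r}"
            )
        label = treatment[: -len("+LPS")] if treatment.endswith("+LPS") else treatment
        cols[(label, time_h)] = ratio_of_ratios(
            matrix[(treatment, time_h)].to_numpy(), lps[time_h].to_numpy()
        )
    out = pd.DataFrame(cols, index=matrix.index)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["treatment", "time_h"])
    out.attrs["semantics"] = "treatment_vs_LPS"
    return out


# ---------------------------------------------------------------------------
# fold-change filtering
# ---------------------------------------------------------------------------

def filter_fold_change(
    matrix: pd.DataFrame,
    threshold: float = 3.0,
    treatments: Iterable[str] | None = None,
    rule: str = "any_treatment",
    direction: str = "both",
    time_h: float | None = None,
    design: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Retain genes changed at least ``threshold``-fold (inclusive).

    A gene counts as up under a treatment iff its linear ratio r satisfies
    r >= threshold, and as down iff r <= 1/threshold; ``rule`` decides whether
    one (``any_treatment``) or every (``all_treatments``) selected treatment
    must pass.  Missing (NaN) ratios never trigger and fail the ``all`` rule.

    Returns a hit table sorted by category then gene_id, one row per
    (gene, direction), with the selected treatments' ratios, the triggering
    treatments, and the time point.
    """
    if threshold <= 1:
        raise ValidationError("fold-change threshold must exceed 1")
    if rule not in ("any_treatment", "all_treatments"):
        raise ValidationError(f"unknown rule {rule!r}")
    if direction not in ("up", "down", "both"):
        raise ValidationError(f"unknown direction {direction!r}")

    if isinstance(matrix.columns, pd.MultiIndex):
        if time_h is None:
            raise ValidationError("time_h is required for a (treatment, time) matrix")
        sub = matrix.xs(float(time_h), axis=1, level="time_h")
    else:
        sub = matrix
    if treatments is None:
        treatments = list(sub.columns)
    else:
        treatments = list(treatments)
    if not treatments:
        raise ValidationError("empty treatment set")
    missing = [t for t in treatments if t not in sub.columns]
    if missing:
        raise ValidationError(f"treatments not in matrix: {missing}")
    sub = sub[treatments]

    vals = sub.to_numpy(dtype=float)
    up = vals >= threshold
    down = vals <= 1.0 / threshold
    combine = np.any if rule == "any_treatment" else np.all
    rows = []
    for direc, mask in (("up", up), ("down", down)):
        if direction not in (direc, "both"):
            continue
        hit = combine(np.where(np.isnan(vals), False, mask), axis=1)
        if rule == "all_treatments":
            hit &= ~np.isnan(vals).any(axis=1)
        for i in np.flatnonzero(hit):
            gene = sub.index[i]
            triggered = [t for j, t in enumerate(treatments) if mask[i, j]]
            row = {"gene_symbol": gene}
            if design is not None:
                drow = design.loc[design["gene_symbol"] == gene]
                if not drow.empty:
                    row["gene_id"] = int(drow["gene_id"].iloc[0])
                    row["category"] = drow["category"].iloc[0]
            row.update({t: sub.iloc[i][t] for t in treatments})
            row["direction"] = direc
            if time_h is not None:
                row["time_h"] = float(time_h)
            row["triggered_by"] = ",".join(triggered)
            rows.append(row)

    columns = ["gene_symbol"]
    if design is not None:
        columns += ["gene_id", "category"]
    columns += list(treatments) + ["direction"]
    if time_h is not None:
        columns.append("time_h")
    columns.append("triggered_by")
    hits = pd.DataFrame(rows, columns=columns)
    if design is not None and not hits.empty:
        order = {c: k for k, c in enumerate(CATEGORIES)}
        hits = hits.sort_values(
            by=["category", "gene_id"],
            key=lambda s: s.map(order) if s.name == "category" else s,
            kind="mergesort",
        ).reset_index(drop=True)
    return hits


class FoldChangeFilter(TransformerMixin, BaseEstimator):
    """Fold-change gene filter with the inclusive >=T / <=1/T rule.

    ``transform`` maps a linear ratio matrix to its hit table.  This is the
    significance rule of the focused-array analysis: no moderated statistics,
    a pure threshold on the ratio (default threefold).
    """

    def __init__(
        self,
        threshold: float = 3.0,
        treatments: Sequence[str] | None = None,
        rule: str = "any_treatment",
        direction: str = "both",
        time_h: float | None = None,
    ):
        self.threshold = threshold
        self.treatments = treatments
        self.rule = rule
        self.direction = direction
        self.time_h = time_h

    def fit(self, X: pd.DataFrame, y=None):
        if self.threshold <= 1:
            raise ValidationError("fold-change threshold must exceed 1")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame, design: pd.DataFrame | None = None) -> pd.DataFrame:
        return filter_fold_change(
            X,
            threshold=self.threshold,
            treatments=self.treatments,
            rule=self.rule,
            direction=self.direction,
            time_h=self.time_h,
            design=design,
        )
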