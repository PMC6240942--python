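"""Internal-standard GC-MS/LC-MS quantification for in vivo variant screens.

The pipeline starts at integrated peak areas. Every extraction is spiked
with an internal standard (IS, e.g. 1-eicosene); the relative yield of a
compound is its peak area divided by the IS area of the same run, averaged
over biological replicates. Absolute titers (mg/L) come from linear
standard curves of normalized response against concentration; a compound
without an authentic standard can be quantified through the curve of a
structurally close compound by assuming an identical response factor.

Derived per-strain specificity metrics:

* ``total`` — summed titers over the quantified compound set;
* ``oxygenated_pct`` — share of total that is not the unmodified substrate
  (compound 1): ``100 * (total - titer_1) / total``;
* ``content2_pct`` — share of total that is the target product (compound 2).

Percentages are reported rounded to integers, fold changes to one decimal
and titers to one decimal; unrounded values are kept throughout.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

IS_COMPOUND = "IS"
PEAK_COLUMNS = ("strain", "variant", "replicate", "timepoint_h", "compound", "area")
CALIBRATION_COLUMNS = ("compound", "concentration_mg_per_L", "area", "is_area")
DEFAULT_QUANTIFIED = ("1", "2", "3", "7")
GROUP_KEYS = ("strain", "variant", "replicate", "timepoint_h")


@dataclass(frozen=True)
class StandardCurve:
    """OLS fit of normalized response (area / IS area) on concentration."""

    compound: str
    slope: float
    intercept: float
    r_squared: float
    concentration_range: tuple[float, float]

    def concentration(self, response: float) -> float:
        """Concentration (mg/L) for a normalized response, floored at 0."""
        return max(0.0, (response - self.intercept) / self.slope)


@dataclass(frozen=True)
class StrainMetrics:
    """Per-strain titers and derived specificity metrics."""

    strain: str
    titers: Mapping[str, float]
    total: float
    oxygenated_pct: float
    content2_pct: float
    fold_changes: Mapping[str, float] = field(default_factory=dict)

    def rounded(self) -> dict[str, float]:
        out: dict[str, float] = {
            "strain": self.strain,
            "total_mg_per_L": round(self.total, 1),
            "oxygenated_pct": round(self.oxygenated_pct),
            "content2_pct": round(self.content2_pct),
        }
        for compound, titer in self.titers.items():
            out[f"titer_{compound}_mg_per_L"] = round(titer, 1)
        for compound, fc in self.fold_changes.items():
            out[f"fold_change_{compound}"] = round(fc, 1) if math.isfinite(fc) else fc
        return out


# ---------------------------------------------------------------------------
# Peak tables


def read_peak_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"strain": str, "variant": str, "compound": str})
    missing = set(PEAK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if (df["area"] < 0).any():
        raise ValueError(f"{path}: negative peak areas present")
    return df


def read_calibration(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"compound": str})
    missing = set(CALIBRATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def _normalize_to_is(peaks: pd.DataFrame) -> pd.DataFrame:
    """Divide every area by the IS area of its (strain, variant, replicate,
    timepoint) group; IS rows are dropped. Raises when a group lacks exactly
    one positive-area IS record."""
    keys = [k for k in GROUP_KEYS if k in peaks.columns]
    out = []
    for group_id, group in peaks.groupby(keys, sort=False):
        is_rows = group[group["compound"] == IS_COMPOUND]
        if len(is_rows) != 1:
            raise ValueError(
                f"group {dict(zip(keys, group_id))} has {len(is_rows)} internal-standard "
                "records; expected exactly 1"
            )
        is_area = float(is_rows["area"].iloc[0])
        if is_area <= 0:
            raise ValueError(
                f"group {dict(zip(keys, group_id))} has non-positive internal-standard area"
            )
        analytes = group[group["compound"] != IS_COMPOUND].copy()
        analytes["relative"] = analytes["area"] / is_area
        out.append(analytes)
    return pd.concat(out, ignore_index=True)


def relative_yield(
    peaks: pd.DataFrame,
    group_by: Sequence[str] = ("strain", "variant", "compound", "timepoint_h"),
) -> pd.DataFrame:
    """Mean IS-normalized response per group, with sample SD and n.

    The SD over biological replicates is what error bars on relative-yield
    plots show.
    """
    normalized = _normalize_to_is(peaks)
    agg = (
        normalized.groupby(list(group_by), sort=False)["relative"]
        .agg(mean="mean", sd=lambda x: x.std(ddof=1), n="count")
        .reset_index()
    )
    return agg


def fold_change(
    yields: pd.DataFrame,
    strain: str,
    reference: str,
    compound: str,
    value_col: str = "mean",
    strain_col: str = "strain",
) -> float:
    """Ratio of a strain's mean response (or titer) to the reference's.

    Returns ``inf`` when the reference mean is 0 and the strain's is not,
    and ``nan`` when both are 0.
    """
    def lookup(name: str) -> float:
        sel = yields[(yields[strain_col] == name) & (yields["compound"] == compound)]
        if sel.empty:
            raise KeyError(f"no rows for strain {name!r}, compound {compound!r}")
        return float(sel[value_col].mean())

    num, den = lookup(strain), lookup(reference)
    if den == 0:
        return math.nan if num == 0 else math.inf
    return num / den


# ---------------------------------------------------------------------------
# Standard curves and titers


def fit_standard_curve(calibration: pd.DataFrame, compound: str) -> StandardCurve:
    """Least-squares line through (concentration, area / IS area) points."""
    points = calibration[calibration["compound"] == compound]
    if points.empty:
        raise ValueError(f"no calibration points for compound {compound!r}")
    conc = points["concentration_mg_per_L"].to_numpy(dtype=float)
    response = (points["area"] / points["is_area"]).to_numpy(dtype=float)
    if len(np.unique(conc)) < 2:
        raise ValueError(
            f"compound {compound!r}: need at least 2 distinct concentrations"
        )
    fit = stats.linregress(conc, response)
    if fit.slope <= 0:
        raise ValueError(f"compound {compound!r}: non-positive calibration slope")
    return StandardCurve(
        compound,
        float(fit.slope),
        float(fit.intercept),
        float(fit.rvalue**2),
        (float(conc.min()), float(conc.max())),
    )


def absolute_titer(
    responses: Mapping[str, float],
    curves: Mapping[str, StandardCurve],
    response_map: Optional[Mapping[str, str]] = None,
) -> dict[str, float]:
    """Titers (mg/L) from mean normalized responses through standard curves.

    ``response_map`` routes a compound to the curve of another compound with
    an assumed identical response factor (e.g. an unidentified derivative
    quantified on its parent's curve). Compounds in ``response_map`` whose
    curve is missing raise; compounds with no mapping and no own curve are
    skipped with a warning.
    """
    response_map = dict(response_map or {})
    titers: dict[str, float] = {}
    for compound, response in responses.items():
        curve_id = response_map.get(compound, compound)
        if curve_id not in curves:
            if compound in response_map:
                raise KeyError(
                    f"compound {compound!r} is mapped to curve {curve_id!r} "
                    "which was not provided"
                )
            logger.warning("compound %r has no standard curve; excluded", compound)
            continue
        titers[compound] = curves[curve_id].concentration(response)
    return titers


def strain_metrics(
    titers: Mapping[str, float],
    strain: str = "",
    reference_titers: Optional[Mapping[str, float]] = None,
    quantified: Sequence[str] = DEFAULT_QUANTIFIED,
) -> StrainMetrics:
    """Total production, oxygenated share, target-product share, fold changes.

    Compound "1" is the unmodified substrate. Missing compounds in the
    quantified set contribute 0. Zero-total strains report 0% rather than
    undefined shares.
    """
    values = {c: float(titers.get(c, 0.0)) for c in quantified}
    total = sum(values.values())
    if total > 0:
        oxygenated = 100.0 * (total - values.get("1", 0.0)) / total
        content2 = 100.0 * values.get("2", 0.0) / total
    else:
        oxygenated = 0.0
        content2 = 0.0
    fold_changes: dict[str, float] = {}
    if reference_titers is not None:
        for compound in quantified:
            ref = float(reference_titers.get(compound, 0.0))
            val = values[compound]
            if ref == 0:
                fold_changes[compound] = math.nan if val == 0 else math.inf
            else:
                fold_changes[compound] = val / ref
    return StrainMetrics(strain, values, total, oxygenated, content2, fold_changes)


# ---------------------------------------------------------------------------
# Statistics and time courses


def compare_groups(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """Two-sided Welch two-sample t-test p-value.

    When both groups have zero variance the p-value is 1 for equal means and
    0 otherwise, by convention.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def timecourse_summary(
    series: pd.DataFrame,
    value_col: str = "value",
    threshold: float = 0.10,
) -> pd.DataFrame:
    """Per strain/compound production series with a stagnation flag.

    A series stagnates when the increase over the final interval is less
    than ``threshold`` of the final value.
    """
    rows = []
    for (strain, compound), group in series.groupby(["strain", "compound"], sort=False):
        g = group.sort_values("timepoint_h")
        values = g[value_col].to_numpy(dtype=float)
        if len(values) < 2:
            raise ValueError(
                f"strain {strain!r} compound {compound!r}: need >= 2 timepoints"
            )
        final = values[-1]
        increase = final - values[-2]
        stagnated = bool(final > 0 and increase < threshold * final)
        rows.append(
            {
                "strain": strain,
                "compound": compound,
                "final_timepoint_h": float(g["timepoint_h"].iloc[-1]),
                "final_value": final,
                "last_interval_increase": increase,
                "stagnated": stagnated,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Reports


def write_metrics_report(metrics: Sequence[StrainMetrics], path: str | Path) -> None:
    """Production-titer report: per-strain totals, titers and specificity."""
    rows = []
    for m in metrics:
        row = {
            "Name": m.strain,
            "Total mg/L": round(m.total, 1),
            "Oxygenated (%)": round(m.oxygenated_pct),
        }
        for compound in m.titers:
            row[f"{compound} mg/L"] = round(m.titers[compound], 1)
        row["Content of 2 (%)"] = round(m.content2_pct)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_fold_change_report(
    yields: pd.DataFrame,
    reference: str,
    compounds: Sequence[str],
    path: str | Path,
    strain_col: str = "strain",
) -> None:
    """Fold changes of each strain vs the reference, one row per strain."""
    strains = [s for s in yields[strain_col].unique()]
    rows = []
    for strain in strains:
        row: dict[str, object] = {"Variant": strain}
        for compound in compounds:
            try:
                fc = fold_change(yields, strain, reference, compound, strain_col=strain_col)
            except KeyError:
                fc = math.nan
            row[f"fold_change_{compound}"] = round(fc, 1) if math.isfinite(fc) else fc
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
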