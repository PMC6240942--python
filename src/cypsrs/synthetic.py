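"""Ground-truthed synthetic inputs for the SRS-mapping and screening pipeline.

Two generators make the full pipeline testable without any external data:

* :func:`simulate_family` draws a star-shaped homologous P450-like family —
  a random ancestor with planted SRS intervals and a planted K-helix ExxR
  motif, mutated residue-wise at region-specific rates, with an optional
  deletion inside SRS6 (mirroring the one-residue SRS6 length difference
  seen among close CYP76AH homologs). Every substitution and deletion is
  logged, so downstream recovery can be scored against the truth.

* :func:`simulate_screen` generates replicate GC-MS peak tables from known
  true titers with compound-specific response factors and multiplicative
  log-normal noise (peak areas are positive and GC-MS response is roughly
  proportional to amount), plus a matching calibration table.

:func:`reference_tables` bundles published experimental values from the
CYP76AH15 engineering screens (identity profiles, microtiter fold changes,
shake-flask titers, forskolin-strain relative yields) as typed regression
fixtures for the reporting arithmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from cypsrs.srs_mapping import (
    SRS_LABELS,
    Interval,
    ProteinRecord,
    SrsAnnotation,
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Interval layout loosely follows the canonical P450 fold: SRS4 on the
# I-helix, the ExxR on the K-helix just ahead of SRS5, SRS6 near the C
# terminus. Region lengths sum to 78 residues, the SRS complement of the
# CYP76AH family.
DEFAULT_SRS_INTERVALS: tuple[Interval, ...] = (
    (95, 114),   # SRS1, 20 aa
    (200, 209),  # SRS2, 10 aa
    (235, 244),  # SRS3, 10 aa
    (290, 301),  # SRS4, 12 aa
    (361, 372),  # SRS5, 12 aa
    (470, 483),  # SRS6, 14 aa
)
DEFAULT_EXXR_POSITION = 356


@dataclass(frozen=True)
class FamilySimConfig:
    """Conditions for a simulated homologous family.

    Substitution probabilities default to divergences typical of close
    paralogs (SRS regions slightly more variable than the scaffold, as in
    the CYP76AH comparisons).
    """

    seed: int = 0
    n_sequences: int = 4
    length: int = 500
    srs_intervals: tuple[Interval, ...] = DEFAULT_SRS_INTERVALS
    srs_sub_prob: float = 0.15
    non_srs_sub_prob: float = 0.10
    exxr_position: int = DEFAULT_EXXR_POSITION
    srs6_indel_prob: float = 0.0
    srs6_indel_length: int = 1

    def __post_init__(self) -> None:
        SrsAnnotation("_config", self.srs_intervals)  # interval validity
        if self.srs_intervals[-1][1] > self.length:
            raise ValueError("SRS6 extends beyond the configured length")
        for p in (self.srs_sub_prob, self.non_srs_sub_prob, self.srs6_indel_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.n_sequences < 1:
            raise ValueError("need at least one descendant")
        motif_span = (self.exxr_position, self.exxr_position + 3)
        if motif_span[1] > self.length:
            raise ValueError("ExxR motif extends beyond the sequence")
        s6 = self.srs_intervals[-1]
        if self.srs6_indel_prob > 0 and s6[0] <= motif_span[1] and motif_span[0] <= s6[1]:
            raise ValueError("ExxR motif must lie outside the SRS6 indel region")
        if self.srs6_indel_length >= s6[1] - s6[0] + 1:
            raise ValueError("SRS6 indel longer than SRS6 itself")


@dataclass(frozen=True)
class PlantedEdit:
    """One true edit of a descendant relative to the ancestor.

    ``position`` is in ancestor coordinates (substitutions happen before the
    optional SRS6 deletion, which is the last region of the sequence).
    """

    sequence_id: str
    kind: str  # "sub" | "del"
    position: int
    ref: str
    new: str


@dataclass(frozen=True)
class FamilySim:
    ancestor: ProteinRecord
    descendants: tuple[ProteinRecord, ...]
    annotations: tuple[SrsAnnotation, ...]  # ancestor first, then descendants
    edits: tuple[PlantedEdit, ...]

    @property
    def records(self) -> tuple[ProteinRecord, ...]:
        return (self.ancestor,) + self.descendants


def _in_any(pos: int, intervals: Sequence[Interval]) -> bool:
    return any(s <= pos <= e for s, e in intervals)


def simulate_family(config: FamilySimConfig) -> FamilySim:
    """Draw an ancestor and mutated descendants; deterministic under the seed.

    The ExxR glutamate and arginine are preserved in all descendants, and no
    glutamate is allowed between the SRS4 end and the planted motif so the
    first downstream E-x-x-R match is always the planted one.
    """
    rng = np.random.default_rng(config.seed)
    length = config.length
    exxr = config.exxr_position
    srs4_end = config.srs_intervals[3][1]
    guard = range(srs4_end + 1, exxr)  # no E here, keeps the motif scan unambiguous

    def draw(position: int) -> str:
        pool = AMINO_ACIDS.replace("E", "") if position in guard else AMINO_ACIDS
        return pool[rng.integers(len(pool))]

    ancestor_residues = [draw(p) for p in range(1, length + 1)]
    ancestor_residues[exxr - 1] = "E"
    ancestor_residues[exxr + 2] = "R"
    ancestor = ProteinRecord("anc", "".join(ancestor_residues))

    annotations = [SrsAnnotation("anc", config.srs_intervals)]
    descendants: list[ProteinRecord] = []
    edits: list[PlantedEdit] = []
    s6_start, s6_end = config.srs_intervals[-1]

    for i in range(config.n_sequences):
        seq_id = f"seq{i + 1}"
        residues = list(ancestor_residues)
        for pos in range(1, length + 1):
            if pos in (exxr, exxr + 3):
                continue
            rate = (
                config.srs_sub_prob
                if _in_any(pos, config.srs_intervals)
                else config.non_srs_sub_prob
            )
            if rng.random() < rate:
                pool = AMINO_ACIDS.replace("E", "") if pos in guard else AMINO_ACIDS
                pool = pool.replace(residues[pos - 1], "")
                new = pool[rng.integers(len(pool))]
                edits.append(PlantedEdit(seq_id, "sub", pos, residues[pos - 1], new))
                residues[pos - 1] = new
        intervals = config.srs_intervals
        if config.srs6_indel_prob > 0 and rng.random() < config.srs6_indel_prob:
            k = config.srs6_indel_length
            del_start = int(rng.integers(s6_start, s6_end - k + 2))
            removed = "".join(residues[del_start - 1 : del_start - 1 + k])
            del residues[del_start - 1 : del_start - 1 + k]
            edits.append(PlantedEdit(seq_id, "del", del_start, removed, ""))
            intervals = config.srs_intervals[:-1] + ((s6_start, s6_end - k),)
        descendants.append(ProteinRecord(seq_id, "".join(residues)))
        annotations.append(SrsAnnotation(seq_id, intervals))

    return FamilySim(ancestor, tuple(descendants), tuple(annotations), tuple(edits))


# ---------------------------------------------------------------------------
# Screen simulation

# Shake-flask study conditions: wild-type CYP76AH15 vs the A99I variant in a
# 13R-manoyl oxide producing background; titers in mg/L for the substrate (1),
# the 11-oxo product (2), the 11-hydroxy product (3) and the oxo-hydroxy
# derivative (7).
DEFAULT_TRUE_TITERS: Mapping[str, Mapping[str, float]] = {
    "WT": {"1": 15.9, "2": 23.4, "3": 0.2, "7": 4.3},
    "A99I": {"1": 0.9, "2": 86.4, "3": 0.4, "7": 0.0},
}
# GC-MS response factors (normalized response per mg/L). Compounds 3 and 7
# share the response factor of 2: only 1 and 2 have authentic standards and
# the close derivatives are quantified on the curve of 2.
DEFAULT_RESPONSE_FACTORS: Mapping[str, float] = {"1": 0.10, "2": 0.09, "3": 0.09, "7": 0.09}
DEFAULT_CALIBRATION_CONCENTRATIONS = (1.0, 2.0, 5.0, 10.0, 25.0, 50.0, 100.0)
DEFAULT_RESPONSE_MAP: Mapping[str, str] = {"3": "2", "7": "2"}


@dataclass(frozen=True)
class ScreenSimConfig:
    """Conditions for a simulated in vivo variant screen.

    Defaults emulate the shake-flask comparison of native CYP76AH15 against
    A99I: three biological replicates, ~10% multiplicative noise on peak
    areas, a single 72 h endpoint and an internal standard in every run.
    """

    seed: int = 0
    true_titers: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_TRUE_TITERS.items()}
    )
    response_factors: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RESPONSE_FACTORS)
    )
    reference_strain: str = "WT"
    n_replicates: int = 3
    cv: float = 0.10
    is_area: float = 1.0e6
    timepoints: tuple[float, ...] = (72.0,)
    calibration_compounds: tuple[str, ...] = ("1", "2")
    calibration_concentrations: tuple[float, ...] = DEFAULT_CALIBRATION_CONCENTRATIONS
    calibration_cv: float = 0.0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        if self.cv < 0 or self.calibration_cv < 0:
            raise ValueError("coefficient of variation must be non-negative")
        for strain, titers in self.true_titers.items():
            for compound, titer in titers.items():
                if titer < 0:
                    raise ValueError(f"{strain}/{compound}: negative titer")
                if compound not in self.response_factors:
                    raise ValueError(f"no response factor for compound {compound!r}")
        if self.reference_strain not in self.true_titers:
            raise ValueError(f"reference strain {self.reference_strain!r} not simulated")


@dataclass(frozen=True)
class ScreenSim:
    peaks: pd.DataFrame
    calibration: pd.DataFrame
    truth: pd.DataFrame  # strain, compound, titer_mg_per_L, fold_change_vs_reference


def simulate_screen(config: ScreenSimConfig) -> ScreenSim:
    """Replicate peak tables from known titers; deterministic under the seed.

    area = titer x response factor x IS area x exp(noise), noise normal with
    sd log(1 + CV). The IS area itself fluctuates run-to-run by the same
    noise law, which IS normalization must cancel.
    """
    rng = np.random.default_rng(config.seed)
    sd = math.log1p(config.cv)
    rows = []
    for strain, titers in config.true_titers.items():
        for timepoint in config.timepoints:
            for replicate in range(1, config.n_replicates + 1):
                run_is = config.is_area * math.exp(rng.normal(0.0, sd)) if sd else config.is_area
                rows.append(
                    {
                        "strain": strain,
                        "variant": strain,
                        "replicate": replicate,
                        "timepoint_h": timepoint,
                        "compound": "IS",
                        "area": run_is,
                    }
                )
                for compound, titer in titers.items():
                    noise = math.exp(rng.normal(0.0, sd)) if sd else 1.0
                    area = titer * config.response_factors[compound] * run_is * noise
                    rows.append(
                        {
                            "strain": strain,
                            "variant": strain,
                            "replicate": replicate,
                            "timepoint_h": timepoint,
                            "compound": compound,
                            "area": area,
                        }
                    )
    peaks = pd.DataFrame(rows)

    cal_sd = math.log1p(config.calibration_cv)
    cal_rows = []
    for compound in config.calibration_compounds:
        rf = config.response_factors[compound]
        for conc in config.calibration_concentrations:
            noise = math.exp(rng.normal(0.0, cal_sd)) if cal_sd else 1.0
            cal_rows.append(
                {
                    "compound": compound,
                    "concentration_mg_per_L": conc,
                    "area": conc * rf * config.is_area * noise,
                    "is_area": config.is_area,
                }
            )
    calibration = pd.DataFrame(cal_rows)

    ref = config.true_titers[config.reference_strain]
    truth_rows = []
    for strain, titers in config.true_titers.items():
        for compound, titer in titers.items():
            ref_titer = float(ref.get(compound, 0.0))
            if ref_titer == 0:
                fc = math.nan if titer == 0 else math.inf
            else:
                fc = titer / ref_titer
            truth_rows.append(
                {
                    "strain": strain,
                    "compound": compound,
                    "titer_mg_per_L": float(titer),
                    "fold_change_vs_reference": fc,
                }
            )
    truth = pd.DataFrame(truth_rows)
    return ScreenSim(peaks, calibration, truth)


# ---------------------------------------------------------------------------
# Published reference values (regression fixtures)


@dataclass(frozen=True)
class ReferenceTables:
    """Published CYP76AH15-engineering measurements as typed fixtures.

    * ``srs_identity`` — per-SRS / pooled / full-length percent identities of
      six CYP76AH pairs;
    * ``microtiter_fold_changes`` — fold changes of products 2 and 3 vs
      native CYP76AH15 in microtiter screens;
    * ``shake_flask_titers`` — per-strain shake-flask titers (mg/L) with the
      printed totals and specificity percentages; the unprinted compound-7
      titer is derived as total minus the printed compounds, floored at 0;
    * ``forskolin_relative_yields`` — IS-normalized relative yields of
      full-pathway forskolin strains (NaN where not detected).
    """

    srs_identity: pd.DataFrame
    microtiter_fold_changes: pd.DataFrame
    shake_flask_titers: pd.DataFrame
    forskolin_relative_yields: pd.DataFrame


def reference_tables() -> ReferenceTables:
    srs_identity = pd.DataFrame(
        [
            ("AH15", "AH8", 79, 88, 75, 89, 100, 50, 82, 87),
            ("AH15", "AH17", 75, 88, 75, 89, 100, 50, 81, 80),
            ("AH8", "AH17", 96, 100, 100, 100, 100, 100, 99, 88),
            ("AH11", "AH16", 54, 88, 50, 89, 82, 63, 71, 76),
            ("AH15", "AH11", 46, 25, 50, 42, 82, 25, 46, 51),
            ("AH15", "AH16", 50, 25, 25, 47, 82, 25, 46, 54),
        ],
        columns=["id_a", "id_b", *SRS_LABELS, "total_srs", "full_length"],
    )
    microtiter_fold_changes = pd.DataFrame(
        [
            ("native", "-", 1.0, 1.0),
            ("A99I", "1", 5.6, 3.0),
            ("S235G Y236F", "3", 5.1, 7.3),
            ("L366F", "5", 2.9, 4.2),
            ("L366E", "5", 3.7, 6.2),
            ("A99I S235G Y236F", "1+3", 6.5, 14.2),
            ("A99I L366F", "1+5", 6.2, 4.9),
            ("S235G Y236F L366E", "3+5", 3.1, 16.5),
            ("A99I S235G Y236F L366F", "1+3+5", 3.2, 31.4),
        ],
        columns=["variant", "srs_sites", "fold_2", "fold_3"],
    )
    flask_rows = [
        ("MO (-)", 43.8, 0, 43.8, 0.0, 0.0, 0),
        ("WT CYP76AH15", 43.8, 64, 15.9, 23.4, 0.2, 53),
        ("A99I", 87.7, 99, 0.9, 86.4, 0.4, 99),
        ("S235G Y236F", 73.5, 94, 4.1, 68.6, 0.8, 93),
        ("L366F", 68.2, 96, 3.1, 64.7, 0.5, 95),
        ("L366E", 69.2, 90, 7.0, 61.2, 1.0, 88),
        ("A99I S235G Y236F", 83.4, 97, 2.2, 79.8, 1.4, 96),
        ("A99I L366F", 75.8, 96, 2.8, 72.6, 0.4, 96),
        ("S235G Y236F L366E", 47.1, 80, 9.6, 34.2, 3.3, 73),
        ("A99I S235G Y236F L366F", 59.6, 83, 10.2, 44.2, 5.1, 74),
    ]
    shake_flask_titers = pd.DataFrame(
        flask_rows,
        columns=[
            "strain",
            "total_mg_per_L",
            "oxygenated_pct",
            "titer_1",
            "titer_2",
            "titer_3",
            "content2_pct",
        ],
    )
    shake_flask_titers["titer_7"] = (
        shake_flask_titers["total_mg_per_L"]
        - shake_flask_titers[["titer_1", "titer_2", "titer_3"]].sum(axis=1)
    ).round(1).clip(lower=0.0) + 0.0  # +0.0 folds -0.0 into 0.0

    nan = math.nan
    forskolin_relative_yields = pd.DataFrame(
        [
            ("MO (-)", 4.1, nan, nan, nan, nan, nan, nan, nan),
            ("FORSK AH15", 1.0, 1.0, nan, 1.0, 1.0, 1.0, 1.0, 1.0),
            ("FORSK A99I", 0.5, 2.1, nan, 0.2, 0.5, 0.3, 3.3, 22.7),
        ],
        columns=["strain", "1", "2", "3", "8", "9", "a", "b", "c"],
    )
    return ReferenceTables(
        srs_identity,
        microtiter_fold_changes,
        shake_flask_titers,
        forskolin_relative_yields,
    )
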