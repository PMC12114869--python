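"""Cannabinoid concentration arithmetic and harvest-timing summaries.

Total cannabinoid concentration (TCC, mg/g dry weight) is the exact sum of
the 14 assayed cannabinoids; total cannabinoid yield (TCY, g) is TCC times
the gross inflorescence weight.  Genotypes are classed into chemovars by
their CBDA:THCA ratio, and harvest timing is summarized by the amber stage
at which each genotype's TCC and TCY peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The 14 assayed cannabinoids (acidic precursors and neutral forms).
ANALYTES = (
    "CBDA", "THCA", "CBD", "THC", "CBC", "CBN", "CBDVA",
    "CBDV", "CBGA", "CBG", "THCV", "THCVA", "CBNA", "CBCA",
)

STAGES = (1, 2, 3, 4)


class MissingAnalyteError(KeyError):
    """A profile is missing one of the 14 analytes (no silent zero-fill)."""


@dataclass
class CannabinoidProfile:
    """Concentrations of the 14 assayed cannabinoids in mg/g dry weight."""

    concentrations: dict[str, float]

    def __post_init__(self) -> None:
        missing = [a for a in ANALYTES if a not in self.concentrations]
        if missing:
            raise MissingAnalyteError(f"missing analytes: {missing}")
        extra = [k for k in self.concentrations if k not in ANALYTES]
        if extra:
            raise ValueError(f"unknown analytes: {extra}")
        neg = {k: v for k, v in self.concentrations.items() if v < 0}
        if neg:
            raise ValueError(f"negative concentrations: {neg}")

    def __getitem__(self, analyte: str) -> float:
        return self.concentrations[analyte]


@dataclass
class InflorescenceRecord:
    genotype_id: str
    amber_stage: int
    harvest_day: float
    inflorescence_weight: float  # g, gross
    profile: CannabinoidProfile
    mean_amber_score: float | None = None

    def __post_init__(self) -> None:
        if self.amber_stage not in STAGES:
            raise ValueError(f"amber_stage must be in 1-4, got {self.amber_stage}")
        if self.inflorescence_weight <= 0:
            raise ValueError(f"inflorescence weight must be > 0, got {self.inflorescence_weight}")


@dataclass
class ChemovarClass:
    label: str  # high-THCA | high-CBDA | even-ratio
    ratio: float  # CBDA:THCA


def total_cannabinoid_concentration(profile: CannabinoidProfile) -> float:
    """TCC in mg/g: the exact 14-term sum over the assayed cannabinoids."""
    return float(sum(profile.concentrations[a] for a in ANALYTES))


def total_cannabinoid_yield(tcc: float, weight: float) -> float:
    """TCY in grams: TCC (mg/g) x gross inflorescence weight (g) / 1000."""
    if weight <= 0:
        raise ValueError(f"weight must be > 0, got {weight}")
    return tcc * weight / 1000.0


def classify_chemovar(cbda: float, thca: float) -> ChemovarClass:
    """Chemovar class from the CBDA:THCA ratio.

    high-CBDA when CBDA:THCA > 3:1, high-THCA when < 1:3, even-ratio
    otherwise; the boundaries themselves (exactly 3:1 or 1:3) are even-ratio
    because the outer classes require strict inequality.  A zero denominator
    maps to an infinite ratio.
    """
    if cbda < 0 or thca < 0:
        raise ValueError("concentrations must be nonnegative")
    if cbda == 0 and thca == 0:
        raise ValueError("chemovar undefined: CBDA and THCA both zero")
    ratio = cbda / thca if thca > 0 else float("inf")
    if ratio > 3.0:
        label = "high-CBDA"
    elif ratio < 1.0 / 3.0:
        label = "high-THCA"
    else:
        label = "even-ratio"
    return ChemovarClass(label=label, ratio=ratio)


def peak_stage(values, tie: str = "earliest") -> int:
    """Stage (1-4) at which a per-stage series peaks.

    Ties resolve to the earliest stage by default (earlier harvest is
    operationally preferable); ``tie="latest"`` flips the rule.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != (4,):
        raise ValueError(f"expected one value per stage (4 values), got shape {values.shape}")
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite value in per-stage series")
    if tie == "earliest":
        return int(np.argmax(values)) + 1
    if tie == "latest":
        return 4 - int(np.argmax(values[::-1]))
    raise ValueError(f"unknown tie rule {tie!r}")


@dataclass
class PopulationSummary:
    """Peak-stage counts plus the per-genotype trajectory table."""

    tcc_peak_counts: tuple[int, int, int, int]
    tcy_peak_counts: tuple[int, int, int, int]
    trajectories: pd.DataFrame = field(repr=False)


def summarize_population(records: list[InflorescenceRecord]) -> PopulationSummary:
    """Count, per amber stage, the genotypes whose TCC and TCY peak there.

    Requires exactly one record per (genotype, stage); duplicate pairs raise
    a data-integrity error, incomplete four-stage series raise as well.  Also
    returns a per-genotype trajectory table (TCC/TCY/weight by stage plus
    chemovar class and peak stages).
    """
    if not records:
        import warnings

        warnings.warn("summarize_population: empty input")
        return PopulationSummary((0, 0, 0, 0), (0, 0, 0, 0), pd.DataFrame())

    seen: dict[tuple[str, int], InflorescenceRecord] = {}
    for rec in records:
        key = (rec.genotype_id, rec.amber_stage)
        if key in seen:
            raise ValueError(f"duplicate (genotype, stage) record: {key}")
        seen[key] = rec

    genotypes = sorted({g for g, _ in seen})
    tcc_counts = [0, 0, 0, 0]
    tcy_counts = [0, 0, 0, 0]
    rows = []
    for g in genotypes:
        missing = [s for s in STAGES if (g, s) not in seen]
        if missing:
            raise ValueError(f"genotype {g}: incomplete series, missing stages {missing}")
        recs = [seen[(g, s)] for s in STAGES]
        tcc = [total_cannabinoid_concentration(r.profile) for r in recs]
        tcy = [total_cannabinoid_yield(c, r.inflorescence_weight) for c, r in zip(tcc, recs)]
        p_tcc = peak_stage(tcc)
        p_tcy = peak_stage(tcy)
        tcc_counts[p_tcc - 1] += 1
        tcy_counts[p_tcy - 1] += 1
        mean_cbda = np.mean([r.profile["CBDA"] for r in recs])
        mean_thca = np.mean([r.profile["THCA"] for r in recs])
        chemovar = classify_chemovar(mean_cbda, mean_thca)
        row = {"genotype": g, "chemovar": chemovar.label, "tcc_peak_stage": p_tcc, "tcy_peak_stage": p_tcy}
        for s, c, y, r in zip(STAGES, tcc, tcy, recs):
            row[f"tcc_stage{s}"] = c
            row[f"tcy_stage{s}"] = y
            row[f"weight_stage{s}"] = r.inflorescence_weight
        rows.append(row)

    return PopulationSummary(tuple(tcc_counts), tuple(tcy_counts), pd.DataFrame(rows))


def records_from_frame(df: pd.DataFrame) -> list[InflorescenceRecord]:
    """Build records from a table with one row per (genotype, stage).

    Required columns: ``genotype``, ``stage``, ``harvest_day``, ``weight``,
    and the 14 analyte columns in mg/g.  Headers are validated strictly.
    """
    required = {"genotype", "stage", "harvest_day", "weight", *ANALYTES}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"input table missing columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        profile = CannabinoidProfile({a: float(row[a]) for a in ANALYTES})
        records.append(
            InflorescenceRecord(
                genotype_id=str(row["genotype"]),
                amber_stage=int(row["stage"]),
                harvest_day=float(row["harvest_day"]),
                inflorescence_weight=float(row["weight"]),
                profile=profile,
                mean_amber_score=float(row["amber_score"]) if "amber_score" in df.columns else None,
            )
        )
    return records
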