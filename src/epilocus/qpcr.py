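"""Relative expression (2^-ΔΔCt) and ChIP-qPCR percent-of-input quantification.

Expression follows the Livak method: technical replicates are averaged on the
Ct scale, ΔCt = Ct(target) - Ct(endogenous control) per biological replicate,
ΔΔCt is taken against the calibrator sample's mean ΔCt, and relative
expression is 2^-ΔΔCt (mean ± SE over biological replicates on the linear
scale).  No amplification-efficiency correction is applied.

ChIP enrichment uses the percent-of-input method: the input Ct is first
adjusted for its dilution (adjusted = Ct_input - log2(1/f) for input fraction
f), then percent = 100 · 2^(adjusted - Ct_chip); the undiluted input is by
definition 100%.  Fold enrichment is a ratio of percents, optionally after
subtracting the no-antibody background (floored at zero).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionResult",
    "ChipResult",
    "relative_expression",
    "percent_of_input",
    "chip_percent_table",
    "fold_enrichment",
]

CT_COLUMNS = ("sample", "replicate", "target", "assay", "ct", "tech_rep")


@dataclass
class ExpressionResult:
    sample: str
    calibrator: str
    delta_ct: float            # mean over biological replicates
    delta_delta_ct: float
    relative_expression: float  # 2^-ΔΔCt of the mean ΔCt; 1.0 for the calibrator
    replicate_values: list[float]  # per-biological-replicate 2^-ΔΔCt
    mean: float
    sem: float | None


def _validate_ct_table(ct_table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ("sample", "replicate", "target", "ct") if c not in ct_table.columns]
    if missing:
        raise ValueError(f"Ct table missing columns {missing}")
    if (ct_table["ct"] <= 0).any() or not np.isfinite(ct_table["ct"]).all():
        bad = ct_table.loc[(ct_table["ct"] <= 0) | ~np.isfinite(ct_table["ct"])]
        raise ValueError(f"non-positive or non-finite Ct values at rows {list(bad.index)}")
    return ct_table


def relative_expression(
    ct_table: pd.DataFrame,
    target: str = "gene_of_interest",
    control: str = "endogenous_control",
    calibrator_sample: str | None = None,
) -> dict[str, ExpressionResult]:
    """2^-ΔΔCt per sample from a long-format Ct table.

    The table needs columns sample, replicate, target, ct (tech_rep optional;
    technical replicates are averaged on the Ct scale first).  The calibrator
    defaults to the first sample in table order.
    """
    table = _validate_ct_table(ct_table)
    table = table[table["target"].isin([target, control])]
    if calibrator_sample is None:
        calibrator_sample = str(table["sample"].iloc[0])

    # Ct per (sample, replicate, target), technical replicates averaged
    ct = table.groupby(["sample", "replicate", "target"], sort=False)["ct"].mean()

    delta: dict[str, dict[str, float]] = {}
    for (sample, replicate), group in ct.groupby(level=[0, 1], sort=False):
        values = group.droplevel([0, 1])
        if target not in values.index:
            raise ValueError(f"sample {sample!r} replicate {replicate!r}: missing target Ct")
        if control not in values.index:
            raise ValueError(f"sample {sample!r} replicate {replicate!r}: missing control Ct")
        delta.setdefault(str(sample), {})[str(replicate)] = float(
            values[target] - values[control]
        )
    if calibrator_sample not in delta:
        raise ValueError(f"calibrator sample {calibrator_sample!r} absent from Ct table")

    cal_delta = float(np.mean(list(delta[calibrator_sample].values())))
    results: dict[str, ExpressionResult] = {}
    for sample, per_rep in delta.items():
        rep_ddct = [d - cal_delta for d in per_rep.values()]
        rep_values = [2.0 ** (-x) for x in rep_ddct]
        mean_delta = float(np.mean(list(per_rep.values())))
        ddct = mean_delta - cal_delta
        sem = (
            float(np.std(rep_values, ddof=1) / math.sqrt(len(rep_values)))
            if len(rep_values) >= 2
            else None
        )
        results[sample] = ExpressionResult(
            sample=sample,
            calibrator=calibrator_sample,
            delta_ct=mean_delta,
            delta_delta_ct=ddct,
            relative_expression=2.0 ** (-ddct),
            replicate_values=rep_values,
            mean=float(np.mean(rep_values)),
            sem=sem,
        )
    return results


def percent_of_input(ct_chip: float, ct_input: float, input_fraction: float = 0.01) -> float:
    """ChIP signal as a percent of dilution-adjusted input chromatin."""
    if not 0.0 < input_fraction <= 1.0:
        raise ValueError(f"input_fraction must be in (0, 1], got {input_fraction}")
    adjusted = ct_input - math.log2(1.0 / input_fraction)
    return 100.0 * 2.0 ** (adjusted - ct_chip)


@dataclass
class ChipResult:
    sample: str
    percent: float          # mean percent-of-input over biological replicates
    sem: float | None
    no_antibody_percent: float | None
    replicate_percents: list[float]


def chip_percent_table(
    ct_table: pd.DataFrame,
    input_fraction: float = 0.01,
    chip_assay: str = "chip",
    input_assay: str = "input",
    no_antibody_assay: str = "no_antibody",
) -> dict[str, ChipResult]:
    """Percent-of-input per sample from a long-format ChIP Ct table.

    Expects columns sample, replicate, assay, ct; technical replicates are
    averaged on the Ct scale, percent-of-input is computed per biological
    replicate against that replicate's own input, then averaged.
    """
    table = _validate_ct_table(ct_table)
    if "assay" not in table.columns:
        raise ValueError("ChIP Ct table needs an 'assay' column")
    ct = table.groupby(["sample", "replicate", "assay"], sort=False)["ct"].mean()
    results: dict[str, ChipResult] = {}
    for sample, sample_group in ct.groupby(level=0, sort=False):
        percents, noab = [], []
        for replicate, group in sample_group.groupby(level=1, sort=False):
            values = group.droplevel([0, 1])
            if input_assay not in values.index:
                raise ValueError(f"sample {sample!r} replicate {replicate!r}: missing input Ct")
            if chip_assay not in values.index:
                raise ValueError(f"sample {sample!r} replicate {replicate!r}: missing ChIP Ct")
            percents.append(
                percent_of_input(values[chip_assay], values[input_assay], input_fraction)
            )
            if no_antibody_assay in values.index:
                noab.append(
                    percent_of_input(values[no_antibody_assay], values[input_assay], input_fraction)
                )
        sem = (
            float(np.std(percents, ddof=1) / math.sqrt(len(percents)))
            if len(percents) >= 2
            else None
        )
        results[str(sample)] = ChipResult(
            sample=str(sample),
            percent=float(np.mean(percents)),
            sem=sem,
            no_antibody_percent=float(np.mean(noab)) if noab else None,
            replicate_percents=[float(p) for p in percents],
        )
    return results


def fold_enrichment(
    percent_a: float,
    percent_b: float,
    no_antibody_percent: float | None = None,
) -> float:
    """Ratio of two percent-of-input values, optionally background-subtracted.

    With a no-antibody percent given, both percents first subtract it
    (floored at 0); a zero denominator after subtraction is an error.
    """
    a, b = percent_a, percent_b
    if no_antibody_percent is not None:
        a = max(a - no_antibody_percent, 0.0)
        b = max(b - no_antibody_percent, 0.0)
    if b == 0:
        raise ZeroDivisionError("reference percent is zero; fold enrichment undefined")
    return a / b
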