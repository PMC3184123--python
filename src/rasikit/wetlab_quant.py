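"""Quantification formulas for ChIP-qPCR, qRT-PCR and Western densitometry.

Standard-curve quantification: a least-squares line Ct = slope*log10(q) + b
fitted per primer set over a genomic-DNA dilution series; amplification
efficiency E = 10^(-1/slope) - 1.  Immunoprecipitated DNA is expressed as a
percent of input chromatin (correcting for the input fraction assayed) and
then as an enrichment factor relative to a euchromatic control locus whose
own factor is 1 by construction.  Relative transcript / copy-number
quantification uses the delta-Ct form 2^(Ct_ref - Ct_target), which assumes
perfect doubling per cycle; an efficiency-corrected variant
(1+E)^dCt is available but off by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class StandardCurve:
    """qPCR calibration line for one primer set."""

    primer_set: str
    slope: float
    intercept: float
    r_squared: float
    efficiency: float
    flagged: bool = False   # efficiency outside (0, 1.1]

    def quantity(self, ct: float) -> float:
        return quantity_from_ct(ct, self)


@dataclass
class TTestResult:
    p_value: float
    statistic: float
    df: float
    degenerate: bool = False


@dataclass
class EnrichmentResult:
    locus: str
    antibody: str
    stage: str
    percent_input: float
    enrichment_factor: float
    sd: float
    p_value: float
    significant: bool


def fit_standard_curve(points: Sequence[tuple[float, float]],
                       primer_set: str = "") -> StandardCurve:
    """Least-squares Ct vs log10(quantity) line from a dilution series.

    Requires at least 3 points with distinct positive quantities.  A perfect
    10-fold series with slope -3.3219 corresponds to efficiency 1 (doubling
    every cycle).
    """
    if len(points) < 3:
        raise ValueError("standard curve needs at least 3 dilution points")
    q = np.array([p[0] for p in points], dtype=float)
    ct = np.array([p[1] for p in points], dtype=float)
    if np.any(q <= 0):
        raise ValueError("dilution quantities must be positive")
    logq = np.log10(q)
    if np.allclose(logq.var(), 0.0):
        raise ValueError("dilution quantities must span more than one value")
    fit = stats.linregress(logq, ct)
    slope = float(fit.slope)
    if slope >= 0:
        raise ValueError(f"standard curve slope must be negative, got {slope:.3f}")
    efficiency = 10.0 ** (-1.0 / slope) - 1.0
    return StandardCurve(
        primer_set=primer_set,
        slope=slope,
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        efficiency=float(efficiency),
        flagged=not (0.0 < efficiency <= 1.1),
    )


def quantity_from_ct(ct: float, curve: StandardCurve) -> float:
    """Invert the calibration line: q = 10^((ct - intercept)/slope)."""
    return 10.0 ** ((ct - curve.intercept) / curve.slope)


def percent_input(ip_quantity: float, input_quantity: float,
                  input_fraction: float = 1.0) -> float:
    """IP DNA as a percent of starting chromatin.

    ``input_fraction`` is the fraction of chromatin assayed as the input
    aliquot; the measured input quantity is scaled back up before the ratio.
    """
    if input_quantity <= 0:
        raise ValueError("input quantity must be positive")
    if not 0 < input_fraction <= 1:
        raise ValueError("input fraction must be in (0, 1]")
    return 100.0 * ip_quantity / (input_quantity / input_fraction)


def enrichment_factor(percent_input_locus: float, percent_input_control: float) -> float:
    """Enrichment of a locus relative to the control locus (control == 1)."""
    if percent_input_control <= 0:
        raise ValueError("control percent input must be positive")
    return percent_input_locus / percent_input_control


def relative_copies_delta_ct(ct_reference: float, ct_target: float,
                             efficiency: Optional[float] = None) -> float:
    """Relative copy number 2^(Ct_ref - Ct_target).

    Assumes 100% amplification efficiency; pass ``efficiency`` to use the
    corrected base (1+E) instead.
    """
    if not (math.isfinite(ct_reference) and math.isfinite(ct_target)):
        raise ValueError("Ct values must be finite")
    base = 2.0 if efficiency is None else 1.0 + efficiency
    return base ** (ct_reference - ct_target)


def genomic_copy_estimate(ct_pairs: Sequence[tuple[float, float]],
                          efficiency: Optional[float] = None
                          ) -> tuple[float, tuple[float, float]]:
    """Per-genome copy number of a repeat relative to a single-copy gene.

    ``ct_pairs`` holds (Ct_single_copy_gene, Ct_repeat) replicate pairs on
    genomic DNA.  Returns the mean and the min-max interval over replicates
    (matching the usual "between X and Y copies" phrasing).
    """
    if not ct_pairs:
        raise ValueError("at least one replicate Ct pair is required")
    values = [relative_copies_delta_ct(ref, te, efficiency) for ref, te in ct_pairs]
    return float(np.mean(values)), (float(min(values)), float(max(values)))


def students_t_test(group_a: Sequence[float], group_b: Sequence[float],
                    paired: bool = False, welch: bool = False) -> TTestResult:
    """Two-sided Student's t-test (pooled variance by default).

    Degenerate conventions: zero variance with equal means gives p = 1;
    zero variance with unequal means gives p = 0 and the result is flagged.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if paired:
        if len(a) != len(b):
            raise ValueError("paired test requires equal group lengths")
        diffs = a - b
        if np.allclose(diffs.var(ddof=1), 0.0):
            equal = np.allclose(diffs.mean(), 0.0)
            return TTestResult(p_value=1.0 if equal else 0.0,
                               statistic=0.0 if equal else math.inf,
                               df=len(a) - 1, degenerate=not equal)
        res = stats.ttest_rel(a, b)
        return TTestResult(float(res.pvalue), float(res.statistic), float(len(a) - 1))
    if np.allclose(a.var(ddof=1), 0.0) and np.allclose(b.var(ddof=1), 0.0):
        equal = np.allclose(a.mean(), b.mean())
        return TTestResult(p_value=1.0 if equal else 0.0,
                           statistic=0.0 if equal else math.inf,
                           df=len(a) + len(b) - 2, degenerate=not equal)
    res = stats.ttest_ind(a, b, equal_var=not welch)
    df = len(a) + len(b) - 2 if not welch else float("nan")
    return TTestResult(float(res.pvalue), float(res.statistic), df)


# ---------------------------------------------------------------------------
# ChIP-qPCR analysis over tidy tables
# ---------------------------------------------------------------------------

def fit_curves(dilutions: pd.DataFrame) -> dict[str, StandardCurve]:
    """Fit one standard curve per primer set from a tidy dilution table.

    Expected columns: primer_set, quantity, ct.
    """
    curves = {}
    for primer, grp in dilutions.groupby("primer_set"):
        pts = list(zip(grp["quantity"], grp["ct"]))
        curves[primer] = fit_standard_curve(pts, primer_set=str(primer))
    return curves


def analyze_chip(dilutions: pd.DataFrame, samples: pd.DataFrame,
                 control_primer: str = "Sf_L37", input_fraction: float = 1.0,
                 alpha: float = 0.05, input_label: str = "input") -> pd.DataFrame:
    """Percent-input and enrichment-factor table from tidy Ct measurements.

    ``samples`` columns: primer_set, antibody, stage, replicate, ct; input
    rows carry ``antibody == input_label``.  Replicate Cts are converted to
    quantities per replicate; percent input is computed per replicate and
    averaged, the SD is over replicates, and significance of the enrichment
    over the control locus is a two-sided pooled-variance Student's t-test
    on the per-replicate percent-input values.
    """
    curves = fit_curves(dilutions)
    missing = set(samples["primer_set"]) - set(curves)
    if missing:
        raise ValueError(f"no standard curve for primer set(s): {sorted(missing)}")

    def _percent_inputs(primer: str, antibody: str, stage: str) -> np.ndarray:
        grp = samples[(samples["primer_set"] == primer)
                      & (samples["antibody"] == antibody)
                      & (samples["stage"] == stage)]
        inp = samples[(samples["primer_set"] == primer)
                      & (samples["antibody"] == input_label)
                      & (samples["stage"] == stage)]
        if grp.empty or inp.empty:
            return np.array([])
        curve = curves[primer]
        input_q = quantity_from_ct(float(inp["ct"].mean()), curve)
        return np.array([
            percent_input(quantity_from_ct(float(ct), curve), input_q, input_fraction)
            for ct in grp["ct"]
        ])

    rows = []
    antibodies = [a for a in samples["antibody"].unique() if a != input_label]
    stages = list(samples["stage"].unique())
    primers = list(samples["primer_set"].unique())
    for stage in stages:
        for antibody in antibodies:
            control_pi = _percent_inputs(control_primer, antibody, stage)
            if control_pi.size == 0:
                continue
            control_mean = float(control_pi.mean())
            for primer in primers:
                pi = _percent_inputs(primer, antibody, stage)
                if pi.size == 0:
                    continue
                factors = pi / control_mean
                if primer == control_primer:
                    ef, sd, p = 1.0, float(factors.std(ddof=1)) if len(factors) > 1 else 0.0, 1.0
                else:
                    ef = float(pi.mean()) / control_mean
                    sd = float(factors.std(ddof=1)) if len(factors) > 1 else 0.0
                    if len(pi) >= 2 and len(control_pi) >= 2:
                        p = students_t_test(pi, control_pi).p_value
                    else:
                        p = float("nan")
                rows.append(EnrichmentResult(
                    locus=str(primer), antibody=str(antibody), stage=str(stage),
                    percent_input=float(pi.mean()), enrichment_factor=ef, sd=sd,
                    p_value=p, significant=bool(p == p and p < alpha),
                ))
    return pd.DataFrame([r.__dict__ for r in rows])


# ---------------------------------------------------------------------------
# densitometry
# ---------------------------------------------------------------------------

def densitometry_normalize(table: pd.DataFrame, reference_protein: str = "H3",
                           reference_stage: str = "E1") -> pd.DataFrame:
    """Two-step Western-blot normalization.

    ``table``: stages (index) x proteins (columns) of band volumes.  Step 1:
    the reference protein's volume at the reference stage is set to 1 and
    the other reference-protein volumes expressed relative to it.  Step 2:
    each modification signal is divided by the reference protein at its own
    stage and then expressed relative to the same ratio at the reference
    stage.  All reference-stage cells equal 1 afterwards.
    """
    if reference_protein not in table.columns:
        raise ValueError(f"reference protein {reference_protein!r} missing")
    if reference_stage not in table.index:
        raise ValueError(f"reference stage {reference_stage!r} missing")
    h3 = table[reference_protein].astype(float)
    if (h3 <= 0).any():
        raise ValueError("reference protein volumes must be positive")
    out = pd.DataFrame(index=table.index, columns=table.columns, dtype=float)
    out[reference_protein] = h3 / h3.loc[reference_stage]
    for col in table.columns:
        if col == reference_protein:
            continue
        ratio = table[col].astype(float) / h3
        ref_ratio = ratio.loc[reference_stage]
        if ref_ratio == 0:
            raise ValueError(f"zero reference volume for {col!r} at {reference_stage!r}")
        out[col] = ratio / ref_ratio
    return out
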