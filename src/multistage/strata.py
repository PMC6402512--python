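"""APOE classification, weighted genetic risk score, tertiles, and
stratified multistage fits.

The genetic machinery is deliberately simple: APOE ε4 carrier status is
a classification of the allele pair, and the genetic risk score (GRS)
is the weighted sum Σ dosageᵢ·betaᵢ over 23 AD-associated variants
(APOE itself excluded), with dosages assumed pre-oriented to each
weight's effect allele.  Tertile cut points are the empirical 1/3 and
2/3 quantiles of the analysed (complete-data) population; scores
exactly at a cut go to the lower tertile, deterministically.

Stratified fits re-run the full accrual/filter/fit chain independently
within each stratum; the zygosity stratification is labelled
exploratory because homozygote strata are typically small.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortTable, VariantWeight
from .errors import (
    DegenerateTertilesError,
    InsufficientDataError,
    MissingGeneticDataError,
)
from .fit import AgePoint, BandFilterConfig, MultistageFit, fit_cohort

Zygosity = Literal["homozygote_e4", "heterozygote_e4", "noncarrier"]
Scheme = Literal["overall", "apoe_carrier", "apoe_zygosity", "grs_tertile", "grs_by_apoe"]

SCHEMES: tuple[str, ...] = ("apoe_carrier", "apoe_zygosity", "grs_tertile", "grs_by_apoe")


@dataclass(frozen=True)
class ApoeClass:
    carrier: bool
    zygosity: Zygosity

    def __post_init__(self) -> None:
        if self.carrier != (self.zygosity != "noncarrier"):
            raise ValueError("carrier flag inconsistent with zygosity")


@dataclass(frozen=True)
class GrsAssignment:
    score: float
    tertile: int  # 1 (low) .. 3 (high)


@dataclass
class StratumRow:
    scheme: str
    label: str
    n_events: int
    n_participants: int
    fit: MultistageFit | None
    note: str = ""


@dataclass
class StratumFitTable:
    """Rows of per-stratum fits, one stratification scheme per block."""

    rows: list[StratumRow]

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            recs.append(
                {
                    "scheme": r.scheme,
                    "stratum": r.label,
                    "n_events": r.n_events,
                    "N": r.n_participants,
                    "slope": r.fit.slope if r.fit else float("nan"),
                    "ci_low": r.fit.slope_ci_low if r.fit else float("nan"),
                    "ci_high": r.fit.slope_ci_high if r.fit else float("nan"),
                    "adjusted_r2": r.fit.adjusted_r2 if r.fit else float("nan"),
                    "n_steps": r.fit.n_steps if r.fit else pd.NA,
                    "note": r.note,
                }
            )
        cols = [
            "scheme", "stratum", "n_events", "N",
            "slope", "ci_low", "ci_high", "adjusted_r2", "n_steps", "note",
        ]
        return pd.DataFrame(recs, columns=cols)

    def write(self, path, sep: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False)


def classify_apoe(alleles: tuple[str, str] | None) -> ApoeClass:
    """Classify an unordered APOE allele pair.

    (e4, e4) is a homozygote carrier; (e2, e4) or (e3, e4) heterozygote
    carriers; anything else a non-carrier.
    """
    if alleles is None or len(alleles) != 2 or any(a is None for a in alleles):
        raise MissingGeneticDataError("APOE genotype missing")
    n_e4 = sum(1 for a in alleles if a == "e4")
    if n_e4 == 2:
        return ApoeClass(True, "homozygote_e4")
    if n_e4 == 1:
        return ApoeClass(True, "heterozygote_e4")
    return ApoeClass(False, "noncarrier")


def compute_grs(
    dosages: Mapping[str, float], weights: Sequence[VariantWeight]
) -> float:
    """Weighted genetic risk score: Σ dosage × beta, matched by variant id.

    Every weighted variant must have a dosage; a missing dosage is a
    missing-score signal and raises, so the participant can be excluded
    from GRS strata.
    """
    score = 0.0
    for w in weights:
        if w.variant_id not in dosages:
            raise MissingGeneticDataError(f"missing dosage for {w.variant_id}")
        score += dosages[w.variant_id] * w.beta
    return score


def cohort_grs(cohort: CohortTable, weights: Sequence[VariantWeight]) -> pd.Series:
    """Vectorised GRS for a whole cohort; NaN where any dosage is missing."""
    missing = [w.variant_id for w in weights if w.variant_id not in cohort.frame.columns]
    if missing:
        raise MissingGeneticDataError(
            f"cohort lacks dosage columns for {len(missing)} weighted variants "
            f"(first: {missing[0]})"
        )
    mat = cohort.frame[[w.variant_id for w in weights]].to_numpy(dtype=float)
    betas = np.array([w.beta for w in weights], dtype=float)
    scores = mat @ betas
    scores[np.isnan(mat).any(axis=1)] = np.nan
    return pd.Series(scores, index=cohort.frame.index, name="grs")


def tertile_cuts(scores: Iterable[float]) -> tuple[float, float]:
    arr = np.asarray([s for s in scores if np.isfinite(s)], dtype=float)
    if arr.size < 3:
        raise InsufficientDataError("need at least 3 scores for tertiles")
    if np.ptp(arr) == 0:
        raise DegenerateTertilesError("all scores identical; tertiles undefined")
    q1, q2 = np.quantile(arr, [1 / 3, 2 / 3])
    return float(q1), float(q2)


def assign_tertiles(scores: Sequence[float]) -> list[GrsAssignment]:
    """Assign each score to a tertile; ties at a cut go to the lower tertile."""
    q1, q2 = tertile_cuts(scores)
    out = []
    for s in scores:
        t = 1 if s <= q1 else (2 if s <= q2 else 3)
        out.append(GrsAssignment(score=float(s), tertile=t))
    return out


def _tertile_labels(scores: np.ndarray, q1: float, q2: float) -> np.ndarray:
    t = np.full(scores.shape, 0, dtype=int)
    finite = np.isfinite(scores)
    t[finite & (scores <= q1)] = 1
    t[finite & (scores > q1) & (scores <= q2)] = 2
    t[finite & (scores > q2)] = 3
    return t


def stratified_fits(
    cohort: CohortTable,
    cfg: BandFilterConfig | None = None,
    schemes: Sequence[str] = SCHEMES,
    weights: Sequence[VariantWeight] | None = None,
    band_width: float = 5.0,
    origin: float = 0.0,
    age_point: AgePoint = "midpoint",
) -> StratumFitTable:
    """Fit the multistage model independently within each genetic stratum.

    Strata within a scheme are mutually exclusive and exhaustive over
    the participants with complete data for that scheme, so the row Ns
    sum to the analysed total.  Band filtering is re-applied per
    stratum.  A stratum whose filtered band table is too sparse is kept
    as a row flagged "insufficient data" rather than failing the table.
    GRS tertile cuts are computed once on the whole analysed population
    (mutually exclusive categories), not re-cut within APOE strata.
    """
    rows: list[StratumRow] = []
    frame = cohort.frame

    needs_grs = any(s in ("grs_tertile", "grs_by_apoe") for s in schemes)
    grs = None
    cuts = None
    if needs_grs:
        if weights is None:
            raise MissingGeneticDataError("GRS schemes need a variant-weight set")
        grs = cohort_grs(cohort, weights).to_numpy()
        cuts = tertile_cuts(grs[np.isfinite(grs)])

    apoe_ok = cohort.has_apoe().to_numpy()
    zyg = np.full(len(frame), "", dtype=object)
    if apoe_ok.any():
        a1 = frame["apoe_a1"].to_numpy(dtype=object)
        a2 = frame["apoe_a2"].to_numpy(dtype=object)
        for i in np.flatnonzero(apoe_ok):
            zyg[i] = classify_apoe((a1[i], a2[i])).zygosity

    def add(scheme: str, label: str, mask: np.ndarray, note: str = "") -> None:
        sub = cohort.subset(mask)
        n_ev = int(sub.frame["event"].sum())
        fit = None
        row_note = note
        if len(sub) > 0:
            try:
                fit = fit_cohort(
                    sub, cfg, band_width=band_width, origin=origin, age_point=age_point
                )
            except InsufficientDataError:
                row_note = (note + "; " if note else "") + "insufficient data"
        else:
            row_note = (note + "; " if note else "") + "insufficient data"
        rows.append(StratumRow(scheme, label, n_ev, len(sub), fit, row_note))

    for scheme in schemes:
        if scheme == "overall":
            add("overall", "all", np.ones(len(frame), dtype=bool))
        elif scheme == "apoe_carrier":
            carrier = apoe_ok & ((zyg == "homozygote_e4") | (zyg == "heterozygote_e4"))
            add(scheme, "carrier", carrier)
            add(scheme, "noncarrier", apoe_ok & (zyg == "noncarrier"))
        elif scheme == "apoe_zygosity":
            add(scheme, "homozygote_e4", apoe_ok & (zyg == "homozygote_e4"), "exploratory")
            add(scheme, "heterozygote_e4", apoe_ok & (zyg == "heterozygote_e4"), "exploratory")
            add(scheme, "noncarrier", apoe_ok & (zyg == "noncarrier"), "exploratory")
        elif scheme == "grs_tertile":
            tert = _tertile_labels(grs, *cuts)
            for t in (1, 2, 3):
                add(scheme, f"tertile_{t}", tert == t)
        elif scheme == "grs_by_apoe":
            tert = _tertile_labels(grs, *cuts)
            carrier = apoe_ok & ((zyg == "homozygote_e4") | (zyg == "heterozygote_e4"))
            noncar = apoe_ok & (zyg == "noncarrier")
            for t in (1, 2, 3):
                add(scheme, f"tertile_{t}/carrier", (tert == t) & carrier)
                add(scheme, f"tertile_{t}/noncarrier", (tert == t) & noncar)
        else:
            raise ValueError(f"unknown stratification scheme {scheme!r}")

    return StratumFitTable(rows)
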