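"""Generative model of an n-step multistage disease process with cohort
realism: delayed entry, competing censoring, and genetic strata.

Two generative modes are provided, because the multistage estimator and
the exact sequential chain are the same model only in a limit:

``hypoexponential`` (default)
    Each subject is a single chain of n sequential exponential waiting
    times with rates λ₁…λₙ; the onset age is their sum (an exact
    hypoexponential draw; a gamma when rates are equal).  This is the
    literal sequential mechanism, and its hazard flattens once λ·t is
    no longer small — useful for studying the estimator's model error.

``powerlaw``
    Onset is drawn from the power-law cumulative hazard
    H(t) = (Πλ) tⁿ / n! by inverse transform.  This is the rare-event,
    many-independent-cells limit in which the age-specific incidence is
    exactly proportional to t^(n-1) — the regime the log-log slope
    estimator targets — so it is the mode used for parameter-recovery
    experiments.

Genetic predisposition is modelled as steps inherited at birth: a
stratum with step deficit k runs an (n - k)-step chain (the first
n - k rates), shifting its incidence curve up and flattening its
log-log slope to n - k - 1.

Reproducibility: one global seed is split into substreams — one for
genetics, one for censoring, and one per truncation redraw round — with
all draws laid out in subject order, so enlarging ``sample_size``
extends the cohort without reshuffling earlier subjects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import optimize, stats

from .cohort import CohortTable, VariantWeight, load_default_variant_weights
from .errors import ConfigurationError

Mode = Literal["hypoexponential", "powerlaw"]

_MAX_REJECTION_ROUNDS = 200


@dataclass(frozen=True)
class GeneticConfig:
    """Genetic structure of the simulated population.

    Frequencies approximate a European-ancestry elderly cohort: ~28%
    APOE ε4 carriers of whom ~2.8% of the population are homozygous.
    ``het_deficit``/``hom_deficit`` are the steps carriers inherit at
    birth (completed before entry).  ``variant_weights`` and matching
    ``allele_freqs`` drive the 23 dosage columns used by the genetic
    risk score; the dosages are genotype draws under Hardy-Weinberg
    proportions and do not feed back into onset (the score machinery is
    what is under test, not a dosage-level disease model).
    """

    carrier_freq: float = 0.28
    homozygote_freq: float = 0.028
    het_deficit: int = 2
    hom_deficit: int = 4
    e2_freq_among_noncarrier_pairs: float = 0.12
    variant_weights: Sequence[VariantWeight] | None = None
    allele_freqs: Sequence[float] | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.homozygote_freq <= self.carrier_freq <= 1.0):
            raise ConfigurationError("need 0 <= homozygote_freq <= carrier_freq <= 1")
        if self.het_deficit < 0 or self.hom_deficit < 0:
            raise ConfigurationError("step deficits must be >= 0")

    def resolved_weights(self) -> list[VariantWeight]:
        return list(self.variant_weights) if self.variant_weights is not None \
            else load_default_variant_weights()

    def resolved_allele_freqs(self, n_variants: int) -> np.ndarray:
        if self.allele_freqs is not None:
            afs = np.asarray(self.allele_freqs, dtype=float)
            if afs.shape != (n_variants,):
                raise ConfigurationError("allele_freqs length must match weights")
        else:
            # fixed, evenly spread frequencies in [0.10, 0.90]
            afs = np.linspace(0.10, 0.90, n_variants)
        if np.any((afs <= 0) | (afs >= 1)):
            raise ConfigurationError("allele frequencies must be in (0, 1)")
        return afs


@dataclass(frozen=True)
class SimulationParams:
    """Ground truth and sampling plan for one synthetic cohort.

    ``step_rates`` are the per-step transition rates λ₁…λₙ (per year);
    ``entry_age_dist`` is ("uniform", low, high) — cohort entry between
    45 and 55+ years emulates a population study's recruitment ages.
    Subjects whose onset precedes entry are redrawn (left truncation by
    rejection: prevalent cases never enter).  Exit is the earliest of
    onset, an exponential competing mortality time from entry, and the
    administrative end of follow-up.
    """

    n_true: int
    step_rates: Sequence[float]
    sample_size: int
    seed: int
    entry_age_dist: tuple[str, float, float] = ("uniform", 45.0, 85.0)
    admin_end_age: float = 100.0
    mortality_rate: float = 0.02  # per year, exponential from entry; 0 disables
    mode: Mode = "hypoexponential"
    genetic: GeneticConfig | None = None

    def __post_init__(self) -> None:
        rates = np.asarray(self.step_rates, dtype=float)
        if self.n_true < 1:
            raise ConfigurationError("n_true must be >= 1")
        if rates.shape != (self.n_true,):
            raise ConfigurationError("step_rates must have length n_true")
        if np.any(rates <= 0):
            raise ConfigurationError("all step rates must be positive")
        if self.sample_size < 1:
            raise ConfigurationError("sample_size must be >= 1")
        kind, lo, hi = self.entry_age_dist
        if kind != "uniform" or not (0 < lo < hi):
            raise ConfigurationError("entry_age_dist must be ('uniform', low, high), 0 < low < high")
        if self.admin_end_age <= hi:
            raise ConfigurationError("admin_end_age must exceed the entry-age upper bound")
        if self.mortality_rate < 0:
            raise ConfigurationError("mortality_rate must be >= 0")
        if self.genetic is not None:
            if max(self.genetic.het_deficit, self.genetic.hom_deficit) >= self.n_true:
                raise ConfigurationError("step deficit must be < n_true")

    @classmethod
    def default(cls, sample_size: int = 10_000, seed: int = 0, **kw) -> "SimulationParams":
        """A 14-step process calibrated to 20% cumulative risk by age 100,
        with the default genetic structure — the study-like conditions."""
        n = kw.pop("n_true", 14)
        mode = kw.pop("mode", "hypoexponential")
        rates = kw.pop("step_rates", None)
        if rates is None:
            rates = calibrate_rates(n, 0.20, 100.0, mode=mode)
        genetic = kw.pop("genetic", GeneticConfig())
        return cls(
            n_true=n, step_rates=rates, sample_size=sample_size, seed=seed,
            mode=mode, genetic=genetic, **kw,
        )


def _stream(seed: int, *labels: int) -> np.random.Generator:
    """Independent substream keyed by (seed, labels...).

    Each logically separate draw (zygosity, dosages, mortality, every
    truncation redraw round and step-count group) gets its own stream
    with draws laid out in subject order, so enlarging the sample never
    shifts the randomness consumed by earlier subjects.
    """
    return np.random.default_rng(
        np.random.SeedSequence([int(seed)] + [int(l) for l in labels])
    )


def sample_onset_age(
    rates: Sequence[float],
    rng: np.random.Generator,
    size: int = 1,
    mode: Mode = "hypoexponential",
) -> np.ndarray:
    """Draw onset ages for an n-step process with the given per-step rates.

    Hypoexponential mode sums n independent exponential waiting times;
    power-law mode inverts H(t) = (Πλ) tⁿ / n!.
    """
    rates = np.asarray(rates, dtype=float)
    if rates.ndim != 1 or rates.size == 0 or np.any(rates <= 0):
        raise ConfigurationError("rates must be a non-empty positive vector")
    n = rates.size
    if mode == "hypoexponential":
        waits = rng.exponential(scale=1.0 / rates, size=(size, n))
        return waits.sum(axis=1)
    if mode == "powerlaw":
        # H(t) = (prod rates) t^n / n!; t = (n! H / prod)^{1/n}, H ~ Exp(1)
        h = rng.exponential(size=size)
        log_prod = float(np.log(rates).sum())
        log_t = (math.lgamma(n + 1) + np.log(h) - log_prod) / n
        return np.exp(log_t)
    raise ConfigurationError(f"unknown mode {mode!r}")


def calibrate_rates(
    n: int,
    target_lifetime_risk: float,
    horizon_age: float,
    mode: Mode = "hypoexponential",
) -> np.ndarray:
    """Equal per-step rates giving P(onset <= horizon) = target.

    Solved numerically on the model's own CDF: the gamma CDF for the
    equal-rate hypoexponential chain, 1 - exp(-(λt)ⁿ/n!) for the
    power-law mode.
    """
    if not (0.0 < target_lifetime_risk < 1.0):
        raise ConfigurationError("target lifetime risk must be in (0, 1)")
    if n < 1 or horizon_age <= 0:
        raise ConfigurationError("need n >= 1 and a positive horizon")
    if mode == "powerlaw":
        h = -math.log1p(-target_lifetime_risk)
        lam = math.exp((math.lgamma(n + 1) + math.log(h)) / n) / horizon_age
        return np.full(n, lam)

    def deficit(lam: float) -> float:
        return stats.gamma.cdf(horizon_age, a=n, scale=1.0 / lam) - target_lifetime_risk

    lo, hi = 1e-12, 1e-12
    while deficit(hi) < 0:
        hi *= 10
        if hi > 1e6:
            raise ConfigurationError("no calibration solution in bracket")
    lam = optimize.brentq(deficit, lo, hi, xtol=1e-14, rtol=1e-12)
    return np.full(n, lam)


def _draw_genetics(gc: GeneticConfig, n: int, seed: int):
    """Per-subject zygosity, step deficits, APOE pairs and dosages."""
    u = _stream(seed, 0, 0).random(n)
    hom = u < gc.homozygote_freq
    het = (~hom) & (u < gc.carrier_freq)
    deficit = np.zeros(n, dtype=int)
    deficit[het] = gc.het_deficit
    deficit[hom] = gc.hom_deficit

    a1 = np.full(n, "e3", dtype=object)
    a2 = np.full(n, "e3", dtype=object)
    a1[hom] = "e4"
    a2[hom] = "e4"
    a2[het] = "e4"
    noncar = ~(hom | het)
    e2 = noncar & (_stream(seed, 0, 1).random(n) < gc.e2_freq_among_noncarrier_pairs)
    a1[e2] = "e2"

    weights = gc.resolved_weights()
    afs = gc.resolved_allele_freqs(len(weights))
    dosages = _stream(seed, 0, 2).binomial(
        2, afs, size=(n, len(weights))
    ).astype(float)
    return a1, a2, deficit, weights, dosages


def simulate_cohort(params: SimulationParams) -> CohortTable:
    """Simulate one cohort under the multistage generative model.

    Deterministic given ``params`` (including the seed); extending
    ``sample_size`` reproduces the original subjects as a prefix.
    """
    n_sub = params.sample_size
    rates = np.asarray(params.step_rates, dtype=float)
    _, ent_lo, ent_hi = params.entry_age_dist

    if params.genetic is not None:
        a1, a2, deficit, weights, dosages = _draw_genetics(
            params.genetic, n_sub, params.seed
        )
    else:
        a1 = a2 = None
        deficit = np.zeros(n_sub, dtype=int)
        weights, dosages = [], None

    if params.mortality_rate > 0:
        death_age = _stream(params.seed, 1, 0).exponential(
            1.0 / params.mortality_rate, size=n_sub
        )
    else:
        death_age = np.full(n_sub, np.inf)

    n_eff = params.n_true - deficit
    onset = np.empty(n_sub)
    entry = np.empty(n_sub)
    pending = np.arange(n_sub)
    total_drawn = 0
    total_accepted = 0
    for rnd in range(_MAX_REJECTION_ROUNDS):
        if pending.size == 0:
            break
        # onset: pending subjects grouped by effective step count, one
        # substream per (round, group) so layouts stay subject-ordered
        ons = np.empty(pending.size)
        for k in np.unique(n_eff[pending]):
            sel = n_eff[pending] == k
            ons[sel] = sample_onset_age(
                rates[:k],
                _stream(params.seed, 2 + rnd, int(k)),
                size=int(sel.sum()),
                mode=params.mode,
            )
        ent = _stream(params.seed, 2 + rnd, 1_000_000).uniform(
            ent_lo, ent_hi, size=pending.size
        )
        ok = ons >= ent
        onset[pending[ok]] = ons[ok]
        entry[pending[ok]] = ent[ok]
        total_drawn += pending.size
        total_accepted += int(ok.sum())
        if rnd == 0 and total_accepted < 0.01 * total_drawn:
            raise ConfigurationError(
                "left-truncation acceptance rate below 1%: pathological parameters "
                "(onset almost always precedes entry)"
            )
        pending = pending[~ok]
    if pending.size:
        raise ConfigurationError(
            f"{pending.size} subjects still truncated after "
            f"{_MAX_REJECTION_ROUNDS} redraw rounds"
        )

    censor_age = np.minimum(entry + death_age, params.admin_end_age)
    exit_age = np.minimum(onset, censor_age)
    event = onset <= censor_age

    import pandas as pd

    width = len(str(n_sub))
    frame = pd.DataFrame(
        {
            "id": [f"s{i:0{width}d}" for i in range(n_sub)],
            "entry_age": entry,
            "exit_age": exit_age,
            "event": event,
        }
    )
    dosage_cols: list[str] = []
    if params.genetic is not None:
        frame["apoe_a1"] = a1
        frame["apoe_a2"] = a2
        dosage_cols = [w.variant_id for w in weights]
        for j, vid in enumerate(dosage_cols):
            frame[vid] = dosages[:, j]
    else:
        frame["apoe_a1"] = None
        frame["apoe_a2"] = None

    return CohortTable(
        frame,
        dosage_cols,
        provenance=(
            f"simulated: n_true={params.n_true}, mode={params.mode}, "
            f"N={n_sub}, seed={params.seed}"
        ),
    )
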