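"""Bioassay and abundance statistics.

PD50 estimation from quantal paralysis dose-response data (binomial GLM
with a logit link on log10 dose, probit optional), per-gram dose
normalisation, venom composition fractions, and the correlation between
transcript expression (FPKM) and proteomic precursor-count intensity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "DoseResponseObservation",
    "PD50Fit",
    "AbundanceRecord",
    "fit_pd50",
    "per_gram",
    "dose_from_concentration",
    "composition_fractions",
    "expression_intensity_correlation",
]

# injection volume of the hand microapplicator, microlitres per fly
INJECTION_VOLUME_UL = 2.1


@dataclass(frozen=True)
class DoseResponseObservation:
    """Paralysis counts for one dose at one observation time."""

    dose: float  # micrograms venom per fly
    n_injected: int
    n_paralysed: int
    timepoint: str = ""

    def __post_init__(self):
        if self.dose < 0:
            raise ValueError("dose must be non-negative")
        if not 0 <= self.n_paralysed <= self.n_injected:
            raise ValueError("n_paralysed must lie in [0, n_injected]")


@dataclass(frozen=True)
class PD50Fit:
    """Median paralytic dose with its 95% confidence interval."""

    pd50: float  # micrograms per fly
    slope: float  # logistic slope on log10(dose)
    ci_low: float
    ci_high: float
    timepoint: str = ""
    stable: bool = True

    def __post_init__(self):
        if self.pd50 <= 0:
            raise ValueError("pd50 must be positive")
        if not self.ci_low <= self.pd50 <= self.ci_high:
            raise ValueError("confidence interval must bracket the estimate")


@dataclass(frozen=True)
class AbundanceRecord:
    """Paired proteomic and transcriptomic abundance of one venom entity."""

    entity_id: str
    family_label: str
    precursor_count_intensity: float
    expression: float

    def __post_init__(self):
        if self.precursor_count_intensity < 0 or self.expression < 0:
            raise ValueError("abundances must be non-negative")


def _is_separated(obs: Sequence[DoseResponseObservation]) -> bool:
    return all(o.n_paralysed in (0, o.n_injected) for o in obs)


def fit_pd50(
    observations: Sequence[DoseResponseObservation],
    link: str = "logit",
    z: float = 1.959963984540054,
) -> PD50Fit:
    """Fit a quantal dose-response curve and return the PD50.

    Maximises the binomial likelihood of a logistic (or probit) curve in
    log10(dose); PD50 is the dose giving 50% response.  The confidence
    interval is computed by delta-method error propagation on the log10
    scale.  When every dose shows an all-or-none response (complete
    separation) no finite slope exists: the fit is flagged unstable and the
    PD50 is reported only as the interval bracketed by the highest fully
    non-paralysing and the lowest fully paralysing dose, with its geometric
    midpoint as the point value.
    """
    obs = [o for o in observations if o.dose > 0]
    doses = sorted({o.dose for o in obs})
    if len(doses) < 3:
        raise ValueError("need at least 3 distinct positive doses")

    if _is_separated(obs):
        by_dose = {d: (0, 0) for d in doses}
        for o in obs:
            k, m = by_dose[o.dose]
            by_dose[o.dose] = (k + o.n_paralysed, m + o.n_injected)
        zeros = [d for d, (k, m) in by_dose.items() if k == 0]
        fulls = [d for d, (k, m) in by_dose.items() if k == m]
        if not zeros or not fulls:
            raise ValueError(
                "complete separation with a one-sided response: PD50 is not "
                "bracketed by the tested doses"
            )
        lo, hi = max(zeros), min(fulls)
        if lo > hi:
            raise ValueError("non-monotone all-or-none responses; cannot bracket PD50")
        mid = math.sqrt(lo * hi)
        return PD50Fit(
            pd50=mid,
            slope=math.nan,
            ci_low=lo,
            ci_high=hi,
            timepoint=obs[0].timepoint,
            stable=False,
        )

    x = np.log10([o.dose for o in obs])
    X = sm.add_constant(x)
    y = np.array([[o.n_paralysed, o.n_injected - o.n_paralysed] for o in obs])
    links = {"logit": sm.families.links.Logit(), "probit": sm.families.links.Probit()}
    if link not in links:
        raise ValueError(f"link must be one of {sorted(links)}")
    model = sm.GLM(y, X, family=sm.families.Binomial(link=links[link]))
    res = model.fit()
    b0, b1 = res.params
    if b1 <= 0:
        raise ValueError("fitted dose-response slope is non-positive")
    log_pd50 = -b0 / b1
    # delta method: grad of -b0/b1 w.r.t. (b0, b1)
    grad = np.array([-1.0 / b1, b0 / b1**2])
    var = float(grad @ res.cov_params() @ grad)
    se = math.sqrt(max(var, 0.0))
    return PD50Fit(
        pd50=10.0 ** log_pd50,
        slope=float(b1),
        ci_low=10.0 ** (log_pd50 - z * se),
        ci_high=10.0 ** (log_pd50 + z * se),
        timepoint=obs[0].timepoint,
        stable=bool(res.converged),
    )


def per_gram(pd50_per_fly: float, fly_mass: float) -> float:
    """Convert a per-animal dose (micrograms) to micrograms per gram body mass."""
    if fly_mass <= 0:
        raise ValueError("fly mass must be positive")
    return pd50_per_fly / fly_mass


def dose_from_concentration(
    concentration_ug_per_ul: float, volume_ul: float = INJECTION_VOLUME_UL
) -> float:
    """Per-fly dose delivered by injecting ``volume_ul`` of diluted venom."""
    if concentration_ug_per_ul < 0 or volume_ul <= 0:
        raise ValueError("concentration must be non-negative and volume positive")
    return concentration_ug_per_ul * volume_ul


def _to_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records.copy()
    return pd.DataFrame([asdict(r) for r in records])


def composition_fractions(
    records: Union[Sequence[AbundanceRecord], pd.DataFrame],
    group_by: str = "family_label",
) -> pd.DataFrame:
    """Per-group percentage of total proteomic intensity and expression.

    Returns a DataFrame indexed by the grouping field with columns
    ``precursor_count_pct`` and ``expression_pct``, each summing to 100.
    """
    df = _to_frame(records)
    out = {}
    for col, name in [
        ("precursor_count_intensity", "precursor_count_pct"),
        ("expression", "expression_pct"),
    ]:
        total = df[col].sum()
        if total <= 0:
            raise ValueError(f"grand total of {col} must be positive")
        out[name] = df.groupby(group_by)[col].sum() / total * 100.0
    return pd.DataFrame(out)


def expression_intensity_correlation(
    records: Union[Sequence[AbundanceRecord], pd.DataFrame],
    log_transform: bool = False,
) -> Tuple[float, float]:
    """Pearson correlation between expression (FPKM) and proteomic intensity.

    Returns ``(r, p)`` with the two-sided p-value from the t transform on
    n - 2 degrees of freedom.  ``log_transform`` correlates log10 values
    (requires strictly positive records).
    """
    df = _to_frame(records)
    x = df["precursor_count_intensity"].to_numpy(dtype=float)
    y = df["expression"].to_numpy(dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 records")
    if log_transform:
        if (x <= 0).any() or (y <= 0).any():
            raise ValueError("log transform requires strictly positive values")
        x, y = np.log10(x), np.log10(y)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
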