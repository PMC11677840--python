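"""Bliss independence interaction analysis for the combined half-dose arm.

Two biocontrol agents act independently (Bliss independence) when their
combined infection rate equals I1 + I2 - I1*I2, i.e. survival probabilities
multiply. The combined half-dose treatment is judged against this null:
the deviation statistic (I_obs - I_exp)^2 / I_exp is referred to a 1-df
chi-square distribution, and the synergy score S = I_obs - I_exp is
classified as synergistic (S > 0), additive (S = 0) or antagonistic (S < 0).

The trial has no half-dose single-agent arms, so the half-dose infection
rates entering the Bliss expectation must be derived from the full-dose
arms; the default convention halves the full-dose any-death rates
(linear low-dose scaling).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .vocab import AGENT_KILLS

COMBINED = "halfmix"
FUNGUS_ARM = "fungi"
NEMATODE_ARM = "nematodes"


@dataclass(frozen=True)
class InfectionRates:
    """Half-dose infection rates entering the Bliss expectation."""

    i_epf: float
    i_epn: float
    source: str = ""

    def __post_init__(self) -> None:
        for name, v in (("i_epf", self.i_epf), ("i_epn", self.i_epn)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} = {v} outside [0, 1]")


@dataclass(frozen=True)
class BlissResult:
    """Observed vs Bliss-expected combined infection, one analysis scope."""

    scope: str
    i_nf: float
    i_bliss: float
    chi2_bliss: float
    p: float
    synergy: float
    verdict: str
    n: int

    def summary(self) -> str:
        from .report import format_p

        return (
            f"{self.scope}: I_NF = {self.i_nf:.4f}, I_Bliss = {self.i_bliss:.4f}, "
            f"chi2 = {self.chi2_bliss:.4f} (p = {format_p(self.p)}), "
            f"S = {self.synergy:.4f} -> {self.verdict}"
        )


class BlissResults:
    """Collection of Bliss results (pooled first, then per block)."""

    def __init__(self, results: list[BlissResult]):
        self.results = results

    @property
    def pooled(self) -> BlissResult:
        return self.results[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.results]).set_index("scope")

    def summary(self) -> str:
        return "\n".join(r.summary() for r in self.results)


def infection_rate(
    records: pd.DataFrame, treatment: str, mortality_definition: str = "any_death"
) -> float:
    """Infection rate of one treatment arm.

    ``any_death`` counts every non-alive outcome (including indeterminate
    deaths); ``agent_specific`` counts only kills attributable to the arm's
    own agent(s).
    """
    sub = records[records["treatment"] == treatment]
    if len(sub) == 0:
        raise ValueError(f"no records for treatment {treatment!r}")
    if mortality_definition == "any_death":
        return float((sub["outcome"] != "alive").mean())
    if mortality_definition == "agent_specific":
        kills = AGENT_KILLS.get(treatment, ())
        return float(sub["outcome"].isin(kills).mean())
    raise ValueError(f"unknown mortality_definition {mortality_definition!r}")


def half_dose_rate(full_dose_rate: float, convention: str = "linear") -> float:
    """Half-dose infection rate from a full-dose rate.

    ``linear`` halves the rate (low-dose linear scaling); ``full`` uses the
    full-dose rate unchanged (a conservative upper bound on the half-dose
    effect).
    """
    if not 0.0 <= full_dose_rate <= 1.0:
        raise ValueError(f"rate {full_dose_rate} outside [0, 1]")
    if convention == "linear":
        return full_dose_rate / 2.0
    if convention == "full":
        return full_dose_rate
    raise ValueError(f"unknown half-dose convention {convention!r}")


def bliss_expected(rates: InfectionRates) -> float:
    """Expected combined infection rate under independent action."""
    return rates.i_epf + rates.i_epn - rates.i_epf * rates.i_epn


def bliss_test(i_nf: float, i_bliss: float) -> tuple[float, float]:
    """Deviation of the observed combined rate from the Bliss expectation.

    Returns (chi2, p) with chi2 = (i_nf - i_bliss)^2 / i_bliss referred to
    chi-square with 1 df.
    """
    if i_bliss == 0.0:
        if i_nf == 0.0:
            return 0.0, 1.0
        raise ZeroDivisionError(
            "Bliss expectation is 0 with nonzero observed rate; statistic unbounded"
        )
    chi2 = (i_nf - i_bliss) ** 2 / i_bliss
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


def classify_synergy(
    i_nf: float, i_bliss: float, tolerance: float = 0.0
) -> tuple[float, str]:
    """Synergy score S = i_nf - i_bliss and its verdict.

    Verdicts: Synergy (S > tolerance), Antagonist (S < -tolerance),
    Additive otherwise. The default tolerance 0 labels every nonzero S.
    """
    for name, v in (("i_nf", i_nf), ("i_bliss", i_bliss)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} = {v} outside [0, 1]")
    s = i_nf - i_bliss
    if s > tolerance:
        verdict = "Synergy"
    elif s < -tolerance:
        verdict = "Antagonist"
    else:
        verdict = "Additive"
    return s, verdict


class BlissAnalysis:
    """Bliss interaction analysis on destructive-sampling records.

    Parameters
    ----------
    records : DataFrame with columns treatment, outcome (and block when
        fitting per block).
    mortality_definition : "any_death" (default) or "agent_specific".
    half_dose_convention : "linear" (default; halve the full-dose rates) or
        "full".
    tolerance : verdict tolerance around S = 0.
    """

    def __init__(
        self,
        records: pd.DataFrame,
        mortality_definition: str = "any_death",
        half_dose_convention: str = "linear",
        tolerance: float = 0.0,
    ):
        self.records = records
        self.mortality_definition = mortality_definition
        self.half_dose_convention = half_dose_convention
        self.tolerance = tolerance

    def _one_scope(self, records: pd.DataFrame, scope: str) -> BlissResult:
        i_epf = half_dose_rate(
            infection_rate(records, FUNGUS_ARM, self.mortality_definition),
            self.half_dose_convention,
        )
        i_epn = half_dose_rate(
            infection_rate(records, NEMATODE_ARM, self.mortality_definition),
            self.half_dose_convention,
        )
        rates = InfectionRates(i_epf, i_epn, source=f"{self.half_dose_convention}-scaled full-dose arms")
        i_bliss = bliss_expected(rates)
        i_nf = infection_rate(records, COMBINED, "any_death")
        chi2, p = bliss_test(i_nf, i_bliss)
        s, verdict = classify_synergy(i_nf, i_bliss, self.tolerance)
        n = int((records["treatment"] == COMBINED).sum())
        return BlissResult(scope, i_nf, i_bliss, chi2, p, s, verdict, n)

    def fit(self, by_block: bool = False) -> BlissResults:
        """Pooled analysis, optionally followed by one result per block.

        Blocks missing any of the three required arms are skipped with a
        warning, never silently.
        """
        required = {FUNGUS_ARM, NEMATODE_ARM, COMBINED}
        present = set(self.records["treatment"])
        missing = required - present
        if missing:
            raise ValueError(f"records lack required treatment arm(s): {sorted(missing)}")
        results = [self._one_scope(self.records, "Total")]
        if by_block:
            if "block" not in self.records.columns:
                raise KeyError("by_block requires a 'block' column")
            for block, sub in self.records.groupby("block", sort=True):
                if not required <= set(sub["treatment"]):
                    warnings.warn(
                        f"block {block!r} missing a required arm; skipped", stacklevel=2
                    )
                    continue
                results.append(self._one_scope(sub, str(block)))
        return BlissResults(results)


def run_bliss_analysis(
    records: pd.DataFrame,
    by_block: bool = False,
    mortality_definition: str = "any_death",
    half_dose_convention: str = "linear",
) -> BlissResults:
    """One-call wrapper around :class:`BlissAnalysis`."""
    return BlissAnalysis(records, mortality_definition, half_dose_convention).fit(by_block=by_block)
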