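"""Rounding profiles and table rendering for paper-style reports.

The display layer rounds each quantity the way the trial's tables print it
(chi-square to 2 d.p., Cramér's V to 3 d.p., Bliss quantities to 4 d.p.,
p-values floored at "<0.001"), so rendered reports can be compared
character-for-character with the published tables.
"""

from __future__ import annotations

import pandas as pd

#: Decimal places per quantity kind.
DEFAULT_ROUNDING = {
    "chi2": 2,
    "cramers_v": 3,
    "bliss": 4,
    "percent": 2,
    "z": 1,
    "ratio": 3,
    "p": 3,
}

P_FLOOR = 0.001


def format_p(p: float, floor: float = P_FLOOR, digits: int = 3) -> str:
    """p-value with the publication floor: values below ``floor`` print as '<floor'."""
    if p < floor:
        return f"<{floor:g}"
    return f"{p:.{digits}f}"


def format_value(kind: str, x: float, rounding: dict[str, int] | None = None) -> str:
    """Round one quantity per the display profile."""
    profile = DEFAULT_ROUNDING if rounding is None else {**DEFAULT_ROUNDING, **rounding}
    if kind == "p":
        return format_p(x, digits=profile["p"])
    return f"{x:.{profile[kind]}f}"


def render_contingency_report(chi_result, table, rounding=None) -> str:
    """Counts, both percentage breakdowns and the Z matrix, as plain text."""
    fmt = lambda k, v: format_value(k, v, rounding)
    parts = [
        "Counts:",
        table.counts.to_string(),
        "",
        "% within rows:",
        table.percent("rows").round(DEFAULT_ROUNDING["percent"]).to_string(),
        "",
        "% within columns:",
        table.percent("columns").round(DEFAULT_ROUNDING["percent"]).to_string(),
        "",
        "Standardized residuals (Z):",
        chi_result.residuals.round(DEFAULT_ROUNDING["z"]).to_string(),
        "",
        f"chi2 = {fmt('chi2', chi_result.statistic)}, df = {chi_result.df}, "
        f"p = {format_p(chi_result.p)}, Cramér's V = {fmt('cramers_v', chi_result.cramers_v)}",
    ]
    return "\n".join(parts)


def render_bliss_report(results, rounding=None) -> pd.DataFrame:
    """Block-by-block Bliss table shaped like the publication's."""
    d = DEFAULT_ROUNDING if rounding is None else {**DEFAULT_ROUNDING, **rounding}
    frame = results.to_frame()
    out = pd.DataFrame(
        {
            "I_NF": frame["i_nf"].round(d["bliss"]),
            "I_Bliss": frame["i_bliss"].round(d["bliss"]),
            "Chi2_Bliss": frame["chi2_bliss"].round(d["bliss"]),
            "p": frame["p"].map(format_p),
            "S": frame["synergy"].round(d["bliss"]),
            "verdict": frame["verdict"],
        },
        index=frame.index,
    )
    return out


def render_emergence_report(full, null, rounding=None) -> str:
    """LRT plus the contrast table, as plain text."""
    from .emergence import lrt_treatment

    chi2, df, p = lrt_treatment(full, null)
    lines = [
        f"LRT: chi2 = {format_value('chi2', chi2, rounding)}, df = {df}, p = {format_p(p)}",
        "Dunnett contrasts (vs control):",
    ]
    for c in full.dunnett_contrasts():
        lines.append(
            f"  {c.contrast}: ratio = {format_value('ratio', c.ratio, rounding)} "
            f"(SE {format_value('ratio', c.se, rounding)}), adj. p = {format_p(c.p_adjusted)}"
        )
    return "\n".join(lines)


def render_community_report(mrpp_results: dict, rounding=None) -> pd.DataFrame:
    """MRPP summary table: one row per dataset/grouping combination."""
    rows = []
    for (dataset, grouping), r in mrpp_results.items():
        rows.append(
            {
                "dataset": dataset,
                "grouping": grouping,
                "A": round(r.A, 3),
                "p": format_p(r.p),
            }
        )
    return pd.DataFrame(rows)
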