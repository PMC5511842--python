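"""Group comparison layer: percent differences, summary tables, inference.

Per-subject relative differences between AC arms are tabulated per region and
quantity (SUV, K1, k2, VT), summarised as mean ± SD, and tested with
Holm-Šídák-adjusted one-sample t-tests plus a fixed-effects two-way ANOVA
(AC method × region) for the balanced design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

BIAS_COLUMNS = ["subject", "region", "quantity", "pair", "percent_diff"]


def percent_diff(test, reference):
    """(test − reference)/reference × 100; reference must be nonzero."""
    test = np.asarray(test, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if np.any(reference == 0):
        raise ZeroDivisionError("percent difference undefined for zero reference")
    out = (test - reference) / reference * 100.0
    return float(out) if out.ndim == 0 else out


def make_bias_table(rows: list[dict]) -> pd.DataFrame:
    """Validate and assemble a tidy bias table (one row per subject×region×quantity×pair)."""
    df = pd.DataFrame(rows, columns=BIAS_COLUMNS)
    if not np.all(np.isfinite(df["percent_diff"])):
        raise ValueError("bias table contains non-finite differences")
    dup = df.duplicated(subset=["subject", "region", "quantity", "pair"])
    if dup.any():
        raise ValueError("duplicate bias-table cells")
    return df


def summarize_bias(table: pd.DataFrame) -> pd.DataFrame:
    """Mean ± sample SD (n−1) per region × quantity × method pair."""
    if table.empty:
        raise ValueError("empty bias table")
    grouped = table.groupby(["quantity", "region", "pair"])["percent_diff"]
    counts = grouped.count()
    if (counts < 2).any():
        raise ValueError("each summary cell needs >= 2 subjects")
    out = grouped.agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count").reset_index()
    return out


def holm_sidak(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Step-down Šídák (Holm-Šídák) adjustment.

    Returns (adjusted p-values, reject flags) in the input order.  Adjusted
    values are monotone in the rank order and clipped to 1.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p, np.zeros(0, dtype=bool)
    _, p_adj, _, _ = multipletests(p, alpha=alpha, method="holm-sidak")
    # strict step-down decision: reject only while adjusted p < alpha
    return p_adj, p_adj < alpha


@dataclass(frozen=True)
class AnovaResult:
    table: pd.DataFrame
    degenerate: bool


def two_way_anova(data: pd.DataFrame, value: str, factor_a: str, factor_b: str) -> AnovaResult:
    """Fixed-effects two-factor ANOVA with interaction, balanced designs only.

    ``data`` is tidy with one observation per row.  Designs with unequal cell
    counts are rejected; a zero within-cell error sum of squares (F would be
    infinite) is flagged as degenerate rather than reported as significant.
    """
    for col in (value, factor_a, factor_b):
        if col not in data.columns:
            raise KeyError(f"missing column {col!r}")
    cells = data.groupby([factor_a, factor_b], observed=True)[value].count()
    n_a = data[factor_a].nunique()
    n_b = data[factor_b].nunique()
    if cells.size != n_a * n_b or cells.nunique() != 1:
        raise ValueError("two-way ANOVA requires a balanced, complete design")
    model = ols(f"{value} ~ C({factor_a}) * C({factor_b})", data=data).fit()
    table = anova_lm(model, typ=2)
    vals = data[value].to_numpy(dtype=float)
    if np.allclose(vals, vals[0], rtol=0.0, atol=1e-12 * max(1.0, abs(vals[0]))):
        # all observations identical: every effect F is 0 by convention
        table.loc[table.index != "Residual", "F"] = 0.0
        table.loc[table.index != "Residual", "PR(>F)"] = 1.0
        return AnovaResult(table=table, degenerate=False)
    resid_ss = float(table.loc["Residual", "sum_sq"])
    total_ss = float(table["sum_sq"].sum())
    degenerate = bool(resid_ss <= 1e-12 * total_ss) or cells.iloc[0] < 2
    return AnovaResult(table=table, degenerate=degenerate)


def one_sample_bias_tests(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-cell one-sample t-tests of percent differences against 0.

    All cells of a quantity are adjusted together with Holm-Šídák; the
    ``significant`` column mirrors the tables' footnote convention
    (marked when adjusted p < alpha).
    """
    rows = []
    for (quantity, region, pair), grp in table.groupby(["quantity", "region", "pair"]):
        v = grp["percent_diff"].to_numpy()
        if v.size < 2 or np.allclose(v, v[0]):
            p = np.nan
            t = np.nan
        else:
            t, p = sps.ttest_1samp(v, 0.0)
        rows.append(dict(quantity=quantity, region=region, pair=pair,
                         mean=v.mean(), sd=v.std(ddof=1), n=v.size, t=t, p_raw=p))
    out = pd.DataFrame(rows)
    adj_all = np.full(len(out), np.nan)
    rej_all = np.zeros(len(out), dtype=bool)
    for _, idx in out.groupby("quantity").groups.items():
        pos = out.index.get_indexer(idx)
        p_raw = out.loc[idx, "p_raw"].to_numpy()
        ok = np.isfinite(p_raw)
        if ok.any():
            adj_ok, rej_ok = holm_sidak(p_raw[ok], alpha=alpha)
            adj_all[pos[ok]] = adj_ok
            rej_all[pos[ok]] = rej_ok
    out["p_holm_sidak"] = adj_all
    out["significant"] = rej_all
    out["marker"] = np.where(out["significant"], "*", "")
    return out


def format_summary_text(summary: pd.DataFrame, tests: pd.DataFrame | None = None) -> str:
    """Human-readable mean ± SD table, starred where adjusted p < 0.05."""
    df = summary.copy()
    if tests is not None:
        df = df.merge(tests[["quantity", "region", "pair", "marker"]],
                      on=["quantity", "region", "pair"], how="left")
        df["marker"] = df["marker"].fillna("")
    else:
        df["marker"] = ""
    lines = []
    for quantity, grp in df.groupby("quantity"):
        lines.append(f"Relative differences (%) — {quantity}")
        piv = grp.pivot(index="region", columns="pair", values=["mean", "sd", "marker"])
        for region in piv.index:
            cells = []
            for pair in sorted(grp["pair"].unique()):
                m = piv.loc[region, ("mean", pair)]
                s = piv.loc[region, ("sd", pair)]
                star = piv.loc[region, ("marker", pair)]
                cells.append(f"{pair}: {m:+.1f} ± {s:.1f}{star}")
            lines.append(f"  {region:6s} " + "   ".join(cells))
        lines.append("")
    lines.append("* adjusted p < 0.05 (Holm-Šídák)")
    return "\n".join(lines)
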