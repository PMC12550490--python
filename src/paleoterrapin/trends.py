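"""Trend coding and association tests between demography, area and climate.

Changes across a period pair (earlier vs later value) are coded by the sign
of earlier - later: negative = increasing, positive = decreasing, zero =
stable.  Codes are cross-tabulated and tested with a chi-squared
independence test; the Phi coefficient measures 2x2 association strength
(species with a stable code are excluded from Phi, which needs binary data).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

PERIOD_AGES_YEARS = {"MIS19": 787_000.0, "LIG": 130_000.0, "LGM": 20_000.0}
PERIOD_PAIRS = [("MIS19", "LIG"), ("LIG", "LGM")]

INCREASING = "increasing"
DECREASING = "decreasing"
STABLE = "stable"


def code_change(value_earlier: float, value_later: float) -> str:
    """Sign coding of earlier minus later."""
    if not (np.isfinite(value_earlier) and np.isfinite(value_later)):
        raise ValueError("values must be finite")
    delta = value_earlier - value_later
    if delta < 0:
        return INCREASING
    if delta > 0:
        return DECREASING
    return STABLE


def build_trend_table(
    ne_values: pd.DataFrame,
    area_values: pd.DataFrame,
    temperature: dict[str, float],
    species_meta: pd.DataFrame | None = None,
    period_pairs: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Per-species, per-period-pair codes for Ne, area and temperature.

    ``ne_values`` and ``area_values``: rows = species, columns = period
    labels holding the period's value (Ne at the period's nominal age;
    suitable area).  ``temperature``: global mean-surface-temperature per
    period, applied to every species.  ``species_meta`` (optional): index =
    species with 'habitat' and 'climate' columns carried through.
    """
    period_pairs = period_pairs or PERIOD_PAIRS
    rows = []
    for sp in ne_values.index:
        for earlier, later in period_pairs:
            rec = {
                "species": sp,
                "pair": f"{earlier}->{later}",
                "ne_code": code_change(ne_values.loc[sp, earlier], ne_values.loc[sp, later]),
                "area_code": code_change(area_values.loc[sp, earlier], area_values.loc[sp, later]),
                "temp_code": code_change(temperature[earlier], temperature[later]),
            }
            if species_meta is not None:
                rec["habitat"] = species_meta.loc[sp, "habitat"]
                rec["climate"] = species_meta.loc[sp, "climate"]
            rows.append(rec)
    return pd.DataFrame(rows)


def build_contingency(
    table: pd.DataFrame,
    rows: str = "ne_code",
    cols: str = "area_code",
    pair: str | None = None,
    subset: dict[str, str] | None = None,
    drop_stable: bool = False,
) -> pd.DataFrame:
    """Cross-tabulate two code columns, optionally restricted to one period
    pair and/or metadata subset; ``drop_stable`` removes species with any
    stable code in the two columns (the binary-data requirement for Phi)."""
    t = table
    if pair is not None:
        t = t[t["pair"] == pair]
    if subset:
        for key, val in subset.items():
            t = t[t[key] == val]
    if drop_stable:
        t = t[(t[rows] != STABLE) & (t[cols] != STABLE)]
    if len(t) == 0:
        raise ValueError("no species left after filtering")
    return pd.crosstab(t[rows], t[cols])


@dataclass
class AssociationResult:
    counts: pd.DataFrame
    chi2: float
    p: float
    chi2_uncorrected: float
    p_uncorrected: float
    phi: float | None
    correction: bool
    n: int
    dof: int


def chi_squared(counts: pd.DataFrame | np.ndarray, correction: bool = True) -> AssociationResult:
    """Pearson chi-squared independence test on a contingency table.

    For 2x2 tables the continuity (Yates) correction is applied by default;
    both corrected and uncorrected statistics are always reported, along
    with Phi for 2x2 tables (from the uncorrected statistic's closed form).
    """
    arr = np.asarray(counts, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need a table of at least 2x2")
    if np.any(arr < 0) or not np.allclose(arr, np.round(arr)):
        raise ValueError("counts must be non-negative integers")
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("zero marginal total")
    chi2_c, p_c, dof, _ = stats.chi2_contingency(arr, correction=True)
    chi2_u, p_u, _, _ = stats.chi2_contingency(arr, correction=False)
    phi = phi_coefficient(arr) if arr.shape == (2, 2) else None
    if correction:
        chi2_val, p_val = chi2_c, p_c
    else:
        chi2_val, p_val = chi2_u, p_u
    df = counts if isinstance(counts, pd.DataFrame) else pd.DataFrame(arr)
    return AssociationResult(
        counts=df,
        chi2=float(chi2_val),
        p=float(p_val),
        chi2_uncorrected=float(chi2_u),
        p_uncorrected=float(p_u),
        phi=phi,
        correction=correction,
        n=int(arr.sum()),
        dof=int(dof),
    )


def phi_coefficient(counts_2x2) -> float:
    """(ad - bc) / sqrt of the marginal product, uncorrected; NaN on a zero
    marginal."""
    arr = np.asarray(counts_2x2, dtype=float)
    if arr.shape != (2, 2):
        raise ValueError("Phi requires a 2x2 table")
    (a, b), (c, d) = arr
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return float("nan")
    return float((a * d - b * c) / np.sqrt(denom))


def association_report(
    trend_table: pd.DataFrame,
    rows: str = "ne_code",
    cols: str = "area_code",
    subsets: dict[str, dict[str, str]] | None = None,
    per_pair: bool = True,
) -> pd.DataFrame:
    """Chi-squared + Phi for each period pair and optional metadata subset.

    ``per_pair=False`` pools species-by-period-pair rows into one table —
    the convention for the global-temperature comparison, where the
    temperature code only varies between period pairs.
    """
    subsets = {"all": {}, **(subsets or {})}
    out = []
    pairs = list(trend_table["pair"].unique()) if per_pair else [None]
    for pair in pairs:
        for name, flt in subsets.items():
            try:
                counts = build_contingency(trend_table, rows, cols, pair=pair, subset=flt or None)
                res = chi_squared(counts)
                phi = None
                try:
                    phi_counts = build_contingency(trend_table, rows, cols, pair=pair, subset=flt or None, drop_stable=True)
                    if phi_counts.shape == (2, 2):
                        phi = phi_coefficient(phi_counts)
                except ValueError:
                    pass
                out.append(
                    {
                        "pair": pair or "pooled",
                        "subset": name,
                        "rows": rows,
                        "cols": cols,
                        "chi2_corrected": res.chi2 if res.counts.shape == (2, 2) else res.chi2_uncorrected,
                        "chi2_uncorrected": res.chi2_uncorrected,
                        "p": res.p,
                        "phi": phi,
                        "n": res.n,
                    }
                )
            except ValueError as exc:
                out.append({"pair": pair or "pooled", "subset": name, "rows": rows, "cols": cols, "error": str(exc)})
    return pd.DataFrame(out)
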