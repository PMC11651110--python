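"""Covariate engineering: growth-reference z-scores, design matrices and
collinearity screening.

Anthropometric measures are standardized with the LMS method,
``z = ((x/M)**L - 1) / (L*S)`` (or ``log(x/M)/S`` when L = 0), against a
reference table of L (Box-Cox power), M (median) and S (coefficient of
variation) curves indexed by sex and age in months.  Collinearity among
design-matrix term groups is measured with the generalized variance
inflation factor (GVIF, Fox & Monette), compared across terms of
different df on the ``GVIF**(1/(2*df))`` scale; a design is considered
acceptable when every scaled GVIF is strictly below 3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LMSReference",
    "synthetic_lms_reference",
    "lms_zscore",
    "classify_zbmi",
    "build_design_matrix",
    "gvif",
    "screen_interactions",
]

GVIF_ACCEPTABLE = 3.0  # strict upper bound on GVIF^(1/(2 df))


class LMSReference:
    """LMS growth-reference curves.

    Backed by a long-format table with columns
    (measure, sex, age_months, L, M, S); rows for one (measure, sex) must
    have strictly increasing ages, M > 0 and S > 0.  Lookups interpolate
    L, M and S linearly in age.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"measure", "sex", "age_months", "L", "M", "S"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"LMS table is missing columns: {sorted(missing)}")
        if (table["M"] <= 0).any() or (table["S"] <= 0).any():
            raise ValueError("LMS reference requires M > 0 and S > 0")
        self.table = table.sort_values(["measure", "sex", "age_months"]).reset_index(drop=True)
        for (meas, sex), grp in self.table.groupby(["measure", "sex"]):
            ages = grp["age_months"].to_numpy()
            if np.any(np.diff(ages) <= 0):
                raise ValueError(f"ages must be strictly increasing for ({meas}, {sex})")

    @classmethod
    def from_csv(cls, path) -> "LMSReference":
        return cls(pd.read_csv(path))

    def lookup(self, measure: str, sex: str, age_months: float) -> tuple[float, float, float]:
        grp = self.table[(self.table["measure"] == measure) & (self.table["sex"] == sex)]
        if grp.empty:
            raise KeyError(f"no LMS rows for measure={measure!r}, sex={sex!r}")
        ages = grp["age_months"].to_numpy(float)
        a = float(np.clip(age_months, ages[0], ages[-1]))
        L = float(np.interp(a, ages, grp["L"].to_numpy(float)))
        M = float(np.interp(a, ages, grp["M"].to_numpy(float)))
        S = float(np.interp(a, ages, grp["S"].to_numpy(float)))
        return L, M, S

    def zscore(self, measure: str, sex: str, age_months: float, x: float) -> float:
        L, M, S = self.lookup(measure, sex, age_months)
        return lms_zscore(x, L, M, S)


def synthetic_lms_reference(age_min_months: int = 36, age_max_months: int = 180) -> LMSReference:
    """A small synthetic LMS table for tests and examples.

    Not a WHO reference: smooth, plausible L/M/S curves for BMI, height
    and weight of 3–15 year olds, for both sexes.  Real WHO tables are
    accepted as CSV with the same columns.
    """
    ages = np.arange(age_min_months, age_max_months + 1, 6, dtype=float)
    rows = []
    for sex, shift in (("M", 0.0), ("F", -0.15)):
        t = (ages - 36.0) / 144.0  # 0..1 over 3-15 y
        for measure, L, M, S in (
            ("bmi", -1.6 + 0.4 * t, 15.5 + 3.0 * t + shift, 0.08 + 0.04 * t),
            ("height", 1.0 + 0.0 * t, 95.0 + 60.0 * t + 2.0 * shift, 0.038 + 0.004 * t),
            ("weight", -0.2 + 0.2 * t, 14.5 + 24.0 * t + shift, 0.11 + 0.03 * t),
        ):
            for a, l, m, s in zip(ages, np.atleast_1d(L) * np.ones_like(t), M, np.atleast_1d(S) * np.ones_like(t)):
                rows.append({"measure": measure, "sex": sex, "age_months": a, "L": l, "M": m, "S": s})
    return LMSReference(pd.DataFrame(rows))


def lms_zscore(x: float, L: float, M: float, S: float):
    """LMS (Box-Cox) z-score: ((x/M)**L - 1)/(L*S), or log(x/M)/S at L=0."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("measurement must be positive")
    if M <= 0 or S <= 0:
        raise ValueError("M and S must be positive")
    if L == 0:
        z = np.log(x / M) / S
    else:
        # expm1 keeps ((x/M)**L - 1)/L accurate as L -> 0
        z = np.expm1(L * np.log(x / M)) / (L * S)
    return float(z) if z.ndim == 0 else z


def classify_zbmi(z: float, cut_overweight: float = 2.0, cut_obese: float = 4.0) -> str:
    """Classify a BMI-for-age z-score.

    normal: -2 <= z <= cut_overweight; overweight: up to and including
    cut_obese; obese above that; z < -2 is reported as underweight.
    """
    if not np.isfinite(z):
        raise ValueError("z must be finite")
    if not cut_overweight < cut_obese:
        raise ValueError("cut_overweight must be below cut_obese")
    if z < -2.0:
        return "underweight"
    if z <= cut_overweight:
        return "normal"
    if z <= cut_obese:
        return "overweight"
    return "obese"


def build_design_matrix(
    cov: pd.DataFrame,
    terms: list[str] | None = None,
    ethnic_ref: str = "U",
    geography_ref: str = "H",
    center_age: bool = True,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Treatment-coded design matrix with a term-group map.

    Default terms: centered age, bmiaz, ethnic (reference ``ethnic_ref``),
    geography (reference ``geography_ref``), and the ethnic x geography
    interaction — with interaction columns only for level pairs actually
    observed in the data.  Returns the design as a DataFrame (intercept
    first) and a map from term name to its columns, as needed by
    :func:`gvif`.

    Generic term syntax: any numeric column name is passed through;
    ``a:b`` denotes an elementwise product of numeric columns.
    """
    if terms is None:
        terms = ["age", "bmiaz", "ethnic", "geography", "ethnic:geography"]
    n = len(cov)
    design: dict[str, np.ndarray] = {"intercept": np.ones(n)}
    groups: dict[str, list[str]] = {}

    def add(term: str, name: str, values: np.ndarray):
        design[name] = np.asarray(values, dtype=float)
        groups.setdefault(term, []).append(name)

    for term in terms:
        if term == "ethnic" or term == "geography":
            ref = ethnic_ref if term == "ethnic" else geography_ref
            levels = sorted(cov[term].astype(str).unique())
            if ref not in levels:
                raise ValueError(f"reference level {ref!r} not present in {term!r}")
            for lev in levels:
                if lev != ref:
                    add(term, f"{term}[{lev}]", (cov[term].astype(str) == lev).to_numpy())
        elif term == "ethnic:geography":
            elev = [l for l in sorted(cov["ethnic"].astype(str).unique()) if l != ethnic_ref]
            glev = [l for l in sorted(cov["geography"].astype(str).unique()) if l != geography_ref]
            added = 0
            for e in elev:
                for g in glev:
                    mask = (cov["ethnic"].astype(str) == e) & (cov["geography"].astype(str) == g)
                    if mask.any():
                        add(term, f"ethnic[{e}]:geography[{g}]", mask.to_numpy())
                        added += 1
            if elev and glev and added == 0:
                raise ValueError("no ethnic x geography level pair is observed in the data")
        elif ":" in term:
            parts = term.split(":")
            prod = np.ones(n)
            for p in parts:
                prod = prod * _numeric_column(cov, p, center_age)
            add(term, term, prod)
        else:
            add(term, term, _numeric_column(cov, term, center_age))
    X = pd.DataFrame(design, index=cov.index)
    return X, groups


def _numeric_column(cov: pd.DataFrame, name: str, center_age: bool) -> np.ndarray:
    if name not in cov.columns:
        raise KeyError(f"covariate {name!r} not found")
    x = cov[name].to_numpy(float)
    if name == "age" and center_age:
        x = x - x.mean()
    return x


def gvif(design: pd.DataFrame, groups: dict[str, list[str]]) -> pd.DataFrame:
    """Generalized variance inflation factors per term group.

    Fox-Monette: on the correlation matrix R of the non-intercept
    columns, ``GVIF(g) = det(R_gg) * det(R_-g-g) / det(R)``.  Reported
    per group with its df and ``GVIF**(1/(2*df))``, the scale on which
    terms of different df are comparable.
    """
    cols = [c for c in design.columns if c != "intercept"]
    X = design[cols].to_numpy(float)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [c for c, s in zip(cols, sd) if s == 0]
        raise ValueError(f"constant (rank-deficient) columns: {bad}")
    R = np.corrcoef(X, rowvar=False)
    if X.shape[1] == 1:
        R = np.array([[1.0]])
    det_all = np.linalg.det(R)
    if det_all <= 1e-12:
        corr = _collinear_columns(X, cols)
        raise ValueError(f"rank-deficient design; collinear columns: {corr}")
    idx = {c: i for i, c in enumerate(cols)}
    rows = []
    for term, members in groups.items():
        gi = [idx[m] for m in members if m in idx]
        if not gi:
            continue
        rest = [i for i in range(len(cols)) if i not in gi]
        det_g = np.linalg.det(R[np.ix_(gi, gi)])
        det_rest = np.linalg.det(R[np.ix_(rest, rest)]) if rest else 1.0
        g = float(det_g * det_rest / det_all)
        df = len(gi)
        rows.append(
            {"term": term, "df": df, "gvif": g, "gvif_scaled": g ** (1.0 / (2.0 * df))}
        )
    return pd.DataFrame(rows)


def _collinear_columns(X: np.ndarray, cols: list[str]) -> list[str]:
    """Name columns involved in an (near-)exact linear dependence."""
    _, s, vt = np.linalg.svd(X - X.mean(axis=0), full_matrices=False)
    null = vt[s < s.max() * 1e-8]
    names: set[str] = set()
    for v in null:
        names.update(c for c, w in zip(cols, v) if abs(w) > 1e-6)
    return sorted(names) or list(cols)


def screen_interactions(
    cov: pd.DataFrame,
    candidates: dict[str, list[str]],
    **design_kwargs,
) -> pd.DataFrame:
    """Rank candidate designs by their worst scaled GVIF.

    ``candidates`` maps a label to a term list for
    :func:`build_design_matrix`.  Each candidate is fitted and reported
    with its maximum ``GVIF**(1/(2*df))``; candidates below the strict
    acceptability bound (3) are flagged acceptable, rank-deficient
    candidates are flagged as such with NaN GVIF.
    """
    if not candidates:
        raise ValueError("need at least one candidate")
    rows = []
    for label, terms in candidates.items():
        try:
            X, groups = build_design_matrix(cov, terms=terms, **design_kwargs)
            report = gvif(X, groups)
            max_scaled = float(report["gvif_scaled"].max())
            rows.append(
                {
                    "candidate": label,
                    "max_gvif_scaled": max_scaled,
                    "acceptable": max_scaled < GVIF_ACCEPTABLE,
                    "rank_deficient": False,
                }
            )
        except ValueError:
            rows.append(
                {
                    "candidate": label,
                    "max_gvif_scaled": float("nan"),
                    "acceptable": False,
                    "rank_deficient": True,
                }
            )
    return pd.DataFrame(rows).sort_values("max_gvif_scaled", na_position="last").reset_index(drop=True)
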