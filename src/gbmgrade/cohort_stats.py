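"""Cohort-level validation statistics for the complexity grade.

Reproduces the validation arm of a grading-system study: feature
prevalence summaries, grade-stratified outcome tables, Pearson chi-square
association tests (grade vs. extent of resection, grade vs. major
complications), and two-rater agreement via Cohen's kappa.

Conventions: percentages are rounded half-up to one decimal, matching
clinical-table style; the chi-square is the plain Pearson statistic
without continuity correction; "major complication" means a
Clavien-Dindo grade strictly above 3a.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .grading import COMPLEXITY_LEVELS, FLAG_NAMES

__all__ = [
    "CLAVIEN_LEVELS",
    "ContingencyTable",
    "Chi2Result",
    "KappaResult",
    "is_major_complication",
    "major_complication",
    "crosstab",
    "rater_crosstab",
    "pearson_chi2",
    "cohens_kappa",
    "summarize_features",
    "summarize_grades",
    "round_half_up",
    "format_counts_table",
]

# ordinal surgical-complication scale; "major" = strictly above 3a
CLAVIEN_LEVELS = ("none", "1", "2", "3a", "3b", "4a", "4b", "5")
_MAJOR = frozenset({"3b", "4a", "4b", "5"})

FEATURE_LABELS = {
    "periventricular": "Periventricular or deep location",
    "callosal_or_bilateral": "Corpus callosum involvement or bilateral location",
    "eloquent": "Eloquent location",
    "large": "Largest diameter ≥ threshold",
    "oedema": "Associated oedema ≥ threshold",
}


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round with ties away from zero (half-up), as clinical tables print."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _pct(count: int, total: int, decimals: int = 1) -> float:
    """Exact-rational percentage, rounded half-up."""
    q = Decimal(1).scaleb(-decimals)
    return float((Decimal(100 * int(count)) / Decimal(int(total))).quantize(q, ROUND_HALF_UP))


def is_major_complication(grade: str) -> bool:
    """True iff the Clavien-Dindo grade is strictly above 3a."""
    g = str(grade)
    if g not in CLAVIEN_LEVELS:
        raise ValueError(f"unknown Clavien-Dindo grade {grade!r}; expected one of {CLAVIEN_LEVELS}")
    return g in _MAJOR


def major_complication(series: pd.Series) -> pd.Series:
    """Vectorised :func:`is_major_complication`."""
    s = series.astype(str)
    bad = ~s.isin(CLAVIEN_LEVELS)
    if bad.any():
        raise ValueError(f"unknown Clavien-Dindo grades: {sorted(s[bad].unique())}")
    return s.isin(_MAJOR)


@dataclass(frozen=True)
class ContingencyTable:
    """An r x c count table with ordered labels."""

    counts: np.ndarray
    row_labels: tuple
    col_labels: tuple

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.ndim != 2:
            raise ValueError("counts must be 2D")
        if (c < 0).any():
            raise ValueError("counts must be non-negative")
        if c.sum() <= 0:
            raise ValueError("grand total must be positive")
        if c.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("labels do not match table shape")
        object.__setattr__(self, "counts", c)
        object.__setattr__(self, "row_labels", tuple(self.row_labels))
        object.__setattr__(self, "col_labels", tuple(self.col_labels))

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.row_labels), columns=list(self.col_labels))


@dataclass(frozen=True)
class Chi2Result:
    statistic: float
    df: int
    p: float
    expected: np.ndarray
    warning_low_expected: bool

    def as_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "df": self.df,
            "p": self.p,
            "p_formatted": f"{self.p:.4f}",
            "expected": np.asarray(self.expected).tolist(),
            "warning_low_expected": self.warning_low_expected,
        }


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    se: float
    p_o: float
    p_e: float
    n: int

    def as_dict(self) -> dict:
        return {
            "kappa": self.kappa,
            "se": self.se,
            "observed_agreement": self.p_o,
            "expected_agreement": self.p_e,
            "n": self.n,
        }


def _ordered_levels(series: pd.Series) -> list:
    """Deterministic level ordering: complexity low<moderate<high, booleans
    False<True, Clavien-Dindo ordinal, otherwise sorted."""
    vals = set(series.unique())
    for order in (COMPLEXITY_LEVELS, (False, True), (0, 1), CLAVIEN_LEVELS):
        if vals <= set(order):
            return [v for v in order if v in vals]
    return sorted(vals)


def crosstab(cohort: pd.DataFrame, row: str, col: str) -> ContingencyTable:
    """Cross-tabulate two cohort variables into a contingency table.

    Rejects missing values, naming the offending subjects.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    for var in (row, col):
        if var not in cohort.columns:
            raise ValueError(f"variable {var!r} not in cohort")
        na = cohort[var].isna()
        if na.any():
            ids = (
                cohort.loc[na, "subject_id"].tolist()
                if "subject_id" in cohort
                else list(cohort.index[na])
            )
            raise ValueError(f"missing values for {var!r} in subjects {ids}")
    rows = _ordered_levels(cohort[row])
    cols = _ordered_levels(cohort[col])
    tab = pd.crosstab(cohort[row], cohort[col]).reindex(index=rows, columns=cols, fill_value=0)
    return ContingencyTable(tab.to_numpy(), tuple(rows), tuple(cols))


def rater_crosstab(cohort: pd.DataFrame, scale: str = "class") -> ContingencyTable:
    """Square rater-1 x rater-2 cross-table on the class (default) or raw
    0-5 score scale, padded so both axes carry the full level set."""
    if scale == "class":
        c1, c2, levels = "complexity", "grade_rater2", list(COMPLEXITY_LEVELS)
    elif scale == "score":
        c1, c2, levels = "score", "score_rater2", list(range(6))
    else:
        raise ValueError("scale must be 'class' or 'score'")
    if c2 not in cohort.columns:
        raise ValueError(f"cohort has no second-rater column {c2!r}")
    tab = pd.crosstab(cohort[c1], cohort[c2]).reindex(index=levels, columns=levels, fill_value=0)
    return ContingencyTable(tab.to_numpy(), tuple(levels), tuple(levels))


def pearson_chi2(table: ContingencyTable) -> Chi2Result:
    """Plain Pearson chi-square test of independence on an r x c table.

    No continuity correction. All-zero rows/columns are dropped with a
    warning; tables degenerating to a single row or column are rejected.
    ``warning_low_expected`` flags any expected cell count below 5.
    """
    counts = table.counts
    keep_r = counts.sum(axis=1) > 0
    keep_c = counts.sum(axis=0) > 0
    if not keep_r.all() or not keep_c.all():
        warnings.warn("dropping all-zero rows/columns before chi-square", stacklevel=2)
        counts = counts[keep_r][:, keep_c]
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError(f"degenerate table of shape {counts.shape}: chi-square needs >= 2x2")
    stat, p, df, expected = stats.chi2_contingency(counts, correction=False)
    return Chi2Result(
        statistic=float(stat),
        df=int(df),
        p=float(p),
        expected=expected,
        warning_low_expected=bool((expected < 5).any()),
    )


def cohens_kappa(cross: ContingencyTable, se_formula: str = "asymptotic") -> KappaResult:
    """Cohen's kappa from a square rater cross-table.

    kappa = (p_o - p_e) / (1 - p_e) with p_o the diagonal proportion and
    p_e the chance agreement from the margins. The default standard error
    is the large-sample non-null estimator of Fleiss, Cohen and Everitt;
    ``se_formula='simple'`` gives sqrt(p_o (1 - p_o) / (n (1 - p_e)^2)).
    """
    counts = cross.counts
    if counts.shape[0] != counts.shape[1]:
        raise ValueError(f"kappa needs a square table, got {counts.shape}")
    n = counts.sum()
    if n < 2:
        raise ValueError("kappa needs at least 2 rated subjects")
    p = counts / n
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    p_o = float(np.trace(p))
    p_e = float(row @ col)
    if p_e >= 1.0 - 1e-12:
        raise ValueError("expected agreement is 1 (all margin mass in one category): kappa undefined")
    kappa = (p_o - p_e) / (1 - p_e)
    if se_formula == "simple":
        var = p_o * (1 - p_o) / (n * (1 - p_e) ** 2)
    elif se_formula == "asymptotic":
        # Fleiss-Cohen-Everitt large-sample variance of kappa-hat
        marg = row[:, None] + col[None, :]  # p_i. + p_.j
        diag = np.diag(p)
        term1 = float(np.sum(diag * ((1 - p_e) - (row + col) * (1 - p_o)) ** 2))
        off = p * (marg.T) ** 2  # weight p_ij by (p_.i + p_j.)^2
        off = off - np.diag(np.diag(off))
        term2 = (1 - p_o) ** 2 * float(off.sum())
        term3 = (p_o * p_e - 2 * p_e + p_o) ** 2
        var = (term1 + term2 - term3) / (n * (1 - p_e) ** 4)
    else:
        raise ValueError("se_formula must be 'asymptotic' or 'simple'")
    return KappaResult(kappa=float(kappa), se=float(np.sqrt(max(var, 0.0))), p_o=p_o, p_e=p_e, n=int(n))


def summarize_features(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-feature prevalence table: count and percentage at each level.

    One pair of rows (absent/present) per binary feature; counts at each
    feature sum to the cohort size; percentages rounded half-up to one
    decimal.
    """
    missing = [f for f in FLAG_NAMES if f not in cohort.columns]
    if missing:
        raise ValueError(f"cohort lacks flag columns: {missing}")
    n = len(cohort)
    if n == 0:
        raise ValueError("cohort is empty")
    rows = []
    for feat in FLAG_NAMES:
        col = cohort[feat]
        if col.isna().any():
            raise ValueError(f"missing values in flag column {feat!r}")
        present = int(col.astype(int).sum())
        for level, count in (("absent", n - present), ("present", present)):
            rows.append(
                {
                    "feature": feat,
                    "label": FEATURE_LABELS[feat],
                    "level": level,
                    "count": count,
                    "pct": _pct(count, n),
                }
            )
    return pd.DataFrame(rows)


def summarize_grades(cohort: pd.DataFrame) -> pd.DataFrame:
    """Grade-stratified outcome table: per complexity class and overall,
    the number of patients, complete resections and major complications
    (counts and half-up percentages)."""
    for col in ("complexity", "complete_resection", "clavien_dindo"):
        if col not in cohort.columns:
            raise ValueError(f"cohort lacks column {col!r}")
    df = cohort.copy()
    df["major"] = major_complication(df["clavien_dindo"])
    df["resected"] = df["complete_resection"].astype(int).astype(bool)
    rows = []
    groups = [(lvl, df[df["complexity"] == lvl]) for lvl in COMPLEXITY_LEVELS]
    groups.append(("total", df))
    for label, g in groups:
        n = len(g)
        res = int(g["resected"].sum())
        maj = int(g["major"].sum())
        rows.append(
            {
                "complexity": label,
                "n": n,
                "complete_resection_n": res,
                "complete_resection_pct": _pct(res, n) if n else float("nan"),
                "major_complication_n": maj,
                "major_complication_pct": _pct(maj, n) if n else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def format_counts_table(df: pd.DataFrame) -> str:
    """Aligned plain-text rendering of a summary table."""
    return df.to_string(index=False)
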