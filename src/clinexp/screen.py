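"""Per-transcript correlation screen for clinal expression.

Each transcript's normalized expression is correlated with sample
latitude (Pearson by default, Spearman for concordance checking);
p-values are Benjamini-Hochberg adjusted and transcripts are classified
as +CE (expression increases with latitude), -CE (decreases) or NS at
the chosen FDR.  Replicate cages/timepoints are treated as independent
points, with an optional population-mean mode.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


class UntestableError(ValueError):
    """Raised for transcripts whose expression is constant across samples."""


def correlate_transcript(
    expr: np.ndarray, latitudes: np.ndarray, method: str = "pearson"
) -> tuple[float, float]:
    """Correlation of one transcript's expression with latitude.

    Pearson uses the product-moment coefficient with a two-sided t test
    on n - 2 degrees of freedom; Spearman is Pearson on midranks.
    """
    expr = np.asarray(expr, float)
    latitudes = np.asarray(latitudes, float)
    if expr.shape != latitudes.shape:
        raise ValueError(f"length mismatch: {expr.shape} vs {latitudes.shape}")
    if expr.size < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(expr) == 0:
        raise UntestableError("constant expression")
    if method == "pearson":
        res = stats.pearsonr(expr, latitudes)
    elif method == "spearman":
        res = stats.spearmanr(expr, latitudes)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(res.statistic), float(res.pvalue)


def _row_pearson(values: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-row Pearson r and two-sided t-test p against y."""
    n = values.shape[1]
    xc = values - values.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum(axis=1))
    sy = np.sqrt((yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ yc) / (sx * sy)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isclose(np.abs(r), 1.0)] = 0.0
    return r, p


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(pvals, float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def screen_latitude(
    values: pd.DataFrame,
    latitudes: np.ndarray,
    fdr: float = 0.01,
    method: str = "pearson",
) -> pd.DataFrame:
    """Correlation screen for every transcript (rows of ``values``).

    Returns a CE-result table with columns ``transcript_id, r_pearson,
    p_pearson, rho_spearman, q, direction``; constant transcripts are
    marked ``untestable`` and excluded from the FDR adjustment.
    """
    lat = np.asarray(latitudes, float)
    arr = values.to_numpy(float)
    if arr.shape[1] != lat.size:
        raise ValueError(f"{arr.shape[1]} samples vs {lat.size} latitudes")
    testable = np.ptp(arr, axis=1) > 0

    r = np.full(len(arr), np.nan)
    p = np.full(len(arr), np.nan)
    rho = np.full(len(arr), np.nan)
    r[testable], p[testable] = _row_pearson(arr[testable], lat)
    ranks = stats.rankdata(arr[testable], axis=1)
    rho[testable], _ = _row_pearson(ranks, stats.rankdata(lat))

    res = pd.DataFrame(
        {
            "transcript_id": values.index,
            "r_pearson": r,
            "p_pearson": p,
            "rho_spearman": rho,
        }
    )
    primary = res["p_pearson"] if method == "pearson" else None
    if method == "spearman":
        # Spearman p via the same t approximation on rank correlations
        n = arr.shape[1]
        with np.errstate(invalid="ignore", divide="ignore"):
            t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
        primary = pd.Series(2.0 * stats.t.sf(np.abs(t), df=n - 2))
    res["p_primary"] = primary
    return classify_ce(res, fdr=fdr, method=method)


def classify_ce(res: pd.DataFrame, fdr: float = 0.01, method: str = "pearson") -> pd.DataFrame:
    """Attach BH q-values and +CE / -CE / NS / untestable labels."""
    if not 0.0 <= fdr <= 1.0:
        raise ValueError(f"fdr must be in [0, 1], got {fdr}")
    res = res.copy()
    pcol = res["p_primary"] if "p_primary" in res else res["p_pearson"]
    coef = res["r_pearson"] if method == "pearson" else res["rho_spearman"]
    testable = pcol.notna().to_numpy()
    q = np.full(len(res), np.nan)
    q[testable] = bh_adjust(pcol.to_numpy(float)[testable])
    res["q"] = q
    direction = np.where(
        ~testable,
        "untestable",
        np.where(q <= fdr, np.where(coef > 0, "+CE", "-CE"), "NS"),
    )
    res["direction"] = direction
    res = res.drop(columns=["p_primary"], errors="ignore")
    return res


def normality_screen(values: pd.DataFrame, fdr: float = 0.01) -> pd.DataFrame:
    """Shapiro-Wilk normality screen per transcript, BH-adjusted flags.

    Constant transcripts are reported untestable.  Returns per-transcript
    p, q and a departure flag at the given FDR; the flagged fraction is
    ``flagged.mean()`` over testable rows.
    """
    arr = values.to_numpy(float)
    if arr.shape[1] < 3:
        raise ValueError("normality screen needs at least 3 samples")
    p = np.full(len(arr), np.nan)
    for i, row in enumerate(arr):
        if np.ptp(row) > 0:
            p[i] = stats.shapiro(row).pvalue
    testable = ~np.isnan(p)
    q = np.full(len(arr), np.nan)
    q[testable] = bh_adjust(p[testable])
    return pd.DataFrame(
        {
            "transcript_id": values.index,
            "p_normality": p,
            "q_normality": q,
            "departs": np.where(testable, q <= fdr, False),
            "testable": testable,
        }
    )


def method_concordance(r_pearson: np.ndarray, rho_spearman: np.ndarray) -> float:
    """Pearson correlation between the two screens' coefficient vectors."""
    a = np.asarray(r_pearson, float)
    b = np.asarray(rho_spearman, float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    ok = np.isfinite(a) & np.isfinite(b)
    return float(np.corrcoef(a[ok], b[ok])[0, 1])


def overlap_test(set_a: set, set_b: set, universe: set):
    """Chi-square test of overlap between two transcript sets.

    Builds the 2x2 membership table over the universe and delegates to
    the contingency machinery (Yates-corrected chi-square with adjusted
    standardized residuals).  Reports observed and expected overlap.
    """
    from .enrich import chi_square_2x2

    if not universe:
        raise ValueError("empty universe")
    set_a, set_b = set_a & universe, set_b & universe
    n = len(universe)
    both = len(set_a & set_b)
    table = np.array(
        [
            [both, len(set_a) - both],
            [len(set_b) - both, n - len(set_a) - len(set_b) + both],
        ]
    )
    result = chi_square_2x2(table)
    result.observed_overlap = both
    result.expected_overlap = len(set_a) * len(set_b) / n
    return result
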