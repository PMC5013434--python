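"""Gene-set representation tests, tau tissue specificity and rank tests.

Covers the trade-off analysis: chi-square (Yates-corrected) 2x2
representation of gene sets among +CE / -CE transcripts with adjusted
standardized residuals, Fisher exact overlap tests, the tau
tissue-specificity index, testis-bias classification by fold change, and
the Wilcoxon-Mann-Whitney comparison of tau between CE directions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class GeneSet:
    name: str
    members: set
    provenance: str = ""

    def __post_init__(self) -> None:
        self.members = set(self.members)


@dataclass
class EnrichmentResult:
    """2x2 contingency outcome with margin-adjusted residuals.

    ``residuals`` are (O - E) / sqrt(E (1 - row/N) (1 - col/N)), whose
    null distribution is standard normal; the focal (top-left) cell's
    sign gives the over/under direction.
    """

    observed: np.ndarray
    expected: np.ndarray
    chi2: float
    p: float
    chi2_uncorrected: float
    p_uncorrected: float
    residuals: np.ndarray
    direction: str = ""
    observed_overlap: float = field(default=np.nan)
    expected_overlap: float = field(default=np.nan)


def chi_square_2x2(table: np.ndarray, yates: bool = True) -> EnrichmentResult:
    """Chi-square test for a 2x2 table with adjusted standardized residuals.

    Both the Yates-corrected and uncorrected statistics are computed; the
    reported (chi2, p) follow the ``yates`` flag.
    """
    obs = np.asarray(table, float)
    if obs.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {obs.shape}")
    n = obs.sum()
    if n == 0:
        raise ValueError("empty table")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    expected = np.outer(row, col) / n
    if (expected == 0).any():
        raise ValueError("expected cell of 0; use the Fisher exact test instead")

    chi2_y, p_y, _, _ = stats.chi2_contingency(obs, correction=True)
    chi2_u, p_u, _, _ = stats.chi2_contingency(obs, correction=False)
    adj = (obs - expected) / np.sqrt(
        expected * (1 - row[:, None] / n) * (1 - col[None, :] / n)
    )
    chi2, p = (chi2_y, p_y) if yates else (chi2_u, p_u)
    direction = "over" if obs[0, 0] > expected[0, 0] else (
        "under" if obs[0, 0] < expected[0, 0] else "none"
    )
    return EnrichmentResult(
        observed=obs.astype(int) if np.allclose(obs, np.round(obs)) else obs,
        expected=expected,
        chi2=float(chi2),
        p=float(p),
        chi2_uncorrected=float(chi2_u),
        p_uncorrected=float(p_u),
        residuals=adj,
        direction=direction,
    )


def set_representation(
    ce: pd.DataFrame,
    direction: str,
    gene_set: GeneSet,
    universe: set | None = None,
    yates: bool = True,
) -> EnrichmentResult:
    """Representation of a gene set among +CE or -CE transcripts.

    Builds the (in direction class vs not) x (in set vs not) table over
    the universe (default: all testable transcripts in ``ce``) and runs
    the 2x2 chi-square.  The focal cell is (direction class, in set), so
    ``direction == 'over'`` means over-representation.
    """
    if direction not in {"+CE", "-CE"}:
        raise ValueError(f"direction must be '+CE' or '-CE', got {direction!r}")
    tested = ce[ce["direction"] != "untestable"]
    ids = set(tested["transcript_id"])
    universe = ids if universe is None else (universe & ids)
    members = gene_set.members & universe
    if not members:
        raise ValueError(f"gene set {gene_set.name!r} shares no transcripts with the universe")
    in_dir = set(tested.loc[tested["direction"] == direction, "transcript_id"]) & universe

    a = len(in_dir & members)
    table = np.array(
        [
            [a, len(in_dir) - a],
            [len(members) - a, len(universe) - len(in_dir) - len(members) + a],
        ]
    )
    return chi_square_2x2(table, yates=yates)


def fisher_overlap(set_a: set, set_b: set, universe: set) -> tuple[float, float]:
    """Two-sided Fisher exact test of overlap; returns (odds ratio, p).

    The sample odds ratio of the 2x2 membership table is reported
    (``inf`` when a margin cell is empty).
    """
    if not universe:
        raise ValueError("empty universe")
    a_set, b_set = set_a & universe, set_b & universe
    both = len(a_set & b_set)
    table = np.array(
        [
            [both, len(a_set) - both],
            [len(b_set) - both, len(universe) - len(a_set) - len(b_set) + both],
        ]
    )
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p)


def tau(profile: np.ndarray) -> float:
    """Tissue-specificity index tau in [0, 1].

    tau = sum_i (1 - x_i / max x) / (N - 1) over N tissues: 0 for a
    uniform profile, 1 for single-tissue expression.  Values above ~0.9
    are typical of tissue-specific genes.  All-zero profiles are
    undefined (NaN).
    """
    x = np.asarray(profile, float)
    if x.size < 2:
        raise ValueError("tau needs at least 2 tissues")
    if (x < 0).any() or not np.isfinite(x).all():
        raise ValueError("tissue expression must be finite and non-negative")
    mx = x.max()
    if mx == 0:
        return float("nan")
    return float(np.sum(1.0 - x / mx) / (x.size - 1))


def tau_table(profiles: pd.DataFrame) -> pd.Series:
    """tau for every transcript (row) of a tissue-profile table."""
    return pd.Series(
        [tau(row) for row in profiles.to_numpy(float)],
        index=profiles.index,
        name="tau",
    )


def classify_testis_biased(
    profile: pd.Series, fold_cutoff: float = 50.0, testis: str = "testis"
) -> bool:
    """Testis bias: testis expression >= fold_cutoff x the next tissue.

    The default 50-fold cutoff matches whole-fly atlas practice; 256
    (2^8, i.e. 8 on the log2 scale) is the stricter cutoff used for
    dedicated testis-expression datasets.
    """
    if testis not in profile.index:
        raise ValueError(f"profile has no {testis!r} tissue")
    t = float(profile[testis])
    rest = profile.drop(testis).to_numpy(float)
    mx = rest.max()
    if t <= 0:
        return False
    if mx == 0:
        return True
    return t / mx >= fold_cutoff


def compare_tau(tau_pos: np.ndarray, tau_neg: np.ndarray) -> tuple[float, float]:
    """Wilcoxon-Mann-Whitney comparison of tau between CE directions.

    Returns (W, p) where W is the rank-sum statistic of the first group
    (as in R's ``wilcox.test``); exact p for small tie-free samples,
    normal approximation with tie correction otherwise.
    """
    a = np.asarray(tau_pos, float)
    b = np.asarray(tau_neg, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)
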