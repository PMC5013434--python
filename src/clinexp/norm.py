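"""Expression filtering and TMM (trimmed mean of M-values) normalization.

The filter retains transcripts with at least ``cpm_min`` counts per
million in at least ``min_samples`` samples.  TMM computes per-sample
scaling factors from doubly trimmed log2 expression ratios against a
reference sample, with precision (delta-method) weights, and rescales
the factors to geometric mean one.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import CountMatrix, NormalizedMatrix


def cpm(cm: CountMatrix, factors: pd.Series | None = None) -> pd.DataFrame:
    """Counts per million: ``count * 1e6 / library_size``.

    With ``factors``, library sizes are multiplied by the TMM factors
    first (effective library sizes).
    """
    lib = cm.library_sizes.astype(float)
    if (lib == 0).any():
        zero = lib.index[lib == 0].tolist()
        raise ValueError(f"zero library size for samples {zero}")
    if factors is not None:
        lib = lib * factors.reindex(lib.index)
    return cm.counts * 1e6 / lib


def filter_low_expression(
    cm: CountMatrix, cpm_min: float = 2.0, min_samples: int = 3
) -> CountMatrix:
    """Keep transcripts with CPM >= cpm_min in at least min_samples samples.

    ``min_samples`` defaults to one population's cage-replicate count.
    Row order is preserved; values are untouched.
    """
    if min_samples < 1:
        raise ValueError(f"min_samples must be >= 1, got {min_samples}")
    keep = (cpm(cm) >= cpm_min).sum(axis=1) >= min_samples
    return CountMatrix(cm.counts.loc[keep])


def _tmm_pair(
    obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
    trim_m: float, trim_a: float,
) -> float:
    """log2 TMM factor of one sample against the reference."""
    both = (obs > 0) & (ref > 0)
    if not both.any():
        raise ValueError("sample shares no nonzero transcripts with the reference")
    y_o, y_r = obs[both].astype(float), ref[both].astype(float)
    m = np.log2((y_o / n_obs) / (y_r / n_ref))
    a = 0.5 * np.log2((y_o / n_obs) * (y_r / n_ref))
    finite = np.isfinite(m) & np.isfinite(a)
    m, a, y_o, y_r = m[finite], a[finite], y_o[finite], y_r[finite]
    if m.size == 0 or np.max(np.abs(m)) < 1e-6:
        return 0.0

    # double trim by rank, matching the canonical recipe
    n = m.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rm, ra = rankdata(m), rankdata(a)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any():
        return 0.0

    # delta-method precision weights on binomial counting noise
    w = (n_obs - y_o) / (n_obs * y_o) + (n_ref - y_r) / (n_ref * y_r)
    f = np.nansum(m[keep] / w[keep]) / np.nansum(1.0 / w[keep])
    return 0.0 if not np.isfinite(f) else f


def tmm_factors(
    cm: CountMatrix, trim_m: float = 0.3, trim_a: float = 0.05,
    reference: str | None = None,
) -> pd.Series:
    """Per-sample TMM normalization factors, geometric mean one.

    The reference sample is the one whose upper-quartile CPM is closest
    to the mean upper-quartile, unless given explicitly.
    """
    counts = cm.counts.to_numpy(float)
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    if (counts.sum(axis=0) == 0).any():
        raise ValueError("every sample needs some nonzero counts")
    lib = counts.sum(axis=0)
    samples = cm.sample_ids

    if reference is None:
        uq = np.quantile(counts / lib, 0.75, axis=0)
        ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        ref_idx = samples.index(reference)

    log_f = np.zeros(len(samples))
    for j in range(len(samples)):
        if j == ref_idx:
            continue
        try:
            log_f[j] = _tmm_pair(
                counts[:, j], counts[:, ref_idx], lib[j], lib[ref_idx], trim_m, trim_a
            )
        except ValueError as exc:
            raise ValueError(f"sample {samples[j]!r}: {exc}") from None
    factors = 2.0 ** log_f
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=samples, name="tmm_factor")


def normalize(cm: CountMatrix, trim_m: float = 0.3, trim_a: float = 0.05) -> NormalizedMatrix:
    """TMM-adjusted CPM for a filtered count matrix."""
    factors = tmm_factors(cm, trim_m=trim_m, trim_a=trim_a)
    return NormalizedMatrix(values=cpm(cm, factors=factors), factors=factors)
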