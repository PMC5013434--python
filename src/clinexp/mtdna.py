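"""mtDNA haplotype-frequency confound check.

Expression clines could in principle be driven by a latitudinal cline in
mitochondrial haplotype frequency rather than by nuclear local
adaptation.  The check estimates the focal-allele frequency per sample
at one biallelic mtDNA site (a HaeIII restriction-site polymorphism in
the motivating system), discards low-coverage samples, and tests the
retained frequencies for a latitude correlation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .screen import UntestableError, correlate_transcript

NO_CLINE_VERDICT = "no frequency cline detected"
CLINE_VERDICT = "frequency cline detected"
CONSTANT_VERDICT = "frequencies constant across samples; consistent with no cline"


def haplotype_frequency(counts: pd.DataFrame, min_depth: int = 10) -> pd.DataFrame:
    """Per-sample focal-allele frequency with a coverage-depth filter.

    frequency = count_A / (count_A + count_other); samples with depth
    below ``min_depth`` are flagged ``retained = False`` and excluded
    from downstream testing (the frequency is still reported where the
    depth is nonzero).
    """
    if (counts[["count_A", "count_other"]].to_numpy() < 0).any():
        raise ValueError("negative allele counts")
    out = counts.copy()
    out["depth"] = out["count_A"] + out["count_other"]
    with np.errstate(invalid="ignore", divide="ignore"):
        out["frequency"] = np.where(
            out["depth"] > 0, out["count_A"] / out["depth"], np.nan
        )
    out["retained"] = out["depth"] >= min_depth
    return out


def frequency_cline_check(
    freqs: np.ndarray, latitudes: np.ndarray, p_threshold: float = 0.05
) -> dict:
    """Pearson correlation of retained haplotype frequencies with latitude.

    Returns a dict with r, p and a verdict string.  Constant frequencies
    are untestable and reported as consistent with 'similar across
    locations', which is the outcome that rules out the confound.
    """
    f = np.asarray(freqs, float)
    lat = np.asarray(latitudes, float)
    ok = np.isfinite(f)
    f, lat = f[ok], lat[ok]
    if f.size < 3 or np.unique(lat).size < 3:
        raise ValueError("need >= 3 retained samples across >= 3 latitudes")
    try:
        r, p = correlate_transcript(f, lat, method="pearson")
    except UntestableError:
        return {"r": np.nan, "p": np.nan, "verdict": CONSTANT_VERDICT, "n": int(f.size)}
    verdict = NO_CLINE_VERDICT if p > p_threshold else CLINE_VERDICT
    return {"r": r, "p": p, "verdict": verdict, "n": int(f.size)}
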