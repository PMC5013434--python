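"""Synthetic data with the statistical structure the pipeline assumes.

The generator emulates a six-population latitudinal transect (roughly
Valencia to Uppsala, ~20 degrees of latitude) with three replicate cages
per population and, optionally, four sampling times.  Per-transcript
counts are negative binomial; the mean follows the transcript's true
cline shape (null / linear / sigmoid / step) expressed as a multiplicative
ratio relative to the southernmost site, so the same parameterization is
shared with :mod:`clinexp.shapes`.  A truth table records every planted
shape, effect size and gene-set membership for recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

SHAPES = ("null", "linear", "sigmoid", "step")

#: Approximate Valencia -> Uppsala transect; configurable, not asserted.
DEFAULT_LATITUDES = (39.5, 43.8, 47.5, 51.2, 55.5, 59.8)

DEFAULT_TISSUES = (
    "brain",
    "midgut",
    "fat_body",
    "malpighian_tubule",
    "salivary_gland",
    "muscle",
    "accessory_gland",
    "testis",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    Attributes
    ----------
    n_populations, latitudes, n_cages, n_timepoints
        The sampling design: one pooled RNA sample per
        (population, cage, timepoint).  One timepoint is the
        common-garden design (18 samples); four timepoints the in-situ
        design (72 samples).
    n_transcripts
        Number of simulated transcripts.
    shape_mixture
        Proportions of true cline shapes over ``(null, linear, sigmoid,
        step)``; must sum to one.
    effect_size_range
        Interval for the effect magnitude ``|d|`` -- the relative change
        in mean expression between the cline extremes (ratio scale,
        1 at the southernmost site).
    baseline_logmean, baseline_logsd
        Log-normal distribution of per-transcript baseline abundance, on
        the counts-per-million scale.
    nb_dispersion
        Mean negative-binomial dispersion (variance = mu + phi * mu^2).
        If ``nb_dispersion_shape`` is not None, per-transcript dispersions
        are gamma distributed with that shape and the given mean;
        otherwise the dispersion is the same scalar for every transcript.
    libsize_logmean, libsize_logsd
        Log-normal per-sample library-size distribution (reads).
    cage_sd
        Standard deviation of an optional cage-level log-normal random
        effect; zero by default (no within-population cage structure).
    metabolic_base_rate, testis_base_rate
        Baseline gene-set membership probabilities.
    set_enrichment_odds
        Odds multipliers tying membership to cline direction: metabolic
        membership is enriched among positive clines, testis bias among
        negative clines.
    """

    n_populations: int = 6
    latitudes: tuple[float, ...] = DEFAULT_LATITUDES
    n_cages: int = 3
    n_timepoints: int = 1
    n_transcripts: int = 2000
    shape_mixture: tuple[float, float, float, float] = (0.85, 0.09, 0.03, 0.03)
    effect_size_range: tuple[float, float] = (0.3, 1.0)
    baseline_logmean: float = float(np.log(30.0))
    baseline_logsd: float = 1.2
    nb_dispersion: float = 0.05
    nb_dispersion_shape: float | None = 2.0
    libsize_logmean: float = float(np.log(2.0e6))
    libsize_logsd: float = 0.15
    cage_sd: float = 0.0
    metabolic_base_rate: float = 0.15
    testis_base_rate: float = 0.10
    set_enrichment_odds: dict[str, float] = field(
        default_factory=lambda: {"metabolic": 3.0, "testis": 3.0}
    )
    sigmoid_steepness_range: tuple[float, float] = (0.5, 2.0)
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_populations < 1:
            raise ValueError(f"n_populations must be >= 1, got {self.n_populations}")
        if len(self.latitudes) != self.n_populations:
            raise ValueError(
                f"latitudes has {len(self.latitudes)} entries for "
                f"{self.n_populations} populations"
            )
        lats = np.asarray(self.latitudes, dtype=float)
        if self.n_populations > 1 and not np.all(np.diff(lats) > 0):
            raise ValueError("latitudes must be strictly increasing")
        for name in ("n_cages", "n_timepoints", "n_transcripts"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        mix = np.asarray(self.shape_mixture, dtype=float)
        if mix.shape != (4,) or np.any(mix < 0):
            raise ValueError("shape_mixture needs 4 non-negative proportions")
        if abs(mix.sum() - 1.0) > 1e-12:
            raise ValueError(f"shape_mixture must sum to 1, got {mix.sum()!r}")
        lo, hi = self.effect_size_range
        if not (0 < lo <= hi):
            raise ValueError(f"effect_size_range must be positive, got {self.effect_size_range}")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if "testis" not in self.tissues:
            raise ValueError("tissues must include 'testis'")

    def with_(self, **kwargs) -> "SimulationConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


def _rng(config: SimulationConfig, salt: int = 0) -> np.random.Generator:
    return np.random.default_rng((config.seed, salt))


def simulate_design(config: SimulationConfig) -> pd.DataFrame:
    """Sample metadata: one row per (population, cage, timepoint).

    Returns a table with columns ``sample_id, population, latitude,
    cage, dataset, timepoint``.  The dataset label is ``common_garden``
    for a single timepoint and ``in_situ`` otherwise.
    """
    dataset = "common_garden" if config.n_timepoints == 1 else "in_situ"
    rows = []
    for p in range(config.n_populations):
        for cage in range(1, config.n_cages + 1):
            for t in range(1, config.n_timepoints + 1):
                sid = f"P{p + 1}C{cage}"
                if config.n_timepoints > 1:
                    sid += f"T{t}"
                rows.append(
                    {
                        "sample_id": sid,
                        "population": f"P{p + 1}",
                        "latitude": config.latitudes[p],
                        "cage": cage,
                        "dataset": dataset,
                        "timepoint": t,
                    }
                )
    return pd.DataFrame(rows)


def _unit_response(
    shape: str, l: np.ndarray, l_max: float, k: float | None, c: float | None, l_c: float | None
) -> np.ndarray:
    """Shape response on a 0..1 scale: 0 at the southern end, 1 at the northern."""
    if shape == "null":
        return np.zeros_like(l)
    if shape == "linear":
        return l / l_max
    if shape == "sigmoid":
        t = np.tanh(k * (l - c))
        t0, t1 = np.tanh(k * (0.0 - c)), np.tanh(k * (l_max - c))
        return (t - t0) / (t1 - t0)
    if shape == "step":
        return (l >= l_c).astype(float)
    raise ValueError(f"unknown shape {shape!r}")


def _draw_truth(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_transcripts
    shapes = rng.choice(SHAPES, size=n, p=np.asarray(config.shape_mixture, float))
    direction = np.where(rng.random(n) < 0.5, 1, -1)
    direction[shapes == "null"] = 0
    lo, hi = config.effect_size_range
    d = rng.uniform(lo, hi, size=n) * direction
    d[shapes == "null"] = 0.0

    lats = np.asarray(config.latitudes, float)
    l_max = float(lats[-1] - lats[0])
    rel = lats - lats[0]
    mids = (rel[:-1] + rel[1:]) / 2 if len(rel) > 1 else np.array([0.0])

    k_lo, k_hi = config.sigmoid_steepness_range
    steep = np.exp(rng.uniform(np.log(k_lo), np.log(k_hi), size=n))
    centre = rng.uniform(0.3 * l_max, 0.7 * l_max, size=n)
    l_c = rng.choice(mids, size=n)

    truth = pd.DataFrame(
        {
            "transcript_id": [f"TR{i + 1:06d}" for i in range(n)],
            "true_shape": shapes,
            "direction": np.where(direction > 0, "+", np.where(direction < 0, "-", "0")),
            "d": d,
            "b": np.where(shapes == "linear", d / l_max, np.nan),
            "s": np.where(shapes == "sigmoid", d * steep / 2.0, np.nan),
            "k": np.where(shapes == "sigmoid", steep, np.nan),
            "c": np.where(shapes == "sigmoid", centre, np.nan),
            "l_c": np.where(shapes == "step", l_c, np.nan),
        }
    )
    truth.loc[truth.true_shape == "null", "d"] = np.nan
    return truth


def _response_matrix(truth: pd.DataFrame, l: np.ndarray, l_max: float) -> np.ndarray:
    """Ratio-scale response (rows: transcripts, cols: samples), 1 at l = 0."""
    resp = np.ones((len(truth), len(l)))
    for i, row in enumerate(truth.itertuples(index=False)):
        if row.true_shape == "null":
            continue
        h = _unit_response(row.true_shape, l, l_max, row.k, row.c, row.l_c)
        resp[i] = 1.0 + row.d * h
    return np.maximum(resp, 0.0)


def simulate_counts(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a transcript x sample count matrix plus its truth table.

    The mean count of transcript ``i`` in sample ``k`` is
    ``libsize_k / 1e6 * baseline_i * response_i(latitude_k)`` and counts
    are negative binomial with the configured dispersion.  Identical
    seeds give bit-identical output.
    """
    rng = _rng(config, salt=1)
    meta = simulate_design(config)
    truth = _draw_truth(config, rng)
    n, m = config.n_transcripts, len(meta)

    lats = np.asarray(config.latitudes, float)
    l = meta["latitude"].to_numpy() - lats[0]
    l_max = float(lats[-1] - lats[0])

    baseline = rng.lognormal(config.baseline_logmean, config.baseline_logsd, size=n)
    libsize = rng.lognormal(config.libsize_logmean, config.libsize_logsd, size=m)
    mean = (libsize / 1e6)[None, :] * baseline[:, None] * _response_matrix(truth, l, l_max)

    if config.cage_sd > 0:
        cage_key = meta["population"].astype(str) + "/" + meta["cage"].astype(str)
        codes = pd.Categorical(cage_key).codes
        effects = rng.normal(0.0, config.cage_sd, size=(n, codes.max() + 1))
        mean = mean * np.exp(effects[:, codes])

    if config.nb_dispersion_shape is not None and config.nb_dispersion > 0:
        shape_par = config.nb_dispersion_shape
        phi = rng.gamma(shape_par, config.nb_dispersion / shape_par, size=n)[:, None]
    else:
        phi = np.full((n, 1), config.nb_dispersion)

    if np.all(phi <= 1e-12):
        counts = rng.poisson(mean)
    else:
        phi = np.maximum(phi, 1e-12)
        size = 1.0 / phi
        p = size / (size + mean)
        counts = rng.negative_binomial(np.broadcast_to(size, mean.shape), p)

    counts_df = pd.DataFrame(
        counts.astype(np.int64),
        index=pd.Index(truth["transcript_id"], name="transcript_id"),
        columns=meta["sample_id"].tolist(),
    )
    return counts_df, truth


def simulate_rescaled_profiles(
    config: SimulationConfig, noise_sd: float = 0.02
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Per-sample expression directly on the 0..1 response scale.

    A convenience generator for shape-recovery experiments: the value of
    transcript ``i`` in sample ``k`` is its unit shape response at the
    sample latitude plus Gaussian noise of standard deviation
    ``noise_sd``, skipping the count layer.  Returns (values, meta, truth).
    """
    rng = _rng(config, salt=2)
    meta = simulate_design(config)
    truth = _draw_truth(config, rng)
    lats = np.asarray(config.latitudes, float)
    l = meta["latitude"].to_numpy() - lats[0]
    l_max = float(lats[-1] - lats[0])

    mu = np.zeros((len(truth), len(meta)))
    for i, row in enumerate(truth.itertuples(index=False)):
        if row.true_shape == "null":
            mu[i] = 0.5
        else:
            h = _unit_response(row.true_shape, l, l_max, row.k, row.c, row.l_c)
            mu[i] = (0.0 if row.d >= 0 else -row.d) + row.d * h
    values = mu + rng.normal(0.0, noise_sd, size=mu.shape)
    values_df = pd.DataFrame(
        values,
        index=pd.Index(truth["transcript_id"], name="transcript_id"),
        columns=meta["sample_id"].tolist(),
    )
    return values_df, meta, truth


def simulate_annotations(
    truth: pd.DataFrame, config: SimulationConfig
) -> tuple[list, pd.DataFrame]:
    """Gene sets and tissue profiles tied to the planted cline directions.

    Metabolic membership is sampled with ``set_enrichment_odds['metabolic']``
    times the baseline odds among positive clinal transcripts; testis bias
    with elevated odds among negative clinal transcripts.  Testis-biased
    transcripts get a profile concentrated in the testis (fold change far
    above the 50x classification cutoff, tau near 1); everything else a
    near-uniform profile.

    Returns ``(gene_sets, tissue_profiles)`` and adds ``is_metabolic`` /
    ``is_testis_biased`` columns to a copy of the truth table accessible
    via ``gene_sets`` membership.
    """
    from .enrich import GeneSet

    rng = _rng(config, salt=3)
    n = len(truth)
    clinal = (truth["true_shape"] != "null").to_numpy()
    pos = clinal & (truth["direction"] == "+").to_numpy()
    neg = clinal & (truth["direction"] == "-").to_numpy()

    def member_flags(base_rate: float, odds_mult: float, boosted: np.ndarray) -> np.ndarray:
        base_odds = base_rate / (1.0 - base_rate)
        odds = np.where(boosted, base_odds * odds_mult, base_odds)
        return rng.random(n) < odds / (1.0 + odds)

    is_metabolic = member_flags(
        config.metabolic_base_rate, config.set_enrichment_odds.get("metabolic", 1.0), pos
    )
    is_testis = member_flags(
        config.testis_base_rate, config.set_enrichment_odds.get("testis", 1.0), neg
    )
    # neutral control set, independent of direction by construction
    is_circadian = rng.random(n) < 0.05

    ids = truth["transcript_id"].to_numpy()
    truth["is_metabolic"] = is_metabolic
    truth["is_testis_biased"] = is_testis

    tissues = list(config.tissues)
    t_idx = tissues.index("testis")
    profiles = rng.uniform(50.0, 150.0, size=(n, len(tissues)))
    biased = np.where(is_testis)[0]
    profiles[biased] = rng.uniform(1.0, 8.0, size=(len(biased), len(tissues)))
    profiles[biased, t_idx] = rng.uniform(800.0, 1500.0, size=len(biased))

    gene_sets = [
        GeneSet("metabolic", set(ids[is_metabolic]), provenance="metabolic"),
        GeneSet("testis_biased", set(ids[is_testis]), provenance="testis-biased"),
        GeneSet("circadian", set(ids[is_circadian]), provenance="circadian"),
    ]
    profile_df = pd.DataFrame(
        profiles, index=pd.Index(ids, name="transcript_id"), columns=tissues
    )
    return gene_sets, profile_df


def simulate_mtdna(
    config: SimulationConfig,
    haplotype_freqs: dict[str, float] | float | None = None,
    mean_depth: float = 60.0,
    n_low_depth: int = 0,
    site: str = "mtDNA_HaeIII",
) -> pd.DataFrame:
    """Binomial allele counts at one biallelic mtDNA site per sample.

    ``haplotype_freqs`` maps population to the true frequency of the focal
    ('A') allele; a scalar applies everywhere (default 0.8, equal across
    populations, i.e. no frequency cline).  ``n_low_depth`` forces that
    many samples to a depth below 10 to exercise the depth filter.
    """
    rng = _rng(config, salt=4)
    meta = simulate_design(config)
    if haplotype_freqs is None:
        haplotype_freqs = 0.8
    if np.isscalar(haplotype_freqs):
        freqs = {p: float(haplotype_freqs) for p in meta["population"].unique()}
    else:
        freqs = dict(haplotype_freqs)
    bad = [p for p, f in freqs.items() if not 0.0 <= f <= 1.0]
    if bad:
        raise ValueError(f"haplotype frequencies outside [0, 1] for populations {bad}")

    depth = rng.poisson(mean_depth, size=len(meta)).astype(int)
    depth = np.maximum(depth, 10)
    if n_low_depth > 0:
        low = rng.choice(len(meta), size=min(n_low_depth, len(meta)), replace=False)
        depth[low] = rng.integers(1, 10, size=len(low))

    f = meta["population"].map(freqs).to_numpy(float)
    count_a = rng.binomial(depth, f)
    return pd.DataFrame(
        {
            "sample_id": meta["sample_id"],
            "site": site,
            "count_A": count_a,
            "count_other": depth - count_a,
        }
    )
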