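"""Synthetic data with the statistical structure of a sequential-seeding
experiment (SSE) and of a biparental RIL mapping population.

The SSE generator emulates the study design the synchrony analysis
assumes: cohorts of plants sown at fixed intervals (so germination is
staggered by design), grown under two temperature regimes a few degrees
apart, flowering when their accumulated photothermal units reach a
threshold (so later cohorts, which meet a cooling season, need more
calendar days), and terminating flowering / senescing on a seasonal cue
shared by all cohorts in a regime.  That combination produces the
signature pattern: desynchronized bolting and flowering initiation
(variance across cohorts grows relative to the germination stagger) but
synchronized flowering termination and whole-plant senescence.

The RIL generator draws each line's genome as a two-state Markov chain
along every chromosome with Haldane recombination fractions between
adjacent markers, then builds replicate phenotypes as a grand mean plus
additive allelic effects, optional pairwise epistasis, and Gaussian
noise; line values are replicate means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .photothermal import EnvironmentSeries, PTUConfig, _daily_contributions
from .qtl import ALLELE_A, ALLELE_B, GeneticMap, RILGenotypes, haldane_r

__all__ = [
    "SimCohortConfig",
    "SimRILConfig",
    "DEFAULT_MAP_SPEC",
    "simulate_environment",
    "simulate_cohort_phenology",
    "simulate_genetic_map",
    "simulate_ril_genotypes",
    "simulate_ril_phenotypes",
    "additive_effect_for_share",
    "realized_qtl_positions",
]


@dataclass(frozen=True)
class SimCohortConfig:
    """Design of a simulated sequential-seeding experiment.

    Defaults mirror the emulated study: 5 cohorts sown at 7-day
    intervals, 8 replicates per cohort, two regimes ~3 degC apart.
    Flowering is threshold-driven (``ptu_flowering_threshold``, in
    degC*daylight-days); bolting happens a fixed PTU lead earlier;
    flowering termination and senescence follow a seasonal rule:
    a fixed day per regime, termination preceding senescence by
    ``ft_lead_days``.

    The environment profile is a cooling season: daylight mean
    temperature declines linearly from ``temp_start`` at ``temp_trend``
    degC/day down to a floor of ``temp_floor``; photoperiod follows a
    smooth annual sinusoid.  Event-day noise is independent Gaussian
    jitter per event (germination itself is exact by design).
    """

    n_cohorts: int = 5
    seeding_interval: int = 7
    replicates_per_cohort: int = 8
    regimes: tuple[tuple[str, float], ...] = (("colder", 0.0), ("warmer", 3.0))
    ptu_flowering_threshold: float = 300.0
    bolting_lead: float = 30.0
    senescence_rule: dict | None = None  # {"kind": "fixed", "day": {regime: day} | int}
    ft_lead_days: int = 14
    event_noise_sd: float = 1.0
    rng_seed: int = 0
    # environment profile
    temp_start: float = 18.0
    temp_trend: float = -0.12
    temp_floor: float = 4.0
    photoperiod_mean: float = 12.0
    photoperiod_amplitude: float = 2.0
    accession: str = "sim"

    def __post_init__(self) -> None:
        if self.n_cohorts < 2:
            raise ValueError("need at least 2 cohorts")
        if self.seeding_interval <= 0:
            raise ValueError("seeding_interval must be positive")
        if self.replicates_per_cohort < 1:
            raise ValueError("need at least 1 replicate per cohort")
        if self.event_noise_sd < 0:
            raise ValueError("event_noise_sd must be non-negative")

    def senescence_day(self, regime: str) -> int:
        rule = self.senescence_rule or {"kind": "fixed", "day": 150}
        if rule.get("kind") != "fixed":
            raise ValueError(f"unknown senescence rule {rule!r}")
        day = rule["day"]
        return int(day[regime]) if isinstance(day, dict) else int(day)


@dataclass(frozen=True)
class SimRILConfig:
    """Design of a simulated RIL population.

    Paper-scale defaults: 105 lines, 8 replicates each, a 5-chromosome
    map with 144 markers.  ``qtl_effects`` lists (chromosome, pos_cm,
    additive effect a): a line carrying allele B at the locus shifts by
    +a, allele A by -a, so a lone QTL contributes variance a^2.
    ``epistatic_pairs`` lists (qtl_index_a, qtl_index_b, interaction
    effect) on the same +/-1 coding.
    """

    n_lines: int = 105
    replicates_per_line: int = 8
    map_spec: tuple[tuple[str, float, int], ...] | None = None
    qtl_effects: tuple[tuple[object, float, float], ...] = ()
    epistatic_pairs: tuple[tuple[int, int, float], ...] = ()
    grand_mean: float = 60.0
    residual_sd: float = 4.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lines < 2:
            raise ValueError("need at least 2 lines")
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be positive")


#: Paper-scale map: 5 chromosomes, 144 markers, lengths on the order of the
#: Arabidopsis genetic map.
DEFAULT_MAP_SPEC: tuple[tuple[str, float, int], ...] = (
    ("1", 120.0, 30),
    ("2", 75.0, 27),
    ("3", 95.0, 29),
    ("4", 80.0, 28),
    ("5", 120.0, 30),
)


# ---------------------------------------------------------------------------
# environment + cohort phenology


def simulate_environment(
    config: SimCohortConfig, start_day: int = 0, n_days: int = 220
) -> dict[str, EnvironmentSeries]:
    """One daily environment series per regime.

    The colder regime follows the configured profile; each other regime
    adds its offset to the daily daylight mean on every day, so the
    between-regime difference is the offset exactly.
    """
    if n_days < 1:
        raise ValueError(f"n_days must be at least 1, got {n_days}")
    days = np.arange(start_day, start_day + n_days, dtype=np.int64)
    t = days - start_day
    base_temp = np.maximum(config.temp_start + config.temp_trend * t, config.temp_floor)
    photo = config.photoperiod_mean + config.photoperiod_amplitude * np.sin(
        2.0 * np.pi * t / 365.0
    )
    photo = np.clip(photo, 0.0, 24.0)
    out = {}
    for label, offset in config.regimes:
        out[label] = EnvironmentSeries(
            day=days, temp=base_temp + offset, photoperiod=photo, label=label
        )
    return out


def _first_crossing(cum: np.ndarray, days: np.ndarray, threshold: float) -> float:
    """First day whose cumulative PTU (end of day) reaches the threshold."""
    idx = np.searchsorted(cum, threshold, side="left")
    if idx >= cum.size:
        return np.nan
    return float(days[idx] + 1)  # event at the start of the following day


def simulate_cohort_phenology(
    config: SimCohortConfig,
    env_by_regime: dict[str, EnvironmentSeries],
    ptu_config: PTUConfig = PTUConfig(),
) -> pd.DataFrame:
    """Phenology table for a full SSE: one row per plant.

    Germination is exactly the cohort's seeding offset.  A plant bolts on
    the first day its accumulated PTU (from germination, half-open days)
    reaches ``threshold - bolting_lead`` and initiates flowering at the
    full threshold; termination and senescence come from the seasonal
    rule.  Gaussian day-jitter (sd ``event_noise_sd``) is added to every
    event except germination and redrawn (up to 100 times, then ordered
    by cumulative max) until g <= bolting <= fi <= ft <= senescence.

    A plant whose threshold is never reached within the environment
    horizon keeps missing flowering/termination dates and is flagged.
    """
    rng = np.random.default_rng(config.rng_seed)
    rows = []
    plant = 0
    for regime, _offset in config.regimes:
        env = env_by_regime[regime]
        contrib = _daily_contributions(env, ptu_config)
        cum = np.cumsum(contrib)
        sen_day = config.senescence_day(regime)
        for cohort in range(1, config.n_cohorts + 1):
            g = (cohort - 1) * config.seeding_interval
            if g < env.start:
                raise ValueError(f"environment does not cover germination day {g}")
            i0 = g - env.start
            cum_from_g = cum[i0:] - (cum[i0 - 1] if i0 > 0 else 0.0)
            days_from_g = env.day[i0:]
            bolt0 = _first_crossing(
                cum_from_g, days_from_g, config.ptu_flowering_threshold - config.bolting_lead
            )
            fi0 = _first_crossing(cum_from_g, days_from_g, config.ptu_flowering_threshold)
            ft0 = float(sen_day - config.ft_lead_days)
            sen0 = float(sen_day)
            for rep in range(config.replicates_per_cohort):
                plant += 1
                flagged = np.isnan(fi0)
                events = _jitter_events(
                    rng, g, bolt0, fi0, ft0, sen0, config.event_noise_sd
                )
                bolting, fi, ft, sen = events
                rows.append(
                    {
                        "plant_id": f"p{plant:04d}",
                        "accession": config.accession,
                        "regime": regime,
                        "cohort": cohort,
                        "germination": int(g),
                        "bolting": bolting,
                        "flowering_init": fi,
                        "flowering_term": ft,
                        "senescence": sen,
                        "leaves_at_bolting": int(rng.poisson(12)),
                        "rosette_diameter_mm": float(np.round(rng.normal(45.0, 4.0), 1)),
                        "fruit_count": int(rng.poisson(120)),
                        "flagged": flagged,
                    }
                )
    return pd.DataFrame(rows)


def _jitter_events(
    rng: np.random.Generator,
    g: float,
    bolt: float,
    fi: float,
    ft: float,
    sen: float,
    sd: float,
) -> tuple:
    """Add per-event day jitter, resampling to preserve event ordering.

    Missing (NaN) events stay missing; present events are rounded to
    integer days.  After 100 failed redraws the jittered values are
    forced monotone with a cumulative max — with realistic noise levels
    this path is essentially never taken.
    """
    base = np.array([bolt, fi, ft, sen], dtype=float)
    present = ~np.isnan(base)
    if sd == 0:
        vals = base
    else:
        for _ in range(100):
            vals = base + rng.normal(0.0, sd, size=4)
            seq = np.concatenate([[g], vals[present]])
            if np.all(np.diff(np.round(seq)) >= 0):
                break
        else:
            vals = np.maximum.accumulate(np.where(present, vals, -np.inf))
            vals = np.where(present, np.maximum(vals, g), np.nan)
    out = np.round(vals)
    out = np.where(present, np.maximum(out, g), np.nan)
    return tuple(float(v) if not np.isnan(v) else np.nan for v in out)


# ---------------------------------------------------------------------------
# RIL population


def simulate_genetic_map(
    map_spec: Sequence[tuple[str, float, int]] | None = None,
    rng_seed: int = 0,
    min_spacing: float = 0.5,
) -> GeneticMap:
    """Random marker map: fixed chromosome lengths, jittered marker spacing.

    The first marker of each chromosome sits at 0 cM and the last at the
    chromosome length; interior markers are drawn uniformly and redrawn
    until all gaps exceed ``min_spacing``.  A marker count that cannot
    satisfy the spacing on the given length is rejected.
    """
    spec = tuple(map_spec) if map_spec is not None else DEFAULT_MAP_SPEC
    rng = np.random.default_rng(rng_seed)
    rows = []
    for chrom, length, n_markers in spec:
        if length <= 0:
            raise ValueError(f"chromosome {chrom!r} length must be positive")
        if n_markers < 2:
            raise ValueError(f"chromosome {chrom!r} needs at least 2 markers")
        if (n_markers - 1) * min_spacing > length:
            raise ValueError(
                f"{n_markers} markers cannot fit on {length} cM with "
                f"{min_spacing} cM minimum spacing"
            )
        if n_markers == 2:
            pos = np.array([0.0, length])
        else:
            for _ in range(1000):
                inner = np.sort(rng.uniform(0.0, length, size=n_markers - 2))
                pos = np.concatenate([[0.0], inner, [length]])
                if np.all(np.diff(pos) >= min_spacing):
                    break
            else:
                pos = np.linspace(0.0, length, n_markers)
        for k, p in enumerate(pos, start=1):
            rows.append(
                {"marker": f"m{chrom}_{k:02d}", "chromosome": chrom, "pos_cm": round(float(p), 2)}
            )
    return GeneticMap(pd.DataFrame(rows))


def simulate_ril_genotypes(gmap: GeneticMap, config: SimRILConfig) -> RILGenotypes:
    """RIL genotypes as a two-state Markov chain along each chromosome.

    The first marker's allele is a fair coin per line (symmetric cross);
    between adjacent markers the allele switches with the Haldane
    recombination fraction for their distance.  The published RIL map is
    taken as-is — no extra map expansion for the selfing generations.
    """
    rng = np.random.default_rng(config.rng_seed)
    n = config.n_lines
    blocks = []
    for chrom in gmap.chromosomes:
        pos = gmap.positions(chrom)
        r = haldane_r(np.diff(pos))
        geno = np.empty((n, pos.size), dtype=np.int8)
        geno[:, 0] = rng.integers(0, 2, size=n)
        for j in range(1, pos.size):
            flip = rng.random(n) < r[j - 1]
            geno[:, j] = np.where(flip, 1 - geno[:, j - 1], geno[:, j - 1])
        blocks.append(geno)
    matrix = np.concatenate(blocks, axis=1)
    line_ids = [f"RIL{k + 1:03d}" for k in range(n)]
    return RILGenotypes(line_ids=line_ids, matrix=matrix, map=gmap)


def _qtl_marker_columns(
    gmap: GeneticMap, qtl_effects: Sequence[tuple[object, float, float]]
) -> list[int]:
    """Snap each QTL to its nearest marker column (positions must be on-map)."""
    cols = []
    chrom_col = gmap.table["chromosome"].to_numpy()
    pos_col = gmap.table["pos_cm"].to_numpy(float)
    for chrom, pos, _effect in qtl_effects:
        idx = np.flatnonzero(chrom_col == chrom)
        if idx.size == 0:
            raise ValueError(f"QTL chromosome {chrom!r} not in map")
        if not (pos_col[idx].min() <= pos <= pos_col[idx].max()):
            raise ValueError(f"QTL position {pos} cM outside chromosome {chrom!r} map")
        cols.append(int(idx[np.argmin(np.abs(pos_col[idx] - pos))]))
    return cols


def realized_qtl_positions(
    gmap: GeneticMap, config: SimRILConfig
) -> list[tuple[object, float]]:
    """The (chromosome, cM) actually used for each configured QTL.

    QTL effects act at the marker nearest the configured position, so the
    realized position is that marker's map position.
    """
    cols = _qtl_marker_columns(gmap, config.qtl_effects)
    return [
        (gmap.table["chromosome"].iat[c], float(gmap.table["pos_cm"].iat[c])) for c in cols
    ]


def simulate_ril_phenotypes(
    genotypes: RILGenotypes, gmap: GeneticMap, config: SimRILConfig
) -> tuple[pd.Series, pd.DataFrame]:
    """Line-mean phenotypes and the underlying replicate table.

    Each replicate is grand mean + sum of additive allelic effects (on
    +/-1 allele coding at the marker nearest each configured QTL) + sum
    of epistatic products + N(0, residual_sd); the line phenotype is the
    mean of its replicates.
    """
    rng = np.random.default_rng(config.rng_seed + 1)
    cols = _qtl_marker_columns(gmap, config.qtl_effects)
    signs = np.where(genotypes.matrix[:, cols] == ALLELE_B, 1.0, -1.0) if cols else np.zeros(
        (genotypes.n_lines, 0)
    )
    effects = np.array([e for _, _, e in config.qtl_effects], dtype=float)
    genetic = np.full(genotypes.n_lines, config.grand_mean)
    if cols:
        genetic = genetic + signs @ effects
    for a, b, ee in config.epistatic_pairs:
        genetic = genetic + ee * signs[:, a] * signs[:, b]

    reps = config.replicates_per_line
    noise = rng.normal(0.0, config.residual_sd, size=(genotypes.n_lines, reps))
    values = genetic[:, None] + noise
    rep_table = pd.DataFrame(
        {
            "line_id": np.repeat(genotypes.line_ids, reps),
            "replicate": np.tile(np.arange(1, reps + 1), genotypes.n_lines),
            "value": values.ravel(),
        }
    )
    means = pd.Series(values.mean(axis=1), index=pd.Index(genotypes.line_ids, name="line_id"))
    means.name = "trait"
    return means, rep_table


def additive_effect_for_share(
    share: float, residual_sd: float, replicates: int
) -> float:
    """Additive effect size giving a lone QTL a target line-mean variance share.

    With +/-1 allele coding at frequency 1/2 the QTL contributes variance
    a^2, while replicate averaging leaves residual variance
    residual_sd^2 / replicates on line means, so
    a = sd_line * sqrt(share / (1 - share)).
    """
    if not 0 < share < 1:
        raise ValueError("share must be in (0, 1)")
    sd_line = residual_sd / np.sqrt(replicates)
    return float(sd_line * np.sqrt(share / (1.0 - share)))
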