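"""Single- and two-locus QTL genome scans for a two-allele RIL population.

The scan machinery is built from scratch for recombinant inbred lines of a
biparental cross, where every line is homozygous at every locus and the
genotype at a position is one of two parental alleles (A/B):

* genetic distances (cM) convert to recombination fractions with the
  Haldane map function, r = (1 - exp(-2d/100)) / 2 (no interference);
* conditional genotype probabilities at markers and pseudomarkers come
  from a two-state hidden Markov chain along each chromosome
  (forward-backward, optional genotyping-error emission);
* the genome scan is Haley-Knott regression: phenotype regressed on the
  expected allele dosage P(B) at each grid position, with
  LOD = (n/2) * log10(RSS_reduced / RSS_full);
* composite interval mapping adds forward-stepwise marker covariates,
  excluded within a window around the tested position;
* genome-wide significance comes from permutation of phenotype labels;
* the credible interval around a peak takes 10^LOD as the likelihood and
  a uniform positional prior on the chromosome;
* a two-dimensional scan decomposes pair LOD into additive and
  interaction (epistatic) components.

Map distances are consumed as given: a published RIL map already embeds
the map expansion of the selfing generations, so no further correction is
applied when converting cM to recombination fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ALLELE_A",
    "ALLELE_B",
    "MISSING",
    "GeneticMap",
    "RILGenotypes",
    "GenotypeProbabilities",
    "ScanResult",
    "QTLPeak",
    "TwoScanResult",
    "haldane_r",
    "genotype_probabilities",
    "hk_scan",
    "cim_scan",
    "permutation_thresholds",
    "bayes_interval",
    "fit_multi_qtl",
    "scan_two",
    "call_peaks",
]

ALLELE_A: int = 0
ALLELE_B: int = 1
MISSING: int = -1

_CODE_TO_CHAR = {ALLELE_A: "A", ALLELE_B: "B", MISSING: "-"}
_CHAR_TO_CODE = {"A": ALLELE_A, "B": ALLELE_B, "-": MISSING}


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class GeneticMap:
    """Marker map: one row per marker with chromosome and position in cM.

    ``table`` columns: marker, chromosome, pos_cm.  Positions are
    non-decreasing within each chromosome and marker names are unique
    genome-wide.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"marker", "chromosome", "pos_cm"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"map table needs columns {sorted(required)}")
        if self.table["marker"].duplicated().any():
            dupes = self.table.loc[self.table["marker"].duplicated(), "marker"].tolist()
            raise ValueError(f"duplicate marker names: {dupes}")
        for chrom, grp in self.table.groupby("chromosome", sort=False):
            pos = grp["pos_cm"].to_numpy(dtype=float)
            if np.any(np.diff(pos) < 0):
                raise ValueError(f"marker positions on chromosome {chrom!r} are not sorted")
            if pos[0] < 0:
                raise ValueError(f"negative position on chromosome {chrom!r}")

    @property
    def chromosomes(self) -> list:
        return list(dict.fromkeys(self.table["chromosome"]))

    @property
    def n_markers(self) -> int:
        return len(self.table)

    def positions(self, chromosome) -> np.ndarray:
        return self.table.loc[self.table["chromosome"] == chromosome, "pos_cm"].to_numpy(float)

    def markers(self, chromosome) -> list[str]:
        return self.table.loc[self.table["chromosome"] == chromosome, "marker"].tolist()


@dataclass(frozen=True)
class RILGenotypes:
    """Genotype matrix of a RIL population: lines x markers, codes A/B/missing.

    ``matrix`` is int8 with values ``ALLELE_A`` (0), ``ALLELE_B`` (1) or
    ``MISSING`` (-1); columns align with the map's marker order.
    """

    line_ids: list[str]
    matrix: np.ndarray
    map: GeneticMap

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.int8)
        if m.shape != (len(self.line_ids), self.map.n_markers):
            raise ValueError(
                f"genotype matrix shape {m.shape} does not match "
                f"{len(self.line_ids)} lines x {self.map.n_markers} markers"
            )
        if not np.isin(m, [ALLELE_A, ALLELE_B, MISSING]).all():
            raise ValueError("genotype codes must be A, B or missing")
        if np.any((m == MISSING).all(axis=1)):
            bad = [self.line_ids[i] for i in np.flatnonzero((m == MISSING).all(axis=1))]
            raise ValueError(f"line(s) with no typed markers: {bad}")
        object.__setattr__(self, "matrix", m)

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    def to_char(self) -> np.ndarray:
        out = np.empty(self.matrix.shape, dtype="U1")
        for code, ch in _CODE_TO_CHAR.items():
            out[self.matrix == code] = ch
        return out


@dataclass(frozen=True)
class GenotypeProbabilities:
    """P(allele B) for every line at every grid position (markers + pseudomarkers).

    ``grid`` columns: name, chromosome, pos_cm, is_marker.  ``p_b`` has
    shape (n_lines, n_grid); P(A) = 1 - P(B).  ``uninformative`` lists
    (line_id, chromosome) pairs where a line had no typed marker on a
    chromosome and the posterior is uniform 0.5 throughout it.
    """

    line_ids: list[str]
    grid: pd.DataFrame
    p_b: np.ndarray
    step: float
    error_rate: float
    map: GeneticMap
    uninformative: list[tuple[str, object]] = field(default_factory=list)

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    def chromosome_slice(self, chromosome) -> np.ndarray:
        return np.flatnonzero((self.grid["chromosome"] == chromosome).to_numpy())

    def dosage_at(self, chromosome, pos_cm: float) -> tuple[np.ndarray, int]:
        """Dosage column at the grid position nearest to (chromosome, pos_cm)."""
        idx = self.chromosome_slice(chromosome)
        if idx.size == 0:
            raise KeyError(f"chromosome {chromosome!r} not in grid")
        pos = self.grid["pos_cm"].to_numpy(float)[idx]
        j = idx[int(np.argmin(np.abs(pos - pos_cm)))]
        return self.p_b[:, j], int(j)


@dataclass
class ScanResult:
    """A single-locus LOD profile over the evaluation grid."""

    profile: pd.DataFrame  # columns: name, chromosome, pos_cm, lod
    method: str  # "hk" or "cim"
    covariates: list[str] = field(default_factory=list)
    thresholds: dict[float, float] = field(default_factory=dict)  # alpha -> LOD
    n_perm: int = 0
    seed: int | None = None

    def max_lod(self) -> float:
        return float(self.profile["lod"].max())


@dataclass(frozen=True)
class QTLPeak:
    chromosome: object
    pos_cm: float
    lod: float
    nearest_marker: str
    ci_lo: float
    ci_hi: float
    r_squared: float  # percent of phenotypic variance
    tier: str  # "significant" or "suggestive"

    def __post_init__(self) -> None:
        if not (self.ci_lo <= self.pos_cm <= self.ci_hi):
            raise ValueError("credible interval must bracket the peak")


@dataclass(frozen=True)
class TwoScanResult:
    """Two-locus scan: full, additive and interaction LOD per position pair."""

    pairs: pd.DataFrame  # chr1, pos1, chr2, pos2, lod_full, lod_add, lod_int
    step: float


# ---------------------------------------------------------------------------
# map function and genotype probabilities


def haldane_r(distance_cm) -> float | np.ndarray:
    """Haldane map function: r = (1 - exp(-2 d / 100)) / 2, d in cM.

    Assumes no crossover interference; r runs from 0 at d = 0 to 0.5 as
    d grows without bound.
    """
    d = np.asarray(distance_cm, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative")
    r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    return float(r) if r.ndim == 0 else r


def _chromosome_grid(positions: np.ndarray, names: list[str], chrom, step: float):
    """Markers plus evenly spaced pseudomarkers so that no gap exceeds ``step``."""
    grid_pos: list[float] = []
    grid_name: list[str] = []
    is_marker: list[bool] = []
    for k, (p, nm) in enumerate(zip(positions, names)):
        if k > 0:
            gap = p - positions[k - 1]
            if gap > step:
                n_insert = int(np.ceil(gap / step)) - 1
                inner = np.linspace(positions[k - 1], p, n_insert + 2)[1:-1]
                for q in inner:
                    grid_pos.append(float(q))
                    grid_name.append(f"c{chrom}.loc{q:g}")
                    is_marker.append(False)
        grid_pos.append(float(p))
        grid_name.append(nm)
        is_marker.append(True)
    return np.asarray(grid_pos), grid_name, is_marker


def genotype_probabilities(
    gmap: GeneticMap,
    genotypes: RILGenotypes,
    step: float = 2.0,
    error_rate: float = 0.0,
) -> GenotypeProbabilities:
    """Conditional genotype probabilities on a pseudomarker grid.

    For each line and chromosome a two-state forward-backward pass runs
    over the markers plus pseudomarkers spaced at most ``step`` cM apart.
    Transition probabilities come from :func:`haldane_r` on inter-position
    distances; the emission at a typed marker assigns probability
    ``1 - error_rate`` to the observed allele.  With ``error_rate = 0``
    the posterior collapses to the observation at typed markers.
    """
    if step <= 0:
        raise ValueError("pseudomarker step must be positive")
    if not 0.0 <= error_rate < 0.5:
        raise ValueError("error_rate must lie in [0, 0.5)")

    n_lines = genotypes.n_lines
    grid_frames = []
    pb_blocks = []
    uninformative: list[tuple[str, object]] = []

    chrom_col = gmap.table["chromosome"].to_numpy()
    for chrom in gmap.chromosomes:
        positions = gmap.positions(chrom)
        names = gmap.markers(chrom)
        marker_cols = np.flatnonzero(chrom_col == chrom)
        obs = genotypes.matrix[:, marker_cols]  # (n_lines, n_markers_chrom)

        gpos, gname, gmark = _chromosome_grid(positions, names, chrom, step)
        n_pos = gpos.size
        marker_at = np.flatnonzero(gmark)

        # emissions: (n_lines, n_pos, 2), ones except at typed markers
        emis = np.ones((n_lines, n_pos, 2))
        for mi, gi in enumerate(marker_at):
            o = obs[:, mi]
            typed_a = o == ALLELE_A
            typed_b = o == ALLELE_B
            emis[typed_a, gi, ALLELE_A] = 1.0 - error_rate
            emis[typed_a, gi, ALLELE_B] = error_rate
            emis[typed_b, gi, ALLELE_B] = 1.0 - error_rate
            emis[typed_b, gi, ALLELE_A] = error_rate

        r = haldane_r(np.diff(gpos)) if n_pos > 1 else np.empty(0)

        # scaled forward-backward, vectorized over lines
        alpha = np.empty((n_lines, n_pos, 2))
        alpha[:, 0, :] = 0.5 * emis[:, 0, :]
        alpha[:, 0, :] /= alpha[:, 0, :].sum(axis=1, keepdims=True)
        for j in range(1, n_pos):
            stay, move = 1.0 - r[j - 1], r[j - 1]
            prev = alpha[:, j - 1, :]
            pred = np.empty_like(prev)
            pred[:, 0] = prev[:, 0] * stay + prev[:, 1] * move
            pred[:, 1] = prev[:, 0] * move + prev[:, 1] * stay
            a = pred * emis[:, j, :]
            alpha[:, j, :] = a / a.sum(axis=1, keepdims=True)

        beta = np.empty((n_lines, n_pos, 2))
        beta[:, -1, :] = 1.0
        for j in range(n_pos - 2, -1, -1):
            stay, move = 1.0 - r[j], r[j]
            nxt = beta[:, j + 1, :] * emis[:, j + 1, :]
            b = np.empty_like(nxt)
            b[:, 0] = nxt[:, 0] * stay + nxt[:, 1] * move
            b[:, 1] = nxt[:, 0] * move + nxt[:, 1] * stay
            beta[:, j, :] = b / b.sum(axis=1, keepdims=True)

        post = alpha * beta
        post /= post.sum(axis=2, keepdims=True)
        pb_blocks.append(post[:, :, ALLELE_B])

        grid_frames.append(
            pd.DataFrame(
                {"name": gname, "chromosome": chrom, "pos_cm": gpos, "is_marker": gmark}
            )
        )

        no_data = (obs == MISSING).all(axis=1)
        for i in np.flatnonzero(no_data):
            uninformative.append((genotypes.line_ids[i], chrom))

    grid = pd.concat(grid_frames, ignore_index=True)
    p_b = np.concatenate(pb_blocks, axis=1)
    return GenotypeProbabilities(
        line_ids=list(genotypes.line_ids),
        grid=grid,
        p_b=p_b,
        step=step,
        error_rate=error_rate,
        map=gmap,
        uninformative=uninformative,
    )


# ---------------------------------------------------------------------------
# Haley-Knott regression scans


def _align_phenotype(
    probs: GenotypeProbabilities, phenotype: pd.Series
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Subset lines to those with both a phenotype and probabilities.

    Returns (dosage matrix, phenotype vector, row indices into probs).
    """
    ids = pd.Index(probs.line_ids)
    common = ids.intersection(phenotype.dropna().index)
    if len(common) < 10:
        raise ValueError(f"need at least 10 lines with phenotype and genotype, got {len(common)}")
    row = ids.get_indexer(common)
    y = phenotype.loc[common].to_numpy(dtype=float)
    return probs.p_b[row, :], y, row


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    return float(resid @ resid)


def _lod_profile_fast(Xd: np.ndarray, y: np.ndarray) -> np.ndarray:
    """LOD of y ~ 1 + x for every column of Xd, via the correlation identity.

    For simple regression with intercept RSS_full = TSS (1 - r^2), so
    LOD = -(n/2) log10(1 - r^2).  Monomorphic (zero-variance) columns get
    LOD 0.
    """
    n = y.size
    yc = y - y.mean()
    sy = np.sqrt((yc @ yc) / n)
    Xc = Xd - Xd.mean(axis=0)
    sx = np.sqrt((Xc**2).mean(axis=0))
    ok = (sx > 0) & (sy > 0)
    r = np.zeros(Xd.shape[1])
    if sy > 0:
        r[ok] = (Xc[:, ok].T @ yc) / (n * sx[ok] * sy)
    r2 = np.clip(r**2, 0.0, 1.0 - 1e-300)
    return -(n / 2.0) * np.log10(1.0 - r2)


def hk_scan(
    probs: GenotypeProbabilities,
    phenotype: pd.Series,
    covariates: np.ndarray | None = None,
    covariate_names: Sequence[str] = (),
    covariate_positions: Sequence[tuple[object, float]] | None = None,
    window: float | None = None,
    method: str = "hk",
) -> ScanResult:
    """Single-QTL Haley-Knott genome scan.

    At each grid position the phenotype is regressed on the expected
    allele dosage P(B) (plus any covariate columns);
    LOD = (n/2) log10(RSS_reduced / RSS_full) where the reduced model
    keeps the covariates but omits the position term.

    When ``covariate_positions`` and ``window`` are given, a covariate
    within ``window`` cM of the tested position on the same chromosome is
    dropped from both models at that position (the CIM exclusion rule).
    """
    Xd, y, _ = _align_phenotype(probs, phenotype)
    n = y.size
    grid = probs.grid

    if covariates is None or covariates.shape[1] == 0:
        lod = _lod_profile_fast(Xd, y)
    else:
        C = np.asarray(covariates, dtype=float)
        if C.shape[0] != n:
            raise ValueError("covariate rows must match phenotyped lines")
        chroms = grid["chromosome"].to_numpy()
        poss = grid["pos_cm"].to_numpy(float)
        ones = np.ones((n, 1))
        lod = np.empty(grid.shape[0])
        for j in range(grid.shape[0]):
            keep = np.ones(C.shape[1], dtype=bool)
            if window is not None and covariate_positions is not None:
                for k, (cchrom, cpos) in enumerate(covariate_positions):
                    if cchrom == chroms[j] and abs(cpos - poss[j]) <= window:
                        keep[k] = False
            Xred = np.hstack([ones, C[:, keep]])
            Xfull = np.hstack([Xred, Xd[:, j : j + 1]])
            rss0 = _rss(Xred, y)
            rss1 = _rss(Xfull, y)
            lod[j] = 0.0 if rss0 <= 0 else max(0.0, (n / 2.0) * np.log10(rss0 / max(rss1, 1e-300)))

    profile = grid[["name", "chromosome", "pos_cm"]].copy()
    profile["lod"] = lod
    return ScanResult(profile=profile, method=method, covariates=list(covariate_names))


def _forward_stepwise(
    Xm: np.ndarray, y: np.ndarray, n_covariates: int, entry_p: float = 0.05
) -> list[int]:
    """Forward selection of marker columns by RSS reduction with an F-test gate.

    Ties in RSS reduction break toward genome order (lowest column index).
    """
    from scipy import stats as sps

    n = y.size
    chosen: list[int] = []
    ones = np.ones((n, 1))
    for _ in range(n_covariates):
        Xcur = np.hstack([ones] + [Xm[:, [j]] for j in chosen])
        rss_cur = _rss(Xcur, y)
        best_j, best_rss = -1, np.inf
        for j in range(Xm.shape[1]):
            if j in chosen:
                continue
            rss_j = _rss(np.hstack([Xcur, Xm[:, [j]]]), y)
            if rss_j < best_rss - 1e-12:
                best_rss, best_j = rss_j, j
        if best_j < 0:
            break
        df_resid = n - (Xcur.shape[1] + 1)
        if df_resid <= 0 or best_rss <= 0:
            break
        f = (rss_cur - best_rss) / (best_rss / df_resid)
        p = sps.f.sf(f, 1, df_resid)
        if p > entry_p:
            break
        chosen.append(best_j)
    return chosen


def cim_scan(
    probs: GenotypeProbabilities,
    phenotype: pd.Series,
    window: float = 2.0,
    n_covariates: int = 3,
) -> ScanResult:
    """Composite interval mapping: HK scan with stepwise marker covariates.

    Covariate markers are chosen by forward stepwise regression of the
    phenotype on the typed-marker dosages (up to ``n_covariates``, entry
    gated by a partial F-test at 0.05); covariates within ``window`` cM of
    the tested position are excluded there.  With zero covariates this
    reduces exactly to :func:`hk_scan`.
    """
    Xd, y, _ = _align_phenotype(probs, phenotype)
    if n_covariates >= y.size:
        raise ValueError(f"n_covariates = {n_covariates} must be below the line count {y.size}")
    if n_covariates == 0:
        res = hk_scan(probs, phenotype)
        res.method = "cim"
        return res

    marker_idx = np.flatnonzero(probs.grid["is_marker"].to_numpy())
    Xm = Xd[:, marker_idx]
    chosen_local = _forward_stepwise(Xm, y, n_covariates)
    chosen = [int(marker_idx[j]) for j in chosen_local]
    names = [probs.grid["name"].iat[j] for j in chosen]
    positions = [
        (probs.grid["chromosome"].iat[j], float(probs.grid["pos_cm"].iat[j])) for j in chosen
    ]
    res = hk_scan(
        probs,
        phenotype,
        covariates=Xd[:, chosen] if chosen else None,
        covariate_names=names,
        covariate_positions=positions,
        window=window,
        method="cim",
    )
    return res


# ---------------------------------------------------------------------------
# permutations, intervals, multi-QTL models


def permutation_thresholds(
    probs: GenotypeProbabilities,
    phenotype: pd.Series,
    n_perm: int = 1000,
    alphas: Sequence[float] = (0.05, 0.63),
    seed: int | None = None,
) -> dict[float, float]:
    """Genome-wide LOD thresholds from phenotype permutations.

    Phenotype labels are shuffled against the (fixed) genotype structure;
    for each permutation the genome-wide maximum HK LOD is recorded and
    threshold(alpha) is the (1 - alpha) empirical quantile of the maxima.
    The RIL design has no family structure, so no stratification is used.
    """
    if n_perm < 100:
        raise ValueError("use at least 100 permutations")
    Xd, y, _ = _align_phenotype(probs, phenotype)
    n = y.size
    rng = np.random.default_rng(seed)

    # standardized dosage columns once; each permutation is a column of Y
    Xc = Xd - Xd.mean(axis=0)
    sx = np.sqrt((Xc**2).mean(axis=0))
    ok = sx > 0
    Z = np.zeros_like(Xc)
    Z[:, ok] = Xc[:, ok] / sx[ok]

    yc = y - y.mean()
    sy = np.sqrt((yc @ yc) / n)
    maxima = np.zeros(n_perm)
    if sy > 0:
        Y = np.empty((n, n_perm))
        for k in range(n_perm):
            Y[:, k] = rng.permutation(yc)
        Y /= sy
        R = (Z.T @ Y) / n  # (n_grid, n_perm)
        r2 = np.clip(R**2, 0.0, 1.0 - 1e-300)
        lod = -(n / 2.0) * np.log10(1.0 - r2)
        maxima = lod.max(axis=0)
    return {float(a): float(np.quantile(maxima, 1.0 - a)) for a in alphas}


def bayes_interval(
    scan: ScanResult, chromosome, prob: float = 0.95
) -> tuple[float, float, bool]:
    """Credible interval for a QTL location on one chromosome.

    The posterior is proportional to 10^LOD over the chromosome's grid
    (uniform prior: the QTL is a priori equally likely anywhere on the
    chromosome).  Starting from the peak (leftmost on ties), the interval
    grows one grid point at a time toward the side with the larger
    posterior until the enclosed mass reaches ``prob``.

    Returns (lo_cm, hi_cm, flat) where ``flat`` marks an uninformative
    all-zero LOD profile (interval = whole chromosome).
    """
    sel = scan.profile[scan.profile["chromosome"] == chromosome]
    if sel.empty:
        raise KeyError(f"scan does not cover chromosome {chromosome!r}")
    pos = sel["pos_cm"].to_numpy(float)
    lod = sel["lod"].to_numpy(float)
    w = np.power(10.0, lod - lod.max())
    w = w / w.sum()
    flat = bool(np.allclose(lod, 0.0))
    peak = int(np.argmax(lod))  # argmax takes the leftmost maximum
    lo = hi = peak
    mass = w[peak]
    while mass < prob and (lo > 0 or hi < w.size - 1):
        left = w[lo - 1] if lo > 0 else -1.0
        right = w[hi + 1] if hi < w.size - 1 else -1.0
        if left >= right:
            lo -= 1
            mass += w[lo]
        else:
            hi += 1
            mass += w[hi]
    return float(pos[lo]), float(pos[hi]), flat


def fit_multi_qtl(
    probs: GenotypeProbabilities,
    phenotype: pd.Series,
    peaks: Sequence[QTLPeak],
    interactions: Sequence[tuple[int, int]] = (),
) -> pd.DataFrame:
    """Joint multiple-QTL regression with drop-one variance decomposition.

    The full model regresses the phenotype on the dosage at every peak
    (plus dosage products for the requested interaction pairs, indexed
    into ``peaks``).  Each term's R^2 is the drop-one share
    100 (RSS_without - RSS_full) / TSS; the ``total`` row reports
    100 (1 - RSS_full / TSS).
    """
    Xd, y, row = _align_phenotype(probs, phenotype)
    n = y.size
    cols = []
    names = []
    for pk in peaks:
        _, j = probs.dosage_at(pk.chromosome, pk.pos_cm)
        cols.append(probs.p_b[row, j])
        names.append(f"{pk.chromosome}@{pk.pos_cm:g}")
    for a, b in interactions:
        cols.append(cols[a] * cols[b])
        names.append(f"{names[a]} x {names[b]}")

    X = np.column_stack(cols)
    corr = np.corrcoef(X, rowvar=False) if X.shape[1] > 1 else np.ones((1, 1))
    for a in range(X.shape[1]):
        for b in range(a + 1, X.shape[1]):
            if abs(corr[a, b]) > 0.99:
                raise ValueError(f"collinear model terms: {names[a]} and {names[b]}")

    ones = np.ones((n, 1))
    tss = float(np.sum((y - y.mean()) ** 2))
    rss_full = _rss(np.hstack([ones, X]), y)
    rows = []
    for k, nm in enumerate(names):
        keep = [c for c in range(X.shape[1]) if c != k]
        rss_wo = _rss(np.hstack([ones, X[:, keep]]) if keep else ones, y)
        rows.append({"term": nm, "r_squared": 100.0 * (rss_wo - rss_full) / tss})
    rows.append({"term": "total", "r_squared": 100.0 * (1.0 - rss_full / tss)})
    return pd.DataFrame(rows)


def scan_two(
    probs: GenotypeProbabilities,
    phenotype: pd.Series,
    step: float = 10.0,
    max_pairs: int = 250_000,
) -> TwoScanResult:
    """Two-dimensional genome scan decomposing pair LOD into additive + epistatic.

    For each position pair (coarsened to ~``step`` cM spacing; same-
    chromosome pairs closer than 2 x step are skipped to avoid
    collinearity): LOD_full compares the model with both dosages and
    their product against the null, LOD_add compares the additive model
    against the null, and LOD_int = LOD_full - LOD_add isolates the
    interaction.
    """
    Xd, y, _ = _align_phenotype(probs, phenotype)
    n = y.size
    grid = probs.grid

    # subsample grid to approximately `step` spacing per chromosome
    keep: list[int] = []
    for chrom in probs.map.chromosomes:
        idx = probs.chromosome_slice(chrom)
        pos = grid["pos_cm"].to_numpy(float)[idx]
        last = -np.inf
        for i, p in zip(idx, pos):
            if p - last >= step - 1e-9:
                keep.append(int(i))
                last = p
    k = len(keep)
    n_pairs = k * (k - 1) // 2
    if n_pairs > max_pairs:
        needed = step * np.sqrt(n_pairs / max_pairs)
        raise ValueError(
            f"{n_pairs} position pairs exceed the budget of {max_pairs}; "
            f"increase step to about {needed:.0f} cM"
        )

    chroms = grid["chromosome"].to_numpy()[keep]
    poss = grid["pos_cm"].to_numpy(float)[keep]
    D = Xd[:, keep]
    rss_null = float(np.sum((y - y.mean()) ** 2))
    if rss_null <= 0:  # constant phenotype: every model fits equally
        rows = []
        for a in range(k):
            for b in range(a + 1, k):
                if chroms[a] == chroms[b] and abs(poss[a] - poss[b]) < 2.0 * step:
                    continue
                rows.append(
                    {"chr1": chroms[a], "pos1": poss[a], "chr2": chroms[b],
                     "pos2": poss[b], "lod_full": 0.0, "lod_add": 0.0, "lod_int": 0.0}
                )
        return TwoScanResult(pairs=pd.DataFrame(rows), step=step)

    rows = []
    for a in range(k):
        for b in range(a + 1, k):
            if chroms[a] == chroms[b] and abs(poss[a] - poss[b]) < 2.0 * step:
                continue
            xa, xb = D[:, a], D[:, b]
            Xadd = np.column_stack([np.ones(n), xa, xb])
            Xfull = np.column_stack([np.ones(n), xa, xb, xa * xb])
            rss_add = _rss(Xadd, y)
            rss_full = _rss(Xfull, y)
            lod_add = max(0.0, (n / 2.0) * np.log10(rss_null / max(rss_add, 1e-300)))
            lod_full = max(0.0, (n / 2.0) * np.log10(rss_null / max(rss_full, 1e-300)))
            rows.append(
                {
                    "chr1": chroms[a],
                    "pos1": poss[a],
                    "chr2": chroms[b],
                    "pos2": poss[b],
                    "lod_full": lod_full,
                    "lod_add": lod_add,
                    "lod_int": lod_full - lod_add,
                }
            )
    return TwoScanResult(pairs=pd.DataFrame(rows), step=step)


def call_peaks(
    scan: ScanResult,
    thresholds: dict[float, float],
    probs: GenotypeProbabilities,
    phenotype: pd.Series,
    ci_prob: float = 0.95,
    significant_alpha: float = 0.05,
    suggestive_alpha: float = 0.63,
) -> list[QTLPeak]:
    """One peak per chromosome clearing the suggestive threshold.

    Each peak is the chromosome's LOD maximum (leftmost on ties), labelled
    significant if it also clears the significant-alpha threshold, and
    annotated with the nearest typed marker, the credible interval and the
    single-locus R^2 at the peak.
    """
    sig_thr = thresholds[significant_alpha]
    sug_thr = thresholds[suggestive_alpha]
    Xd, y, row = _align_phenotype(probs, phenotype)
    n = y.size
    tss = float(np.sum((y - y.mean()) ** 2))

    peaks: list[QTLPeak] = []
    for chrom in scan.profile["chromosome"].unique():
        sel = scan.profile[scan.profile["chromosome"] == chrom].reset_index(drop=True)
        j = int(sel["lod"].to_numpy().argmax())
        lod = float(sel["lod"].iat[j])
        if lod < sug_thr:
            continue
        pos = float(sel["pos_cm"].iat[j])
        mk = probs.grid[(probs.grid["chromosome"] == chrom) & probs.grid["is_marker"]]
        nearest = mk.iloc[int(np.argmin(np.abs(mk["pos_cm"].to_numpy(float) - pos)))]["name"]
        lo, hi, _ = bayes_interval(scan, chrom, ci_prob)
        d, _ = probs.dosage_at(chrom, pos)
        rss1 = _rss(np.column_stack([np.ones(n), d[row]]), y)
        r2 = 100.0 * (1.0 - rss1 / tss) if tss > 0 else 0.0
        peaks.append(
            QTLPeak(
                chromosome=chrom,
                pos_cm=pos,
                lod=lod,
                nearest_marker=str(nearest),
                ci_lo=min(lo, pos),
                ci_hi=max(hi, pos),
                r_squared=r2,
                tier="significant" if lod >= sig_thr else "suggestive",
            )
        )
    return peaks
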