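"""Quantitative-genetic analyses for RIL mapping and NIL validation.

* broad-sense heritability H^2 = V_G / V_P by one-way random-effects method
  of moments (among-line vs within-line mean squares, unbalanced n0)
* single-QTL genome scan by Haley-Knott regression on a pseudomarker grid,
  with Haldane recombination fractions adjusted for selfed RILs
  (R = 2c / (1 + 2c)); LOD = (n/2) * log10(RSS0 / RSS1)
* genome-wide significance thresholds from permutations of the line-mean
  phenotypes
* NIL-vs-recurrent-parent comparison with a fixed genotype + block linear
  model (adjusted means, differences, t statistics)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .markers import GenotypeMatrix

SCORE = {"D": 1.0, "R": 0.0}  # donor-allele dosage used in the regression


@dataclass
class HeritabilityEstimate:
    v_g: float
    v_e: float
    v_p: float
    h2: float


def read_phenotype_table(path) -> pd.DataFrame:
    """Phenotype CSV with columns line, block, value (optional row, column)."""
    df = pd.read_csv(path)
    required = {"line", "block", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"phenotype table needs columns {sorted(required)}")
    return df


def line_means(ph: pd.DataFrame) -> pd.Series:
    return ph.groupby("line")["value"].mean()


def broad_sense_heritability(ph: pd.DataFrame) -> HeritabilityEstimate:
    """One-way random-effects method of moments.

    V_E is the within-line mean square; V_G = (MS_among - MS_within) / n0
    with the standard unbalanced n0 = (N - sum(n_i^2)/N) / (a - 1); negative
    V_G is truncated to zero so H^2 stays in [0, 1].
    """
    if not np.isfinite(ph["value"]).all():
        raise ValueError("phenotype values must be finite")
    sizes = ph.groupby("line")["value"].count()
    a = len(sizes)
    n_total = int(sizes.sum())
    if a < 2:
        raise ValueError("heritability needs at least 2 lines")
    if n_total <= a:
        raise ValueError("heritability needs replicated lines (N > number of lines)")
    grand = ph["value"].mean()
    means = ph.groupby("line")["value"].mean()
    ss_among = float((sizes * (means - grand) ** 2).sum())
    ss_within = float(((ph["value"] - ph["line"].map(means)) ** 2).sum())
    ms_among = ss_among / (a - 1)
    ms_within = ss_within / (n_total - a)
    n0 = (n_total - float((sizes**2).sum()) / n_total) / (a - 1)
    v_g = max((ms_among - ms_within) / n0, 0.0)
    v_e = ms_within
    v_p = v_g + v_e
    h2 = v_g / v_p if v_p > 0 else 0.0
    return HeritabilityEstimate(v_g, v_e, v_p, h2)


# --- Haley-Knott scan --------------------------------------------------------


def haldane_c(d_cM: np.ndarray) -> np.ndarray:
    """Haldane map function: recombination fraction for a distance in cM."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cM, dtype=float) / 100.0))


def ril_recomb(d_cM: np.ndarray) -> np.ndarray:
    """Recombination fraction between fixed genotypes of selfed RILs:
    R = 2c / (1 + 2c) applied to the Haldane c."""
    c = haldane_c(d_cM)
    return 2.0 * c / (1.0 + 2.0 * c)


@dataclass
class ScanResult:
    positions: pd.DataFrame  # chrom, cM
    lod: np.ndarray
    line_ids: List[str]
    scores: np.ndarray  # n_lines x n_positions expected donor dosage
    phenotype: np.ndarray  # line means, aligned with line_ids
    threshold: Optional[float] = None
    peak_chrom: Optional[int] = None
    peak_cM: Optional[float] = None
    peak_lod: float = 0.0
    variance_explained: float = 0.0

    @property
    def peak_index(self) -> int:
        return int(np.argmax(self.lod))

    def to_frame(self) -> pd.DataFrame:
        df = self.positions.copy()
        df["lod"] = self.lod
        return df


def _expected_scores(
    pos: np.ndarray, geno: np.ndarray, grid: np.ndarray, ril_adjusted: bool = True
) -> np.ndarray:
    """Expected donor dosage at grid positions given informative flanking
    genotypes (0/1) via the Markov conditional on the nearest informative
    flanking markers."""
    rec = ril_recomb if ril_adjusted else haldane_c
    if len(pos) == 0:
        return np.full(len(grid), 0.5)
    li = np.searchsorted(pos, grid, side="right") - 1
    ri = li + 1
    has_l = li >= 0
    has_r = ri < len(pos)
    lix = np.clip(li, 0, len(pos) - 1)
    rix = np.clip(ri, 0, len(pos) - 1)
    rl = rec(np.abs(grid - pos[lix]))
    rr = rec(np.abs(pos[rix] - grid))
    gl, gr = geno[lix], geno[rix]
    t1 = np.where(gl == 1, 1 - rl, rl) * np.where(gr == 1, 1 - rr, rr)
    t0 = np.where(gl == 0, 1 - rl, rl) * np.where(gr == 0, 1 - rr, rr)
    with np.errstate(invalid="ignore"):
        p_both = t1 / (t1 + t0)
    p_left = np.where(gl == 1, 1 - rl, rl)
    p_right = np.where(gr == 1, 1 - rr, rr)
    out = np.where(
        has_l & has_r, p_both, np.where(has_l, p_left, np.where(has_r, p_right, 0.5))
    )
    return out


def genotype_scores(
    gm: GenotypeMatrix, step_cM: float = 1.0, ril_adjusted: bool = True
) -> Tuple[pd.DataFrame, np.ndarray]:
    """Pseudomarker grid and expected donor dosages for every line.

    Heterozygous/undetermined/missing calls are treated as uninformative for
    conditioning (H is rare in a RIL-type matrix); a chromosome with no
    informative markers for any line is skipped with a warning.
    """
    chroms = []
    grids = []
    for chrom in gm.map.chromosomes:
        ids = [m.id for m in gm.map.chrom_markers(chrom)]
        informative = gm.calls[ids].isin(("D", "R")).to_numpy().any()
        if not informative:
            warnings.warn(f"chromosome {chrom}: no informative markers, skipped")
            continue
        L = gm.map.chrom_lengths_cM[chrom]
        grid = np.arange(0.0, L + step_cM / 2.0, step_cM)
        chroms.append(chrom)
        grids.append(grid)
    positions = pd.DataFrame(
        {
            "chrom": np.concatenate([[c] * len(g) for c, g in zip(chroms, grids)]),
            "cM": np.concatenate(grids),
        }
    )
    scores = np.empty((gm.n_lines, len(positions)))
    all_calls = gm.calls.to_numpy(dtype="U1")
    col_index = {mid: j for j, mid in enumerate(gm.map.ids)}
    col = 0
    for chrom, grid in zip(chroms, grids):
        ms = gm.map.chrom_markers(chrom)
        jdx = np.array([col_index[m.id] for m in ms])
        mpos = np.array([m.genetic_pos for m in ms])
        chrom_calls = all_calls[:, jdx]
        informative = (chrom_calls == "D") | (chrom_calls == "R")
        dosage = (chrom_calls == "D").astype(float)
        for r in range(gm.n_lines):
            keep = informative[r]
            scores[r, col : col + len(grid)] = _expected_scores(
                mpos[keep], dosage[r, keep], grid, ril_adjusted
            )
        col += len(grid)
    return positions, scores


def _lod_curve(y: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """LOD per score column for a simple regression of y on each column."""
    n = len(y)
    yc = y - y.mean()
    ssy = float(yc @ yc)
    xc = scores - scores.mean(axis=0)
    ssx = np.einsum("ij,ij->j", xc, xc)
    sxy = yc @ xc
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(ssx > 0, sxy**2 / np.maximum(ssx * ssy, 1e-300), 0.0)
    r2 = np.clip(r2, 0.0, 1.0 - 1e-12)
    return -(n / 2.0) * np.log10(1.0 - r2)


def hk_scan(
    gm: GenotypeMatrix,
    ph: pd.DataFrame,
    step_cM: float = 1.0,
    ril_adjusted: bool = True,
) -> ScanResult:
    """Single-QTL Haley-Knott genome scan on line-mean phenotypes."""
    means = line_means(ph)
    lines = [l for l in gm.line_ids if l in means.index]
    if not lines:
        raise ValueError("no phenotyped lines present in the genotype matrix")
    sub = gm.subset_lines(lines)
    y = means.loc[lines].to_numpy(dtype=float)
    positions, scores = genotype_scores(sub, step_cM, ril_adjusted)
    lod = _lod_curve(y, scores)
    peak = int(np.argmax(lod))
    res = ScanResult(
        positions=positions,
        lod=lod,
        line_ids=lines,
        scores=scores,
        phenotype=y,
        peak_chrom=int(positions["chrom"].iloc[peak]),
        peak_cM=float(positions["cM"].iloc[peak]),
        peak_lod=float(lod[peak]),
    )
    res.variance_explained = variance_explained(res)
    return res


def variance_explained(scan: ScanResult, index: Optional[int] = None) -> float:
    """1 - RSS1/RSS0 for the regression at the peak (or given) pseudomarker."""
    i = scan.peak_index if index is None else index
    y = scan.phenotype
    x = scan.scores[:, i]
    yc = y - y.mean()
    xc = x - x.mean()
    ssx = float(xc @ xc)
    if ssx == 0:
        return 0.0
    ssy = float(yc @ yc)
    if ssy == 0:
        return 0.0
    return float((yc @ xc) ** 2 / (ssx * ssy))


def permutation_threshold(
    gm: GenotypeMatrix,
    ph: pd.DataFrame,
    n_perm: int = 1000,
    alpha: float = 0.05,
    rng: Optional[np.random.Generator] = None,
    step_cM: float = 1.0,
    ril_adjusted: bool = True,
) -> float:
    """Genome-wide LOD threshold: the empirical (1 - alpha) quantile of the
    maximum LOD over ``n_perm`` permutations of the line-mean phenotypes."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if n_perm < 1.0 / alpha:
        warnings.warn(f"n_perm={n_perm} is below 1/alpha={1/alpha:.0f}; quantile is unstable")
    rng = rng if rng is not None else np.random.default_rng(0)
    means = line_means(ph)
    lines = [l for l in gm.line_ids if l in means.index]
    sub = gm.subset_lines(lines)
    y = means.loc[lines].to_numpy(dtype=float)
    _, scores = genotype_scores(sub, step_cM, ril_adjusted)
    maxima = permutation_maxima(y, scores, n_perm, rng)
    return float(np.quantile(maxima, 1.0 - alpha))


def permutation_maxima(
    y: np.ndarray, scores: np.ndarray, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Genome-wide maximum LOD for each phenotype permutation (vectorized)."""
    n = len(y)
    perms = np.array([rng.permutation(y) for _ in range(n_perm)])
    pc = perms - perms.mean(axis=1, keepdims=True)
    ssy = np.einsum("ij,ij->i", pc, pc)
    xc = scores - scores.mean(axis=0)
    ssx = np.einsum("ij,ij->j", xc, xc)
    sxy = pc @ xc  # n_perm x n_pos
    denom = np.outer(ssy, ssx)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(denom > 0, sxy**2 / np.maximum(denom, 1e-300), 0.0)
    r2 = np.clip(r2, 0.0, 1.0 - 1e-12)
    lod = -(n / 2.0) * np.log10(1.0 - r2)
    return lod.max(axis=1)


# --- NIL validation ----------------------------------------------------------


@dataclass
class ValidationResult:
    table: pd.DataFrame  # genotype, mean, se, difference, t, p
    pairwise: pd.DataFrame  # NIL-vs-NIL contrasts
    dropped: List[str] = field(default_factory=list)


def compare_to_recurrent(
    ph: pd.DataFrame, nil_lines: Sequence[str], recurrent: str
) -> ValidationResult:
    """NIL validation: fixed genotype + block linear model.

    Reports block-adjusted genotype means with standard errors, each NIL -
    recurrent difference with its t statistic and p value, and the pairwise
    NIL-vs-NIL contrasts. Genotypes with fewer than 2 replicates are dropped
    with a warning.
    """
    import statsmodels.api as sm

    genotypes = [recurrent] + [l for l in nil_lines if l != recurrent]
    df = ph[ph["line"].isin(genotypes)].copy()
    counts = df.groupby("line")["value"].count()
    if recurrent not in counts.index or counts.get(recurrent, 0) < 2:
        raise ValueError(f"recurrent line {recurrent!r} needs at least 2 replicates")
    dropped = [g for g in genotypes if counts.get(g, 0) < 2]
    for g in dropped:
        warnings.warn(f"genotype {g!r} has fewer than 2 replicates; dropped")
    genotypes = [g for g in genotypes if g not in dropped]
    df = df[df["line"].isin(genotypes)]

    blocks = sorted(df["block"].unique())
    geno_idx = {g: i for i, g in enumerate(genotypes)}
    block_idx = {b: i for i, b in enumerate(blocks)}
    n = len(df)
    # design: intercept, genotype dummies (recurrent = reference), block dummies
    X = np.zeros((n, 1 + (len(genotypes) - 1) + (len(blocks) - 1)))
    X[:, 0] = 1.0
    for r, (_, rec) in enumerate(df.iterrows()):
        gi = geno_idx[rec["line"]]
        if gi > 0:
            X[r, gi] = 1.0
        bi = block_idx[rec["block"]]
        if bi > 0:
            X[r, len(genotypes) - 1 + bi] = 1.0
    model = sm.OLS(df["value"].to_numpy(dtype=float), X).fit()

    # block-adjusted means: prediction averaged over blocks
    block_adjust = np.concatenate([[0.0], model.params[len(genotypes):]]).mean()
    rows = []
    for g in genotypes:
        gi = geno_idx[g]
        coef = 0.0 if gi == 0 else model.params[gi]
        mean = model.params[0] + coef + block_adjust
        if gi == 0:
            se_mean = float(np.sqrt(model.cov_params()[0, 0]))
            rows.append({"genotype": g, "mean": mean, "se": se_mean,
                         "difference": np.nan, "t": np.nan, "p": np.nan})
        else:
            rows.append(
                {
                    "genotype": g,
                    "mean": mean,
                    "se": float(model.bse[gi]),
                    "difference": float(coef),
                    "t": float(model.tvalues[gi]),
                    "p": float(model.pvalues[gi]),
                }
            )
    pair_rows = []
    nils = genotypes[1:]
    for i, g1 in enumerate(nils):
        for g2 in nils[i + 1:]:
            contrast = np.zeros(X.shape[1])
            contrast[geno_idx[g1]] = 1.0
            contrast[geno_idx[g2]] = -1.0
            tt = model.t_test(contrast)
            pair_rows.append(
                {
                    "contrast": f"{g1} - {g2}",
                    "difference": float(np.squeeze(tt.effect)),
                    "t": float(np.squeeze(tt.tvalue)),
                    "p": float(np.squeeze(tt.pvalue)),
                }
            )
    return ValidationResult(
        pd.DataFrame(rows),
        pd.DataFrame(pair_rows, columns=["contrast", "difference", "t", "p"]),
        dropped,
    )


def simulate_line_phenotypes(
    gm: GenotypeMatrix,
    rng: np.random.Generator,
    qtl_marker: Optional[str] = None,
    r2: float = 0.0,
) -> pd.DataFrame:
    """Synthetic line-mean phenotypes for calibration studies: unit residual
    variance plus an additive effect at ``qtl_marker`` sized so the QTL
    explains ``r2`` of the phenotypic variance (r2 = 0 or no marker -> pure
    noise / null trait)."""
    y = rng.standard_normal(gm.n_lines)
    if qtl_marker is not None and r2 > 0:
        calls = gm.calls[qtl_marker]
        score = calls.map({"D": 1.0, "R": 0.0, "H": 0.5}).fillna(0.5).to_numpy()
        v = score.var()
        if v <= 0:
            raise ValueError(f"marker {qtl_marker} is monomorphic; cannot plant a QTL")
        beta = np.sqrt(r2 / ((1.0 - r2) * v))
        y = y + beta * score
    return pd.DataFrame({"line": gm.line_ids, "block": 1, "value": y})
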