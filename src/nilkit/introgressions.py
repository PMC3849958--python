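"""Run-based introgression calling and population summaries.

A donor introgression is scored from a line's ordered genotype calls as a
run of at least ``min_run`` (default 3) consecutive markers with the donor
genotype; the run is terminated by ``boundary_run`` (default 3) consecutive
informative markers of a different genotype, or by the chromosome end.
Missing (M) and undetermined (U) calls are transparent: they neither extend
nor terminate a run and never count toward the minimum. Isolated opposite
calls inside a run are treated as occasional genotyping errors: they do not
count as support and do not terminate the run unless ``boundary_run`` of
them occur consecutively.

Homozygous-donor (D) and heterozygous (H) runs are scored independently, so
a heterozygous shoulder next to a homozygous core yields two introgressions.
Physical bounds are the positions of the outermost supporting markers and
lengths are closed-interval bp (end - start + 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .markers import GenotypeMatrix

ZYGOSITY_OF_TARGET = {"D": "hom", "H": "het"}


@dataclass(frozen=True)
class Introgression:
    """A called donor run."""

    line_id: str
    chromosome: int
    zygosity: str  # 'hom' or 'het'
    first_marker: str
    last_marker: str
    start_bp: int
    end_bp: int
    n_support: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1

    @property
    def interval(self) -> Tuple[int, int]:
        return (self.start_bp, self.end_bp)


def scan_runs(
    calls: Sequence[str], target: str, min_run: int = 3, boundary_run: int = 3
) -> List[Tuple[int, int, int]]:
    """Scan one call string for qualifying runs of ``target``.

    Returns (first supporting index, last supporting index, support count)
    per run. M and U are transparent; a run ends after ``boundary_run``
    consecutive informative non-target calls or at the end of the sequence.
    """
    if min_run < 1 or boundary_run < 1:
        raise ValueError("min_run and boundary_run must be >= 1")
    runs: List[Tuple[int, int, int]] = []
    in_run = False
    support = first = last = 0
    opposite = 0
    for i, c in enumerate(calls):
        if c in ("M", "U"):
            continue
        if c == target:
            if not in_run:
                in_run, support, first = True, 0, i
            support += 1
            last = i
            opposite = 0
        elif in_run:
            opposite += 1
            if opposite >= boundary_run:
                if support >= min_run:
                    runs.append((first, last, support))
                in_run = False
                opposite = 0
    if in_run and support >= min_run:
        runs.append((first, last, support))
    return runs


def call_introgressions(
    gm: GenotypeMatrix,
    line_id: str,
    min_run: int = 3,
    boundary_run: int = 3,
    targets: Tuple[str, ...] = ("D", "H"),
) -> List[Introgression]:
    """Call introgressions for one line, per chromosome and target genotype
    class (D -> homozygous-donor, H -> heterozygous, scored independently)."""
    out: List[Introgression] = []
    for chrom in gm.map.chromosomes:
        markers = gm.map.chrom_markers(chrom)
        calls = gm.line_calls(line_id, chrom).tolist()
        for target in targets:
            zyg = ZYGOSITY_OF_TARGET.get(target, target)
            for first, last, support in scan_runs(calls, target, min_run, boundary_run):
                out.append(
                    Introgression(
                        line_id,
                        chrom,
                        zyg,
                        markers[first].id,
                        markers[last].id,
                        markers[first].physical_pos,
                        markers[last].physical_pos,
                        support,
                    )
                )
    return sorted(out, key=lambda x: (x.chromosome, x.start_bp, x.zygosity))


def introgressions_table(introgressions: Sequence[Introgression]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "line": i.line_id,
                "chromosome": i.chromosome,
                "zygosity": i.zygosity,
                "first_marker": i.first_marker,
                "last_marker": i.last_marker,
                "start_bp": i.start_bp,
                "end_bp": i.end_bp,
                "n_support": i.n_support,
                "length_bp": i.length_bp,
            }
            for i in introgressions
        ],
        columns=[
            "line", "chromosome", "zygosity", "first_marker", "last_marker",
            "start_bp", "end_bp", "n_support", "length_bp",
        ],
    )


@dataclass
class PopulationSummary:
    """Introgression summary over a genotype matrix."""

    introgressions: List[Introgression]
    per_line: pd.DataFrame  # index line; n_hom, n_het, hom_bp, het_bp
    per_chromosome: pd.DataFrame  # index chromosome; n_hom, n_het, n_total
    mean_count: Dict[str, float] = field(default_factory=dict)
    count_range: Dict[str, Tuple[int, int]] = field(default_factory=dict)
    mean_length_bp: Dict[str, float] = field(default_factory=dict)
    total_length_bp: Dict[str, int] = field(default_factory=dict)


def summarize_introgressions(
    gm: GenotypeMatrix, min_run: int = 3, boundary_run: int = 3
) -> PopulationSummary:
    """Call introgressions for every line and aggregate counts and lengths by
    zygosity and chromosome."""
    if gm.n_lines == 0:
        raise ValueError("empty genotype matrix")
    all_intro: List[Introgression] = []
    rows = []
    for lid in gm.line_ids:
        intro = call_introgressions(gm, lid, min_run, boundary_run)
        all_intro.extend(intro)
        hom = [i for i in intro if i.zygosity == "hom"]
        het = [i for i in intro if i.zygosity == "het"]
        rows.append(
            {
                "line": lid,
                "n_hom": len(hom),
                "n_het": len(het),
                "hom_bp": sum(i.length_bp for i in hom),
                "het_bp": sum(i.length_bp for i in het),
            }
        )
    per_line = pd.DataFrame(rows).set_index("line")
    per_chrom = pd.DataFrame(
        [
            {
                "chromosome": c,
                "n_hom": sum(1 for i in all_intro if i.chromosome == c and i.zygosity == "hom"),
                "n_het": sum(1 for i in all_intro if i.chromosome == c and i.zygosity == "het"),
            }
            for c in gm.map.chromosomes
        ]
    ).set_index("chromosome")
    per_chrom["n_total"] = per_chrom["n_hom"] + per_chrom["n_het"]
    summary = PopulationSummary(all_intro, per_line, per_chrom)
    for zyg, col in (("hom", "n_hom"), ("het", "n_het")):
        lens = [i.length_bp for i in all_intro if i.zygosity == zyg]
        summary.mean_count[zyg] = float(per_line[col].mean())
        summary.count_range[zyg] = (int(per_line[col].min()), int(per_line[col].max()))
        summary.mean_length_bp[zyg] = float(np.mean(lens)) if lens else 0.0
        summary.total_length_bp[zyg] = int(sum(lens))
    return summary


@dataclass
class MapComparison:
    """Coarse-vs-dense map comparison of the same lines."""

    dense: PopulationSummary
    coarse: PopulationSummary
    dense_only: List[Introgression]
    count_ratio: Dict[str, float]  # dense count / coarse count
    mean_size_ratio: Dict[str, float]  # coarse mean length / dense mean length


def compare_maps(
    gm_dense: GenotypeMatrix,
    coarse_marker_ids: Sequence[str],
    min_run: int = 3,
    boundary_run: int = 3,
) -> MapComparison:
    """Re-call introgressions with a coarse marker subset and compare with
    the dense map: dense-only discoveries, count ratios and mean-size ratios
    by zygosity."""
    if not list(coarse_marker_ids):
        raise ValueError("empty coarse marker subset")
    dense = summarize_introgressions(gm_dense, min_run, boundary_run)
    coarse = summarize_introgressions(
        gm_dense.subset_markers(coarse_marker_ids), min_run, boundary_run
    )
    coarse_by_key: Dict[Tuple[str, int, str], List[Introgression]] = {}
    for i in coarse.introgressions:
        coarse_by_key.setdefault((i.line_id, i.chromosome, i.zygosity), []).append(i)
    dense_only = [
        i
        for i in dense.introgressions
        if not any(
            c.start_bp <= i.end_bp and i.start_bp <= c.end_bp
            for c in coarse_by_key.get((i.line_id, i.chromosome, i.zygosity), [])
        )
    ]
    count_ratio = {}
    size_ratio = {}
    for zyg in ("hom", "het"):
        n_dense = sum(1 for i in dense.introgressions if i.zygosity == zyg)
        n_coarse = sum(1 for i in coarse.introgressions if i.zygosity == zyg)
        count_ratio[zyg] = n_dense / n_coarse if n_coarse else float("inf") if n_dense else 1.0
        d_mean, c_mean = dense.mean_length_bp[zyg], coarse.mean_length_bp[zyg]
        size_ratio[zyg] = c_mean / d_mean if d_mean else float("nan")
    return MapComparison(dense, coarse, dense_only, count_ratio, size_ratio)


def subsample_marker_density(
    gm: GenotypeMatrix,
    densities: Sequence[int],
    reps: int = 10,
    rng: Optional[np.random.Generator] = None,
    min_run: int = 3,
    boundary_run: int = 3,
) -> pd.DataFrame:
    """Introgression discovery at reduced marker densities.

    For each requested marker count, draws ``reps`` uniform random marker
    subsets (without replacement, genome-wide) and re-calls introgressions.
    Returns a table with columns density, mean, sd, mean_hom, mean_het.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    all_ids = np.array(gm.map.ids)
    n_total = len(all_ids)
    rows = []
    for d in densities:
        if d > n_total:
            raise ValueError(f"density {d} exceeds total marker count {n_total}")
        if d < min_run:
            warnings.warn(f"density {d} below the minimum run length; no introgression is callable")
            rows.append({"density": d, "mean": 0.0, "sd": 0.0, "mean_hom": 0.0, "mean_het": 0.0})
            continue
        totals, homs, hets = [], [], []
        for _ in range(reps):
            ids = all_ids[np.sort(rng.choice(n_total, size=d, replace=False))]
            s = summarize_introgressions(gm.subset_markers(ids), min_run, boundary_run)
            n_hom = sum(1 for i in s.introgressions if i.zygosity == "hom")
            n_het = sum(1 for i in s.introgressions if i.zygosity == "het")
            totals.append(n_hom + n_het)
            homs.append(n_hom)
            hets.append(n_het)
        rows.append(
            {
                "density": d,
                "mean": float(np.mean(totals)),
                "sd": float(np.std(totals, ddof=1)) if reps > 1 else 0.0,
                "mean_hom": float(np.mean(homs)),
                "mean_het": float(np.mean(hets)),
            }
        )
    return pd.DataFrame(rows)


class ExponentialFitError(RuntimeError):
    """The exponential-rise fit failed or the data are degenerate."""


def fit_exponential_rise(
    x: Sequence[float], y: Sequence[float]
) -> Tuple[float, float, float]:
    """Least-squares fit of the saturation curve y = a * (1 - exp(-b * x)).

    Returns (a, b, r_squared); the asymptote a is the predicted total number
    of discoverable introgressions. Initial values: a0 = max(y), b0 solved
    from the first point with positive y; both parameters bounded positive.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points to fit the exponential rise")
    if np.any(np.diff(x) <= 0):
        raise ValueError("x must be strictly increasing")
    if np.any(y < 0):
        raise ValueError("y must be non-negative")
    if np.allclose(y, y[0]):
        raise ExponentialFitError("constant y: exponential rise is unidentifiable")
    a0 = float(np.max(y)) or 1.0
    b0 = 1.0 / float(np.mean(x))
    pos = np.nonzero(y > 0)[0]
    if len(pos):
        i = pos[0]
        frac = min(y[i] / (a0 * 1.001), 1 - 1e-9)
        if 0 < frac < 1:
            b0 = max(-np.log(1.0 - frac) / x[i], 1e-12)

    def model(xx, a, b):
        return a * (1.0 - np.exp(-b * xx))

    try:
        popt, _ = curve_fit(
            model, x, y, p0=(a0 * 1.001, b0),
            bounds=((1e-12, 1e-12), (np.inf, np.inf)), maxfev=20000,
        )
    except RuntimeError as exc:
        raise ExponentialFitError(
            f"exponential-rise fit did not converge (p0=({a0}, {b0})): {exc}"
        ) from exc
    resid = y - model(x, *popt)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    return float(popt[0]), float(popt[1]), r2
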