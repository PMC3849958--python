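"""Breeding-design selection algorithms.

* chromosome-isogenic RIL selection (lines fully donor across one chromosome)
* greedy selection of a genome-covering NIL subset (weighted set cover:
  maximize newly covered donor-introgression bp, penalize off-target
  background introgressions)
* sub-NIL recombinant class selection within a fine-mapping interval
* candidate-interval refinement from NIL validation results (single-locus
  intersection logic plus the regions each significant NIL excludes)
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import pandas as pd

from . import intervals as iv
from .introgressions import Introgression, call_introgressions
from .markers import GenotypeMatrix

DOSAGE = {"R": 0, "H": 1, "D": 2}


def select_isogenic_rils(
    ril_gm: GenotypeMatrix, max_missing: int = 0
) -> Dict[int, List[str]]:
    """Lines homozygous donor across an entire chromosome.

    A line qualifies for a chromosome when every informative call there is D
    (zero R/H), at most ``max_missing`` calls are M/U, and at least one D
    call is present. Returns {chromosome: [line ids]}; empty lists are valid.
    """
    out: Dict[int, List[str]] = {}
    for chrom in ril_gm.map.chromosomes:
        ids = [m.id for m in ril_gm.map.chrom_markers(chrom)]
        sub = ril_gm.calls[ids]
        n_d = (sub == "D").sum(axis=1)
        n_other = sub.isin(("R", "H")).sum(axis=1)
        n_miss = sub.isin(("M", "U")).sum(axis=1)
        ok = (n_other == 0) & (n_miss <= max_missing) & (n_d >= 1)
        out[chrom] = sorted(sub.index[ok])
    return out


@dataclass
class CoverageGoal:
    """Target for the genome-covering NIL subset."""

    target_zygosities: Tuple[str, ...] = ("hom", "het")
    fraction: float = 1.0
    background_weight: float = 0.5

    def __post_init__(self):
        if not (0 < self.fraction <= 1):
            raise ValueError("fraction must be in (0, 1]")
        if self.background_weight < 0:
            raise ValueError("background weight must be >= 0")


@dataclass
class NilSelection:
    """Ranked greedy selection with its coverage trace."""

    order: List[str]
    trace: pd.DataFrame  # rank, line, new_bp, background_bp, per-class coverage fractions
    covered: Dict[str, Dict[int, List[iv.Interval]]]  # zygosity -> chrom -> intervals
    goal_reached: bool
    uncovered: Dict[str, Dict[int, List[iv.Interval]]]


def _line_introgressions(
    gm: GenotypeMatrix, min_run: int, boundary_run: int
) -> Dict[str, List[Introgression]]:
    return {lid: call_introgressions(gm, lid, min_run, boundary_run) for lid in gm.line_ids}


def select_covering_nils(
    candidate_gm: GenotypeMatrix,
    goal: CoverageGoal = CoverageGoal(),
    k_max: int = 103,
    min_run: int = 3,
    boundary_run: int = 3,
    fill_to_k: bool = False,
) -> NilSelection:
    """Greedy weighted-cover ranking of candidate lines.

    At each step the line maximizing (newly covered target-introgression bp)
    - weight x (background donor bp outside the line's largest target
    introgression) is selected; ties break on smaller background bp, then
    lexicographic line id. Stops at ``k_max`` lines, when the goal fraction is
    reached in every target class, or when no line adds new coverage. An
    unreachable goal returns the best effort plus the uncovered intervals.

    With ``fill_to_k`` the ranking continues past coverage saturation: the
    remaining ranks go to lines that carry at least one target introgression,
    cleanest background first (building a redundant library rather than a
    minimal cover).
    """
    intro = _line_introgressions(candidate_gm, min_run, boundary_run)
    genome_bp = candidate_gm.map.total_bp
    chroms = candidate_gm.map.chromosomes

    background: Dict[str, int] = {}
    target_ivs: Dict[str, Dict[str, Dict[int, List[iv.Interval]]]] = {}
    for lid, items in intro.items():
        target = [i for i in items if i.zygosity in goal.target_zygosities]
        largest = max((i.length_bp for i in target), default=0)
        background[lid] = sum(i.length_bp for i in items) - largest
        per = {z: {c: [] for c in chroms} for z in goal.target_zygosities}
        for i in target:
            per[i.zygosity][i.chromosome].append(i.interval)
        target_ivs[lid] = per

    covered: Dict[str, Dict[int, List[iv.Interval]]] = {
        z: {c: [] for c in chroms} for z in goal.target_zygosities
    }

    def new_bp(lid: str) -> int:
        total = 0
        for z in goal.target_zygosities:
            for c in chroms:
                for seg in target_ivs[lid][z][c]:
                    total += sum(
                        iv.total_length_bp([s]) for s in iv.subtract([seg], covered[z][c])
                    )
        return total

    def class_fraction(z: str) -> float:
        return sum(iv.total_length_bp(covered[z][c]) for c in chroms) / genome_bp

    remaining = set(candidate_gm.line_ids)
    order: List[str] = []
    rows = []
    goal_reached = False
    while remaining and len(order) < k_max:
        scored = []
        for lid in remaining:
            nb = new_bp(lid)
            if nb <= 0:  # a line adding no new coverage is never selected
                continue
            score = nb - goal.background_weight * background[lid]
            scored.append((score, nb, lid))
        if not scored:
            break
        scored.sort(key=lambda t: (-t[0], background[t[2]], t[2]))
        score, nb, best = scored[0]
        order.append(best)
        remaining.discard(best)
        for z in goal.target_zygosities:
            for c in chroms:
                covered[z][c] = iv.union(covered[z][c], target_ivs[best][z][c])
        fractions = {z: class_fraction(z) for z in goal.target_zygosities}
        rows.append(
            {
                "rank": len(order),
                "line": best,
                "new_bp": nb,
                "background_bp": background[best],
                **{f"covered_{z}": fractions[z] for z in goal.target_zygosities},
            }
        )
        if all(f >= goal.fraction for f in fractions.values()):
            goal_reached = True
            break
    if fill_to_k and not goal_reached:
        extras = sorted(
            (
                lid
                for lid in remaining
                if any(
                    target_ivs[lid][z][c]
                    for z in goal.target_zygosities
                    for c in chroms
                )
            ),
            key=lambda lid: (background[lid], lid),
        )
        for lid in extras[: k_max - len(order)]:
            order.append(lid)
            rows.append(
                {
                    "rank": len(order),
                    "line": lid,
                    "new_bp": 0,
                    "background_bp": background[lid],
                    **{f"covered_{z}": class_fraction(z) for z in goal.target_zygosities},
                }
            )
    uncovered = {
        z: {
            c: iv.subtract([(1, candidate_gm.map.chrom_lengths_bp[c])], covered[z][c])
            for c in chroms
        }
        for z in goal.target_zygosities
    }
    return NilSelection(order, pd.DataFrame(rows), covered, goal_reached, uncovered)


@dataclass
class CoverageReport:
    fraction: Dict[str, float]  # zygosity -> genome-wide covered fraction
    per_chromosome: pd.DataFrame  # zygosity, chromosome, covered_fraction
    gaps: Dict[str, Dict[int, List[iv.Interval]]]


def coverage_report(
    selection: Sequence[str],
    gm: GenotypeMatrix,
    zygosities: Tuple[str, ...] = ("hom", "het"),
    min_run: int = 3,
    boundary_run: int = 3,
) -> CoverageReport:
    """Union of introgression intervals over a selection, by zygosity:
    covered bp fraction per chromosome and genome-wide, plus the uncovered
    intervals."""
    if not list(selection):
        raise ValueError("empty selection")
    chroms = gm.map.chromosomes
    covered = {z: {c: [] for c in chroms} for z in zygosities}
    for lid in selection:
        for i in call_introgressions(gm, lid, min_run, boundary_run):
            if i.zygosity in zygosities:
                covered[i.zygosity][i.chromosome] = iv.union(
                    covered[i.zygosity][i.chromosome], [i.interval]
                )
    genome_bp = gm.map.total_bp
    rows = []
    fraction = {}
    gaps = {}
    for z in zygosities:
        total = 0
        gaps[z] = {}
        for c in chroms:
            clen = gm.map.chrom_lengths_bp[c]
            cov = iv.total_length_bp(covered[z][c])
            total += cov
            rows.append({"zygosity": z, "chromosome": c, "covered_fraction": cov / clen})
            gaps[z][c] = iv.subtract([(1, clen)], covered[z][c])
        fraction[z] = total / genome_bp
    return CoverageReport(fraction, pd.DataFrame(rows), gaps)


@dataclass
class RecombinantClass:
    """One distinct interval genotype vector among sub-NIL progeny."""

    vector: Tuple[str, ...]
    line_ids: List[str]
    representative: str
    crossovers: int
    is_homozygous: bool
    n_missing: int
    is_double_recombinant: bool


@dataclass
class SubNilClasses:
    classes: List[RecombinantClass]
    kept_markers: List[str]
    dropped_markers: pd.DataFrame  # marker, reason
    double_recombinants_missing: bool


def _crossovers(vector: Sequence[str]) -> Tuple[int, bool]:
    """Crossover count within the interval (dosage steps between adjacent
    informative markers) and whether the dosage path is non-monotonic
    (a double recombinant)."""
    dosages = [DOSAGE[c] for c in vector if c in DOSAGE]
    steps = [b - a for a, b in zip(dosages, dosages[1:]) if b != a]
    n = sum(abs(s) for s in steps)
    double = any(s > 0 for s in steps) and any(s < 0 for s in steps)
    return n, double


def select_subnil_recombinants(
    progeny_gm: GenotypeMatrix,
    chrom: int,
    start_bp: int,
    end_bp: int,
) -> SubNilClasses:
    """Group fine-mapping progeny by their genotype vector over the interval
    markers.

    Markers that do not segregate among the progeny (identical informative
    call in every line) are dropped with a report. Classes are ranked
    preferring fully homozygous vectors, then fewest M/U calls; the
    representative of a class is its lexicographically first line.
    """
    markers = [
        m for m in progeny_gm.map.chrom_markers(chrom) if start_bp <= m.physical_pos <= end_bp
    ]
    if len(markers) < 2:
        raise ValueError(
            f"interval chr{chrom}:{start_bp}-{end_bp} contains fewer than 2 markers"
        )
    dropped = []
    kept = []
    for m in markers:
        col = progeny_gm.calls[m.id]
        informative = col[col.isin(("D", "R", "H"))]
        if informative.nunique() <= 1:
            call = informative.iloc[0] if len(informative) else "none"
            dropped.append({"marker": m.id, "reason": f"does not segregate (all {call})"})
        else:
            kept.append(m.id)
    if len(kept) < 2:
        raise ValueError(
            f"interval chr{chrom}:{start_bp}-{end_bp} has fewer than 2 segregating markers"
        )
    groups: Dict[Tuple[str, ...], List[str]] = {}
    for lid in progeny_gm.line_ids:
        vec = tuple(progeny_gm.calls.loc[lid, kept])
        groups.setdefault(vec, []).append(lid)
    classes = []
    for vec, lids in groups.items():
        xo, double = _crossovers(vec)
        classes.append(
            RecombinantClass(
                vector=vec,
                line_ids=sorted(lids),
                representative=sorted(lids)[0],
                crossovers=xo,
                is_homozygous=all(c in ("D", "R") for c in vec),
                n_missing=sum(1 for c in vec if c in ("M", "U")),
                is_double_recombinant=double,
            )
        )
    classes.sort(key=lambda c: (not c.is_homozygous, c.n_missing, c.vector))
    return SubNilClasses(
        classes,
        kept,
        pd.DataFrame(dropped, columns=["marker", "reason"]),
        double_recombinants_missing=not any(c.is_double_recombinant for c in classes),
    )


@dataclass
class NilValidationResult:
    """Input record for interval refinement: one phenotyped NIL."""

    line_id: str
    introgressions: List[iv.Interval]  # donor intervals on the focal chromosome, bp
    significant: bool


@dataclass
class IntervalRefinement:
    candidate: List[iv.Interval]  # intersection over significant lines
    per_line: Dict[str, List[iv.Interval]]
    exclusions: Dict[str, List[iv.Interval]]  # regions each significant line rules out
    no_consistent_interval: bool


def refine_candidate_interval(
    nil_results: Sequence[NilValidationResult],
) -> IntervalRefinement:
    """Single-causal-locus refinement from NIL validation outcomes.

    The candidate region is the intersection, over all significant lines, of
    each line's donor-introgression coverage on the focal chromosome. The
    exclusion log lists, per significant line, the regions inside other
    lines' introgressions but outside its own (regions it eliminates). An
    empty intersection is flagged (multi-locus architecture or an error),
    not raised.
    """
    significant = [r for r in nil_results if r.significant]
    if not significant:
        raise ValueError("at least one significant line is required")
    order_invariant = sorted(significant, key=lambda r: r.line_id)
    candidate = iv.normalize(order_invariant[0].introgressions)
    for r in order_invariant[1:]:
        candidate = iv.intersect(candidate, r.introgressions)
    exclusions: Dict[str, List[iv.Interval]] = {}
    for r in order_invariant:
        others = iv.union(
            *[o.introgressions for o in nil_results if o.line_id != r.line_id]
        )
        exclusions[r.line_id] = iv.subtract(others, r.introgressions)
    return IntervalRefinement(
        candidate,
        {r.line_id: iv.normalize(r.introgressions) for r in nil_results},
        exclusions,
        no_consistent_interval=not candidate,
    )
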