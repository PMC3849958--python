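"""Breeding-scheme simulator for a biparental NIL library.

Simulates the marker-assisted program used to build a near-isogenic line
(NIL) library from a recombinant inbred line (RIL) population: RILs are
derived from a donor x recurrent cross by single-seed descent, chromosome-
isogenic RILs are crossed to the recurrent parent, confirmed F1s are
backcrossed to create BC1 families, BC1 plants carrying donor alleles at the
focal chromosome are selfed for several generations, and every stage can be
genotyped against a mixed-density marker panel (a few dozen SSR/SNP-style
anchors plus several hundred RAD-style loci) with realistic missing-call
rates and Poisson-coverage/binomial-error read counts.

Meiosis uses the Haldane (no-interference) model: the number of crossovers
per chromosome is Poisson(L_cM / 100) with breakpoints uniform on the
genetic map. Genetic <-> physical coordinates are piecewise-linear between
anchor pairs (by default one pair per chromosome end).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .intervals import Interval
from .markers import GenotypeMatrix, Marker, MarkerMap

DONOR, RECURRENT = 1, 0

# Arabidopsis-like physical chromosome lengths (bp); total ~119 Mb.
_DEFAULT_BP = (30427671, 19698289, 23459830, 18585056, 26975502)
_DEFAULT_TOTAL_CM = 450.8


@dataclass
class SimGenome:
    """Per-chromosome genetic (cM) and physical (bp) lengths plus anchor
    pairs for genetic<->physical interpolation."""

    chrom_lengths_cM: Tuple[float, ...]
    chrom_lengths_bp: Tuple[int, ...]
    # per chromosome: (cM anchor array, bp anchor array), both increasing
    anchors: List[Tuple[np.ndarray, np.ndarray]] = field(default_factory=list)

    def __post_init__(self):
        if len(self.chrom_lengths_cM) != len(self.chrom_lengths_bp):
            raise ValueError("cM and bp length lists must match")
        if any(l <= 0 for l in self.chrom_lengths_bp) or any(l < 0 for l in self.chrom_lengths_cM):
            raise ValueError("chromosome lengths must be positive")
        if not self.anchors:
            self.anchors = [
                (np.array([0.0, lc]), np.array([1.0, float(lb)]))
                if lc > 0
                else (np.array([0.0]), np.array([float(lb)]))
                for lc, lb in zip(self.chrom_lengths_cM, self.chrom_lengths_bp)
            ]
        for cm, bp in self.anchors:
            if np.any(np.diff(cm) <= 0) or np.any(np.diff(bp) <= 0):
                raise ValueError("anchors must be strictly increasing in both coordinates")

    @property
    def n_chromosomes(self) -> int:
        return len(self.chrom_lengths_cM)

    @property
    def total_cM(self) -> float:
        return float(sum(self.chrom_lengths_cM))

    @property
    def total_bp(self) -> int:
        return int(sum(self.chrom_lengths_bp))


def default_genome(total_cM: float = _DEFAULT_TOTAL_CM) -> SimGenome:
    """Five-chromosome genome with Arabidopsis-like physical lengths and a
    genetic map of ``total_cM`` distributed proportionally to bp."""
    total_bp = sum(_DEFAULT_BP)
    cms = tuple(total_cM * b / total_bp for b in _DEFAULT_BP)
    return SimGenome(cms, _DEFAULT_BP)


def interpolate_physical(pos_cM: float, chrom: int, genome: SimGenome) -> int:
    """Genetic -> physical position via piecewise-linear anchor interpolation
    (chrom is 1-based)."""
    cm, bp = genome.anchors[chrom - 1]
    if pos_cM < cm[0] - 1e-9 or pos_cM > cm[-1] + 1e-9:
        raise ValueError(f"position {pos_cM} cM outside chromosome {chrom} [{cm[0]}, {cm[-1]}]")
    return int(round(float(np.interp(pos_cM, cm, bp))))


def interpolate_genetic(pos_bp: float, chrom: int, genome: SimGenome) -> float:
    """Physical -> genetic position (inverse of :func:`interpolate_physical`)."""
    cm, bp = genome.anchors[chrom - 1]
    if pos_bp < bp[0] - 0.5 or pos_bp > bp[-1] + 0.5:
        raise ValueError(f"position {pos_bp} bp outside chromosome {chrom} [{bp[0]}, {bp[-1]}]")
    return float(np.interp(pos_bp, bp, cm))


# --- haplotypes -------------------------------------------------------------
# A haplotype on one chromosome is a founder-label mosaic stored as
# (ends, labels): ends[i] is the cM end of segment i (ends[-1] == L) and
# labels[i] in {DONOR, RECURRENT}. Adjacent segments always differ in label.

Hap = Tuple[np.ndarray, np.ndarray]


def _merge_segments(ends: np.ndarray, labels: np.ndarray) -> Hap:
    if len(ends) <= 1:
        return ends, labels
    keep = np.append(labels[:-1] != labels[1:], True)
    return ends[keep], labels[keep]


def _splice(hap_a: Hap, hap_b: Hap, cuts: np.ndarray, start: int, L: float) -> Hap:
    """Build a recombinant mosaic switching source haplotype at each cut."""
    haps = (hap_a, hap_b)
    bounds = np.concatenate([[0.0], cuts, [L]])
    ends_out: List[np.ndarray] = []
    labels_out: List[np.ndarray] = []
    src = start
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        if hi <= lo:
            src ^= 1
            continue
        ends, labels = haps[src]
        i = int(np.searchsorted(ends, lo, side="right"))
        j = int(np.searchsorted(ends, hi, side="left"))
        ends_out.append(np.append(ends[i:j], hi))
        labels_out.append(labels[i : j + 1])
        src ^= 1
    return _merge_segments(np.concatenate(ends_out), np.concatenate(labels_out))


@dataclass
class DiploidGenotype:
    """Two founder-mosaic haplotypes per chromosome."""

    haplotypes: List[Tuple[Hap, Hap]]  # per chromosome

    def is_homozygous(self) -> bool:
        for h0, h1 in self.haplotypes:
            if len(h0[0]) != len(h1[0]):
                return False
            if not (np.array_equal(h0[0], h1[0]) and np.array_equal(h0[1], h1[1])):
                return False
        return True


def founder(genome: SimGenome, label: int) -> DiploidGenotype:
    haps = []
    for L in genome.chrom_lengths_cM:
        h = (np.array([float(L)]), np.array([label], dtype=np.int8))
        haps.append((h, (h[0].copy(), h[1].copy())))
    return DiploidGenotype(haps)


def simulate_gamete(parent: DiploidGenotype, genome: SimGenome, rng: np.random.Generator) -> List[Hap]:
    """One meiotic product: per chromosome, Poisson(L/100) crossovers at
    uniform positions, no interference."""
    gamete = []
    for c, L in enumerate(genome.chrom_lengths_cM):
        h0, h1 = parent.haplotypes[c]
        start = int(rng.integers(2))
        n_xo = int(rng.poisson(L / 100.0)) if L > 0 else 0
        if n_xo == 0:
            src = (h0, h1)[start]
            gamete.append((src[0].copy(), src[1].copy()))
            continue
        cuts = np.sort(rng.uniform(0.0, L, size=n_xo))
        gamete.append(_splice(h0, h1, cuts, start, float(L)))
    return gamete


def mate(
    a: DiploidGenotype, b: DiploidGenotype, genome: SimGenome, rng: np.random.Generator
) -> DiploidGenotype:
    """Offspring from one gamete of each parent; selfing is mate(a, a)."""
    ga = simulate_gamete(a, genome, rng)
    gb = simulate_gamete(b, genome, rng)
    return DiploidGenotype(list(zip(ga, gb)))


def simulate_ril_population(
    n: int, selfing_gens: int, genome: SimGenome, rng: np.random.Generator
) -> List[DiploidGenotype]:
    """n F1-derived lines advanced by single-seed descent for ``selfing_gens``
    generations of selfing."""
    if n < 1 or selfing_gens < 1:
        raise ValueError("n and selfing_gens must be >= 1")
    f1 = mate(founder(genome, DONOR), founder(genome, RECURRENT), genome, rng)
    lines = []
    for _ in range(n):
        ind = f1
        for _ in range(selfing_gens):
            ind = mate(ind, ind, genome, rng)
        lines.append(ind)
    return lines


# --- genotyping against a marker panel -------------------------------------


def _hap_labels_at(hap: Hap, pos_cM: np.ndarray) -> np.ndarray:
    ends, labels = hap
    idx = np.searchsorted(ends, pos_cM, side="left")
    idx = np.minimum(idx, len(labels) - 1)
    return labels[idx]


def genotype_calls(ind: DiploidGenotype, panel: MarkerMap, genome: SimGenome) -> List[str]:
    """True genotype calls (D/H/R) of an individual at the panel markers."""
    out: List[str] = []
    for chrom in panel.chromosomes:
        ms = panel.chrom_markers(chrom)
        pos = np.array([m.genetic_pos for m in ms])
        h0, h1 = ind.haplotypes[chrom - 1]
        a = _hap_labels_at(h0, pos)
        b = _hap_labels_at(h1, pos)
        dose = a.astype(int) + b.astype(int)
        out.extend(np.array(["R", "H", "D"])[dose].tolist())
    return out


def genotype_matrix(
    individuals: Sequence[Tuple[str, DiploidGenotype]],
    panel: MarkerMap,
    genome: SimGenome,
    missing_rate: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> GenotypeMatrix:
    """Genotype a set of individuals at the panel; each call is independently
    masked to M with probability ``missing_rate``."""
    rows = {lid: genotype_calls(ind, panel, genome) for lid, ind in individuals}
    df = pd.DataFrame.from_dict(rows, orient="index", columns=panel.ids)
    if missing_rate > 0:
        if rng is None:
            raise ValueError("missing_rate > 0 requires an rng")
        mask = rng.random(df.shape) < missing_rate
        arr = df.to_numpy(dtype=object)
        arr[mask] = "M"
        df = pd.DataFrame(arr, index=df.index, columns=df.columns)
    return GenotypeMatrix(df, panel)


def study_marker_panel(
    genome: SimGenome,
    n_anchor: int = 81,
    n_rad: int = 930,
    rng: Optional[np.random.Generator] = None,
) -> MarkerMap:
    """Mixed-density panel: evenly spaced anchors (SSR/SNP-like) plus
    uniformly placed RAD-like loci, allocated to chromosomes in proportion to
    genetic length. Marker ids are ``C<chrom>_<bp>``."""
    rng = rng if rng is not None else np.random.default_rng(0)
    cms = np.array(genome.chrom_lengths_cM)
    markers: List[Marker] = []

    def allocate(total: int) -> np.ndarray:
        raw = total * cms / cms.sum()
        base = np.floor(raw).astype(int)
        rem = total - base.sum()
        order = np.argsort(-(raw - base))
        base[order[:rem]] += 1
        return base

    n_anchor_c = allocate(n_anchor)
    n_rad_c = allocate(n_rad)
    for c in range(genome.n_chromosomes):
        chrom = c + 1
        L = genome.chrom_lengths_cM[c]
        anchor_cm = np.linspace(0.0, L, n_anchor_c[c] + 2)[1:-1] if n_anchor_c[c] else []
        rad_cm = rng.uniform(0.0, L, size=n_rad_c[c])
        taken = set()
        for cm in np.sort(np.concatenate([anchor_cm, rad_cm])):
            bp = interpolate_physical(float(cm), chrom, genome)
            while bp in taken:
                bp += 1
            taken.add(bp)
            gpos = interpolate_genetic(bp, chrom, genome)
            markers.append(Marker(f"C{chrom}_{bp}", chrom, gpos, bp))
    return MarkerMap(
        markers,
        {c + 1: float(genome.chrom_lengths_cM[c]) for c in range(genome.n_chromosomes)},
        {c + 1: int(genome.chrom_lengths_bp[c]) for c in range(genome.n_chromosomes)},
    )


# --- read counts ------------------------------------------------------------


def simulate_read_counts(
    gm: GenotypeMatrix,
    coverage: float,
    error_rate: float,
    rng: np.random.Generator,
    donor_allele: str = "G",
    recurrent_allele: str = "A",
) -> pd.DataFrame:
    """Per sample x locus allele read counts.

    Coverage is Poisson(``coverage``); each read reports the donor allele with
    probability 1-e (donor hom), 1/2 (het) or e (recurrent hom), where e is
    the symmetric per-read error rate. M/U calls yield zero coverage. Returns
    a long table (sample, locus, allele, count).
    """
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    if not (0 <= error_rate < 0.5):
        raise ValueError("error_rate must be in [0, 0.5)")
    calls = gm.calls.to_numpy(dtype="U1")
    p_donor = np.zeros(calls.shape)
    p_donor[calls == "D"] = 1.0 - error_rate
    p_donor[calls == "H"] = 0.5
    p_donor[calls == "R"] = error_rate
    observed = np.isin(calls, ("D", "H", "R"))
    cov = np.where(observed, rng.poisson(coverage, size=calls.shape), 0)
    donor_counts = rng.binomial(cov, p_donor)
    rec_counts = cov - donor_counts
    n_lines, n_mark = calls.shape
    samples = np.repeat(gm.line_ids, n_mark)
    loci = np.tile(gm.map.ids, n_lines)
    df = pd.DataFrame(
        {
            "sample": np.concatenate([samples, samples]),
            "locus": np.concatenate([loci, loci]),
            "allele": [donor_allele] * (n_lines * n_mark) + [recurrent_allele] * (n_lines * n_mark),
            "count": np.concatenate([donor_counts.ravel(), rec_counts.ravel()]),
        }
    )
    return df.sort_values(["sample", "locus", "allele"], kind="stable").reset_index(drop=True)


# --- true introgression segments (simulation truth) -------------------------


def true_segments(
    ind: DiploidGenotype, genome: SimGenome, chrom: int
) -> Dict[str, List[Interval]]:
    """True donor segments of an individual on one chromosome, in bp, split
    by zygosity ('hom' = donor/donor, 'het' = donor/recurrent)."""
    h0, h1 = ind.haplotypes[chrom - 1]
    bounds = np.unique(np.concatenate([[0.0], h0[0], h1[0]]))
    out: Dict[str, List[Interval]] = {"hom": [], "het": []}
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        mid = np.array([(lo + hi) / 2.0])
        dose = int(_hap_labels_at(h0, mid)[0]) + int(_hap_labels_at(h1, mid)[0])
        if dose == 0:
            continue
        key = "hom" if dose == 2 else "het"
        seg = (
            interpolate_physical(float(lo), chrom, genome),
            interpolate_physical(float(hi), chrom, genome),
        )
        if out[key] and out[key][-1][1] >= seg[0]:
            out[key][-1] = (out[key][-1][0], seg[1])
        else:
            out[key].append(seg)
    return out


def donor_fraction(ind: DiploidGenotype, genome: SimGenome) -> float:
    """Fraction of the diploid genetic map carried by donor segments
    (heterozygous segments count 1/2)."""
    total = 2.0 * genome.total_cM
    donor = 0.0
    for (h0, h1) in ind.haplotypes:
        for ends, labels in (h0, h1):
            seg_lens = np.diff(np.concatenate([[0.0], ends]))
            donor += float(seg_lens[labels == DONOR].sum())
    return donor / total


# --- full breeding program ---------------------------------------------------


@dataclass
class SimConfig:
    """Parameters of the simulated breeding program.

    Defaults mirror the study design: 346 RILs (selfed 6 generations),
    chromosome-isogenic RIL selection over 5 chromosomes, 25 BC1 families of
    24 plants, marker-assisted retention at the focal chromosome, three
    selfing generations, a 1011-marker mixed panel, 15% missing calls, and a
    20x / 0.5% read-count model.
    """

    genome: SimGenome = field(default_factory=default_genome)
    marker_map: Optional[MarkerMap] = None
    n_anchor: int = 81
    n_rad: int = 930
    n_rils: int = 346
    ril_selfing_gens: int = 6
    n_bc1_families: int = 25
    bc1_family_size: int = 24
    selfing_gens: int = 3
    stages: Tuple[str, ...] = ("RIL", "F1", "BC1", "BC1S1", "BC1S2", "BC1S3")
    missing_rate: float = 0.15
    coverage: float = 20.0
    error_rate: float = 0.005
    contaminant_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.missing_rate <= 1 and 0 <= self.contaminant_rate <= 1):
            raise ValueError("rates must be probabilities")
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")


@dataclass
class BreedingResult:
    """All emitted stages of a simulated program."""

    panel: MarkerMap
    matrices: Dict[str, GenotypeMatrix]
    individuals: Dict[str, List[Tuple[str, DiploidGenotype]]]
    focal_chrom: Dict[str, int]  # line id -> targeted chromosome
    selected_rils: Dict[int, List[str]]


class EmptySelectionError(RuntimeError):
    """A selection step retained zero individuals."""


def _default_ril_selection(
    rils: Sequence[Tuple[str, DiploidGenotype]],
    panel: MarkerMap,
    genome: SimGenome,
) -> Dict[int, List[str]]:
    """Chromosome-isogenic selection on true genotypes: lines fully donor
    across one chromosome."""
    out: Dict[int, List[str]] = {c: [] for c in panel.chromosomes}
    for lid, ind in rils:
        for chrom in panel.chromosomes:
            h0, h1 = ind.haplotypes[chrom - 1]
            if (
                len(h0[1]) == 1 and len(h1[1]) == 1
                and h0[1][0] == DONOR and h1[1][0] == DONOR
            ):
                out[chrom].append(lid)
    return out


def simulate_breeding_program(
    cfg: SimConfig,
    rng: Optional[np.random.Generator] = None,
    ril_selector: Optional[Callable[..., Dict[int, List[str]]]] = None,
) -> BreedingResult:
    """End-to-end realization of the NIL breeding scheme.

    RILs -> chromosome-isogenic selection -> F1 (with optional accidental-self
    contaminants, which are culled by F1 confirmation genotyping) -> BC1
    families -> marker-assisted retention of plants carrying donor alleles on
    the focal chromosome -> single-seed selfing generations. Every stage
    listed in ``cfg.stages`` is emitted as a GenotypeMatrix against the panel.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    genome = cfg.genome
    panel = cfg.marker_map or study_marker_panel(genome, cfg.n_anchor, cfg.n_rad, rng)
    recurrent = founder(genome, RECURRENT)

    rils = [
        (f"RIL_{i + 1:03d}", ind)
        for i, ind in enumerate(simulate_ril_population(cfg.n_rils, cfg.ril_selfing_gens, genome, rng))
    ]
    selector = ril_selector or _default_ril_selection
    selected = selector(rils, panel, genome)
    flat = [(chrom, lid) for chrom, lids in selected.items() for lid in lids]
    if not flat:
        raise EmptySelectionError("empty selection at stage RIL (no chromosome-isogenic lines)")
    ril_by_id = dict(rils)

    # one F1 per BC1 family, assigned round-robin over the selected RILs
    f1s: List[Tuple[str, DiploidGenotype, int]] = []
    fam = 0
    max_attempts = cfg.n_bc1_families * 1000
    while len(f1s) < cfg.n_bc1_families:
        if fam >= max_attempts:
            raise EmptySelectionError("empty selection at stage F1 (no confirmed F1s)")
        chrom, lid = flat[fam % len(flat)]
        fam += 1
        parent = ril_by_id[lid]
        if rng.random() < cfg.contaminant_rate:
            child = mate(parent, parent, genome, rng)  # accidental self
        else:
            child = mate(parent, recurrent, genome, rng)
        # F1 confirmation: a true F1 is heterozygous across the focal chromosome
        h0, h1 = child.haplotypes[chrom - 1]
        confirmed = (
            len(h0[1]) == 1 and len(h1[1]) == 1 and int(h0[1][0]) + int(h1[1][0]) == 1
        )
        if confirmed:
            f1s.append((f"F1_{fam:02d}", child, chrom))
    if not f1s:
        raise EmptySelectionError("empty selection at stage F1 (no confirmed F1s)")

    bc1: List[Tuple[str, DiploidGenotype, int]] = []
    for fam_idx, (fid, f1, chrom) in enumerate(f1s, start=1):
        focal = [m.genetic_pos for m in panel.chrom_markers(chrom)]
        pos = np.array(focal)
        for p in range(cfg.bc1_family_size):
            child = mate(f1, recurrent, genome, rng)
            h0, h1 = child.haplotypes[chrom - 1]
            dose = _hap_labels_at(h0, pos).astype(int) + _hap_labels_at(h1, pos).astype(int)
            if np.any(dose >= 1):  # carries donor alleles on the focal chromosome
                bc1.append((f"BC1_{fam_idx:02d}_{p + 1:02d}", child, chrom))
    if not bc1:
        raise EmptySelectionError("empty selection at stage BC1 (marker-assisted retention)")

    stage_inds: Dict[str, List[Tuple[str, DiploidGenotype]]] = {
        "RIL": rils,
        "F1": [(i, g) for i, g, _ in f1s],
        "BC1": [(i, g) for i, g, _ in bc1],
    }
    focal_chrom = {i: c for i, _, c in bc1}
    focal_chrom.update({i: c for i, _, c in f1s})

    prev = bc1
    for s in range(1, cfg.selfing_gens + 1):
        cur = [(lid, mate(ind, ind, genome, rng), chrom) for lid, ind, chrom in prev]
        stage_inds[f"BC1S{s}"] = [(i, g) for i, g, _ in cur]
        prev = cur

    matrices = {
        stage: genotype_matrix(inds, panel, genome, cfg.missing_rate, rng)
        for stage, inds in stage_inds.items()
        if stage in cfg.stages
    }
    return BreedingResult(panel, matrices, stage_inds, focal_chrom, selected)
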