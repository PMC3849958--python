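"""Marker maps, genotype matrices and graphical genotypes.

The shared coordinate system for the toolkit: ordered markers with a
chromosome, a genetic position (cM) and a physical position (bp, 1-based).
Genotype calls live in the closed alphabet

    D  donor homozygous (e.g. Kas-1)
    R  recurrent homozygous (e.g. Tsu-1)
    H  heterozygous
    U  undetermined (called but ambiguous)
    M  missing (insufficient data)

U and M are distinct states: U is a made call that could not be classified,
M means no usable data at all.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

CALL_ALPHABET = ("D", "R", "H", "U", "M")
INFORMATIVE = ("D", "R", "H")

#: Rendering palette used by the paper-style graphical genotypes.
CALL_COLORS = {"D": "red", "R": "blue", "H": "green", "U": "0.7", "M": "0.7"}

_ID_RE = re.compile(r"^C(\d+)_(\d+)$")


class GenotypeParseError(ValueError):
    """Raised when a genotype table contains symbols outside the alphabet."""


@dataclass(frozen=True)
class Marker:
    """A single genotyped locus on the shared genetic/physical map."""

    id: str
    chromosome: int
    genetic_pos: float  # cM
    physical_pos: int  # bp, 1-based

    def __post_init__(self):
        if self.chromosome < 1:
            raise ValueError(f"marker {self.id}: chromosome must be >= 1")
        if self.genetic_pos < 0:
            raise ValueError(f"marker {self.id}: genetic position must be >= 0 cM")
        if self.physical_pos < 1:
            raise ValueError(f"marker {self.id}: physical position must be >= 1 bp")
        m = _ID_RE.match(self.id)
        if m and (int(m.group(1)) != self.chromosome or int(m.group(2)) != self.physical_pos):
            raise ValueError(
                f"marker id {self.id!r} disagrees with chromosome {self.chromosome} / "
                f"position {self.physical_pos}"
            )


def parse_marker_id(marker_id: str) -> Marker:
    """Parse a ``C<chrom>_<bp>`` identifier into a Marker (genetic_pos 0)."""
    m = _ID_RE.match(marker_id)
    if not m:
        raise ValueError(f"marker id {marker_id!r} does not match C<chrom>_<bp>")
    return Marker(marker_id, int(m.group(1)), 0.0, int(m.group(2)))


@dataclass
class MarkerMap:
    """Ordered marker list plus per-chromosome map lengths.

    Markers are sorted by (chromosome, physical_pos). Within a chromosome the
    genetic positions must be non-decreasing with physical position.
    """

    markers: List[Marker]
    chrom_lengths_cM: Dict[int, float] = field(default_factory=dict)
    chrom_lengths_bp: Dict[int, int] = field(default_factory=dict)

    def __post_init__(self):
        self.markers = sorted(self.markers, key=lambda m: (m.chromosome, m.physical_pos))
        ids = [m.id for m in self.markers]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate marker ids: {dupes}")
        offenders = []
        for chrom in self.chromosomes:
            ms = self.chrom_markers(chrom)
            for a, b in zip(ms, ms[1:]):
                if a.physical_pos == b.physical_pos:
                    offenders.append((a.id, b.id, "duplicate physical position"))
                if b.genetic_pos < a.genetic_pos:
                    offenders.append((a.id, b.id, "cM decreases while bp increases"))
        if offenders:
            raise ValueError(f"non-monotone map: {offenders}")
        for chrom in self.chromosomes:
            ms = self.chrom_markers(chrom)
            self.chrom_lengths_cM.setdefault(chrom, ms[-1].genetic_pos)
            self.chrom_lengths_bp.setdefault(chrom, ms[-1].physical_pos)

    @property
    def ids(self) -> List[str]:
        return [m.id for m in self.markers]

    @property
    def chromosomes(self) -> List[int]:
        return sorted({m.chromosome for m in self.markers})

    def chrom_markers(self, chrom: int) -> List[Marker]:
        return [m for m in self.markers if m.chromosome == chrom]

    @property
    def total_cM(self) -> float:
        return float(sum(self.chrom_lengths_cM.values()))

    @property
    def total_bp(self) -> int:
        return int(sum(self.chrom_lengths_bp.values()))

    def density_per_cM(self) -> float:
        """Marker density, markers per cM over the whole map."""
        return len(self.markers) / self.total_cM

    def subset(self, marker_ids: Iterable[str]) -> "MarkerMap":
        keep = set(marker_ids)
        unknown = keep - set(self.ids)
        if unknown:
            raise KeyError(f"unknown markers: {sorted(unknown)}")
        return MarkerMap(
            [m for m in self.markers if m.id in keep],
            dict(self.chrom_lengths_cM),
            dict(self.chrom_lengths_bp),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker": self.ids,
                "chromosome": [m.chromosome for m in self.markers],
                "cM": [m.genetic_pos for m in self.markers],
                "bp": [m.physical_pos for m in self.markers],
            }
        )


def infer_map_from_ids(marker_ids: Sequence[str]) -> MarkerMap:
    """Build a MarkerMap by parsing ``C<chrom>_<bp>`` ids (genetic pos = 0)."""
    return MarkerMap([parse_marker_id(i) for i in marker_ids])


@dataclass
class GenotypeMatrix:
    """Lines x markers call matrix over the {D,R,H,U,M} alphabet.

    ``calls`` is a pandas DataFrame indexed by line id with one column per
    marker, in map order.
    """

    calls: pd.DataFrame
    map: MarkerMap

    def __post_init__(self):
        if self.calls.index.duplicated().any():
            raise ValueError("duplicate line ids")
        if list(self.calls.columns) != self.map.ids:
            # reorder to map order; every map marker must be present
            missing = set(self.map.ids) - set(self.calls.columns)
            extra = set(self.calls.columns) - set(self.map.ids)
            if missing or extra:
                raise ValueError(
                    f"calls/map marker mismatch (missing={sorted(missing)[:5]}, "
                    f"extra={sorted(extra)[:5]})"
                )
            self.calls = self.calls[self.map.ids]
        bad = ~self.calls.isin(CALL_ALPHABET)
        if bad.to_numpy().any():
            r, c = np.argwhere(bad.to_numpy())[0]
            raise GenotypeParseError(
                f"unknown call {self.calls.iat[r, c]!r} at line "
                f"{self.calls.index[r]!r}, marker {self.calls.columns[c]!r}"
            )

    @property
    def line_ids(self) -> List[str]:
        return list(self.calls.index)

    @property
    def n_lines(self) -> int:
        return len(self.calls.index)

    def line_calls(self, line_id: str, chrom: Optional[int] = None) -> pd.Series:
        if line_id not in self.calls.index:
            raise KeyError(f"unknown line id {line_id!r}")
        row = self.calls.loc[line_id]
        if chrom is None:
            return row
        ids = [m.id for m in self.map.chrom_markers(chrom)]
        return row[ids]

    def subset_markers(self, marker_ids: Iterable[str]) -> "GenotypeMatrix":
        sub = self.map.subset(marker_ids)
        return GenotypeMatrix(self.calls[sub.ids].copy(), sub)

    def subset_lines(self, line_ids: Iterable[str]) -> "GenotypeMatrix":
        ids = list(line_ids)
        unknown = set(ids) - set(self.calls.index)
        if unknown:
            raise KeyError(f"unknown line ids: {sorted(unknown)}")
        return GenotypeMatrix(self.calls.loc[ids].copy(), self.map)


DEFAULT_SYNONYMS: Mapping[str, str] = {
    "D": "D", "R": "R", "H": "H", "U": "U", "M": "M",
    "A": "D", "B": "R", "NA": "M", "-": "M", "": "M",
}


def read_genotype_table(
    path,
    map: Optional[MarkerMap] = None,
    synonyms: Optional[Mapping[str, str]] = None,
) -> GenotypeMatrix:
    """Read a lines x markers genotype CSV.

    The header row holds marker ids; the first column holds line ids. Call
    symbols outside the canonical alphabet are translated through
    ``synonyms`` (default accepts A/B/NA-style synonyms). If ``map`` is None
    a map is inferred by parsing ``C<chrom>_<bp>`` marker ids.
    """
    syn = dict(DEFAULT_SYNONYMS)
    if synonyms:
        syn.update(synonyms)
    df = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns.name = None

    def translate(col: pd.Series) -> pd.Series:
        out = col.str.strip().map(lambda s: syn.get(s, s))
        bad = ~out.isin(CALL_ALPHABET)
        if bad.any():
            line = out.index[bad.to_numpy().argmax()]
            raise GenotypeParseError(
                f"unknown call symbol {col[line]!r} at line {line!r}, marker {col.name!r}"
            )
        return out

    df = df.apply(translate)
    if map is None:
        map = infer_map_from_ids(list(df.columns))
    return GenotypeMatrix(df, map)


def write_genotype_table(gm: GenotypeMatrix, path, palette: Optional[Mapping[str, str]] = None):
    """Write a genotype matrix as CSV, optionally recoding calls via ``palette``."""
    df = gm.calls
    if palette:
        df = df.apply(lambda col: col.map(lambda c: palette.get(c, c)))
    df.to_csv(path, index_label="line")
    return path


def read_marker_map(path) -> MarkerMap:
    """Read a marker-map TSV with columns marker, chromosome, cM, bp."""
    df = pd.read_csv(path, sep="\t")
    required = {"marker", "chromosome", "cM", "bp"}
    if not required.issubset(df.columns):
        raise ValueError(f"marker map needs columns {sorted(required)}, got {list(df.columns)}")
    markers = [
        Marker(str(r.marker), int(r.chromosome), float(r.cM), int(r.bp))
        for r in df.itertuples()
    ]
    return MarkerMap(markers)


def write_marker_map(mm: MarkerMap, path):
    mm.to_frame().to_csv(path, sep="\t", index=False)
    return path


def render_text_genotypes(gm: GenotypeMatrix, lines: Optional[Sequence[str]] = None) -> str:
    """Plain-text graphical genotypes: one character per marker, one row per
    line per chromosome, markers in map order."""
    lines = list(lines) if lines is not None else gm.line_ids
    if not lines:
        raise ValueError("empty line selection")
    rows = []
    for lid in lines:
        for chrom in gm.map.chromosomes:
            calls = gm.line_calls(lid, chrom)
            rows.append(f"{lid}\tchr{chrom}\t{''.join(calls.tolist())}")
    return "\n".join(rows)


def _segment_bounds(positions: np.ndarray, chrom_len: int) -> np.ndarray:
    """Breaks between marker-colored segments: midpoints between neighbours,
    extended to the chromosome ends."""
    mids = (positions[:-1] + positions[1:]) / 2.0
    return np.concatenate([[0.0], mids, [float(chrom_len)]])


def render_graphical_genotypes(
    gm: GenotypeMatrix,
    lines: Optional[Sequence[str]] = None,
    out=None,
):
    """Paper-style chromosome paintings: donor red, recurrent blue,
    heterozygous green, missing/undetermined grey; segment widths scaled to
    physical length. Returns (text rendering, matplotlib figure); the figure
    is also written to ``out`` when given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    lines = list(lines) if lines is not None else gm.line_ids
    text = render_text_genotypes(gm, lines)

    chroms = gm.map.chromosomes
    fig, axes = plt.subplots(
        len(lines), len(chroms),
        figsize=(2.2 * len(chroms), 0.5 * len(lines) + 0.8),
        squeeze=False,
    )
    for i, lid in enumerate(lines):
        for j, chrom in enumerate(chroms):
            ax = axes[i][j]
            ms = gm.map.chrom_markers(chrom)
            pos = np.array([m.physical_pos for m in ms], dtype=float)
            bounds = _segment_bounds(pos, gm.map.chrom_lengths_bp[chrom])
            calls = gm.line_calls(lid, chrom).tolist()
            for k, call in enumerate(calls):
                ax.axvspan(bounds[k], bounds[k + 1], color=CALL_COLORS[call])
            ax.set_xlim(0, gm.map.chrom_lengths_bp[chrom])
            ax.set_yticks([])
            ax.set_xticks([])
            if i == 0:
                ax.set_title(f"chr{chrom}", fontsize=8)
            if j == 0:
                ax.set_ylabel(lid, rotation=0, ha="right", va="center", fontsize=7)
    fig.tight_layout()
    if out is not None:
        fig.savefig(out)
    return text, fig
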