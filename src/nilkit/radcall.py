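"""Threshold genotype calling from per-locus allele read counts.

Reduced-representation (2b-RAD-style) genotyping: each sample x locus read
pile is classified by minor allele frequency (MAF):

* coverage below the minimum -> missing (M)
* MAF < 1%               -> homozygous for the major allele
* MAF > 25%              -> heterozygous
* 1% <= MAF <= 25%       -> undetermined (U)

Parental genomes are called under a stricter coverage minimum (20x by
default vs 10x for library samples). Homozygous sample calls are then
compared with the two parental genotypes to encode each locus as donor (D),
recurrent (R) or heterozygous (H) background; loci where the parents share a
genotype are uninformative and dropped. Parental genotypes missing in the
direct parental samples can be imputed from a resequencing reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .markers import GenotypeMatrix, MarkerMap, infer_map_from_ids

MAF_HOM_MAX = 0.01  # exclusive: MAF < 1% -> homozygous
MAF_HET_MIN = 0.25  # exclusive: MAF > 25% -> heterozygous
DEFAULT_MIN_COVERAGE = 10
PARENT_MIN_COVERAGE = 20


def call_genotype_from_counts(
    counts: Mapping[str, int], min_coverage: int = DEFAULT_MIN_COVERAGE
) -> Tuple[str, Optional[str]]:
    """Classify one read pile.

    Returns ``(status, major_allele)`` with status in {'hom', 'het',
    'undetermined', 'missing'}; major_allele is None unless status is 'hom'.
    With more than two alleles the MAF is (coverage - max count) / coverage,
    so error-like third alleles count toward the minor fraction.
    """
    if any(c < 0 for c in counts.values()):
        raise ValueError("allele counts must be non-negative")
    coverage = sum(counts.values())
    if coverage < min_coverage or coverage == 0:
        return "missing", None
    major = min((a for a in counts if counts[a] == max(counts.values())))
    maf = (coverage - counts[major]) / coverage
    if maf < MAF_HOM_MAX:
        return "hom", major
    if maf > MAF_HET_MIN:
        return "het", None
    return "undetermined", None


def call_genotypes(counts: pd.DataFrame, min_coverage: int = DEFAULT_MIN_COVERAGE) -> pd.DataFrame:
    """Vectorized per-sample calling over a long counts table.

    ``counts`` has columns sample, locus, allele, count. Returns one row per
    (sample, locus) with columns status and allele (major allele for 'hom').
    """
    required = {"sample", "locus", "allele", "count"}
    if not required.issubset(counts.columns):
        raise ValueError(f"counts table needs columns {sorted(required)}")
    g = counts.sort_values("allele", kind="stable").groupby(["sample", "locus"], sort=True)
    cov = g["count"].sum()
    idx_max = g["count"].idxmax()  # first max -> lexicographically smallest major allele
    major_count = counts.loc[idx_max, "count"].to_numpy()
    major_allele = counts.loc[idx_max, "allele"].to_numpy()
    cov_arr = cov.to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        maf = np.where(cov_arr > 0, (cov_arr - major_count) / np.maximum(cov_arr, 1), np.nan)
    status = np.full(len(cov_arr), "undetermined", dtype=object)
    status[maf < MAF_HOM_MAX] = "hom"
    status[maf > MAF_HET_MIN] = "het"
    status[cov_arr < max(min_coverage, 1)] = "missing"
    out = pd.DataFrame(index=cov.index)
    out["status"] = status
    out["allele"] = np.where(status == "hom", major_allele, None)
    return out.reset_index()


@dataclass
class ParentalReference:
    """Per-locus homozygous genotypes of the two parents.

    ``donor``/``recurrent`` map locus -> allele; ``provenance`` records
    'direct' (called from the parental samples) or 'imputed' (filled from a
    resequencing reference).
    """

    donor: Dict[str, str]
    recurrent: Dict[str, str]
    provenance: Dict[str, str]

    @property
    def informative_loci(self) -> list:
        """Loci genotyped in both parents with distinct alleles."""
        return sorted(
            l
            for l in set(self.donor) & set(self.recurrent)
            if self.donor[l] != self.recurrent[l]
        )


def build_parental_reference(
    counts: pd.DataFrame,
    donor_sample: str,
    recurrent_sample: str,
    min_coverage: int = PARENT_MIN_COVERAGE,
    resequencing: Optional[Tuple[Mapping[str, str], Mapping[str, str]]] = None,
) -> ParentalReference:
    """Call parental genotypes from their read piles (stringent coverage) and
    impute loci genotyped in one parent but not the other from an optional
    resequencing reference (donor map, recurrent map)."""
    calls = call_genotypes(
        counts[counts["sample"].isin([donor_sample, recurrent_sample])], min_coverage
    )
    ref = ParentalReference({}, {}, {})
    for parent, target in ((donor_sample, ref.donor), (recurrent_sample, ref.recurrent)):
        sub = calls[(calls["sample"] == parent) & (calls["status"] == "hom")]
        for r in sub.itertuples():
            target[r.locus] = r.allele
            ref.provenance[r.locus] = "direct"
    if resequencing is not None:
        reseq_donor, reseq_rec = resequencing
        for locus in set(ref.donor) ^ set(ref.recurrent):
            if locus not in ref.donor and locus in reseq_donor:
                ref.donor[locus] = reseq_donor[locus]
                ref.provenance[locus] = "imputed"
            if locus not in ref.recurrent and locus in reseq_rec:
                ref.recurrent[locus] = reseq_rec[locus]
                ref.provenance[locus] = "imputed"
    return ref


def encode_parental_background(
    sample_calls: pd.DataFrame,
    ref: ParentalReference,
    map: Optional[MarkerMap] = None,
) -> Tuple[GenotypeMatrix, pd.DataFrame, int]:
    """Encode threshold calls against the parental backgrounds.

    Homozygous calls matching the donor allele become D, matching the
    recurrent allele R; heterozygous calls H; undetermined U; missing M.
    Homozygous calls matching neither parent are discordant and emitted as U.
    Loci not informative between the parents (shared genotype, or either
    parent unknown after imputation) are dropped. Returns (matrix,
    dropped-locus report, discordant-call count).
    """
    loci = sorted(sample_calls["locus"].unique())
    informative = set(ref.informative_loci)
    report = []
    for locus in loci:
        if locus not in informative:
            if locus not in ref.donor or locus not in ref.recurrent:
                report.append({"locus": locus, "reason": "parent genotype unknown"})
            else:
                report.append({"locus": locus, "reason": "parents share a genotype"})
    kept = [l for l in loci if l in informative]
    pivot_status = sample_calls.pivot(index="sample", columns="locus", values="status")
    pivot_allele = sample_calls.pivot(index="sample", columns="locus", values="allele")
    discordant = 0
    cols = {}
    for locus in kept:
        st = pivot_status[locus]
        al = pivot_allele[locus]
        col = pd.Series("M", index=st.index, dtype=object)
        col[st == "het"] = "H"
        col[st == "undetermined"] = "U"
        hom = st == "hom"
        col[hom & (al == ref.donor[locus])] = "D"
        col[hom & (al == ref.recurrent[locus])] = "R"
        disc = hom & (al != ref.donor[locus]) & (al != ref.recurrent[locus])
        discordant += int(disc.sum())
        col[disc] = "U"
        cols[locus] = col
    df = pd.DataFrame(cols)
    if map is None:
        map = infer_map_from_ids(kept)
    else:
        map = map.subset(kept)
    gm = GenotypeMatrix(df, map)
    return gm, pd.DataFrame(report, columns=["locus", "reason"]), discordant


def filter_segregating_loci(
    gm: GenotypeMatrix,
    constraints: Optional[Mapping[str, Mapping[int, str]]] = None,
    tolerance: float = 0.2,
) -> Tuple[GenotypeMatrix, pd.DataFrame]:
    """Pedigree segregation filter.

    Retains loci that are polymorphic in the encoded matrix and not
    contradicted by pedigree constraints. ``constraints`` maps line id ->
    {chromosome: expected call}; a locus on a constrained chromosome is
    dropped when more than ``tolerance`` of the constrained lines carry an
    informative call that contradicts the expectation. Returns the filtered
    matrix and a report of dropped loci.
    """
    if gm.n_lines == 0 or not gm.map.markers:
        raise ValueError("empty genotype matrix")
    report = []
    drop = set()
    calls = gm.calls
    for m in gm.map.markers:
        col = calls[m.id]
        informative = col.isin(("D", "R", "H"))
        if informative.any() and col[informative].nunique() == 1 and col[informative].iloc[0] in ("D", "R"):
            # constant homozygous call across lines: nothing segregates
            drop.add(m.id)
            report.append({"locus": m.id, "reason": "monomorphic"})
            continue
        if constraints:
            n_constrained = 0
            n_bad = 0
            for lid, chrom_expect in constraints.items():
                if m.chromosome not in chrom_expect or lid not in calls.index:
                    continue
                call = col.loc[lid]
                if call in ("M", "U"):
                    continue
                n_constrained += 1
                if call != chrom_expect[m.chromosome]:
                    n_bad += 1
            if n_constrained and n_bad / n_constrained > tolerance:
                drop.add(m.id)
                report.append(
                    {
                        "locus": m.id,
                        "reason": f"contradicts pedigree ({n_bad}/{n_constrained} constrained lines)",
                    }
                )
    kept = [i for i in gm.map.ids if i not in drop]
    return gm.subset_markers(kept), pd.DataFrame(report, columns=["locus", "reason"])


def read_counts_table(path) -> pd.DataFrame:
    """Read a wide counts TSV (sample, locus, alleleA, countA, alleleB,
    countB, ...) into the long (sample, locus, allele, count) form."""
    df = pd.read_csv(path, sep="\t")
    allele_cols = [c for c in df.columns if c.startswith("allele")]
    rows = []
    for r in df.itertuples(index=False):
        d = r._asdict()
        for ac in allele_cols:
            cc = "count" + ac[len("allele"):]
            if pd.isna(d[ac]):
                continue
            rows.append(
                {"sample": d["sample"], "locus": d["locus"], "allele": d[ac], "count": int(d[cc])}
            )
    return pd.DataFrame(rows)
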