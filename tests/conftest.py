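import numpy as np
import pandas as pd
import pytest

from nilkit.markers import GenotypeMatrix, Marker, MarkerMap


def make_gm(rows, spacing_bp=1_000_000, spacing_cM=5.0):
    """Build a GenotypeMatrix from per-line, per-chromosome call strings.

    ``rows`` maps line id -> {chromosome: "DRHMU..."}; all lines must give the
    same string length per chromosome. Markers are evenly spaced.
    """
    chroms = sorted({c for r in rows.values() for c in r})
    markers = []
    for c in chroms:
        n = len(next(iter(rows.values()))[c])
        for i in range(n):
            bp = (i + 1) * spacing_bp
            markers.append(Marker(f"C{c}_{bp}", c, (i + 1) * spacing_cM, bp))
    mm = MarkerMap(markers)
    data = {
        lid: list("".join(r[c] for c in chroms)) for lid, r in rows.items()
    }
    df = pd.DataFrame.from_dict(data, orient="index", columns=mm.ids)
    return GenotypeMatrix(df, mm)


def oracle_runs(calls, target, min_run=3, boundary_run=3):
    """Independent brute-force run enumerator.

    Groups the positions of ``target`` calls; two consecutive target
    positions fall in different runs iff at least ``boundary_run``
    informative (D/R/H) non-target calls lie strictly between them. Groups
    with at least ``min_run`` members are runs, reported as (first index,
    last index, support).
    """
    tpos = [i for i, c in enumerate(calls) if c == target]
    groups = []
    for p in tpos:
        if groups:
            prev = groups[-1][-1]
            gap = sum(1 for k in range(prev + 1, p) if calls[k] in ("D", "R", "H"))
            if gap < boundary_run:
                groups[-1].append(p)
                continue
        groups.append([p])
    return [(g[0], g[-1], len(g)) for g in groups if len(g) >= min_run]


@pytest.fixture
def rng():
    return np.random.default_rng(20130925)
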