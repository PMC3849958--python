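import numpy as np
import pandas as pd
import pytest

from nilkit.markers import Marker, MarkerMap
from nilkit.qtl import (
    broad_sense_heritability,
    compare_to_recurrent,
    haldane_c,
    hk_scan,
    line_means,
    permutation_threshold,
    ril_recomb,
    simulate_line_phenotypes,
    variance_explained,
)
from nilkit.simulate import (
    SimGenome,
    genotype_matrix,
    simulate_ril_population,
    study_marker_panel,
)


def _ril_gm(rng, n_lines=120, n_markers=40, L=100.0, fix_het=False):
    genome = SimGenome((L,), (10_000_000,))
    panel = study_marker_panel(genome, 0, n_markers, rng)
    lines = simulate_ril_population(n_lines, 6, genome, rng)
    gm = genotype_matrix([(f"L{i:03d}", ind) for i, ind in enumerate(lines)], panel, genome)
    if fix_het:
        # treat residual heterozygosity as fixed to the recurrent allele so
        # every call is informative (fully observed D/R matrix)
        from nilkit.markers import GenotypeMatrix

        gm = GenotypeMatrix(gm.calls.replace("H", "R"), gm.map)
    return gm, genome


# --- heritability ------------------------------------------------------------


def test_heritability_balanced_toy():
    ph = pd.DataFrame({"line": ["a", "a", "b", "b"], "block": [1, 2, 1, 2],
                       "value": [1.0, 1.0, 3.0, 3.0]})
    est = broad_sense_heritability(ph)
    assert est.v_e == 0.0
    assert est.h2 == 1.0


def test_heritability_zero_when_lines_identical(rng):
    ph = pd.DataFrame(
        {
            "line": np.repeat([f"l{i}" for i in range(30)], 4),
            "block": np.tile([1, 2, 3, 4], 30),
            "value": rng.standard_normal(120),  # no among-line signal
        }
    )
    est = broad_sense_heritability(ph)
    assert 0.0 <= est.h2 < 0.25
    # degenerate all-equal means with pure noise: truncation keeps H2 >= 0
    ph0 = ph.copy()
    ph0["value"] = np.tile(rng.standard_normal(4), 30)  # same per-block values per line
    assert broad_sense_heritability(ph0).h2 == 0.0


def test_heritability_affine_invariance(rng):
    ph = pd.DataFrame(
        {
            "line": np.repeat([f"l{i}" for i in range(20)], 3),
            "block": np.tile([1, 2, 3], 20),
            "value": rng.standard_normal(60) + np.repeat(rng.standard_normal(20), 3),
        }
    )
    base = broad_sense_heritability(ph).h2
    shifted = ph.copy()
    shifted["value"] = ph["value"] + 100.0
    scaled = ph.copy()
    scaled["value"] = ph["value"] * 7.5
    assert broad_sense_heritability(shifted).h2 == pytest.approx(base, abs=1e-12)
    assert broad_sense_heritability(scaled).h2 == pytest.approx(base, abs=1e-10)


def test_heritability_recovery_unbalanced(rng):
    """Method-of-moments recovers a simulated H2 = 0.21 on average."""
    h2_true = 0.21
    estimates = []
    for _ in range(60):
        n_lines = 300
        line_eff = rng.normal(0, np.sqrt(h2_true), n_lines)
        vals, lines, blocks = [], [], []
        for i in range(n_lines):
            for b in range(2):
                lines.append(f"l{i}")
                blocks.append(b)
                vals.append(line_eff[i] + rng.normal(0, np.sqrt(1 - h2_true)))
        estimates.append(
            broad_sense_heritability(
                pd.DataFrame({"line": lines, "block": blocks, "value": vals})
            ).h2
        )
    assert np.mean(estimates) == pytest.approx(h2_true, abs=0.02)


def test_heritability_errors():
    with pytest.raises(ValueError, match="2 lines"):
        broad_sense_heritability(pd.DataFrame({"line": ["a", "a"], "block": [1, 2],
                                               "value": [1.0, 2.0]}))
    with pytest.raises(ValueError, match="replicated"):
        broad_sense_heritability(pd.DataFrame({"line": ["a", "b"], "block": [1, 1],
                                               "value": [1.0, 2.0]}))


# --- Haley-Knott scan ---------------------------------------------------------


def test_scan_at_marker_equals_marker_regression(rng):
    """A pseudomarker coinciding with a fully observed marker reduces to the
    single-marker regression LOD exactly."""
    gm, _ = _ril_gm(rng, n_lines=80, n_markers=20, fix_het=True)
    ph = simulate_line_phenotypes(gm, rng, qtl_marker=gm.map.ids[7], r2=0.2)
    marker = gm.map.markers[7]
    res = hk_scan(gm, ph, step_cM=0.5)
    # direct single-marker regression on D/R dosage
    y = line_means(ph).loc[gm.line_ids].to_numpy()
    x = gm.calls[marker.id].map({"D": 1.0, "R": 0.0}).to_numpy()
    keep = ~np.isnan(x)
    # fully observed here (missing_rate 0)
    assert keep.all()
    r = np.corrcoef(x, y)[0, 1]
    lod_direct = -(len(y) / 2.0) * np.log10(1.0 - r**2)
    idx = np.argmin(
        np.abs(res.positions["cM"].to_numpy() - marker.genetic_pos)
        + 1e9 * (res.positions["chrom"].to_numpy() != marker.chromosome)
    )
    grid_cm = res.positions["cM"].iloc[idx]
    if abs(grid_cm - marker.genetic_pos) < 1e-9:
        assert res.lod[idx] == pytest.approx(lod_direct, abs=1e-9)
    else:
        # nearest grid point: conditional expectation degenerates smoothly
        assert res.lod[idx] == pytest.approx(lod_direct, rel=0.05)


def test_scan_exact_at_grid_aligned_marker():
    # hand-built matrix with markers exactly on the grid
    markers = [Marker(f"C1_{(i+1)*1000}", 1, float(i * 10), (i + 1) * 1000) for i in range(5)]
    mm = MarkerMap(markers, {1: 40.0}, {1: 5000})
    calls = pd.DataFrame(
        [list("DDRRD"), list("RRDDR"), list("DRDRD"), list("RDRDR"),
         list("DDDDD"), list("RRRRR")],
        index=[f"L{i}" for i in range(6)], columns=mm.ids,
    )
    from nilkit.markers import GenotypeMatrix

    gm = GenotypeMatrix(calls, mm)
    y = np.array([3.0, 1.0, 2.0, 1.5, 3.5, 0.5])
    ph = pd.DataFrame({"line": gm.line_ids, "block": 1, "value": y})
    res = hk_scan(gm, ph, step_cM=10.0)
    for j, m in enumerate(markers):
        x = calls[m.id].map({"D": 1.0, "R": 0.0}).to_numpy()
        r = np.corrcoef(x, y)[0, 1]
        lod_direct = -(len(y) / 2.0) * np.log10(1.0 - r**2)
        idx = res.positions.index[
            (res.positions["chrom"] == 1) & (np.isclose(res.positions["cM"], m.genetic_pos))
        ][0]
        assert res.lod[idx] == pytest.approx(lod_direct, abs=1e-9)


def test_lod_invariant_to_affine_phenotype_transform(rng):
    gm, _ = _ril_gm(rng, n_lines=60, n_markers=15)
    ph = simulate_line_phenotypes(gm, rng, qtl_marker=gm.map.ids[3], r2=0.15)
    res1 = hk_scan(gm, ph)
    ph2 = ph.copy()
    ph2["value"] = 3.0 * ph["value"] - 17.0
    res2 = hk_scan(gm, ph2)
    np.testing.assert_allclose(res1.lod, res2.lod, atol=1e-9)


def test_scan_handles_missing_flanking_data(rng):
    gm, _ = _ril_gm(rng, n_lines=60, n_markers=15)
    calls = gm.calls.copy()
    calls.iloc[:, 0] = "M"  # entire first marker missing
    calls.iloc[0, :] = "M"  # one line fully missing
    from nilkit.markers import GenotypeMatrix

    gm2 = GenotypeMatrix(calls, gm.map)
    ph = simulate_line_phenotypes(gm2, rng, qtl_marker=gm.map.ids[7], r2=0.2)
    res = hk_scan(gm2, ph)
    assert np.isfinite(res.lod).all()
    assert (res.lod >= 0).all()


def test_variance_explained_extremes(rng):
    # grid-aligned markers so the peak pseudomarker coincides with the QTL
    markers = [Marker(f"C1_{(i+1)*1000}", 1, float(i * 10), (i + 1) * 1000) for i in range(5)]
    mm = MarkerMap(markers, {1: 40.0}, {1: 5000})
    calls = pd.DataFrame(
        [list(v) for v in ("DDRRD", "RRDDR", "DRDRD", "RDRDR", "DDDDD", "RRRRR",
                           "DRRRD", "RDDDR")],
        index=[f"L{i}" for i in range(8)], columns=mm.ids,
    )
    from nilkit.markers import GenotypeMatrix

    gm = GenotypeMatrix(calls, mm)
    score = calls[mm.ids[2]].map({"D": 1.0, "R": 0.0}).to_numpy()
    ph = pd.DataFrame({"line": gm.line_ids, "block": 1, "value": score})
    res = hk_scan(gm, ph, step_cM=10.0)
    assert res.variance_explained == pytest.approx(1.0, abs=1e-9)
    # independent phenotype at larger n: variance explained near zero
    gm2, _ = _ril_gm(rng, n_lines=200, n_markers=10)
    ph_null = pd.DataFrame({"line": gm2.line_ids, "block": 1,
                            "value": rng.standard_normal(gm2.n_lines)})
    res_null = hk_scan(gm2, ph_null)
    assert res_null.variance_explained < 0.12


def test_permutation_threshold_properties(rng):
    gm, _ = _ril_gm(rng, n_lines=60, n_markers=15)
    ph = simulate_line_phenotypes(gm, rng)
    t1 = permutation_threshold(gm, ph, 200, 0.05, np.random.default_rng(5))
    t2 = permutation_threshold(gm, ph, 200, 0.05, np.random.default_rng(5))
    assert t1 == t2  # seeded determinism
    thresholds = [
        permutation_threshold(gm, ph, 200, a, np.random.default_rng(5))
        for a in (0.01, 0.05, 0.2)
    ]
    assert thresholds[0] >= thresholds[1] >= thresholds[2]
    t_min = permutation_threshold(gm, ph, 50, 1.0, np.random.default_rng(5))
    # alpha = 1: the threshold is the minimum of the permuted maxima
    assert t_min <= thresholds[2]
    with pytest.warns(UserWarning, match="unstable"):
        permutation_threshold(gm, ph, 10, 0.05, np.random.default_rng(5))


def test_ril_recombination_adjustment():
    # R = 2c/(1+2c); at large distance c -> 1/2 so R -> 1/2... for selfed RILs
    assert ril_recomb(np.array([0.0]))[0] == 0.0
    c = haldane_c(np.array([10.0]))[0]
    assert c == pytest.approx(0.0906, abs=1e-4)
    assert ril_recomb(np.array([10.0]))[0] == pytest.approx(2 * c / (1 + 2 * c))


# --- NIL validation ----------------------------------------------------------


def _validation_table(means, blocks=3, reps=6, block_effects=None, noise=None):
    """Balanced validation design; residuals sum to zero within each
    genotype x block cell unless explicit noise is given."""
    rows = []
    for g, mu in means.items():
        for b in range(blocks):
            be = block_effects[b] if block_effects is not None else 0.0
            for r in range(reps):
                eps = noise[g][b][r] if noise is not None else (0.1 if r % 2 else -0.1)
                rows.append({"line": g, "block": b, "value": mu + be + eps})
    return pd.DataFrame(rows)


def test_validation_difference_from_adjusted_means():
    ph = _validation_table(
        {"Tsu-1": 119.76, "TK201_137_6": 52.42, "KT116_63_15": 67.45},
        block_effects=[-5.0, 0.0, 5.0],
    )
    res = compare_to_recurrent(ph, ["TK201_137_6", "KT116_63_15"], "Tsu-1")
    t = res.table.set_index("genotype")
    assert t.loc["TK201_137_6", "difference"] == pytest.approx(-67.34, abs=1e-9)
    assert t.loc["KT116_63_15", "difference"] == pytest.approx(-52.31, abs=0.01)
    assert t.loc["Tsu-1", "mean"] == pytest.approx(119.76, abs=1e-9)
    # NIL-vs-NIL contrast reported
    assert len(res.pairwise) == 1
    assert res.pairwise["difference"].iloc[0] == pytest.approx(52.42 - 67.45, abs=1e-9)


def test_validation_identical_groups_zero_difference(rng):
    noise = {g: rng.standard_normal((3, 6)) for g in ("Tsu-1", "NILX")}
    noise["NILX"] = noise["Tsu-1"]  # identical replicate values
    ph = _validation_table({"Tsu-1": 10.0, "NILX": 10.0}, noise=noise)
    res = compare_to_recurrent(ph, ["NILX"], "Tsu-1")
    t = res.table.set_index("genotype")
    assert t.loc["NILX", "difference"] == pytest.approx(0.0, abs=1e-9)
    assert t.loc["NILX", "t"] == pytest.approx(0.0, abs=1e-9)


def test_validation_drops_underreplicated_genotype():
    ph = _validation_table({"Tsu-1": 100.0, "NIL1": 50.0})
    ph = pd.concat(
        [ph, pd.DataFrame([{"line": "NIL2", "block": 0, "value": 42.0}])],
        ignore_index=True,
    )
    with pytest.warns(UserWarning, match="NIL2"):
        res = compare_to_recurrent(ph, ["NIL1", "NIL2"], "Tsu-1")
    assert res.dropped == ["NIL2"]
    assert "NIL2" not in res.table["genotype"].tolist()


def test_validation_recovers_simulated_shift(rng):
    """Estimated NIL - recurrent difference is within 2 SE of the true -60
    shift in nearly all replicate experiments (3 blocks x 6 reps)."""
    hits = 0
    n_sims = 60
    for _ in range(n_sims):
        rows = []
        block_eff = rng.normal(0, 10, 3)
        for g, mu in (("Tsu-1", 120.0), ("NIL", 60.0)):
            for b in range(3):
                for _r in range(6):
                    rows.append(
                        {"line": g, "block": b,
                         "value": mu + block_eff[b] + rng.normal(0, 25)}
                    )
        res = compare_to_recurrent(pd.DataFrame(rows), ["NIL"], "Tsu-1")
        t = res.table.set_index("genotype")
        diff = t.loc["NIL", "difference"]
        se = t.loc["NIL", "se"]
        if abs(diff - (-60.0)) <= 2 * se:
            hits += 1
    assert hits / n_sims >= 0.90
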