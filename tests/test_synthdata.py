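"""Synthetic-data generator: packaged defaults, determinism, and
ground-truth round trips through the pipeline."""

import numpy as np
import pandas as pd
import pytest

from nitroprof import (
    build_enrichment_table,
    correct_pixel_grid,
    correction_matrix,
    default_model,
    parse_formula,
    plant_differential_flow,
    simulate_peak_table,
    simulate_pixel_grid,
    simulate_timecourse,
    timecourse_auc,
)
from nitroprof.tables_io import UNLABELLED


def test_registry_dimensions(registry):
    assert len(registry) == 30
    assert registry["proteinogenic"].sum() == 20
    uridine = registry[registry["tracer"] == "uridine"].iloc[0]
    assert uridine["n_labelled"] == 2


def test_catalog_dimensions(catalog):
    assert len(catalog) >= 100
    ump = catalog[catalog["metabolite"] == "UMP"].iloc[0]
    assert ump["formula"] == "C9H13N2O9P"
    assert parse_formula(ump["formula"]).count("N") == 2
    reps = set(catalog.loc[catalog["representative"], "pathway"])
    assert reps == set(catalog["pathway"])
    # Figure-style representatives are present.
    rep_mets = set(catalog.loc[catalog["representative"], "metabolite"])
    assert {"UMP", "UDP", "UTP", "glutamate", "glutathione"} <= rep_mets


def test_every_catalog_formula_contains_nitrogen(catalog):
    assert all(parse_formula(f).count("N") >= 1 for f in catalog["formula"])


def test_cognate_transfer_in_every_condition():
    model = default_model()
    for row in model.registry.itertuples():
        for cond in model.conditions:
            frac, _ = model.transfers[(row.tracer, row.nutrient, cond)]
            assert frac > 0


def test_plant_differential_flow_validates_ids():
    model = default_model()
    plant_differential_flow(model, "leucine", "glutamate", 0.4, 0.1)
    assert model.transfers[("leucine", "glutamate", "A")] == (0.4, "single")
    with pytest.raises(ValueError):
        plant_differential_flow(model, "leucine", "unobtainium", 0.4, 0.1)
    with pytest.raises(ValueError):
        plant_differential_flow(model, "nope", "glutamate", 0.4, 0.1)
    with pytest.raises(ValueError):
        plant_differential_flow(model, "leucine", "glutamate", 1.4, 0.1)


def test_simulation_is_deterministic(tmp_path):
    a = simulate_peak_table(default_model(noise_cv=0.1, seed=11))
    b = simulate_peak_table(default_model(noise_cv=0.1, seed=11))
    pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
    a.to_csv(pa, index=False)
    b.to_csv(pb, index=False)
    assert pa.read_bytes() == pb.read_bytes()
    c = simulate_peak_table(default_model(noise_cv=0.1, seed=12))
    assert not a["intensity"].equals(c["intensity"])


def test_intact_channel_places_mass_at_m2():
    """15N2-uridine salvage into UMP appears at M+2, not M+1."""
    model = default_model(noise_cv=0.0, seed=0)
    plant_differential_flow(model, "uridine", "UMP", 0.3, 0.3, channel="intact")
    records = simulate_peak_table(model)
    table = build_enrichment_table(records, model.catalog, model.registry)
    row = table[(table["condition"] == "A") & (table["tracer"] == "uridine")
                & (table["metabolite"] == "UMP")]
    fe = row.set_index("k")["fe_mean"]
    assert fe[2] == pytest.approx(0.3, abs=1e-9)
    assert fe[1] == pytest.approx(0.0, abs=1e-9)


def test_single_channel_places_mass_at_m1():
    """Amide-nitrogen transfer from glutamine into UMP appears at M+1."""
    model = default_model(noise_cv=0.0, seed=0)
    plant_differential_flow(model, "glutamine-amide", "UMP", 0.2, 0.2,
                            channel="single")
    records = simulate_peak_table(model)
    table = build_enrichment_table(records, model.catalog, model.registry)
    row = table[(table["condition"] == "A")
                & (table["tracer"] == "glutamine-amide")
                & (table["metabolite"] == "UMP")]
    fe = row.set_index("k")["fe_mean"]
    assert fe[1] == pytest.approx(0.2, abs=1e-9)


def test_end_to_end_recovery_of_planted_fractions():
    """Pipeline estimates of planted transfer fractions are within 0.02 of
    truth at 5% noise with 3 replicates, across seeds."""
    errs = []
    for seed in range(5):
        model = default_model(cognate_fraction=0.5, noise_cv=0.05, seed=seed)
        plant_differential_flow(model, "leucine", "glutamate", 0.35, 0.15)
        records = simulate_peak_table(model, n_replicates=3)
        table = build_enrichment_table(records, model.catalog, model.registry)
        key = table.drop_duplicates(["condition", "tracer", "metabolite"]).set_index(
            ["condition", "tracer", "metabolite"])["total_labelling"]
        errs.append(abs(key[("A", "leucine", "glutamate")] - 0.35))
        errs.append(abs(key[("B", "leucine", "glutamate")] - 0.15))
        errs.append(abs(key[("A", "glutamine", "glutamine")] - 0.5))
    assert max(errs) < 0.02


def test_controls_never_trip_contamination_rule():
    """Correctly generated tracer-free controls stay far below the 3%
    contamination bound at 5% noise."""
    from nitroprof import sample_enrichment

    model = default_model(noise_cv=0.05, seed=21)
    records = simulate_peak_table(model, n_replicates=2)
    per_sample = sample_enrichment(records, model.catalog)
    ctrl = per_sample[per_sample["tracer"] == UNLABELLED]
    assert ctrl["total_labelling"].max() * 100 < 3.0


def test_pixel_grid_phantom_two_regions():
    left = np.zeros((8, 10), dtype=bool)
    left[:, :5] = True
    grid, truth = simulate_pixel_grid(
        "C9H13N2O9P", 10, 8, [(left, 0.05), (~left, 0.30)],
        noise_cv=0.05, seed=5)
    C = correction_matrix(parse_formula("C9H13N2O9P"))
    fe = correct_pixel_grid(grid, C)[..., 1]
    assert abs(fe[left].mean() - 0.05) < 0.01
    assert abs(fe[~left].mean() - 0.30) < 0.01


def test_pixel_grid_unlabelled_region_corrects_to_zero():
    mask = np.ones((4, 4), dtype=bool)
    grid, _ = simulate_pixel_grid("C9H13N2O9P", 4, 4, [(mask, 0.0)],
                                  noise_cv=0.0, seed=0)
    C = correction_matrix(parse_formula("C9H13N2O9P"))
    fe = correct_pixel_grid(grid, C)
    assert np.nanmax(fe[..., 1:]) < 0.005


def test_pixel_grid_rejects_bad_masks():
    full = np.ones((4, 4), dtype=bool)
    with pytest.raises(ValueError, match="overlap"):
        simulate_pixel_grid("NH3", 4, 4, [(full, 0.1), (full, 0.2)])
    empty = np.zeros((4, 4), dtype=bool)
    empty[0, 0] = True
    with pytest.raises(ValueError, match="cover"):
        simulate_pixel_grid("NH3", 4, 4, [(empty, 0.1)])


def test_timecourse_shapes():
    t = np.array([0.0, 2.0, 6.0, 18.0])
    fast = simulate_timecourse(t, 0.4, rate=100.0)
    assert np.allclose(fast[1:], 0.4, atol=1e-4)
    flat = simulate_timecourse(t, 0.0, rate=0.5)
    assert timecourse_auc(t, flat) == pytest.approx(0.0)
    with pytest.raises(ValueError):
        simulate_timecourse([0.0], 0.4, 0.5)
    with pytest.raises(ValueError):
        simulate_timecourse(t, 0.4, -1.0)


def test_timecourse_auc_contrast_detects_deprivation():
    """Replete vs deprived uridine time courses separate by AUC."""
    t = np.array([0.0, 3.0, 6.0, 12.0, 24.0])
    replete = simulate_timecourse(t, 0.5, 0.3, noise_cv=0.05, seed=1)
    deprived = simulate_timecourse(t, 0.1, 0.3, noise_cv=0.05, seed=2)
    assert timecourse_auc(t, replete) > 3 * timecourse_auc(t, deprived)
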