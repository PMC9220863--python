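"""Synthetic field generator: determinism, truth bookkeeping, containment,
and statistical equivalence to the null when no structure is requested."""

import numpy as np
import pandas as pd
import pytest

from neurofish import (
    GridGeometry,
    assign_spots,
    build_prints,
    generate_synthetic_fov,
    nn_compare,
    nn_distances,
    simulate_matched_null,
    skeletons_for,
)
from neurofish.synthetic import SyntheticTruth


def test_fixed_seed_is_bit_identical():
    a = generate_synthetic_fov(n_spots=150, truth=SyntheticTruth(seed=11))
    b = generate_synthetic_fov(n_spots=150, truth=SyntheticTruth(seed=11))
    pd.testing.assert_frame_equal(a.spots, b.spots)
    pd.testing.assert_frame_equal(a.synapses, b.synapses)
    for key in a.raw_masks:
        assert (a.raw_masks[key] == b.raw_masks[key]).all()
    c = generate_synthetic_fov(n_spots=150, truth=SyntheticTruth(seed=12))
    assert not (a.spots.x_nm.to_numpy() == c.spots.x_nm.to_numpy()).all()


@pytest.mark.parametrize("n_spots,pair_fraction", [(0, 0.0), (77, 0.0), (120, 0.5)])
def test_truth_rows_match_requested_spot_count(n_spots, pair_fraction):
    fov = generate_synthetic_fov(
        n_spots=n_spots,
        truth=SyntheticTruth(pair_fraction=pair_fraction, seed=2),
    )
    assert len(fov.spots) == n_spots
    assert len(fov.truth) == n_spots


def test_every_spot_inside_its_true_compartment_mask():
    fov = generate_synthetic_fov(
        n_spots=400,
        truth=SyntheticTruth(synapse_enrichment=2.0, pair_fraction=0.3, seed=4),
    )
    g = fov.geometry
    row, col = g.to_pixel(fov.spots.x_nm.to_numpy(), fov.spots.y_nm.to_numpy())
    for i, t in fov.truth.iterrows():
        if t.true_compartment == "dendrite":
            mask = fov.raw_masks[f"dendrite_{int(t.true_dendrite_id)}"]
        else:
            mask = fov.raw_masks[t.true_compartment]
        assert mask[row[i], col[i]]


def test_enrichment_places_spots_near_synapses():
    truth = SyntheticTruth(
        somatic_fraction=0.0, dendrite_decay_length_um=None, synapse_enrichment=3.0, seed=6
    )
    fov = generate_synthetic_fov(n_spots=300, n_synapses=20, truth=truth)
    assert fov.truth.synapse_associated.any()
    assoc = fov.truth[fov.truth.synapse_associated]
    sx = fov.synapses.x_nm.to_numpy()
    sy = fov.synapses.y_nm.to_numpy()
    for i in assoc.index:
        d = np.hypot(fov.spots.x_nm[i] - sx, fov.spots.y_nm[i] - sy).min()
        assert d <= 500.0 + 107.5 * np.sqrt(2)  # pixel-resolution placement


def test_pairs_sit_at_the_requested_distance():
    truth = SyntheticTruth(
        somatic_fraction=0.0, dendrite_decay_length_um=None,
        pair_fraction=1.0, pair_distance_nm=200.0, seed=9,
    )
    fov = generate_synthetic_fov(n_spots=100, n_synapses=0, truth=truth)
    paired = fov.truth[fov.truth.pair_id >= 0]
    assert len(paired) == 100  # every spot belongs to a pair
    for pid, grp in paired.groupby("pair_id"):
        assert len(grp) == 2
        i, j = grp.index
        d = np.hypot(
            fov.spots.x_nm[i] - fov.spots.x_nm[j], fov.spots.y_nm[i] - fov.spots.y_nm[j]
        )
        assert d == pytest.approx(200.0, abs=1e-6)


def test_structureless_spots_match_null_placement():
    """With no decay, enrichment or pairs the generated dendritic pattern
    is statistically indistinguishable from the random-placement null."""
    ok = 0
    for seed in range(10):
        truth = SyntheticTruth(
            somatic_fraction=0.0, dendrite_decay_length_um=None, seed=seed
        )
        fov = generate_synthetic_fov(n_spots=250, n_synapses=0, truth=truth)
        prints = build_prints(fov.raw_masks, closing_radius_px=1)
        sk = skeletons_for(prints, fov.geometry)
        a = assign_spots(fov.spots, prints, sk, fov.geometry)
        dend = a[a.compartment == "dendrite"]
        xy = fov.spots.set_index("spot_id").loc[dend.spot_id]
        null = simulate_matched_null(a, prints, fov.geometry, n_sims=25, seed=seed + 5000)
        ok += nn_compare(xy, null).ks_p > 0.05
    assert ok >= 9


def test_geometry_too_small_is_an_error():
    with pytest.raises(ValueError, match="too small"):
        generate_synthetic_fov(geometry=GridGeometry(64, 64), soma_radius_px=40.0)
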