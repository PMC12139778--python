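"""Spot detection, bead registration, colocalization, trace extraction."""
import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist
from scipy.special import ndtr

import simpull_stoich as ss
from simpull_stoich.detect import fit_affine
from simpull_stoich.simulate import apply_affine


def spots_frame(coords):
    coords = np.atleast_2d(coords)
    return pd.DataFrame({"spot_id": np.arange(len(coords)),
                         "row": coords[:, 0], "col": coords[:, 1]})


def brute_force_pairs(green, farred, coloc_distance=2.0):
    """All-pairs mutual-nearest-neighbor reference implementation."""
    if len(green) == 0 or len(farred) == 0:
        return set()
    d = cdist(green, farred)
    out = set()
    for gi in range(len(green)):
        fi = int(np.argmin(d[gi]))
        if int(np.argmin(d[:, fi])) == gi and d[gi, fi] <= coloc_distance:
            out.add((gi, fi))
    return out


class TestRegistration:
    def test_identical_bead_sets_give_identity(self):
        beads = np.array([[10.0, 10.0], [40.0, 12.0], [25.0, 44.0],
                          [60.0, 60.0]])
        reg = ss.estimate_registration(beads, beads)
        assert np.allclose(reg.matrix, [[1, 0, 0], [0, 1, 0]], atol=1e-9)
        assert reg.rms_residual < 1e-9
        assert not reg.warning

    def test_noiseless_translation_recovered_exactly(self):
        rng = np.random.default_rng(0)
        green = rng.uniform(10, 200, (12, 2))
        farred = green - np.array([3.2, -1.7])  # farred -> green is +(3.2,-1.7)
        reg = ss.estimate_registration(green, farred)
        assert np.abs(reg.apply(farred) - green).max() < 1e-6
        assert np.allclose(reg.matrix[:, 2], [3.2, -1.7], atol=1e-6)

    def test_two_beads_are_under_determined(self):
        with pytest.raises(ValueError):
            ss.estimate_registration(np.array([[5.0, 5.0], [20.0, 20.0]]),
                                     np.array([[5.0, 5.0], [20.0, 20.0]]))

    def test_collinear_beads_are_rejected(self):
        pts = np.array([[i, 2.0 * i] for i in range(3, 9)], dtype=float)
        with pytest.raises(ValueError, match="collinear"):
            fit_affine(pts, pts)

    def test_reported_rms_matches_recomputed_residual(self):
        rng = np.random.default_rng(1)
        grid = np.stack(np.meshgrid(np.arange(30, 200, 40),
                                    np.arange(30, 190, 40)), -1).reshape(-1, 2)
        farred = grid + rng.uniform(-8, 8, grid.shape)
        A = ss.make_affine(translation=(1.0, 2.0), rotation_deg=0.8)
        green = apply_affine(A, farred) + rng.normal(0, 0.1, farred.shape)
        reg = ss.estimate_registration(green, farred)
        resid = np.sqrt(np.mean(np.sum((reg.apply(farred) - green) ** 2,
                                       axis=1)))
        assert np.isclose(resid, reg.rms_residual, atol=1e-12)


class TestDetectSpots:
    def test_constant_image_has_no_spots(self):
        spots, status = ss.detect_spots(np.full((5, 64, 64), 100.0))
        assert len(spots) == 0 and status == "ok"

    def test_well_separated_spots_found_with_subpixel_accuracy(self):
        # 10 persistent bright spots: all found, centroids within 0.5 px
        acq = ss.AcquisitionParams(image_shape=(128, 128), n_frames=50)
        for seed in (40, 50, 60):
            truth = ss.simulate_complexes(ss.StoichModel(p_farred={0: 1.0}),
                                          10, (128, 128),
                                          min_separation=15.0, seed=seed)
            ss.simulate_traces(truth, acq, seed=seed + 1)
            truth.fluorophores["bleach_frame"] = 1e9  # static field
            sim = ss.render_movie(truth, acq, seed=seed + 1)
            spots, status = ss.detect_spots(sim.green)
            assert status == "ok"
            assert len(spots) == 10
            d = cdist(spots[["row", "col"]].to_numpy(), truth.positions)
            assert d.min(axis=1).max() < 0.5

    def test_field_over_density_cap_is_flagged_not_truncated(self):
        acq = ss.AcquisitionParams(image_shape=(128, 128), n_frames=50)
        truth = ss.simulate_complexes(ss.StoichModel(p_farred={0: 1.0}), 12,
                                      (128, 128), min_separation=12.0,
                                      seed=70)
        ss.simulate_traces(truth, acq, seed=71)
        truth.fluorophores["bleach_frame"] = 1e9
        sim = ss.render_movie(truth, acq, seed=71)
        spots, status = ss.detect_spots(sim.green, max_spots=5)
        assert status == "rejected"
        assert len(spots) == 12  # spots still returned


class TestColocalize:
    def test_coincident_spots_pair_at_distance_zero(self):
        pairs = ss.colocalize(spots_frame([[10.0, 10.0]]),
                              spots_frame([[10.0, 10.0]]))
        assert len(pairs) == 1 and pairs["distance"].iloc[0] == 0.0

    def test_pairing_respects_the_two_pixel_gate(self):
        inside = ss.colocalize(spots_frame([[10.0, 10.0]]),
                               spots_frame([[11.5, 10.0]]))
        assert len(inside) == 1 and np.isclose(inside["distance"][0], 1.5)
        outside = ss.colocalize(spots_frame([[10.0, 10.0]]),
                                spots_frame([[13.0, 10.0]]))
        assert len(outside) == 0

    def test_matches_brute_force_on_random_fields(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            ng, nf = rng.integers(0, 51, 2)
            g = rng.uniform(0, 60, (ng, 2))
            f = rng.uniform(0, 60, (nf, 2))
            got = ss.colocalize(spots_frame(g), spots_frame(f))
            got_set = set(zip(got["green_spot_id"], got["farred_spot_id"]))
            assert got_set == brute_force_pairs(g, f)

    def test_invariant_to_spot_order_and_channel_role(self):
        rng = np.random.default_rng(3)
        g = rng.uniform(0, 40, (25, 2))
        f = rng.uniform(0, 40, (30, 2))
        base = ss.colocalize(spots_frame(g), spots_frame(f))
        base_set = set(zip(base["green_spot_id"], base["farred_spot_id"]))

        perm = rng.permutation(len(g))
        gp = spots_frame(g[perm])
        gp["spot_id"] = perm  # same ids, shuffled rows
        shuffled = ss.colocalize(gp, spots_frame(f))
        assert set(zip(shuffled["green_spot_id"],
                       shuffled["farred_spot_id"])) == base_set

        swapped = ss.colocalize(spots_frame(f), spots_frame(g))
        assert {(b, a) for a, b in
                zip(swapped["green_spot_id"],
                    swapped["farred_spot_id"])} == base_set


class TestExtractTrace:
    def test_uniform_image_gives_zero_after_background_subtraction(self):
        movie = np.full((30, 40, 40), 7.5)
        trace = ss.extract_trace(movie, 20.0, 20.0)
        assert trace.ok
        assert np.allclose(trace.values, 0.0)

    def test_noiseless_fluorophore_matches_closed_form_psf_mass(self):
        acq = ss.AcquisitionParams(image_shape=(64, 64), n_frames=60,
                                   read_noise_sd=0.0, step_amplitude_sd=0.0,
                                   step_amplitude_mean=300.0, blink_rate=0.0,
                                   farred_halftime_frac=1.0)
        truth = ss.GroundTruthTable(positions=[[30.0, 30.0]],
                                    green_count=[0], farred_count=[1])
        sim = ss.render_movie(truth, acq, seed=20, shot_noise=False)
        trace = ss.extract_trace(sim.farred, 30.0, 30.0)
        bleach = truth.fluorophores["bleach_frame"].iloc[0]

        # closed-form expectation: 5x5 PSF mass minus 25x ring median
        r = np.arange(-4, 5)
        g1d = ndtr((r + 0.5) / acq.psf_sigma) - ndtr((r - 0.5) / acq.psf_sigma)
        patch = np.outer(g1d, g1d)
        ring = np.ones((9, 9), dtype=bool)
        ring[2:7, 2:7] = False
        expected = 300.0 * (patch[2:7, 2:7].sum()
                            - 25.0 * np.median(patch[ring]))
        alive = np.arange(acq.n_frames) < np.floor(bleach)
        assert np.allclose(trace.values[alive], expected, rtol=1e-6)
        after = ~alive & (np.arange(acq.n_frames) > np.ceil(bleach))
        assert np.allclose(trace.values[after], 0.0, atol=1e-6)

    def test_border_spot_is_flagged(self):
        movie = np.zeros((10, 32, 32))
        trace = ss.extract_trace(movie, 1.0, 1.0)
        assert not trace.ok
        assert np.isnan(trace.values).all()


def test_round_trip_recovers_true_pairs_at_default_snr():
    """simulate -> render -> detect -> register -> colocalize recovers
    >= 95% of dual-labeled complexes with a false-pair rate <= 2%."""
    recovered = true_total = false = 0
    offset = ss.make_affine(translation=(1.5, -0.8), rotation_deg=0.3,
                            center=(64, 64))
    for seed in range(5):
        acq = ss.AcquisitionParams(image_shape=(128, 128))
        truth = ss.simulate_complexes(ss.StoichModel(), 40,
                                      image_shape=(128, 128),
                                      min_separation=6.0, seed=seed)
        sim = ss.render_movie(truth, acq, channel_offset=offset,
                              seed=seed + 1000)
        reg = ss.estimate_registration(sim.beads_green, sim.beads_farred)
        g_spots, _ = ss.detect_spots(sim.green)
        f_spots, _ = ss.detect_spots(sim.farred)
        pairs = ss.colocalize(g_spots, f_spots, reg)
        both = (truth.green_count >= 1) & (truth.farred_count >= 1)
        true_total += int(both.sum())
        g = g_spots.set_index("spot_id")
        for r in pairs.itertuples():
            gp = g.loc[r.green_spot_id]
            d = np.hypot(truth.positions[:, 0] - gp.row,
                         truth.positions[:, 1] - gp.col)
            if d.min() < 1.5 and both[int(d.argmin())]:
                recovered += 1
            else:
                false += 1
    assert recovered / true_total >= 0.95
    assert false / max(1, recovered + false) <= 0.02
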