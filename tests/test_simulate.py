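"""Simulator: determinism, bookkeeping, artifact plumbing, effect fidelity."""

import numpy as np
import pandas as pd
import pytest

from synaptoscreen import (
    ArtifactSpec,
    EffectMap,
    FieldSpec,
    PlateLayout,
    apply_artifacts,
    generate_field,
    generate_plate,
    plate_truth_table,
    wellwise_planted_density,
)

SMALL = dict(image_shape=(96, 96), n_slices=2, n_neuronal_nuclei=2,
             n_astrocyte_nuclei=2, n_on_puncta=10, n_off_puncta=3,
             n_neurite_segments=3)


class TestGenerateField:
    def test_empty_presynaptic_channel_when_nothing_planted(self):
        spec = FieldSpec(seed=0, n_on_puncta=0, n_off_puncta=0,
                         n_neuronal_nuclei=0, n_astrocyte_nuclei=0,
                         image_shape=(96, 96), n_slices=2)
        stack, truth = generate_field(spec)
        assert truth.puncta == []
        # background + noise only: nothing far above the background level
        ch = stack.channels["presynaptic"]
        assert abs(ch.mean() - spec.background_level) < 5 * spec.noise_sd
        assert ch.max() < spec.background_level + 10 * np.sqrt(
            spec.background_level
        ) + 10 * spec.noise_sd

    def test_truth_bookkeeping_counts(self):
        spec = FieldSpec(seed=3, n_on_puncta=40, n_off_puncta=10, **{
            k: v for k, v in SMALL.items() if "puncta" not in k})
        _, truth = generate_field(spec)
        assert sum(p.on_neurite for p in truth.puncta) == 40
        assert sum(not p.on_neurite for p in truth.puncta) == 10

    def test_on_neurite_puncta_lie_on_true_mask(self):
        _, truth = generate_field(FieldSpec(seed=5, **SMALL))
        for p in truth.puncta:
            if p.on_neurite:
                assert truth.neurite_mask_true[int(p.y), int(p.x)]
        area = truth.neurite_mask_true.sum()
        assert truth.planted_density == pytest.approx(truth.n_on_neurite / area)

    def test_determinism_same_seed_bit_identical(self):
        spec = FieldSpec(seed=9, **SMALL)
        s1, t1 = generate_field(spec)
        s2, t2 = generate_field(spec)
        for c in s1.channels:
            np.testing.assert_array_equal(s1.channels[c], s2.channels[c])
        assert [(p.y, p.x, p.on_neurite) for p in t1.puncta] == [
            (p.y, p.x, p.on_neurite) for p in t2.puncta
        ]

    def test_render_false_same_truth(self):
        spec = FieldSpec(seed=9, **SMALL)
        _, t1 = generate_field(spec)
        none_stack, t2 = generate_field(spec, render=False)
        assert none_stack is None
        assert [(p.y, p.x) for p in t1.puncta] == [(p.y, p.x) for p in t2.puncta]
        np.testing.assert_array_equal(t1.neurite_mask_true, t2.neurite_mask_true)

    def test_too_small_image_fails_explicitly(self):
        spec = FieldSpec(seed=0, image_shape=(24, 24), n_slices=1,
                         n_neurite_segments=1, n_on_puncta=5000)
        with pytest.raises(ValueError, match="too small|candidate"):
            generate_field(spec)


class TestApplyArtifacts:
    def test_identity_under_zero_shift_unit_gain(self):
        stack, _ = generate_field(FieldSpec(seed=2, **SMALL))
        out = apply_artifacts(stack, ArtifactSpec())
        for c in stack.channels:
            np.testing.assert_allclose(out.channels[c], stack.channels[c])

    def test_shift_recovered_by_brute_force_cross_correlation(self):
        stack, _ = generate_field(FieldSpec(seed=2, **SMALL))
        out = apply_artifacts(stack, ArtifactSpec(channel_shift=(3, -2)))
        a = stack.channels["presynaptic"][0]
        b = out.channels["presynaptic"][0]
        best, best_v = None, -np.inf
        for dy in range(-5, 6):
            for dx in range(-5, 6):
                ys = slice(max(dy, 0), min(96 + dy, 96))
                xs = slice(max(dx, 0), min(96 + dx, 96))
                yo = slice(max(-dy, 0), min(96 - dy, 96))
                xo = slice(max(-dx, 0), min(96 - dx, 96))
                aa = a[yo, xo] - a.mean()
                bb = b[ys, xs] - b.mean()
                v = float((aa * bb).sum() / np.sqrt((aa**2).sum() * (bb**2).sum()))
                if v > best_v:
                    best, best_v = (dy, dx), v
        assert best == (3, -2)

    def test_gain_plane_makes_column_means_increase(self):
        stack, _ = generate_field(
            FieldSpec(seed=0, image_shape=(64, 64), n_slices=1, noise_sd=0.0,
                      background_level=100, n_on_puncta=0, n_off_puncta=0,
                      n_neurite_segments=0, n_neuronal_nuclei=0,
                      n_astrocyte_nuclei=0)
        )
        # replace with a noiseless constant stack to isolate the gain
        const = {c: np.full_like(v, 100.0) for c, v in stack.channels.items()}
        stack.channels = const
        out = apply_artifacts(stack, ArtifactSpec(illumination_gradient=(1.0, 0.0, 0.001)))
        cols = out.channels["dendrite"][0].mean(axis=0)
        assert np.all(np.diff(cols) > 0)

    def test_nonpositive_gain_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            ArtifactSpec(illumination_gradient=(1.0, 0.0, -0.2)).gain_plane((64, 64))

    def test_shift_beyond_max_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            ArtifactSpec(channel_shift=(20, 0))


class TestGeneratePlate:
    def test_field_count_is_wells_times_fields_per_well(self):
        layout = PlateLayout(plate_id="P1")
        spec = FieldSpec(seed=1, image_shape=(48, 48), n_slices=1,
                         n_on_puncta=2, n_off_puncta=0, n_neurite_segments=2,
                         n_neuronal_nuclei=0, n_astrocyte_nuclei=0)
        n = sum(1 for _ in generate_plate(layout, spec, fields_per_well=2, render=False))
        assert n == 60 * 2

    def test_effect_map_outside_layout_fails(self):
        layout = PlateLayout(plate_id="P1")
        eff = EffectMap(density_multipliers={"A01": 2.0})
        with pytest.raises(ValueError, match="outside the layout"):
            list(generate_plate(layout, FieldSpec(seed=0, **SMALL), eff, 1))

    def test_control_well_multiplier_must_be_one(self):
        layout = PlateLayout(plate_id="P1")
        ctrl = layout.control_wells()[0]
        eff = EffectMap(density_multipliers={ctrl: 2.0})
        with pytest.raises(ValueError, match="exactly 1"):
            list(generate_plate(layout, FieldSpec(seed=0, **SMALL), eff, 1))

    def test_planted_multiplier_recovered_from_truth_table(self):
        layout = PlateLayout(plate_id="P1")
        treated = [w for w in layout.assay_wells() if int(w[1:]) == 5]
        eff = EffectMap(density_multipliers={w: 2.0 for w in treated})
        spec = FieldSpec(seed=21, image_shape=(96, 96), n_slices=1,
                         n_neurite_segments=3, n_on_puncta=30, n_off_puncta=5,
                         n_neuronal_nuclei=0, n_astrocyte_nuclei=0)
        tt = plate_truth_table(layout, spec, eff, fields_per_well=4)
        per_well = wellwise_planted_density(tt)
        treated_mean = per_well[per_well.well.isin(treated)].planted_density.mean()
        ctrl_mean = per_well[per_well.role == "control"].planted_density.mean()
        assert treated_mean / ctrl_mean == pytest.approx(2.0, rel=0.10)

    def test_null_plate_densities_vary_only_by_sampling(self):
        layout = PlateLayout(plate_id="P1")
        spec = FieldSpec(seed=8, image_shape=(96, 96), n_slices=1,
                         n_neurite_segments=3, n_on_puncta=30, n_off_puncta=5,
                         n_neuronal_nuclei=0, n_astrocyte_nuclei=0)
        per_well = wellwise_planted_density(
            plate_truth_table(layout, spec, fields_per_well=3)
        )
        cv = per_well.planted_density.std() / per_well.planted_density.mean()
        assert cv < 0.15
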