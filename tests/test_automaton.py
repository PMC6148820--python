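import numpy as np
import pytest

from rvseg.automaton import (
    BACKGROUND,
    FOREGROUND,
    UNLABELED,
    AutomatonConfig,
    LabelField,
    evolve,
    extract_contour,
    init_labels,
    normalize_slice,
    optimize_seed,
)
from rvseg.contour_metrics import contour_dice, rasterize
from rvseg.io_formats import CineStack, Contour
from rvseg.phantom import perturb_seed

OFFSETS = ((-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1))


def evolve_oracle(labels, theta, feature, lam=1.0, offsets=OFFSETS, max_iters=10_000):
    """Straightforward per-pixel re-implementation of the synchronous rule."""
    labels = labels.copy()
    theta = theta.copy()
    rows, cols = labels.shape
    for it in range(1, max_iters + 1):
        new_labels = labels.copy()
        new_theta = theta.copy()
        changed = False
        for r in range(rows):
            for c in range(cols):
                best_attack, best_label = 0.0, UNLABELED
                for dr, dc in offsets:
                    qr, qc = r + dr, c + dc
                    if not (0 <= qr < rows and 0 <= qc < cols):
                        continue
                    if labels[qr, qc] == UNLABELED:
                        continue
                    g = lam * (1.0 - abs(feature[r, c] - feature[qr, qc]))
                    attack = max(g, 0.0) * theta[qr, qc]
                    if attack > best_attack:
                        best_attack, best_label = attack, labels[qr, qc]
                if best_label != UNLABELED and best_attack > theta[r, c]:
                    new_labels[r, c] = best_label
                    new_theta[r, c] = best_attack
                    changed = True
        labels, theta = new_labels, new_theta
        if not changed:
            return labels, theta, it
    return labels, theta, max_iters


def make_field(image, fg_seeds, bg_seeds):
    feature = normalize_slice(image)
    labels = np.full(image.shape, UNLABELED, dtype=np.int8)
    for r, c in fg_seeds:
        labels[r, c] = FOREGROUND
    for r, c in bg_seeds:
        labels[r, c] = BACKGROUND
    theta = np.where(labels != UNLABELED, 1.0, 0.0)
    return LabelField(labels=labels, strength=theta, feature=feature)


def square_contour(x0, y0, side, phase=0, sl=0):
    return Contour(phase, sl, "rv_endo",
                   np.array([[x0, y0], [x0 + side, y0], [x0 + side, y0 + side], [x0, y0 + side]]))


class TestEvolve:
    def test_two_region_image_splits_exactly_at_zero_attenuation(self):
        img = np.zeros((10, 10))
        img[:, 5:] = 1.0  # after normalization g across the boundary is 0
        field = make_field(img, fg_seeds=[(5, 1)], bg_seeds=[(5, 8)])
        out = evolve(field)
        assert out.converged
        assert (out.labels[:, :5] == FOREGROUND).all()
        assert (out.labels[:, 5:] == BACKGROUND).all()

    def test_uniform_image_matches_oracle_wavefront(self):
        img = np.full((11, 11), 0.5)
        field = make_field(img, fg_seeds=[(5, 5)],
                          bg_seeds=[(0, c) for c in range(11)])
        out = evolve(field)
        ol, ot, _ = evolve_oracle(field.labels, field.strength, field.feature)
        assert np.array_equal(out.labels, ol)
        np.testing.assert_allclose(out.strength, ot)

    @pytest.mark.parametrize("trial", range(12))
    def test_fixpoint_matches_oracle_on_random_small_images(self, trial):
        rng = np.random.default_rng(trial)
        rows, cols = rng.integers(4, 13, size=2)
        img = rng.random((rows, cols))
        n_fg = rng.integers(1, 3)
        n_bg = rng.integers(1, 3)
        cells = [(r, c) for r in range(rows) for c in range(cols)]
        picks = rng.choice(len(cells), size=n_fg + n_bg, replace=False)
        fg = [cells[i] for i in picks[:n_fg]]
        bg = [cells[i] for i in picks[n_fg:]]
        field = make_field(img, fg, bg)
        out = evolve(field)
        ol, ot, oiters = evolve_oracle(field.labels, field.strength, field.feature)
        assert out.converged and out.n_iterations <= rows * cols
        assert np.array_equal(out.labels, ol)
        np.testing.assert_allclose(out.strength, ot, atol=1e-12)

    def test_strengths_nondecreasing_every_iteration(self):
        rng = np.random.default_rng(5)
        img = rng.random((9, 9))
        field = make_field(img, [(4, 4)], [(0, 0), (8, 8)])
        cfg = AutomatonConfig()
        prev = field
        for _ in range(30):
            nxt = evolve(prev, AutomatonConfig(max_iterations=1))
            assert (nxt.strength >= prev.strength - 1e-15).all()
            if nxt.converged:
                break
            prev = nxt

    def test_idempotent_at_fixpoint(self):
        rng = np.random.default_rng(6)
        img = rng.random((10, 10))
        field = make_field(img, [(5, 5)], [(0, 0)])
        out = evolve(field)
        again = evolve(out)
        assert np.array_equal(out.labels, again.labels)
        np.testing.assert_allclose(out.strength, again.strength)
        assert (out.strength >= 0).all() and (out.strength <= 1).all()

    def test_requires_both_seed_classes(self):
        img = np.zeros((5, 5))
        field = make_field(img, [(2, 2)], [])
        with pytest.raises(ValueError, match="seed"):
            evolve(field)


class TestInitLabels:
    @staticmethod
    def static_stack(image, n_phases=4):
        arr = np.repeat(image[None, None], n_phases, axis=0)
        return CineStack(arr, (1.0, 1.0), 8.0, 2.0)

    def test_foreground_equals_eroded_polygon_rasterization(self):
        from scipy import ndimage
        from skimage.morphology import disk

        img = np.full((40, 40), 0.5)
        seed = square_contour(9.5, 9.5, 20)
        stack = self.static_stack(img)
        field = init_labels(img, seed, stack, 0)
        expected = ndimage.binary_erosion(rasterize(seed, (40, 40)).mask, structure=disk(2))
        assert np.array_equal(field.labels == FOREGROUND, expected)
        assert (field.strength[field.labels != UNLABELED] == 1.0).all()
        assert (field.strength[field.labels == UNLABELED] == 0.0).all()

    def test_border_pixels_background_seeded(self):
        img = np.full((30, 30), 0.5)
        seed = square_contour(9.5, 9.5, 10)
        field = init_labels(img, seed, self.static_stack(img), 0)
        border = np.zeros((30, 30), bool)
        border[0] = border[-1] = True
        border[:, 0] = border[:, -1] = True
        assert (field.labels[border] == BACKGROUND).all()

    def test_static_stack_seeds_everything_outside_dilated_polygon(self):
        from scipy import ndimage
        from skimage.morphology import disk

        img = np.full((40, 40), 0.5)
        seed = square_contour(14.5, 14.5, 10)
        field = init_labels(img, seed, self.static_stack(img), 0)
        dilated = ndimage.binary_dilation(rasterize(seed, (40, 40)).mask, structure=disk(10))
        assert np.array_equal(field.labels == BACKGROUND, ~dilated)

    def test_tiny_seed_rejected_with_guidance(self):
        img = np.full((30, 30), 0.5)
        tiny = Contour(0, 0, "rv_endo", np.array([[5.0, 5.0], [6.5, 5.0], [6.5, 6.5], [5.0, 6.5]]))
        with pytest.raises(ValueError, match="larger seed"):
            init_labels(img, tiny, self.static_stack(img), 0)


class TestExtractContour:
    def test_filled_square_area_recovered(self):
        labels = np.full((40, 40), BACKGROUND, dtype=np.int8)
        labels[10:30, 10:30] = FOREGROUND
        field = LabelField(labels, np.ones((40, 40)), np.zeros((40, 40)))
        c = extract_contour(field, 0, 0)
        assert c.area_px2() == pytest.approx(400, rel=0.05)
        assert c.is_simple()

    def test_keeps_largest_component_only(self):
        labels = np.full((40, 40), BACKGROUND, dtype=np.int8)
        labels[5:25, 5:25] = FOREGROUND  # 400 px
        labels[32:35, 32:35] = FOREGROUND  # 9 px
        field = LabelField(labels, np.ones((40, 40)), np.zeros((40, 40)))
        c = extract_contour(field, 0, 0)
        assert c.area_px2() == pytest.approx(400, rel=0.05)
        assert rasterize(c, (40, 40)).mask[33, 33] == False  # noqa: E712

    def test_interior_holes_filled(self):
        labels = np.full((40, 40), BACKGROUND, dtype=np.int8)
        labels[10:30, 10:30] = FOREGROUND
        labels[19:21, 19:21] = BACKGROUND  # 2x2 hole
        field = LabelField(labels, np.ones((40, 40)), np.zeros((40, 40)))
        c = extract_contour(field, 0, 0)
        assert c.area_px2() == pytest.approx(400, rel=0.05)

    def test_no_foreground_rejected(self):
        labels = np.full((10, 10), BACKGROUND, dtype=np.int8)
        field = LabelField(labels, np.ones((10, 10)), np.zeros((10, 10)))
        with pytest.raises(ValueError, match="foreground"):
            extract_contour(field, 0, 0)


class TestOptimizeSeed:
    def test_refinement_improves_rough_seed(self, clean_phantom):
        spec = clean_phantom.spec
        phase, s = 0, 4
        truth = clean_phantom.truth.get(phase, s, "rv_endo")
        rough = perturb_seed(truth, 3.0, 21, spec.pixel_spacing_mm)
        refined = optimize_seed(
            clean_phantom.stack.intensities[phase, s], rough, clean_phantom.stack, phase
        )
        d_rough = contour_dice(rough, truth, spec.image_shape, spec.pixel_spacing_mm)
        d_refined = contour_dice(refined, truth, spec.image_shape, spec.pixel_spacing_mm)
        assert d_refined > d_rough

    def test_truth_seed_recovers_truth_on_clean_slice(self, clean_phantom):
        spec = clean_phantom.spec
        phase, s = 0, 4
        truth = clean_phantom.truth.get(phase, s, "rv_endo")
        refined = optimize_seed(
            clean_phantom.stack.intensities[phase, s], truth, clean_phantom.stack, phase
        )
        assert contour_dice(refined, truth, spec.image_shape, spec.pixel_spacing_mm) >= 0.98

    def test_seed_in_homogeneous_background_flagged(self, clean_phantom):
        phase, s = 0, 4
        stray = square_contour(100.5, 100.5, 5, phase=phase, sl=s)
        _, info = optimize_seed(
            clean_phantom.stack.intensities[phase, s],
            stray,
            clean_phantom.stack,
            phase,
            return_info=True,
        )
        assert "area_change_gt_300_percent" in info["warnings"]
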