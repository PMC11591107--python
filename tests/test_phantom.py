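import numpy as np
import pytest
from matplotlib.path import Path as MplPath

from stemopt.phantom import (
    LabeledImage,
    PhantomError,
    PhantomParams,
    StemSpec,
    generate_femur_phantom,
    generate_stem_profile,
    read_labeled_image,
    resect_and_insert,
    write_labeled_image,
)
from tests.conftest import COARSE_PARAMS, COARSE_PX


def _stem_for(image, length):
    lm = image.landmarks
    return generate_stem_profile(length, axis_x=lm["shaft_axis_x"],
                                 top_y=lm["stem_top_y"])


def test_default_extent_rasterizes_to_expected_grid():
    img = generate_femur_phantom(PhantomParams(), 0.5)
    assert img.shape == (263, 201)  # ceil(131.2 / 0.5) x ceil(100.4 / 0.5)


def test_phantom_is_reproducible_under_a_seed():
    p = PhantomParams(shell_head_mm=4.0, shell_shaft_mm=6.0,
                      noise_amplitude=0.05, seed=7)
    a = generate_femur_phantom(p, COARSE_PX)
    b = generate_femur_phantom(p, COARSE_PX)
    assert np.array_equal(a.labels, b.labels)
    assert np.array_equal(a.density, b.density)


def test_labels_and_densities_are_well_formed(coarse_image):
    assert set(np.unique(coarse_image.labels)) <= {0, 1, 2}
    bone = coarse_image.labels > 0
    assert (coarse_image.density[bone] > 0).all()
    # marrow canal is present as very-low-density cancellous bone
    marrow = (coarse_image.labels == 2) & (coarse_image.density == 0.01)
    assert marrow.sum() > 0


def test_cortical_shell_encloses_the_cancellous_interior(coarse_image):
    # every cancellous pixel on the image border of the bone (except the
    # base cut) would break the closed-shell property; check that boundary
    # bone pixels above the base are cortical
    labels = coarse_image.labels
    nr, nc = labels.shape
    interiorish = labels[:-1, :]  # exclude the base cut row
    pad = np.pad(labels > 0, 1)
    on_surface = (labels > 0) & ~(
        pad[2:, 1:-1] & pad[:-2, 1:-1] & pad[1:-1, 2:] & pad[1:-1, :-2])
    surface_above_base = on_surface.copy()
    surface_above_base[-6:, :] = False
    frac_cortical = (labels[surface_above_base] == 1).mean()
    assert frac_cortical > 0.99


def test_too_coarse_pixels_are_rejected():
    with pytest.raises(PhantomError, match="coarse"):
        generate_femur_phantom(PhantomParams(), 2.0)  # 1.6 mm shell < 2 px


def test_stem_tip_lands_on_the_named_levels(coarse_image):
    lm = coarse_image.landmarks
    short = _stem_for(coarse_image, 68.75)
    assert short.tip_y == pytest.approx(lm["lesser_troch_y"])
    longest = _stem_for(coarse_image, 117.25)
    assert longest.tip_y == pytest.approx(131.2)


def test_stem_length_only_stretches_the_distal_wedge(coarse_image):
    a = _stem_for(coarse_image, 80.0)
    b = _stem_for(coarse_image, 90.0)
    assert b.tip_y - a.tip_y == pytest.approx(10.0)
    # identical above the wedge start
    from shapely.geometry import box
    window = box(-50, -50, 200, a.wedge_start_y)
    diff = a.polygon.intersection(window).symmetric_difference(
        b.polygon.intersection(window))
    assert diff.area < 1e-3  # identical up to polygon-smoothing round-off


def test_stem_shorter_than_fixed_proximal_section_is_rejected():
    with pytest.raises(PhantomError):
        generate_stem_profile(20.0, StemSpec(shoulder_length=30.0))


def test_insertion_never_touches_retained_cortical_bone(coarse_image):
    """Cortical pixels vanish only with the resected head; none become stem."""
    post = resect_and_insert(coarse_image, _stem_for(coarse_image, 100.0))
    pre_cortical = coarse_image.labels == 1
    post_cortical = post.labels == 1
    X, Y = coarse_image.pixel_centers()
    cx, cy = coarse_image.landmarks["resection_point"]
    dx, dy = coarse_image.landmarks["neck_direction"]
    above = (X - cx) * dx + (Y - cy) * dy > 0
    # no new cortical pixels appear
    assert not (post_cortical & ~pre_cortical).any()
    # retained (below-plane) cortical pixels are untouched by the stem
    retained = pre_cortical & ~above
    assert np.array_equal(retained, post_cortical & ~above)
    assert not (retained & (post.labels == 3)).any()
    # removals happen only on the head side of the resection plane
    assert not ((pre_cortical & ~post_cortical) & ~above).any()


def test_pixel_bookkeeping_balances(coarse_image):
    """bone_pre = bone_post + stem-converted + resected pixels."""
    post = resect_and_insert(coarse_image, _stem_for(coarse_image, 100.0))
    bone_pre = (coarse_image.labels > 0).sum()
    bone_post = (post.labels == 1).sum() + (post.labels == 2).sum()
    stem_from_bone = ((post.labels == 3) & (coarse_image.labels > 0)).sum()
    resected = ((post.labels == 0) & (coarse_image.labels > 0)
                & ~(post.labels == 3)).sum()
    assert bone_pre == bone_post + stem_from_bone + resected


def test_inserted_pixels_match_point_in_polygon_oracle(coarse_image):
    stem = _stem_for(coarse_image, 95.0)
    post = resect_and_insert(coarse_image, stem)
    X, Y = coarse_image.pixel_centers()
    path = MplPath(np.asarray(stem.polygon.exterior.coords))
    inside = path.contains_points(
        np.column_stack([X.ravel(), Y.ravel()])).reshape(coarse_image.shape)
    assert np.array_equal(post.labels == 3, inside)


def test_insertion_is_idempotent(coarse_image):
    stem = _stem_for(coarse_image, 100.0)
    once = resect_and_insert(coarse_image, stem)
    twice = resect_and_insert(once, stem)
    assert np.array_equal(once.labels, twice.labels)
    assert np.array_equal(once.density, twice.density)


def test_resection_without_a_stem_only_removes_the_head(coarse_image):
    post = resect_and_insert(coarse_image, None)
    assert (post.labels == 3).sum() == 0
    assert (post.labels == 0).sum() > (coarse_image.labels == 0).sum()
    assert post.landmarks["resected"]


def test_raster_roundtrip_is_lossless(tmp_path, coarse_image):
    write_labeled_image(coarse_image, tmp_path / "phantom")
    back = read_labeled_image(tmp_path / "phantom")
    assert np.array_equal(back.labels, coarse_image.labels)
    assert np.array_equal(back.density, coarse_image.density)
    assert back.pixel_size == coarse_image.pixel_size


def test_bad_labels_in_file_are_rejected(tmp_path, coarse_image):
    import imageio.v3 as iio
    write_labeled_image(coarse_image, tmp_path / "phantom")
    bad = coarse_image.labels.copy()
    bad[0, 0] = 7
    iio.imwrite(tmp_path / "phantom" / "labels.png", bad)
    with pytest.raises(PhantomError, match="7"):
        read_labeled_image(tmp_path / "phantom")


def test_missing_sidecar_names_required_keys(tmp_path, coarse_image):
    write_labeled_image(coarse_image, tmp_path / "phantom")
    (tmp_path / "phantom" / "meta.json").unlink()
    with pytest.raises(PhantomError, match="pixel_size_mm"):
        read_labeled_image(tmp_path / "phantom")


def test_labeled_image_validates_its_invariants():
    with pytest.raises(PhantomError):
        LabeledImage(np.array([[5]]), np.array([[0.5]]), 1.0)
    with pytest.raises(PhantomError):
        LabeledImage(np.array([[2]]), np.array([[0.0]]), 1.0)
    with pytest.raises(PhantomError):
        LabeledImage(np.array([[2]]), np.array([[0.5]]), -1.0)
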