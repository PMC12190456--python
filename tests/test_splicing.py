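"""Splicing transform: median sizing, flatten/concat/reshape, exact inverse."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from complexion.roi import ROI_ORDER, ROIBox, ROICrop, ROIName
from complexion.splicing import (
    SizeManifest,
    SpliceRecord,
    _median_half_up,
    build_spliced_dataset,
    median_roi_sizes,
    splice_sample,
    train_on_spliced,
    unsplice,
)


def _crop(roi, arr):
    arr = np.asarray(arr, dtype=np.uint8)
    h, w = arr.shape[:2]
    return ROICrop(roi, ROIBox(0, 0, w, h), arr)


def _own_sizes(crops):
    return SizeManifest(tuple(c.roi for c in crops),
                        {c.roi: (c.image.shape[0], c.image.shape[1]) for c in crops})


@pytest.mark.parametrize("values,expected", [((10, 12, 14), 12), ((10, 12), 11), ((7,), 7)])
def test_median_half_up(values, expected):
    assert _median_half_up(np.array(values)) == expected


def test_median_sizes_single_sample_equals_own(small_samples):
    sizes = median_roi_sizes(small_samples[:1], ROI_ORDER)
    from complexion.roi import segment_rois

    for crop in segment_rois(small_samples[0], ROI_ORDER):
        assert sizes.sizes[crop.roi] == (crop.box.height, crop.box.width)


def test_median_sizes_empty_manifest():
    with pytest.raises(ValueError, match="empty"):
        median_roi_sizes([], ROI_ORDER)


def test_splice_hand_traced_column_image():
    """1x2 crop (a0, a1) + 1x1 crop (b0) -> P=3, w=1, h=3, rows a0,a1,b0."""
    a = _crop(ROIName.NOSE, [[[1, 1, 1], [2, 2, 2]]])
    b = _crop(ROIName.FOREHEAD, [[[3, 3, 3]]])
    sizes = _own_sizes([a, b])
    spliced, record = splice_sample([a, b], sizes)
    assert spliced.shape == (3, 1, 3)
    np.testing.assert_array_equal(spliced[:, 0, 0], [1, 2, 3])
    assert record.pad_length == 0


def test_splice_pads_to_near_square():
    """P=5 -> w_out=floor(sqrt 5)=2, h_out=ceil(5/2)=3, one zero pad cell."""
    a = _crop(ROIName.NOSE, np.full((1, 2, 3), 9))
    b = _crop(ROIName.CHIN, np.full((1, 3, 3), 7))
    sizes = _own_sizes([a, b])
    spliced, record = splice_sample([a, b], sizes)
    assert spliced.shape == (3, 2, 3)
    assert record.pad_length == 1
    np.testing.assert_array_equal(spliced[2, 1], [0, 0, 0])


def test_splice_preserves_constant_value():
    crops = [_crop(r, np.full((3, 4, 3), 42)) for r in ROI_ORDER]
    sizes = _own_sizes(crops)
    spliced, record = splice_sample(crops, sizes)
    flat = spliced.reshape(-1, 3)
    non_pad = flat[: sizes.total_pixels]
    assert (non_pad == 42).all()


def test_splice_rejects_wrong_order():
    a = _crop(ROIName.NOSE, np.zeros((2, 2, 3)))
    b = _crop(ROIName.CHIN, np.zeros((2, 2, 3)))
    sizes = _own_sizes([a, b])
    with pytest.raises(ValueError, match="order"):
        splice_sample([b, a], sizes)


@settings(deadline=None, derandomize=True, max_examples=25)
@given(st.lists(st.tuples(st.integers(1, 7), st.integers(1, 7)), min_size=1, max_size=6),
       st.integers(0, 2**31 - 1))
def test_splice_round_trip_is_exact(shapes, seed):
    rng = np.random.default_rng(seed)
    crops = [
        _crop(roi, rng.integers(0, 256, (h, w, 3), dtype=np.uint8))
        for roi, (h, w) in zip(ROI_ORDER, shapes)
    ]
    sizes = _own_sizes(crops)
    spliced, record = splice_sample(crops, sizes)
    recovered = unsplice(spliced, record)
    for orig, back in zip(crops, recovered):
        assert back.roi is orig.roi
        np.testing.assert_array_equal(back.image, orig.image)
    # pixel conservation: non-pad multiset equals the crop multiset
    non_pad = spliced.reshape(-1, 3)[: sizes.total_pixels]
    all_pixels = np.concatenate([c.image.reshape(-1, 3) for c in crops])
    np.testing.assert_array_equal(
        np.sort(non_pad.view("u1,u1,u1").ravel()), np.sort(all_pixels.view("u1,u1,u1").ravel())
    )


def test_pad_cells_outside_crop_spans():
    a = _crop(ROIName.NOSE, np.full((1, 2, 3), 9))
    b = _crop(ROIName.CHIN, np.full((1, 3, 3), 7))
    spliced, record = splice_sample([a, b], _own_sizes([a, b]))
    tampered = spliced.copy()
    tampered[2, 1] = (255, 255, 255)
    for orig, back in zip([a, b], unsplice(tampered, record)):
        np.testing.assert_array_equal(back.image, orig.image)


def test_unsplice_rejects_mismatched_record():
    a = _crop(ROIName.NOSE, np.zeros((2, 2, 3)))
    spliced, record = splice_sample([a], _own_sizes([a]))
    bad = SpliceRecord(record.rois, {ROIName.NOSE: (5, 5)}, 0)
    with pytest.raises(ValueError, match="cells"):
        unsplice(spliced, bad)


def test_order_permutation_permutes_spans():
    rng = np.random.default_rng(3)
    imgs = {r: rng.integers(0, 256, (2, 3, 3), dtype=np.uint8) for r in ROI_ORDER[:3]}
    fwd = [_crop(r, imgs[r]) for r in ROI_ORDER[:3]]
    rev = [_crop(r, imgs[r]) for r in reversed(ROI_ORDER[:3])]
    sp_f, rec_f = splice_sample(fwd, _own_sizes(fwd))
    sp_r, rec_r = splice_sample(rev, _own_sizes(rev))
    assert not np.array_equal(sp_f, sp_r)
    by_roi_f = {c.roi: c.image for c in unsplice(sp_f, rec_f)}
    by_roi_r = {c.roi: c.image for c in unsplice(sp_r, rec_r)}
    for r in ROI_ORDER[:3]:
        np.testing.assert_array_equal(by_roi_f[r], by_roi_r[r])


def test_splice_record_json_roundtrip():
    record = SpliceRecord((ROIName.NOSE, ROIName.CHIN), {ROIName.NOSE: (2, 3), ROIName.CHIN: (1, 4)}, 2)
    back = SpliceRecord.from_json(record.to_json())
    assert back == record


def test_build_spliced_dataset_writes_per_sample(tmp_path, small_samples):
    from complexion.data_model import DatasetManifest, load_manifest

    manifest = DatasetManifest(small_samples[:10])
    sizes = median_roi_sizes(manifest, ROI_ORDER)
    spliced = build_spliced_dataset(manifest, ROI_ORDER, sizes, tmp_path)
    assert len(spliced) == 10
    reloaded = load_manifest(tmp_path / "spliced.csv")
    assert len(reloaded) == 10
    assert reloaded.class_counts == manifest.class_counts
    with pytest.raises(ValueError, match="empty"):
        build_spliced_dataset(manifest, (), sizes, tmp_path)


def test_train_on_spliced_contracts(small_samples):
    from complexion.backbone import TrainConfig
    from complexion.data_model import DatasetManifest
    from complexion.splicing import WholeImageConfig

    manifest = DatasetManifest(small_samples)
    sizes = median_roi_sizes(manifest, ROI_ORDER)
    composites = []
    from complexion.data_model import FaceSample
    from complexion.roi import segment_rois

    for s in manifest:
        img, _ = splice_sample(segment_rois(s, ROI_ORDER), sizes)
        composites.append(FaceSample(s.sample_id, s.label, _image=img))
    cfg = WholeImageConfig(train=TrainConfig(epochs=0, input_side=32, seed=0))
    clf, history = train_on_spliced(composites, cfg)
    assert history == []
    cfg2 = WholeImageConfig(train=TrainConfig(epochs=2, input_side=32, seed=1))
    _, h1 = train_on_spliced(composites, cfg2)
    _, h2 = train_on_spliced(composites, cfg2)
    assert h1 == h2 and len(h1) == 2
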