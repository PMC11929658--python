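"""Synthetic phantom generator: determinism, splits, contrast, I/O."""

import numpy as np
import pytest

from brainnext.errors import ConfigurationError
from brainnext.phantoms import (PhantomConfig, generate_phantoms,
                                histogram_centroid_accuracy, read_image_set,
                                write_image_set)


def test_fixed_seed_determinism():
    cfg = PhantomConfig(n_per_class=10, seed=7)
    a = generate_phantoms(cfg)
    b = generate_phantoms(PhantomConfig(n_per_class=10, seed=7))
    assert all(np.array_equal(x.image, y.image)
               for x, y in zip(a.items, b.items))
    assert [x.split for x in a.items] == [y.split for y in b.items]


def test_different_seed_differs():
    a = generate_phantoms(PhantomConfig(n_per_class=2, seed=1))
    b = generate_phantoms(PhantomConfig(n_per_class=2, seed=2))
    assert not all(np.array_equal(x.image, y.image)
                   for x, y in zip(a.items, b.items))


def test_growing_n_keeps_existing_images():
    """Image i of class c is a fixed function of (seed, c, i)."""
    small = generate_phantoms(PhantomConfig(n_per_class=3, seed=5))
    big = generate_phantoms(PhantomConfig(n_per_class=6, seed=5))
    for c in range(4):
        s = [it.image for it in small.items if it.label == c]
        b = [it.image for it in big.items if it.label == c]
        for x, y in zip(s, b):
            assert np.array_equal(x, y)


def test_stratified_split_counts():
    iset = generate_phantoms(PhantomConfig(n_per_class=5, split_fraction=0.2))
    for c in range(4):
        tr = sum(1 for it in iset.items
                 if it.label == c and it.split == "train")
        te = sum(1 for it in iset.items
                 if it.label == c and it.split == "test")
        assert (tr, te) == (4, 1)


@pytest.mark.parametrize("field,value", [
    ("n_per_class", 0), ("image_size", 32), ("split_fraction", 1.0),
    ("noise_sd", -0.1)])
def test_invalid_config_names_field(field, value):
    cfg = PhantomConfig(**{field: value})
    with pytest.raises(ConfigurationError, match=field):
        generate_phantoms(cfg)


def test_ms_lesion_contrast_positive():
    """Mean intensity inside the generator's own MS lesion masks strictly
    exceeds the matched lesion-free interior mean."""
    iset, masks = generate_phantoms(PhantomConfig(n_per_class=40, seed=1),
                                    return_masks=True)
    ms = [i for i, it in enumerate(iset.items)
          if iset.class_names[it.label] == "MS"]
    assert ms
    for i in ms:
        img = iset.items[i].image[:, :, 0]
        lesion, clean = masks[i]["lesion"], masks[i]["interior"]
        assert lesion.any()
        assert img[lesion].mean() > img[clean].mean()


def test_intensities_in_unit_interval():
    iset = generate_phantoms(PhantomConfig(n_per_class=2, seed=3))
    for it in iset.items:
        assert it.image.min() >= 0.0 and it.image.max() <= 1.0
        assert it.image.shape == (224, 224, 3)


def test_histogram_separability(phantom_set):
    """Classes are constructed to be separable: a histogram nearest-centroid
    probe clears 70% on default phantoms."""
    assert histogram_centroid_accuracy(phantom_set) > 0.70


def test_imbalanced_counts_follow_ratios():
    iset = generate_phantoms(PhantomConfig(n_per_class=20, imbalanced=True))
    counts = [sum(1 for it in iset.items if it.label == c) for c in range(4)]
    # AD:CI:MS:Control ratios 900:302:897:1027 scaled to max 20
    assert counts == [round(20 * 900 / 1027), round(20 * 302 / 1027),
                      round(20 * 897 / 1027), 20]


class TestImageSetIO:
    def test_write_layout_and_manifest(self, tmp_path):
        iset = generate_phantoms(PhantomConfig(n_per_class=2, seed=1,
                                               image_size=64))
        manifest = write_image_set(iset, tmp_path / "data")
        assert manifest.name == "manifest.csv"
        subdirs = sorted(p.name for p in (tmp_path / "data").iterdir()
                         if p.is_dir())
        assert subdirs == sorted(iset.class_names)
        assert len(manifest.read_text().strip().splitlines()) == 1 + 8

    def test_round_trip_pixels_and_labels(self, tmp_path):
        iset = generate_phantoms(PhantomConfig(n_per_class=2, seed=2,
                                               image_size=64))
        manifest = write_image_set(iset, tmp_path / "rt")
        back = read_image_set(manifest)
        assert back.class_names == iset.class_names
        for a, b in zip(iset.items, back.items):
            assert a.label == b.label and a.split == b.split
            assert np.allclose(a.image, b.image, atol=1e-6)

    def test_empty_set_manifest_only(self, tmp_path):
        from brainnext.phantoms import LabeledImageSet
        manifest = write_image_set(LabeledImageSet([], ("A", "B")),
                                   tmp_path / "empty")
        assert manifest.read_text().strip() == "path,label,split"
        assert not [p for p in manifest.parent.iterdir() if p.is_dir()]
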